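"""Cleavage-site enumeration and P1 residue frequency analysis.

Each quantified peptide is mapped back to its source protein.  An internal
fragment requires two proteolytic cleavages (one creating its N-terminus, one
its C-terminus); a fragment at the protein N- or C-terminus requires one; a
full-length protein none.  The P1 residue — the residue on the N-terminal side
of the cleaved bond — is tallied per fold-change category, because proteasome
β-subunits differ in which P1 residues they prefer (the chymotrypsin-like β5
site cleaves after hydrophobic residues, the trypsin-like β2 after basic
ones, the caspase-like β1 after acidic ones).

Two counting conventions about protein N-termini:

* a peptide starting at residue 1 **or 2** is treated as a protein-N-terminal
  fragment, because initiator-Met removal is ubiquitous co-translational
  processing, not a proteasome cleavage;
* an N-terminally acetylated peptide never contributes an N-side cleavage
  site, since acetylation marks the (processed) protein N-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import Peptide

__all__ = [
    "HYDROPHOBIC",
    "BASIC",
    "ACIDIC",
    "RESIDUES",
    "ProteinSpan",
    "CleavageSite",
    "FreqTable",
    "PeptideLocationError",
    "locate_peptide",
    "cleavage_sites",
    "p1_residue",
    "p1_frequency_table",
]

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC = frozenset("LIMVFYW")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")


class PeptideLocationError(KeyError):
    """Peptide sequence not found in its named protein."""


@dataclass(frozen=True)
class ProteinSpan:
    """1-based inclusive location of a peptide within its source protein."""

    protein_id: str
    start: int
    end: int
    terminal_status: str  # n_terminal | c_terminal | internal | full_length
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end}]")


@dataclass(frozen=True)
class CleavageSite:
    """A cleaved bond between protein residues ``position`` and ``position+1``."""

    protein_id: str
    position: int  # 1-based index of the P1 residue
    p1: str
    p1_prime: str
    side: str  # generates_peptide_nterm | generates_peptide_cterm


def _terminal_status(start: int, end: int, protein_len: int, acetylated: bool) -> str:
    # an acetylated peptide is anchored at the protein N-terminus regardless of
    # start position; its N-side is never a proteasome cleavage
    n_side_free = start <= 2 or acetylated
    c_side_free = end == protein_len
    if n_side_free and c_side_free:
        return "full_length"
    if n_side_free:
        return "n_terminal"
    if c_side_free:
        return "c_terminal"
    return "internal"


def locate_peptide(p: Peptide, proteome: Mapping[str, str]) -> ProteinSpan:
    """Exact substring search of a peptide within its named protein.

    Multiple matches use the first occurrence and set ``ambiguous`` (such
    spans are excluded from frequency tables by default).
    """
    if p.protein_id is None or p.protein_id not in proteome:
        raise PeptideLocationError(f"protein {p.protein_id!r} not in proteome")
    seq = proteome[p.protein_id]
    pos = seq.find(p.sequence)
    if pos < 0:
        raise PeptideLocationError(
            f"peptide {p.sequence!r} not found in protein {p.protein_id!r}"
        )
    ambiguous = seq.find(p.sequence, pos + 1) >= 0
    start, end = pos + 1, pos + len(p.sequence)
    return ProteinSpan(
        protein_id=p.protein_id,
        start=start,
        end=end,
        terminal_status=_terminal_status(start, end, len(seq), p.n_term_acetylated),
        ambiguous=ambiguous,
    )


def cleavage_sites(span: ProteinSpan, peptide: Peptide, protein: str) -> List[CleavageSite]:
    """The 0–2 cleavage events required to excise ``peptide`` from ``protein``.

    Internal fragments contribute the bond before their first residue and the
    bond after their last; terminal fragments only the non-terminal bond;
    full-length (or N-terminally processed/acetylated peptides reaching the
    protein C-terminus) none.
    """
    sites: List[CleavageSite] = []
    n_side_needed = span.terminal_status in ("internal", "c_terminal")
    c_side_needed = span.terminal_status in ("internal", "n_terminal")
    if n_side_needed:
        i = span.start - 1
        sites.append(
            CleavageSite(
                protein_id=span.protein_id,
                position=i,
                p1=protein[i - 1],
                p1_prime=protein[i],
                side="generates_peptide_nterm",
            )
        )
    if c_side_needed:
        i = span.end
        sites.append(
            CleavageSite(
                protein_id=span.protein_id,
                position=i,
                p1=protein[i - 1],
                p1_prime=protein[i],
                side="generates_peptide_cterm",
            )
        )
    return sites


def p1_residue(site: CleavageSite, protein: str) -> str:
    """Residue N-terminal to the cleaved bond (the protein N-terminus, index 0,
    is not a cleavage and has no P1)."""
    if site.position < 1:
        raise ValueError("protein N-terminus is not a cleavage site")
    return protein[site.position - 1]


class FreqTable:
    """Category × residue cleavage-site counts with derived proportions."""

    def __init__(self, counts: pd.DataFrame):
        self.counts = counts  # index: residues, columns: categories

    @classmethod
    def from_observations(
        cls, observations: Iterable[Tuple[str, Sequence[CleavageSite]]]
    ) -> "FreqTable":
        """Build from ``(category, sites)`` pairs, one pair per peptide
        observation (a peptide seen in several experiments/replicates appears
        once per observation, so counts reflect detection frequency)."""
        categories: List[str] = []
        counts: Dict[str, Dict[str, int]] = {}
        for category, sites in observations:
            if category not in counts:
                counts[category] = {r: 0 for r in RESIDUES}
                categories.append(category)
            for site in sites:
                counts[category][site.p1] += 1
        df = pd.DataFrame(
            {c: pd.Series(counts[c]) for c in categories},
            index=list(RESIDUES),
            dtype=int,
        ).fillna(0)
        return cls(df)

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts / totals.replace(0, np.nan)

    def class_fractions(self) -> pd.DataFrame:
        """Fraction of each category's sites with hydrophobic/basic/acidic P1."""
        prop = self.proportions
        rows = {
            "hydrophobic": prop.loc[list(HYDROPHOBIC & set(prop.index))].sum(),
            "basic": prop.loc[list(BASIC & set(prop.index))].sum(),
            "acidic": prop.loc[list(ACIDIC & set(prop.index))].sum(),
        }
        return pd.DataFrame(rows).T

    def total_sites(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "residue"
        out.to_csv(path, sep="\t")


def p1_frequency_table(
    observations: pd.DataFrame,
    proteome: Mapping[str, str],
    pool: Optional[Mapping[str, str]] = None,
    exclude_ambiguous: bool = True,
) -> Tuple[FreqTable, pd.DataFrame]:
    """Category-wise P1 residue counts from peptide observations.

    ``observations`` needs columns ``sequence``, ``protein_id``,
    ``n_term_acetylated``, ``category`` — one row per observation (the caller
    chooses whether an observation is a replicate or an experiment; counting
    each detection weights the table by peptide abundance/frequency).  ``pool``
    optionally maps category labels onto pooled labels (e.g. merging two
    mutant genotypes into one group).

    Returns the frequency table and a tidy per-site table.
    """
    obs_pairs: List[Tuple[str, Sequence[CleavageSite]]] = []
    site_rows: List[dict] = []
    for row in observations.itertuples(index=False):
        pep = Peptide(
            sequence=row.sequence,
            n_term_acetylated=bool(getattr(row, "n_term_acetylated", False)),
            protein_id=row.protein_id,
        )
        try:
            span = locate_peptide(pep, proteome)
        except PeptideLocationError:
            continue
        if exclude_ambiguous and span.ambiguous:
            continue
        category = row.category
        if pool is not None:
            category = pool.get(category, category)
        sites = cleavage_sites(span, pep, proteome[pep.protein_id])
        obs_pairs.append((category, sites))
        for site in sites:
            site_rows.append(
                {
                    "protein_id": site.protein_id,
                    "position": site.position,
                    "p1": site.p1,
                    "p1_prime": site.p1_prime,
                    "side": site.side,
                    "sequence": row.sequence,
                    "category": category,
                }
            )
    table = FreqTable.from_observations(obs_pairs)
    sites_df = pd.DataFrame(
        site_rows,
        columns=["protein_id", "position", "p1", "p1_prime", "side", "sequence", "category"],
    )
    return table, sites_df
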