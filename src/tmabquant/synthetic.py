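"""Synthetic degradome and multiplex MS1 spectrum generator.

Emulates a quantitative peptidomics study of proteasome products:

* a random proteome;
* a degradome drawn from it under a cleavage-preference model in which the P1
  residue of every proteolytic cut is sampled from configurable weights
  (proteasomes favour hydrophobic and, to a lesser extent, charged P1
  residues);
* per-replicate peptide abundances in which "treatment" conditions suppress
  proteasome-product peptides by a condition effect ratio, while a configurable
  fraction of peptides (those not requiring proteasome processing, like the
  thymosin β-family) are exempt;
* rendered centroid MS1 peak lists: one isotope cluster per (peptide, charge,
  tag channel) with per-channel intensities proportional to abundance, plus
  detection-limit censoring, m/z and retention-time jitter, random noise
  peaks, and injected co-eluting interferents.

Every stochastic step runs off a :class:`numpy.random.Generator` seeded by the
caller, and ground truth for every rendered signal is returned so downstream
stages can be tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import (
    C13_MINUS_C12,
    DEFAULT_CONSTANTS,
    MassConstants,
    Peptide,
    TAGS,
    count_tmab_labels,
    peptide_neutral_mass,
    theoretical_mz,
)
from .cleavage import HYDROPHOBIC, RESIDUES
from .detect import SpectrumRun
from .scheme import LabelingScheme, SchemeError

__all__ = [
    "DegradomeModel",
    "EffectDesign",
    "SpectrumParams",
    "simulate_proteome",
    "simulate_degradome",
    "simulate_abundances",
    "render_runs",
    "write_fasta",
    "read_fasta",
    "DEFAULT_P1_WEIGHTS",
]

# Roughly SwissProt-like background amino-acid frequencies.
DEFAULT_AA_FREQS: Dict[str, float] = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.040, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "Y": 0.029,
}

#: Default cleavage preference: 65% of the P1 mass on the hydrophobic set
#: {L,I,M,V,F,Y,W} (weighted toward Leu), the rest spread over the remaining
#: residues — mimicking the chymotrypsin-like bias of proteasome products.
DEFAULT_P1_WEIGHTS: Dict[str, float] = {}
_hydro_w = {"L": 0.30, "I": 0.08, "M": 0.06, "V": 0.09, "F": 0.06, "Y": 0.04, "W": 0.02}
_rest = [r for r in RESIDUES if r not in _hydro_w]
DEFAULT_P1_WEIGHTS.update(_hydro_w)
DEFAULT_P1_WEIGHTS.update({r: 0.35 / len(_rest) for r in _rest})


def _normalize(weights: Mapping[str, float]) -> Dict[str, float]:
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have positive mass")
    return {k: v / total for k, v in weights.items()}


@dataclass
class DegradomeModel:
    """Cleavage-preference model generating peptides from a proteome."""

    p1_weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P1_WEIGHTS))
    length_range: Tuple[int, int] = (6, 30)
    n_peptides_per_protein: int = 5
    acetylated_nterm_prob: float = 0.5
    terminal_fraction: float = 0.15  # fraction of peptides that are protein-terminal

    def __post_init__(self) -> None:
        self.p1_weights = _normalize(self.p1_weights)
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 2 <= min <= max")


@dataclass
class EffectDesign:
    """Condition structure of the experiment.

    ``effects`` maps each condition to the ratio applied to proteasome-product
    peptides (reference must be 1.0); exempt peptides keep effect 1.0
    everywhere.  Replicate noise is lognormal with sigma ``cv``.
    """

    conditions: Dict[str, int]  # condition -> replicate count
    reference: str
    effects: Dict[str, float]
    non_product_fraction: float = 0.1
    cv: float = 0.15

    def __post_init__(self) -> None:
        if self.reference not in self.conditions:
            raise ValueError("reference must be one of the conditions")
        if not math.isclose(self.effects.get(self.reference, 1.0), 1.0):
            raise ValueError("reference condition effect ratio must be 1.0")
        self.effects.setdefault(self.reference, 1.0)
        missing = set(self.conditions) - set(self.effects)
        if missing:
            raise ValueError(f"no effect ratio for conditions {sorted(missing)}")
        if self.cv < 0 or not 0 <= self.non_product_fraction <= 1:
            raise ValueError("cv must be >= 0 and non_product_fraction in [0, 1]")


@dataclass
class SpectrumParams:
    """Rendering parameters for the centroid peak lists."""

    mz_jitter_ppm: float = 0.0
    rt_jitter: float = 0.0  # SD of per-channel RT jitter, minutes
    iso_per_kda: float = 0.55  # Poisson rate of heavy-isotope count per 1000 Da
    # three isotopomers keep a channel's envelope clear of the next channel's
    # monoisotopic peak (3 x 13C spacing ~ the 3-Da tag step); the k=3 peak is
    # negligible for peptides in this mass range anyway
    n_isotopomers: int = 3
    lod: float = 0.0  # intensity detection limit; channels below are censored
    n_noise_peaks: int = 0
    noise_intensity: float = 200.0  # mean of exponential noise amplitude
    overlap_injection_rate: float = 0.0
    extra_charge_prob: float = 0.0  # chance of rendering a second charge state
    deuterium_rt_shift: float = 0.0  # optional per-deuterium RT offset, minutes
    mz_range: Tuple[float, float] = (300.0, 1600.0)
    rt_range: Tuple[float, float] = (10.0, 50.0)
    base_intensity: float = 1.0e4  # median base abundance scale

    def __post_init__(self) -> None:
        for name in (
            "mz_jitter_ppm", "rt_jitter", "iso_per_kda", "lod",
            "n_noise_peaks", "noise_intensity", "overlap_injection_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def simulate_proteome(
    n_proteins: int,
    length_range: Tuple[int, int] = (250, 500),
    aa_freqs: Optional[Mapping[str, float]] = None,
    seed: int | np.random.Generator = 0,
) -> Dict[str, str]:
    """Random protein sequences drawn i.i.d. from ``aa_freqs``.

    Deterministic for a fixed seed.  Every protein starts with Met, mirroring
    translation initiation (the remaining residues are i.i.d.).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = _normalize(aa_freqs or DEFAULT_AA_FREQS)
    letters = np.array(sorted(freqs))
    probs = np.array([freqs[a] for a in letters])
    proteome: Dict[str, str] = {}
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(letters, size=length - 1, p=probs))
        proteome[f"PROT{i+1:04d}"] = "M" + body
    return proteome


def write_fasta(proteome: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------

def _sample_position(
    rng: np.random.Generator, positions: np.ndarray
) -> Optional[int]:
    if positions.size == 0:
        return None
    return int(rng.choice(positions))


def simulate_degradome(
    proteome: Mapping[str, str],
    model: DegradomeModel,
    seed: int | np.random.Generator = 0,
) -> Tuple[List[Peptide], pd.DataFrame]:
    """Draw peptides whose flanking P1 residues follow ``model.p1_weights``.

    For an internal peptide, the residue preceding its first residue and its
    own last residue are both P1 positions: each is sampled from the weights
    first, then a concrete cleavage position carrying that residue is chosen
    uniformly, so the empirical P1 distribution converges to the weights.
    Internal cuts are restricted to positions 2..len-1 so ground truth agrees
    with the downstream counting rule (position 1 counts as initiator-Met
    processing, not proteolysis).

    Returns the peptides and a ground-truth table (one row per peptide) with
    the span, terminal status and flanking P1 residues.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    residues = sorted(model.p1_weights)
    weights = np.array([model.p1_weights[r] for r in residues])
    min_len, max_len = model.length_range

    peptides: List[Peptide] = []
    truth_rows: List[dict] = []

    def record(peptide: Peptide, protein_id: str, start: int, end: int, status: str) -> None:
        seq = proteome[protein_id]
        peptides.append(peptide)
        truth_rows.append(
            {
                "peptide_id": f"pep{len(peptides):05d}",
                "sequence": peptide.sequence,
                "protein_id": protein_id,
                "start": start,
                "end": end,
                "terminal_status": status,
                "n_term_acetylated": peptide.n_term_acetylated,
                "p1_nside": seq[start - 2] if status in ("internal", "c_terminal") else "",
                "p1_cside": seq[end - 1] if status in ("internal", "n_terminal") else "",
                "n_labels": count_tmab_labels(peptide),
            }
        )

    n_terminal_draws = 0
    for protein_id in sorted(proteome):
        seq = proteome[protein_id]
        n = len(seq)
        if n < min_len + 2:
            continue  # too short to host internal peptides; skip quietly
        # index of positions (1-based) carrying each residue, cut sites 2..n-1
        pos_of: Dict[str, np.ndarray] = {}
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        for r in residues:
            hits = np.nonzero(arr == r)[0] + 1
            pos_of[r] = hits[(hits >= 2) & (hits <= n - 1)]
        for _ in range(model.n_peptides_per_protein):
            if rng.random() < model.terminal_fraction:
                n_terminal_draws += 1  # drawn globally below
                continue
            pep = _draw_internal(rng, protein_id, seq, model, residues, weights, pos_of)
            if pep is None:
                continue
            record(*pep[:1], protein_id, *pep[1:])

    # Terminal fragments are drawn proteome-wide: the anchor P1 residue is
    # sampled from the weights first and the concrete protein terminus chosen
    # uniformly among every compatible window in the proteome, so even rare
    # residues keep their nominal P1 frequency.
    nterm_idx, cterm_idx = _terminal_indexes(proteome, residues, min_len, max_len)
    ids = sorted(proteome)
    for _ in range(n_terminal_draws):
        if rng.random() < 0.5:  # N-terminal fragment
            acetylated = bool(rng.random() < model.acetylated_nterm_prob)
            start = 1 if acetylated or rng.random() < 0.5 else 2
            r2 = residues[int(rng.choice(len(residues), p=weights))]
            cands = nterm_idx[start].get(r2, ())
            if not len(cands):
                continue
            pid_i, end = cands[int(rng.integers(len(cands)))]
            protein_id = ids[pid_i]
            record(
                Peptide(
                    sequence=proteome[protein_id][start - 1 : end],
                    n_term_acetylated=acetylated,
                    protein_id=protein_id,
                ),
                protein_id,
                start,
                int(end),
                "n_terminal",
            )
        else:  # C-terminal fragment
            r1 = residues[int(rng.choice(len(residues), p=weights))]
            cands = cterm_idx.get(r1, ())
            if not len(cands):
                continue
            pid_i, start = cands[int(rng.integers(len(cands)))]
            protein_id = ids[pid_i]
            seq = proteome[protein_id]
            record(
                Peptide(sequence=seq[start - 1 :], protein_id=protein_id),
                protein_id,
                int(start),
                len(seq),
                "c_terminal",
            )
    truth = pd.DataFrame(truth_rows)
    return peptides, truth


def _terminal_indexes(proteome, residues, min_len, max_len):
    """Per-residue candidate (protein, position) arrays for terminal fragments."""
    ids = sorted(proteome)
    nterm: Dict[int, Dict[str, List[Tuple[int, int]]]] = {1: {}, 2: {}}
    cterm: Dict[str, List[Tuple[int, int]]] = {}
    for pi, protein_id in enumerate(ids):
        seq = proteome[protein_id]
        n = len(seq)
        for start in (1, 2):
            lo, hi = start + min_len - 1, min(start + max_len - 1, n - 1)
            for j in range(lo, hi + 1):
                nterm[start].setdefault(seq[j - 1], []).append((pi, j))
        lo, hi = max(3, n - max_len + 1), n - min_len + 1
        for s in range(lo, hi + 1):
            cterm.setdefault(seq[s - 2], []).append((pi, s))  # P1 at s-1
    return nterm, cterm


def _draw_internal(rng, protein_id, seq, model, residues, weights, pos_of):
    # Sample both flanking P1 residues from the weights FIRST, then choose
    # uniformly among every (cut_i, cut_j) position pair compatible with the
    # length range.  Conditioning on the residues before the positions keeps
    # the empirical P1 distribution equal to the weights; the only residual
    # bias is the (rare) event that a residue pair admits no compatible pair
    # anywhere in the protein.
    min_len, max_len = model.length_range
    for _ in range(25):  # bounded retries
        r1 = residues[int(rng.choice(len(residues), p=weights))]
        r2 = residues[int(rng.choice(len(residues), p=weights))]
        pos1 = pos_of[r1]  # cut after i -> peptide starts at i+1; need i >= 2
        pos1 = pos1[pos1 >= 2]
        pos2 = pos_of[r2]  # cut after j -> peptide ends at j; need j <= n-1
        if pos1.size == 0 or pos2.size == 0:
            continue
        # peptide length = j - i, so i in [j - max_len, j - min_len]
        lo = np.searchsorted(pos1, pos2 - max_len, side="left")
        hi = np.searchsorted(pos1, pos2 - min_len, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        pick = int(rng.integers(total))
        j_idx = int(np.searchsorted(np.cumsum(counts), pick, side="right"))
        i = int(pos1[lo[j_idx] + pick - int(np.cumsum(counts)[j_idx]) + int(counts[j_idx])])
        j = int(pos2[j_idx])
        start, end = i + 1, j
        return (
            Peptide(sequence=seq[start - 1 : end], protein_id=protein_id),
            start,
            end,
            "internal",
        )
    return None


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def simulate_abundances(
    peptides: Sequence[Peptide],
    truth: pd.DataFrame,
    design: EffectDesign,
    seed: int | np.random.Generator = 0,
    base_intensity: float = 1.0e4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide × replicate abundance matrix under the condition effects.

    ``abundance = base(peptide) × effect(condition) × lognormal(0, cv)``,
    with effect 1.0 for exempt (non-proteasome-product) peptides.  Returns the
    abundance table (rows = peptide_id, columns = (condition, replicate)
    MultiIndex) and the ground-truth effect table.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = truth["peptide_id"].tolist()
    n_pep = len(ids)
    exempt = rng.random(n_pep) < design.non_product_fraction
    # base abundances spread over ~2 orders of magnitude
    base = base_intensity * np.exp(rng.normal(0.0, 1.0, size=n_pep))

    columns = []
    for cond, n_rep in design.conditions.items():
        for i in range(n_rep):
            columns.append((cond, f"{cond}_r{i+1}"))
    data = np.empty((n_pep, len(columns)))
    effect_rows = []
    for j, (cond, _rep) in enumerate(columns):
        eff = np.where(exempt, 1.0, design.effects[cond])
        noise = np.exp(rng.normal(0.0, design.cv, size=n_pep)) if design.cv > 0 else 1.0
        data[:, j] = base * eff * noise
    for i, pid in enumerate(ids):
        effect_rows.append(
            {
                "peptide_id": pid,
                "exempt": bool(exempt[i]),
                **{
                    cond: (1.0 if exempt[i] else design.effects[cond])
                    for cond in design.conditions
                },
            }
        )
    abundances = pd.DataFrame(
        data, index=pd.Index(ids, name="peptide_id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"]),
    )
    return abundances, pd.DataFrame(effect_rows)


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

def _envelope(neutral_mass: float, params: SpectrumParams) -> np.ndarray:
    """Relative isotopomer intensities (Poisson heavy-isotope model).

    The same envelope is used for every tag channel of a peptide: the tags
    change only defined atoms (D for H, 13C for 12C), not the stochastic
    natural-isotope content, so channel envelopes are identical in shape.
    """
    lam = params.iso_per_kda * neutral_mass / 1000.0
    k = np.arange(params.n_isotopomers)
    w = np.exp(-lam) * lam**k / np.array([math.factorial(int(i)) for i in k])
    return w / w.max()


def render_runs(
    abundances: pd.DataFrame,
    truth: pd.DataFrame,
    peptides: Sequence[Peptide],
    scheme: LabelingScheme,
    params: SpectrumParams = SpectrumParams(),
    constants: MassConstants = DEFAULT_CONSTANTS,
    seed: int | np.random.Generator = 0,
) -> Tuple[List[SpectrumRun], pd.DataFrame]:
    """Render centroid MS1 peak lists for every run in the scheme.

    Every (peptide, charge state, tag channel) becomes one isotope cluster at
    its theoretical m/z (channel spacing is therefore exactly the chemistry
    module's prediction), scaled by the replicate abundance.  Channels whose
    representative intensity falls below the detection limit are omitted and
    flagged missing in the ground truth.  Returns the runs and a ground-truth
    signal table (one row per peptide × run × charge × tag).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pep_by_id = {row.peptide_id: pep for row, pep in zip(truth.itertuples(), peptides)}
    rep_to_col = {rep: (cond, rep) for cond, rep in abundances.columns}

    runs: List[SpectrumRun] = []
    gt_rows: List[dict] = []
    for run_id in scheme.run_ids:
        channels = scheme.runs[run_id]
        tags = list(channels)
        if len(set(tags)) != len(tags):
            raise SchemeError(f"duplicate tag assignment in run {run_id!r}")
        peak_rows: List[Tuple[float, float, float]] = []
        for prow in truth.itertuples():
            pep = pep_by_id[prow.peptide_id]
            n_labels = count_tmab_labels(pep)
            if n_labels == 0:
                continue
            rt_base = float(rng.uniform(*params.rt_range))
            z_states = [max(n_labels, 1)]
            if params.extra_charge_prob > 0 and rng.random() < params.extra_charge_prob:
                z_states.append(z_states[0] + 1)
            # decide overlap injection once per peptide/run
            inject_overlap = rng.random() < params.overlap_injection_rate
            overlap_tag = tags[int(rng.integers(len(tags)))] if inject_overlap else None
            for z in z_states:
                env = _envelope(
                    peptide_neutral_mass(pep, constants) + n_labels * constants.tag_base_mass,
                    params,
                )
                for tag_name in tags:
                    cond, rep = channels[tag_name]
                    abundance = float(abundances.loc[prow.peptide_id, rep_to_col[rep]])
                    rep_intensity = abundance  # envelope max is 1 -> tallest peak
                    missing = rep_intensity < params.lod
                    mono = theoretical_mz(pep, TAGS[tag_name], z, constants)
                    rt = (
                        rt_base
                        + TAGS[tag_name].deuterium_count * params.deuterium_rt_shift
                        + (rng.normal(0.0, params.rt_jitter) if params.rt_jitter > 0 else 0.0)
                    )
                    gt_rows.append(
                        {
                            "peptide_id": prow.peptide_id,
                            "run_id": run_id,
                            "tag": tag_name,
                            "condition": cond,
                            "replicate": rep,
                            "z": z,
                            "n_labels": n_labels,
                            "mono_mz": mono,
                            "rt": rt_base,
                            "intensity": rep_intensity,
                            "missing": bool(missing),
                            "overlap_injected": tag_name == overlap_tag,
                        }
                    )
                    if missing:
                        continue
                    for k, w in enumerate(env):
                        mz = mono + k * C13_MINUS_C12 / z
                        if params.mz_jitter_ppm > 0:
                            mz += mz * rng.normal(0.0, params.mz_jitter_ppm) * 1e-6
                        peak_rows.append((rt, mz, abundance * w))
                    if tag_name == overlap_tag:
                        # co-eluting interferent half an isotopomer step away
                        shift = 0.45 * C13_MINUS_C12 / z
                        for k, w in enumerate(env[:2]):
                            peak_rows.append(
                                (rt, mono + shift + k * C13_MINUS_C12 / z, abundance * w * 0.8)
                            )
        for _ in range(params.n_noise_peaks):
            peak_rows.append(
                (
                    float(rng.uniform(*params.rt_range)),
                    float(rng.uniform(*params.mz_range)),
                    float(rng.exponential(params.noise_intensity)),
                )
            )
        peaks = pd.DataFrame(peak_rows, columns=["rt", "mz", "intensity"])
        runs.append(SpectrumRun(run_id=run_id, peaks=peaks))
    return runs, pd.DataFrame(gt_rows)
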