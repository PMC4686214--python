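"""Peptide location, cleavage-site enumeration and P1 frequency tables."""

from collections import Counter

import pandas as pd
import pytest

from tmabquant.chemistry import Peptide
from tmabquant.cleavage import (
    ACIDIC,
    BASIC,
    HYDROPHOBIC,
    FreqTable,
    PeptideLocationError,
    cleavage_sites,
    locate_peptide,
    p1_frequency_table,
    p1_residue,
)

TOY_PROTEOME = {
    # hand-designed 5-protein toy set; spans and flanks are enumerable by eye
    "P1": "MAGLKDEFLWSTRVHQLNCYPMAK",
    "P2": "MSDFLKAGHTRVVLPQWEYCIN",
    "P3": "MLLLLLLLLLLLLLLLLLLLL",
    "P4": "MKRDEGGSTAPQVVFY",
    "P5": "MAGLKDEFMAGLKDEFTTTT",  # repeated 8-mer -> ambiguity
}


class TestLocatePeptide:
    def test_internal_peptide_coordinates(self):
        span = locate_peptide(Peptide("DEFLW", protein_id="P1"), TOY_PROTEOME)
        assert (span.start, span.end) == (6, 10)
        assert span.terminal_status == "internal"
        assert not span.ambiguous

    def test_full_protein_is_full_length(self):
        seq = TOY_PROTEOME["P2"]
        span = locate_peptide(Peptide(seq, protein_id="P2"), TOY_PROTEOME)
        assert span.terminal_status == "full_length"

    def test_met_removed_nterminal_fragment(self):
        # starts at residue 2: initiator-Met removal, still protein N-terminus
        span = locate_peptide(Peptide("SDFLK", protein_id="P2"), TOY_PROTEOME)
        assert span.start == 2
        assert span.terminal_status == "n_terminal"

    def test_ambiguous_multi_locus_peptide_flagged(self):
        span = locate_peptide(Peptide("AGLKDEF", protein_id="P5"), TOY_PROTEOME)
        assert span.ambiguous
        assert span.start == 2  # first occurrence

    def test_absent_sequence_raises(self):
        with pytest.raises(PeptideLocationError):
            locate_peptide(Peptide("WWWWW", protein_id="P1"), TOY_PROTEOME)
        with pytest.raises(PeptideLocationError):
            locate_peptide(Peptide("AG", protein_id="NOPE"), TOY_PROTEOME)


class TestCleavageSites:
    def _sites(self, sequence, protein_id, acetylated=False):
        pep = Peptide(sequence, n_term_acetylated=acetylated, protein_id=protein_id)
        span = locate_peptide(pep, TOY_PROTEOME)
        return span, cleavage_sites(span, pep, TOY_PROTEOME[protein_id])

    def test_internal_peptide_has_two_sites(self):
        span, sites = self._sites("DEFLW", "P1")
        assert len(sites) == 2
        n_side, c_side = sites
        assert n_side.side == "generates_peptide_nterm"
        assert n_side.position == 5 and n_side.p1 == "K"  # bond K5/D6
        assert c_side.side == "generates_peptide_cterm"
        assert c_side.position == 10 and c_side.p1 == "W"  # bond W10/S11

    def test_cterminal_fragment_needs_one_cut(self):
        span, sites = self._sites("PMAK", "P1")
        assert span.terminal_status == "c_terminal"
        assert len(sites) == 1
        assert sites[0].p1 == "Y"  # residue before the fragment

    def test_acetylated_nterminal_peptide_single_site(self):
        # acetylated peptide retaining the initiator Met: only the C-side cut counts
        span, sites = self._sites("MAGLK", "P1", acetylated=True)
        assert len(sites) == 1
        assert sites[0].side == "generates_peptide_cterm"
        assert sites[0].p1 == "K"

    def test_full_length_no_sites(self):
        _, sites = self._sites(TOY_PROTEOME["P2"], "P2")
        assert sites == []

    def test_p1_of_cterminal_site_is_last_residue(self):
        pep = Peptide("SDAKSFVLNL", protein_id="PX")
        proteome = {"PX": "MAR" + pep.sequence + "GKD"}
        span = locate_peptide(pep, proteome)
        sites = cleavage_sites(span, pep, proteome["PX"])
        c_side = [s for s in sites if s.side == "generates_peptide_cterm"][0]
        assert p1_residue(c_side, proteome["PX"]) == "L" == pep.sequence[-1]

    def test_protein_nterminus_is_not_a_cleavage(self):
        from tmabquant.cleavage import CleavageSite

        with pytest.raises(ValueError):
            p1_residue(
                CleavageSite(protein_id="P1", position=0, p1="M", p1_prime="A", side="x"),
                TOY_PROTEOME["P1"],
            )


def brute_force_p1_counts(observations, proteome):
    """Independent enumeration: scan each protein for the peptide and count
    flanking residues by string arithmetic only."""
    counts = {}
    for row in observations.itertuples(index=False):
        seq = proteome[row.protein_id]
        pos = seq.find(row.sequence)
        if seq.find(row.sequence, pos + 1) >= 0:
            continue  # ambiguous: excluded
        start, end = pos + 1, pos + len(row.sequence)
        cat = counts.setdefault(row.category, Counter())
        if start > 2 and not row.n_term_acetylated:
            cat[seq[start - 2]] += 1
        if end < len(seq):
            cat[seq[end - 1]] += 1
    return counts


class TestFrequencyTable:
    OBSERVATIONS = pd.DataFrame(
        [
            # one observation per detection: repeated rows weight the table
            ("DEFLW", "P1", False, "decrease"),
            ("DEFLW", "P1", False, "decrease"),
            ("SDFLK", "P2", False, "decrease"),
            ("PMAK", "P1", False, "no_change"),
            ("MAGLK", "P1", True, "decrease"),
            ("VVFY", "P4", False, "increase"),
            ("AGLKDEF", "P5", False, "decrease"),  # ambiguous: dropped
            (TOY_PROTEOME["P2"], "P2", False, "no_change"),  # full length: no sites
        ],
        columns=["sequence", "protein_id", "n_term_acetylated", "category"],
    )

    def test_counts_equal_brute_force_enumeration(self):
        table, sites = p1_frequency_table(self.OBSERVATIONS, TOY_PROTEOME)
        expected = brute_force_p1_counts(self.OBSERVATIONS, TOY_PROTEOME)
        for category, counter in expected.items():
            for residue, count in counter.items():
                assert table.counts.loc[residue, category] == count
            assert table.counts[category].sum() == sum(counter.values())

    def test_internal_two_terminal_one_fulllength_zero(self):
        table, sites = p1_frequency_table(self.OBSERVATIONS, TOY_PROTEOME)
        per_obs = sites.groupby(["sequence", "category"]).size()
        assert per_obs[("DEFLW", "decrease")] == 4  # 2 observations x 2 sites
        assert per_obs[("SDFLK", "decrease")] == 1  # N-terminal fragment
        assert per_obs[("MAGLK", "decrease")] == 1  # acetylated N-terminus
        assert ("AGLKDEF", "decrease") not in per_obs  # ambiguous excluded
        full = TOY_PROTEOME["P2"]
        assert (sites["sequence"] == full).sum() == 0

    def test_site_count_at_least_observation_count(self):
        table, sites = p1_frequency_table(self.OBSERVATIONS, TOY_PROTEOME)
        n_obs_with_sites = 6  # all except the ambiguous and full-length rows
        assert len(sites) >= n_obs_with_sites

    def test_pooling_merges_categories(self):
        pooled, _ = p1_frequency_table(
            self.OBSERVATIONS,
            TOY_PROTEOME,
            pool={"decrease": "down", "no_change": "down"},
        )
        plain, _ = p1_frequency_table(self.OBSERVATIONS, TOY_PROTEOME)
        assert pooled.counts["down"].sum() == (
            plain.counts["decrease"].sum() + plain.counts["no_change"].sum()
        )

    def test_empty_observations_give_empty_table(self):
        table, sites = p1_frequency_table(
            pd.DataFrame(columns=["sequence", "protein_id", "n_term_acetylated", "category"]),
            TOY_PROTEOME,
        )
        assert table.counts.to_numpy().sum() == 0
        assert sites.empty

    def test_degenerate_all_leucine_internal_set(self):
        proteome = {"PL": "MALVVVLAG"}  # VVVL: preceded by L, ends in L
        obs = pd.DataFrame(
            [("VVVL", "PL", False, "decrease")],
            columns=["sequence", "protein_id", "n_term_acetylated", "category"],
        )
        table, _ = p1_frequency_table(obs, proteome)
        assert table.proportions.loc["L", "decrease"] == pytest.approx(1.0)

    def test_proportions_sum_to_one_and_classes_disjoint(self):
        table, _ = p1_frequency_table(self.OBSERVATIONS, TOY_PROTEOME)
        sums = table.proportions.sum(axis=0)
        assert (abs(sums - 1.0) < 1e-12).all()
        assert not (HYDROPHOBIC & BASIC) and not (HYDROPHOBIC & ACIDIC) and not (BASIC & ACIDIC)
        cf = table.class_fractions()
        assert (cf.sum(axis=0) <= 1.0 + 1e-12).all()
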