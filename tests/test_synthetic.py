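"""Synthetic proteome / degradome / spectrum generator properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmabquant.chemistry import TAGS, peakgroup_spacing
from tmabquant.cleavage import HYDROPHOBIC
from tmabquant.scheme import LabelingScheme
from tmabquant.synthetic import (
    DegradomeModel,
    EffectDesign,
    SpectrumParams,
    render_runs,
    simulate_abundances,
    simulate_degradome,
    simulate_proteome,
)


class TestProteome:
    def test_seeded_determinism(self):
        a = simulate_proteome(3, (50, 50), seed=9)
        b = simulate_proteome(3, (50, 50), seed=9)
        assert a == b

    def test_empirical_residue_frequencies_uniform(self):
        freqs = {a: 0.05 for a in "ACDEFGHIKLMNPQRSTVWY"}
        proteome = simulate_proteome(40, (400, 400), aa_freqs=freqs, seed=3)
        counts = pd.Series(list("".join(s[1:] for s in proteome.values()))).value_counts()
        n = counts.sum()
        for residue, c in counts.items():
            p = c / n
            sigma = np.sqrt(0.05 * 0.95 / n)
            assert abs(p - 0.05) < 4 * sigma, residue

    def test_zero_proteins_rejected(self):
        with pytest.raises(ValueError):
            simulate_proteome(0)


class TestDegradome:
    def test_peptides_are_exact_substrings_at_recorded_spans(self):
        proteome = simulate_proteome(5, seed=4)
        peptides, truth = simulate_degradome(proteome, DegradomeModel(), seed=5)
        assert len(peptides) > 0
        for pep, row in zip(peptides, truth.itertuples()):
            protein = proteome[row.protein_id]
            assert protein[row.start - 1 : row.end] == pep.sequence

    def test_degenerate_weights_force_leucine_flanks(self):
        proteome = simulate_proteome(10, seed=6)
        model = DegradomeModel(p1_weights={"L": 1.0}, terminal_fraction=0.0)
        peptides, truth = simulate_degradome(proteome, model, seed=7)
        assert (truth["p1_cside"] == "L").all()  # every peptide ends in L
        assert (truth["p1_nside"] == "L").all()  # and is preceded by L
        assert all(p.sequence.endswith("L") for p in peptides)

    def test_p1_distribution_matches_weights(self):
        proteome = simulate_proteome(300, seed=8)
        model = DegradomeModel()
        _, truth = simulate_degradome(proteome, model, seed=9)
        p1 = pd.concat([truth["p1_nside"], truth["p1_cside"]])
        p1 = p1[p1 != ""]
        n = len(p1)
        obs = p1.value_counts().reindex(sorted(model.p1_weights)).fillna(0)
        expected = pd.Series({r: model.p1_weights[r] * n for r in sorted(model.p1_weights)})
        assert stats.chisquare(obs, expected).pvalue > 0.01

    def test_lengths_respect_model_range(self):
        proteome = simulate_proteome(10, seed=10)
        model = DegradomeModel(length_range=(8, 12))
        peptides, _ = simulate_degradome(proteome, model, seed=11)
        assert all(8 <= len(p) <= 12 for p in peptides)


class TestAbundances:
    def _design(self, cv, exempt=0.0):
        return EffectDesign(
            conditions={"ctl": 2, "trt": 3},
            reference="ctl",
            effects={"ctl": 1.0, "trt": 0.35},
            non_product_fraction=exempt,
            cv=cv,
        )

    @pytest.fixture
    def degradome(self):
        proteome = simulate_proteome(10, seed=12)
        return simulate_degradome(proteome, DegradomeModel(), seed=13)

    def test_noise_free_ratios_exact(self, degradome):
        peptides, truth = degradome
        ab, effects = simulate_abundances(peptides, truth, self._design(cv=0.0), seed=1)
        ctl = ab.xs("ctl", axis=1, level="condition")
        trt = ab.xs("trt", axis=1, level="condition")
        assert np.allclose(ctl.values, ctl.values[:, [0]])  # replicates identical
        assert np.allclose(trt.values / ctl.values[:, [0]], 0.35)

    def test_exempt_peptides_unaffected(self, degradome):
        peptides, truth = degradome
        ab, effects = simulate_abundances(peptides, truth, self._design(0.0, exempt=0.5), seed=2)
        exempt_ids = effects.loc[effects["exempt"], "peptide_id"]
        assert len(exempt_ids) > 0
        sub = ab.loc[exempt_ids]
        assert np.allclose(sub.values, sub.values[:, [0]])

    def test_lognormal_noise_recovers_effect_geometrically(self, degradome):
        peptides, truth = degradome
        design = EffectDesign(
            conditions={"ctl": 6, "trt": 6},
            reference="ctl",
            effects={"ctl": 1.0, "trt": 0.35},
            non_product_fraction=0.0,
            cv=0.2,
        )
        ab, _ = simulate_abundances(peptides, truth, design, seed=3)
        ctl = ab.xs("ctl", axis=1, level="condition").to_numpy()
        trt = ab.xs("trt", axis=1, level="condition").to_numpy()
        log_ratio = np.log(trt).mean() - np.log(ctl).mean()
        n = trt.size
        se = 0.2 * np.sqrt(2.0 / n)
        assert abs(log_ratio - np.log(0.35)) < 4 * se


class TestRenderRuns:
    @pytest.fixture
    def staged(self):
        proteome = simulate_proteome(6, seed=20)
        peptides, truth = simulate_degradome(proteome, DegradomeModel(), seed=21)
        design = EffectDesign(
            conditions={"ctl": 2, "trt": 2},
            reference="ctl",
            effects={"ctl": 1.0, "trt": 0.4},
            non_product_fraction=0.0,
            cv=0.0,
        )
        ab, _ = simulate_abundances(peptides, truth, design, seed=22)
        scheme = LabelingScheme.balanced(design.conditions, "ctl", tags_per_run=4)
        return proteome, peptides, truth, ab, scheme

    def test_noise_free_peaks_at_exact_theoretical_positions(self, staged):
        _, peptides, truth, ab, scheme = staged
        runs, gt = render_runs(ab, truth, peptides, scheme, SpectrumParams(), seed=23)
        run = runs[0]
        present = gt[(gt["run_id"] == run.run_id) & (~gt["missing"])]
        mz = run.peaks["mz"].to_numpy()
        for row in present.itertuples():
            assert np.isclose(mz, row.mono_mz, rtol=0, atol=1e-9).any()

    def test_rendered_channel_spacing_matches_chemistry(self, staged):
        _, peptides, truth, ab, scheme = staged
        runs, gt = render_runs(ab, truth, peptides, scheme, SpectrumParams(), seed=23)
        sub = gt[gt["run_id"] == runs[0].run_id]
        for (pid, z), grp in sub.groupby(["peptide_id", "z"]):
            grp = grp.set_index("tag")
            n = grp["n_labels"].iloc[0]
            tags = list(grp.index)
            for a, b in zip(tags, tags[1:]):
                expected = peakgroup_spacing(n, TAGS[a], TAGS[b], z)
                assert grp.loc[b, "mono_mz"] - grp.loc[a, "mono_mz"] == pytest.approx(
                    expected, abs=1e-6
                )

    def test_detection_limit_censors_and_flags_channels(self, staged):
        _, peptides, truth, ab, scheme = staged
        lod = float(np.median(ab.to_numpy())) * 0.6
        runs, gt = render_runs(
            ab, truth, peptides, scheme, SpectrumParams(lod=lod), seed=24
        )
        assert gt["missing"].any()
        censored = gt[gt["missing"]]
        assert (censored["intensity"] < lod).all()
        # no peaks rendered at a censored channel's position
        for row in censored.itertuples():
            run = next(r for r in runs if r.run_id == row.run_id)
            assert not np.isclose(run.peaks["mz"].to_numpy(), row.mono_mz, atol=1e-9).any()

    def test_seeded_determinism_byte_identical(self, staged, tmp_path):
        from tmabquant.detect import write_centroid_tsv

        _, peptides, truth, ab, scheme = staged
        params = SpectrumParams(mz_jitter_ppm=2.0, n_noise_peaks=50)
        for name in ("a", "b"):
            runs, _ = render_runs(ab, truth, peptides, scheme, params, seed=99)
            write_centroid_tsv(runs, tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_abundance_ratio_below_lod_yields_missing_treated_channel(self, staged):
        _, peptides, truth, ab, scheme = staged
        # LOD between the treated (0.4x) and control levels of the strongest
        # peptide: its treated channels must be censored, controls kept
        pid = ab.mean(axis=1).idxmax()
        ctl = ab.loc[pid].xs("ctl", level="condition").min()
        lod = 0.7 * ctl
        runs, gt = render_runs(ab, truth, peptides, scheme, SpectrumParams(lod=lod), seed=25)
        sub = gt[gt["peptide_id"] == pid]
        assert sub.loc[sub["condition"] == "trt", "missing"].all()
        assert not sub.loc[sub["condition"] == "ctl", "missing"].any()
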