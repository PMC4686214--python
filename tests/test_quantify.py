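"""Ratio computation, capping, form merging, summaries and classification."""

import math

import numpy as np
import pandas as pd
import pytest

from tmabquant.quantify import (
    UnquantifiableGroupError,
    cap_ratio,
    classify_change,
    condition_summary,
    heat_bin,
    merge_peptide_forms,
    records_to_frame,
    replicate_ratios,
    significance_stars,
)


class TestCapRatio:
    @pytest.mark.parametrize(
        "raw, expected, flag",
        [
            (0.05, 0.20, "low"),
            (7.3, 5.0, "high"),
            (0.43, 0.43, "none"),
            (0.20, 0.20, "none"),
            (5.0, 5.0, "none"),
        ],
    )
    def test_capping(self, raw, expected, flag):
        assert cap_ratio(raw) == (expected, flag)

    def test_high_cap_can_be_disabled(self):
        assert cap_ratio(7.3, high=None) == (7.3, "none")

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            cap_ratio(-0.1)


class TestReplicateRatios:
    def test_reference_mean_denominator(self, group_factory, five_plex_scheme):
        group = group_factory({"D0": 100.0, "D3": 100.0, "D6": 43.0, "D9": 86.0, "D12": 200.0})
        records = records_to_frame(replicate_ratios(group, five_plex_scheme))
        by_tag = records.set_index("tag")["capped_ratio"]
        assert by_tag["D6"] == pytest.approx(0.43)
        assert by_tag["D9"] == pytest.approx(0.86)
        assert by_tag["D12"] == pytest.approx(2.0)

    def test_reference_self_ratios_average_one(self, group_factory, five_plex_scheme):
        group = group_factory({"D0": 120.0, "D3": 80.0, "D6": 50.0, "D9": None, "D12": None})
        records = records_to_frame(replicate_ratios(group, five_plex_scheme))
        refs = records[records["condition"] == "control"]["raw_ratio"]
        assert refs.mean() == pytest.approx(1.0)

    def test_missing_test_channel_reported_at_low_cap(self, group_factory, five_plex_scheme):
        group = group_factory({"D0": 100.0, "D3": 100.0, "D6": None, "D9": 40.0, "D12": 50.0})
        records = records_to_frame(replicate_ratios(group, five_plex_scheme))
        d6 = records[records["tag"] == "D6"].iloc[0]
        assert d6["capped_ratio"] == 0.20
        assert d6["cap_flag"] == "low"
        assert math.isnan(d6["raw_ratio"])

    def test_missing_reference_channel_contributes_nothing(self, group_factory, five_plex_scheme):
        group = group_factory({"D0": 100.0, "D3": None, "D6": 35.0, "D9": 35.0, "D12": 35.0})
        records = records_to_frame(replicate_ratios(group, five_plex_scheme))
        assert "D3" not in set(records["tag"])
        assert records.set_index("tag")["capped_ratio"]["D6"] == pytest.approx(0.35)

    def test_all_reference_channels_missing_is_unquantifiable(
        self, group_factory, five_plex_scheme
    ):
        group = group_factory({"D0": None, "D3": None, "D6": 35.0, "D9": 35.0, "D12": 35.0})
        with pytest.raises(UnquantifiableGroupError):
            replicate_ratios(group, five_plex_scheme)

    def test_overlap_flagged_channel_skipped(self, group_factory, five_plex_scheme):
        group = group_factory({"D0": 100.0, "D3": 100.0, "D6": 43.0, "D9": 86.0, "D12": 10.0})
        group.channel_overlap = {"D12": True}
        records = records_to_frame(replicate_ratios(group, five_plex_scheme))
        assert "D12" not in set(records["tag"])


class TestMergeForms:
    def test_two_forms_average(self):
        assert merge_peptide_forms([0.40, 0.46]) == pytest.approx(0.43)

    def test_single_form_identity(self):
        assert merge_peptide_forms([0.7]) == 0.7

    def test_all_forms_excluded_gives_missing(self):
        assert math.isnan(merge_peptide_forms([]))


class TestConditionSummary:
    def test_mean_sd_and_counts(self):
        out = condition_summary(
            {"q7q111": [0.40, 0.50, 0.40, 0.42, 0.43], "ctl": [1.0, 1.0, 1.0, 1.0]},
            reference="ctl",
        ).set_index("condition")
        row = out.loc["q7q111"]
        assert row["mean"] == pytest.approx(0.43)
        assert row["n"] == 5
        assert row["sd"] == pytest.approx(np.std([0.40, 0.50, 0.40, 0.42, 0.43], ddof=1))

    def test_identical_samples_give_p_one(self):
        out = condition_summary(
            {"trt": [1.0, 1.0, 1.0], "ctl": [1.0, 1.0, 1.0]}, reference="ctl"
        ).set_index("condition")
        assert out.loc["trt", "p_value"] == pytest.approx(1.0)

    def test_p_value_matches_textbook_two_sample_t(self):
        a = [0.40, 0.45, 0.38, 0.42]
        b = [0.98, 1.02, 1.00, 1.01, 0.99]
        out = condition_summary({"trt": a, "ctl": b}, reference="ctl").set_index("condition")
        # closed-form pooled-variance t statistic and survival function
        na, nb = len(a), len(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), na + nb - 2)
        assert out.loc["trt", "p_value"] == pytest.approx(p, rel=1e-10)

    def test_single_value_yields_no_p(self):
        out = condition_summary({"trt": [0.4], "ctl": [1.0, 1.0]}, reference="ctl")
        row = out.set_index("condition").loc["trt"]
        assert math.isnan(row["p_value"])

    def test_empty_condition_absent(self):
        out = condition_summary({"trt": [], "ctl": [1.0, 1.0]}, reference="ctl")
        assert "trt" not in set(out["condition"])


class TestClassification:
    @pytest.mark.parametrize(
        "mean, category",
        [
            (0.43, "decrease"),
            (0.80, "decrease"),
            (0.801, "no_change"),
            (0.87, "no_change"),
            (1.24, "no_change"),
            (1.249, "no_change"),
            (1.25, "increase"),
            (1.59, "increase"),
        ],
    )
    def test_fold_change_categories(self, mean, category):
        assert classify_change(mean) == category

    @pytest.mark.parametrize(
        "value, bin_",
        [
            (0.43, "bright_green"),
            (0.599, "bright_green"),
            (0.60, "dark_green"),
            (0.80, "dark_green"),
            (0.801, "grey"),
            (1.0, "grey"),
            (1.199, "grey"),
            (1.20, "dark_red"),
            (1.40, "dark_red"),
            (1.401, "bright_red"),
            (float("nan"), "white"),
            (None, "white"),
        ],
    )
    def test_heat_bins(self, value, bin_):
        assert heat_bin(value) == bin_

    @pytest.mark.parametrize(
        "p, stars", [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, ""), (float("nan"), "")]
    )
    def test_significance_stars(self, p, stars):
        assert significance_stars(p) == stars

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_change(-0.1)
        with pytest.raises(ValueError):
            heat_bin(-0.1)


class TestCappingInvariants:
    def test_all_emitted_ratios_inside_caps(self, roundtrip):
        r = roundtrip.ratios
        assert (r["capped_ratio"] >= 0.20).all()
        assert (r["capped_ratio"] <= 5.0).all()
        unflagged = r[r["cap_flag"] == "none"]
        assert np.allclose(unflagged["raw_ratio"], unflagged["capped_ratio"])

    def test_reference_self_ratio_mean_is_one_per_run_and_group(self, roundtrip):
        r = roundtrip.ratios
        refs = r[r["condition"] == roundtrip.scheme.reference]
        means = refs.groupby(["run_id", "peptide_id", "z"])["raw_ratio"].mean()
        assert np.allclose(means, 1.0)
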