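"""Run-relative ratio quantification, capping, and fold-change classification.

Every channel intensity is divided by the within-run mean of the reference
channels, so reference replicates yield self-ratios that average exactly 1 per
run.  Ratios outside the quantifiable dynamic range (set by a typical 5:1
signal-to-noise ratio) are capped at 0.20, and optionally at 5.0 on the high
side; a channel that is undetected while the reference is present is reported
as a capped-low record.  Peptides seen as several forms (different charge
states and/or label counts) are averaged to one value per replicate, then
summarized per condition as mean ± SD with a two-tailed unpaired Student's
t-test against the reference self-ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .detect import PeakGroup, representative_intensity
from .scheme import LabelingScheme, SchemeError

__all__ = [
    "LabelingScheme",
    "RatioRecord",
    "LOW_CAP",
    "HIGH_CAP",
    "cap_ratio",
    "replicate_ratios",
    "merge_peptide_forms",
    "condition_summary",
    "classify_change",
    "heat_bin",
    "significance_stars",
    "summarize",
]

LOW_CAP = 0.20
HIGH_CAP = 5.0

CATEGORIES = ("decrease", "no_change", "increase")
HEAT_BINS = ("bright_green", "dark_green", "grey", "dark_red", "bright_red", "white")


@dataclass(frozen=True)
class RatioRecord:
    """One channel of one peak group expressed relative to the run's reference."""

    peptide_id: Optional[str]
    run_id: str
    condition: str
    replicate: str
    tag: str
    raw_ratio: float  # NaN for a missing channel reported at the low cap
    capped_ratio: float
    cap_flag: str  # none | low | high
    z: int
    n_labels: int

    @property
    def form(self) -> Tuple[int, int]:
        return (self.z, self.n_labels)


def cap_ratio(
    r: float, low: float = LOW_CAP, high: Optional[float] = HIGH_CAP
) -> Tuple[float, str]:
    """Clamp a ratio to the quantifiable range.

    ``high=None`` disables the upper cap (experiments without an expected
    increase use the low cap only).
    """
    if r < 0:
        raise ValueError(f"ratio must be non-negative, got {r}")
    if r < low:
        return low, "low"
    if high is not None and r > high:
        return high, "high"
    return float(r), "none"


class UnquantifiableGroupError(ValueError):
    """All reference channels of a peak group are missing or overlap-flagged."""


def replicate_ratios(
    group: PeakGroup,
    scheme: LabelingScheme,
    peptide_id: Optional[str] = None,
    low: float = LOW_CAP,
    high: Optional[float] = HIGH_CAP,
) -> List[RatioRecord]:
    """Per-replicate ratios for one peak group.

    The denominator is the mean representative intensity of the run's
    reference channels (those present and not overlap-flagged).  Every usable
    channel — including the reference replicates themselves — yields a record.
    A missing non-reference channel with a present reference is evidence the
    peptide fell below detection, so it is reported at the low cap.
    """
    if group.run_id not in scheme.runs:
        raise SchemeError(f"run {group.run_id!r} not in labeling scheme")
    channels = scheme.runs[group.run_id]
    ref_tags = scheme.reference_tags(group.run_id)

    def usable(tag: str) -> Optional[float]:
        if group.channel_overlap.get(tag, False):
            return None
        return group.intensity(tag)

    ref_intensities = [v for t in ref_tags if (v := usable(t)) is not None]
    if not ref_intensities:
        raise UnquantifiableGroupError(
            f"group in run {group.run_id!r} has no usable reference channel"
        )
    denom = float(np.mean(ref_intensities))

    records: List[RatioRecord] = []
    for tag, (condition, replicate) in channels.items():
        if group.channel_overlap.get(tag, False):
            continue  # overlapped channels are excluded, not imputed
        intensity = group.intensity(tag)
        if intensity is None:
            if condition == scheme.reference:
                continue  # a missing reference channel simply contributes nothing
            raw, capped, flag = float("nan"), low, "low"
        else:
            raw = intensity / denom
            capped, flag = cap_ratio(raw, low, high)
        records.append(
            RatioRecord(
                peptide_id=peptide_id,
                run_id=group.run_id,
                condition=condition,
                replicate=replicate,
                tag=tag,
                raw_ratio=raw,
                capped_ratio=capped,
                cap_flag=flag,
                z=group.z,
                n_labels=group.n_labels,
            )
        )
    return records


def records_to_frame(records: Iterable[RatioRecord]) -> pd.DataFrame:
    rows = [
        {
            "peptide_id": r.peptide_id,
            "run_id": r.run_id,
            "condition": r.condition,
            "replicate": r.replicate,
            "tag": r.tag,
            "raw_ratio": r.raw_ratio,
            "capped_ratio": r.capped_ratio,
            "cap_flag": r.cap_flag,
            "z": r.z,
            "n_labels": r.n_labels,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id",
            "run_id",
            "condition",
            "replicate",
            "tag",
            "raw_ratio",
            "capped_ratio",
            "cap_flag",
            "z",
            "n_labels",
        ],
    )


def merge_peptide_forms(capped_ratios: Sequence[float]) -> float:
    """Average the capped ratios of one peptide's forms within one replicate.

    Forms that were wholly overlap-flagged never produce records, so an empty
    input means the replicate value is missing (NaN, rendered white).
    """
    if len(capped_ratios) == 0:
        return float("nan")
    return float(np.mean(capped_ratios))


def merge_forms_frame(records: pd.DataFrame) -> pd.DataFrame:
    """One merged value per (peptide, condition, replicate) from tidy records."""
    df = records.dropna(subset=["peptide_id"])
    merged = (
        df.groupby(["peptide_id", "condition", "replicate"], sort=True)["capped_ratio"]
        .mean()
        .rename("ratio")
        .reset_index()
    )
    return merged


def classify_change(mean_ratio: float) -> str:
    """Fold-change category: decrease ≤ 0.80 < no_change < 1.25 ≤ increase.

    The printed 0.81–1.24 no-change band is treated as the half-open interval
    (0.80, 1.25): two-decimal rounding, not a gap.
    """
    if mean_ratio < 0:
        raise ValueError("mean ratio must be non-negative")
    if mean_ratio <= 0.80:
        return "decrease"
    if mean_ratio >= 1.25:
        return "increase"
    return "no_change"


def heat_bin(mean_ratio: Optional[float]) -> str:
    """Heat-map bin for a (merged) ratio; missing values render white.

    Bins: <0.60 bright_green; 0.60–0.80 dark_green; >0.80 but <1.20 grey;
    1.20–1.40 dark_red; >1.40 bright_red.
    """
    if mean_ratio is None or (isinstance(mean_ratio, float) and np.isnan(mean_ratio)):
        return "white"
    if mean_ratio < 0:
        raise ValueError("ratio must be non-negative")
    if mean_ratio < 0.60:
        return "bright_green"
    if mean_ratio <= 0.80:
        return "dark_green"
    if mean_ratio < 1.20:
        return "grey"
    if mean_ratio <= 1.40:
        return "dark_red"
    return "bright_red"


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def condition_summary(
    values_by_condition: Mapping[str, Sequence[float]], reference: str
) -> pd.DataFrame:
    """Per-condition mean, sample SD, n, and t-test vs the reference self-ratios.

    The test is a two-sample, two-tailed, equal-variance Student's t-test of
    the condition's replicate values against the reference condition's
    self-ratio values.  A p-value needs at least two values on each side.
    """
    ref_values = np.asarray(values_by_condition.get(reference, ()), dtype=float)
    ref_values = ref_values[~np.isnan(ref_values)]
    rows = []
    for condition, vals in values_by_condition.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            continue
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        if condition == reference or v.size < 2 or ref_values.size < 2:
            p = float("nan") if condition != reference else float("nan")
        else:
            if np.allclose(v, v[0]) and np.allclose(ref_values, ref_values[0]) and np.isclose(
                v[0], ref_values[0]
            ):
                p = 1.0  # identical constant samples: t = 0 by convention
            else:
                with warnings.catch_warnings():
                    # nearly-identical samples trip scipy's precision warning;
                    # the resulting p ~ 1 is exactly what we want reported
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(stats.ttest_ind(v, ref_values, equal_var=True).pvalue)
        rows.append(
            {
                "condition": condition,
                "mean": mean,
                "sd": sd,
                "n": int(v.size),
                "p_value": p,
                "stars": significance_stars(p) if condition != reference else "",
                "category": classify_change(mean),
                "heat_bin": heat_bin(mean),
            }
        )
    return pd.DataFrame(rows)


def summarize(merged: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-peptide condition summaries from merged per-replicate values.

    ``merged`` has columns peptide_id, condition, replicate, ratio (the output
    of :func:`merge_forms_frame`).
    """
    out = []
    for pep, sub in merged.groupby("peptide_id", sort=True):
        values = {c: s["ratio"].tolist() for c, s in sub.groupby("condition", sort=True)}
        summary = condition_summary(values, reference)
        summary.insert(0, "peptide_id", pep)
        out.append(summary)
    if not out:
        return pd.DataFrame(
            columns=["peptide_id", "condition", "mean", "sd", "n", "p_value", "stars", "category", "heat_bin"]
        )
    return pd.concat(out, ignore_index=True)
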