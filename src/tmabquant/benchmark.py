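"""Self-contained benchmark scenarios exercising the whole pipeline.

These drive the synthetic generator through detection, quantification and
cleavage analysis at desk scale and return the quantities a user would check:
detection recall, ratio recovery, classification counts, and P1-frequency
recovery.  Used by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .chemistry import count_tmab_labels
from .cleavage import HYDROPHOBIC, p1_frequency_table
from .detect import detect_isotope_clusters, find_peak_groups, flag_overlaps
from .pipeline import match_identifications, quantify_groups
from .quantify import merge_forms_frame, summarize
from .scheme import LabelingScheme
from .synthetic import (
    DegradomeModel,
    EffectDesign,
    SpectrumParams,
    render_runs,
    simulate_abundances,
    simulate_degradome,
    simulate_proteome,
)

__all__ = ["ScenarioResult", "run_scenario", "recovery_scenario", "roundtrip_scenario"]

#: Spectral settings of the shipped benchmark: instrument-grade m/z jitter,
#: slight RT scatter, ambient noise peaks and occasional co-eluting overlaps.
BENCHMARK_SPECTRUM = dict(
    mz_jitter_ppm=2.0,
    rt_jitter=0.02,
    n_noise_peaks=500,
    overlap_injection_rate=0.02,
    extra_charge_prob=0.25,
)


@dataclass
class ScenarioResult:
    """Everything downstream checks need from one simulated study."""

    truth: pd.DataFrame
    effects: pd.DataFrame
    ground_truth_signals: pd.DataFrame
    scheme: LabelingScheme
    groups: list
    peptide_ids: List[Optional[str]]
    ratios: pd.DataFrame
    merged: pd.DataFrame
    summary: pd.DataFrame
    proteome: Dict[str, str]

    @property
    def n_expected_forms(self) -> int:
        gt = self.ground_truth_signals
        detectable = gt[~gt["missing"]].groupby(["peptide_id", "run_id", "z"]).size()
        return int((detectable >= 2).sum())

    def detected_forms(self) -> int:
        return len(self.groups)


def run_scenario(
    seed: int,
    n_proteins: int = 40,
    effect: float = 0.35,
    cv: float = 0.15,
    n_reference: int = 6,
    n_treated: int = 6,
    non_product_fraction: float = 0.1,
    tags_per_run: int = 4,
    params: Optional[SpectrumParams] = None,
    model: Optional[DegradomeModel] = None,
    high_cap: Optional[float] = 5.0,
) -> ScenarioResult:
    """Simulate a two-condition study and push it through the full pipeline."""
    ss = np.random.SeedSequence(seed)
    s_prot, s_deg, s_ab, s_render = [np.random.default_rng(s) for s in ss.spawn(4)]
    proteome = simulate_proteome(n_proteins, seed=s_prot)
    peptides, truth = simulate_degradome(proteome, model or DegradomeModel(), seed=s_deg)
    design = EffectDesign(
        conditions={"control": n_reference, "treated": n_treated},
        reference="control",
        effects={"control": 1.0, "treated": effect},
        non_product_fraction=non_product_fraction,
        cv=cv,
    )
    abundances, effects = simulate_abundances(peptides, truth, design, seed=s_ab)
    scheme = LabelingScheme.balanced(design.conditions, "control", tags_per_run)
    params = params or SpectrumParams(**BENCHMARK_SPECTRUM)
    runs, gt = render_runs(abundances, truth, peptides, scheme, params, seed=s_render)

    idents = truth[["peptide_id", "sequence", "protein_id", "n_term_acetylated"]]
    groups = []
    for run in runs:
        clusters = detect_isotope_clusters(run)
        found = find_peak_groups(
            clusters, scheme.tags_in_run(run.run_id), run_id=run.run_id
        )
        flag_overlaps(found, clusters)
        groups.extend(found)
    peptide_ids = match_identifications(groups, idents)
    ratios = quantify_groups(groups, scheme, peptide_ids, high=high_cap)
    merged = merge_forms_frame(ratios)
    summary = summarize(merged, scheme.reference)
    summary = summary.merge(effects[["peptide_id", "exempt"]], on="peptide_id", how="left")
    return ScenarioResult(
        truth=truth,
        effects=effects,
        ground_truth_signals=gt,
        scheme=scheme,
        groups=groups,
        peptide_ids=peptide_ids,
        ratios=ratios,
        merged=merged,
        summary=summary,
        proteome=proteome,
    )


def roundtrip_scenario(seed: int, n_proteins: int = 10) -> ScenarioResult:
    """Noise-free study (no jitter, no noise, no detection limit): the
    detector must recover every rendered peak group and every design ratio
    exactly."""
    return run_scenario(
        seed,
        n_proteins=n_proteins,
        cv=0.0,
        n_reference=2,
        n_treated=3,
        non_product_fraction=0.0,
        tags_per_run=5,
        params=SpectrumParams(),  # all noise terms zero
    )


def recovery_scenario(seed: int) -> ScenarioResult:
    """The shipped parameter-recovery benchmark: ~200 peptides, 6 + 6
    replicates, effect 0.35, replicate CV 0.15, benchmark spectral noise."""
    return run_scenario(seed)


def recovery_stats(result: ScenarioResult, effect: float = 0.35, rel_tol: float = 0.15):
    """Fraction of affected peptides whose estimated mean ratio lies within
    ``rel_tol`` of the design effect, plus the exempt-peptide centre."""
    t = result.summary[
        (result.summary["condition"] == "treated") & result.summary["exempt"].notna()
    ]
    affected = t[~t["exempt"].astype(bool)]
    exempt = t[t["exempt"].astype(bool)]
    within = (affected["mean"] - effect).abs() / effect <= rel_tol
    return {
        "n_affected": int(len(affected)),
        "n_within": int(within.sum()),
        "fraction_within": float(within.mean()) if len(affected) else float("nan"),
        "exempt_center": float(exempt["mean"].mean()) if len(exempt) else float("nan"),
    }


def p1_recovery(seed: int, n_proteins: int = 1100, per_protein: int = 5):
    """Generate ~10,000 cleavage sites and recover the P1 table through
    peptide location + site enumeration (not from ground truth)."""
    ss = np.random.SeedSequence(seed)
    s_prot, s_deg = [np.random.default_rng(s) for s in ss.spawn(2)]
    model = DegradomeModel(n_peptides_per_protein=per_protein)
    proteome = simulate_proteome(n_proteins, seed=s_prot)
    peptides, truth = simulate_degradome(proteome, model, seed=s_deg)
    observations = truth[["sequence", "protein_id", "n_term_acetylated"]].copy()
    observations["category"] = "decrease"
    table, sites = p1_frequency_table(observations, proteome)
    prop = table.proportions["decrease"]
    hydro = float(prop[list(HYDROPHOBIC)].sum())
    target = sum(model.p1_weights[r] for r in HYDROPHOBIC)
    n_sites = int(table.total_sites()["decrease"])
    sigma = float(np.sqrt(target * (1 - target) / n_sites))
    return {
        "n_sites": n_sites,
        "hydrophobic_fraction": hydro,
        "target_fraction": float(target),
        "binomial_sigma": sigma,
        "weights": model.p1_weights,
        "proportions": prop,
    }
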