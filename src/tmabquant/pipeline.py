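"""End-to-end pipeline: (simulate) → detect → quantify → cleavage → report.

Each stage reads and writes plain TSV so intermediate results are inspectable
and every reported number is re-derivable from the written tables.  A manifest
records the config hash, seed, and row counts of every artifact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chemistry import DEFAULT_CONSTANTS, MassConstants, Peptide, count_tmab_labels, peptide_neutral_mass
from .cleavage import p1_frequency_table
from .config import ConfigError, PipelineConfig
from .detect import (
    PeakGroup,
    SpectrumRun,
    detect_isotope_clusters,
    find_peak_groups,
    flag_overlaps,
    groups_to_frame,
    read_centroid_tsv,
    write_centroid_tsv,
)
from .quantify import (
    RatioRecord,
    UnquantifiableGroupError,
    merge_forms_frame,
    records_to_frame,
    replicate_ratios,
    summarize,
)
from .report import heatmap_matrix, plot_heatmap, plot_rank_series, rank_plot_data
from .scheme import LabelingScheme
from .synthetic import (
    DegradomeModel,
    EffectDesign,
    SpectrumParams,
    read_fasta,
    render_runs,
    simulate_abundances,
    simulate_degradome,
    simulate_proteome,
    write_fasta,
)

__all__ = ["match_identifications", "quantify_groups", "run_pipeline"]


def match_identifications(
    groups: Sequence[PeakGroup],
    identifications: pd.DataFrame,
    ppm_tol: float = 10.0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> List[Optional[str]]:
    """Assign each peak group the identification matching its inferred neutral
    mass (within ``ppm_tol``) and label count, or None.

    ``identifications`` needs columns peptide_id, sequence, n_term_acetylated;
    optional mod_mass (summed variable-modification mass).
    """
    ids = identifications.copy()
    masses = []
    labels = []
    for row in ids.itertuples(index=False):
        pep = Peptide(
            sequence=row.sequence,
            n_term_acetylated=bool(getattr(row, "n_term_acetylated", False)),
        )
        m = peptide_neutral_mass(pep, constants) + float(getattr(row, "mod_mass", 0.0) or 0.0)
        masses.append(m)
        labels.append(count_tmab_labels(pep))
    masses = np.asarray(masses)
    labels = np.asarray(labels)
    out: List[Optional[str]] = []
    for g in groups:
        cand = np.nonzero(labels == g.n_labels)[0]
        if cand.size == 0:
            out.append(None)
            continue
        d = np.abs(masses[cand] - g.neutral_mass)
        best = int(cand[np.argmin(d)])
        tol = masses[best] * ppm_tol * 1e-6
        out.append(str(ids.iloc[best]["peptide_id"]) if d.min() <= tol else None)
    return out


def quantify_groups(
    groups: Sequence[PeakGroup],
    scheme: LabelingScheme,
    peptide_ids: Optional[Sequence[Optional[str]]] = None,
    low: float = 0.20,
    high: Optional[float] = 5.0,
) -> pd.DataFrame:
    """Replicate ratio records for all quantifiable groups, as a tidy frame."""
    records: List[RatioRecord] = []
    if peptide_ids is None:
        peptide_ids = [None] * len(groups)
    for g, pid in zip(groups, peptide_ids):
        try:
            records.extend(replicate_ratios(g, scheme, peptide_id=pid, low=low, high=high))
        except UnquantifiableGroupError:
            continue
    return records_to_frame(records)


def _simulate_inputs(cfg: Mapping, seed: int, out: Path) -> Dict[str, object]:
    """Generate FASTA, identifications, scheme and peak lists per config."""
    ss = np.random.SeedSequence(seed)
    s_prot, s_deg, s_ab, s_render = [np.random.default_rng(s) for s in ss.spawn(4)]
    proteome = simulate_proteome(
        int(cfg.get("n_proteins", 30)),
        tuple(cfg.get("protein_length_range", (250, 500))),
        seed=s_prot,
    )
    model = DegradomeModel(
        p1_weights=cfg.get("p1_weights") or DegradomeModel().p1_weights,
        length_range=tuple(cfg.get("length_range", (6, 30))),
        n_peptides_per_protein=int(cfg.get("n_peptides_per_protein", 5)),
        acetylated_nterm_prob=float(cfg.get("acetylated_nterm_prob", 0.5)),
        terminal_fraction=float(cfg.get("terminal_fraction", 0.15)),
    )
    peptides, truth = simulate_degradome(proteome, model, seed=s_deg)
    design = EffectDesign(
        conditions=dict(cfg["conditions"]),
        reference=cfg["reference"],
        effects={k: float(v) for k, v in cfg["effects"].items()},
        non_product_fraction=float(cfg.get("non_product_fraction", 0.1)),
        cv=float(cfg.get("cv", 0.15)),
    )
    abundances, effects = simulate_abundances(peptides, truth, design, seed=s_ab)
    scheme = LabelingScheme.balanced(
        design.conditions, design.reference, int(cfg.get("tags_per_run", 5))
    )
    params = SpectrumParams(**cfg.get("spectrum", {}))
    runs, ground_truth = render_runs(
        abundances, truth, peptides, scheme, params, seed=s_render
    )

    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_fasta(proteome, inputs / "proteome.fasta")
    idents = truth[
        ["peptide_id", "sequence", "protein_id", "n_term_acetylated", "n_labels"]
    ].copy()
    idents.to_csv(inputs / "identifications.tsv", sep="\t", index=False)
    scheme.to_yaml(inputs / "scheme.yaml")
    write_centroid_tsv(runs, inputs / "peaks.tsv")
    truth.to_csv(inputs / "ground_truth_peptides.tsv", sep="\t", index=False)
    effects.to_csv(inputs / "ground_truth_effects.tsv", sep="\t", index=False)
    ground_truth.to_csv(inputs / "ground_truth_signals.tsv", sep="\t", index=False)
    return {
        "runs": runs,
        "proteome": proteome,
        "identifications": idents,
        "scheme": scheme,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, Path]:
    """Execute all stages and write artifacts into ``out_dir``.

    Deterministic for a fixed config and seed: rerunning produces identical
    tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tol = config.tolerances
    caps = config.caps

    if config.simulate is not None:
        staged = _simulate_inputs(config.simulate, config.seed, out)
        runs: List[SpectrumRun] = staged["runs"]
        proteome = staged["proteome"]
        identifications = staged["identifications"]
        scheme = staged["scheme"]
    else:
        paths = config.inputs
        runs = read_centroid_tsv(paths["runs"])
        proteome = read_fasta(paths["fasta"])
        identifications = pd.read_csv(paths["identifications"], sep="\t")
        scheme = LabelingScheme.from_yaml(paths["scheme"])

    # -- detect ----------------------------------------------------------
    z_range = tuple(range(1, int(tol["z_max"]) + 1))
    all_groups: List[PeakGroup] = []
    for run in runs:
        clusters = detect_isotope_clusters(
            run, z_range, tol["ppm"], tol["rt"], int(tol["max_isotopomers"])
        )
        groups = find_peak_groups(
            clusters,
            scheme.tags_in_run(run.run_id),
            run_id=run.run_id,
            max_labels=int(tol["max_labels"]),
            ppm_tol=tol["ppm"],
            rt_tol=tol["rt"],
        )
        flag_overlaps(groups, clusters, tol["ppm"], tol["rt"])
        all_groups.extend(groups)
    pep_ids = match_identifications(all_groups, identifications, tol["ppm"])
    groups_frame = groups_to_frame(all_groups)
    groups_frame["peptide_id"] = [
        pep_ids[i] for i in groups_frame["group_id"]
    ] if len(groups_frame) else []
    artifacts: Dict[str, Path] = {}
    artifacts["groups"] = out / "groups.tsv"
    groups_frame.to_csv(artifacts["groups"], sep="\t", index=False)

    # -- quantify --------------------------------------------------------
    ratios = quantify_groups(all_groups, scheme, pep_ids, caps["low"], caps["high"])
    artifacts["ratios"] = out / "ratios.tsv"
    ratios.to_csv(artifacts["ratios"], sep="\t", index=False)
    merged = merge_forms_frame(ratios)
    artifacts["merged"] = out / "merged.tsv"
    merged.to_csv(artifacts["merged"], sep="\t", index=False)
    summary = summarize(merged, scheme.reference)
    id_cols = identifications.set_index("peptide_id")
    summary["sequence"] = summary["peptide_id"].map(id_cols["sequence"])
    summary["protein_id"] = summary["peptide_id"].map(id_cols["protein_id"])
    artifacts["summary"] = out / "summary.tsv"
    summary.to_csv(artifacts["summary"], sep="\t", index=False)

    # -- cleavage --------------------------------------------------------
    obs_rows = []
    acet = id_cols["n_term_acetylated"].to_dict() if "n_term_acetylated" in id_cols else {}
    counts_per_obs = (
        merged.groupby(["peptide_id", "condition"])["ratio"].count()
        if config.counting_mode == "per_replicate"
        else None
    )
    for row in summary.itertuples(index=False):
        if row.condition == scheme.reference:
            continue
        n_obs = (
            int(counts_per_obs.get((row.peptide_id, row.condition), 0))
            if counts_per_obs is not None
            else 1
        )
        for _ in range(n_obs):
            obs_rows.append(
                {
                    "sequence": row.sequence,
                    "protein_id": row.protein_id,
                    "n_term_acetylated": bool(acet.get(row.peptide_id, False)),
                    "category": row.category,
                }
            )
    observations = pd.DataFrame(
        obs_rows, columns=["sequence", "protein_id", "n_term_acetylated", "category"]
    )
    freq, sites = p1_frequency_table(observations, proteome)
    artifacts["sites"] = out / "cleavage_sites.tsv"
    sites.to_csv(artifacts["sites"], sep="\t", index=False)
    artifacts["p1_counts"] = out / "p1_counts.tsv"
    freq.to_tsv(artifacts["p1_counts"])
    artifacts["p1_proportions"] = out / "p1_proportions.tsv"
    prop = freq.proportions
    prop.index.name = "residue"
    prop.to_csv(artifacts["p1_proportions"], sep="\t")
    artifacts["p1_classes"] = out / "p1_classes.tsv"
    cls = freq.class_fractions()
    cls.index.name = "residue_class"
    cls.to_csv(artifacts["p1_classes"], sep="\t")

    # -- report ----------------------------------------------------------
    rank = rank_plot_data(merged, scheme.reference)
    artifacts["rank_data"] = out / "rank_plot.tsv"
    rank.to_csv(artifacts["rank_data"], sep="\t", index=False)
    plot_rank_series(rank, out / "rank_plot.svg")
    heat = heatmap_matrix(merged)
    artifacts["heatmap_data"] = out / "heatmap.tsv"
    heat.to_csv(artifacts["heatmap_data"], sep="\t")
    if len(heat):
        plot_heatmap(heat, out / "heatmap.svg")

    manifest = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "counting_mode": config.counting_mode,
        "rows": {name: int(pd.read_csv(p, sep="\t").shape[0]) for name, p in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = manifest_path
    return artifacts
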