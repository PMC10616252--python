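"""End-to-end orchestration.

Runs the full workflow on simulated or user-supplied data: load/simulate
-> absorption labels -> diversity + host-variable effect sizes -> genus
ranking -> learning curve -> biomarker selection -> host-variable
encoding and fusion -> tuned model -> cross-batch transfer -> hybrid
calibration -> shared-feature cross-cohort refinement.  Every stage
writes a TSV/JSON artifact into the run directory, and a provenance
manifest records the config hash, seeds and artifact list.  Identical
config + seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from .data import align, read_abundance, read_metadata
from .encoding import EncodingSpec, bin_age, bin_bmi, one_hot_encode
from .features import learning_curve, rank_features, select_biomarkers, \
    shared_biomarkers
from .model import CalibrationCurve, calibrate_hybrid, cross_cohort_refine, \
    train_bundle, transfer_evaluate
from .simulate import SyntheticSpec, derive_absorption_labels, \
    generate_cohort, spec_from_dict, write_cohort

logger = logging.getLogger(__name__)

SCAN_VARIABLES = ["class", "gender", "age_group", "bmi_group", "probiotics",
                  "health_status"]


@dataclass
class PipelineConfig:
    """Everything the pipeline consumes, round-trippable through YAML."""

    abundance_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None           # SyntheticSpec fields
    threshold_pct: float = 10.0
    top_k: int = 10
    alpha: float = 0.01
    n_permutations: int = 999
    n_mix_values: list[int] = field(default_factory=lambda: [5, 10, 15, 20, 25, 30])
    n_repeats: int = 5
    test_fraction: float = 0.3
    cv_folds: int = 5
    learning_curve_k: list[int] = field(
        default_factory=lambda: [1, 3, 5, 8, 10, 15, 20, 30, 49])
    seed: int = 0
    out_dir: str = "sehybrid_run"
    make_plots: bool = True

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def to_yaml(self, path) -> None:
        Path(path).write_text(self.to_yaml_str())

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml_str().encode()).hexdigest()


def demo_config(out_dir: str = "sehybrid_demo", seed: int = 7,
                fast: bool = True) -> PipelineConfig:
    """A desk-scale synthetic configuration exercising every stage:
    three batches over two regions, five planted discriminative genera
    of which three are region-stable, and a visible batch shift."""
    synthetic = {
        "n_genera": 49,
        "n_samples_per_batch": [120, 44, 40] if fast else [156, 43, 40],
        "n_batches": 3,
        "n_regions": 2,
        "batch_to_region": {0: 0, 1: 0, 2: 1},
        "signal_genera": list(range(10)),
        "stable_signal_genera": [0, 1, 2],
        "signal_effect": 0.8,
        "batch_shift_sd": 0.8,
        "region_shift_sd": 0.6,
        "seed": seed,
    }
    return PipelineConfig(synthetic=synthetic, seed=seed, out_dir=out_dir,
                          n_permutations=199,
                          learning_curve_k=[1, 3, 5, 10, 20, 49])


def _json_safe(x):
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set)):
        return [_json_safe(v) for v in sorted(x)] if isinstance(x, set) \
            else [_json_safe(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        return None if x is None or not np.isfinite(x) else float(x)
    return x


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    if config.synthetic is None and not (config.abundance_path
                                         and config.metadata_path):
        raise ValueError("config needs either synthetic spec or data paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    summary: dict = {}

    def save_tsv(df: pd.DataFrame, name: str, **kw):
        df.to_csv(out / name, sep="\t", float_format="%.10g", **kw)
        artifacts.append(name)

    # -- stage: load or simulate -------------------------------------------
    if config.synthetic is not None:
        spec = spec_from_dict(config.synthetic)
        table, meta, truth = generate_cohort(spec)
        write_cohort(out / "cohort", table, meta, truth)
        artifacts += [f"cohort/{p.name}" for p in sorted((out / "cohort").iterdir())]
    elif config.abundance_path and config.metadata_path:
        table = read_abundance(config.abundance_path)
        meta = read_metadata(config.metadata_path)
    else:
        raise ValueError("config needs either synthetic spec or data paths")

    # -- stage: absorption labels ------------------------------------------
    labels = derive_absorption_labels(meta, config.threshold_pct)
    meta = meta.loc[labels.index]
    table, meta = align(table, meta)
    labels = labels.loc[meta.index]
    save_tsv(labels.to_frame(), "labels.tsv", index_label="sample_id")
    summary["n_samples"] = len(labels)
    summary["class_counts"] = labels.value_counts().to_dict()
    logger.info("labels at %.1f%%: %s", config.threshold_pct,
                summary["class_counts"])

    scan_meta = meta.copy()
    scan_meta["class"] = labels
    scan_meta["age_group"] = [bin_age(a) for a in meta["age"]]
    scan_meta["bmi_group"] = [bin_bmi(b) for b in meta["bmi"]]

    # -- stage: diversity ---------------------------------------------------
    alpha_df = dv.alpha_diversity(table)
    save_tsv(alpha_df, "alpha_diversity.tsv", index_label="sample_id")
    dm = dv.bray_curtis(table)
    dv.write_distance_matrix(dm, out / "bray_curtis.tsv")
    artifacts.append("bray_curtis.tsv")

    variables = [v for v in SCAN_VARIABLES if scan_meta[v].nunique() > 1]
    for extra in ("batch", "region"):
        if scan_meta[extra].nunique() > 1:
            variables.append(extra)
    scan = dv.effect_size_scan(dm, scan_meta, variables,
                               n_permutations=config.n_permutations,
                               seed=config.seed)
    scan_df = dv.scan_to_frame(scan)
    save_tsv(scan_df, "effect_sizes.tsv", index=False)
    summary["effect_sizes"] = {r.variable: {"r_squared": r.r_squared,
                                            "p_value": r.p_value}
                               for r in scan}

    # -- stage: batch layout -------------------------------------------------
    batches = list(dict.fromkeys(meta["batch"]))
    base_batch = batches[0]
    base_ids = meta.index[meta["batch"] == base_batch]
    base_table = table.subset_samples(base_ids)
    base_meta = meta.loc[base_ids]
    base_y = labels.loc[base_ids]
    base_region = base_meta["region"].iloc[0]
    summary["base_batch"] = base_batch

    # -- stage: ranking + learning curve on the base batch -------------------
    ranking = rank_features(base_table.data, base_y, seed=config.seed)
    save_tsv(ranking.to_frame(), "ranking.tsv")
    ks = sorted({min(k, len(ranking)) for k in config.learning_curve_k})
    curve = learning_curve(ranking, base_table.data, base_y, ks,
                           cv_folds=config.cv_folds, seed=config.seed)
    save_tsv(pd.DataFrame(curve, columns=["k", "mean_cv_auc"]),
             "learning_curve.tsv", index=False)

    biomarkers = select_biomarkers(ranking, k=min(config.top_k, len(ranking)))
    (out / "biomarkers.txt").write_text("\n".join(biomarkers) + "\n")
    artifacts.append("biomarkers.txt")
    summary["biomarkers"] = biomarkers

    # -- stage: the three base-batch models (all genera / biomarkers / fused)
    enc = EncodingSpec()
    all_bundle = train_bundle(base_table, base_meta, base_y,
                              use_metadata=False, cv_folds=config.cv_folds,
                              seed=config.seed, source=f"{base_batch}-all-genus")
    bio_bundle = train_bundle(base_table, base_meta, base_y,
                              genus_subset=biomarkers, use_metadata=False,
                              cv_folds=config.cv_folds, seed=config.seed,
                              source=f"{base_batch}-biomarkers")
    fused_bundle = train_bundle(base_table, base_meta, base_y,
                                genus_subset=biomarkers, encoding=enc,
                                use_metadata=True, cv_folds=config.cv_folds,
                                seed=config.seed, source=f"{base_batch}-fused")
    summary["cv_auc"] = {"all_genus": all_bundle.cv_auc,
                         "biomarkers": bio_bundle.cv_auc,
                         "fused": fused_bundle.cv_auc}
    summary["hyperparams"] = fused_bundle.hyperparams
    fused_bundle.save(out / "model")
    artifacts += [f"model/{p.name}" for p in sorted((out / "model").iterdir())]

    # -- stage: cross-batch transfer + hybrid calibration --------------------
    same_region = [b for b in batches[1:]
                   if meta.loc[meta["batch"] == b, "region"].iloc[0] == base_region]
    if same_region:
        nb = same_region[0]
        nb_ids = meta.index[meta["batch"] == nb]
        nb_table, nb_meta = table.subset_samples(nb_ids), meta.loc[nb_ids]
        nb_y = labels.loc[nb_ids]
        rep = transfer_evaluate(fused_bundle, nb_table, nb_meta, nb_y)
        summary["transfer_auc_new_batch"] = rep.auc
        base_X = fused_bundle.recipe.build(base_table, base_meta)
        nb_X = fused_bundle.recipe.build(nb_table, nb_meta)
        feasible = [n for n in config.n_mix_values
                    if n <= len(nb_X) - round(config.test_fraction * len(nb_X))]
        cal = calibrate_hybrid(base_X, base_y, nb_X, nb_y,
                               n_mix_values=feasible,
                               test_fraction=config.test_fraction,
                               n_repeats=config.n_repeats,
                               hyperparams=fused_bundle.hyperparams,
                               seed=config.seed)
        save_tsv(cal.to_frame(), "calibration_curve.tsv", index=False)
        summary["calibration"] = cal.points
        if config.make_plots:
            _plot_curves(out, curve, cal)
            artifacts += ["learning_curve.png", "calibration_curve.png"]

    # -- stage: cross-cohort shared-feature refinement ------------------------
    other_region_ids = meta.index[meta["region"] != base_region]
    if len(other_region_ids) and labels.loc[other_region_ids].nunique() > 1:
        coh1_ids = meta.index[meta["region"] == base_region]
        coh1_table, coh1_meta = table.subset_samples(coh1_ids), meta.loc[coh1_ids]
        coh1_y = labels.loc[coh1_ids]
        tgt_table = table.subset_samples(other_region_ids)
        tgt_meta = meta.loc[other_region_ids]
        tgt_y = labels.loc[other_region_ids]

        per_batch_rankings = []
        for b in batches:
            ids_b = meta.index[meta["batch"] == b]
            y_b = labels.loc[ids_b]
            if len(ids_b) >= 10 and y_b.nunique() > 1:
                per_batch_rankings.append(
                    rank_features(table.subset_samples(ids_b).data, y_b,
                                  seed=config.seed))
        if len(per_batch_rankings) >= 2:
            shared = shared_biomarkers(per_batch_rankings, k=config.top_k)
        else:
            shared = set(biomarkers)
        summary["shared_biomarkers"] = sorted(shared)

        coh1_bundle = train_bundle(coh1_table, coh1_meta, coh1_y,
                                   genus_subset=biomarkers, encoding=enc,
                                   hyperparams=fused_bundle.hyperparams,
                                   cv_folds=config.cv_folds, seed=config.seed,
                                   source="cohort1-fused")
        naive = transfer_evaluate(coh1_bundle, tgt_table, tgt_meta, tgt_y)
        summary["cross_cohort_naive_auc"] = naive.auc
        if shared:
            refined = cross_cohort_refine(
                coh1_table, coh1_meta, coh1_y, shared, tgt_table, tgt_meta,
                tgt_y, encoding=enc, hyperparams=fused_bundle.hyperparams,
                cv_folds=config.cv_folds, seed=config.seed)
            summary["cross_cohort_refined_auc"] = refined.auc

    # -- manifest -------------------------------------------------------------
    (out / "summary.json").write_text(
        json.dumps(_json_safe(summary), indent=2, sort_keys=True) + "\n")
    artifacts.append("summary.json")
    config.to_yaml(out / "config.yaml")
    artifacts.append("config.yaml")
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "artifacts": sorted(set(artifacts))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for name in manifest["artifacts"]:
        if not (out / name).exists():
            raise RuntimeError(f"manifest artifact missing: {name}")
    return out


def _plot_curves(out: Path, lcurve: list[tuple[int, float]],
                 cal: CalibrationCurve) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ks, aucs = zip(*lcurve)
    ax.plot(ks, aucs, "o-")
    ax.set_xlabel("top-k genera")
    ax.set_ylabel("mean CV AUC")
    ax.set_title("Feature-refinement learning curve")
    fig.tight_layout()
    fig.savefig(out / "learning_curve.png", metadata={})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    df = cal.to_frame()
    ax.errorbar(df["n_mixed"], df["auc_mean"], yerr=df["auc_sd"], fmt="o-")
    ax.set_xlabel("new-batch samples mixed (n)")
    ax.set_ylabel("test AUC")
    ax.set_title("Hybrid calibration")
    fig.tight_layout()
    fig.savefig(out / "calibration_curve.png", metadata={})
    plt.close(fig)
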