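"""End-to-end orchestration: counts -> normalization -> DE -> classes ->
enrichment -> regulator nomination, plus recovery scoring against planted
truth.

The pipeline is driven by a flat key/value config (YAML mapping). Every
statistical threshold is a config key whose default matches the analysis it
reproduces: NB dispersion 0.1, raw p < 0.05, |log2FC| > 0.75, average
log2CPM > 0, Wilcoxon shift p < 0.05. Outputs are plain TSV/JSON files; a
structured log records feature counts at each stage. Runs are idempotent:
the same config and seed give byte-identical outputs.

Config keys
-----------
simulate (bool, default true); when false: mrna_counts, mirna_counts,
design, targets (input TSV paths). Simulation keys mirror
:class:`mirtraj.simulate.SimulationConfig` field names. Analysis keys:
dispersion, p_max, lfc_min, logcpm_min, prior_count, use_fdr, min_targets,
shift_p_threshold, gene_sets (optional GMT path), seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .classify import CLASSES, class_trajectories, classify_features
from .de import Contrast, call_de, nb_exact_test, venn_partition
from .enrichment import read_gene_sets
from .normalize import log_cpm, standardize_features, tmm_factors
from .regulators import (anticorrelated_target_enrichment, nominate_regulators,
                         pair_correlations, regulator_shift_test)
from .simulate import PlantedTruth, SimulationConfig, simulate_dataset

__all__ = ["load_config", "run_pipeline", "evaluate_recovery",
           "RunArtifacts", "RecoveryMetrics", "default_contrasts"]

ANALYSIS_DEFAULTS = {
    "simulate": True,
    "dispersion": 0.1,
    "p_max": 0.05,
    "lfc_min": 0.75,
    "logcpm_min": 0.0,
    "prior_count": 0.5,
    "use_fdr": False,
    "min_targets": 5,
    "shift_p_threshold": 0.05,
    "gene_sets": None,
}


@dataclass(frozen=True)
class RunArtifacts:
    out_dir: Path
    paths: dict
    metadata: dict


@dataclass(frozen=True)
class RecoveryMetrics:
    """Exact set-arithmetic scores of the run against planted truth."""

    regulator_recall: float
    regulator_precision: float | None
    class_accuracy: float          # planted four-class features correctly classified
    null_class_rate: float         # truly-null features given any class
    per_class: dict                # class -> {"sensitivity": ..., "specificity": ...}
    de_type1: dict                 # contrast -> raw DE call rate among null features


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key/value mapping")
    return cfg


def _split_config(config: dict) -> tuple[SimulationConfig, dict]:
    sim_fields = {f.name for f in dc_fields(SimulationConfig)}
    sim_kwargs = {k: v for k, v in config.items() if k in sim_fields}
    analysis = dict(ANALYSIS_DEFAULTS)
    unknown = set(config) - sim_fields - set(ANALYSIS_DEFAULTS) - {
        "mrna_counts", "mirna_counts", "design", "targets"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    analysis.update({k: v for k, v in config.items() if k in ANALYSIS_DEFAULTS})
    if "seed" in config:
        sim_kwargs["seed"] = int(config["seed"])
    return SimulationConfig(**sim_kwargs), analysis


def default_contrasts(design: pd.DataFrame) -> dict:
    """The two contrasts the trajectory classes derive from, plus the
    per-genotype differentiation contrasts used for the shared/specific
    partition.

    diff: WT RA vs WT ESC (differentiation response in wild type);
    geno: dKO RA vs WT RA (genotype effect among differentiated cells).
    """
    return {
        "diff": Contrast.from_design(design, "diff",
                                     a={"genotype": "WT", "stage": "ESC"},
                                     b={"genotype": "WT", "stage": "RA"}),
        "geno": Contrast.from_design(design, "geno",
                                     a={"genotype": "WT", "stage": "RA"},
                                     b={"genotype": "dKO", "stage": "RA"}),
        "diff_dko": Contrast.from_design(design, "diff_dko",
                                         a={"genotype": "dKO", "stage": "ESC"},
                                         b={"genotype": "dKO", "stage": "RA"}),
    }


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: dict):
    for key in ("mrna_counts", "mirna_counts", "design", "targets"):
        if key not in config:
            raise ValueError(f"simulate=false requires config key {key!r}")
        if not Path(config[key]).exists():
            raise FileNotFoundError(f"input file not found: {config[key]}")
    return (io.read_counts(config["mrna_counts"]),
            io.read_counts(config["mirna_counts"]),
            io.read_design(config["design"]),
            io.read_target_map(config["targets"]))


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None) -> RunArtifacts:
    """Execute every stage in fixed order, writing all intermediates.

    ``seed`` overrides the config's seed. Raises on the first failing stage
    with the stage named in the exception.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    sim_config, analysis = _split_config(config)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    log_lines: list[str] = []

    def log(stage, message):
        log_lines.append(f"[{stage}] {message}")

    def emit(name, frame, **kwargs):
        path = out_dir / name
        io.write_table(frame, path, **kwargs)
        paths[name] = path

    stage = "inputs"
    try:
        truth: PlantedTruth | None = None
        if analysis["simulate"]:
            dataset = simulate_dataset(sim_config)
            mrna, mirna = dataset.mrna_counts, dataset.mirna_counts
            design, targets = dataset.design, dataset.target_map
            truth = dataset.truth
            io.write_counts(mrna, out_dir / "mrna_counts.tsv")
            io.write_counts(mirna, out_dir / "mirna_counts.tsv")
            io.write_design(design, out_dir / "design.tsv")
            io.write_target_map(targets, out_dir / "targets.tsv")
            truth_table = pd.concat([
                truth.gene_truth.assign(feature_type="gene"),
                truth.mirna_truth.assign(feature_type="mirna"),
            ])
            truth_table["is_regulator"] = truth_table.index.isin(truth.regulator_ids)
            emit("truth.tsv", truth_table.rename_axis("feature_id"),
                 index=True)
            paths.update({n: out_dir / n for n in
                          ("mrna_counts.tsv", "mirna_counts.tsv", "design.tsv",
                           "targets.tsv")})
        else:
            mrna, mirna, design, targets = _load_inputs(config)
        if not mrna.columns.equals(mirna.columns):
            raise ValueError("mRNA and miRNA count matrices cover different samples")
        log(stage, f"genes={len(mrna)} mirnas={len(mirna)} samples={mrna.shape[1]} "
                   f"edges={len(targets)}")

        stage = "normalization"
        mrna_factors = tmm_factors(mrna)
        mirna_factors = tmm_factors(mirna)
        prior = analysis["prior_count"]
        mrna_logcpm = log_cpm(mrna, mrna_factors, prior_count=prior)
        mirna_logcpm = log_cpm(mirna, mirna_factors, prior_count=prior)
        mrna_z, mrna_const = standardize_features(mrna_logcpm)
        mirna_z, mirna_const = standardize_features(mirna_logcpm)
        emit("normalization_factors.tsv",
             pd.DataFrame({"sample_id": mrna.columns,
                           "mrna_tmm": mrna_factors.to_numpy(),
                           "mirna_tmm": mirna_factors.to_numpy()}))
        emit("mrna_logcpm.tsv", mrna_logcpm, index=True, index_label="feature_id")
        emit("mirna_logcpm.tsv", mirna_logcpm, index=True, index_label="feature_id")
        log(stage, f"constant rows: mrna={len(mrna_const)} mirna={len(mirna_const)}")

        stage = "differential_expression"
        contrasts = default_contrasts(design)
        tables, calls = {}, {}
        for kind, counts, factors in (("mrna", mrna, mrna_factors),
                                      ("mirna", mirna, mirna_factors)):
            for cname in ("diff", "geno"):
                table = nb_exact_test(counts, contrasts[cname],
                                      dispersion=analysis["dispersion"],
                                      factors=factors,
                                      prior_count=prior)
                call = call_de(table, p_max=analysis["p_max"],
                               lfc_min=analysis["lfc_min"],
                               logcpm_min=analysis["logcpm_min"],
                               use_fdr=analysis["use_fdr"])
                tables[(kind, cname)] = table
                calls[(kind, cname)] = call
                out = table.copy()
                out["call"] = "none"
                out.loc[out.index.isin(call.up), "call"] = "up"
                out.loc[out.index.isin(call.down), "call"] = "down"
                emit(f"de_{kind}_{cname}.tsv", out.rename_axis("feature_id"),
                     index=True)
                log(stage, f"{kind}/{cname}: tested={len(table)} "
                           f"up={len(call.up)} down={len(call.down)}")
        # shared/specific differentiation responses between genotypes
        diff_dko_table = nb_exact_test(mrna, contrasts["diff_dko"],
                                       dispersion=analysis["dispersion"],
                                       factors=mrna_factors, prior_count=prior)
        diff_dko_call = call_de(diff_dko_table, p_max=analysis["p_max"],
                                lfc_min=analysis["lfc_min"],
                                logcpm_min=analysis["logcpm_min"],
                                use_fdr=analysis["use_fdr"])
        venn = venn_partition(calls[("mrna", "diff")], diff_dko_call)
        emit("venn_diff_wt_vs_dko.tsv", pd.DataFrame([{
            "shared_up": len(venn.shared_up), "shared_down": len(venn.shared_down),
            "wt_only_up": len(venn.a_only_up), "wt_only_down": len(venn.a_only_down),
            "dko_only_up": len(venn.b_only_up), "dko_only_down": len(venn.b_only_down),
            "shared_fraction": venn.shared_fraction}]))
        log(stage, f"differentiation shared fraction={venn.shared_fraction:.4f}")

        stage = "trajectory_classes"
        gene_classes = classify_features(calls[("mrna", "diff")], calls[("mrna", "geno")])
        mirna_classes = classify_features(calls[("mirna", "diff")], calls[("mirna", "geno")])
        emit("classes_mrna.tsv", gene_classes.to_frame().rename_axis("feature_id"),
             index=True)
        emit("classes_mirna.tsv", mirna_classes.to_frame().rename_axis("feature_id"),
             index=True)
        trajectories = class_trajectories(mrna_z, design, gene_classes)
        emit("class_trajectories.tsv", trajectories)
        counts_by_class = gene_classes.value_counts().to_dict()
        log(stage, "mrna classes: " + " ".join(
            f"{c}={counts_by_class.get(c, 0)}" for c in CLASSES))

        stage = "enrichment"
        universe = set(tables[("mrna", "diff")].index[
            tables[("mrna", "diff")]["logCPM"] > analysis["logcpm_min"]])
        if analysis["gene_sets"]:
            collection = read_gene_sets(analysis["gene_sets"], fmt="gmt")
            queries = {cls: set(gene_classes.index[gene_classes == cls]) & universe
                       for cls in CLASSES}
            queries = {k: v for k, v in queries.items() if v}
            enr = enrich_collection(queries, collection, universe)
            emit("class_enrichment.tsv", enr)
            log(stage, f"class enrichment rows={len(enr)}")
        else:
            collection = None
            log(stage, "no gene-set collection configured; skipped")

        stage = "regulators"
        pairs = pair_correlations(mirna_z, mrna_z, targets)
        shift = regulator_shift_test(pairs, min_targets=analysis["min_targets"])
        reg = nominate_regulators(shift, mirna_classes, gene_classes, pairs,
                                  p_threshold=analysis["shift_p_threshold"])
        emit("pair_correlations.tsv", pairs)
        emit("regulators.tsv", reg.rename_axis("mirna_id"), index=True)
        n_cand = int(reg["candidate"].sum()) if len(reg) else 0
        log(stage, f"edges tested={len(pairs)} mirnas tested={len(shift)} "
                   f"candidates={n_cand}")
        if collection is not None:
            target_enr = anticorrelated_target_enrichment(reg, gene_classes,
                                                          collection, universe)
            emit("anticorrelated_target_enrichment.tsv", target_enr)

        stage = "recovery"
        if truth is not None:
            metrics = evaluate_recovery(truth, reg, gene_classes,
                                        de_calls={"diff": calls[("mrna", "diff")],
                                                  "geno": calls[("mrna", "geno")]})
            emit("recovery_metrics.tsv", _recovery_frame(metrics))
            log(stage, f"regulator recall={metrics.regulator_recall:.3f} "
                       f"precision={metrics.regulator_precision}")

        stage = "metadata"
        metadata = {"seed": sim_config.seed, "config_hash": _config_hash(config),
                    "package": "mirtraj", "version": "0.1.0",
                    "n_genes": len(mrna), "n_mirnas": len(mirna),
                    "n_samples": mrna.shape[1]}
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
        paths["run_metadata.json"] = out_dir / "run_metadata.json"
        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        paths["run_log.txt"] = out_dir / "run_log.txt"
        return RunArtifacts(out_dir=out_dir, paths=paths, metadata=metadata)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _recovery_frame(metrics: RecoveryMetrics) -> pd.DataFrame:
    rows = [{"metric": "regulator_recall", "value": metrics.regulator_recall},
            {"metric": "regulator_precision",
             "value": metrics.regulator_precision if metrics.regulator_precision
             is not None else float("nan")},
            {"metric": "class_accuracy", "value": metrics.class_accuracy},
            {"metric": "null_class_rate", "value": metrics.null_class_rate}]
    for cls, d in metrics.per_class.items():
        rows.append({"metric": f"{cls}_sensitivity", "value": d["sensitivity"]})
        rows.append({"metric": f"{cls}_specificity", "value": d["specificity"]})
    for contrast, rate in metrics.de_type1.items():
        rows.append({"metric": f"de_type1_{contrast}", "value": rate})
    return pd.DataFrame(rows)


def evaluate_recovery(truth: PlantedTruth, regulators: pd.DataFrame,
                      gene_classes: pd.Series, de_calls: dict | None = None) -> RecoveryMetrics:
    """Score nominated regulators and class assignments against planted truth.

    All rates are exact set arithmetic. Regulator precision is ``None`` when
    nothing was nominated. ``de_calls`` may map contrast names ("diff",
    "geno") to :class:`mirtraj.de.DECall` objects; for each, the raw DE call
    rate among features with no planted effect in that contrast is reported.
    """
    if len(truth.gene_truth) == 0:
        raise ValueError("planted truth is empty")
    nominated = set(regulators.index[regulators["candidate"]]) if len(regulators) else set()
    true_reg = set(truth.regulator_ids)
    recall = len(nominated & true_reg) / len(true_reg) if true_reg else float("nan")
    precision = (len(nominated & true_reg) / len(nominated)) if nominated else None

    gt = truth.gene_truth["true_class"]
    assigned = gene_classes.reindex(gt.index).fillna("unclassified")
    planted = gt.index[gt.isin(CLASSES)]
    class_accuracy = float((assigned.loc[planted] == gt.loc[planted]).mean()) \
        if len(planted) else float("nan")
    # null = no planted effect in either contrast (features with a single
    # planted effect genuinely respond in one contrast and are excluded)
    fully_null = gt.index[(truth.gene_truth["lfc_diff"] == 0)
                          & (truth.gene_truth["lfc_geno"] == 0)]
    null_class_rate = float(assigned.loc[fully_null].isin(CLASSES).mean()) \
        if len(fully_null) else float("nan")

    per_class = {}
    for cls in CLASSES:
        true_pos = set(gt.index[gt == cls])
        pred_pos = set(assigned.index[assigned == cls])
        sens = len(true_pos & pred_pos) / len(true_pos) if true_pos else float("nan")
        true_neg = set(gt.index) - true_pos
        spec = len(true_neg - pred_pos) / len(true_neg) if true_neg else float("nan")
        per_class[cls] = {"sensitivity": sens, "specificity": spec}

    de_type1 = {}
    if de_calls:
        lfc_col = {"diff": "lfc_diff", "geno": "lfc_geno"}
        for name, call in de_calls.items():
            null_for_contrast = set(gt.index[truth.gene_truth[lfc_col[name]] == 0])
            called = (call.up | call.down) & null_for_contrast
            de_type1[name] = len(called) / len(null_for_contrast) if null_for_contrast else float("nan")

    return RecoveryMetrics(regulator_recall=recall, regulator_precision=precision,
                           class_accuracy=class_accuracy,
                           null_class_rate=null_class_rate,
                           per_class=per_class, de_type1=de_type1)
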