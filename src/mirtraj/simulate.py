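"""Seeded synthetic mRNA/miRNA count data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a 2-genotype (WT, dKO) x 2-stage (ESC, RA) factorial with
``n_reps_per_condition`` replicates per cell, negative-binomial counts
(variance = mu + dispersion * mu^2) on log-normally varying library sizes,
log-normal baseline abundances, planted differentiation and genotype log2
fold-change effects partitioned into the four trajectory classes, and
miRNA -> target repression that couples a functional target's mean to its
regulator miRNA's standardized latent (noise-free) abundance, producing
controlled negative expression correlations.

The expected count is

    mu_gs = lib_s * p_gs,   p_gs  proportional to
            q_g * 2^(x_diff(s) * L_diff_g + x_geno(s) * L_geno_g
                     - repression_strength * z_m(s))

with p_gs renormalized to sum to one within each sample — sequencing
observes proportions, so expected column totals stay at the drawn library
sizes and strong planted effects create exactly the composition bias TMM
normalization is designed to correct. Here x_diff(s) indicates the RA stage, x_geno(s) indicates dKO cells at the
RA stage (the genotype effect manifests upon differentiation, matching a
genotype contrast taken among differentiated cells), and z_m(s) is the
standardized latent log2 abundance of the gene's functional regulator miRNA
(zero for untargeted genes). Regulator miRNAs are planted in the down_down /
down_up classes and their functional targets in up_up / up_down classes;
decoy target-map edges point at genes with no planted effects.

All randomness flows from one ``numpy.random.default_rng(seed)`` generator
in a fixed, documented draw order, so identical configs give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GENOTYPES, STAGES, validate_design

__all__ = ["SimulationConfig", "PlantedTruth", "SyntheticDataset",
           "build_design", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale study in which effects are strong
    (|log2FC| = 2) and dispersion matches the analysis' assumed 0.1, with
    20 regulator miRNAs among 200 and a quarter of target-map edges decoys.
    """

    n_genes: int = 5000
    n_mirnas: int = 200
    n_reps_per_condition: int = 3
    lib_size_mean: float = 1_000_000.0
    lib_size_cv: float = 0.2
    mirna_lib_size_mean: float = 500_000.0
    dispersion_true: float = 0.1
    frac_diff_up: float = 0.15
    frac_diff_down: float = 0.15
    frac_geno_effect: float = 0.6
    effect_lfc_diff: float = 2.0
    effect_lfc_geno: float = 2.0
    n_regulator_mirnas: int = 20
    targets_per_mirna: int = 25
    repression_strength: float = 1.0
    decoy_target_fraction: float = 0.25
    gene_abundance_sdlog: float = 1.2
    mirna_abundance_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_mirnas", "n_reps_per_condition",
                     "n_regulator_mirnas", "targets_per_mirna"):
            if getattr(self, name) < 0 or (name in ("n_genes", "n_mirnas") and getattr(self, name) < 1):
                raise ValueError(f"{name} must be a valid count")
        for name in ("frac_diff_up", "frac_diff_down", "frac_geno_effect",
                     "decoy_target_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_diff_up + self.frac_diff_down > 1:
            raise ValueError("frac_diff_up + frac_diff_down must be <= 1")
        if self.dispersion_true <= 0:
            raise ValueError("dispersion_true must be positive")
        if self.lib_size_mean <= 0 or self.mirna_lib_size_mean <= 0:
            raise ValueError("library size means must be positive")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be non-negative")
        if self.repression_strength < 0:
            raise ValueError("repression_strength must be non-negative")
        if self.targets_per_mirna * max(self.n_regulator_mirnas, 1) > self.n_genes:
            raise ValueError(
                "infeasible config: targets_per_mirna x n_regulator_mirnas exceeds n_genes"
            )
        if self.n_regulator_mirnas > self.n_mirnas:
            raise ValueError("more regulator miRNAs than miRNAs")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth ledger exactly describing the planted structure."""

    gene_truth: pd.DataFrame      # index gene id: true_class, lfc_diff, lfc_geno
    mirna_truth: pd.DataFrame     # index mirna id: true_class, lfc_diff, lfc_geno
    regulator_ids: tuple          # true regulator miRNA ids
    edges: pd.DataFrame           # mirna_id, target_gene_id, functional (bool)


@dataclass(frozen=True)
class SyntheticDataset:
    mrna_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    design: pd.DataFrame
    target_map: pd.DataFrame      # mirna_id, target_gene_id, evidence
    truth: PlantedTruth
    config: SimulationConfig


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic 2x2 factorial design with replicate sample ids.

    Sample ids look like ``WT_ESC_r1``; ordering is genotype-major
    (WT before dKO), stage next (ESC before RA), replicate last.
    """
    if config.n_reps_per_condition < 2:
        raise ValueError("n_reps_per_condition must be >= 2 (contrasts need replication)")
    rows = []
    for genotype in GENOTYPES:
        for stage in STAGES:
            for rep in range(1, config.n_reps_per_condition + 1):
                rows.append({"sample_id": f"{genotype}_{stage}_r{rep}",
                             "genotype": genotype, "stage": stage, "replicate": rep})
    design = pd.DataFrame(rows)
    validate_design(design)
    return design


def _true_class(lfc_diff: float, lfc_geno: float) -> str:
    if lfc_diff == 0 or lfc_geno == 0:
        return "none"
    first = "up" if lfc_diff > 0 else "down"
    second = "up" if lfc_geno > 0 else "down"
    return f"{first}_{second}"


def _plant_effects(rng: np.random.Generator, ids: np.ndarray,
                   config: SimulationConfig, forced_down: np.ndarray) -> pd.DataFrame:
    """Assign per-feature true log2 effects for both contrasts.

    Which features carry effects is random, but the *counts* are
    deterministic functions of the configured fractions: genotype effects go
    to a fixed fraction of each differentiation-direction group, split
    evenly between positive and negative signs, so the four planted classes
    have reproducible sizes. ``forced_down`` ids (regulator miRNAs) always
    get a negative differentiation effect; half of them (rounded up) get a
    negative genotype effect (down_down), the rest positive (down_up).
    """
    n = len(ids)
    lfc_diff = np.zeros(n)
    lfc_geno = np.zeros(n)
    forced_mask = np.isin(ids, forced_down)
    free_idx = np.flatnonzero(~forced_mask)

    n_up = int(round(config.frac_diff_up * len(free_idx)))
    n_down = int(round(config.frac_diff_down * len(free_idx)))
    chosen = rng.choice(free_idx, size=n_up + n_down, replace=False)
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]
    lfc_diff[up_idx] = config.effect_lfc_diff
    lfc_diff[down_idx] = -config.effect_lfc_diff

    for group in (up_idx, down_idx):
        n_geno = int(round(config.frac_geno_effect * len(group)))
        geno_idx = rng.permutation(group)[:n_geno]
        n_pos = n_geno // 2 + (n_geno % 2)
        lfc_geno[geno_idx[:n_pos]] = config.effect_lfc_geno
        lfc_geno[geno_idx[n_pos:]] = -config.effect_lfc_geno

    forced_idx = rng.permutation(np.flatnonzero(forced_mask))
    lfc_diff[forced_idx] = -config.effect_lfc_diff
    n_dd = len(forced_idx) // 2 + (len(forced_idx) % 2)
    lfc_geno[forced_idx[:n_dd]] = -config.effect_lfc_geno   # down_down
    lfc_geno[forced_idx[n_dd:]] = config.effect_lfc_geno    # down_up

    truth = pd.DataFrame({"lfc_diff": lfc_diff, "lfc_geno": lfc_geno}, index=ids)
    truth["true_class"] = [_true_class(d, g) for d, g in zip(lfc_diff, lfc_geno)]
    return truth[["true_class", "lfc_diff", "lfc_geno"]]


def _lognormal_with_mean(rng: np.random.Generator, mean: float, cv: float,
                         size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: NB with variance mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset plus its ground-truth ledger.

    Draw order (fixed for reproducibility): mRNA library sizes, miRNA
    library sizes, gene baseline abundances, miRNA baseline abundances,
    regulator selection, miRNA effect assignment, gene effect assignment,
    target-map sampling, mRNA gamma/Poisson counts, miRNA gamma/Poisson
    counts.
    """
    rng = np.random.default_rng(config.seed)
    design = build_design(config)
    n_samples = len(design)
    gene_ids = np.array([f"gene_{i + 1:05d}" for i in range(config.n_genes)])
    mirna_ids = np.array([f"mir_{i + 1:04d}" for i in range(config.n_mirnas)])

    lib_mrna = _lognormal_with_mean(rng, config.lib_size_mean, config.lib_size_cv, n_samples)
    lib_mirna = _lognormal_with_mean(rng, config.mirna_lib_size_mean, config.lib_size_cv, n_samples)

    q_gene = rng.lognormal(0.0, config.gene_abundance_sdlog, size=config.n_genes)
    q_gene /= q_gene.sum()
    q_mirna = rng.lognormal(0.0, config.mirna_abundance_sdlog, size=config.n_mirnas)
    q_mirna /= q_mirna.sum()

    regulator_ids = np.sort(rng.choice(mirna_ids, size=config.n_regulator_mirnas,
                                       replace=False))
    mirna_truth = _plant_effects(rng, mirna_ids, config, forced_down=regulator_ids)
    gene_truth = _plant_effects(rng, gene_ids, config,
                                forced_down=np.array([], dtype=gene_ids.dtype))

    # condition indicators per sample
    x_diff = (design["stage"] == "RA").to_numpy(dtype=float)
    x_geno = ((design["genotype"] == "dKO") & (design["stage"] == "RA")).to_numpy(dtype=float)

    # target map. Functional edges respect the de-repression logic: a
    # down_down regulator (lost in the mutant) leaves its targets
    # de-repressed, so they rise with the mutation (up_up); a down_up
    # regulator's targets fall with the mutation (up_down). The planted
    # repression term then reinforces, never contradicts, the target's own
    # planted class. Decoy edges point at genes with no planted effects.
    n_func_per = int(round((1 - config.decoy_target_fraction) * config.targets_per_mirna))
    pool_for = {
        "down_down": gene_truth.index[gene_truth["true_class"] == "up_up"].to_numpy(),
        "down_up": gene_truth.index[gene_truth["true_class"] == "up_down"].to_numpy(),
    }
    null_pool = gene_truth.index[(gene_truth["lfc_diff"] == 0)
                                 & (gene_truth["lfc_geno"] == 0)].to_numpy()
    reg_flavor = mirna_truth.loc[regulator_ids, "true_class"] if len(regulator_ids) \
        else pd.Series(dtype=object)
    for flavor, pool in pool_for.items():
        need = n_func_per * int((reg_flavor == flavor).sum())
        if need > len(pool):
            raise ValueError(
                f"infeasible config: {need} functional targets needed for "
                f"{flavor} regulators but only {len(pool)} "
                f"{'up_up' if flavor == 'down_down' else 'up_down'} genes available")
    shuffled_pools = {flavor: rng.permutation(pool)
                      for flavor, pool in pool_for.items()}

    edge_rows = []
    gene_regulator = {}   # gene id -> regulator mirna id (at most one)
    regulator_set = set(regulator_ids)
    cursors = {flavor: 0 for flavor in pool_for}
    for m in mirna_ids:
        is_reg = m in regulator_set
        n_func = n_func_per if is_reg else 0
        n_decoy = config.targets_per_mirna - n_func
        if is_reg:
            flavor = mirna_truth.loc[m, "true_class"]
            pool = shuffled_pools[flavor]
            start = cursors[flavor]
            for g in pool[start:start + n_func]:
                edge_rows.append((m, g, True))
                gene_regulator[g] = m
            cursors[flavor] = start + n_func
        if n_decoy > 0 and len(null_pool) > 0:
            decoys = rng.choice(null_pool, size=min(n_decoy, len(null_pool)), replace=False)
            for g in decoys:
                edge_rows.append((m, g, False))
    edges = pd.DataFrame(edge_rows, columns=["mirna_id", "target_gene_id", "functional"])

    # latent per-sample standardized miRNA abundance (noise-free, population SD)
    latent_log2 = (np.log2(q_mirna)[:, None]
                   + np.outer(mirna_truth["lfc_diff"].to_numpy(), x_diff)
                   + np.outer(mirna_truth["lfc_geno"].to_numpy(), x_geno))
    lat_mean = latent_log2.mean(axis=1, keepdims=True)
    lat_sd = latent_log2.std(axis=1, keepdims=True)
    z_mirna = np.divide(latent_log2 - lat_mean, lat_sd,
                        out=np.zeros_like(latent_log2), where=lat_sd > 0)
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}

    # per-gene per-sample log2 offsets
    gene_offsets = (np.outer(gene_truth["lfc_diff"].to_numpy(), x_diff)
                    + np.outer(gene_truth["lfc_geno"].to_numpy(), x_geno))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for g, m in gene_regulator.items():
        gene_offsets[gene_index[g]] -= config.repression_strength * z_mirna[mirna_index[m]]

    # per-sample renormalization: sequencing observes proportions, so the
    # expected column total stays at the drawn library size and planted
    # effects create the composition bias TMM is meant to correct
    prop_mrna = q_gene[:, None] * 2.0 ** gene_offsets
    prop_mrna /= prop_mrna.sum(axis=0, keepdims=True)
    mu_mrna = lib_mrna[None, :] * prop_mrna
    prop_mirna = q_mirna[:, None] * 2.0 ** (
        np.outer(mirna_truth["lfc_diff"].to_numpy(), x_diff)
        + np.outer(mirna_truth["lfc_geno"].to_numpy(), x_geno))
    prop_mirna /= prop_mirna.sum(axis=0, keepdims=True)
    mu_mirna = lib_mirna[None, :] * prop_mirna

    mrna_counts = pd.DataFrame(_nb_counts(rng, mu_mrna, config.dispersion_true),
                               index=gene_ids, columns=design["sample_id"].to_numpy())
    mirna_counts = pd.DataFrame(_nb_counts(rng, mu_mirna, config.dispersion_true),
                                index=mirna_ids, columns=design["sample_id"].to_numpy())

    target_map = edges[["mirna_id", "target_gene_id"]].copy()
    target_map["evidence"] = np.where(edges["functional"], "functional", "decoy")
    truth = PlantedTruth(gene_truth=gene_truth, mirna_truth=mirna_truth,
                         regulator_ids=tuple(regulator_ids), edges=edges)
    return SyntheticDataset(mrna_counts=mrna_counts, mirna_counts=mirna_counts,
                            design=design, target_map=target_map, truth=truth,
                            config=config)
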