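"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream analyses
assume, with all generating parameters recorded so recovery can be checked:

* a three-arm bulk RNA-seq design (control / disease / treated) in which a
  fraction of genes carry a disease log2 fold change partially undone by
  treatment — the *reversal fraction* rho is the quantity the TLS stage
  estimates (sign-flipped);
* a two-condition time course (vehicle vs. drug at several exposure times)
  with persistence classes controlling at which timepoints a gene responds;
* phenotypes linearly coupled to a per-sample score;
* instrument-level summary statistics for two-sample Mendelian randomization
  with a known causal effect;
* noisy convex mixtures of cell-type expression profiles for deconvolution.

Counts are negative binomial with variance mu + alpha * mu^2 (per-gene
dispersion alpha drawn log-normal), and per-sample library-size factors are
log-uniform in [0.5, 2] so that normalization is non-trivial. Identical
parameters (including the seed) give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, GeneSet, PhenotypeTable, SampleDesign, ValidationError

__all__ = [
    "SimulationParams",
    "TimecourseParams",
    "gen_counts",
    "gen_timecourse",
    "gen_phenotypes",
    "gen_mr_summary",
    "gen_mixture",
]

ARM_CONTROL = "control"
ARM_DISEASE = "disease"
ARM_TREATED = "treated"

#: persistence classes for the time course: at which timepoints the drug
#: effect is nonzero.  "all" = every timepoint, "late" = all but the first,
#: "early" = first timepoint only (transient), "null" = never.
PERSISTENCE_CLASSES = ("all", "late", "early", "null")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the three-arm count simulation.

    Baseline means and NB dispersions are log-normal across genes;
    ``pi_disease`` genes receive a disease effect delta ~ Normal(0, tau^2)
    (log2 units) and the treated arm carries delta * (1 - rho), i.e. a
    fraction ``rho`` of the disease effect is reversed.
    """

    n_genes: int = 10_000
    n_per_arm: int = 10
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 1.0
    dispersion_log_mean: float = math.log(0.08)
    dispersion_log_sd: float = 0.3
    pi_disease: float = 0.2
    tau: float = 2.0
    rho: float = 0.5
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_disease <= 1.0:
            raise ValidationError("pi_disease must be in [0, 1]")
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if ((rho < 0) | (rho > 1)).any():
            raise ValidationError("rho must be in [0, 1]")
        if self.n_genes < 1 or self.n_per_arm < 2:
            raise ValidationError("need n_genes >= 1 and n_per_arm >= 2")


@dataclass(frozen=True)
class TimecourseParams:
    """Parameters of the two-condition time-course simulation."""

    n_genes: int = 2_000
    n_per_group: int = 4
    timepoints: tuple[float, ...] = (6.0, 12.0, 24.0)
    class_probs: tuple[float, ...] = (0.10, 0.10, 0.10, 0.70)  # all/late/early/null
    effect_size: float = 1.0  # |log2FC| for responding genes
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    # isogenic culture replicates: much lower biological dispersion than tissue
    dispersion_log_mean: float = math.log(0.01)
    dispersion_log_sd: float = 0.3
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValidationError("need at least 2 timepoints")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or len(self.class_probs) != 4:
            raise ValidationError("class_probs must be 4 probabilities summing to 1")


def _size_factors(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB counts with variance mean + alpha * mean^2 (alpha broadcast per gene)."""
    if not np.all(np.isfinite(mean)):
        raise ValidationError("non-finite NB means in simulation")
    r = 1.0 / np.maximum(alpha, 1e-12)[:, None]
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, mean.shape), p)


def gen_counts(params: SimulationParams) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Simulate the three-arm design; returns (counts, design, truth).

    Arm effects in log2 units: control 0, disease delta_g, treated
    delta_g * (1 - rho_g); the truth table records delta, rho, the affected
    flag and the implied treated-vs-disease log2FC, -rho_g * delta_g.
    """
    rng = np.random.default_rng(params.seed)
    G, n = params.n_genes, params.n_per_arm

    baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=G)
    alpha = rng.lognormal(params.dispersion_log_mean, params.dispersion_log_sd, size=G)
    affected = rng.random(G) < params.pi_disease
    delta = np.where(affected, rng.normal(0.0, params.tau, size=G), 0.0)
    rho = np.broadcast_to(np.asarray(params.rho, dtype=float), (G,)).copy()

    arms = [ARM_CONTROL] * n + [ARM_DISEASE] * n + [ARM_TREATED] * n
    sample_ids = [f"{a}_{i + 1:02d}" for a in (ARM_CONTROL, ARM_DISEASE, ARM_TREATED)
                  for i in range(n)]
    sf = _size_factors(rng, 3 * n, *params.size_factor_range)

    arm_lfc = np.zeros((G, 3 * n))
    arm_lfc[:, n:2 * n] = delta[:, None]
    arm_lfc[:, 2 * n:] = (delta * (1.0 - rho))[:, None]
    mean = baseline[:, None] * np.exp2(arm_lfc) * sf[None, :]

    counts = _nb_sample(rng, mean, alpha)
    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    cm = CountMatrix(pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                                  columns=sample_ids))
    design = SampleDesign(pd.DataFrame(
        {"arm": arms, "size_factor_true": sf},
        index=pd.Index(sample_ids, name="sample")))
    truth = pd.DataFrame(
        {
            "affected": affected,
            "delta": delta,
            "rho": rho,
            "lfc_disease_vs_control": delta,
            "lfc_treated_vs_disease": -rho * delta,
            "baseline_mean": baseline,
            "dispersion": alpha,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return cm, design, truth


def gen_timecourse(params: TimecourseParams) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Simulate a vehicle-vs-drug time course with persistence classes.

    Each gene is assigned one of ``PERSISTENCE_CLASSES`` and, unless null, a
    direction (+1 up, -1 down under drug); the drug effect at a timepoint is
    ``direction * effect_size`` log2 units when the class makes that
    timepoint active, else 0.  The truth table records class, direction and
    the per-timepoint effect.
    """
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    tps = list(params.timepoints)

    baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=G)
    alpha = rng.lognormal(params.dispersion_log_mean, params.dispersion_log_sd, size=G)
    cls_idx = rng.choice(len(PERSISTENCE_CLASSES), size=G, p=list(params.class_probs))
    cls = np.array(PERSISTENCE_CLASSES)[cls_idx]
    direction = np.where(cls == "null", 0, rng.choice([-1, 1], size=G))

    active = np.zeros((G, len(tps)), dtype=bool)
    active[cls == "all", :] = True
    active[cls == "late", 1:] = True
    active[cls == "early", 0] = True
    effects = active * (direction[:, None] * params.effect_size)

    sample_ids, arms, times = [], [], []
    for t in tps:
        for arm in ("vehicle", "drug"):
            for i in range(params.n_per_group):
                sample_ids.append(f"{arm}_{t:g}h_{i + 1:02d}")
                arms.append(arm)
                times.append(t)
    S = len(sample_ids)
    sf = _size_factors(rng, S, *params.size_factor_range)

    lfc = np.zeros((G, S))
    for j, (arm, t) in enumerate(zip(arms, times)):
        if arm == "drug":
            lfc[:, j] = effects[:, tps.index(t)]
    mean = baseline[:, None] * np.exp2(lfc) * sf[None, :]
    counts = _nb_sample(rng, mean, alpha)

    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    cm = CountMatrix(pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                                  columns=sample_ids))
    design = SampleDesign(pd.DataFrame(
        {"arm": arms, "timepoint": times, "size_factor_true": sf},
        index=pd.Index(sample_ids, name="sample")))
    truth = pd.DataFrame(
        {"persistence_class": cls, "direction": direction,
         **{f"effect_{t:g}h": effects[:, k] for k, t in enumerate(tps)}},
        index=pd.Index(gene_ids, name="gene"),
    )
    return cm, design, truth


def gen_phenotypes(scores: pd.Series, betas: Sequence[float], noise_sd: float,
                   seed: int, names: Sequence[str] | None = None,
                   ) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Phenotypes linearly coupled to a standardized per-sample score.

    phenotype_p = beta_p * z(score) + Normal(0, noise_sd).  Returns the table
    and a truth frame of the generating betas.
    """
    if len(scores) < 3:
        raise ValidationError("need at least 3 samples to generate phenotypes")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    sd = s.std(ddof=0)
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)

    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, dtype=float)
    if names is None:
        names = [f"pheno_{i + 1}" for i in range(len(betas))]
    values = betas[None, :] * z[:, None] + rng.normal(0.0, noise_sd, size=(len(s), len(betas)))
    table = PhenotypeTable(pd.DataFrame(values, index=scores.index, columns=list(names)))
    truth = pd.DataFrame({"beta": betas}, index=pd.Index(list(names), name="phenotype"))
    return table, truth


def gen_mr_summary(n_instruments: int, theta: float, seed: int,
                   beta_exp_sd: float = 0.3, se_exp: float = 0.02,
                   se_out: float = 0.05, pleiotropy_sd: float = 0.0,
                   min_strength: float = 2.0, sample_noise: bool = True,
                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Instrument-level summary statistics with a known causal effect theta.

    True exposure effects are Normal(0, beta_exp_sd^2) truncated away from
    zero at |beta_exp| >= min_strength * se_exp (weak instruments excluded by
    default); true outcome effects are theta * beta_exp plus a balanced
    pleiotropy term.  With ``sample_noise`` the observed effects add
    Normal(0, se^2) estimation noise on both sides; without it the observed
    effects equal the true ones (the reported SEs are unchanged).
    """
    if n_instruments < 1:
        raise ValidationError("need at least 1 instrument")
    if se_exp < 0 or se_out < 0:
        raise ValidationError("SEs must be non-negative")
    rng = np.random.default_rng(seed)

    lo = min_strength * se_exp
    beta_exp = np.empty(n_instruments)
    filled = 0
    while filled < n_instruments:
        draw = rng.normal(0.0, beta_exp_sd, size=2 * (n_instruments - filled) + 8)
        keep = draw[np.abs(draw) >= lo][: n_instruments - filled]
        beta_exp[filled:filled + len(keep)] = keep
        filled += len(keep)

    pleio = rng.normal(0.0, pleiotropy_sd, size=n_instruments) if pleiotropy_sd > 0 else 0.0
    beta_out_true = theta * beta_exp + pleio
    if sample_noise:
        obs_exp = beta_exp + rng.normal(0.0, se_exp, size=n_instruments)
        obs_out = beta_out_true + rng.normal(0.0, se_out, size=n_instruments)
    else:
        obs_exp, obs_out = beta_exp, beta_out_true

    table = pd.DataFrame(
        {
            "beta_exp": obs_exp,
            "se_exp": np.full(n_instruments, se_exp),
            "beta_out": obs_out,
            "se_out": np.full(n_instruments, se_out),
        },
        index=pd.Index([f"rs{i + 1:05d}" for i in range(n_instruments)], name="variant"),
    )
    truth = {"theta": float(theta), "pleiotropy_sd": float(pleiotropy_sd)}
    return table, truth


def gen_mixture(signature: pd.DataFrame, proportions: pd.DataFrame,
                noise_sd: float, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk profiles as convex mixtures of cell-type expression profiles.

    ``signature`` is cell types x genes (linear-scale mean expression);
    ``proportions`` is samples x cell types, each row on the simplex.
    bulk_s = sum_c p_cs * signature_c + Normal(0, noise_sd), clipped at 0.
    Returns (bulk genes x samples, truth proportions).
    """
    P = proportions.to_numpy(dtype=float)
    if (P < 0).any():
        raise ValidationError("proportions must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("proportions must sum to 1 per sample")
    missing = set(proportions.columns) - set(signature.index)
    if missing:
        raise ValidationError(f"cell types missing from signature: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    S = signature.loc[list(proportions.columns)].to_numpy(dtype=float)  # C x G
    bulk = P @ S  # samples x genes
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, None)
    out = pd.DataFrame(bulk.T, index=signature.columns.copy(), columns=list(proportions.index))
    out.index.name = "gene"
    return out, proportions.copy()
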