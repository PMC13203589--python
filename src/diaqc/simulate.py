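"""Two-stage generative model of scWGA + sequencing, with perturbations.

Each heterozygous locus is simulated in two binomial stages: the amplicon
pool ``K ~ Binomial(DIA, p)`` (whole-genome-amplification stage) and the
read counts ``y ~ Binomial(M, K/DIA)`` (sequencing stage). On top of the
baseline the module implements the robustness perturbations used to stress
the estimator:

* locus-to-locus DIA variation (truncated-normal or uniform around a mean),
* reduced sequencing depth and locus counts,
* amplification-stage allelic misreadings at rate ``error_rate``,
* non-diploid allele fractions ``p`` (CNV / aneuploidy).

The baseline scenario is 100,000 independent loci at fixed depth M = 30
and p = 0.5, with accuracy experiments averaged over 100 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import estimation_accuracy

__all__ = [
    "DiaDistributionSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "draw_dia_values",
    "inject_amplification_errors",
    "run_accuracy_experiment",
    "simulate_amplicon_pool",
    "simulate_dataset",
    "simulate_reads",
    "summarize_accuracy",
]


@dataclass(frozen=True)
class DiaDistributionSpec:
    """Locus-level distribution of the actual DIA.

    kind
        ``"fixed"`` — every locus has DIA = ``dia_avg``;
        ``"truncated_normal"`` — ``dia_avg * X`` with ``X ~ N(1, cv)``
        truncated to ``X > truncation_point`` (default 0);
        ``"uniform"`` — ``dia_avg * U(1 - delta, 1 + delta)``.
    Continuous draws are rounded to the nearest integer with a floor of 1
    (binomial sampling needs integer trials).

    The accuracy ground truth is ``dia_avg`` for fixed/uniform and the
    truncated-normal conditional mean ``dia_avg * E[X | X > a]`` with

        E[X | X > a] = mu + sigma * phi((a-mu)/sigma) / (1 - Phi((a-mu)/sigma))

    for the truncated-normal spec (mu = 1, sigma = cv).
    """

    kind: str = "fixed"
    dia_avg: float = 30.0
    cv: float = 0.0
    delta: float = 0.0
    truncation_point: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "truncated_normal", "uniform"}:
            raise ValueError(f"unknown DIA distribution kind: {self.kind!r}")
        if self.dia_avg < 1:
            raise ValueError("dia_avg must be >= 1")
        if not 0.0 <= self.cv <= 1.0:
            raise ValueError("cv must lie in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")

    @property
    def ground_truth(self) -> float:
        """Effective mean DIA against which accuracy is measured."""
        if self.kind == "truncated_normal" and self.cv > 0:
            mu, sigma, a = 1.0, self.cv, self.truncation_point
            z = (a - mu) / sigma
            mult = mu + sigma * stats.norm.pdf(z) / stats.norm.sf(z)
            return self.dia_avg * mult
        return self.dia_avg


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulated scWGA + sequencing experiment."""

    n_loci: int = 100_000
    depth: int | np.ndarray = 30
    allele_p: float | np.ndarray = 0.5
    dia_spec: DiaDistributionSpec = field(default_factory=DiaDistributionSpec)
    error_rate: float = 0.0
    symmetric_errors: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if np.any(np.asarray(self.depth) < 1):
            raise ValueError("depth must be >= 1")
        p = np.asarray(self.allele_p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("allele_p must lie in (0, 1)")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


class SimulatedDataset(NamedTuple):
    """Observations (the estimator's view) plus per-locus ground truth."""

    observations: pd.DataFrame  # chrom, pos, depth_total, depth_alt
    truth: pd.DataFrame  # dia_actual, k_alt, k_alt_after_error
    config: SimulationConfig

    @property
    def ground_truth_dia(self) -> float:
        return self.config.dia_spec.ground_truth


def draw_dia_values(
    spec: DiaDistributionSpec, n: int, seed=None
) -> tuple[np.ndarray, float]:
    """Draw per-locus integer DIA values and return the accuracy ground truth.

    Truncated-normal draws use exact rejection-free sampling via
    ``scipy.stats.truncnorm``; continuous values are rounded to the nearest
    integer and floored at 1.
    """
    rng = np.random.default_rng(seed)
    if spec.kind == "fixed" or (spec.kind == "truncated_normal" and spec.cv == 0.0) or (
        spec.kind == "uniform" and spec.delta == 0.0
    ):
        values = np.full(n, max(1, round(spec.dia_avg)), dtype=np.int64)
        return values, spec.ground_truth
    if spec.kind == "truncated_normal":
        a = (spec.truncation_point - 1.0) / spec.cv
        x = stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=spec.cv, size=n, random_state=rng)
    else:  # uniform
        x = rng.uniform(1.0 - spec.delta, 1.0 + spec.delta, size=n)
    values = np.maximum(1, np.rint(x * spec.dia_avg)).astype(np.int64)
    return values, spec.ground_truth


def simulate_amplicon_pool(dia, p, seed=None, rng=None) -> np.ndarray | int:
    """Sample the tracked-allele amplicon count ``K ~ Binomial(DIA, p)``."""
    dia_arr = np.asarray(dia)
    if not np.issubdtype(dia_arr.dtype, np.integer):
        if not np.all(dia_arr == np.rint(dia_arr)):
            raise ValueError("dia must be integer-valued for binomial sampling")
        dia_arr = dia_arr.astype(np.int64)
    if np.any(dia_arr < 1):
        raise ValueError("dia must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    k = rng.binomial(dia_arr, p)
    return k if np.ndim(dia) else int(k)


def inject_amplification_errors(
    k_alt, dia, error_rate: float, seed=None, rng=None, symmetric: bool = True
):
    """Apply amplification-stage allelic misreadings at rate ``error_rate``.

    Each tracked-allele amplicon is misread as the other allele with
    probability epsilon (``E_A ~ Binomial(K, eps)``); in the default
    symmetric mode the other allele's pool is corrupted the same way
    (``E_B ~ Binomial(DIA - K, eps)``) and ``K' = K - E_A + E_B``. The
    asymmetric mode (``symmetric=False``) corrupts only the tracked pool,
    ``K' = K - E_A``.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    k = np.asarray(k_alt)
    d = np.asarray(dia)
    if np.any((k < 0) | (k > d)):
        raise ValueError("k_alt must satisfy 0 <= k_alt <= dia")
    if error_rate == 0.0:
        return k_alt
    rng = rng if rng is not None else np.random.default_rng(seed)
    e_a = rng.binomial(k, error_rate)
    if symmetric:
        e_b = rng.binomial(d - k, error_rate)
        out = k - e_a + e_b
    else:
        out = k - e_a
    return out if np.ndim(k_alt) else int(out)


def simulate_reads(k_alt, dia, depth, seed=None, rng=None):
    """Sample tracked-allele reads ``y ~ Binomial(M, K/DIA)``."""
    k = np.asarray(k_alt, dtype=float)
    d = np.asarray(dia, dtype=float)
    if np.any(d < 1):
        raise ValueError("dia must be >= 1")
    if np.any((k < 0) | (k > d)):
        raise ValueError("k_alt must satisfy 0 <= k_alt <= dia")
    rng = rng if rng is not None else np.random.default_rng(seed)
    y = rng.binomial(np.asarray(depth), k / d)
    return y if np.ndim(k_alt) or np.ndim(depth) else int(y)


def simulate_dataset(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Simulate one dataset of heterozygous-locus observations.

    Per locus: draw the actual DIA from ``config.dia_spec``, the amplicon
    pool ``K ~ Binomial(DIA, p)``, apply error injection at
    ``config.error_rate``, then reads ``y ~ Binomial(M, K'/DIA)``.
    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_loci
    dia_values, _ = draw_dia_values(config.dia_spec, n, seed=rng)
    depth = np.broadcast_to(np.asarray(config.depth, dtype=np.int64), (n,))
    p = np.broadcast_to(np.asarray(config.allele_p, dtype=float), (n,))
    k = simulate_amplicon_pool(dia_values, p, rng=rng)
    k_err = inject_amplification_errors(
        k, dia_values, config.error_rate, rng=rng, symmetric=config.symmetric_errors
    )
    y = simulate_reads(k_err, dia_values, depth, rng=rng)
    observations = pd.DataFrame(
        {
            "chrom": "sim",
            "pos": np.arange(1, n + 1, dtype=np.int64),
            "depth_total": depth.astype(np.int64),
            "depth_alt": np.asarray(y, dtype=np.int64),
        }
    )
    truth = pd.DataFrame(
        {
            "dia_actual": dia_values,
            "k_alt": np.asarray(k, dtype=np.int64),
            "k_alt_after_error": np.asarray(k_err, dtype=np.int64),
        }
    )
    return SimulatedDataset(observations, truth, replace(config, seed=seed))


def _estimate_replicates(config: SimulationConfig, n_reps: int, rng) -> np.ndarray:
    """Vectorized simulate -> estimate over replicates; returns estimates.

    Simulates all replicates as one (n_reps * n_loci) block for speed; the
    per-locus generative process is identical to :func:`simulate_dataset`.
    Saturated replicates are returned as ``inf``.
    """
    n = config.n_loci
    total = n_reps * n
    dia_values, _ = draw_dia_values(config.dia_spec, total, seed=rng)
    depth = np.broadcast_to(np.asarray(config.depth, dtype=np.int64), (n,))
    depth_all = np.tile(depth, n_reps)
    p_locus = np.broadcast_to(np.asarray(config.allele_p, dtype=float), (n,))
    p_all = np.tile(p_locus, n_reps)
    k = rng.binomial(dia_values, p_all)
    if config.error_rate > 0:
        k = inject_amplification_errors(
            k, dia_values, config.error_rate, rng=rng, symmetric=config.symmetric_errors
        )
    y = rng.binomial(depth_all, k / dia_values)
    vaf = y / depth_all
    num_terms = (depth_all - 1.0).reshape(n_reps, n)
    den_terms = (
        depth_all * (vaf - p_all) ** 2 / (p_all * (1.0 - p_all)) - 1.0
    ).reshape(n_reps, n)
    num = num_terms.sum(axis=1)
    den = den_terms.sum(axis=1)
    with np.errstate(divide="ignore"):
        est = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return est


def run_accuracy_experiment(
    configs: Iterable[SimulationConfig] | SimulationConfig,
    n_reps: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Replicate simulate -> estimate cycles for each condition.

    Returns a long-format DataFrame with one row per (condition, replicate):
    condition parameters, the ground-truth DIA, the replicate estimate and
    its saturation flag, and the per-replicate accuracy. Use
    :func:`summarize_accuracy` to reduce to per-condition accuracy.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(configs, SimulationConfig):
        configs = [configs]
    rng = np.random.default_rng(seed)
    rows = []
    for cond, config in enumerate(configs):
        truth = config.dia_spec.ground_truth
        est = _estimate_replicates(config, n_reps, rng)
        finite = np.isfinite(est)
        rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "dia_kind": config.dia_spec.kind,
                    "dia_avg": config.dia_spec.dia_avg,
                    "cv": config.dia_spec.cv,
                    "delta": config.dia_spec.delta,
                    "n_loci": config.n_loci,
                    "depth": np.mean(config.depth),
                    "allele_p": np.mean(config.allele_p),
                    "error_rate": config.error_rate,
                    "dia_true": truth,
                    "replicate": np.arange(n_reps),
                    "dia_hat": est,
                    "saturated": ~finite,
                    "accuracy": np.where(
                        finite, 1.0 - np.abs(est - truth) / truth, np.nan
                    ),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def summarize_accuracy(replicates: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary of an accuracy experiment.

    ``accuracy_of_mean`` applies the accuracy formula to the mean of the
    replicate estimates (the headline form); ``mean_accuracy`` averages
    per-replicate accuracies (the dispersion-sensitive form). Saturated
    replicates are excluded from both and counted.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        finite = g.loc[~g["saturated"]]
        truth = g["dia_true"].iloc[0]
        mean_est = finite["dia_hat"].mean() if len(finite) else np.nan
        return pd.Series(
            {
                "dia_true": truth,
                "mean_estimate": mean_est,
                "sd_estimate": finite["dia_hat"].std(ddof=1) if len(finite) > 1 else np.nan,
                "accuracy_of_mean": (
                    estimation_accuracy(mean_est, truth) if len(finite) else np.nan
                ),
                "mean_accuracy": finite["accuracy"].mean() if len(finite) else np.nan,
                "n_replicates": len(g),
                "n_saturated": int(g["saturated"].sum()),
            }
        )

    keys = [
        "condition",
        "dia_kind",
        "dia_avg",
        "cv",
        "delta",
        "n_loci",
        "depth",
        "allele_p",
        "error_rate",
    ]
    out = replicates.groupby(keys, sort=False).apply(_agg, include_groups=False)
    return out.reset_index()
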