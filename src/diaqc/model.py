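"""Method-of-moments estimation of the depth of independent amplicons.

Model
-----
At a heterozygous locus *i* with expected allele fraction ``p`` (0.5 for a
diploid heterozygote), single-cell whole-genome amplification draws the
allele of each of ``DIA`` independent amplicons as a Bernoulli(p) trial, so
the count of amplicons carrying the tracked allele is
``K_i ~ Binomial(DIA, p)``. Sequencing then samples reads from the amplicon
pool, ``y_i ~ Binomial(M_i, K_i / DIA)`` with total depth ``M_i``. The law
of total variance gives the observed-VAF variance

    Var(p_hat_i) = p(1-p) * [ 1/M_i + (1/DIA) * (M_i - 1)/M_i ]

which interpolates between the pure sequencing-binomial floor
``p(1-p)/M`` (DIA -> inf) and the full Bernoulli variance ``p(1-p)``
(DIA = 1). Equating the per-locus standardized second moment
``M_i (p_hat_i - p)^2 / (p(1-p))`` with its expectation
``1 + (M_i - 1)/DIA`` and summing over loci yields the estimator

    DIA_hat = sum_i (M_i - 1) / sum_i [ M_i (p_hat_i - p)^2 / (p(1-p)) - 1 ]

A non-positive denominator means the observed dispersion does not exceed
the infinite-DIA binomial floor; the estimate is then reported as ``inf``
with ``saturated=True``. Uncertainty is quantified by bootstrap resampling
of loci (percentile intervals).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleModel",
    "BootstrapInterval",
    "DIAEstimate",
    "DIAModel",
    "DIAResults",
    "HetLocusObservation",
    "SaturatedIntervalError",
    "bootstrap_ci",
    "estimate_dia",
    "estimation_accuracy",
    "theoretical_vaf_variance",
]


class SaturatedIntervalError(RuntimeError):
    """Raised when every bootstrap resample is saturated."""


class HetLocusObservation(NamedTuple):
    """One bulk-confirmed heterozygous locus in an amplified sample.

    ``depth_total`` is the allelic depth M_i (ref + alt reads used for the
    VAF), ``depth_alt`` the reads supporting the tracked allele y_i.
    """

    chrom: str
    pos: int
    depth_total: int
    depth_alt: int

    @property
    def vaf(self) -> float:
        return self.depth_alt / self.depth_total


@dataclass(frozen=True)
class AlleleModel:
    """Expected allele fraction at the modelled loci.

    ``p = 0.5`` for diploid heterozygotes; adjust for aneuploid or
    CNV regions (e.g. 1/3 for an A/B/B triploid segment).
    """

    p: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele fraction p must lie in (0, 1); got {self.p}")


@dataclass
class DIAEstimate:
    """Point estimate of the depth of independent amplicons."""

    dia_hat: float
    n_loci: int
    numerator: float
    denominator: float
    saturated: bool
    ci_low: float | None = None
    ci_high: float | None = None
    region: str = "whole-genome"

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")


class BootstrapInterval(NamedTuple):
    """Percentile bootstrap interval; saturated resamples are excluded."""

    ci_low: float
    ci_high: float
    n_saturated: int
    estimates: np.ndarray


def theoretical_vaf_variance(p, depth, dia):
    """Theoretical variance of the observed VAF under the two-stage model.

    Parameters
    ----------
    p : float
        Expected allele fraction, in (0, 1).
    depth : int or array
        Sequencing depth M (>= 1).
    dia : float or array
        Depth of independent amplicons (>= 1); ``numpy.inf`` gives the
        sequencing-only binomial limit p(1-p)/M.

    Returns
    -------
    float or ndarray
        ``p(1-p) * (1/M + (1/DIA) * (M-1)/M)``.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele fraction p must lie in (0, 1); got {p}")
    depth = np.asarray(depth, dtype=float)
    dia = np.asarray(dia, dtype=float)
    if np.any(depth < 1):
        raise ValueError("depth must be >= 1")
    if np.any(dia < 1):
        raise ValueError("dia must be >= 1")
    with np.errstate(divide="ignore"):
        amplification = np.where(np.isinf(dia), 0.0, 1.0 / dia) * (depth - 1.0) / depth
    out = p * (1.0 - p) * (1.0 / depth + amplification)
    return out.item() if out.ndim == 0 else out


def _as_arrays(
    observations,
) -> tuple[np.ndarray, np.ndarray]:
    """Coerce observations to (depth_total, depth_alt) float arrays."""
    if isinstance(observations, pd.DataFrame):
        m = observations["depth_total"].to_numpy(dtype=float)
        y = observations["depth_alt"].to_numpy(dtype=float)
    elif isinstance(observations, tuple) and len(observations) == 2:
        m = np.asarray(observations[0], dtype=float)
        y = np.asarray(observations[1], dtype=float)
    else:
        obs = list(observations)
        m = np.array([o.depth_total for o in obs], dtype=float)
        y = np.array([o.depth_alt for o in obs], dtype=float)
    if m.size == 0:
        raise ValueError("at least one heterozygous-locus observation is required")
    if np.any(m < 1):
        raise ValueError("depth_total must be >= 1 at every locus")
    if np.any((y < 0) | (y > m)):
        raise ValueError("depth_alt must satisfy 0 <= depth_alt <= depth_total")
    return m, y


def _moment_terms(m: np.ndarray, y: np.ndarray, p) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator (M_i - 1) and denominator terms of the estimator.

    ``p`` may be scalar or per-locus (CNV-aware regional allele fractions).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele fraction p must lie in (0, 1)")
    vaf = y / m
    num = m - 1.0
    den = m * (vaf - p) ** 2 / (p * (1.0 - p)) - 1.0
    return num, den


def estimate_dia(
    observations,
    model: AlleleModel | float = AlleleModel(),
    region: str = "whole-genome",
    warn_single_read_fraction: float = 0.10,
) -> DIAEstimate:
    """Method-of-moments DIA estimate from heterozygous-locus allele counts.

    Parameters
    ----------
    observations
        Sequence of :class:`HetLocusObservation`, a DataFrame with
        ``depth_total``/``depth_alt`` columns, or a ``(depth_total,
        depth_alt)`` pair of arrays.
    model
        :class:`AlleleModel` (or bare float / per-locus array of expected
        allele fractions).
    region
        Label attached to the estimate (whole genome, chromosome, bin).

    Notes
    -----
    Loci with ``M_i = 1`` carry no numerator information; a warning is
    emitted when they exceed ``warn_single_read_fraction`` of loci. If all
    loci have ``M_i = 1`` the data are uninformative and an error is raised.
    """
    m, y = _as_arrays(observations)
    p = model.p if isinstance(model, AlleleModel) else model
    num_t, den_t = _moment_terms(m, y, p)
    single = np.count_nonzero(m == 1)
    if single == m.size:
        raise ValueError(
            "all loci have depth 1: the numerator is zero and the data carry "
            "no dispersion information"
        )
    if single > warn_single_read_fraction * m.size:
        warnings.warn(
            f"{single}/{m.size} loci have depth 1 and contribute no numerator "
            "information",
            stacklevel=2,
        )
    numerator = float(num_t.sum())
    denominator = float(den_t.sum())
    saturated = denominator <= 0.0
    dia_hat = math.inf if saturated else numerator / denominator
    return DIAEstimate(
        dia_hat=dia_hat,
        n_loci=int(m.size),
        numerator=numerator,
        denominator=denominator,
        saturated=saturated,
        region=region,
    )


def bootstrap_ci(
    observations,
    model: AlleleModel | float = AlleleModel(),
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
) -> BootstrapInterval:
    """Percentile bootstrap confidence interval for the DIA estimate.

    Loci are resampled with replacement ``n_boot`` times and the estimator
    re-evaluated on each resample. Saturated resamples (non-positive
    denominator) are excluded from the percentile computation; their count
    is reported in the result. If every resample saturates a
    :class:`SaturatedIntervalError` is raised.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m, y = _as_arrays(observations)
    p = model.p if isinstance(model, AlleleModel) else model
    num_t, den_t = _moment_terms(m, y, p)
    rng = np.random.default_rng(seed)
    n = m.size
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        den = den_t[idx].sum()
        estimates[b] = num_t[idx].sum() / den if den > 0 else np.inf
    finite = estimates[np.isfinite(estimates)]
    n_saturated = int(n_boot - finite.size)
    if finite.size == 0:
        raise SaturatedIntervalError(
            "every bootstrap resample saturated; no finite interval exists"
        )
    alpha = 1.0 - level
    lo, hi = np.percentile(finite, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapInterval(float(lo), float(hi), n_saturated, estimates)


def estimation_accuracy(dia_hat: float, dia_true: float) -> float:
    """Relative estimation accuracy ``1 - |dia_hat - dia_true| / dia_true``.

    Equals 1 for exact recovery and decreases linearly with relative error
    (can be negative for gross misestimation). ``dia_hat`` may be the mean
    of replicate estimates.
    """
    if dia_true <= 0:
        raise ValueError("dia_true must be positive")
    if not math.isfinite(dia_hat):
        raise ValueError("accuracy is undefined for a saturated (infinite) estimate")
    return 1.0 - abs(dia_hat - dia_true) / dia_true


class DIAModel:
    """Depth-of-independent-amplicons model for one amplified sample.

    Parameters
    ----------
    depth_total, depth_alt : array-like of int
        Allelic depth M_i and tracked-allele reads y_i per heterozygous
        locus.
    chrom, pos : array-like, optional
        Genomic coordinates (1-based positions); required for partitioned
        fits.
    p : float or array-like, default 0.5
        Expected allele fraction (scalar, or per-locus for CNV-aware fits).

    Examples
    --------
    >>> model = DIAModel([30, 30, 30, 30], [10, 20, 2, 28])
    >>> res = model.fit(n_boot=200, seed=0)
    >>> round(res.dia_hat, 3)  # doctest: +SKIP
    2.332
    """

    def __init__(self, depth_total, depth_alt, *, chrom=None, pos=None, p=0.5):
        m, y = _as_arrays((depth_total, depth_alt))
        self.depth_total = m
        self.depth_alt = y
        self.chrom = None if chrom is None else np.asarray(chrom)
        self.pos = None if pos is None else np.asarray(pos, dtype=np.int64)
        p_arr = np.asarray(p, dtype=float)
        if p_arr.ndim and p_arr.size != m.size:
            raise ValueError("per-locus p must match the number of loci")
        self.p = p_arr if p_arr.ndim else float(p_arr)
        self.nobs = int(m.size)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, p=0.5) -> "DIAModel":
        """Build from a DataFrame with depth_total/depth_alt (+chrom/pos)."""
        kwargs = {}
        if "chrom" in df.columns:
            kwargs["chrom"] = df["chrom"].to_numpy()
        if "pos" in df.columns:
            kwargs["pos"] = df["pos"].to_numpy()
        if "p" in df.columns:
            p = df["p"].to_numpy(dtype=float)
        return cls(
            df["depth_total"].to_numpy(),
            df["depth_alt"].to_numpy(),
            p=p,
            **kwargs,
        )

    @classmethod
    def from_observations(cls, observations: Sequence[HetLocusObservation], p=0.5):
        obs = list(observations)
        return cls(
            [o.depth_total for o in obs],
            [o.depth_alt for o in obs],
            chrom=[o.chrom for o in obs],
            pos=[o.pos for o in obs],
            p=p,
        )

    @classmethod
    def from_vcf(
        cls,
        path,
        bulk_sample: str,
        amplified_sample: str,
        *,
        min_gq: int = 20,
        min_dp: int = 10,
        autosomes_only: bool = True,
        cnv_segments: pd.DataFrame | None = None,
        p: float = 0.5,
    ) -> "DIAModel":
        """Build from a multi-sample VCF of bulk-confirmed heterozygous loci.

        See :func:`diaqc.vcfio.extract_het_loci` for the selection and
        filtering rules.
        """
        from .vcfio import QualityFilters, apply_cnv_allele_p, extract_het_loci

        df = extract_het_loci(
            path,
            bulk_sample,
            amplified_sample,
            filters=QualityFilters(min_gq=min_gq, min_dp=min_dp, autosomes_only=autosomes_only),
        )
        if cnv_segments is not None:
            df = apply_cnv_allele_p(df, cnv_segments, default_p=p)
        elif "p" not in df.columns:
            df = df.assign(p=p)
        return cls.from_dataframe(df)

    # ------------------------------------------------------------------ #
    def to_frame(self) -> pd.DataFrame:
        data = {"depth_total": self.depth_total.astype(int), "depth_alt": self.depth_alt.astype(int)}
        if self.chrom is not None:
            data["chrom"] = self.chrom
        if self.pos is not None:
            data["pos"] = self.pos
        if np.ndim(self.p):
            data["p"] = self.p
        return pd.DataFrame(data)

    def fit(
        self,
        *,
        bootstrap: bool = True,
        n_boot: int = 1000,
        level: float = 0.95,
        seed=None,
        region: str = "whole-genome",
    ) -> "DIAResults":
        """Estimate the DIA; optionally attach a bootstrap interval."""
        est = estimate_dia((self.depth_total, self.depth_alt), self.p, region=region)
        interval = None
        if bootstrap and not est.saturated:
            try:
                interval = bootstrap_ci(
                    (self.depth_total, self.depth_alt),
                    self.p,
                    n_boot=n_boot,
                    level=level,
                    seed=seed,
                )
                est.ci_low, est.ci_high = interval.ci_low, interval.ci_high
            except SaturatedIntervalError:
                interval = None
        return DIAResults(self, est, interval, level=level, n_boot=n_boot if bootstrap else 0)


class DIAResults:
    """Fit results: point estimate, bootstrap interval, diagnostics."""

    def __init__(self, model: DIAModel, estimate: DIAEstimate, interval, *, level, n_boot):
        self.model = model
        self.estimate = estimate
        self.interval = interval
        self.level = level
        self.n_boot = n_boot

    # Scalar accessors ------------------------------------------------- #
    @property
    def dia_hat(self) -> float:
        return self.estimate.dia_hat

    @property
    def saturated(self) -> bool:
        return self.estimate.saturated

    @property
    def nobs(self) -> int:
        return self.estimate.n_loci

    @property
    def ci_low(self):
        return self.estimate.ci_low

    @property
    def ci_high(self):
        return self.estimate.ci_high

    @property
    def mean_depth(self) -> float:
        return float(self.model.depth_total.mean())

    def accuracy(self, dia_true: float) -> float:
        """Estimation accuracy against a known ground-truth DIA."""
        return estimation_accuracy(self.dia_hat, dia_true)

    def to_dict(self) -> dict:
        e = self.estimate
        return {
            "region": e.region,
            "dia_hat": e.dia_hat,
            "n_loci": e.n_loci,
            "saturated": e.saturated,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "ci_level": self.level if self.interval is not None else None,
            "n_boot": self.n_boot,
            "n_boot_saturated": None if self.interval is None else self.interval.n_saturated,
            "mean_depth": self.mean_depth,
        }

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        e = self.estimate
        dia = "saturated (inf)" if e.saturated else f"{e.dia_hat:.3f}"
        lines = [
            "Depth of Independent Amplicons — method-of-moments fit",
            "=" * 56,
            f"{'Region':<28}{e.region}",
            f"{'No. heterozygous loci':<28}{e.n_loci}",
            f"{'Mean allelic depth':<28}{self.mean_depth:.2f}",
            f"{'DIA estimate':<28}{dia}",
        ]
        if e.ci_low is not None:
            lines.append(
                f"{f'{self.level:.0%} bootstrap CI':<28}"
                f"[{e.ci_low:.3f}, {e.ci_high:.3f}]  (B={self.n_boot}, "
                f"{self.interval.n_saturated} saturated)"
            )
        if e.saturated:
            lines.append(
                "Observed VAF dispersion is at or below the sequencing-binomial "
                "floor; no finite DIA is identifiable."
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tail = "saturated" if self.saturated else f"dia_hat={self.dia_hat:.3f}"
        return f"<DIAResults n_loci={self.nobs} {tail}>"
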