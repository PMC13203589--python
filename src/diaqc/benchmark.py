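"""SNV-calling fidelity as a function of DIA and enzymatic error rate.

Genotyping errors in single-cell data arise from two coupled sources: the
finite number of independent amplicons (DIA), which causes allele dropout
when one allele is never captured, and amplification-stage misreadings at
rate epsilon, which plant the wrong allele in the pool. This module
estimates per-locus genotyping-error probabilities under the two-stage
model (Monte Carlo, with an exact binomial-enumeration mode) and projects
them to genome-scale expected TP/FN/FP/ADO counts, sensitivity and
precision.

A convenient collapse makes the enumeration exact and cheap: starting from
``K ~ Binomial(DIA, p)`` and flipping every amplicon's allele independently
with probability epsilon leaves the pool binomial,
``K' ~ Binomial(DIA, p(1-eps) + (1-p)eps)``. Homozygous loci therefore have
``K_alt' ~ Binomial(DIA, eps)`` (reference) or ``Binomial(DIA, 1-eps)``
(alternative), and genotype-call probabilities reduce to a double binomial
sum over (K', y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CallMetrics",
    "GenomeModel",
    "GenotypeThresholds",
    "GenotypingErrorProfile",
    "benchmark_grid",
    "estimate_error_probabilities",
    "genotype_call",
    "project_genome_metrics",
]

GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class GenotypeThresholds:
    """VAF-threshold genotyper settings.

    VAF below ``t_low`` is homozygous reference; above ``t_high`` is
    homozygous alternative; otherwise heterozygous — but any non-reference
    call requires at least ``min_alt_reads`` supporting reads (a locus that
    fails this is called homozygous reference). The defaults (0.1 / 0.9,
    two reads) mirror common hard-filter heuristics and make allele
    dropout at DIA = 1 exact.
    """

    t_low: float = 0.1
    t_high: float = 0.9
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.t_low < self.t_high < 1.0:
            raise ValueError("need 0 < t_low < t_high < 1")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")


def _call_codes(y, depth, thresholds: GenotypeThresholds) -> np.ndarray:
    """Vectorized genotype calls: 0 = hom_ref, 1 = het, 2 = hom_alt."""
    y = np.asarray(y)
    depth = np.asarray(depth)
    vaf = y / depth
    codes = np.ones(np.broadcast(y, depth).shape, dtype=np.int8)
    codes[np.broadcast_to(vaf > thresholds.t_high, codes.shape)] = 2
    ref = (vaf < thresholds.t_low) | (y < thresholds.min_alt_reads)
    codes[np.broadcast_to(ref, codes.shape)] = 0
    return codes


def genotype_call(
    y_alt: int, depth: int, thresholds: GenotypeThresholds = GenotypeThresholds()
) -> str:
    """Call a genotype from alt-supporting reads out of total depth."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= y_alt <= depth:
        raise ValueError("y_alt must satisfy 0 <= y_alt <= depth")
    return GENOTYPES[int(_call_codes(np.int64(y_alt), np.int64(depth), thresholds))]


@dataclass(frozen=True)
class GenotypingErrorProfile:
    """Per-truth-genotype call probabilities at one (DIA, M, eps) setting.

    ``het``, ``hom_ref`` and ``hom_alt`` each hold the probability triple
    (called hom_ref, called het, called hom_alt) given that truth; each
    triple sums to 1. Named accessors expose the conventional error rates.
    """

    het: tuple[float, float, float]
    hom_ref: tuple[float, float, float]
    hom_alt: tuple[float, float, float]
    context: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, triple in (("het", self.het), ("hom_ref", self.hom_ref), ("hom_alt", self.hom_alt)):
            arr = np.asarray(triple, dtype=float)
            if arr.shape != (3,) or np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must be three probabilities in [0, 1]")
            if not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} probabilities must sum to 1 (got {arr.sum()})")

    @property
    def p_ado(self) -> float:
        """True heterozygote called homozygous (either direction)."""
        return self.het[0] + self.het[2]

    @property
    def p_het_correct(self) -> float:
        return self.het[1]

    @property
    def p_homo_to_het(self) -> float:
        """True homozygous-reference site called heterozygous."""
        return self.hom_ref[1]

    @property
    def p_homo_to_homo(self) -> float:
        """True homozygous-reference site called homozygous-alternative."""
        return self.hom_ref[2]

    @property
    def p_homo_correct(self) -> float:
        return self.hom_ref[0]


def _effective_alt_fraction(truth: str, p: float, error_rate: float, symmetric: bool) -> float:
    """Post-error per-amplicon probability of carrying the alt allele."""
    if truth == "het":
        if symmetric:
            return p * (1.0 - error_rate) + (1.0 - p) * error_rate
        return p * (1.0 - error_rate)
    if truth == "hom_ref":
        return error_rate
    if truth == "hom_alt":
        return 1.0 - error_rate
    raise ValueError(f"unknown truth genotype: {truth!r}")


def _exact_call_probs(
    dia: int, depth: int, p_alt: float, thresholds: GenotypeThresholds
) -> np.ndarray:
    """Exact (hom_ref, het, hom_alt) call probabilities by enumeration.

    Sums Binomial(K'; DIA, p_alt) * Binomial(y; M, K'/DIA) over the call
    regions; O(DIA * M)."""
    ks = np.arange(dia + 1)
    wk = stats.binom.pmf(ks, dia, p_alt)
    ys = np.arange(depth + 1)
    codes = _call_codes(ys, depth, thresholds)
    # P(y | K') matrix: rows K', cols y
    py = stats.binom.pmf(ys[None, :], depth, (ks / dia)[:, None])
    probs = np.array([(wk[:, None] * py[:, codes == c]).sum() for c in range(3)])
    return probs / probs.sum()


def estimate_error_probabilities(
    dia: int,
    depth: int,
    error_rate: float,
    n_mc: int = 100_000,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    seed=None,
    method: str = "mc",
    symmetric_errors: bool = True,
) -> GenotypingErrorProfile:
    """Genotyping-error probabilities at one (DIA, depth, error-rate) cell.

    ``method="mc"`` simulates ``n_mc`` loci per truth genotype through the
    two-stage model with error injection and tallies call frequencies;
    ``method="exact"`` enumerates the binomial double sum (the oracle the
    Monte-Carlo mode is validated against).
    """
    if dia < 1 or int(dia) != dia:
        raise ValueError("dia must be a positive integer")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    dia = int(dia)
    triples = {}
    rng = np.random.default_rng(seed)
    for truth in GENOTYPES:
        p_alt = _effective_alt_fraction(truth, 0.5, error_rate, symmetric_errors)
        if method == "exact":
            triples[truth] = tuple(_exact_call_probs(dia, depth, p_alt, thresholds))
        elif method == "mc":
            if n_mc < 1:
                raise ValueError("n_mc must be >= 1")
            k = rng.binomial(dia, p_alt, size=n_mc)
            y = rng.binomial(depth, k / dia)
            codes = _call_codes(y, depth, thresholds)
            counts = np.bincount(codes, minlength=3)
            triples[truth] = tuple(counts / n_mc)
        else:
            raise ValueError(f"unknown method: {method!r}")
    return GenotypingErrorProfile(
        het=triples["het"],
        hom_ref=triples["hom_ref"],
        hom_alt=triples["hom_alt"],
        context={
            "dia": dia,
            "depth": depth,
            "error_rate": error_rate,
            "thresholds": thresholds,
            "method": method,
            "n_mc": n_mc if method == "mc" else None,
            "symmetric_errors": symmetric_errors,
        },
    )


@dataclass(frozen=True)
class GenomeModel:
    """Site composition of the genome used for expected-count projection."""

    n_total_sites: float = 3e9
    n_het_true: float = 1e6
    n_hom_alt_true: float = 1e6

    def __post_init__(self) -> None:
        if self.n_het_true + self.n_hom_alt_true > self.n_total_sites:
            raise ValueError("variant sites cannot exceed total sites")

    @property
    def n_hom_ref_true(self) -> float:
        return self.n_total_sites - self.n_het_true - self.n_hom_alt_true


class CallMetrics(NamedTuple):
    """Genome-scale expected SNV-calling outcome counts and rates."""

    tp: float
    fn: float
    fp: float
    ado: float
    sensitivity: float
    precision: float | None


def project_genome_metrics(
    profile: GenotypingErrorProfile,
    genome: GenomeModel = GenomeModel(),
    genotype_exact: bool = False,
) -> CallMetrics:
    """Project per-locus call probabilities to genome-scale expected counts.

    Germline definitions: a variant site (true 0/1 or 1/1) called non-
    reference counts as TP (set ``genotype_exact=True`` to require the
    exact genotype instead); called 0/0 it is an FN. A true 0/0 site
    called non-reference is an FP. ADO counts true heterozygous sites
    called homozygous in either direction. Counts are deterministic
    expectations; precision is ``None`` when TP + FP = 0.
    """
    het, ref, alt = profile.het, profile.hom_ref, profile.hom_alt
    if genotype_exact:
        tp = genome.n_het_true * het[1] + genome.n_hom_alt_true * alt[2]
    else:
        tp = genome.n_het_true * (het[1] + het[2]) + genome.n_hom_alt_true * (alt[1] + alt[2])
    fn = genome.n_het_true * het[0] + genome.n_hom_alt_true * alt[0]
    fp = genome.n_hom_ref_true * (ref[1] + ref[2])
    ado = genome.n_het_true * (het[0] + het[2])
    sensitivity = tp / (tp + fn) if tp + fn > 0 else np.nan
    precision = tp / (tp + fp) if tp + fp > 0 else None
    return CallMetrics(tp, fn, fp, ado, sensitivity, precision)


def benchmark_grid(
    dia_values: Iterable[int] = (1, 2, 5, 10, 20, 30, 50, 100),
    error_rates: Iterable[float] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2),
    depth: int = 30,
    genome: GenomeModel = GenomeModel(),
    n_mc: int = 100_000,
    seed=None,
    method: str = "exact",
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    genotype_exact: bool = False,
) -> pd.DataFrame:
    """Evaluate SNV-calling fidelity over a (DIA, error-rate) grid.

    Returns a long-format DataFrame with one row per cell: dia,
    error_rate, depth, expected tp/fn/fp/ado counts, sensitivity and
    precision. The exact-enumeration mode is the default because genome-
    scale FP expectations involve per-site probabilities far below
    Monte-Carlo resolution at realistic ``n_mc``.
    """
    dia_values = list(dia_values)
    error_rates = list(error_rates)
    if not dia_values or not error_rates:
        raise ValueError("dia_values and error_rates must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for eps in error_rates:
        for dia in dia_values:
            profile = estimate_error_probabilities(
                dia,
                depth,
                eps,
                n_mc=n_mc,
                thresholds=thresholds,
                seed=rng,
                method=method,
            )
            metrics = project_genome_metrics(profile, genome, genotype_exact=genotype_exact)
            rows.append(
                {
                    "dia": dia,
                    "error_rate": eps,
                    "depth": depth,
                    "tp": metrics.tp,
                    "fn": metrics.fn,
                    "fp": metrics.fp,
                    "ado": metrics.ado,
                    "sensitivity": metrics.sensitivity,
                    "precision": metrics.precision,
                    "p_ado": profile.p_ado,
                    "p_homo_to_het": profile.p_homo_to_het,
                    "p_homo_to_homo": profile.p_homo_to_homo,
                }
            )
    return pd.DataFrame(rows)
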