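"""Coverage-uniformity metrics over fixed genomic windows.

These are the classical descriptive QC summaries the DIA is contrasted
with: they describe the final read-depth distribution, not the molecular
independence of the library, and shift under depth manipulation while the
DIA (computed from allele counts) does not.
"""

from __future__ import annotations

import numpy as np

__all__ = ["depth_cap_downsample", "gini_index", "kl_uniformity"]


def _validated(depths) -> np.ndarray:
    x = np.asarray(depths, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("window depths must be a non-empty 1-D vector")
    if np.any(x < 0):
        raise ValueError("window depths must be non-negative")
    if not np.any(x > 0):
        raise ValueError("all-zero depth vector: uniformity is undefined")
    return x


def gini_index(window_depths) -> float:
    """Gini index of per-window depths: 0 = perfectly uniform coverage.

    Computed on sorted values x_(1) <= ... <= x_(n) as
    ``sum_i (2i - n - 1) x_(i) / (n^2 * mean)``; a one-hot vector of
    length n attains the maximum (n-1)/n. Scale-invariant.
    """
    x = np.sort(_validated(window_depths))
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * n * x.mean()))


def kl_uniformity(window_depths) -> float:
    """KL divergence (natural log) of the depth distribution from uniform.

    The depth vector is normalized to a probability vector q over windows
    and compared against the uniform reference u_i = 1/n:
    ``KL(q || u) = sum_i q_i ln(q_i * n)``, with 0 ln 0 := 0. Zero iff the
    coverage is perfectly uniform; scale-invariant.
    """
    x = _validated(window_depths)
    q = x / x.sum()
    nz = q > 0
    return float((q[nz] * np.log(q[nz] * x.size)).sum())


def depth_cap_downsample(
    window_depths,
    quantile_cutoff: float,
    target_mean: float = 20.0,
    seed=None,
) -> np.ndarray:
    """Emulate coverage-capping down-sampling on a per-window depth vector.

    Depths above the ``quantile_cutoff``-th quantile are capped at that
    quantile, then the vector is rescaled globally so its mean is
    ``target_mean`` (the second, uniform down-sampling round). Operates on
    window-level mean depths, so the capping is deterministic; ``seed`` is
    accepted for interface symmetry with read-level down-sampling.
    """
    if not 0.0 < quantile_cutoff <= 1.0:
        raise ValueError("quantile_cutoff must lie in (0, 1]")
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    x = _validated(window_depths)
    cap = np.quantile(x, quantile_cutoff)
    capped = np.minimum(x, cap)
    return capped * (target_mean / capped.mean())
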