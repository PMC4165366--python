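"""Inverse-variance meta-analysis of per-SNV scores within a gene.

Each SNV contributes a score ``z_i`` (an FT value in the one-sample analysis,
a proportion difference in the two-sample analysis) with a known variance
``v_i``.  The gene-level score is the fixed-effects inverse-variance-weighted
average, and Cochran's Q measures between-SNV heterogeneity of the scores —
large Q flags genes whose SNVs disagree on the extent of imbalance, a pattern
compatible with isoform-specific ASE.

The DerSimonian-Laird between-SNV variance tau^2 is computed as a diagnostic
only; the point estimate stays fixed-effects, and the heterogeneity inference
uses the simulated null distribution of Q rather than the chi-square
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MetaResult", "combine", "combine_arrays"]


@dataclass(frozen=True)
class MetaResult:
    """Gene-level combined score, its variance, and the heterogeneity Q."""

    combined_z: float
    combined_variance: float
    q_stat: float
    k: int
    tau2: float = 0.0


def combine(scores: Sequence[tuple[float, float]]) -> MetaResult:
    """Fixed-effects combination of ``(z_i, v_i)`` pairs.

    combined_z = sum(z_i / v_i) / sum(1 / v_i)
    combined_variance = 1 / sum(1 / v_i)
    Q = sum((z_i - combined_z)^2 / v_i)
    """
    if len(scores) == 0:
        raise ValueError("cannot combine an empty score sequence")
    z = np.array([s[0] for s in scores], dtype=float)
    v = np.array([s[1] for s in scores], dtype=float)
    if np.any(v <= 0.0):
        raise ValueError("variances must be strictly positive")
    w = 1.0 / v
    sw = w.sum()
    zbar = float(np.dot(w, z) / sw)
    k = len(scores)
    q = float(np.dot(w, (z - zbar) ** 2)) if k > 1 else 0.0  # exact at k = 1
    # DerSimonian-Laird tau^2, diagnostic only
    if k > 1:
        denom = sw - float(np.dot(w, w)) / sw
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    return MetaResult(
        combined_z=zbar, combined_variance=float(1.0 / sw), q_stat=q, k=k, tau2=tau2
    )


def combine_arrays(z: np.ndarray, v: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fixed-effects combination along ``axis``.

    ``z`` holds scores for k SNVs across many replicates; ``v`` broadcasts
    against it.  Returns (combined_z, q_stat) with ``axis`` reduced.  Used on
    the Monte-Carlo hot path, where building per-replicate MetaResult objects
    would dominate runtime.
    """
    w = 1.0 / np.asarray(v, dtype=float)
    sw = np.sum(w * np.ones_like(z, dtype=float), axis=axis)
    zbar = np.sum(w * z, axis=axis) / sw
    q = np.sum(w * (z - np.expand_dims(zbar, axis)) ** 2, axis=axis)
    return zbar, q
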