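"""Two-sample (e.g. tumor vs. normal) differential ASE.

The target of inference is the haplotype frequency difference
``D = p_hap1,tumor - p_hap1,normal``.  SNVs are phased by voting on the sample
of interest only (the tumor anchors the phase; the same per-SNV major-allele
identity is imposed on the other sample), each SNV contributes a proportion
difference

    z = x_t / n_t - x_n / n_n,

with null variance ``p (1 - p) / n_t + p (1 - p) / n_n`` evaluated at a pooled
estimate of the common haplotype frequency ``p`` under H0 (inflated by
``rho (n - 1) + 1`` per sample when overdispersed), and the gene-level
statistic ``T_PD`` is the inverse-variance-weighted combination — already on
the frequency-difference scale, so no backtransform is applied.  As in the
one-sample analysis, p-values come from re-simulating both samples' counts
under H0 at the pooled frequency, re-phasing on the simulated sample of
interest, and recomputing (T_PD, Q).  No variance-stabilizing transform is
used on the PD scale, so single outlier SNVs move T_PD more than they would
move T_FT.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .distributions import betabin_draw, bias_adjusted_mu
from .meta import combine, combine_arrays
from .onesample import _TIE_EPS, ModelParams, _trim_cache
from .phasing import PhasedGene, SnvCount, phase_by_other_sample

__all__ = [
    "GenePair",
    "TwoSampleAseResult",
    "pd_score",
    "estimate_null_p",
    "run_two_sample",
]

_CHUNK = 200_000


@dataclass(frozen=True)
class GenePair:
    """One gene's SNV counts in the sample of interest and the comparison sample."""

    ase_id: str
    snvs_interest: tuple[SnvCount, ...]
    snvs_other: tuple[SnvCount, ...]

    def __post_init__(self) -> None:
        if not self.snvs_interest:
            raise ValueError(f"gene {self.ase_id} has no SNVs")
        if [s.locus_id for s in self.snvs_interest] != [
            s.locus_id for s in self.snvs_other
        ]:
            raise ValueError(f"gene {self.ase_id}: loci differ between samples")


@dataclass(frozen=True)
class TwoSampleAseResult:
    ase_id: str
    maf_difference: float
    p_ase: float
    p_heterogeneity: Optional[float]
    q_stat: float
    n_snvs: int
    null_p_hap1: float
    n_sim_used: int
    phase_interest: Optional[PhasedGene] = None
    phase_other: Optional[PhasedGene] = None
    error: Optional[str] = None


def pd_score(
    x_t: int, n_t: int, x_n: int, n_n: int, p_null: float, rho: float = 0.0
) -> tuple[float, float]:
    """Per-SNV proportion difference and its null variance at ``p_null``."""
    if n_t < 1 or n_n < 1:
        raise ValueError("totals must be positive")
    if not 0 <= x_t <= n_t or not 0 <= x_n <= n_n:
        raise ValueError("counts must lie within totals")
    if not 0.0 < p_null < 1.0:
        raise ValueError("p_null must lie strictly in (0, 1)")
    z = x_t / n_t - x_n / n_n
    pq = p_null * (1.0 - p_null)
    variance = pq / n_t * (rho * (n_t - 1) + 1.0) + pq / n_n * (rho * (n_n - 1) + 1.0)
    return z, variance


def estimate_null_p(phased_pair: tuple[PhasedGene, PhasedGene]) -> float:
    """Pooled major-haplotype frequency across both samples under H0.

    Counts are pooled over SNVs and samples; the estimate is clipped to
    ``[1/(N+2), 1 - 1/(N+2)]`` (N = pooled total) so the null variance never
    degenerates to zero for monoallelic observations.
    """
    a, b = phased_pair
    x = sum(a.major_counts) + sum(b.major_counts)
    n = sum(a.totals) + sum(b.totals)
    eps = 1.0 / (n + 2.0)
    return float(np.clip(x / n, eps, 1.0 - eps))


def _pair_statistic(
    anchored: PhasedGene, imposed: PhasedGene, mu_null: np.ndarray, rho: float
) -> tuple[float, float]:
    scores = [
        pd_score(xt, nt, xn, nn, float(mu), rho)
        for xt, nt, xn, nn, mu in zip(
            anchored.major_counts,
            anchored.totals,
            imposed.major_counts,
            imposed.totals,
            mu_null,
        )
    ]
    res = combine(scores)
    return res.combined_z, res.q_stat


def _simulate_null_pair(
    n_t: np.ndarray,
    n_n: np.ndarray,
    mu_hap1: np.ndarray,
    rho: float,
    n_sim: int,
    seed: int,
    key: tuple,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint null draws of (T_PD, Q) with tumor-anchored re-phasing.

    Haplotype-1 counts in both samples are drawn at the common observed-scale
    mean ``mu_hap1``; each replicate is re-phased by voting on the simulated
    sample of interest, and the PD statistic recomputed with the same null
    variance weights as the observed data.
    """
    k = len(n_t)
    key_hash = zlib.crc32(repr(key).encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed, key_hash]))
    pq = mu_hap1 * (1.0 - mu_hap1)
    v = (
        pq / n_t * (rho * (n_t - 1) + 1.0) + pq / n_n * (rho * (n_n - 1) + 1.0)
    )[:, None]
    t_parts, q_parts = [], []
    remaining = n_sim
    nt_col = n_t[:, None]
    nn_col = n_n[:, None]
    mu_col = mu_hap1[:, None]
    while remaining > 0:
        size = min(_CHUNK, remaining)
        xt = betabin_draw(rng, nt_col, mu_col, rho, (k, size))
        xn = betabin_draw(rng, nn_col, mu_col, rho, (k, size))
        # voting on the simulated sample of interest; the flip carries to both
        flip = xt < nt_col - xt
        xt_m = np.where(flip, nt_col - xt, xt)
        xn_m = np.where(flip, nn_col - xn, xn)
        z = xt_m / nt_col - xn_m / nn_col
        zbar, q = combine_arrays(z, v, axis=0)
        t_parts.append(zbar)
        q_parts.append(q)
        remaining -= size
    return np.concatenate(t_parts), np.concatenate(q_parts)


def run_two_sample(
    gene_pairs: Sequence[GenePair],
    params: ModelParams = ModelParams(),
    n_sim: int = 100_000,
    seed: int = 0,
    null_cache: Optional[dict] = None,
) -> list[TwoSampleAseResult]:
    """Differential ASE over a batch of genes observed in both samples."""
    cache: dict = {} if null_cache is None else null_cache
    f = params.f_ref_null
    results: list[TwoSampleAseResult] = []
    for pair in gene_pairs:
        try:
            anchored, imposed = phase_by_other_sample(
                pair.snvs_interest, pair.snvs_other, ase_id=pair.ase_id
            )
            p_null = estimate_null_p((anchored, imposed))
            n_t = np.array(anchored.totals, dtype=np.int64)
            n_n = np.array(imposed.totals, dtype=np.int64)
            # observation-scale null mean of the major-haplotype allele at
            # each SNV: the pooled frequency pushed through the bias map of
            # whichever allele (ref or alt) anchors the major haplotype
            f_major = np.where(np.array(anchored.major_is_ref), f, 1.0 - f)
            if f == 0.5:
                mu_hap1 = np.full(len(n_t), p_null)
            else:
                mu_hap1 = bias_adjusted_mu(np.full(len(n_t), p_null), f_major)
            t_pd, q = _pair_statistic(anchored, imposed, mu_hap1, params.rho)
            key = (
                tuple(sorted(zip(anchored.totals, imposed.totals, mu_hap1.round(10)))),
                round(params.rho, 12),
                n_sim,
            )
            if key not in cache:
                _trim_cache(cache)
                cache[key] = _simulate_null_pair(
                    n_t, n_n, mu_hap1, params.rho, n_sim, seed, key
                )
            t_null, q_null = cache[key]
            floor = 1.0 / (n_sim + 1.0)
            p_ase = max(float(np.sum(t_null >= t_pd - _TIE_EPS)) / n_sim, floor)
            if len(pair.snvs_interest) > 1:
                p_het = max(float(np.sum(q_null >= q - _TIE_EPS)) / n_sim, floor)
            else:
                p_het = None
            results.append(
                TwoSampleAseResult(
                    ase_id=pair.ase_id,
                    maf_difference=t_pd,
                    p_ase=p_ase,
                    p_heterogeneity=p_het,
                    q_stat=q,
                    n_snvs=len(pair.snvs_interest),
                    null_p_hap1=p_null,
                    n_sim_used=n_sim,
                    phase_interest=anchored,
                    phase_other=imposed,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-gene isolation
            results.append(
                TwoSampleAseResult(
                    ase_id=pair.ase_id,
                    maf_difference=float("nan"),
                    p_ase=float("nan"),
                    p_heterogeneity=None,
                    q_stat=float("nan"),
                    n_snvs=len(pair.snvs_interest),
                    null_p_hap1=float("nan"),
                    n_sim_used=0,
                    error=str(exc),
                )
            )
    return results
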