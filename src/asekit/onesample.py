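"""One-sample gene-level ASE inference.

For each gene the major-haplotype counts (pseudo-phased, or phased from
supplied labels) are FT-transformed, combined across SNVs by inverse-variance
weighting, and backtransformed into a gene-level major haplotype frequency
estimate ``T_FT``.  Because pseudo-phasing takes a per-SNV maximum, ``T_FT``
is biased above 0.5 under the null of balanced expression and its nominal
normal-theory p-value is anti-conservative.  Significance is therefore
assessed against a Monte-Carlo null: holding each SNV's total read count
fixed, reference counts are redrawn from the null (beta-)binomial, the
identical phasing and estimation pipeline is re-applied, and

    p_ase = #(T_sim >= T_obs) / N_sim
    p_het = #(Q_sim >= Q_obs) / N_sim   (multi-SNV genes only)

Null distributions depend only on the multiset of per-SNV totals (plus rho,
bias and the phase mode), so they are cached and shared across genes with the
same "shape".
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .distributions import (
    BiasSpec,
    betabin_draw,
    bias_invert_mu,
    ft_backtransform,
    ft_transform,
    ft_variance,
)
from .meta import combine, combine_arrays
from .phasing import PhasedGene, SnvCount, phase_from_labels, pseudo_phase

__all__ = [
    "ModelParams",
    "AseUnit",
    "AseResult",
    "NullModel",
    "NullDistribution",
    "gene_statistic",
    "simulate_null",
    "p_values",
    "run_one_sample",
]

_CHUNK = 200_000  # replicates per simulation block; bounds peak memory
_TIE_EPS = 1e-12  # absorbs float noise between scalar and vectorized paths
_CACHE_MAX = 3000  # cached null distributions; oldest half evicted beyond this


def _trim_cache(cache: dict) -> None:
    if len(cache) > _CACHE_MAX:
        for key in list(cache.keys())[: len(cache) // 2]:
            del cache[key]


@dataclass(frozen=True)
class ModelParams:
    """Global nuisance parameters: overdispersion and pre-existing bias."""

    rho: float = 0.0
    f_ref_null: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        BiasSpec(self.f_ref_null)  # validates range

    @property
    def bias(self) -> BiasSpec:
        return BiasSpec(self.f_ref_null)


@dataclass(frozen=True)
class AseUnit:
    """A gene (or other ASE unit) with its heterozygous SNV counts."""

    ase_id: str
    snvs: tuple[SnvCount, ...]

    def __post_init__(self) -> None:
        if not self.snvs:
            raise ValueError(f"gene {self.ase_id} has no SNVs")

    @property
    def has_phase_labels(self) -> bool:
        return all(s.hap1_is_ref is not None for s in self.snvs)


@dataclass(frozen=True)
class AseResult:
    """Per-gene output of the one-sample analysis."""

    ase_id: str
    maf_estimate: float
    p_ase: float
    p_heterogeneity: Optional[float]
    q_stat: float
    n_snvs: int
    phase: Optional[PhasedGene]
    n_sim_used: int
    tau2: float = 0.0
    error: Optional[str] = None


@dataclass(frozen=True)
class NullModel:
    """Shape of one gene's Monte-Carlo null.

    ``hap1_f`` is the per-SNV observation probability of the haplotype-1
    allele under balanced expression; for pseudo-phased genes it is the
    reference allele's ``f`` at every SNV.
    """

    totals: tuple[int, ...]
    rho: float
    n_sim: int
    seed: int
    hap1_f: tuple[float, ...]
    known_phase: bool = False

    def cache_key(self) -> tuple:
        paired = tuple(sorted(zip(self.totals, self.hap1_f)))
        return (self.known_phase, paired, round(self.rho, 12), self.n_sim)


@dataclass
class NullDistribution:
    """Empirical joint null draws of (T, Q) for one gene shape."""

    t_null: np.ndarray
    q_null: np.ndarray
    n_sim: int


def _safe_invert_bias(mu, f):
    """Bias inversion tolerant of boundary values produced by clipping."""
    mu_arr = np.clip(np.asarray(mu, dtype=float), 1e-12, 1.0 - 1e-12)
    f_arr = np.asarray(f, dtype=float)
    out = bias_invert_mu(mu_arr, f_arr)
    return out


def _gene_stats_full(phased: PhasedGene, params: ModelParams):
    if phased.k == 0:
        raise ValueError("empty gene")
    n = np.array(phased.totals)
    x = np.array(phased.major_counts)
    z, v = ft_transform(x, n, rho=params.rho)
    z = np.atleast_1d(z)
    v = np.atleast_1d(v)
    res = combine(list(zip(z, v)))
    mu_hat = ft_backtransform(res.combined_z)
    f = params.f_ref_null
    f_major = np.where(np.array(phased.major_is_ref), f, 1.0 - f)
    w = 1.0 / v
    f_eff = float(np.dot(w, f_major) / w.sum())
    t = float(_safe_invert_bias(mu_hat, f_eff))
    if phased.phase_source == "known":
        t = max(t, 1.0 - t)
    return t, res


def gene_statistic(phased: PhasedGene, params: ModelParams) -> tuple[float, float]:
    """Gene-level (T_FT, Q) from a phased gene.

    Major-haplotype counts are FT-transformed with variance
    ``(rho (n - 1) + 1) / (n + 0.5)``, combined by inverse variance, the
    combined score backtransformed to the observed-count scale, and finally
    mapped to the transcript scale by inverting the pre-existing bias with an
    inverse-variance-weighted effective ``f`` of the major alleles.
    """
    t, res = _gene_stats_full(phased, params)
    return t, res.q_stat


def _simulate_block(
    rng: np.random.Generator, model: NullModel, size: int
) -> tuple[np.ndarray, np.ndarray]:
    n = np.array(model.totals, dtype=np.int64)[:, None]
    k = len(model.totals)
    f_hap1 = np.array(model.hap1_f, dtype=float)[:, None]
    x = betabin_draw(rng, n, f_hap1, model.rho, (k, size))
    v = ft_variance(n, rho=model.rho)  # (k, 1)
    w = 1.0 / v
    sw = w.sum()
    if model.known_phase:
        counts = x
        f_major = np.broadcast_to(f_hap1, (k, size))
    else:
        counts = np.maximum(x, n - x)
        ref_major = x >= n - x  # ties -> reference allele is major
        f_major = np.where(ref_major, f_hap1, 1.0 - f_hap1)
    z, _ = ft_transform(counts, np.broadcast_to(n, (k, size)))
    zbar, q = combine_arrays(z, v, axis=0)
    mu_hat = np.sin(np.clip(zbar, 0.0, np.pi) / 2.0) ** 2
    f_eff = (w * f_major).sum(axis=0) / sw
    t = _safe_invert_bias(mu_hat, f_eff)
    if model.known_phase:
        t = np.maximum(t, 1.0 - t)
    return t, q


def simulate_null(model: NullModel) -> NullDistribution:
    """Empirical null of (T_FT, Q) at fixed per-SNV totals.

    Counts are drawn from the null (beta-)binomial at the balanced-expression
    observation probability, re-phased exactly as observed data would be, and
    pushed through the same gene-level estimator.  T and Q come from the same
    replicates (joint draws).  Deterministic for a fixed model (including its
    seed), independent of gene order.
    """
    if model.n_sim < 100:
        import warnings

        warnings.warn("n_sim < 100 gives unusable empirical p-values", stacklevel=2)
    key_hash = zlib.crc32(repr(model.cache_key()).encode())
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, key_hash]))
    t_parts, q_parts = [], []
    remaining = model.n_sim
    while remaining > 0:
        size = min(_CHUNK, remaining)
        t, q = _simulate_block(rng, model, size)
        t_parts.append(t)
        q_parts.append(q)
        remaining -= size
    return NullDistribution(
        t_null=np.concatenate(t_parts), q_null=np.concatenate(q_parts), n_sim=model.n_sim
    )


def p_values(
    observed: tuple[float, float], null: NullDistribution, k: int = 2
) -> tuple[float, Optional[float]]:
    """Right-tail empirical p-values for (T, Q) with a 1/(N_sim + 1) floor."""
    t_obs, q_obs = observed
    n_sim = null.n_sim
    floor = 1.0 / (n_sim + 1.0)
    p_ase = max(float(np.sum(null.t_null >= t_obs - _TIE_EPS)) / n_sim, floor)
    if k <= 1:
        return p_ase, None
    p_het = max(float(np.sum(null.q_null >= q_obs - _TIE_EPS)) / n_sim, floor)
    return p_ase, p_het


def _null_model_for(phased: PhasedGene, params: ModelParams, n_sim: int, seed: int) -> NullModel:
    f = params.f_ref_null
    if phased.phase_source == "known":
        hap1_f = tuple(f if s.hap1_is_ref else 1.0 - f for s in phased.snvs)
        known = True
    else:
        hap1_f = tuple(f for _ in phased.snvs)
        known = False
    return NullModel(
        totals=phased.totals,
        rho=params.rho,
        n_sim=n_sim,
        seed=seed,
        hap1_f=hap1_f,
        known_phase=known,
    )


def run_one_sample(
    genes: Sequence[AseUnit],
    params: ModelParams = ModelParams(),
    n_sim: int = 100_000,
    seed: int = 0,
    null_cache: Optional[dict] = None,
) -> list[AseResult]:
    """Analyze a batch of genes; null distributions are cached per shape.

    A gene that fails (e.g. malformed counts) yields a flagged record with
    NaN estimates rather than aborting the batch.  No multiple-testing
    adjustment is applied here; see :mod:`asekit.calling`.
    """
    cache: dict = {} if null_cache is None else null_cache
    results: list[AseResult] = []
    for gene in genes:
        try:
            if gene.has_phase_labels:
                phased = phase_from_labels(gene.snvs, ase_id=gene.ase_id)
            else:
                phased = pseudo_phase(gene.snvs, ase_id=gene.ase_id)
            t, res = _gene_stats_full(phased, params)
            q = res.q_stat
            model = _null_model_for(phased, params, n_sim, seed)
            key = model.cache_key()
            if key not in cache:
                _trim_cache(cache)
                cache[key] = simulate_null(model)
            null = cache[key]
            p_ase, p_het = p_values((t, q), null, k=phased.k)
            results.append(
                AseResult(
                    ase_id=gene.ase_id,
                    maf_estimate=t,
                    p_ase=p_ase,
                    p_heterogeneity=p_het,
                    q_stat=q,
                    n_snvs=phased.k,
                    phase=phased,
                    n_sim_used=n_sim,
                    tau2=res.tau2,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-gene isolation is the contract
            results.append(
                AseResult(
                    ase_id=gene.ase_id,
                    maf_estimate=float("nan"),
                    p_ase=float("nan"),
                    p_heterogeneity=None,
                    q_stat=float("nan"),
                    n_snvs=len(gene.snvs),
                    phase=None,
                    n_sim_used=0,
                    error=str(exc),
                )
            )
    return results
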