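"""Stratified power/FDR benchmark on synthetic allelic counts.

The generator emulates the statistical structure assumed by the model: genes
fall into a 5 x 5 grid of strata (number of SNVs per gene: 1, 2, 3, 4, 5+;
mean reads per SNV: 10-20, 20-30, 30-40, 40-50, 50+), a fixed fraction of
genes per stratum are true positives whose major-haplotype allele counts are
drawn Beta-Binomial(n, mu_A, rho) at a constant signal MAF, and the remaining
genes are true negatives with reference counts Beta-Binomial(n, mu_ref, rho).
Under global pre-existing bias f != 0.5, mu_ref = f and mu_A is the signal
MAF pushed through the odds-weighting bias map of whichever allele carries
the major haplotype.  Per-SNV totals are drawn uniformly within the coverage
bin (the open-ended bins resolve to 50-100 reads and 5-8 SNVs), so stratum
membership — not a particular empirical coverage profile — is what the
benchmark conditions on.

The study scores true-positive rate and false discovery rate of BH-gated
calls per stratum and overall, with strata weighted by their gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import CallConfig, call_ase
from .distributions import betabin_draw, bias_adjusted_mu
from .onesample import AseUnit, ModelParams, run_one_sample
from .phasing import SnvCount
from .twosample import GenePair, run_two_sample

__all__ = [
    "SNV_BINS",
    "COVERAGE_BINS",
    "StratumSpec",
    "SimConfig",
    "SimReport",
    "default_strata",
    "generate_dataset",
    "score",
    "run_study",
]

# "5+" SNVs resolves to uniform 5-8; "50+" coverage to uniform 50-100
SNV_BINS: tuple[str, ...] = ("1", "2", "3", "4", "5+")
COVERAGE_BINS: tuple[tuple[int, int], ...] = (
    (10, 20),
    (20, 30),
    (30, 40),
    (40, 50),
    (50, 100),
)
_COVERAGE_LABELS = ("10-20", "20-30", "30-40", "40-50", "50+")


@dataclass(frozen=True)
class StratumSpec:
    """One cell of the SNV-count x coverage grid."""

    snv_bin: str  # one of SNV_BINS
    coverage_bin: str  # one of _COVERAGE_LABELS
    n_genes: int

    def __post_init__(self) -> None:
        if self.snv_bin not in SNV_BINS:
            raise ValueError(f"unknown SNV bin {self.snv_bin!r}")
        if self.coverage_bin not in _COVERAGE_LABELS:
            raise ValueError(f"unknown coverage bin {self.coverage_bin!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    @property
    def label(self) -> str:
        return f"snv={self.snv_bin},cov={self.coverage_bin}"

    def draw_shape(self, rng: np.random.Generator) -> np.ndarray:
        """Per-SNV totals for one gene in this stratum."""
        if self.snv_bin == "5+":
            k = int(rng.integers(5, 9))
        else:
            k = int(self.snv_bin)
        lo, hi = COVERAGE_BINS[_COVERAGE_LABELS.index(self.coverage_bin)]
        return rng.integers(lo, hi + 1, size=k)


def default_strata(n_genes_per_stratum: int = 40) -> list[StratumSpec]:
    """The full 25-stratum grid with equal gene counts."""
    return [
        StratumSpec(snv_bin=s, coverage_bin=c, n_genes=n_genes_per_stratum)
        for s in SNV_BINS
        for c in _COVERAGE_LABELS
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run."""

    tp_fraction: float = 0.25
    maf_signal: float = 0.8
    rho: float = 0.004
    f_ref_null: float = 0.5
    n_replicates: int = 10
    n_sim: int = 10_000
    mode: str = "one_sample"  # or "two_sample"
    maf_gate: bool = False  # effect-size cutoff in addition to BH
    phase_labels: bool = False  # attach the generating haplotype as true phase
    fdr_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tp_fraction <= 1.0:
            raise ValueError("tp_fraction must lie in [0, 1]")
        if not 0.5 < self.maf_signal < 1.0:
            raise ValueError("maf_signal must lie in (0.5, 1)")
        if self.mode not in ("one_sample", "two_sample"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _draw_gene_counts(
    rng: np.random.Generator,
    totals: np.ndarray,
    is_tp: bool,
    cfg: SimConfig,
) -> list[SnvCount]:
    """Reference/alt counts for one gene (one sample)."""
    f = cfg.f_ref_null
    snvs = []
    for i, n in enumerate(totals):
        n = int(n)
        if is_tp:
            # allele A (randomly ref or alt per SNV) carries the major haplotype
            a_is_ref = bool(rng.integers(0, 2))
            f_a = f if a_is_ref else 1.0 - f
            mu_a = cfg.maf_signal if f == 0.5 else bias_adjusted_mu(cfg.maf_signal, f_a)
            x_a = int(betabin_draw(rng, n, mu_a, cfg.rho, (1,))[0])
            ref = x_a if a_is_ref else n - x_a
            hap1_is_ref = a_is_ref
        else:
            ref = int(betabin_draw(rng, n, f, cfg.rho, (1,))[0])
            hap1_is_ref = bool(rng.integers(0, 2))
        snvs.append(
            SnvCount(
                locus_id=f"snv{i}",
                ref_count=ref,
                alt_count=n - ref,
                hap1_is_ref=hap1_is_ref if cfg.phase_labels else None,
            )
        )
    return snvs


def generate_dataset(
    strata: Sequence[StratumSpec],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
):
    """One replicate's genes with truth labels.

    Returns ``(units, truth)`` where ``units`` is a list of :class:`AseUnit`
    (one-sample mode) or :class:`GenePair` (two-sample mode; the comparison
    sample is always balanced, so every true positive is sample-specific) and
    ``truth`` is a DataFrame with columns ``ase_id``, ``stratum``, ``is_tp``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    units: list = []
    rows = []
    for si, stratum in enumerate(strata):
        n_tp = int(round(cfg.tp_fraction * stratum.n_genes))
        tp_flags = np.zeros(stratum.n_genes, dtype=bool)
        tp_flags[rng.choice(stratum.n_genes, size=n_tp, replace=False)] = True
        for gi in range(stratum.n_genes):
            ase_id = f"s{si}_g{gi}"
            totals = stratum.draw_shape(rng)
            snvs = _draw_gene_counts(rng, totals, bool(tp_flags[gi]), cfg)
            if cfg.mode == "two_sample":
                lo, hi = COVERAGE_BINS[_COVERAGE_LABELS.index(stratum.coverage_bin)]
                totals_other = rng.integers(lo, hi + 1, size=len(totals))
                other = []
                for i, n in enumerate(totals_other):
                    n = int(n)
                    ref = int(betabin_draw(rng, n, cfg.f_ref_null, cfg.rho, (1,))[0])
                    other.append(
                        SnvCount(locus_id=f"snv{i}", ref_count=ref, alt_count=n - ref)
                    )
                units.append(
                    GenePair(
                        ase_id=ase_id,
                        snvs_interest=tuple(snvs),
                        snvs_other=tuple(other),
                    )
                )
            else:
                units.append(AseUnit(ase_id=ase_id, snvs=tuple(snvs)))
            rows.append(
                {"ase_id": ase_id, "stratum": stratum.label, "is_tp": bool(tp_flags[gi])}
            )
    return units, pd.DataFrame(rows)


@dataclass
class SimReport:
    """Replicate-averaged TPR/FDR per stratum and overall."""

    per_stratum: pd.DataFrame
    overall_tpr: float
    overall_tpr_se: float
    overall_fdr: float
    overall_fdr_se: float
    n_replicates: int
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        df = self.per_stratum.copy()
        df["maf_signal"] = self.config.maf_signal
        return df


def score(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum TPR and FDR for one replicate.

    ``calls`` must carry ``ase_called``, ``is_tp`` and ``stratum`` columns.
    FDR is 0 by convention when nothing is called in a stratum.
    """
    required = {"ase_called", "is_tp", "stratum"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")
    out = []
    for label, grp in calls.groupby("stratum", sort=True):
        called = grp["ase_called"].to_numpy(dtype=bool)
        tp = grp["is_tp"].to_numpy(dtype=bool)
        n_tp = int(tp.sum())
        tpr = float((called & tp).sum() / n_tp) if n_tp else float("nan")
        n_called = int(called.sum())
        fdr = float((called & ~tp).sum() / n_called) if n_called else 0.0
        out.append(
            {"stratum": label, "tpr": tpr, "fdr": fdr, "n_genes": len(grp)}
        )
    return pd.DataFrame(out)


def _weighted_overall(stratum_df: pd.DataFrame, col: str) -> float:
    w = stratum_df["n_genes"].to_numpy(dtype=float)
    v = stratum_df[col].to_numpy(dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def run_study(
    cfg: SimConfig,
    strata: Optional[Sequence[StratumSpec]] = None,
    null_cache: Optional[dict] = None,
) -> SimReport:
    """Run the replicate loop: generate, analyze, call, score, aggregate.

    Calls use the significance gate alone by default (``cfg.maf_gate`` adds
    the MAF >= 0.7 or dMAF >= 0.2 effect-size cutoff).  The Monte-Carlo null
    cache is shared across replicates: null distributions depend only on gene
    shape and the analysis seed, not on the replicate's data.
    """
    if strata is None:
        strata = default_strata()
    params = ModelParams(rho=cfg.rho, f_ref_null=cfg.f_ref_null)
    cache: dict = {} if null_cache is None else null_cache
    if cfg.mode == "two_sample":
        call_cfg = CallConfig(
            fdr_level=cfg.fdr_level,
            maf_diff_cutoff=0.2 if cfg.maf_gate else None,
            require_one_sample_support=False,
        )
    else:
        call_cfg = CallConfig(
            fdr_level=cfg.fdr_level,
            maf_cutoff=0.7 if cfg.maf_gate else None,
        )
    stratum_frames = []
    overall_tpr, overall_fdr = [], []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_000_000 + rep]))
        units, truth = generate_dataset(strata, cfg, rng=rng)
        if cfg.mode == "two_sample":
            results = run_two_sample(
                units, params, n_sim=cfg.n_sim, seed=cfg.seed, null_cache=cache
            )
        else:
            results = run_one_sample(
                units, params, n_sim=cfg.n_sim, seed=cfg.seed, null_cache=cache
            )
        calls = call_ase(results, call_cfg)
        calls = calls.merge(truth, on="ase_id", validate="one_to_one")
        rep_scores = score(calls)
        rep_scores["replicate"] = rep
        stratum_frames.append(rep_scores)
        overall_tpr.append(_weighted_overall(rep_scores, "tpr"))
        overall_fdr.append(_weighted_overall(rep_scores, "fdr"))
    all_reps = pd.concat(stratum_frames, ignore_index=True)
    per_stratum = (
        all_reps.groupby("stratum", sort=True)
        .agg(
            tpr_mean=("tpr", "mean"),
            tpr_se=("tpr", "sem"),
            fdr_mean=("fdr", "mean"),
            fdr_se=("fdr", "sem"),
            n_genes=("n_genes", "first"),
        )
        .reset_index()
    )
    tpr_arr = np.array(overall_tpr, dtype=float)
    fdr_arr = np.array(overall_fdr, dtype=float)
    sem = lambda a: float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0
    return SimReport(
        per_stratum=per_stratum,
        overall_tpr=float(np.nanmean(tpr_arr)),
        overall_tpr_se=sem(tpr_arr[np.isfinite(tpr_arr)]),
        overall_fdr=float(np.nanmean(fdr_arr)),
        overall_fdr_se=sem(fdr_arr[np.isfinite(fdr_arr)]),
        n_replicates=cfg.n_replicates,
        config=cfg,
    )
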