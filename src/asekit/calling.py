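"""Turning per-gene statistics into ASE calls.

A gene is declared ASE when it clears both a significance gate (BH-adjusted
Monte-Carlo p-value at a chosen FDR level, adjusted within one sample's batch
of tested genes) and an effect-size gate (estimated MAF >= 0.7 in one-sample
mode, estimated MAF difference >= 0.2 in two-sample mode) — highly covered
genes otherwise reach significance at allelic ratios too close to 1:1 to be
biologically interesting.  Two-sample calls can additionally require the gene
to show one-sample ASE evidence in the sample of interest.  Multi-SNV genes
whose heterogeneity p-value survives its own BH adjustment are flagged as
possibly isoform-specific; single-SNV genes have no heterogeneity test and
are excluded from that adjustment family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .onesample import AseResult
from .twosample import TwoSampleAseResult

__all__ = ["CallConfig", "bh_adjust", "call_ase", "results_frame"]


@dataclass(frozen=True)
class CallConfig:
    fdr_level: float = 0.05
    maf_cutoff: Optional[float] = 0.7
    maf_diff_cutoff: Optional[float] = 0.2
    het_fdr_level: float = 0.05
    require_one_sample_support: bool = True

    def __post_init__(self) -> None:
        for name in ("fdr_level", "maf_cutoff", "maf_diff_cutoff", "het_fdr_level"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_frame(
    results: Sequence[Union[AseResult, TwoSampleAseResult]]
) -> pd.DataFrame:
    """Tabulate a result batch; one row per gene."""
    if not results:
        return pd.DataFrame(
            columns=["ase_id", "n_snvs", "effect", "p_ase", "p_het", "error"]
        )
    two_sample = isinstance(results[0], TwoSampleAseResult)
    rows = []
    for r in results:
        rows.append(
            {
                "ase_id": r.ase_id,
                "n_snvs": r.n_snvs,
                "effect": r.maf_difference if two_sample else r.maf_estimate,
                "p_ase": r.p_ase,
                "p_het": r.p_heterogeneity if r.p_heterogeneity is not None else np.nan,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


def call_ase(
    results: Sequence[Union[AseResult, TwoSampleAseResult]],
    cfg: CallConfig = CallConfig(),
    one_sample_support: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Annotate one sample's batch of results with ASE call flags.

    Returns the :func:`results_frame` table with columns ``p_ase_adjusted``,
    ``p_het_adjusted``, ``ase_called`` and ``isoform_specific_flag``.  BH
    adjustment spans the batch (one sample = one multiplicity family);
    heterogeneity adjustment spans multi-SNV genes only.  In two-sample mode,
    ``one_sample_support`` supplies the per-gene one-sample call for the
    sample of interest when ``require_one_sample_support`` is set.
    """
    if not results:
        raise ValueError("empty result batch")
    kinds = {isinstance(r, TwoSampleAseResult) for r in results}
    if len(kinds) > 1:
        raise ValueError("mixed one-sample and two-sample results in one batch")
    two_sample = kinds.pop()
    df = results_frame(results)
    ok = df["p_ase"].notna().to_numpy()

    p_adj = np.full(len(df), np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(df.loc[ok, "p_ase"].to_numpy())
    df["p_ase_adjusted"] = p_adj

    het_adj = np.full(len(df), np.nan)
    het_mask = ok & (df["n_snvs"].to_numpy() > 1) & df["p_het"].notna().to_numpy()
    if het_mask.any():
        het_adj[het_mask] = bh_adjust(df.loc[het_mask, "p_het"].to_numpy())
    df["p_het_adjusted"] = het_adj

    sig = np.where(np.isnan(p_adj), False, p_adj <= cfg.fdr_level)
    effect = df["effect"].to_numpy()
    if two_sample:
        gate = (
            np.ones(len(df), dtype=bool)
            if cfg.maf_diff_cutoff is None
            else effect >= cfg.maf_diff_cutoff
        )
        called = sig & gate
        if cfg.require_one_sample_support:
            if one_sample_support is None:
                raise ValueError(
                    "two-sample calling with require_one_sample_support needs "
                    "one_sample_support flags (or disable the gate)"
                )
            called &= np.asarray(one_sample_support, dtype=bool)
    else:
        gate = (
            np.ones(len(df), dtype=bool)
            if cfg.maf_cutoff is None
            else effect >= cfg.maf_cutoff
        )
        called = sig & gate
    df["ase_called"] = called
    df["isoform_specific_flag"] = np.where(
        np.isnan(het_adj), False, het_adj <= cfg.het_fdr_level
    )
    return df
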