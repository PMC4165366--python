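"""Model/Results interface over the one- and two-sample analyses.

`AseModel` holds one sample's allelic counts plus the global nuisance
parameters (overdispersion rho, pre-existing reference bias f); `fit()` runs
the Monte-Carlo-calibrated meta-analysis and returns an `AseResults` carrying
per-gene MAF estimates, p-values, heterogeneity diagnostics and call flags.
`DifferentialAseModel` is the two-sample analogue testing for sample-specific
imbalance.  Both constructors accept the tabular schema of
:mod:`asekit.io` via ``from_dataframe``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import CallConfig, call_ase
from .io import table_to_gene_pairs, table_to_units
from .onesample import AseResult, AseUnit, ModelParams, run_one_sample
from .twosample import GenePair, TwoSampleAseResult, run_two_sample

__all__ = ["AseModel", "AseResults", "DifferentialAseModel", "DifferentialAseResults"]


class AseModel:
    """One-sample allele-specific expression model.

    Parameters
    ----------
    units : sequence of AseUnit
        Genes with their per-SNV allelic counts (and optional phase labels).
    rho : float
        Beta-binomial overdispersion shared across SNVs.
    f_ref_null : float
        Probability of observing the reference allele under balanced
        expression (0.5 = no pre-existing bias).
    """

    def __init__(self, units: Sequence[AseUnit], rho: float = 0.0, f_ref_null: float = 0.5):
        self.units = list(units)
        self.params = ModelParams(rho=rho, f_ref_null=f_ref_null)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        rho: float = 0.0,
        f_ref_null: float = 0.5,
        sample: Optional[str] = None,
    ) -> "AseModel":
        return cls(table_to_units(df, sample=sample), rho=rho, f_ref_null=f_ref_null)

    def fit(
        self, n_sim: int = 100_000, seed: int = 0, null_cache: Optional[dict] = None
    ) -> "AseResults":
        results = run_one_sample(
            self.units, self.params, n_sim=n_sim, seed=seed, null_cache=null_cache
        )
        return AseResults(self, results)


class AseResults:
    """Fitted one-sample results; one row per gene."""

    def __init__(self, model: AseModel, results: list[AseResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "ase_id": r.ase_id,
                    "n_snvs": r.n_snvs,
                    "maf": r.maf_estimate,
                    "p_ase": r.p_ase,
                    "p_het": np.nan if r.p_heterogeneity is None else r.p_heterogeneity,
                    "q_stat": r.q_stat,
                    "tau2": r.tau2,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)

    def call(self, cfg: CallConfig = CallConfig()) -> pd.DataFrame:
        """BH-adjust within this batch and apply the calling gates."""
        return call_ase(self.results, cfg)

    def summary(self, cfg: CallConfig = CallConfig()) -> str:
        calls = self.call(cfg)
        n = len(calls)
        n_called = int(calls["ase_called"].sum())
        n_flag = int(calls["isoform_specific_flag"].sum())
        params = self.model.params
        lines = [
            "One-sample allele-specific expression results",
            "=" * 61,
            f"Genes tested:            {n}",
            f"ASE calls (BH<={cfg.fdr_level:g}, MAF>={cfg.maf_cutoff}): {n_called}",
            f"Isoform-specific flags:  {n_flag}",
            f"Overdispersion rho:      {params.rho:g}",
            f"Reference bias f(0.5):   {params.f_ref_null:g}",
            "-" * 61,
            calls[
                ["ase_id", "n_snvs", "effect", "p_ase", "p_ase_adjusted", "ase_called"]
            ]
            .rename(columns={"effect": "maf"})
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def save(self, path: str, cfg: Optional[CallConfig] = None) -> pd.DataFrame:
        from .io import write_results

        return write_results(self.results, path, cfg=cfg)


class DifferentialAseModel:
    """Two-sample (sample-of-interest vs. comparison) differential ASE model."""

    def __init__(self, pairs: Sequence[GenePair], rho: float = 0.0, f_ref_null: float = 0.5):
        self.pairs = list(pairs)
        self.params = ModelParams(rho=rho, f_ref_null=f_ref_null)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, rho: float = 0.0, f_ref_null: float = 0.5
    ) -> "DifferentialAseModel":
        return cls(table_to_gene_pairs(df), rho=rho, f_ref_null=f_ref_null)

    def fit(
        self, n_sim: int = 100_000, seed: int = 0, null_cache: Optional[dict] = None
    ) -> "DifferentialAseResults":
        results = run_two_sample(
            self.pairs, self.params, n_sim=n_sim, seed=seed, null_cache=null_cache
        )
        return DifferentialAseResults(self, results)


class DifferentialAseResults:
    """Fitted two-sample results; effect is the MAF difference."""

    def __init__(self, model: DifferentialAseModel, results: list[TwoSampleAseResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "ase_id": r.ase_id,
                    "n_snvs": r.n_snvs,
                    "maf_difference": r.maf_difference,
                    "p_ase": r.p_ase,
                    "p_het": np.nan if r.p_heterogeneity is None else r.p_heterogeneity,
                    "q_stat": r.q_stat,
                    "null_p_hap1": r.null_p_hap1,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)

    def one_sample_support(
        self, n_sim: int = 100_000, seed: int = 0, cfg: CallConfig = CallConfig()
    ) -> np.ndarray:
        """One-sample ASE calls for the sample of interest, from the same counts."""
        units = [
            AseUnit(ase_id=p.ase_id, snvs=p.snvs_interest) for p in self.model.pairs
        ]
        sub = AseModel(
            units,
            rho=self.model.params.rho,
            f_ref_null=self.model.params.f_ref_null,
        ).fit(n_sim=n_sim, seed=seed)
        return sub.call(cfg)["ase_called"].to_numpy(dtype=bool)

    def call(
        self,
        cfg: CallConfig = CallConfig(),
        one_sample_support: Optional[Sequence[bool]] = None,
        n_sim_support: int = 10_000,
        seed: int = 0,
    ) -> pd.DataFrame:
        if cfg.require_one_sample_support and one_sample_support is None:
            one_sample_support = self.one_sample_support(n_sim=n_sim_support, seed=seed)
        return call_ase(self.results, cfg, one_sample_support=one_sample_support)

    def summary(self, cfg: CallConfig = CallConfig(), **kwargs) -> str:
        calls = self.call(cfg, **kwargs)
        lines = [
            "Two-sample differential allele-specific expression results",
            "=" * 61,
            f"Genes tested:       {len(calls)}",
            f"Differential calls: {int(calls['ase_called'].sum())}",
            "-" * 61,
            calls[
                ["ase_id", "n_snvs", "effect", "p_ase", "p_ase_adjusted", "ase_called"]
            ]
            .rename(columns={"effect": "maf_difference"})
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def save(self, path: str, cfg: Optional[CallConfig] = None, **kwargs) -> pd.DataFrame:
        from .io import write_results

        support = kwargs.pop("one_sample_support", None)
        if support is None and (cfg is None or cfg.require_one_sample_support):
            if cfg is None:
                cfg = CallConfig()
            support = self.one_sample_support(cfg=cfg)
        return write_results(self.results, path, cfg=cfg, one_sample_support=support)
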