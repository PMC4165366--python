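"""Readers, writers, filters and nuisance-parameter estimators.

The tabular interchange format ("SNV table") is a TSV with one row per
heterozygous SNV and sample:

    sample_id  ase_id  chrom  pos  ref  alt  rna_ref_count  rna_alt_count
    [dna_ref_count  dna_alt_count]  [rna_ref_count2  rna_alt_count2]
    [hap1_is_ref]

Positions are 1-based (VCF convention); BED gene maps are converted on read.
VCF input is supported read-only through cyvcf2, taking per-sample allelic
depths (AD) and assigning genes from a BED interval map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calling import CallConfig, call_ase
from .distributions import BiasSpec
from .onesample import AseResult, AseUnit
from .phasing import SnvCount
from .twosample import GenePair, TwoSampleAseResult

logger = logging.getLogger("asekit")

__all__ = [
    "REQUIRED_COLUMNS",
    "FilterLog",
    "read_snv_table",
    "filter_heterozygous",
    "estimate_global_bias",
    "estimate_overdispersion",
    "table_to_units",
    "table_to_gene_pairs",
    "units_to_table",
    "write_results",
    "read_results",
    "generate_fixtures",
]

REQUIRED_COLUMNS = (
    "sample_id",
    "ase_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "rna_ref_count",
    "rna_alt_count",
)
_BASES = {"A", "C", "G", "T"}


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNV table missing required columns: {missing}")
    n_input = len(df)
    bad = pd.Series(False, index=df.index)
    for col in ("rna_ref_count", "rna_alt_count", "dna_ref_count", "dna_alt_count"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad |= vals.isna() | (vals < 0) | (vals != vals.round())
    multi = ~(df["ref"].isin(_BASES) & df["alt"].isin(_BASES)) | (
        df["ref"] == df["alt"]
    )
    if multi.any():
        logger.warning("dropping %d multi-allelic/non-SNV rows", int(multi.sum()))
    bad |= multi
    if bad.any():
        for idx in df.index[bad][:20]:
            logger.warning("malformed SNV row dropped: index %s", idx)
    if n_input and (bad & ~multi).sum() / n_input > 0.01:
        raise ValueError(
            f"{int((bad & ~multi).sum())} of {n_input} rows malformed (>1%); "
            "refusing to proceed"
        )
    df = df.loc[~bad].copy()
    df["pos"] = df["pos"].astype(int)
    for col in ("rna_ref_count", "rna_alt_count", "dna_ref_count", "dna_alt_count"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    dup = df.duplicated(subset=["sample_id", "chrom", "pos"], keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (chrom, pos) within sample at rows {list(df.index[dup][:5])}"
        )
    return df.reset_index(drop=True)


def _read_gene_map(path: str) -> dict:
    """BED gene map -> per-chromosome interval trees (1-based inclusive)."""
    from intervaltree import IntervalTree

    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=range(4),
    )
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed.groupby("chrom"):
        tree = IntervalTree()
        for _, row in grp.iterrows():
            # BED half-open 0-based -> tree over 1-based positions
            tree[int(row["start"]) + 1 : int(row["end"]) + 1] = row["name"]
        trees[str(chrom)] = tree
    return trees


def _read_vcf(path: str, gene_map: str, sample: Optional[str] = None) -> pd.DataFrame:
    from cyvcf2 import VCF

    trees = _read_gene_map(gene_map)
    vcf = VCF(path)
    samples = vcf.samples
    if sample is None:
        if len(samples) != 1:
            raise ValueError(f"VCF has samples {samples}; pass sample=")
        sample = samples[0]
    s_idx = samples.index(sample)
    rows = []
    n_multi = n_unassigned = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            logger.warning("skipping multi-allelic record at %s:%d", var.CHROM, var.POS)
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        ref_c, alt_c = int(ad[s_idx][0]), int(ad[s_idx][1])
        hits = trees.get(var.CHROM, None)
        names = sorted(iv.data for iv in hits[var.POS]) if hits else []
        if not names:
            n_unassigned += 1
            continue
        rows.append(
            {
                "sample_id": sample,
                "ase_id": names[0],
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "rna_ref_count": ref_c,
                "rna_alt_count": alt_c,
            }
        )
    if n_multi or n_unassigned:
        logger.info(
            "VCF read: %d multi-allelic skipped, %d outside gene map", n_multi, n_unassigned
        )
    return pd.DataFrame(rows)


def read_snv_table(
    path: str,
    dialect: str = "tsv",
    gene_map: Optional[str] = None,
    sample: Optional[str] = None,
) -> pd.DataFrame:
    """Read and validate an SNV table from TSV or VCF (+ BED gene map)."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "vcf":
        if gene_map is None:
            raise ValueError("VCF input needs a BED gene map")
        df = _read_vcf(path, gene_map, sample=sample)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _validate_table(df)


@dataclass
class FilterLog:
    """Per-rule counts of SNVs removed by :func:`filter_heterozygous`."""

    dna_min_reads: int = 0
    dna_min_fraction: int = 0
    variant_proximity: int = 0
    rna_min_reads: int = 0
    read_sharing_merge: int = 0
    blacklist: int = 0

    def total(self) -> int:
        return (
            self.dna_min_reads
            + self.dna_min_fraction
            + self.variant_proximity
            + self.rna_min_reads
            + self.read_sharing_merge
            + self.blacklist
        )


def filter_heterozygous(
    table: pd.DataFrame,
    min_dna_reads: int = 5,
    min_dna_fraction: float = 0.10,
    proximity_bp: int = 10,
    min_rna_reads: int = 10,
    merge_distance_bp: int = 76,
    blacklist: Optional[str] = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Heterozygosity and coverage filters applied per sample.

    Rules, in order: (1) both alleles supported by >= ``min_dna_reads`` DNA
    reads and >= ``min_dna_fraction`` of the DNA reads at the locus (applied
    only when DNA columns are present); (2) SNVs within ``proximity_bp`` of
    another variant are removed (both of them); (3) RNA coverage >=
    ``min_rna_reads``; (4) of any SNVs closer than ``merge_distance_bp``
    (default one read length — such loci can share reads, violating the
    independence assumption), only the highest-RNA-coverage locus is kept;
    (5) optional blacklist BED drops annotated artifact regions.  The whole
    pipeline is idempotent.
    """
    df = table.copy()
    log = FilterLog()
    has_dna = {"dna_ref_count", "dna_alt_count"}.issubset(df.columns)
    if has_dna:
        dna_n = df["dna_ref_count"] + df["dna_alt_count"]
        ok_reads = (df["dna_ref_count"] >= min_dna_reads) & (
            df["dna_alt_count"] >= min_dna_reads
        )
        log.dna_min_reads = int((~ok_reads).sum())
        df = df[ok_reads]
        dna_n = dna_n[ok_reads]
        frac_ref = df["dna_ref_count"] / dna_n
        ok_frac = (frac_ref >= min_dna_fraction) & (1.0 - frac_ref >= min_dna_fraction)
        log.dna_min_fraction = int((~ok_frac).sum())
        df = df[ok_frac]

    if blacklist is not None:
        trees = _read_gene_map(blacklist)
        hit = df.apply(
            lambda r: r["chrom"] in trees and bool(trees[r["chrom"]][r["pos"]]), axis=1
        )
        log.blacklist = int(hit.sum())
        df = df[~hit.to_numpy(dtype=bool)] if len(df) else df

    # proximity: drop every SNV with a neighbor within proximity_bp
    keep_idx = []
    for _, grp in df.groupby(["sample_id", "chrom"], sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        close = np.zeros(len(pos_sorted), dtype=bool)
        gaps = np.diff(pos_sorted)
        close[:-1] |= gaps <= proximity_bp
        close[1:] |= gaps <= proximity_bp
        keep_idx.extend(grp.index[order[~close]])
    log.variant_proximity = len(df) - len(keep_idx)
    df = df.loc[sorted(keep_idx)]

    rna_n = df["rna_ref_count"] + df["rna_alt_count"]
    ok_rna = rna_n >= min_rna_reads
    log.rna_min_reads = int((~ok_rna).sum())
    df = df[ok_rna]

    # read-sharing merge: within a chain of loci linked by gaps < merge
    # distance, keep the highest-RNA-coverage one (ties: first position)
    keep_idx = []
    for _, grp in df.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        cov = (grp["rna_ref_count"] + grp["rna_alt_count"]).to_numpy()
        chain_start = np.concatenate([[True], np.diff(pos) >= merge_distance_bp])
        chain_id = np.cumsum(chain_start)
        for _, members in pd.Series(range(len(pos)), index=chain_id).groupby(level=0):
            ix = members.to_numpy()
            keep_idx.append(grp.index[ix[np.argmax(cov[ix])]])
    log.read_sharing_merge = len(df) - len(keep_idx)
    df = df.loc[sorted(keep_idx)]

    if log.total():
        logger.info("filter_heterozygous removed %d SNVs: %s", log.total(), log)
    return df.reset_index(drop=True), log


def estimate_global_bias(table: pd.DataFrame) -> BiasSpec:
    """Count-weighted mean reference fraction across heterozygous SNVs.

    A method-of-moments stand-in for the global pre-existing bias f_ref(0.5);
    it assumes imbalance directions are symmetric across the transcriptome so
    haplotype effects average out.
    """
    if len(table) == 0:
        raise ValueError("cannot estimate bias from an empty table")
    if len(table) < 100:
        logger.warning("bias estimate from only %d SNVs is unstable", len(table))
    ref = table["rna_ref_count"].to_numpy(dtype=float)
    n = ref + table["rna_alt_count"].to_numpy(dtype=float)
    f = float(ref.sum() / n.sum())
    return BiasSpec(f_ref_null=min(max(f, 1e-6), 1.0 - 1e-6))


def estimate_overdispersion(table: pd.DataFrame, f_ref_null: Optional[float] = None) -> float:
    """Method-of-moments overdispersion from excess variance of ref fractions.

    For a beta-binomial ref fraction p_i at total n_i with mean f,
    E[(p_i - f)^2] = f (1 - f) (rho (n_i - 1) + 1) / n_i; solving the averaged
    moment equation for rho and flooring at 0.  Genes with genuine ASE inflate
    the estimate, so this is best run on a large SNV set where strong
    imbalance is rare.
    """
    if len(table) == 0:
        raise ValueError("cannot estimate overdispersion from an empty table")
    ref = table["rna_ref_count"].to_numpy(dtype=float)
    n = ref + table["rna_alt_count"].to_numpy(dtype=float)
    if np.any(n <= 0):
        raise ValueError("zero-coverage rows present; filter first")
    f = f_ref_null if f_ref_null is not None else float(ref.sum() / n.sum())
    p = ref / n
    mean_sq = float(np.mean((p - f) ** 2))
    inv_n = float(np.mean(1.0 / n))
    denom = f * (1.0 - f) * float(np.mean(1.0 - 1.0 / n))
    if denom <= 0:
        return 0.0
    rho = (mean_sq - f * (1.0 - f) * inv_n) / denom
    return max(0.0, float(rho))


def _sort_key(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos"], kind="mergesort")


def table_to_units(table: pd.DataFrame, sample: Optional[str] = None) -> list[AseUnit]:
    """Group one sample's rows into :class:`AseUnit` genes (position order)."""
    df = table if sample is None else table[table["sample_id"] == sample]
    units = []
    has_labels = "hap1_is_ref" in df.columns
    for ase_id, grp in df.groupby("ase_id", sort=True):
        grp = _sort_key(grp)
        snvs = tuple(
            SnvCount(
                locus_id=f"{r.chrom}:{r.pos}",
                ref_count=int(r.rna_ref_count),
                alt_count=int(r.rna_alt_count),
                ref_allele=str(r.ref),
                alt_allele=str(r.alt),
                hap1_is_ref=(
                    bool(r.hap1_is_ref)
                    if has_labels and pd.notna(r.hap1_is_ref)
                    else None
                ),
            )
            for r in grp.itertuples()
        )
        units.append(AseUnit(ase_id=str(ase_id), snvs=snvs))
    return units


def table_to_gene_pairs(table: pd.DataFrame) -> list[GenePair]:
    """Build two-sample gene pairs from rna_*_count2 companion columns."""
    if not {"rna_ref_count2", "rna_alt_count2"}.issubset(table.columns):
        raise ValueError("two-sample input needs rna_ref_count2/rna_alt_count2 columns")
    pairs = []
    for ase_id, grp in table.groupby("ase_id", sort=True):
        grp = _sort_key(grp)
        interest, other = [], []
        for r in grp.itertuples():
            locus = f"{r.chrom}:{r.pos}"
            interest.append(
                SnvCount(locus_id=locus, ref_count=int(r.rna_ref_count),
                         alt_count=int(r.rna_alt_count),
                         ref_allele=str(r.ref), alt_allele=str(r.alt))
            )
            other.append(
                SnvCount(locus_id=locus, ref_count=int(r.rna_ref_count2),
                         alt_count=int(r.rna_alt_count2),
                         ref_allele=str(r.ref), alt_allele=str(r.alt))
            )
        pairs.append(
            GenePair(ase_id=str(ase_id), snvs_interest=tuple(interest),
                     snvs_other=tuple(other))
        )
    return pairs


def units_to_table(
    units: Sequence[Union[AseUnit, GenePair]], sample_id: str = "sample1"
) -> pd.DataFrame:
    """Serialize generated units back to the tabular schema (synthetic loci)."""
    rows = []
    pos = 1000
    for unit in units:
        two = isinstance(unit, GenePair)
        snvs = unit.snvs_interest if two else unit.snvs
        for i, s in enumerate(snvs):
            row = {
                "sample_id": sample_id,
                "ase_id": unit.ase_id,
                "chrom": "chrS",
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "rna_ref_count": s.ref_count,
                "rna_alt_count": s.alt_count,
            }
            if s.hap1_is_ref is not None:
                row["hap1_is_ref"] = s.hap1_is_ref
            if two:
                o = unit.snvs_other[i]
                row["rna_ref_count2"] = o.ref_count
                row["rna_alt_count2"] = o.alt_count
            rows.append(row)
            pos += 200
    return pd.DataFrame(rows)


RESULT_COLUMNS = [
    "ase_id",
    "n_snvs",
    "effect",
    "p_ase",
    "p_ase_adjusted",
    "p_het",
    "p_het_adjusted",
    "ase_called",
    "isoform_specific_flag",
    "phase",
]


def write_results(
    results: Sequence[Union[AseResult, TwoSampleAseResult]],
    path: str,
    cfg: Optional[CallConfig] = None,
    one_sample_support: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Write per-gene results (with BH-adjusted p-values and call flags) as TSV.

    The ``effect`` column is the MAF estimate in one-sample mode and the MAF
    difference in two-sample mode; ``phase`` lists the major allele per SNV.
    Returns the written frame.  An empty batch writes a header-only file.
    """
    if not results:
        pd.DataFrame(columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    two_sample = isinstance(results[0], TwoSampleAseResult)
    if cfg is None:
        cfg = (
            CallConfig(require_one_sample_support=one_sample_support is not None)
            if two_sample
            else CallConfig()
        )
    df = call_ase(results, cfg, one_sample_support=one_sample_support)
    phases = []
    for r in results:
        phased = r.phase_interest if two_sample else r.phase
        if phased is None:
            phases.append("")
        else:
            phases.append(
                ",".join("ref" if m else "alt" for m in phased.major_is_ref)
            )
    df = df.copy()
    df["phase"] = phases
    out = df[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return out


def read_results(path: str) -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` output."""
    return pd.read_csv(path, sep="\t")


def generate_fixtures(cfg, out_prefix: str, strata=None, sample_id: str = "sim") -> dict:
    """Write a synthetic SNV table plus truth sidecar; bit-identical per seed.

    ``cfg`` is a :class:`asekit.simulation.SimConfig`; the default strata are
    a compact mix covering single- and multi-SNV genes at several coverages.
    Returns the paths written.
    """
    from .simulation import StratumSpec, generate_dataset

    if strata is None:
        strata = [
            StratumSpec("1", "10-20", 10),
            StratumSpec("2", "20-30", 10),
            StratumSpec("3", "30-40", 5),
            StratumSpec("5+", "50+", 5),
        ]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 424242]))
    units, truth = generate_dataset(strata, cfg, rng=rng)
    table = units_to_table(units, sample_id=sample_id)
    counts_path = f"{out_prefix}.counts.tsv"
    truth_path = f"{out_prefix}.truth.tsv"
    table.to_csv(counts_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"counts": counts_path, "truth": truth_path}
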