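"""Genome-wide heterozygosity from a single-sample genotype table.

Heterozygosity is the proportion of heterozygous genotypes among all
retained genotypes INCLUDING monomorphic (hom-ref) sites, after
removing sites with divergent read depth (> 3-fold or < 0.3-fold of
the expected mean, strict inequalities) and sites with too much
missing data (> 5%; for a single sample this removes missing calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from ._util import InputError

#: genotype codes used in the ``gt`` column
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class GenotypeTable:
    """Per-site genotype class and read depth for one sample.

    Columns: chrom, pos (1-based, VCF convention), gt (0 hom-ref /
    1 het / 2 hom-alt / -1 missing), depth.  ``filter_counts`` carries
    bookkeeping once :func:`filter_sites` has run.
    """

    df: pd.DataFrame
    filter_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        need = {"chrom", "pos", "gt", "depth"}
        if not need <= set(self.df.columns):
            raise InputError(f"genotype table needs columns {sorted(need)}")
        if (self.df["depth"] < 0).any():
            raise InputError("negative depths")
        if self.df.duplicated(["chrom", "pos"]).any():
            raise InputError("duplicate positions")

    def __len__(self):
        return len(self.df)


@dataclass
class HetEstimate:
    """Heterozygosity with full filter bookkeeping."""

    n_sites_total: int
    n_removed_depth: int
    n_removed_missing: int
    n_retained: int
    n_het: int
    heterozygosity: float
    exact: Fraction

    def __post_init__(self):
        if self.n_sites_total != self.n_retained + self.n_removed_depth + self.n_removed_missing:
            raise InputError("heterozygosity bookkeeping does not sum")


def filter_sites(
    table: GenotypeTable,
    mean_depth: float,
    high_fold: float = 3.0,
    low_fold: float = 0.3,
    max_missing: float = 0.05,
) -> GenotypeTable:
    """Depth and missingness filters, in that order.

    Removes sites with depth > ``high_fold`` * mean or depth <
    ``low_fold`` * mean (strict inequalities: at mean 20 a depth of 60
    is kept, 61 removed; 6 kept, 5 removed), then sites whose missing
    fraction exceeds ``max_missing`` (a single missing genotype is
    fraction 1).  Counts are recorded on the returned table.
    """
    if mean_depth <= 0:
        raise InputError("mean_depth must be > 0")
    df = table.df
    depth_bad = (df["depth"] > high_fold * mean_depth) | (df["depth"] < low_fold * mean_depth)
    n_depth = int(depth_bad.sum())
    df2 = df[~depth_bad]
    missing_frac = (df2["gt"] == MISSING).astype(float)  # single sample: 0 or 1
    miss_bad = missing_frac > max_missing
    n_miss = int(miss_bad.sum())
    out = GenotypeTable(df2[~miss_bad].reset_index(drop=True))
    out.filter_counts = {
        "n_input": len(df),
        "n_removed_depth": n_depth,
        "n_removed_missing": n_miss,
        "mean_depth": float(mean_depth),
    }
    return out


def heterozygosity(table: GenotypeTable) -> HetEstimate:
    """n_het / n_retained, monomorphic sites included in the denominator."""
    if len(table) == 0:
        raise InputError("empty genotype table")
    n_het = int((table.df["gt"] == HET).sum())
    n_ret = len(table)
    fc = table.filter_counts
    n_depth = fc.get("n_removed_depth", 0)
    n_miss = fc.get("n_removed_missing", 0)
    return HetEstimate(
        n_sites_total=fc.get("n_input", n_ret),
        n_removed_depth=n_depth,
        n_removed_missing=n_miss,
        n_retained=n_ret,
        n_het=n_het,
        heterozygosity=n_het / n_ret,
        exact=Fraction(n_het, n_ret),
    )


# ---------------------------------------------------------------------------
# VCF I/O (minimal single-sample: CHROM POS REF ALT GT DP)

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path, sample: str = "sample1") -> None:
    """Write a minimal single-sample VCF (GT and DP fields)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(table.df["chrom"]):
            n = int(table.df.loc[table.df["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={n + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for row in table.df.itertuples(index=False):
            alt = "A" if row.gt in (HET, HOM_ALT) else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\tG\t{alt}\t.\tPASS\t.\tGT:DP\t"
                f"{_GT_STRINGS[int(row.gt)]}:{int(row.depth)}\n"
            )


def read_vcf(path) -> GenotypeTable:
    """Read GT and DP for one sample; multi-sample files are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if len(vcf.samples) != 1:
        raise InputError(
            f"expected a single-sample VCF, found {len(vcf.samples)} samples"
        )
    chroms, poss, gts, depths = [], [], [], []
    for var in vcf:
        code = int(var.gt_types[0])  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        gt = MISSING if code == 3 else code
        try:
            dp = int(var.format("DP")[0][0])
        except (TypeError, KeyError):
            dp = 0
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gts.append(gt)
        depths.append(max(dp, 0))
    return GenotypeTable(
        pd.DataFrame({"chrom": chroms, "pos": poss, "gt": gts, "depth": depths})
    )


def report_tsv(est: HetEstimate, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "n_sites_total\tn_removed_depth\tn_removed_missing\tn_retained\t"
            "n_het\theterozygosity\texact\n"
        )
        fh.write(
            f"{est.n_sites_total}\t{est.n_removed_depth}\t{est.n_removed_missing}\t"
            f"{est.n_retained}\t{est.n_het}\t{est.heterozygosity:.6g}\t{est.exact}\n"
        )
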