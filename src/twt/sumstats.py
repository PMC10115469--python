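"""Reading, harmonizing and grouping GWAS summary statistics.

Summary data arrive as flat tables of per-(SNP, trait) Wald Z-scores with
allele labels; the reference panel supplies genotypes (VCF or PLINK
bed/bim/fam) for LD estimation.  Before any testing the two sources must
agree on which allele each Z-score counts: by default a SNP whose
(counted, alternative) allele pair differs from the panel's is removed
outright; an optional swap mode instead accepts a reversed pair by negating
the Z-score, except for strand-ambiguous A/T and C/G variants whose
orientation cannot be resolved from labels alone.

SNPs are grouped into gene-level test units by position: a SNP belongs to
every gene whose region, widened by a flank (5 kb by default), contains it
— overlapping genes each receive the SNP.  Genes with too few or too many
SNPs are excluded from testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .corr import (
    CovariateKind,
    SnpCorrMatrix,
    compute_principal_coordinates,
    partial_genotype_correlation,
    pearson_genotype_correlation,
)
from .stats import ZMatrix

__all__ = [
    "SummaryTable",
    "ReferencePanel",
    "GeneRegion",
    "GeneTestUnit",
    "read_summary_table",
    "read_vcf_panel",
    "read_plink_panel",
    "read_gene_regions",
    "harmonize_alleles",
    "assign_snps_to_genes",
    "build_gene_units",
]

logger = logging.getLogger("twt")

REQUIRED_COLUMNS = ("snp", "trait", "z", "counted_allele", "other_allele")
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryTable:
    """Long-format summary statistics: one row per (SNP, trait)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"summary table is missing column(s): {', '.join(missing)}")
        dup = self.data.duplicated(subset=["snp", "trait"])
        if dup.any():
            keys = self.data.loc[dup, ["snp", "trait"]].iloc[0].tolist()
            raise ValueError(f"duplicate (SNP, trait) record, e.g. {tuple(keys)}")
        if not np.all(np.isfinite(self.data["z"].to_numpy(dtype=float))):
            raise ValueError("summary table contains non-finite Z values")

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def snps(self) -> list[str]:
        return list(pd.unique(self.data["snp"]))

    def alleles(self) -> pd.DataFrame:
        return (
            self.data.drop_duplicates("snp")
            .set_index("snp")[["counted_allele", "other_allele"]]
        )

    def positions(self) -> pd.DataFrame:
        if not {"chrom", "pos"}.issubset(self.data.columns):
            raise ValueError("summary table carries no chrom/pos columns")
        return self.data.drop_duplicates("snp").set_index("snp")[["chrom", "pos"]]

    def z_matrix(self, snps: list[str]) -> ZMatrix | None:
        """Assemble the traits x SNPs Z matrix; None if any cell is missing."""
        wide = self.data.pivot(index="trait", columns="snp", values="z")
        missing = [s for s in snps if s not in wide.columns]
        if missing or wide.loc[:, snps].isna().any().any():
            return None
        wide = wide.loc[self.traits, snps]
        return ZMatrix(list(wide.index), snps, wide.to_numpy(dtype=float))

    def to_file(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_summary_table(path, strict: bool = False) -> SummaryTable:
    """Read a delimited summary-statistics file.

    Requires columns snp, trait, z, counted_allele, other_allele (chrom and
    pos are carried through when present).  Unparsable Z entries ("NA" etc.)
    are dropped with a logged count, or raise in strict mode.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"summary file is missing column(s): {', '.join(missing)}")
    z = pd.to_numeric(frame["z"], errors="coerce")
    bad = ~np.isfinite(z)
    if bad.any():
        if strict:
            raise ValueError(f"{int(bad.sum())} unparsable Z value(s) in strict mode")
        logger.warning("dropping %d record(s) with unparsable Z", int(bad.sum()))
        frame = frame.loc[~bad].copy()
        z = z[~bad]
    frame["z"] = z.astype(float)
    for col in ("counted_allele", "other_allele"):
        frame[col] = frame[col].astype(str).str.upper()
    if "chrom" in frame.columns:
        frame["chrom"] = frame["chrom"].astype(str)
    return SummaryTable(frame.reset_index(drop=True))


@dataclass
class ReferencePanel:
    """Genotype dosages from a reference cohort of the target population.

    ``dosages`` counts copies of the counted allele (0/1/2, NaN missing).
    """

    snps: list[str]
    counted_allele: list[str]
    other_allele: list[str]
    dosages: np.ndarray
    chrom: list[str] | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage columns do not match SNP labels")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def subset(self, snps: list[str]) -> "ReferencePanel":
        index = {s: i for i, s in enumerate(self.snps)}
        cols = [index[s] for s in snps]
        return ReferencePanel(
            snps=list(snps),
            counted_allele=[self.counted_allele[i] for i in cols],
            other_allele=[self.other_allele[i] for i in cols],
            dosages=self.dosages[:, cols],
            chrom=[self.chrom[i] for i in cols] if self.chrom else None,
            pos=self.pos[cols] if self.pos is not None else None,
        )

    def alleles(self) -> dict[str, tuple[str, str]]:
        return {
            s: (a, b)
            for s, a, b in zip(self.snps, self.counted_allele, self.other_allele)
        }


def read_vcf_panel(path) -> ReferencePanel:
    """Load a VCF as a reference panel; the ALT allele is the counted allele.

    Dosages come from the GT field.  Multi-allelic records are skipped with
    a log entry.
    """
    from cyvcf2 import VCF

    snps, counted, other, chrom, pos, cols = [], [], [], [], [], []
    skipped = 0
    vcf = VCF(str(path))
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(variant.gt_types)
        dose = np.full(gt.shape, np.nan)
        dose[gt == 0] = 0.0
        dose[gt == 1] = 1.0
        dose[gt == 3] = 2.0
        ident = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snps.append(ident)
        counted.append(variant.ALT[0].upper())
        other.append(variant.REF.upper())
        chrom.append(str(variant.CHROM))
        pos.append(int(variant.POS))
        cols.append(dose)
    vcf.close()
    if skipped:
        logger.warning("skipped %d multi-allelic VCF record(s)", skipped)
    if not cols:
        raise ValueError("VCF contains no usable bi-allelic records")
    return ReferencePanel(
        snps=snps,
        counted_allele=counted,
        other_allele=other,
        dosages=np.column_stack(cols),
        chrom=chrom,
        pos=np.asarray(pos),
    )


# PLINK .bed 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
_BED_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink_panel(prefix) -> ReferencePanel:
    """Load a PLINK bed/bim/fam triplet; A1 (first .bim allele) is counted."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError("not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit genotype codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_DOSAGE[codes].T  # n x m
    return ReferencePanel(
        snps=bim["snp"].tolist(),
        counted_allele=bim["a1"].str.upper().tolist(),
        other_allele=bim["a2"].str.upper().tolist(),
        dosages=dosages,
        chrom=bim["chrom"].tolist(),
        pos=bim["pos"].to_numpy(),
    )


def read_panel(path) -> ReferencePanel:
    """Dispatch on file type: ``.vcf``/``.vcf.gz`` or a PLINK triplet prefix."""
    p = Path(path)
    if p.name.endswith((".vcf", ".vcf.gz")):
        return read_vcf_panel(p)
    return read_plink_panel(p.with_suffix("") if p.suffix == ".bed" else p)


@dataclass
class GeneRegion:
    """A gene interval (1-based, inclusive) with a symmetric testing flank."""

    gene: str
    chrom: str
    start: int
    end: int
    flank: int = 5000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")

    @property
    def window(self) -> tuple[int, int]:
        return max(1, self.start - self.flank), self.end + self.flank


def read_gene_regions(path, flank: int = 5000) -> list[GeneRegion]:
    """Read gene regions from a BED file (0-based half-open, converted here)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    return [
        GeneRegion(row.gene, row.chrom, int(row.start) + 1, int(row.end), flank)
        for row in frame.itertuples()
    ]


def harmonize_alleles(
    summary: SummaryTable, panel: ReferencePanel, mode: str = "strict"
) -> SummaryTable:
    """Reconcile summary-statistic alleles with the reference panel.

    ``strict`` (default) keeps only SNPs whose (counted, alternative) pair
    matches the panel exactly and drops everything else.  ``swap``
    additionally accepts reversed pairs by negating the Z-score, but still
    drops strand-ambiguous A/T and C/G variants, whose orientation is
    undecidable from allele labels.  Absolute Z values are never altered.
    """
    if mode not in {"strict", "swap"}:
        raise ValueError("mode must be 'strict' or 'swap'")
    panel_alleles = panel.alleles()
    keep_rows = []
    dropped_absent = dropped_mismatch = dropped_ambiguous = flipped = 0
    for snp, group in summary.data.groupby("snp", sort=False):
        counted = group["counted_allele"].iloc[0]
        other = group["other_allele"].iloc[0]
        if snp not in panel_alleles:
            dropped_absent += 1
            continue
        ref_counted, ref_other = panel_alleles[snp]
        if (counted, other) == (ref_counted, ref_other):
            keep_rows.append(group)
        elif mode == "swap" and (counted, other) == (ref_other, ref_counted):
            if (counted, other) in AMBIGUOUS_PAIRS:
                dropped_ambiguous += 1
                continue
            swapped = group.copy()
            swapped["z"] = -swapped["z"]
            swapped["counted_allele"] = ref_counted
            swapped["other_allele"] = ref_other
            keep_rows.append(swapped)
            flipped += 1
        else:
            dropped_mismatch += 1
    if dropped_absent or dropped_mismatch or dropped_ambiguous or flipped:
        logger.info(
            "allele harmonization: %d absent from panel, %d mismatched, "
            "%d strand-ambiguous dropped, %d sign-flipped",
            dropped_absent,
            dropped_mismatch,
            dropped_ambiguous,
            flipped,
        )
    if not keep_rows:
        return SummaryTable(summary.data.iloc[0:0].copy())
    return SummaryTable(pd.concat(keep_rows, ignore_index=True))


def assign_snps_to_genes(
    positions: pd.DataFrame,
    regions: list[GeneRegion],
    m_min: int = 2,
    m_max: int = 500,
) -> dict[str, list[str]]:
    """Map each gene to the SNPs inside its flanked window.

    ``positions`` is indexed by SNP id with columns chrom and pos (1-based).
    A SNP inside several overlapping windows is assigned to every one of
    them.  Genes with fewer than ``m_min`` or more than ``m_max`` SNPs are
    excluded (logged).  Within each gene, SNPs are ordered by position.
    """
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        lo, hi = region.window
        trees.setdefault(str(region.chrom), IntervalTree()).addi(
            lo, hi + 1, region.gene
        )  # interval end is exclusive
    assignment: dict[str, list[tuple[int, str]]] = {}
    for snp in sorted(positions.index):
        chrom = str(positions.loc[snp, "chrom"])
        pos = int(positions.loc[snp, "pos"])
        for hit in trees.get(chrom, IntervalTree())[pos]:
            assignment.setdefault(hit.data, []).append((pos, snp))
    out: dict[str, list[str]] = {}
    excluded = 0
    for gene, pairs in assignment.items():
        if not m_min <= len(pairs) <= m_max:
            excluded += 1
            continue
        out[gene] = [snp for _, snp in sorted(pairs)]
    if excluded:
        logger.info(
            "excluded %d gene(s) outside the [%d, %d] SNP-count range",
            excluded,
            m_min,
            m_max,
        )
    return out


@dataclass
class GeneTestUnit:
    """Everything needed to test one gene: its Z matrix and SNP correlation."""

    gene: str
    snps: list[str]
    z: ZMatrix
    snp_corr: SnpCorrMatrix

    def __post_init__(self) -> None:
        if self.z.snps != self.snps or self.snp_corr.labels != self.snps:
            raise ValueError(f"gene {self.gene}: SNP ordering mismatch")


def build_gene_units(
    summary: SummaryTable,
    panel: ReferencePanel,
    regions: list[GeneRegion],
    covariate_kind: CovariateKind = CovariateKind.ENVIRONMENT_ONLY,
    n_axes: int = 2,
    m_min: int = 2,
    m_max: int = 500,
) -> list[GeneTestUnit]:
    """Assemble per-gene test units from harmonized inputs.

    For stratification-adjusted summary statistics the panel's top
    principal coordinates are projected out of the gene's dosages before
    LD estimation; otherwise plain Pearson LD is used.  Genes whose Z
    matrix has any missing (trait, SNP) cell are skipped with a log entry.
    """
    gene_map = assign_snps_to_genes(summary.positions(), regions, m_min, m_max)
    design = None
    if covariate_kind is not CovariateKind.ENVIRONMENT_ONLY:
        design = compute_principal_coordinates(
            panel.dosages, n_axes, kind=covariate_kind
        )
    units = []
    panel_snps = set(panel.snps)
    for gene in sorted(gene_map):
        snps = [s for s in gene_map[gene] if s in panel_snps]
        if len(snps) < m_min:
            logger.info("gene %s: too few SNPs present in the panel; skipped", gene)
            continue
        z = summary.z_matrix(snps)
        if z is None:
            logger.info("gene %s: missing Z for some (trait, SNP); skipped", gene)
            continue
        sub = panel.subset(snps)
        if design is None:
            snp_corr = pearson_genotype_correlation(sub.dosages, snps)
        else:
            snp_corr = partial_genotype_correlation(sub.dosages, design, snps)
        units.append(GeneTestUnit(gene=gene, snps=snps, z=z, snp_corr=snp_corr))
    return units
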