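"""Genotype containers, quality control, LD and perfect-LD pruning.

Genotypes are additive dosages coded 0/1/2 (count of the alternate
allele), ``NaN`` for missing.  Chromosomes are the mouse autosomes
``"1" .. "19"`` plus ``"X"``; positions are 1-based bp, strictly
increasing within each chromosome.  Males are hemizygous on X and carry
doubled dosages {0, 2} so that a single additive column works genome-wide.

QC reproduces a standard array-genotyping pipeline: drop SNPs with
heterozygosity above 0.9, missingness above 5%, or minor allele frequency
below 5%; then collapse groups of SNPs in perfect LD (r² = 1) to a single
representative, keeping the full panel around for LD-based region
delimitation afterwards.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = [
    "GenotypePanel",
    "QCReport",
    "apply_qc_filters",
    "ld_r2",
    "prune_perfect_ld",
    "mean_impute",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
]

CHROMOSOMES = tuple(str(c) for c in range(1, 20)) + ("X",)


@dataclasses.dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with SNP metadata."""

    genotypes: NDArray                 # (n, p) float, values {0,1,2,NaN}
    snp_ids: list[str]
    chrom: NDArray                     # (p,) str
    pos: NDArray                       # (p,) int, 1-based
    individual_ids: list[str]
    sex: NDArray | None = None         # (n,) 'M'/'F', optional

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        g = self.genotypes
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chr {c}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_x(self) -> NDArray:
        return np.asarray(self.chrom) == "X"

    def subset_snps(self, mask_or_idx: NDArray) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            genotypes=self.genotypes[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            individual_ids=list(self.individual_ids),
            sex=self.sex,
        )

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError as exc:
            raise KeyError(f"SNP {snp_id!r} not in panel") from exc


@dataclasses.dataclass
class QCReport:
    n_input: int
    removed_het: int
    removed_missing: int
    removed_maf: int
    n_surviving: int

    def __post_init__(self) -> None:
        total = self.removed_het + self.removed_missing + self.removed_maf
        assert total + self.n_surviving == self.n_input

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "filter": ["heterozygosity", "missingness", "maf", "surviving"],
                "count": [
                    self.removed_het,
                    self.removed_missing,
                    self.removed_maf,
                    self.n_surviving,
                ],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


def _snp_stats(g: NDArray) -> tuple[NDArray, NDArray, NDArray]:
    """Per-SNP heterozygosity, missingness and MAF from the dosage matrix."""
    miss = np.isnan(g)
    n_obs = (~miss).sum(axis=0)
    n_obs_safe = np.maximum(n_obs, 1)
    het = np.nansum(g == 1.0, axis=0) / n_obs_safe
    missingness = miss.mean(axis=0)
    af = np.nansum(g, axis=0) / (2 * n_obs_safe)
    maf = np.minimum(af, 1 - af)
    maf[n_obs == 0] = 0.0
    return het, missingness, maf


def apply_qc_filters(
    panel: GenotypePanel,
    het_max: float = 0.9,
    miss_max: float = 0.05,
    maf_min: float = 0.05,
) -> tuple[GenotypePanel, QCReport]:
    """Remove SNPs failing heterozygosity, missingness or MAF thresholds.

    A SNP failing several criteria is counted once, attributed to the
    first failing criterion in the order listed above.
    """
    for t in (het_max, miss_max, maf_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    if panel.n_snps == 0:
        return panel, QCReport(0, 0, 0, 0, 0)
    het, miss, maf = _snp_stats(panel.genotypes)
    fail_het = het > het_max
    fail_miss = (~fail_het) & (miss > miss_max)
    fail_maf = (~fail_het) & (~fail_miss) & (maf < maf_min)
    keep = ~(fail_het | fail_miss | fail_maf)
    report = QCReport(
        n_input=panel.n_snps,
        removed_het=int(fail_het.sum()),
        removed_missing=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
        n_surviving=int(keep.sum()),
    )
    return panel.subset_snps(keep), report


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(g_a: NDArray, g_b: NDArray) -> float:
    """Squared Pearson correlation of two genotype dosage vectors.

    Pairs with a missing entry in either vector are dropped first; a
    constant vector has undefined LD and raises ``ValueError``.
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a constant genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def prune_perfect_ld(
    panel: GenotypePanel, tol: float = 1e-12
) -> tuple[GenotypePanel, dict[str, list[str]]]:
    """Collapse same-chromosome SNPs in perfect LD to one representative.

    SNPs are scanned left to right within each chromosome; a SNP whose r²
    with an already-kept SNP reaches 1 (within ``tol``) is pruned and
    recorded under that representative, so the retained SNP is always the
    left-most of its perfect-LD group.
    """
    keep_mask = np.ones(panel.n_snps, dtype=bool)
    kept_to_pruned: dict[str, list[str]] = {}
    g = panel.genotypes
    for c in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        idx = idx[np.argsort(panel.pos[idx])]
        kept: list[int] = []
        for j in idx:
            pruned_into = None
            for i in kept:
                try:
                    r2 = ld_r2(g[:, i], g[:, j])
                except ValueError:
                    continue
                if r2 >= 1.0 - tol:
                    pruned_into = i
                    break
            if pruned_into is None:
                kept.append(j)
            else:
                keep_mask[j] = False
                rep = panel.snp_ids[pruned_into]
                kept_to_pruned.setdefault(rep, []).append(panel.snp_ids[j])
    return panel.subset_snps(keep_mask), kept_to_pruned


def mean_impute(panel: GenotypePanel) -> NDArray:
    """Dosage matrix with missing entries replaced by per-SNP means.

    Used only at association time; LD is always computed on observed
    genotypes.
    """
    g = panel.genotypes.copy()
    if np.isnan(g).any():
        col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(g))
        g[nan_r, nan_c] = col_mean[nan_c]
    return g


# ---------------------------------------------------------------------------
# I/O


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed diploid-GT VCF (REF=A, ALT=T)."""
    lines = ["##fileformat=VCFv4.2"]
    for c in CHROMOSOMES:
        if (panel.chrom == c).any():
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"]
    header += list(panel.individual_ids)
    lines.append("\t".join(header))
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = np.lexsort(
        (panel.pos, [CHROMOSOMES.index(str(c)) for c in panel.chrom])
    )
    for j in order:
        gts = [
            "./." if np.isnan(v) else code[v] for v in panel.genotypes[:, j]
        ]
        row = [
            str(panel.chrom[j]),
            str(int(panel.pos[j])),
            panel.snp_ids[j],
            "A",
            "T",
            ".",
            "PASS",
            ".",
            "GT",
        ] + gts
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, sex: NDArray | None = None) -> GenotypePanel:
    """Read a diploid-GT VCF into a panel (dosage = alternate-allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows: list[NDArray] = []
    snp_ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom ref,1 het,2 unknown,3 hom alt
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        rows.append(dosage)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM).removeprefix("chr"))
        pos.append(var.POS)
    geno = (
        np.vstack(rows).T if rows else np.empty((len(ids), 0))
    )
    return GenotypePanel(
        genotypes=geno,
        snp_ids=snp_ids,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        individual_ids=ids,
        sex=sex,
    )


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Tab-separated dosage matrix with a 3-line header (id/chrom/pos)."""
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(panel.snp_ids) + "\n")
        fh.write("chromosome\t" + "\t".join(map(str, panel.chrom)) + "\n")
        fh.write("position\t" + "\t".join(map(str, panel.pos)) + "\n")
        for i, ind in enumerate(panel.individual_ids):
            vals = [
                "NA" if np.isnan(v) else f"{v:g}" for v in panel.genotypes[i]
            ]
            fh.write(ind + "\t" + "\t".join(vals) + "\n")


def read_dosage_tsv(path: str | Path, sex: NDArray | None = None) -> GenotypePanel:
    with open(path) as fh:
        snp_ids = fh.readline().rstrip("\n").split("\t")[1:]
        chrom = fh.readline().rstrip("\n").split("\t")[1:]
        pos = [int(x) for x in fh.readline().rstrip("\n").split("\t")[1:]]
        ind_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts[0]:
                continue
            ind_ids.append(parts[0])
            rows.append(
                [np.nan if v == "NA" else float(v) for v in parts[1:]]
            )
    return GenotypePanel(
        genotypes=np.asarray(rows, dtype=float),
        snp_ids=snp_ids,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        individual_ids=ind_ids,
        sex=sex,
    )
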