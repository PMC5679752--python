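"""QTL region delimitation by LD and region-level shape effect sizes.

Significant SNPs rarely act alone: the causal region is delimited by
linkage disequilibrium with neighbouring SNPs in the *full* panel (before
perfect-LD pruning).  The region spans from the left-most to the
right-most same-chromosome SNP whose r² with the best SNP exceeds 0.8;
interior SNPs below the threshold do not split the span.  A significant
SNP with no linked neighbour gets a fallback region of 250 kb to each side
(500 kb total), clipped to the chromosome.  Overlapping regions on one
chromosome are merged, keeping the overall lowest-p SNP as the best.

The effect of a region on shape is the fraction of *total* retained shape
variance explained by the best SNP's genotype: the variance-weighted mean
over retained PCs of the squared correlation between PC scores and dosage.
This refers the effect to overall shape variation rather than to the
single PC the SNP was mapped with.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .geno import GenotypePanel, ld_r2

__all__ = ["QTLRegion", "delimit_region", "merge_regions", "effect_size",
           "name_regions", "regions_table"]


@dataclasses.dataclass
class QTLRegion:
    """A genomic interval associated with shape, 1-based closed coordinates."""

    name: str
    chromosome: str
    start: int
    end: int
    best_snp: str
    best_pos: int
    best_p: float
    phenotype: str | None = None
    effect_size: float | None = None
    member_snps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start <= self.best_pos <= self.end:
            raise ValueError("best SNP must lie inside its region")

    @property
    def width(self) -> int:
        """Span in bp (end minus start)."""
        return self.end - self.start


def delimit_region(
    best_snp: str,
    full_panel: GenotypePanel,
    r2_threshold: float = 0.8,
    fallback_halfwidth: int = 250_000,
    chromosome_length: int | None = None,
    best_p: float = float("nan"),
    phenotype: str | None = None,
) -> QTLRegion:
    """Delimit the region around one significant SNP using the full panel."""
    j = full_panel.snp_index(best_snp)
    chrom = str(full_panel.chrom[j])
    pos = int(full_panel.pos[j])
    same = np.flatnonzero(full_panel.chrom == chrom)
    linked = []
    for i in same:
        if i == j:
            continue
        try:
            r2 = ld_r2(full_panel.genotypes[:, i], full_panel.genotypes[:, j])
        except ValueError:
            continue
        if r2 > r2_threshold:
            linked.append(i)
    if linked:
        pos_linked = full_panel.pos[linked]
        start = int(min(pos, pos_linked.min()))
        end = int(max(pos, pos_linked.max()))
        members = tuple(
            full_panel.snp_ids[i]
            for i in sorted(linked + [j], key=lambda i: full_panel.pos[i])
        )
    else:
        start = max(1, pos - fallback_halfwidth)
        end = pos + fallback_halfwidth
        if chromosome_length is not None:
            end = min(end, chromosome_length)
        members = (best_snp,)
    return QTLRegion(
        name=f"Mo.{chrom}",
        chromosome=chrom,
        start=start,
        end=end,
        best_snp=best_snp,
        best_pos=pos,
        best_p=best_p,
        phenotype=phenotype,
        member_snps=members,
    )


def merge_regions(regions: list[QTLRegion]) -> list[QTLRegion]:
    """Merge overlapping same-chromosome regions (order-independent).

    The merged region keeps the overall lowest-p SNP as best and the union
    of member SNPs.
    """
    out: list[QTLRegion] = []
    by_chrom: dict[str, list[QTLRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        merged: list[QTLRegion] = []
        for r in rs:
            if merged and r.start <= merged[-1].end:
                prev = merged[-1]
                best = min((prev, r), key=lambda q: (q.best_p, q.best_pos))
                merged[-1] = QTLRegion(
                    name=prev.name,
                    chromosome=chrom,
                    start=prev.start,
                    end=max(prev.end, r.end),
                    best_snp=best.best_snp,
                    best_pos=best.best_pos,
                    best_p=best.best_p,
                    phenotype=best.phenotype,
                    effect_size=best.effect_size,
                    member_snps=tuple(
                        dict.fromkeys(prev.member_snps + r.member_snps)
                    ),
                )
            else:
                merged.append(r)
        out.extend(merged)
    return name_regions(out)


def name_regions(regions: list[QTLRegion]) -> list[QTLRegion]:
    """Assign names Mo.<chr>[.k], numbering by ascending start per chromosome."""
    out = []
    by_chrom: dict[str, list[QTLRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for i, r in enumerate(rs):
            name = (
                f"Mo.{chrom}" if len(rs) == 1 else f"Mo.{chrom}.{i + 1}"
            )
            out.append(dataclasses.replace(r, name=name))
    return sorted(out, key=lambda r: (r.chromosome, r.start))


def effect_size(
    retained_pc_scores: NDArray,
    g: NDArray,
    mode: str = "variance_weighted",
) -> float:
    """Fraction of total retained shape variance explained by a SNP.

    ``variance_weighted`` (default): sum over PCs of Var(score_k) * r²_k,
    divided by the total retained variance, with r²_k the squared
    correlation between PC k's scores and the dosage.  ``multivariate``:
    R² of the ordinary regression of the dosage on all retained scores
    jointly (an alternative reading of the same quantity).
    """
    S = np.asarray(retained_pc_scores, dtype=float)
    g = np.asarray(g, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if np.ptp(g) == 0:
        raise ValueError("constant genotype vector")
    gc = g - g.mean()
    Sc = S - S.mean(axis=0)
    if mode == "variance_weighted":
        var = Sc.var(axis=0, ddof=1)
        num = (gc @ Sc) ** 2
        den = (gc @ gc) * (Sc**2).sum(axis=0)
        r2 = num / den
        return float((var * r2).sum() / var.sum())
    if mode == "multivariate":
        beta, *_ = np.linalg.lstsq(Sc, gc, rcond=None)
        resid = gc - Sc @ beta
        return float(1.0 - (resid @ resid) / (gc @ gc))
    raise ValueError(f"unknown effect-size mode {mode!r}")


def regions_table(regions: list[QTLRegion]) -> pd.DataFrame:
    """Summary table (QTL, Chr, Position, Best SNP, p-value, Effect size, PC)."""
    return pd.DataFrame(
        {
            "QTL": [r.name for r in regions],
            "Chr": [f"chr{r.chromosome}" for r in regions],
            "Position": [r.best_pos for r in regions],
            "Best_SNP": [r.best_snp for r in regions],
            "p_value": [r.best_p for r in regions],
            "Effect_size": [r.effect_size for r in regions],
            "PC_axis": [r.phenotype for r in regions],
            "Start": [r.start for r in regions],
            "End": [r.end for r in regions],
        }
    )
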