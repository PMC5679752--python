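"""Synthetic data with the statistical structure the mapping assumes.

The generator emulates the study system end to end: a sample of related
male mice (sibships and half-sibships bred from small founder groups), a
dense biallelic SNP panel on 19 autosomes plus X, tooth-crown surfaces
described by corresponded semi-landmarks, age-dependent cusp wear, and a
shape architecture that is mostly polygenic (weighted heritability around
0.65) with a handful of QTL each explaining 1-3% of total shape variance.
Mutant-line groups with fixed mean-shape offsets mirror the validation
panel (group sizes 5, 5, 10, 2, 4, 5 mutants plus 5 wild types).

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh
from numpy.typing import NDArray

from .geno import GenotypePanel
from .morpho import Template, write_landmark_csv

__all__ = [
    "MOUSE_CHROMOSOMES",
    "MUTANT_GROUP_SIZES",
    "SimConfig",
    "TruthRecord",
    "make_tooth_template",
    "simulate_genotypes",
    "simulate_shapes",
    "simulate_mutant_groups",
    "write_simulation",
]

# Approximate mouse chromosome lengths (bp), GRCm38 scale.
MOUSE_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("1", 195_000_000), ("2", 182_000_000), ("3", 160_000_000),
    ("4", 157_000_000), ("5", 152_000_000), ("6", 150_000_000),
    ("7", 145_000_000), ("8", 129_000_000), ("9", 124_000_000),
    ("10", 131_000_000), ("11", 122_000_000), ("12", 120_000_000),
    ("13", 120_000_000), ("14", 125_000_000), ("15", 104_000_000),
    ("16", 98_000_000), ("17", 95_000_000), ("18", 91_000_000),
    ("19", 61_000_000), ("X", 171_000_000),
)

# Mutant validation panel: group label -> size, wild type last.
MUTANT_GROUP_SIZES: dict[str, int] = {
    "vga9_het": 5,
    "vga9_hom": 5,
    "enu22_hom": 10,
    "wh_het": 2,
    "wh_hom": 4,
    "wh_mi": 5,
    "WT": 5,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of one synthetic mapping study.

    Defaults mirror the emulated study: 183 males aged 9-12 weeks in
    sibships, ~145k post-QC-like SNPs over 19 autosomes + X, five QTL
    with effects between 1% and 3% of total shape variance, and a
    polygenic background of 0.65.
    """

    n_individuals: int = 183
    n_families: int = 23
    sibship_sizes: tuple[int, ...] | None = None
    founders_per_family: tuple[int, int] = (2, 2)   # (dams, sires)
    n_snps: int = 145_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    chromosomes: tuple[tuple[str, int], ...] = MOUSE_CHROMOSOMES
    n_qtl: int = 5
    qtl_effect_fractions: tuple[float, ...] = (0.011, 0.032, 0.028, 0.016, 0.022)
    polygenic_h2: float = 0.65
    n_polygenic_fields: int = 200
    wear_rate: float = 0.012            # mm of cusp height lost per week
    age_range: tuple[float, float] = (9.0, 12.0)
    noise_sd: float = 0.004             # per-coordinate shape noise, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sibship_sizes is None:
            base = self.n_individuals // self.n_families
            sizes = [base] * self.n_families
            for i in range(self.n_individuals - base * self.n_families):
                sizes[i] += 1
            self.sibship_sizes = tuple(sizes)
        if sum(self.sibship_sizes) != self.n_individuals:
            raise ValueError(
                f"sibship sizes sum to {sum(self.sibship_sizes)}, "
                f"expected n_individuals={self.n_individuals}"
            )
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0, 0.5]")
        if len(self.qtl_effect_fractions) != self.n_qtl:
            raise ValueError("need one effect fraction per QTL")
        total = sum(self.qtl_effect_fractions) + self.polygenic_h2
        if total > 1.0:
            raise ValueError(
                f"QTL fractions + polygenic h2 = {total:.3f} exceed 1"
            )
        if min(self.n_individuals, self.n_snps, self.n_qtl) < 0:
            raise ValueError("counts must be non-negative")
        if not self.chromosomes:
            raise ValueError("at least one chromosome must be defined")


@dataclasses.dataclass
class TruthRecord:
    """Ground truth of one simulated sample, for parameter-recovery tests."""

    qtl_snp_ids: list[str]
    qtl_fields: NDArray          # (n_qtl, k, 3) scaled displacement per copy
    genetic_values: NDArray      # (n, k, 3) total genetic displacement
    true_h2: float
    qtl_fractions: tuple[float, ...]
    polygenic_h2: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "qtl_snp_ids": self.qtl_snp_ids,
                    "qtl_fields": self.qtl_fields.tolist(),
                    "true_h2": self.true_h2,
                    "qtl_fractions": list(self.qtl_fractions),
                    "polygenic_h2": self.polygenic_h2,
                },
                indent=1,
            )
        )


# ---------------------------------------------------------------------------
# tooth-like template


def make_tooth_template(
    grid: tuple[int, int] = (26, 16),
    cusp_rows: int = 2,
    cusp_cols: int = 4,
    crown_height: float = 0.45,
    seed: int = 0,
) -> Template:
    """A synthetic molar-crown surface: a cusped height field over an ellipse.

    The crown is a smooth surface ``z(x, y)`` with ``cusp_rows x cusp_cols``
    Gaussian cusps (the murine first upper molar carries about eight), the
    occlusal axis being z.  All surface vertices inside the crown outline
    serve as the ordered semi-landmarks; ten anchors sit on cusp apices and
    the crown margin.  Units are millimetres, sized like a mouse molar
    (about 2 x 1.2 mm).
    """
    nx, ny = grid
    xs = np.linspace(-1.0, 1.0, nx)
    ys = np.linspace(-0.6, 0.6, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cx = np.linspace(-0.7, 0.7, cusp_cols)
    cy = np.linspace(-0.3, 0.3, cusp_rows)
    Z = np.zeros_like(X)
    rng = np.random.default_rng(seed)
    for i, x0 in enumerate(cx):
        for j, y0 in enumerate(cy):
            amp = crown_height * (0.85 + 0.3 * rng.random())
            Z += amp * np.exp(-(((X - x0) / 0.22) ** 2 + ((Y - y0) / 0.16) ** 2))
    inside = (X / 1.0) ** 2 + (Y / 0.6) ** 2 <= 1.0

    idx_map = -np.ones((nx, ny), dtype=int)
    verts = []
    for i in range(nx):
        for j in range(ny):
            if inside[i, j]:
                idx_map[i, j] = len(verts)
                verts.append((X[i, j], Y[i, j], Z[i, j]))
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = idx_map[i, j], idx_map[i + 1, j]
            c, d = idx_map[i + 1, j + 1], idx_map[i, j + 1]
            if min(a, b, c) >= 0:
                faces.append((a, b, c))
            if min(a, c, d) >= 0:
                faces.append((a, c, d))
    mesh = trimesh.Trimesh(
        vertices=np.asarray(verts, dtype=float),
        faces=np.asarray(faces, dtype=int),
        process=False,
    )
    vertices = np.asarray(mesh.vertices)
    # anchors: 8 cusp apices (nearest vertex to each cusp center) + 2 margin
    anchors = []
    for x0 in cx:
        for y0 in cy:
            d = (vertices[:, 0] - x0) ** 2 + (vertices[:, 1] - y0) ** 2
            anchors.append(vertices[int(np.argmin(d))])
    for xm in (-1.0, 1.0):
        d = (vertices[:, 0] - xm) ** 2 + vertices[:, 1] ** 2
        anchors.append(vertices[int(np.argmin(d))])
    return Template(
        mesh=mesh,
        semilandmark_indices=np.arange(len(vertices)),
        anchors=np.asarray(anchors, dtype=float),
        wear_free=False,
        cut_height=None,
    )


# ---------------------------------------------------------------------------
# genotypes


def _allocate_snps(config: SimConfig) -> tuple[NDArray, NDArray]:
    """SNP chromosome labels and positions, counts proportional to length."""
    lengths = np.array([L for _, L in config.chromosomes], dtype=float)
    raw = lengths / lengths.sum() * config.n_snps
    counts = np.floor(raw).astype(int)
    remainder = config.n_snps - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(counts)]] += 1
    chrom_labels: list[str] = []
    positions: list[int] = []
    rng = np.random.default_rng(config.seed + 101)
    for (name, length), c in zip(config.chromosomes, counts):
        if c == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(1, length + 1), size=c, replace=False)
        )
        chrom_labels.extend([name] * c)
        positions.extend(pos.tolist())
    return np.asarray(chrom_labels, dtype=object), np.asarray(
        positions, dtype=np.int64
    )


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Sibship-structured dosage panel by Mendelian drop from family founders.

    Per family a small founder pool (by default 2 dams and 2 sires) is
    drawn from Hardy-Weinberg at per-SNP allele frequencies uniform on
    ``maf_range``; each offspring picks a dam and a sire at random from the
    pool, yielding a mix of full and half sibs.  All offspring are male
    (as in the emulated sample): X genotypes descend from the dam only and
    are coded hemizygous-doubled {0, 2}.
    """
    rng = np.random.default_rng(config.seed)
    chrom, pos = _allocate_snps(config)
    p_alt = rng.uniform(*config.maf_range, size=config.n_snps)
    is_x = chrom == "X"
    n = config.n_individuals
    geno = np.empty((n, config.n_snps), dtype=float)
    n_dams, n_sires = config.founders_per_family
    row = 0
    for fam_size in config.sibship_sizes:
        # founder haplotypes: (founder, 2 copies, snp)
        dams = rng.random((n_dams, 2, config.n_snps)) < p_alt
        sires = rng.random((n_sires, 2, config.n_snps)) < p_alt
        for _ in range(fam_size):
            d = rng.integers(n_dams)
            s = rng.integers(n_sires)
            from_dam = dams[d, rng.integers(2, size=config.n_snps),
                            np.arange(config.n_snps)]
            from_sire = sires[s, rng.integers(2, size=config.n_snps),
                              np.arange(config.n_snps)]
            g = from_dam.astype(float) + from_sire.astype(float)
            # male X: maternal copy only, hemizygous doubled
            g[is_x] = 2.0 * from_dam[is_x]
            geno[row] = g
            row += 1
    return GenotypePanel(
        genotypes=geno,
        snp_ids=[f"s{c}_{p}" for c, p in zip(chrom, pos)],
        chrom=chrom,
        pos=pos,
        individual_ids=[f"ind{i:04d}" for i in range(n)],
        sex=np.asarray(["M"] * n),
    )


# ---------------------------------------------------------------------------
# shapes


def _random_field(rng: np.random.Generator, k: int) -> NDArray:
    """Random unit-norm per-vertex displacement field, (k, 3)."""
    f = rng.standard_normal((k, 3))
    return f / np.linalg.norm(f)


def simulate_shapes(
    panel: GenotypePanel,
    config: SimConfig,
    template: Template,
) -> tuple[NDArray, NDArray, TruthRecord]:
    """Additive shape model plus age-dependent wear.

    Each individual's configuration is the template mean plus per-QTL
    displacement fields scaled by genotype, a polygenic term (many small
    SNP-attached random fields, rescaled so the polygenic fraction of total
    variance hits ``polygenic_h2``), and isotropic Gaussian noise; finally
    the wear operator projects every vertex above the individual's wear
    plane (crown apex minus ``wear_rate * age``) down onto it.

    Returns ``(configs, ages, truth)`` with configs of shape (n, k, 3).
    """
    if panel.n_individuals != config.n_individuals:
        raise ValueError("panel rows do not match configured individuals")
    rng = np.random.default_rng(config.seed + 7)
    base = template.semilandmarks
    k = base.shape[0]
    n = panel.n_individuals
    ages = rng.uniform(*config.age_range, size=n)

    zmax, zmin = base[:, 2].max(), base[:, 2].min()
    crown_height = zmax - zmin
    if config.wear_rate * max(config.age_range) >= crown_height:
        raise ValueError("wear would erase the whole crown at the oldest age")

    residual = 1.0 - sum(config.qtl_effect_fractions) - config.polygenic_h2
    if residual <= 0 and config.noise_sd > 0:
        raise ValueError("no residual variance left for the noise term")
    total_var = (
        3 * k * config.noise_sd**2 / residual if residual > 0 else 1.0
    )

    autosomal = np.flatnonzero(~panel.is_x)
    g_var = np.nanvar(panel.genotypes, axis=0, ddof=1)
    candidates = autosomal[g_var[autosomal] > 1e-8]
    if len(candidates) < config.n_qtl:
        raise ValueError("not enough polymorphic autosomal SNPs for the QTL")
    qtl_idx = rng.choice(candidates, size=config.n_qtl, replace=False)

    genetic = np.zeros((n, k, 3))
    qtl_fields = np.zeros((config.n_qtl, k, 3))
    for j, (snp, frac) in enumerate(zip(qtl_idx, config.qtl_effect_fractions)):
        delta = _random_field(rng, k)
        g = panel.genotypes[:, snp]
        scale = np.sqrt(frac * total_var / (g.var(ddof=1) + 1e-300))
        qtl_fields[j] = scale * delta
        genetic += g[:, None, None] * qtl_fields[j][None]

    if config.polygenic_h2 > 0 and config.n_polygenic_fields > 0:
        poly_snps = rng.choice(
            np.arange(panel.n_snps),
            size=min(config.n_polygenic_fields, panel.n_snps),
            replace=False,
        )
        poly = np.zeros((n, k, 3))
        for snp in poly_snps:
            field = rng.standard_normal((k, 3)) / np.sqrt(len(poly_snps))
            poly += panel.genotypes[:, snp][:, None, None] * field[None]
        flat = poly.reshape(n, -1)
        realized = flat.var(axis=0, ddof=1).sum()
        poly *= np.sqrt(config.polygenic_h2 * total_var / (realized + 1e-300))
        genetic += poly

    noise = rng.standard_normal((n, k, 3)) * config.noise_sd
    configs = base[None] + genetic + noise

    # wear: per-individual plane truncation
    wear_plane = zmax - config.wear_rate * ages
    configs[..., 2] = np.minimum(configs[..., 2], wear_plane[:, None])

    truth = TruthRecord(
        qtl_snp_ids=[panel.snp_ids[i] for i in qtl_idx],
        qtl_fields=qtl_fields,
        genetic_values=genetic,
        true_h2=float(sum(config.qtl_effect_fractions) + config.polygenic_h2),
        qtl_fractions=config.qtl_effect_fractions,
        polygenic_h2=config.polygenic_h2,
    )
    return configs, ages, truth


# ---------------------------------------------------------------------------
# mutant groups


def simulate_mutant_groups(
    template: Template,
    group_offsets: dict[str, NDArray],
    group_sizes: dict[str, int],
    noise_sd: float,
    seed: int,
    wild_type: str = "WT",
) -> dict[str, NDArray]:
    """Labelled groups drawn as template mean + fixed offset + noise.

    ``wild_type`` must be present in ``group_sizes`` with a zero offset
    (an absent entry in ``group_offsets`` counts as zero).
    """
    if wild_type not in group_sizes:
        raise ValueError(f"wild-type label {wild_type!r} missing from sizes")
    wt_off = group_offsets.get(wild_type)
    if wt_off is not None and np.any(np.asarray(wt_off) != 0):
        raise ValueError("wild-type offset must be zero")
    rng = np.random.default_rng(seed)
    base = template.semilandmarks
    k = base.shape[0]
    out: dict[str, NDArray] = {}
    for label, size in group_sizes.items():
        offset = np.asarray(
            group_offsets.get(label, np.zeros((k, 3))), dtype=float
        )
        if offset.shape != (k, 3):
            raise ValueError(f"offset for {label!r} must be (k, 3)")
        out[label] = (
            base[None]
            + offset[None]
            + rng.standard_normal((size, k, 3)) * noise_sd
        )
    return out


# ---------------------------------------------------------------------------
# on-disk bundle


def write_simulation(
    out_dir: str | Path,
    panel: GenotypePanel,
    configs: NDArray,
    ages: NDArray,
    truth: TruthRecord,
) -> None:
    """Write genotypes (VCF + dosage TSV), shapes (CSV), ages and truth."""
    from .geno import write_dosage_tsv, write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(panel, out / "genotypes.vcf")
    write_dosage_tsv(panel, out / "genotypes.tsv")
    write_landmark_csv(out / "shapes.csv", configs, panel.individual_ids)
    with open(out / "ages.tsv", "w") as fh:
        fh.write("specimen_id\tage_weeks\n")
        for sid, a in zip(panel.individual_ids, ages):
            fh.write(f"{sid}\t{a:.4f}\n")
    truth.to_json(out / "truth.json")
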