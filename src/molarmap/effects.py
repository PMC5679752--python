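"""Comparing shape effects across independent Procrustes superimpositions.

PC axes from two different superimpositions live in different coordinate
systems, so their loadings cannot be compared directly.  The workaround
implemented here characterises every effect (a SNP, a mutant line, a PC
axis) by something superimposition-free:

1. the effect is represented by a *pair* of reconstructed surfaces — one
   per homozygous genotype, wild-type mean vs mutant mean, or the shapes
   at the two extremes of a PC;
2. the Euclidean distance between corresponding vertices of the pair
   gives a per-vertex distance profile over the template surface;
3. two effects are compared by correlating their profiles: if both
   effects displace the same parts of the crown strongly, the profiles
   correlate;
4. the expected correlation between *orthogonal* directions of change is
   estimated by comparing the retained PCs' own signatures pairwise —
   this baseline distribution calibrates any observed correlation.

Distances are unsigned; a signed (outward-normal) displacement channel is
available for heat-map export only, never for correlation.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
import trimesh
from numpy.typing import NDArray
from scipy import stats

from .morpho import PCModel, Template, gpa_align
from .tps import ThinPlateSpline

__all__ = [
    "EffectSignature",
    "ComparisonResult",
    "reconstruct_config",
    "warp_template_mesh",
    "reconstruct_surface",
    "signature_from_configs",
    "signature_for_snp",
    "signature_for_groups",
    "signature_for_pc",
    "compare_signatures",
    "pc_baseline",
    "export_signature_ply",
]


@dataclasses.dataclass
class EffectSignature:
    """A pair of reconstructed surfaces and their per-vertex distance profile."""

    label: str
    surface_a: trimesh.Trimesh
    surface_b: trimesh.Trimesh
    profile: NDArray               # (n_vertices,) unsigned distances

    def __post_init__(self) -> None:
        if len(self.surface_a.vertices) != len(self.surface_b.vertices):
            raise ValueError("surface pair must share the template vertex set")
        if len(self.profile) != len(self.surface_a.vertices):
            raise ValueError("profile length must equal the vertex count")


@dataclasses.dataclass
class ComparisonResult:
    """A query correlation placed within the PC-pair baseline distribution."""

    label_a: str
    label_b: str
    correlation: float
    baseline: NDArray
    percentile: float


# ---------------------------------------------------------------------------
# reconstruction


def reconstruct_config(pc_model: PCModel, scores: NDArray) -> NDArray:
    """Semi-landmark configuration at a point of PC space: consensus + s·V."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (pc_model.eigenvectors.shape[0],):
        raise ValueError(
            f"scores vector must have length {pc_model.eigenvectors.shape[0]}"
        )
    flat = pc_model.consensus.ravel() + scores @ pc_model.eigenvectors
    return flat.reshape(pc_model.consensus.shape)


def warp_template_mesh(template: Template, target_config: NDArray) -> trimesh.Trimesh:
    """Warp the template mesh by the TPS sending its semi-landmarks to a config."""
    target_config = np.asarray(target_config, dtype=float)
    if target_config.shape != (template.n_semilandmarks, 3):
        raise ValueError("target configuration does not match the template")
    src = template.semilandmarks
    verts = np.asarray(template.mesh.vertices, dtype=float)
    if len(template.semilandmark_indices) == len(verts) and np.array_equal(
        np.sort(template.semilandmark_indices), np.arange(len(verts))
    ):
        # semi-landmarks are the full vertex set: the warp is the config itself
        new_verts = np.empty_like(verts)
        new_verts[template.semilandmark_indices] = target_config
    else:
        new_verts = ThinPlateSpline(src, target_config).transform(verts)
    return trimesh.Trimesh(
        vertices=new_verts, faces=template.mesh.faces.copy(), process=False
    )


def reconstruct_surface(
    pc_model: PCModel | None,
    target: NDArray,
    template: Template,
) -> trimesh.Trimesh:
    """Reconstruct a surface from a scores vector or a consensus configuration.

    With a ``pc_model`` the target is interpreted as a scores vector; with
    ``pc_model=None`` it must be a (k, 3) semi-landmark configuration.
    The output inherits the template's faces.
    """
    if pc_model is not None:
        config = reconstruct_config(pc_model, np.asarray(target))
    else:
        config = np.asarray(target, dtype=float)
    return warp_template_mesh(template, config)


# ---------------------------------------------------------------------------
# signatures


def signature_from_configs(
    config_a: NDArray, config_b: NDArray, template: Template, label: str
) -> EffectSignature:
    """Signature from two corresponded semi-landmark configurations."""
    mesh_a = warp_template_mesh(template, config_a)
    mesh_b = warp_template_mesh(template, config_b)
    profile = np.linalg.norm(
        np.asarray(mesh_a.vertices) - np.asarray(mesh_b.vertices), axis=1
    )
    return EffectSignature(
        label=label, surface_a=mesh_a, surface_b=mesh_b, profile=profile
    )


def signature_for_snp(
    pc_model: PCModel,
    genotypes: NDArray,
    configs: NDArray,
    template: Template,
    label: str = "snp",
) -> EffectSignature:
    """Effect of a SNP: the shape difference between its homozygote classes.

    ``configs`` are the aligned configurations underlying the PC model
    (one per individual, same order as ``genotypes``).
    """
    g = np.asarray(genotypes, dtype=float)
    configs = np.asarray(configs, dtype=float)
    for code, name in ((0.0, "reference"), (2.0, "alternate")):
        if not np.any(g == code):
            raise ValueError(f"no {name}-homozygote individuals for this SNP")
    mean_a = configs[g == 0.0].mean(axis=0)
    mean_b = configs[g == 2.0].mean(axis=0)
    return signature_from_configs(mean_a, mean_b, template, label)


def signature_for_groups(
    wt_configs: NDArray,
    mutant_configs: NDArray,
    template: Template,
    label: str = "mutant",
) -> EffectSignature:
    """Effect of a mutant line: wild-type mean surface vs mutant mean surface.

    The two groups are superimposed jointly before taking the means.
    """
    wt = np.asarray(wt_configs, dtype=float)
    mut = np.asarray(mutant_configs, dtype=float)
    if len(wt) == 0 or len(mut) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([wt, mut], axis=0)
    aligned = gpa_align(pooled)
    mean_wt = aligned.configs[: len(wt)].mean(axis=0)
    mean_mut = aligned.configs[len(wt):].mean(axis=0)
    return signature_from_configs(mean_wt, mean_mut, template, label)


def signature_for_pc(
    pc_model: PCModel,
    axis: int,
    template: Template,
    span: tuple[float, float] | None = None,
) -> EffectSignature:
    """Effect of one PC: surfaces reconstructed at the axis extremes.

    ``span`` defaults to the (min, max) observed scores on the axis.
    """
    if span is None:
        s = pc_model.scores[:, axis]
        span = (float(s.min()), float(s.max()))
    n_axes = pc_model.eigenvectors.shape[0]
    lo = np.zeros(n_axes)
    hi = np.zeros(n_axes)
    lo[axis], hi[axis] = span
    return signature_from_configs(
        reconstruct_config(pc_model, lo),
        reconstruct_config(pc_model, hi),
        template,
        label=f"PC{axis + 1}",
    )


# ---------------------------------------------------------------------------
# comparison


def compare_signatures(
    a: EffectSignature, b: EffectSignature, method: str = "pearson"
) -> float:
    """Correlation of two per-vertex distance profiles."""
    if len(a.profile) != len(b.profile):
        raise ValueError("signatures come from different templates")
    if np.ptp(a.profile) == 0 or np.ptp(b.profile) == 0:
        raise ValueError("constant distance profile carries no signal")
    if method == "pearson":
        return float(stats.pearsonr(a.profile, b.profile)[0])
    if method == "spearman":
        return float(stats.spearmanr(a.profile, b.profile)[0])
    raise ValueError(f"unknown method {method!r}")


def pc_baseline(
    pc_model: PCModel,
    template: Template,
    method: str = "pearson",
) -> tuple[NDArray, list[EffectSignature]]:
    """Pairwise signature correlations among the retained PCs.

    Returns the baseline distribution — C(n_retained, 2) values — and the
    per-PC signatures for reuse in queries.
    """
    n = pc_model.n_retained
    if n < 3:
        raise ValueError("need at least 3 retained PCs for a baseline")
    sigs = [signature_for_pc(pc_model, i, template) for i in range(n)]
    baseline = np.array(
        [
            compare_signatures(sigs[i], sigs[j], method=method)
            for i, j in itertools.combinations(range(n), 2)
        ]
    )
    return baseline, sigs


def place_in_baseline(
    query: float, baseline: NDArray, label_a: str = "", label_b: str = ""
) -> ComparisonResult:
    """Percentile of an observed correlation within the PC-pair baseline."""
    baseline = np.asarray(baseline, dtype=float)
    pct = 100.0 * np.mean(baseline <= query)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        correlation=float(query),
        baseline=baseline,
        percentile=float(pct),
    )


# ---------------------------------------------------------------------------
# export


def export_signature_ply(
    sig: EffectSignature, path: str | Path, signed: bool = False
) -> None:
    """ASCII PLY of surface A with a per-vertex scalar quality channel.

    Unsigned profile distances by default; with ``signed=True`` the
    displacement is signed by the outward normal of surface A (expansion
    positive, compression negative) — a visualisation aid only.
    """
    mesh = sig.surface_a
    verts = np.asarray(mesh.vertices)
    if signed:
        disp = np.asarray(sig.surface_b.vertices) - verts
        quality = np.einsum("ij,ij->i", disp, np.asarray(mesh.vertex_normals))
    else:
        quality = sig.profile
    faces = np.asarray(mesh.faces)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(verts)}",
        "property float x",
        "property float y",
        "property float z",
        "property float quality",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, q in zip(verts, quality):
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {q:.6f}")
    for f in faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")
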