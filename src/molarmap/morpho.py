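"""Template-based 3D semi-landmark phenotyping of tooth crowns.

The phenotyping chain is the standard surface-morphometrics pipeline:

1. a *template* (a crown surface mesh with an ordered set of semi-landmarks
   and a handful of anchor landmarks) is warped onto each specimen by a
   thin-plate spline through the anchors, and the warped semi-landmarks are
   projected onto the specimen surface;
2. semi-landmarks *slide* within their local tangent planes to minimise the
   TPS bending energy of each specimen relative to the current Procrustes
   consensus;
3. a full generalized Procrustes analysis (GPA) removes position, scale and
   orientation, yielding Procrustes shape coordinates and centroid sizes;
4. a PCA of the aligned coordinates produces the shape phenotypes; axes
   carrying more than a retention threshold (default 1%) of total variance
   are kept for mapping.

A *wear-free* template has its cusp tips truncated at a fixed height so
that between-individual differences in occlusal wear never enter the shape
variables.  The occlusal (height) axis is the third coordinate of the
template frame; specimens are brought into that frame by the anchoring
warp, which makes the truncation reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh
from numpy.typing import NDArray

from .tps import ThinPlateSpline, bending_energy, bending_energy_matrix

__all__ = [
    "Template",
    "AlignedShapes",
    "PCModel",
    "build_wear_free_template",
    "suggest_cut_height",
    "resample_semilandmarks",
    "anchor_template",
    "phenotype_config",
    "truncate_config",
    "slide_semilandmarks",
    "gpa_align",
    "procrustes_distance",
    "compute_pca",
    "regress_shape_on_covariate",
    "read_landmark_csv",
    "write_landmark_csv",
]


# ---------------------------------------------------------------------------
# domain containers


@dataclasses.dataclass
class Template:
    """Crown surface with its semi-landmark scheme.

    ``semilandmark_indices`` index into ``mesh.vertices`` and fix, once and
    for all, the number and order of points every specimen is described by.
    ``anchors`` are the manually placed landmarks used to warp the template
    onto each specimen (10 for a complete crown, 7 for a truncated one).
    """

    mesh: trimesh.Trimesh
    semilandmark_indices: NDArray
    anchors: NDArray
    wear_free: bool = False
    cut_height: float | None = None

    @property
    def semilandmarks(self) -> NDArray:
        return np.asarray(self.mesh.vertices)[self.semilandmark_indices]

    @property
    def n_semilandmarks(self) -> int:
        return len(self.semilandmark_indices)

    def save(self, mesh_path: str | Path, sidecar_path: str | Path) -> None:
        self.mesh.export(str(mesh_path))
        sidecar = {
            "semilandmark_indices": self.semilandmark_indices.tolist(),
            "anchors": np.asarray(self.anchors).tolist(),
            "wear_free": bool(self.wear_free),
            "cut_height": self.cut_height,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, mesh_path: str | Path, sidecar_path: str | Path) -> "Template":
        mesh = trimesh.load(str(mesh_path), force="mesh")
        meta = json.loads(Path(sidecar_path).read_text())
        return cls(
            mesh=mesh,
            semilandmark_indices=np.asarray(meta["semilandmark_indices"], dtype=int),
            anchors=np.asarray(meta["anchors"], dtype=float),
            wear_free=bool(meta["wear_free"]),
            cut_height=meta["cut_height"],
        )


@dataclasses.dataclass
class AlignedShapes:
    """Output of a full GPA: aligned configs, consensus, centroid sizes."""

    configs: NDArray          # (n, k, 3), unit centroid size, consensus frame
    consensus: NDArray        # (k, 3)
    centroid_sizes: NDArray   # (n,), sizes before scaling
    specimen_ids: list[str] | None = None

    @property
    def n_specimens(self) -> int:
        return self.configs.shape[0]


@dataclasses.dataclass
class PCModel:
    """Eigenbasis of aligned shape space; houses the mapping phenotypes."""

    eigenvectors: NDArray      # (n_axes, 3k), orthonormal rows
    variance_pct: NDArray      # (n_axes,), non-increasing, sums to <= 100
    scores: NDArray            # (n, n_axes), centered
    n_retained: int            # axes with variance share > threshold
    consensus: NDArray         # (k, 3)
    centroid_sizes: NDArray | None = None
    specimen_ids: list[str] | None = None

    @property
    def retained_scores(self) -> NDArray:
        return self.scores[:, : self.n_retained]

    @property
    def retained_variance_pct(self) -> NDArray:
        return self.variance_pct[: self.n_retained]


# ---------------------------------------------------------------------------
# template construction


def suggest_cut_height(configs: NDArray, margin_frac: float = 0.05) -> float:
    """Minimal valid truncation height for a set of (worn) specimens.

    Returns the lowest specimen apex minus a safety margin expressed as a
    fraction of total crown height, guaranteeing that even the most worn
    specimen still reaches the cut plane.
    """
    configs = np.asarray(configs, dtype=float)
    apex_per_specimen = configs[..., 2].max(axis=1)
    crown_height = configs[..., 2].max() - configs[..., 2].min()
    return float(apex_per_specimen.min() - margin_frac * crown_height)


def build_wear_free_template(template: Template, cut_height: float) -> Template:
    """Truncate a template's cusps at ``cut_height`` along the occlusal axis.

    Vertices above the cut plane are projected straight down onto it,
    producing flat caps where the cusp tips were; the triangulation is
    preserved.  Raises ``ValueError`` when the cut lies at or below the
    crown base (the whole crown would be planed away).
    """
    verts = np.asarray(template.mesh.vertices, dtype=float).copy()
    zmin, zmax = verts[:, 2].min(), verts[:, 2].max()
    if cut_height <= zmin:
        raise ValueError(
            f"cut height {cut_height} at or below crown base {zmin}: "
            "no describable surface would remain"
        )
    if cut_height >= zmax:
        new_mesh = template.mesh.copy()
    else:
        verts[:, 2] = np.minimum(verts[:, 2], cut_height)
        new_mesh = trimesh.Trimesh(
            vertices=verts, faces=template.mesh.faces.copy(), process=False
        )
    anchors = np.asarray(template.anchors, dtype=float).copy()
    anchors[:, 2] = np.minimum(anchors[:, 2], cut_height)
    return Template(
        mesh=new_mesh,
        semilandmark_indices=template.semilandmark_indices.copy(),
        anchors=anchors,
        wear_free=True,
        cut_height=float(cut_height),
    )


def resample_semilandmarks(
    mesh: trimesh.Trimesh, n_requested: int, seed: int = 0
) -> NDArray:
    """Equally spaced surface sampling, snapped to mesh vertices.

    Blue-noise-style sampling at a spacing derived from the surface area;
    the spacing is relaxed until at least ``n_requested`` distinct vertex
    indices are obtained, so the returned count overshoots the request
    (as equal-area samplers do).  Returns the ordered vertex indices.
    """
    if n_requested < 1:
        raise ValueError("n_requested must be positive")
    rng = np.random.default_rng(seed)
    area = mesh.area
    radius = np.sqrt(area / (np.pi * n_requested))
    for _ in range(20):
        pts, _ = trimesh.sample.sample_surface(
            mesh, count=max(8 * n_requested, 2000), seed=int(rng.integers(2**31))
        )
        kept: list[np.ndarray] = []
        for p in pts:
            if not kept or np.min(
                np.linalg.norm(np.asarray(kept) - p[None, :], axis=1)
            ) >= radius:
                kept.append(p)
        kept_arr = np.asarray(kept)
        _, vidx = trimesh.proximity.ProximityQuery(mesh).vertex(kept_arr)
        vidx = np.unique(vidx)
        if len(vidx) >= n_requested:
            return np.sort(vidx)
        radius *= 0.8
    raise RuntimeError("could not sample the requested number of semi-landmarks")


# ---------------------------------------------------------------------------
# anchoring and wear-aware phenotyping


def anchor_template(
    template: Template,
    specimen_mesh: trimesh.Trimesh,
    specimen_anchors: NDArray,
    project: bool = True,
) -> NDArray:
    """Warp the template's semi-landmarks onto a specimen surface.

    A TPS interpolating the template anchors to the specimen anchors is
    applied to the template semi-landmarks; each warped point is then
    projected to the nearest point of the specimen mesh.  Returns the
    (k, 3) semi-landmark configuration of the specimen.
    """
    specimen_anchors = np.asarray(specimen_anchors, dtype=float)
    t_anchors = np.asarray(template.anchors, dtype=float)
    if specimen_anchors.shape != t_anchors.shape:
        raise ValueError(
            f"specimen anchors {specimen_anchors.shape} do not match "
            f"template anchors {t_anchors.shape}"
        )
    warp = ThinPlateSpline(t_anchors, specimen_anchors)
    warped = warp.transform(template.semilandmarks)
    if not project:
        return warped
    return project_to_surface(specimen_mesh, warped)


def project_to_surface(mesh: trimesh.Trimesh, points: NDArray) -> NDArray:
    """Nearest point on the mesh surface for each query point.

    Exhaustive point-to-triangle projection (barycentric clamping); exact,
    and fast enough at template scale.
    """
    tri = np.asarray(mesh.triangles)          # (F, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    out = np.empty_like(np.asarray(points, dtype=float))
    for i, p in enumerate(np.atleast_2d(points)):
        ap = p[None, :] - a
        d1 = np.einsum("ij,ij->i", ab, ap)
        d2 = np.einsum("ij,ij->i", ac, ap)
        bp = p[None, :] - b
        d3 = np.einsum("ij,ij->i", ab, bp)
        d4 = np.einsum("ij,ij->i", ac, bp)
        cp = p[None, :] - c
        d5 = np.einsum("ij,ij->i", ab, cp)
        d6 = np.einsum("ij,ij->i", ac, cp)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        v = np.where(np.abs(denom) > 1e-300, vb / denom, 0.0)
        w = np.where(np.abs(denom) > 1e-300, vc / denom, 0.0)
        cand = a + v[:, None] * ab + w[:, None] * ac   # interior foot

        # clamp to edges / vertices region by region
        vertex_a = (d1 <= 0) & (d2 <= 0)
        vertex_b = (d3 >= 0) & (d4 <= d3)
        vertex_c = (d6 >= 0) & (d5 <= d6)
        t_ab = np.clip(
            np.where(np.abs(d1 - d3) > 1e-300, d1 / (d1 - d3 + 1e-300), 0.0),
            0, 1,
        )
        edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        t_ac = np.clip(
            np.where(np.abs(d2 - d6) > 1e-300, d2 / (d2 - d6 + 1e-300), 0.0),
            0, 1,
        )
        edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6) + 1e-300), 0, 1)
        edge_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

        cand = np.where(edge_bc[:, None], b + t_bc[:, None] * (c - b), cand)
        cand = np.where(edge_ac[:, None], a + t_ac[:, None] * ac, cand)
        cand = np.where(edge_ab[:, None], a + t_ab[:, None] * ab, cand)
        cand = np.where(vertex_c[:, None], c, cand)
        cand = np.where(vertex_b[:, None], b, cand)
        cand = np.where(vertex_a[:, None], a, cand)

        d = np.einsum("ij,ij->i", cand - p[None, :], cand - p[None, :])
        out[i] = cand[int(np.argmin(d))]
    return out


def truncate_config(config: NDArray, cut_height: float) -> NDArray:
    """Project every point above the cut plane down onto it."""
    out = np.asarray(config, dtype=float).copy()
    out[..., 2] = np.minimum(out[..., 2], cut_height)
    return out


def phenotype_config(template: Template, config: NDArray) -> NDArray:
    """Describe a corresponded semi-landmark configuration with a template.

    With a complete template this is the identity.  With a wear-free
    template the configuration is truncated at the template's cut height,
    which removes any signal above the cut — two copies of a specimen worn
    to different depths (both above the cut) become identical.
    """
    config = np.asarray(config, dtype=float)
    if config.shape[-2] != template.n_semilandmarks:
        raise ValueError("configuration does not match template semi-landmark count")
    if template.wear_free:
        if template.cut_height is None:
            raise ValueError("wear-free template lacks a cut height")
        return truncate_config(config, template.cut_height)
    return config.copy()


# ---------------------------------------------------------------------------
# Procrustes machinery


def _center_scale(config: NDArray) -> tuple[NDArray, float]:
    c = config - config.mean(axis=0, keepdims=True)
    cs = float(np.sqrt((c**2).sum()))
    if cs == 0:
        raise ValueError("configuration with zero centroid size")
    return c / cs, cs


def _kabsch(source: NDArray, target: NDArray) -> NDArray:
    """Rotation (no reflection) best aligning centered ``source`` to ``target``."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _canonical_rotation(consensus: NDArray) -> NDArray:
    """Deterministic orientation: principal axes of the consensus.

    Signs are fixed from the projected coordinates (the landmark with the
    largest absolute projection on each axis is made positive), which is
    invariant to how the consensus happened to be oriented coming in.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    proj = consensus @ vecs
    for j in range(3):
        i = int(np.argmax(np.abs(proj[:, j])))
        if proj[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def gpa_align(
    configs: NDArray | Sequence[NDArray],
    specimen_ids: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> AlignedShapes:
    """Full generalized Procrustes superimposition.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated (Kabsch, reflections disallowed) to the running
    mean until the consensus stabilises.  The consensus is re-oriented to
    its principal axes with deterministic signs so the result does not
    depend on specimen order.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need at least two configurations of equal size")
    n = arr.shape[0]
    scaled = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _center_scale(arr[i])

    # order-invariant initialisation: every config rotated to its own
    # canonical principal-axes frame before the first averaging
    for i in range(n):
        scaled[i] = scaled[i] @ _canonical_rotation(scaled[i])
    mean = scaled.mean(axis=0)
    mean = mean / np.sqrt((mean**2).sum())
    prev = None
    for _ in range(max_iter):
        for i in range(n):
            R = _kabsch(scaled[i], mean)
            scaled[i] = scaled[i] @ R
        mean = scaled.mean(axis=0)
        mean = mean / np.sqrt((mean**2).sum())
        if prev is not None and np.sqrt(((mean - prev) ** 2).sum()) < tol:
            break
        prev = mean.copy()

    Rc = _canonical_rotation(mean)
    mean = mean @ Rc
    scaled = scaled @ Rc
    consensus = scaled.mean(axis=0)
    return AlignedShapes(
        configs=scaled,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=specimen_ids,
    )


def procrustes_distance(a: NDArray, b: NDArray) -> float:
    """Full Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, the optimal
    rotation (no reflection) is applied, and the Frobenius distance of the
    aligned coordinates is returned.
    """
    a_s, _ = _center_scale(np.asarray(a, dtype=float))
    b_s, _ = _center_scale(np.asarray(b, dtype=float))
    R = _kabsch(a_s, b_s)
    return float(np.linalg.norm(a_s @ R - b_s))


# ---------------------------------------------------------------------------
# sliding semi-landmarks


def _tangent_bases(normals: NDArray) -> NDArray:
    """Orthonormal pair of tangent vectors per point, (k, 2, 3)."""
    k = normals.shape[0]
    n = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (k, 1))
    near = np.abs(n[:, 0]) > 0.9
    ref[near] = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(n, u)
    return np.stack([u, v], axis=1)


def _slide_one(
    config: NDArray, consensus: NDArray, B: NDArray, tangents: NDArray
) -> NDArray:
    """Closed-form GLS slide of one configuration toward the consensus.

    Minimises ``tr((Y + Δ - C)^T B (Y + Δ - C))`` over tangent-plane
    displacements ``Δ_i = t_i1 u_i + t_i2 v_i`` jointly for all points.
    """
    k = config.shape[0]
    D = config - consensus
    W = tangents.reshape(2 * k, 3)           # rows (i,a) -> tangent vector
    G = W @ W.T                              # (2k, 2k) tangent inner products
    Bexp = np.repeat(np.repeat(B, 2, axis=0), 2, axis=1)
    M = Bexp * G
    BD = B @ D                               # (k, 3)
    g = np.einsum("pj,pj->p", W, np.repeat(BD, 2, axis=0))
    t = np.linalg.lstsq(M, -g, rcond=None)[0]
    delta = (t[:, None] * W).reshape(k, 2, 3).sum(axis=1)
    return config + delta


def slide_semilandmarks(
    configs: NDArray,
    template: Template | None = None,
    normals: NDArray | None = None,
    max_iter: int = 3,
    tol: float = 1e-6,
) -> tuple[NDArray, AlignedShapes, bool]:
    """Slide semi-landmarks to minimise bending energy toward the consensus.

    Tangent planes are taken from the specimen surface when per-specimen
    ``normals`` are supplied, and from the template's vertex normals
    otherwise.  Each outer iteration slides every specimen against the
    current consensus (closed-form generalized least squares in the
    tangent basis) and then re-runs GPA to refresh the consensus; the loop
    stops when the consensus RMS change drops below ``tol``.

    Returns ``(slid_configs, aligned, converged)``; on hitting ``max_iter``
    the last iterate is returned with ``converged=False``.
    """
    configs = np.asarray(configs, dtype=float).copy()
    n, k, _ = configs.shape
    if normals is None:
        if template is None:
            raise ValueError("need either a template or per-specimen normals")
        vn = np.asarray(template.mesh.vertex_normals)[template.semilandmark_indices]
        normals = np.tile(vn[None, :, :], (n, 1, 1))
    aligned = gpa_align(configs)
    converged = False
    for _ in range(max_iter):
        consensus = aligned.consensus
        B = bending_energy_matrix(consensus)
        for i in range(n):
            cur = aligned.configs[i]
            tangents = _tangent_bases(normals[i])
            new = _slide_one(cur, consensus, B, tangents)
            if bending_energy(B, consensus, new) <= bending_energy(
                B, consensus, cur
            ):
                aligned.configs[i] = new
        new_aligned = gpa_align(aligned.configs)
        new_aligned.centroid_sizes = aligned.centroid_sizes
        shift = np.sqrt(((new_aligned.consensus - aligned.consensus) ** 2).mean())
        aligned = new_aligned
        if shift < tol:
            converged = True
            break
    return aligned.configs, aligned, converged


# ---------------------------------------------------------------------------
# PCA phenotypes and the age regression


def compute_pca(
    aligned: AlignedShapes, retain_threshold: float = 1.0
) -> PCModel:
    """PCA of the covariance of the aligned (flattened) shape coordinates.

    ``retain_threshold`` is a percentage of total variance; axes strictly
    above it become the mapping phenotypes.
    """
    if not 0.0 < retain_threshold < 100.0:
        raise ValueError("retain_threshold must lie in (0, 100) percent")
    X = aligned.configs.reshape(aligned.n_specimens, -1)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data: eigenvectors of the covariance matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    keep = eigvals > max(eigvals.max(), 1.0) * 1e-14
    eigvals, Vt, U, s = eigvals[keep], Vt[keep], U[:, keep], s[keep]
    var_pct = 100.0 * eigvals / eigvals.sum()
    scores = U * s
    n_retained = int(np.sum(var_pct > retain_threshold))
    return PCModel(
        eigenvectors=Vt,
        variance_pct=var_pct,
        scores=scores,
        n_retained=n_retained,
        consensus=aligned.consensus,
        centroid_sizes=aligned.centroid_sizes,
        specimen_ids=aligned.specimen_ids,
    )


def regress_shape_on_covariate(
    pc_scores: NDArray,
    covariate: NDArray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Multivariate regression of retained PC scores on a covariate.

    The summary r² is the fraction of *total* retained-score variance
    explained by the covariate (variance-weighted over PCs); its p-value
    comes from a permutation test (covariate shuffled across specimens).
    Per-PC r² and permutation p-values are returned alongside.
    """
    scores = np.asarray(pc_scores, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n, q = scores.shape
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if n <= q + 1:
        raise ValueError("need more specimens than PCs + 1")

    def _r2_per_pc(xv: NDArray) -> NDArray:
        xc = xv - xv.mean()
        yc = scores - scores.mean(axis=0)
        num = (xc @ yc) ** 2
        den = (xc @ xc) * (yc**2).sum(axis=0)
        return num / den

    var = scores.var(axis=0, ddof=1)
    r2_pc = _r2_per_pc(x)
    r2_total = float((var * r2_pc).sum() / var.sum())

    rng = np.random.default_rng(seed)
    exceed_total = 0
    exceed_pc = np.zeros(q)
    for _ in range(n_perm):
        xp = rng.permutation(x)
        r2p = _r2_per_pc(xp)
        if (var * r2p).sum() / var.sum() >= r2_total:
            exceed_total += 1
        exceed_pc += r2p >= r2_pc
    p_total = (exceed_total + 1) / (n_perm + 1)
    p_pc = (exceed_pc + 1) / (n_perm + 1)
    return {
        "r2": r2_total,
        "p": float(p_total),
        "r2_per_pc": r2_pc,
        "p_per_pc": p_pc,
    }


# ---------------------------------------------------------------------------
# landmark file I/O (long-format CSV)


def write_landmark_csv(
    path: str | Path, configs: NDArray, specimen_ids: Sequence[str]
) -> None:
    """Write configurations as long CSV (specimen_id, point_index, x, y, z)."""
    configs = np.asarray(configs, dtype=float)
    n, k, _ = configs.shape
    df = pd.DataFrame(
        {
            "specimen_id": np.repeat(list(specimen_ids), k),
            "point_index": np.tile(np.arange(k), n),
            "x": configs[:, :, 0].ravel(),
            "y": configs[:, :, 1].ravel(),
            "z": configs[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_landmark_csv(path: str | Path) -> tuple[NDArray, list[str]]:
    """Read long-format landmark CSV back into an (n, k, 3) array."""
    df = pd.read_csv(path)
    ids = list(dict.fromkeys(df["specimen_id"].astype(str)))
    k = df["point_index"].max() + 1
    configs = np.empty((len(ids), k, 3))
    for i, sid in enumerate(ids):
        sub = df[df["specimen_id"].astype(str) == sid].sort_values("point_index")
        if len(sub) != k:
            raise ValueError(f"specimen {sid} has {len(sub)} points, expected {k}")
        configs[i] = sub[["x", "y", "z"]].to_numpy()
    return configs, ids
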