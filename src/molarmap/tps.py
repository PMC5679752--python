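"""Thin-plate spline warps and bending energy in three dimensions.

The TPS with kernel ``U(r) = r`` (the 3D biharmonic radial basis) is the
workhorse of template-based morphometrics: it interpolates a set of control
points exactly, reproduces affine maps with zero deformation cost, and its
quadratic deformation cost ("bending energy") is the criterion minimised
when semi-landmarks slide.

Given k control points ``P`` the interpolation system is::

    L = | K   Q |        K_ij = U(|p_i - p_j|) = -|p_i - p_j|,
        | Q^T 0 |        Q = [1 | P]  (k x 4)

The upper-left k x k block of ``L^{-1}`` is the bending-energy matrix
``B``; for a warp sending ``P`` to targets ``Y`` the bending energy is
``trace(Y^T B Y)``. ``B`` is symmetric, positive semi-definite, and
annihilates affine functions of ``P`` (so rigid motions cost nothing).
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

__all__ = ["ThinPlateSpline", "bending_energy_matrix", "bending_energy"]


def _kernel(r: NDArray) -> NDArray:
    # 3D biharmonic kernel; the minus sign makes it conditionally positive
    # definite, so the bending-energy quadratic form comes out PSD
    return -r


def _build_L(points: NDArray) -> NDArray:
    k = points.shape[0]
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    K = _kernel(d)
    Q = np.hstack([np.ones((k, 1)), points])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    return L


class ThinPlateSpline:
    """Exact TPS interpolant from ``source`` control points to ``target``.

    Raises ``np.linalg.LinAlgError`` when the control points are affinely
    degenerate (coplanar-collinear configurations make the system singular).
    """

    def __init__(self, source: NDArray, target: NDArray):
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
            raise ValueError("source and target must be matching (k, 3) arrays")
        if source.shape[0] < 4:
            raise ValueError("TPS in 3D needs at least 4 control points")
        self.source = source
        L = _build_L(source)
        k = source.shape[0]
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = target
        cond = np.linalg.cond(L)
        if not np.isfinite(cond) or cond > 1e13:
            raise np.linalg.LinAlgError(
                "degenerate TPS control points (affinely dependent anchors)"
            )
        coefs = np.linalg.solve(L, rhs)
        self._w = coefs[:k]       # non-affine weights, (k, 3)
        self._a = coefs[k:]       # affine part, (4, 3)

    def transform(self, points: NDArray) -> NDArray:
        """Apply the warp to an (m, 3) array of points."""
        points = np.asarray(points, dtype=float)
        d = np.linalg.norm(points[:, None, :] - self.source[None, :, :], axis=2)
        U = _kernel(d)
        affine = np.hstack([np.ones((points.shape[0], 1)), points]) @ self._a
        return affine + U @ self._w


def bending_energy_matrix(points: NDArray) -> NDArray:
    """Bending-energy matrix ``B`` (k x k) of a reference configuration.

    ``B`` is the upper-left block of ``L^{-1}``; it is symmetrised on
    return to guard against round-off and annihilates [1 | points].
    """
    points = np.asarray(points, dtype=float)
    k = points.shape[0]
    L = _build_L(points)
    Linv = np.linalg.pinv(L)
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


def bending_energy(B: NDArray, reference: NDArray, config: NDArray) -> float:
    """TPS bending energy of the map sending ``reference`` to ``config``.

    ``B`` must come from :func:`bending_energy_matrix` on ``reference``.
    Because ``B`` annihilates affine functions the energy can equivalently
    be evaluated on the displacement ``config - reference``.
    """
    disp = np.asarray(config, dtype=float) - np.asarray(reference, dtype=float)
    return float(np.einsum("id,ij,jd->", disp, B, disp))
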