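"""Mutant-line validation statistics.

Each mutant genotype group is tested against the wild-type group on its
own pooled superimposition: GPA on the two groups together, PCA of the
pooled aligned shapes, then a two-sample Hotelling T² on the first two PC
scores with the classical F approximation.  Tests across groups are
corrected with the Holm step-down adjustment.  Groups too small for the F
approximation (fewer than ``n_pcs + 1`` members) are excluded with a
reason rather than tested.

Procrustes distances of individual specimens to a consensus (the grand
mean for a mapping sample; the wild-type mean for mutants) summarise how
far each line moves relative to natural shape variation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats

from .morpho import compute_pca, gpa_align, procrustes_distance

__all__ = [
    "GroupTestResult",
    "hotelling_t2",
    "pairwise_group_test",
    "holm_bonferroni",
    "distances_to_consensus",
    "mutant_panel_tests",
]


@dataclasses.dataclass
class GroupTestResult:
    group: str
    n_group: int
    n_wt: int
    t2: float | None
    p: float | None
    p_adjusted: float | None
    procrustes_distance: float
    status: str = "tested"        # or "excluded: <reason>"


def hotelling_t2(a: NDArray, b: NDArray) -> tuple[float, float]:
    """Two-sample Hotelling T² with pooled covariance and the F transform.

    ``T² = n1 n2/(n1+n2) · d̄ᵀ S⁻¹ d̄`` with ``S`` the pooled covariance;
    ``F = (n1+n2-q-1)/(q(n1+n2-2)) · T²`` on (q, n1+n2-q-1) df.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, q = a.shape
    n2 = b.shape[0]
    if n1 + n2 - q - 1 <= 0:
        raise ValueError("samples too small for the F approximation")
    d = a.mean(axis=0) - b.mean(axis=0)
    S = (
        (n1 - 1) * np.cov(a, rowvar=False, ddof=1)
        + (n2 - 1) * np.cov(b, rowvar=False, ddof=1)
    ) / (n1 + n2 - 2)
    S = np.atleast_2d(S)
    t2 = n1 * n2 / (n1 + n2) * float(d @ np.linalg.solve(S, d))
    f_stat = (n1 + n2 - q - 1) / (q * (n1 + n2 - 2)) * t2
    p = float(stats.f.sf(f_stat, q, n1 + n2 - q - 1))
    return t2, p


def pairwise_group_test(
    group_configs: NDArray,
    wt_configs: NDArray,
    n_pcs: int = 2,
    group_label: str = "group",
    permutation_fallback: int = 0,
    seed: int = 0,
) -> GroupTestResult:
    """Test one mutant group against wild type on a pooled superimposition.

    The pooled pair is superimposed and decomposed by PCA from scratch for
    every test (scores are not shared across tests).  A group with fewer
    than ``n_pcs + 1`` members cannot support the F approximation and is
    returned with an excluded status; when ``permutation_fallback`` > 0 a
    label-permutation p-value is computed instead for such groups.
    """
    grp = np.asarray(group_configs, dtype=float)
    wt = np.asarray(wt_configs, dtype=float)
    if len(wt) == 0:
        raise ValueError("empty wild-type group")
    n1, n2 = len(grp), len(wt)
    pooled = np.concatenate([grp, wt], axis=0)
    aligned = gpa_align(pooled)
    dist = procrustes_distance(
        aligned.configs[:n1].mean(axis=0), aligned.configs[n1:].mean(axis=0)
    )
    if n1 + n2 <= n_pcs + 2 or min(n1, n2) <= n_pcs:
        result = GroupTestResult(
            group=group_label,
            n_group=n1,
            n_wt=n2,
            t2=None,
            p=None,
            p_adjusted=None,
            procrustes_distance=dist,
            status=f"excluded: group of {min(n1, n2)} too small for "
            f"{n_pcs}-PC test",
        )
        if permutation_fallback > 0:
            result.p = _permutation_p(
                aligned.configs, n1, n_pcs, permutation_fallback, seed
            )
            result.status += " (permutation p reported)"
        return result
    model = compute_pca(aligned)
    scores = model.scores[:, :n_pcs]
    t2, p = hotelling_t2(scores[:n1], scores[n1:])
    return GroupTestResult(
        group=group_label,
        n_group=n1,
        n_wt=n2,
        t2=t2,
        p=p,
        p_adjusted=None,
        procrustes_distance=dist,
    )


def _permutation_p(
    aligned_configs: NDArray, n1: int, n_pcs: int, n_perm: int, seed: int
) -> float:
    """Label-permutation p on the mean-difference norm in PC space."""
    model = compute_pca(gpa_align(aligned_configs))
    scores = model.scores[:, :n_pcs]
    obs = np.linalg.norm(scores[:n1].mean(axis=0) - scores[n1:].mean(axis=0))
    rng = np.random.default_rng(seed)
    count = 0
    n = len(scores)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        s = scores[idx]
        if np.linalg.norm(s[:n1].mean(axis=0) - s[n1:].mean(axis=0)) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def holm_bonferroni(pvals: NDArray) -> NDArray:
    """Holm step-down adjustment, returned in the input order.

    ``adjusted_(k) = max_{j<=k} min(1, (m-j+1) * p_(j))`` over the
    ascending order statistics.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[idx]))
        adjusted[idx] = running
    return adjusted


def distances_to_consensus(
    configs: NDArray,
    reference: str = "grand-mean",
    wt_mask: NDArray | None = None,
) -> NDArray:
    """Full Procrustes distance of each specimen to a designated consensus.

    ``reference="grand-mean"`` uses the mean of all aligned specimens;
    ``"wt-mean"`` uses the mean of the specimens flagged by ``wt_mask``
    (the wild-type group), everything superimposed in one GPA.
    """
    configs = np.asarray(configs, dtype=float)
    aligned = gpa_align(configs)
    if reference == "grand-mean":
        ref = aligned.configs.mean(axis=0)
    elif reference == "wt-mean":
        if wt_mask is None or not np.any(wt_mask):
            raise ValueError("wt-mean reference needs a non-empty wt_mask")
        ref = aligned.configs[np.asarray(wt_mask, dtype=bool)].mean(axis=0)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return np.array(
        [procrustes_distance(c, ref) for c in aligned.configs]
    )


def mutant_panel_tests(
    groups: dict[str, NDArray],
    wild_type: str = "WT",
    n_pcs: int = 2,
) -> pd.DataFrame:
    """Run every mutant group against wild type and Holm-adjust the p-values."""
    if wild_type not in groups:
        raise ValueError(f"wild-type group {wild_type!r} missing")
    wt = groups[wild_type]
    results = [
        pairwise_group_test(cfgs, wt, n_pcs=n_pcs, group_label=label)
        for label, cfgs in groups.items()
        if label != wild_type
    ]
    tested = [r for r in results if r.p is not None]
    if tested:
        adj = holm_bonferroni([r.p for r in tested])
        for r, a in zip(tested, adj):
            r.p_adjusted = float(a)
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "n_group": [r.n_group for r in results],
            "n_wt": [r.n_wt for r in results],
            "T2": [r.t2 for r in results],
            "p": [r.p for r in results],
            "p_holm": [r.p_adjusted for r in results],
            "procrustes_distance": [r.procrustes_distance for r in results],
            "status": [r.status for r in results],
        }
    )
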