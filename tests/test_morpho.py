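"""Template truncation, anchoring, sliding, GPA, PCA, age regression."""

import numpy as np
import pytest
import trimesh

from molarmap import morpho, simdata
from molarmap.morpho import AlignedShapes
from molarmap.tps import bending_energy, bending_energy_matrix


# -- wear-free template ------------------------------------------------------


def test_cut_above_apex_only_sets_flag(tooth_template):
    zmax = tooth_template.mesh.vertices[:, 2].max()
    wf = morpho.build_wear_free_template(tooth_template, zmax + 1.0)
    assert wf.wear_free
    np.testing.assert_array_equal(wf.mesh.vertices, tooth_template.mesh.vertices)


def test_cut_truncates_all_retained_vertices(tooth_template):
    zmax = tooth_template.mesh.vertices[:, 2].max()
    cut = 0.6 * zmax
    wf = morpho.build_wear_free_template(tooth_template, cut)
    assert wf.semilandmarks[:, 2].max() <= cut + 1e-12
    assert wf.n_semilandmarks == tooth_template.n_semilandmarks


def test_cut_below_crown_base_raises(tooth_template):
    zmin = tooth_template.mesh.vertices[:, 2].min()
    with pytest.raises(ValueError, match="crown base"):
        morpho.build_wear_free_template(tooth_template, zmin - 0.1)


def test_resampler_overshoots_requested_count(tooth_template):
    idx = morpho.resample_semilandmarks(tooth_template.mesh, 40, seed=0)
    assert len(idx) >= 40
    assert len(np.unique(idx)) == len(idx)


# -- anchoring ---------------------------------------------------------------


def test_anchoring_identity_specimen(tooth_template):
    out = morpho.anchor_template(
        tooth_template, tooth_template.mesh, tooth_template.anchors
    )
    np.testing.assert_allclose(out, tooth_template.semilandmarks, atol=1e-6)


def test_anchoring_rigid_motion_specimen(tooth_template):
    """TPS reproduces a rigid transform exactly; projection lands on it."""
    theta = 0.4
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0],
         [np.sin(theta), np.cos(theta), 0],
         [0, 0, 1.0]]
    )
    t = np.array([0.5, -0.2, 0.3])
    moved = trimesh.Trimesh(
        vertices=np.asarray(tooth_template.mesh.vertices) @ R.T + t,
        faces=tooth_template.mesh.faces.copy(),
        process=False,
    )
    out = morpho.anchor_template(
        tooth_template, moved, tooth_template.anchors @ R.T + t
    )
    np.testing.assert_allclose(
        out, tooth_template.semilandmarks @ R.T + t, atol=1e-6
    )


def test_anchor_count_mismatch_raises(tooth_template):
    with pytest.raises(ValueError, match="anchors"):
        morpho.anchor_template(
            tooth_template, tooth_template.mesh, tooth_template.anchors[:5]
        )


# -- GPA ---------------------------------------------------------------------


def test_gpa_identical_configs_distance_zero(rng):
    c = rng.standard_normal((10, 3))
    aligned = morpho.gpa_align(np.stack([c, c, c]))
    assert np.linalg.norm(aligned.configs[0] - aligned.configs[1]) < 1e-12
    np.testing.assert_allclose(aligned.consensus.mean(axis=0), 0, atol=1e-12)


def test_gpa_removes_rigid_motion_and_scale(rng):
    c = rng.standard_normal((12, 3))
    theta = 1.1
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0],
         [np.sin(theta), np.cos(theta), 0],
         [0, 0, 1.0]]
    )
    c2 = 2.7 * c @ R.T + np.array([3.0, -1.0, 2.0])
    aligned = morpho.gpa_align(np.stack([c, c2]))
    assert np.linalg.norm(aligned.configs[0] - aligned.configs[1]) < 1e-10
    assert morpho.procrustes_distance(c, c2) < 1e-10
    # centroid sizes recorded before scaling
    assert aligned.centroid_sizes[1] / aligned.centroid_sizes[0] == pytest.approx(2.7)


def test_gpa_consensus_invariant_to_specimen_order(rng):
    configs = rng.standard_normal((8, 15, 3))
    a = morpho.gpa_align(configs)
    b = morpho.gpa_align(configs[::-1])
    np.testing.assert_allclose(a.consensus, b.consensus, atol=1e-10)


def test_zero_centroid_size_raises():
    configs = np.zeros((2, 5, 3))
    with pytest.raises(ValueError, match="centroid"):
        morpho.gpa_align(configs)


def test_procrustes_distance_matches_planar_closed_form(rng):
    """Planar triangles: the complex-arithmetic closed form is the oracle."""
    tri_a = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.5, 1.5, 0.0]])
    tri_b = np.array([[0.1, -0.2, 0.0], [1.7, 0.4, 0.0], [0.2, 1.1, 0.0]])

    def complex_oracle(a, b):
        za = (a[:, 0] + 1j * a[:, 1]) - (a[:, 0] + 1j * a[:, 1]).mean()
        zb = (b[:, 0] + 1j * b[:, 1]) - (b[:, 0] + 1j * b[:, 1]).mean()
        za /= np.linalg.norm(za)
        zb /= np.linalg.norm(zb)
        # a 3D rotation can also flip the plane, i.e. conjugate the shape
        s = max(abs(np.vdot(za, zb)), abs(np.vdot(np.conj(za), zb)))
        return np.sqrt(max(2.0 - 2.0 * s, 0.0))

    assert morpho.procrustes_distance(tri_a, tri_b) == pytest.approx(
        complex_oracle(tri_a, tri_b), abs=1e-10
    )


# -- sliding -----------------------------------------------------------------


def test_config_at_consensus_does_not_slide(tooth_template):
    base = tooth_template.semilandmarks
    configs = np.stack([base, base, base])
    slid, aligned, converged = morpho.slide_semilandmarks(
        configs, tooth_template, max_iter=2
    )
    assert converged
    assert np.linalg.norm(slid[0] - slid[1]) < 1e-10


def test_sliding_never_increases_bending_energy(tooth_template, rng):
    base = tooth_template.semilandmarks
    configs = base[None] + 0.01 * rng.standard_normal((6,) + base.shape)
    aligned0 = morpho.gpa_align(configs)
    B = bending_energy_matrix(aligned0.consensus)
    before = [
        bending_energy(B, aligned0.consensus, c) for c in aligned0.configs
    ]
    vn = np.asarray(tooth_template.mesh.vertex_normals)[
        tooth_template.semilandmark_indices
    ]
    normals = np.tile(vn[None], (6, 1, 1))
    from molarmap.morpho import _slide_one, _tangent_bases

    after = []
    for i in range(6):
        new = _slide_one(
            aligned0.configs[i], aligned0.consensus, B, _tangent_bases(normals[i])
        )
        after.append(bending_energy(B, aligned0.consensus, new))
    assert all(a <= b + 1e-10 for a, b in zip(after, before))


def test_single_landmark_slide_matches_grid_search(rng):
    """Closed-form tangent solution equals a dense 2D grid search."""
    from molarmap.morpho import _slide_one

    consensus = rng.standard_normal((20, 3))
    B = bending_energy_matrix(consensus)
    config = consensus.copy()
    config[7] += np.array([0.15, -0.1, 0.08])
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    tangents = np.zeros((20, 2, 3))
    tangents[7, 0] = u
    tangents[7, 1] = v

    new = _slide_one(config, consensus, B, tangents)
    e_closed = bending_energy(B, consensus, new)

    grid = np.linspace(-0.4, 0.4, 161)
    best = np.inf
    for t1 in grid:
        for t2 in grid:
            trial = config.copy()
            trial[7] += t1 * u + t2 * v
            e = bending_energy(B, consensus, trial)
            best = min(best, e)
    assert e_closed <= best + 1e-6


# -- PCA ---------------------------------------------------------------------


def _aligned_from_flat(X):
    n, m = X.shape
    k = m // 3
    return AlignedShapes(
        configs=X.reshape(n, k, 3),
        consensus=X.mean(axis=0).reshape(k, 3),
        centroid_sizes=np.ones(n),
    )


def test_rank_two_variation_gives_two_axes(rng):
    base = rng.standard_normal(30)
    d1, d2 = rng.standard_normal((2, 30))
    X = base[None] + np.outer(rng.standard_normal(25), d1) + np.outer(
        rng.standard_normal(25), d2
    )
    model = morpho.compute_pca(_aligned_from_flat(X))
    assert len(model.variance_pct) == 2


def test_retained_axis_count_matches_constructed_spectrum(rng):
    """A spectrum with exactly 18 axes above 1% retains 18 phenotypes."""
    shares = np.array(
        [18.9, 15.4, 9.9, 7.1, 5.9, 5.1, 3.9, 3.2, 2.8, 2.5, 2.1, 1.8,
         1.7, 1.5, 1.4, 1.3, 1.2, 1.0 + 1e-6] + [0.95] * 14
    )
    n, m = 40, len(shares)
    Z = np.linalg.qr(rng.standard_normal((n, m)))[0]
    Z -= Z.mean(axis=0)
    Z = np.linalg.qr(Z)[0]
    X = Z @ np.diag(np.sqrt(shares * (n - 1))) @ np.eye(m, 45)
    model = morpho.compute_pca(_aligned_from_flat(X))
    assert model.n_retained == 18


def test_scores_uncorrelated_and_reconstruction_exact(rng):
    X = rng.standard_normal((20, 27))
    model = morpho.compute_pca(_aligned_from_flat(X))
    corr = np.corrcoef(model.scores[:, 0], model.scores[:, 1])[0, 1]
    assert abs(corr) < 1e-10
    recon = X.mean(axis=0)[None] + model.scores @ model.eigenvectors
    np.testing.assert_allclose(recon, X, atol=1e-10)


def test_retain_threshold_out_of_range_raises(rng):
    X = rng.standard_normal((10, 9))
    with pytest.raises(ValueError, match="retain"):
        morpho.compute_pca(_aligned_from_flat(X), retain_threshold=0.0)


# -- age regression ----------------------------------------------------------


def test_self_regression_r2_one_on_pc1(rng):
    X = rng.standard_normal((30, 15))
    model = morpho.compute_pca(_aligned_from_flat(X))
    res = morpho.regress_shape_on_covariate(
        model.scores[:, :5], model.scores[:, 0], n_perm=200, seed=0
    )
    assert res["r2_per_pc"][0] == pytest.approx(1.0)
    assert np.all(np.abs(res["r2_per_pc"][1:]) < 1e-10)


def test_null_covariate_r2_matches_expectation(rng):
    """Independent covariate: E[r2] is about 1/(n-1)."""
    n = 60
    vals = []
    for rep in range(150):
        scores = rng.standard_normal((n, 4))
        cov = rng.standard_normal(n)
        res = morpho.regress_shape_on_covariate(scores, cov, n_perm=1, seed=rep)
        vals.append(res["r2"])
    assert np.mean(vals) == pytest.approx(1 / (n - 1), rel=0.2)


def test_injected_age_effect_recovered(rng):
    """An age effect built to explain 4.6% of a PC's variance is recovered."""
    n = 200
    age = rng.uniform(9, 12, n)
    agec = (age - age.mean()) / age.std()
    noise = rng.standard_normal(n)
    noise -= noise @ agec / (agec @ agec) * agec  # orthogonalize
    target = 0.046
    pc3 = np.sqrt(target) * agec + np.sqrt(1 - target) * noise / noise.std()
    scores = np.column_stack([rng.standard_normal((n, 2)), pc3])
    res = morpho.regress_shape_on_covariate(scores, age, n_perm=200, seed=1)
    assert res["r2_per_pc"][2] == pytest.approx(0.046, abs=0.005)


def test_constant_covariate_raises(rng):
    with pytest.raises(ValueError, match="constant"):
        morpho.regress_shape_on_covariate(
            rng.standard_normal((20, 3)), np.ones(20)
        )


# -- wear invariance ---------------------------------------------------------


def test_wear_free_template_is_wear_invariant(tooth_template, rng):
    """Same tooth worn to two depths: identical under the wear-free
    template, distinguishable under the complete template."""
    base = tooth_template.semilandmarks
    spec = base + 0.01 * rng.standard_normal(base.shape)
    zmax = spec[:, 2].max()
    worn_a = morpho.truncate_config(spec, zmax - 0.05)
    worn_b = morpho.truncate_config(spec, zmax - 0.12)
    cut = zmax - 0.15
    wf = morpho.build_wear_free_template(tooth_template, cut)
    pa = morpho.phenotype_config(wf, worn_a)
    pb = morpho.phenotype_config(wf, worn_b)
    assert morpho.procrustes_distance(pa, pb) < 1e-12
    ca = morpho.phenotype_config(tooth_template, worn_a)
    cb = morpho.phenotype_config(tooth_template, worn_b)
    assert morpho.procrustes_distance(ca, cb) > 1e-4


def test_landmark_csv_round_trip(tmp_path, rng):
    configs = rng.standard_normal((4, 7, 3))
    ids = [f"m{i}" for i in range(4)]
    morpho.write_landmark_csv(tmp_path / "lm.csv", configs, ids)
    back, back_ids = morpho.read_landmark_csv(tmp_path / "lm.csv")
    np.testing.assert_allclose(back, configs, atol=1e-12)
    assert back_ids == ids
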