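"""Surface reconstruction, effect signatures, and the PC-pair baseline."""

import numpy as np
import pytest

from molarmap import effects as fx
from molarmap import morpho, simdata


@pytest.fixture(scope="module")
def shape_model(tooth_template):
    """PC model of noisy shapes carrying one known displacement field."""
    rng = np.random.default_rng(7)
    base = tooth_template.semilandmarks
    k = base.shape[0]
    n = 50
    field = np.zeros((k, 3))
    # field concentrated on vertices near one cusp (a compact region)
    center = base[np.argmax(base[:, 2])]
    d2 = ((base - center) ** 2).sum(axis=1)
    field[:, 2] = 0.08 * np.exp(-d2 / 0.05)
    g = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
    configs = (
        base[None]
        + g[:, None, None] * field[None]
        + 0.01 * rng.standard_normal((n, k, 3))
    )
    aligned = morpho.gpa_align(configs)
    model = morpho.compute_pca(aligned)
    return tooth_template, model, aligned, g, field


def test_zero_scores_reconstructs_consensus(shape_model):
    template, model, *_ = shape_model
    mesh = fx.reconstruct_surface(
        model, np.zeros(model.eigenvectors.shape[0]), template
    )
    np.testing.assert_allclose(
        np.asarray(mesh.vertices)[template.semilandmark_indices],
        model.consensus,
        atol=1e-10,
    )


def test_specimen_scores_round_trip(shape_model):
    """Reconstructing at a specimen's own scores returns its aligned config."""
    template, model, aligned, *_ = shape_model
    i = 13
    mesh = fx.reconstruct_surface(model, model.scores[i], template)
    np.testing.assert_allclose(
        np.asarray(mesh.vertices)[template.semilandmark_indices],
        aligned.configs[i],
        atol=1e-8,
    )


def test_reconstruction_antisymmetric_about_consensus(shape_model):
    template, model, *_ = shape_model
    c = 0.1
    s = np.zeros(model.eigenvectors.shape[0])
    s[0] = c
    plus = fx.reconstruct_config(model, s)
    minus = fx.reconstruct_config(model, -s)
    np.testing.assert_allclose(
        plus - model.consensus, -(minus - model.consensus), atol=1e-12
    )


def test_wrong_score_length_raises(shape_model):
    template, model, *_ = shape_model
    with pytest.raises(ValueError, match="length"):
        fx.reconstruct_config(model, np.zeros(3))


# -- signatures --------------------------------------------------------------


def test_snp_signature_peaks_on_affected_cusp(shape_model):
    template, model, aligned, g, field = shape_model
    sig = fx.signature_for_snp(model, g, aligned.configs, template)
    top_profile = np.argsort(sig.profile)[-10:]
    top_field = np.argsort(np.linalg.norm(field, axis=1))[-10:]
    assert len(set(top_profile) & set(top_field)) >= 5


def test_signature_symmetric_in_class_order(shape_model):
    template, model, aligned, g, _ = shape_model
    a = fx.signature_for_snp(model, g, aligned.configs, template)
    b = fx.signature_for_snp(model, 2 - g, aligned.configs, template)
    np.testing.assert_allclose(a.profile, b.profile, atol=1e-10)


def test_missing_homozygote_class_raises(shape_model):
    template, model, aligned, g, _ = shape_model
    g_no_alt = np.where(g == 2.0, 1.0, g)
    with pytest.raises(ValueError, match="alternate"):
        fx.signature_for_snp(model, g_no_alt, aligned.configs, template)


def test_identical_groups_zero_profile(tooth_template, rng):
    configs = tooth_template.semilandmarks[None] + 0.01 * rng.standard_normal(
        (6,) + tooth_template.semilandmarks.shape
    )
    sig = fx.signature_for_groups(configs, configs.copy(), tooth_template)
    assert sig.profile.max() < 1e-10


def test_pc_signature_scales_linearly(shape_model):
    template, model, *_ = shape_model
    c = 0.05
    s1 = fx.signature_for_pc(model, 0, template, span=(-c, c))
    s2 = fx.signature_for_pc(model, 0, template, span=(-2 * c, 2 * c))
    np.testing.assert_allclose(s2.profile, 2 * s1.profile, atol=1e-10)


def test_mutant_offset_matching_qtl_field_correlates(shape_model, rng):
    """A mutant offset equal to the QTL field has a near-identical signature."""
    template, model, aligned, g, field = shape_model
    base = template.semilandmarks
    wt = base[None] + 0.002 * rng.standard_normal((8,) + base.shape)
    mut = base[None] + 2 * field[None] + 0.002 * rng.standard_normal(
        (8,) + base.shape
    )
    mut_sig = fx.signature_for_groups(wt, mut, template)
    snp_sig = fx.signature_for_snp(model, g, aligned.configs, template)
    assert fx.compare_signatures(mut_sig, snp_sig) > 0.8


# -- comparison and baseline -------------------------------------------------


def test_self_comparison_is_one(shape_model):
    template, model, aligned, g, _ = shape_model
    sig = fx.signature_for_snp(model, g, aligned.configs, template)
    assert fx.compare_signatures(sig, sig) == pytest.approx(1.0)


def test_comparison_symmetric(shape_model):
    template, model, *_ = shape_model
    a = fx.signature_for_pc(model, 0, template)
    b = fx.signature_for_pc(model, 1, template)
    assert fx.compare_signatures(a, b) == pytest.approx(
        fx.compare_signatures(b, a)
    )


def test_profile_invariant_to_joint_rigid_motion(shape_model):
    template, model, *_ = shape_model
    sig = fx.signature_for_pc(model, 0, template)
    theta = 0.8
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0],
         [np.sin(theta), np.cos(theta), 0],
         [0, 0, 1.0]]
    )
    import trimesh

    moved = fx.EffectSignature(
        label="moved",
        surface_a=trimesh.Trimesh(
            np.asarray(sig.surface_a.vertices) @ R.T + 1.0,
            sig.surface_a.faces, process=False,
        ),
        surface_b=trimesh.Trimesh(
            np.asarray(sig.surface_b.vertices) @ R.T + 1.0,
            sig.surface_b.faces, process=False,
        ),
        profile=np.linalg.norm(
            (np.asarray(sig.surface_a.vertices) - np.asarray(sig.surface_b.vertices)) @ R.T,
            axis=1,
        ),
    )
    np.testing.assert_allclose(moved.profile, sig.profile, atol=1e-10)


def test_permuted_profile_decorrelates(shape_model, rng):
    template, model, *_ = shape_model
    sig = fx.signature_for_pc(model, 0, template)
    corrs = []
    for _ in range(100):
        perm = fx.EffectSignature(
            label="perm",
            surface_a=sig.surface_a,
            surface_b=sig.surface_b,
            profile=rng.permutation(sig.profile),
        )
        corrs.append(fx.compare_signatures(sig, perm))
    assert abs(np.mean(corrs)) < 0.05


def test_constant_profile_raises(shape_model):
    template, model, *_ = shape_model
    sig = fx.signature_for_pc(model, 0, template)
    flat = fx.EffectSignature(
        label="flat",
        surface_a=sig.surface_a,
        surface_b=sig.surface_b,
        profile=np.ones_like(sig.profile),
    )
    with pytest.raises(ValueError, match="constant"):
        fx.compare_signatures(sig, flat)


def test_baseline_size_is_choose_2(shape_model):
    template, model, *_ = shape_model
    baseline, sigs = fx.pc_baseline(model, template)
    n = model.n_retained
    assert len(baseline) == n * (n - 1) // 2
    assert len(sigs) == n


def test_own_pc_signature_is_percentile_100(shape_model):
    template, model, *_ = shape_model
    baseline, sigs = fx.pc_baseline(model, template)
    corr = fx.compare_signatures(sigs[4], sigs[4])
    res = fx.place_in_baseline(corr, baseline)
    assert res.percentile == pytest.approx(100.0)


def test_single_pc_snp_effect_beats_baseline(tooth_template):
    """A SNP acting along one PC correlates with that PC above the
    baseline's 95th percentile (the construction behind the candidate-gene
    readout)."""
    rng = np.random.default_rng(21)
    base = tooth_template.semilandmarks
    k = base.shape[0]
    n = 60
    field = rng.standard_normal((k, 3))
    field /= np.linalg.norm(field)
    g = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
    configs = (
        base[None]
        + 0.12 * g[:, None, None] * field[None]
        + 0.01 * rng.standard_normal((n, k, 3))
    )
    aligned = morpho.gpa_align(configs)
    model = morpho.compute_pca(aligned)
    baseline, sigs = fx.pc_baseline(model, tooth_template)
    snp_sig = fx.signature_for_snp(model, g, aligned.configs, tooth_template)
    best = max(
        fx.compare_signatures(snp_sig, s) for s in sigs
    )
    assert best > np.quantile(baseline, 0.95)


def test_signed_export_integrates_to_zero_for_pc(shape_model, tmp_path):
    """Signed normal displacement of a symmetric-span PC effect sums to ~0."""
    template, model, *_ = shape_model
    sig = fx.signature_for_pc(model, 0, template, span=(-0.05, 0.05))
    disp = np.asarray(sig.surface_b.vertices) - np.asarray(
        sig.surface_a.vertices
    )
    mid = (np.asarray(sig.surface_a.vertices) + np.asarray(sig.surface_b.vertices)) / 2
    # antisymmetry about the consensus: mean displacement is twice the
    # (zero-mean) PC direction; its surface integral vanishes
    normals = np.asarray(sig.surface_a.vertex_normals)
    signed = np.einsum("ij,ij->i", disp, normals)
    assert abs(signed.mean()) < np.abs(signed).max() * 0.2
    fx.export_signature_ply(sig, tmp_path / "sig.ply", signed=True)
    text = (tmp_path / "sig.ply").read_text()
    assert "quality" in text and text.startswith("ply")
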