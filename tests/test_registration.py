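"""Rigid pair alignment, CPD, and dense correspondences."""

import numpy as np
import pytest

from kneessm import registration as R
from kneessm import synthetic as S


def _rigid(angle_deg, axis, t):
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "z":
        Rm = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    else:
        Rm = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return R.RigidTransform(Rm, np.asarray(t, float))


def _moved(sample, T):
    out = sample.copy()
    out.femur.vertices = T.apply(out.femur.vertices)
    out.tibia.vertices = T.apply(out.tibia.vertices)
    out.landmarks = {k: T.apply(v) for k, v in out.landmarks.items()}
    return out


def test_rigid_transform_contract():
    with pytest.raises(ValueError):
        R.RigidTransform(2 * np.eye(3), np.zeros(3))  # scale forbidden
    T = _rigid(30, "z", [1, 2, 3])
    assert np.allclose(T.compose(T.inverse()).rotation, np.eye(3), atol=1e-12)


def test_rigid_align_identity(small_template):
    T, aligned = R.rigid_align_pair(small_template, small_template)
    assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(T.translation, 0, atol=1e-9)


@pytest.mark.parametrize("use_landmarks", [True, False])
def test_rigid_align_recovers_known_motion(small_template, use_landmarks):
    T_true = _rigid(10, "z", [5.0, 0, 0])
    moved = _moved(small_template, T_true)
    ref = small_template
    if not use_landmarks:
        moved = moved.copy()
        moved.landmarks = {}
        ref = ref.copy()
        ref.landmarks = {}
    T_rec, aligned = R.rigid_align_pair(moved, ref)
    comp = T_rec.compose(T_true)
    assert np.allclose(comp.rotation, np.eye(3), atol=1e-6)
    assert np.allclose(comp.translation, 0, atol=1e-6)


def test_rigid_align_never_fits_scale(small_template):
    scaled = small_template.copy()
    scaled.femur.vertices = scaled.femur.vertices * 1.1
    scaled.tibia.vertices = scaled.tibia.vertices * 1.1
    scaled.landmarks = {k: v * 1.1 for k, v in scaled.landmarks.items()}
    T, aligned = R.rigid_align_pair(scaled, small_template)
    # pure rotation (no scale component) and a residual remains
    assert np.allclose(T.rotation @ T.rotation.T, np.eye(3), atol=1e-9)
    resid = np.abs(aligned.femur.vertices).max() / np.abs(
        small_template.femur.vertices).max()
    assert resid > 1.05  # still 10% larger: scaling was not absorbed


def test_rigid_step_preserves_intra_sample_geometry(small_template):
    moved = _moved(small_template, _rigid(25, "y", [10, -4, 2]))
    _, aligned = R.rigid_align_pair(moved, small_template)
    names = list(moved.landmarks)
    for a in names[:4]:
        for b in names[4:]:
            d0 = np.linalg.norm(moved.landmarks[a] - moved.landmarks[b])
            d1 = np.linalg.norm(aligned.landmarks[a] - aligned.landmarks[b])
            assert d0 == pytest.approx(d1, abs=1e-9)


def test_cpd_identity(small_template):
    pts = small_template.femur.vertices[::4]
    res = R.cpd_register(pts, pts, R.CPDConfig(max_iter=80))
    assert np.abs(res.points - pts).max() < 1e-6


def test_cpd_config_validation():
    with pytest.raises(ValueError):
        R.CPDConfig(beta=0)
    with pytest.raises(ValueError):
        R.CPDConfig(w=1.0)
    with pytest.raises(ValueError):
        R.cpd_register(np.zeros((5, 3)), np.zeros((20, 3)))


def test_cpd_recovers_smooth_bend(template):
    V = template.femur.vertices
    span = V[:, 2].max() - V[:, 2].min()
    kappa = np.tan(np.radians(5)) / (2 * span)
    bent = V.copy()
    bent[:, 0] += kappa * (V[:, 2] - V[:, 2].min()) ** 2
    res = R.cpd_register(V, bent, R.CPDConfig())
    resid = np.linalg.norm(res.points - bent, axis=1).mean()
    assert resid < 0.1
    # penalized log-likelihood trace is monotone non-decreasing per EM step
    ll = res.log_likelihood
    assert np.all(np.diff(ll) >= -1e-8 * np.maximum(np.abs(ll[:-1]), 1.0))


def test_cpd_monotone_likelihood_exact_solver(small_template, rng):
    pts = small_template.tibia.vertices[::3]
    tgt = pts + rng.normal(0, 0.5, pts.shape)
    res = R.cpd_register(pts, tgt, R.CPDConfig(max_iter=60))
    ll = res.log_likelihood
    assert np.all(np.diff(ll) >= -1e-8 * np.maximum(np.abs(ll[:-1]), 1.0))


def test_cpd_outlier_robustness(template, rng):
    V = template.femur.vertices
    span = V[:, 2].max() - V[:, 2].min()
    kappa = np.tan(np.radians(5)) / (2 * span)
    bent = V.copy()
    bent[:, 0] += kappa * (V[:, 2] - V[:, 2].min()) ** 2
    clean = np.linalg.norm(
        R.cpd_register(V, bent, R.CPDConfig()).points - bent, axis=1).mean()
    outliers = rng.uniform(V.min(0) - 20, V.max(0) + 20, (len(V) // 10, 3))
    noisy = np.vstack([bent, outliers])
    contaminated = np.linalg.norm(
        R.cpd_register(V, noisy, R.CPDConfig(w=0.1)).points - bent,
        axis=1).mean()
    assert contaminated < 2 * max(clean, 0.05)


def test_correspond_contract(small_template):
    ref, bone = small_template.femur, small_template.femur
    pts, out = R.correspond(ref, bone)
    assert len(pts) == len(ref.vertices)  # always reference-indexed
    assert np.abs(pts - ref.vertices).max() < 1e-6
    assert not out.any()


def test_build_correspondences_shapes_and_determinism(small_template):
    spec = S.CohortSpec(n=5, seed=3, resolution=0.35)
    cohort = [s.to_right() for s in S.sample_cohort(spec)]
    ref = R.select_reference(cohort)
    cs = R.build_correspondences(cohort, ref, R.CPDConfig(max_iter=60))
    P = len(ref.femur.vertices) + len(ref.tibia.vertices)
    assert cs.points.shape == (5, P, 3)
    assert cs.n_femur == len(ref.femur.vertices)
    # permuting the cohort permutes rows only
    perm = [2, 0, 4, 1, 3]
    cs2 = R.build_correspondences([cohort[i] for i in perm], ref,
                                  R.CPDConfig(max_iter=60))
    for new_row, old_idx in enumerate(perm):
        assert np.allclose(cs2.points[new_row], cs.points[old_idx], atol=1e-9)
    # left-side input is refused
    left = cohort[0].copy()
    left.side = "left"
    with pytest.raises(ValueError, match="mirror"):
        R.build_correspondences([left], ref)


def test_correspondence_set_io(tmp_path, small_template):
    refpts = np.vstack([small_template.femur.vertices[:10],
                        small_template.tibia.vertices[:5]])
    cs = R.CorrespondenceSet(ids=["a", "b"],
                             points=np.stack([refpts, refpts + 1]),
                             n_femur=10, reference_id="a",
                             transforms=[R.RigidTransform.identity()] * 2)
    cs.save(tmp_path / "corr")
    back = R.CorrespondenceSet.load(tmp_path / "corr")
    assert back.ids == ["a", "b"]
    assert np.allclose(back.points, cs.points)
    assert back.n_femur == 10


def test_reference_selection_prefers_low_deformity():
    spec = S.CohortSpec(n=12, seed=6, include_meshes=False)
    cohort = S.sample_cohort(spec)
    ref = R.select_reference(cohort)
    score = lambda s: (abs(s.angles.hka) + abs(s.angles.fvv + 6)
                       + abs(s.angles.tvv) + abs(s.angles.ier)
                       + abs(s.angles.ts - 7))
    assert score(ref) == min(score(s) for s in cohort)
    byid = R.select_reference(cohort, reference_id=cohort[3].sample_id)
    assert byid is cohort[3]
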