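"""Synthetic cohort generator: template, deformations, ground-truth angles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from kneessm import synthetic as S
from kneessm.angles import compute_angles
from kneessm.mesh import mirror_ml


def test_template_is_neutral(template):
    assert template.femur.is_watertight and template.tibia.is_watertight
    assert template.femur.volume > 0 and template.tibia.volume > 0
    ang = compute_angles(template.landmarks)
    assert ang.hka == pytest.approx(0.0, abs=1e-9)
    assert ang.tvv == pytest.approx(0.0, abs=1e-9)
    assert ang.ier == pytest.approx(0.0, abs=1e-9)
    assert ang.ts == pytest.approx(7.0, abs=1e-9)   # physiological slope
    assert ang.fvv == pytest.approx(-6.0, abs=1e-9)  # physiological valgum


def test_identity_params_reproduce_template(template):
    out = S.apply_params(template, S.NEUTRAL_PARAMS)
    assert np.allclose(out.femur.vertices, template.femur.vertices, atol=1e-9)
    assert np.allclose(out.tibia.vertices, template.tibia.vertices, atol=1e-9)
    for k in template.landmarks:
        assert np.allclose(out.landmarks[k], template.landmarks[k], atol=1e-9)


@pytest.mark.parametrize("field,angle,value", [
    ("rel_frontal_rot", "hka", 5.0),
    ("rel_axial_rot", "ier", 8.0),
    ("plateau_slope", "ts", 12.0),
    ("femoral_jointline_tilt", "fvv", -2.0),
    ("tibial_jointline_tilt", "tvv", 4.0),
])
def test_single_parameter_maps_to_its_angle(template, field, angle, value):
    p = dataclasses.replace(S.NEUTRAL_PARAMS, **{field: value})
    out = S.apply_params(template, p)
    got = compute_angles(out.landmarks)
    assert getattr(got, angle) == pytest.approx(value, abs=1e-6)
    # the other four stay at their neutral values
    for other in ("hka", "fvv", "tvv", "ier", "ts"):
        if other != angle:
            neutral = getattr(S.NEUTRAL_PARAMS.target_angles(), other)
            assert getattr(got, other) == pytest.approx(neutral, abs=1e-6)


def test_joint_deformity_round_trip(template):
    """All five angles recovered simultaneously, under shape deformations."""
    p = S.GenerativeParams(rel_frontal_rot=-9, rel_axial_rot=6, plateau_slope=13,
                           femoral_jointline_tilt=-3, tibial_jointline_tilt=-5,
                           femur_bend_frontal=3, tibia_bend_frontal=-2,
                           femur_shaft_len=36, global_scale=1.08)
    out = S.apply_params(template, p)
    got = compute_angles(out.landmarks).as_array()
    assert np.allclose(got, p.target_angles().as_array(), atol=1e-6)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        S.GenerativeParams(noise_sd=-1)
    with pytest.raises(ValueError):
        S.GenerativeParams(femur_shaft_len=50)  # outside crop range
    with pytest.raises(ValueError):
        S.GenerativeParams(global_scale=np.nan)
    with pytest.raises(ValueError):
        S.ParamDist(0.0, -1.0)


def test_cohort_seeded_determinism_and_size():
    spec = S.CohortSpec(n=10, seed=1, resolution=0.35)
    c1, c2 = S.sample_cohort(spec), S.sample_cohort(spec)
    assert len(c1) == 10
    for a, b in zip(c1, c2):
        assert np.array_equal(a.femur.vertices, b.femur.vertices)
        assert a.side == b.side
    with pytest.raises(ValueError):
        S.CohortSpec(n=2, seed=0)


def test_left_sample_mirrors_to_right_twin(small_template):
    base = {f: getattr(S.NEUTRAL_PARAMS, f) for f in
            ("rel_frontal_rot", "plateau_slope")}
    pl = dataclasses.replace(S.NEUTRAL_PARAMS, side="left", rel_frontal_rot=6.0,
                             noise_sd=0.3)
    pr = dataclasses.replace(pl, side="right")
    sl = S.apply_params(small_template, pl, rng=np.random.default_rng(9))
    sr = S.apply_params(small_template, pr, rng=np.random.default_rng(9))
    assert np.allclose(mirror_ml(sl.femur).vertices, sr.femur.vertices, atol=1e-9)
    assert np.allclose(mirror_ml(sl.tibia).vertices, sr.tibia.vertices, atol=1e-9)
    # and the right-converted left sample measures the recorded angles
    got = compute_angles(sl.to_right().landmarks).as_array()
    assert np.allclose(got, sl.angles.as_array(), atol=1e-6)


def test_round_trip_on_noise_free_cohort():
    """Measured angles equal the generative angles across a seeded cohort."""
    dists = dict(S.DEFAULT_DISTRIBUTIONS)
    dists["noise_sd"] = S.ParamDist(0.0, 0.0)
    spec = S.CohortSpec(n=30, seed=4, distributions=dists, include_meshes=False)
    for s in S.sample_cohort(spec):
        got = compute_angles(s.to_right().landmarks).as_array()
        assert np.allclose(got, s.angles.as_array(), atol=1e-6)


def test_unstable_fraction_matches_truncated_normal_tail():
    spec = S.CohortSpec(n=200, seed=2, include_meshes=False)
    cohort = S.sample_cohort(spec)
    frac = np.mean([abs(s.angles.hka) > 3 for s in cohort])
    d = S.DEFAULT_DISTRIBUTIONS["rel_frontal_rot"]
    lo, hi = d.bounds()
    tn = stats.truncnorm((lo - d.mean) / d.sd, (hi - d.mean) / d.sd,
                         loc=d.mean, scale=d.sd)
    analytic = 1.0 - (tn.cdf(3.0) - tn.cdf(-3.0))
    assert abs(frac - analytic) <= 0.07


def test_cohort_statistics_converge():
    """Empirical parameter means/SDs approach the specification at n=500."""
    spec = S.CohortSpec(n=500, seed=2, include_meshes=False)
    cohort = S.sample_cohort(spec)
    for name in ("rel_frontal_rot", "plateau_slope", "femur_shaft_len"):
        d = S.DEFAULT_DISTRIBUTIONS[name]
        vals = np.array([getattr(s.params, name) for s in cohort])
        lo, hi = d.bounds()
        tn = stats.truncnorm((lo - d.mean) / d.sd, (hi - d.mean) / d.sd,
                             loc=d.mean, scale=d.sd)
        se = tn.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - tn.mean()) <= 3 * se
        assert abs(vals.std(ddof=1) - tn.std()) <= 3 * tn.std() / np.sqrt(len(vals))


def test_cohort_io_round_trip(tmp_path):
    spec = S.CohortSpec(n=3, seed=5, resolution=0.35)
    cohort = S.sample_cohort(spec)
    S.write_cohort(cohort, tmp_path)
    assert len(list(tmp_path.glob("*.ply"))) == 6
    back = S.read_cohort(tmp_path)
    assert [s.sample_id for s in back] == [s.sample_id for s in cohort]
    for a, b in zip(cohort, back):
        assert np.allclose(a.femur.vertices, b.femur.vertices, atol=1e-5)
        assert np.allclose(a.angles.as_array(), b.angles.as_array())
        for k in a.landmarks:
            assert np.allclose(a.landmarks[k], b.landmarks[k])
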