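"""Wave scheduling, occlusion law, deformation and volume conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastroflow.geometry import build_geometry, tube_params
from gastroflow.motility import (
    ACWParams,
    MotilityError,
    MotilityModel,
    occlusion,
    periodic_onset,
)

TUBE_ACW = ACWParams(birth_arclength=8.0, life_span=30.0)


@pytest.fixture(scope="module")
def tube_motility(tube):
    return MotilityModel(tube, TUBE_ACW)


# -- wave bookkeeping -------------------------------------------------------


def test_one_wave_shortly_after_start(model):
    waves = model.active_waves(10.0)
    assert len(waves) == 1
    assert waves[0].age(10.0) == pytest.approx(10.0)


def test_three_waves_at_t45(model):
    ages = sorted(w.age(45.0) for w in model.active_waves(45.0))
    assert ages == pytest.approx([5.0, 25.0, 45.0])


def test_wave_count_alternates_in_periodic_regime(model):
    """Brute-force count over two cycles: 2 or 3 live waves after 38 s."""
    counts = {len(model.active_waves(t)) for t in np.arange(38.0, 78.0, 0.25)}
    assert counts == {2, 3}


def test_wave_center_translation(model):
    w = model.active_waves(10.0)[0]
    assert w.center_x(0.0) == pytest.approx(model.x_birth)
    assert w.center_x(10.0) == pytest.approx(model.x_birth + 2.3)
    xs = [w.center_x(t) for t in np.arange(0, 58, 1.0)]
    assert np.all(np.diff(xs) > 0)


# -- occlusion law ----------------------------------------------------------


@pytest.mark.parametrize(
    "age, expected",
    [(0.0, 0.0), (17.5, 0.40), (20.0, 0.40), (33.5, 0.40), (58.0, 0.80)],
)
def test_occlusion_profile_knots(age, expected):
    assert occlusion(age) == pytest.approx(expected, abs=1e-12)


def test_occlusion_terminal_ramp_midpoint():
    # linear between 40% at 33.5 s and 80% at 58 s
    assert occlusion(45.75) == pytest.approx(0.60, abs=1e-12)


def test_occlusion_outside_life_raises():
    with pytest.raises(MotilityError):
        occlusion(-1.0)
    with pytest.raises(MotilityError):
        occlusion(58.1)


@given(st.floats(0.0, 58.0), st.floats(0.0, 58.0))
@settings(max_examples=50, deadline=None)
def test_occlusion_monotone_nondecreasing(a, b):
    lo, hi = sorted((a, b))
    assert occlusion(hi) >= occlusion(lo) - 1e-12


# -- deformation ------------------------------------------------------------


def test_rest_state_at_t0(model):
    assert np.allclose(model.radii(0.0), model.rest_radii, atol=1e-12)


def test_disjoint_waves_deform_disjoint_sections(model):
    """At t=45 the three waves' supports are disjoint; sections outside all
    supports keep their rest radius (before the tonic term)."""
    t = 45.0
    r = model.wave_deformed_radii(t)
    supports = []
    for w in model.active_waves(t):
        s_w = model.wave_arclength(w, t)
        supports.append((s_w - 1.0, s_w + 1.0))
    supports.sort()
    assert all(supports[i][1] < supports[i + 1][0] for i in range(len(supports) - 1))
    outside = np.ones_like(model.s, bool)
    for lo, hi in supports:
        outside &= (model.s < lo - 1e-9) | (model.s > hi + 1e-9)
    assert np.allclose(r[outside], model.rest_radii[outside], atol=1e-12)


def test_peak_occlusion_narrows_lumen_by_stated_fraction(tube):
    """A wave at 40% occlusion leaves a 60%-width lumen at its peak."""
    m = MotilityModel(tube, TUBE_ACW)
    t = 17.5  # end of the initial ramp: occlusion 0.40
    w = m.active_waves(t)[0]
    s_w = m.wave_arclength(w, t)
    k = int(np.argmin(np.abs(m.s - s_w)))
    bump = np.cos(np.pi * (m.s[k] - s_w) / 2.0) ** 2
    expected = 1.0 - 0.40 * bump
    assert m.wave_deformed_radii(t)[k] / m.rest_radii[k] == pytest.approx(expected, rel=1e-9)


def test_wave_slides_off_pylorus_smoothly(model):
    """The indentation vanishes before the wave's life ends: the wall does
    not jump when the oldest wave expires at t = 58 s."""
    eps = 1e-4
    r_before = model.wave_deformed_radii(58.0 - eps)
    r_after = model.wave_deformed_radii(58.0 + eps)
    assert np.abs(r_before - r_after).max() < 1e-3


# -- tonic contraction / volume conservation --------------------------------


def test_fundus_scale_zero_without_waves(stomach):
    quiet = ACWParams(occlusion_knots=((0.0, 0.0), (58.0, 0.0)))
    m = MotilityModel(stomach, quiet)
    assert m.fundus_scale(25.0) == 0.0


def test_volume_conserved_and_scale_bounded(model):
    for t in np.linspace(40.0, 60.0, 9):
        state = model.deform(t)
        assert abs(state.volume * 1000 - model.rest_volume) / model.rest_volume < 1e-6
        assert abs(state.fundus_fraction) <= 0.08


def test_fundus_scale_matches_bisection_oracle(model):
    """200-iteration bisection oracle agrees with the root solve to 1e-4."""
    t = 50.0
    r_wave = model.wave_deformed_radii(t)
    w = model.tonic.profile(model.s)

    def residual(f):
        return model._volume(r_wave * (1 + f * w)) - model.rest_volume

    lo, hi = -0.08, 0.08
    for _ in range(200):
        mid = (lo + hi) / 2
        if residual(lo) * residual(mid) <= 0:
            hi = mid
        else:
            lo = mid
    assert model.fundus_scale(t) == pytest.approx((lo + hi) / 2, abs=1e-4)


# -- wall velocity ----------------------------------------------------------


def test_wall_velocity_zero_without_motion(stomach):
    quiet = ACWParams(occlusion_knots=((0.0, 0.0), (58.0, 0.0)))
    m = MotilityModel(stomach, quiet)
    assert np.abs(m.wall_velocity(10.0)).max() < 1e-12


def test_wall_velocity_richardson(model):
    """Central differences at dt and dt/10 agree to first order."""
    v1 = model.wall_velocity(45.0, dt=1e-3)
    v2 = model.wall_velocity(45.0, dt=1e-4)
    scale = np.abs(v2).max()
    assert np.abs(v1 - v2).max() < 0.02 * scale + 1e-9


# -- curvature-wise wave speeds --------------------------------------------


def test_tube_wave_speed_matches_horizontal_speed(tube_motility):
    for branch in ("greater", "lesser"):
        sp = tube_motility.curve_speed(branch)
        assert sp["mean"] == pytest.approx(2.3, rel=0.01)


def test_greater_faster_than_lesser(model):
    assert model.curve_speed("greater")["mean"] > model.curve_speed("lesser")["mean"]


# -- periodicity ------------------------------------------------------------


def test_periodic_onset_formula():
    assert periodic_onset() == pytest.approx(38.0)
    assert periodic_onset(ACWParams(life_span=30.0, birth_interval=20.0)) == pytest.approx(10.0)


def test_wall_state_repeats_each_cycle(model):
    """Direct state comparison: radii at t and t+20 coincide for t >= 38."""
    for t in np.arange(38.0, 58.0, 2.5):
        d = np.abs(model.radii(t) - model.radii(t + 20.0)).max()
        assert d < 1e-9


def test_invalid_params_rejected():
    with pytest.raises(MotilityError):
        ACWParams(life_span=10.0, birth_interval=20.0)
    with pytest.raises(MotilityError):
        ACWParams(occlusion_knots=((0.0, 0.0), (58.0, 0.9)))
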