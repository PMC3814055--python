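"""Two-compartment kinetics: rates, fraction kills, evolution, full courses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorlq import (
    CellState,
    DomainError,
    Fraction,
    KineticParams,
    RadiosensitivityParams,
    TreatmentSchedule,
    VolumeSeries,
    apply_fraction,
    decay_rate,
    evolve_interval,
    expand_regimen,
    growth_rate,
    simulate_course,
    state_at,
    survival_fraction,
)


@pytest.mark.parametrize(
    "t_pot, expected",
    [
        (5.5, 0.12602676010180824),   # lung potential doubling time
        (4.5, 0.15403270679109896),   # cervix potential doubling time
        (math.log(2.0), 1.0),
    ],
)
def test_growth_rate(t_pot, expected):
    assert growth_rate(KineticParams(t_pot=t_pot, t_half=30.0)) == pytest.approx(
        expected, rel=1e-12
    )


@pytest.mark.parametrize(
    "t_half, expected",
    [
        (42.5, 0.016309345424939888),
        (13.9, 0.04986670363740613),
        (math.log(2.0), 1.0),
    ],
)
def test_decay_rate(t_half, expected):
    assert decay_rate(KineticParams(t_pot=5.0, t_half=t_half)) == pytest.approx(
        expected, rel=1e-12
    )


@pytest.mark.parametrize("kwargs", [{"t_pot": 0.0}, {"t_pot": -1.0}, {"t_half": 0.0}])
def test_invalid_kinetics_rejected(kwargs):
    with pytest.raises(DomainError):
        KineticParams(**{"t_pot": 5.0, "t_half": 30.0, **kwargs})


class TestApplyFraction:
    def test_moves_killed_cells_to_dead_pool(self):
        out = apply_fraction(CellState(100.0, 0.0), 0.2)
        assert out.n_viable == pytest.approx(20.0)
        assert out.n_dead == pytest.approx(80.0)

    def test_nothing_to_kill(self):
        out = apply_fraction(CellState(0.0, 5.0), 0.5)
        assert (out.n_viable, out.n_dead) == (0.0, 5.0)

    def test_unit_survival_is_identity(self):
        state = CellState(3.7, 1.2)
        out = apply_fraction(state, 1.0)
        assert (out.n_viable, out.n_dead) == (state.n_viable, state.n_dead)

    def test_nonpositive_survival_rejected(self):
        with pytest.raises(DomainError):
            apply_fraction(CellState(1.0, 0.0), 0.0)

    @given(
        nv=st.floats(0.0, 1e6),
        nd=st.floats(0.0, 1e6),
        s=st.floats(1e-12, 1.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_total_conserved(self, nv, nd, s):
        """Irradiation relabels cells; it never changes the total count."""
        state = CellState(nv, nd)
        out = apply_fraction(state, s)
        assert out.total == pytest.approx(state.total, rel=1e-12, abs=1e-300)


class TestEvolveInterval:
    def test_zero_interval_is_identity(self, lung_kinetics):
        state = CellState(2.0, 3.0)
        out = evolve_interval(state, lung_kinetics, 0.0)
        assert (out.n_viable, out.n_dead) == (2.0, 3.0)

    def test_one_doubling_time_doubles_viable(self):
        kin = KineticParams(t_pot=5.5, t_half=10.0)
        out = evolve_interval(CellState(1.0, 1.0), kin, 5.5)
        assert out.n_viable == pytest.approx(2.0, rel=1e-12)

    def test_three_halvings_of_dead_pool(self):
        kin = KineticParams(t_pot=5.5, t_half=10.0)
        out = evolve_interval(CellState(0.0, 8.0), kin, 30.0)
        assert out.n_dead == pytest.approx(1.0, rel=1e-12)

    def test_negative_interval_rejected(self, lung_kinetics):
        with pytest.raises(DomainError):
            evolve_interval(CellState(1.0, 0.0), lung_kinetics, -1.0)


class TestSchedule:
    def test_times_must_strictly_increase(self):
        with pytest.raises(DomainError):
            TreatmentSchedule.from_arrays([0.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_doses_must_be_positive(self):
        with pytest.raises(DomainError):
            TreatmentSchedule.from_arrays([0.0, 1.0], [2.0, 0.0])

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            TreatmentSchedule((Fraction(-1.0, 2.0),))

    def test_expand_regimen_weekday_pattern(self):
        sched = expand_regimen(n_fractions=25, dose_gy=2.0, fractions_per_week=5)
        assert len(sched) == 25
        assert list(sched.times[:7]) == [0.0, 1.0, 2.0, 3.0, 4.0, 7.0, 8.0]
        assert sched.times[-1] == 32.0
        assert np.all(sched.doses == 2.0)

    def test_expand_regimen_validates(self):
        with pytest.raises(DomainError):
            expand_regimen(n_fractions=0)
        with pytest.raises(DomainError):
            expand_regimen(fractions_per_week=8)


class TestVolumeSeries:
    def test_rejects_nonpositive_volume(self):
        with pytest.raises(DomainError):
            VolumeSeries(times=np.array([0.0, 1.0]), volumes=np.array([1.0, 0.0]))

    def test_rejects_decreasing_times(self):
        with pytest.raises(DomainError):
            VolumeSeries(times=np.array([1.0, 0.0]), volumes=np.array([1.0, 1.0]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(DomainError):
            VolumeSeries(times=np.array([0.0]), volumes=np.array([1.0, 2.0]))


def _uniform_closed_form(v0, s, lam, mu, dt, k):
    """Independent geometric closed form for k fractions at spacing dt.

    Evaluated immediately after fraction k (at t = (k-1)*dt), with the
    course starting all-viable at the first fraction:

      viable = S^k * exp(lam*(k-1)*dt)
      dead   = (1-S) * sum_{j=1}^{k} S^(j-1) e^{lam*(j-1)dt} e^{-mu*(k-j)dt}
             = (1-S) e^{-mu*(k-1)dt} * (r^k - 1)/(r - 1),  r = S e^{(lam+mu)dt}
    """
    viable = s**k * math.exp(lam * (k - 1) * dt)
    r = s * math.exp((lam + mu) * dt)
    if abs(r - 1.0) < 1e-12:
        geom = float(k)
    else:
        geom = (r**k - 1.0) / (r - 1.0)
    dead = (1.0 - s) * math.exp(-mu * (k - 1) * dt) * geom
    return v0 * (viable + dead)


def test_uniform_schedule_matches_closed_form(default_radio):
    """The recursion reproduces the geometric-sum solution for 1..30 fractions."""
    kin = KineticParams(t_pot=5.5, t_half=20.0)
    dt, dose, v0 = 1.0, 2.0, 50.0
    s = survival_fraction(default_radio, dose)
    lam, mu = growth_rate(kin), decay_rate(kin)
    for k in range(1, 31):
        sched = TreatmentSchedule.from_arrays(
            dt * np.arange(k), np.full(k, dose)
        )
        sim = simulate_course(v0, sched, default_radio, kin, [dt * (k - 1)])
        expected = _uniform_closed_form(v0, s, lam, mu, dt, k)
        assert sim.volumes[0] == pytest.approx(expected, rel=1e-10)


def test_no_fractions_is_pure_exponential_growth(default_radio, lung_kinetics):
    empty = TreatmentSchedule(())
    times = np.array([0.0, 3.0, 10.0, 25.0])
    sim = simulate_course(80.0, empty, default_radio, lung_kinetics, times)
    expected = 80.0 * np.exp(growth_rate(lung_kinetics) * times)
    np.testing.assert_allclose(sim.volumes, expected, rtol=1e-12)


def test_unit_survival_course_is_pure_growth(standard_course, lung_kinetics):
    """When every fraction kills nothing the course is exponential regrowth."""
    # event count underflows to ~0 so S = 1 exactly per fraction
    radio = RadiosensitivityParams(alpha=0.0, beta=1e-320, corr_a=1.0, corr_b=0.0)
    times = np.array([0.0, 10.0, 32.0, 60.0])
    sim = simulate_course(10.0, standard_course, radio, lung_kinetics, times)
    expected = 10.0 * np.exp(growth_rate(lung_kinetics) * times)
    np.testing.assert_allclose(sim.volumes, expected, rtol=1e-12)


def test_resume_equals_single_run(default_radio, lung_kinetics, standard_course):
    """Semigroup property: stop at t', resume from the saved state."""
    v0 = 120.0
    times = np.array([0.0, 5.0, 17.0, 23.0, 33.0, 50.0])
    one_shot = simulate_course(v0, standard_course, default_radio, lung_kinetics, times)
    t_mid = 17.0
    mid_state = state_at(standard_course, default_radio, lung_kinetics, t_mid)
    tail = times[times >= t_mid]
    resumed = simulate_course(
        v0, standard_course, default_radio, lung_kinetics, tail,
        initial_state=mid_state, t_start=t_mid,
    )
    np.testing.assert_allclose(
        resumed.volumes, one_shot.volumes[times >= t_mid], rtol=1e-12
    )


def test_post_fraction_convention(default_radio, lung_kinetics):
    """At a fraction time the reported state is the post-kill one."""
    sched = TreatmentSchedule.from_arrays([5.0], [2.0])
    s = survival_fraction(default_radio, 2.0)
    state = state_at(sched, default_radio, lung_kinetics, 5.0)
    grown = math.exp(growth_rate(lung_kinetics) * 5.0)
    assert state.n_viable == pytest.approx(grown * s, rel=1e-12)
    assert state.n_dead == pytest.approx(grown * (1.0 - s), rel=1e-12)
    # total count (hence volume) is continuous across the instant
    assert state.total == pytest.approx(grown, rel=1e-12)


def test_final_volume_monotone_in_corr_a(standard_course, lung_kinetics):
    """Stronger kill (larger A) can only shrink the post-course volume."""
    vols = []
    for a in [0.1, 0.3, 0.6, 1.0, 1.5, 2.0]:
        radio = RadiosensitivityParams(0.35, 0.035, corr_a=a, corr_b=-0.5)
        sim = simulate_course(100.0, standard_course, radio, lung_kinetics, [45.0])
        vols.append(sim.volumes[0])
    assert all(b <= a for a, b in zip(vols, vols[1:]))


def test_volumes_always_positive(rng, lung_kinetics):
    for _ in range(50):
        n = int(rng.integers(1, 30))
        times = np.sort(rng.uniform(0.0, 40.0, n))
        times += np.arange(n) * 1e-3  # enforce strict increase
        doses = rng.uniform(0.5, 8.0, n)
        sched = TreatmentSchedule.from_arrays(times, doses)
        radio = RadiosensitivityParams(
            0.35, 0.035, corr_a=float(rng.uniform(0.05, 2.5)),
            corr_b=float(rng.uniform(-4.0, 0.0)),
        )
        eval_times = np.sort(rng.uniform(0.0, 80.0, 6))
        sim = simulate_course(50.0, sched, radio, lung_kinetics, eval_times)
        assert np.all(sim.volumes > 0.0)


def test_eval_before_origin_rejected(default_radio, lung_kinetics, standard_course):
    with pytest.raises(DomainError):
        simulate_course(10.0, standard_course, default_radio, lung_kinetics, [-1.0, 5.0])


def test_nonpositive_v0_rejected(default_radio, lung_kinetics, standard_course):
    with pytest.raises(DomainError):
        simulate_course(0.0, standard_course, default_radio, lung_kinetics, [0.0])
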