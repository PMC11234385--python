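"""Integration, period/limit-cycle extraction, orbit geometry, fates."""

import numpy as np
import pytest

from orbitempo.dynamics import (
    Orbit,
    Trajectory,
    detect_fate,
    estimate_period,
    find_limit_cycle,
    find_steady_state,
    integrate,
    normalize_orbit,
    orbit_from_points,
    resample_arclength,
    time_factor,
)
from orbitempo.errors import (
    DegenerateOrbitError,
    IntegrationError,
    NotOscillatoryError,
)
from orbitempo.metrics import frechet_distance
from orbitempo.models import GRNModel, apply_scalar_prefactor
from orbitempo.parameters import ParameterSet


def _linear_decay():
    return GRNModel("decay", ("x",), lambda x, t: -x,
                    ParameterSet("decay", {"k": 1.0}))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_integrate_linear_decay_matches_closed_form():
    traj = integrate(_linear_decay(), [1.0], (0.0, 1.0), rtol=1e-10, atol=1e-12)
    assert traj.terminal_state()[0] == pytest.approx(np.exp(-1.0), rel=1e-8)


def test_integrate_convergence_under_tolerance_refinement(neural_model, neural_x0):
    coarse = integrate(neural_model, neural_x0, (0, 40), rtol=1e-6, atol=1e-9)
    fine = integrate(neural_model, neural_x0, (0, 40), rtol=5e-7, atol=1e-9)
    assert np.max(np.abs(coarse.terminal_state() - fine.terminal_state())) < 1e-5


def test_integrate_rejects_bad_inputs():
    model = _linear_decay()
    with pytest.raises(IntegrationError):
        integrate(model, [-1.0], (0, 1))
    with pytest.raises(IntegrationError):
        integrate(model, [1.0], (1, 1))


def test_trajectory_invariants_enforced():
    with pytest.raises(ValueError):
        Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros((3, 1)))
    with pytest.raises(ValueError):
        Trajectory(np.array([0.0, 1.0]), np.array([[0.0], [np.nan]]))


def test_find_steady_state_agrees_with_root_oracle(bistable_model):
    from scipy.optimize import fsolve

    state = find_steady_state(bistable_model, [1.4, 0.1], tol=1e-9)
    root = fsolve(lambda x: bistable_model.rate_fn(x, 0.0), state, xtol=1e-13)
    assert np.allclose(state, root, atol=1e-6)
    # an exact fixed point is returned unchanged (to solver precision)
    again = find_steady_state(bistable_model, state, tol=1e-8)
    assert np.allclose(again, state, atol=1e-8)


def test_find_steady_state_flags_oscillators(reduced_model, reduced_x0):
    from orbitempo.errors import NonConvergenceError

    with pytest.raises(NonConvergenceError):
        find_steady_state(reduced_model, reduced_x0, tol=1e-10, max_time=400.0)


# ---------------------------------------------------------------------------
# periods
# ---------------------------------------------------------------------------

def test_estimate_period_on_sine_is_exact_and_matches_fft():
    T = 7.3
    t = np.linspace(0, 40 * T, 20000)
    traj = Trajectory(t, (1.0 + np.sin(2 * np.pi * t / T))[:, None])
    est = estimate_period(traj)
    assert est.period == pytest.approx(T, rel=1e-3)
    assert est.cv < 1e-6
    # FFT dominant-peak oracle
    x = traj.component(0) - traj.component(0).mean()
    freqs = np.fft.rfftfreq(len(t), t[1] - t[0])
    peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
    assert est.period == pytest.approx(1.0 / peak, rel=0.02)


def test_estimate_period_rejects_constant_trajectory():
    t = np.linspace(0, 10, 100)
    with pytest.raises(NotOscillatoryError):
        estimate_period(Trajectory(t, np.ones((100, 1))))


def test_estimate_period_warns_on_irregular_cycles():
    t = np.linspace(0, 100, 20000)
    # chirped signal: strongly drifting inter-crossing intervals
    x = np.sin(2 * np.pi * t ** 1.5 / 40)
    with pytest.warns(UserWarning, match="CV"):
        estimate_period(Trajectory(t, 1 + x[:, None]))


# ---------------------------------------------------------------------------
# limit cycle
# ---------------------------------------------------------------------------

def test_limit_cycle_is_closed_and_periodic(reduced_cycle):
    orbit, per = reduced_cycle
    assert orbit.closed
    assert per.cv < 1e-4
    assert np.linalg.norm(orbit.points[0] - orbit.points[-1]) < 1e-6 * orbit.length


def test_limit_cycle_period_invariant_to_section_choice(reduced_model, reduced_x0,
                                                        reduced_cycle):
    orbit, per = reduced_cycle
    orbit2, per2 = find_limit_cycle(reduced_model, reduced_x0, section_species=4,
                                    period_guess=per.period, n_points=500)
    assert per2.period == pytest.approx(per.period, rel=5e-3)
    from orbitempo.dynamics import align_cycle_start, resample_arclength

    aligned = resample_arclength(align_cycle_start(orbit2, orbit), 500)
    d = frechet_distance(normalize_orbit(orbit), normalize_orbit(aligned),
                         closed=True, compute_alignment=False)
    assert d.value < 1e-3


def test_symmetric_reduced_repressilator_proteins_are_phase_shifted():
    """With identical genes the three proteins repeat each other at T/3 lags."""
    from orbitempo.models import (build_repressilator_reduced,
                                  default_initial_state,
                                  default_repressilator_reduced_params)

    params = default_repressilator_reduced_params().with_updates(
        r_1=25.0, r_2=25.0, r_3=25.0)
    model = build_repressilator_reduced(params)
    x0 = default_initial_state(model)
    _, per = find_limit_cycle(model, x0, period_guess=222.0)
    T = per.period
    traj = integrate(model, x0, (0, 20 * T),
                     t_eval=np.linspace(15 * T, 20 * T, 6000))
    t = traj.times
    keep = t <= t[0] + 3 * T
    # firing order follows the repression ring backwards: 1 -> 3 -> 2
    p1 = np.interp(t[keep], t, traj.component(3))
    p3_shifted = np.interp(t[keep] + T / 3, t, traj.component(5))
    p2_shifted = np.interp(t[keep] + 2 * T / 3, t, traj.component(4))
    amp = p1.max() - p1.min()
    assert np.max(np.abs(p1 - p3_shifted)) < 0.05 * amp
    assert np.max(np.abs(p1 - p2_shifted)) < 0.05 * amp


def test_scalar_prefactor_halves_period_preserves_orbit(reduced_model, reduced_x0,
                                                        reduced_cycle):
    orbit_ref, per_ref = reduced_cycle
    fast = apply_scalar_prefactor(reduced_model, 2.0)
    orbit2, per2 = find_limit_cycle(fast, reduced_x0,
                                    period_guess=per_ref.period / 2,
                                    n_points=500)
    assert per2.period / per_ref.period == pytest.approx(0.5, rel=0.01)
    d = frechet_distance(normalize_orbit(orbit_ref), normalize_orbit(orbit2),
                         closed=True, compute_alignment=False)
    assert d.value < 1e-3


def test_limit_cycle_requires_oscillation(bistable_model):
    with pytest.raises(NotOscillatoryError):
        find_limit_cycle(bistable_model, [1.5, 0.5], period_guess=10.0,
                         total_periods=10, transient_periods=2)


# ---------------------------------------------------------------------------
# orbit geometry
# ---------------------------------------------------------------------------

def test_resample_straight_segment_uniform_spacing():
    pts = np.stack([np.linspace(0, 1, 40) ** 2, np.zeros(40)], axis=1)
    orbit = resample_arclength(orbit_from_points(pts), 9)
    assert np.allclose(orbit.points[:, 0], np.linspace(0, 1, 9), atol=1e-12)


def test_resample_nonuniform_circle_gives_uniform_spacing():
    u = np.sort(np.random.default_rng(0).uniform(0, 2 * np.pi, 400))
    pts = np.stack([np.cos(u), np.sin(u)], axis=1)
    orbit = resample_arclength(orbit_from_points(pts), 100)
    spacing = np.linalg.norm(np.diff(orbit.points, axis=0), axis=1)
    assert spacing.std() / spacing.mean() < 0.01


def test_resample_is_idempotent():
    rng = np.random.default_rng(7)
    orbit = resample_arclength(orbit_from_points(rng.normal(size=(50, 3))), 64)
    again = resample_arclength(orbit, 64)
    assert np.allclose(orbit.points, again.points, atol=1e-9)


def test_resample_validates_inputs():
    seg = orbit_from_points([[0.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValueError):
        resample_arclength(seg, 4)
    with pytest.raises(DegenerateOrbitError):
        orbit_from_points([[1.0, 1.0], [1.0, 1.0]])


def test_resampled_arclength_converges(reduced_cycle):
    orbit, _ = reduced_cycle
    L1 = resample_arclength(orbit, 500).length
    L2 = resample_arclength(orbit, 1000).length
    assert abs(L2 - L1) / L1 < 0.005


def test_normalize_orbit_scale_invariance_and_modes():
    rng = np.random.default_rng(3)
    pts = np.abs(rng.normal(size=(30, 2))) + 0.1
    orbit = orbit_from_points(pts)
    scaled = orbit_from_points(pts * np.array([10.0, 1.0]))
    a = normalize_orbit(orbit)
    b = normalize_orbit(scaled)
    assert np.allclose(a.points, b.points, atol=1e-12)
    # idempotence
    assert np.allclose(normalize_orbit(a).points, a.points, atol=1e-12)
    # reference mode differs from own mode by the ratio of maxima
    ref = orbit_from_points(2.0 * pts)
    c = normalize_orbit(orbit, mode="reference", reference=ref)
    assert np.allclose(c.points, a.points / 2.0, atol=1e-12)


def test_normalize_orbit_flags_zero_range_species():
    orbit = orbit_from_points([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
    normed = normalize_orbit(orbit)
    assert normed.meta["zero_range_species"] == [0]


# ---------------------------------------------------------------------------
# fates and event timing
# ---------------------------------------------------------------------------

def _terminal_traj(terminal):
    t = np.linspace(0, 1, 10)
    states = np.tile(np.asarray(terminal, dtype=float), (10, 1))
    return Trajectory(t, states)


NT = ["Pax6", "Olig2", "Nkx22", "Irx3"]


@pytest.mark.parametrize("terminal,expected", [
    ([0.01, 0.02, 0.9, 0.01], "V3"),
    ([0.1, 0.8, 0.05, 0.1], "MN"),
    ([0.9, 0.0, 0.0, 0.2], "progenitor"),
    ([0.9, 0.0, 0.0, 0.89], "progenitor"),   # Pax6/Irx3 tie stays progenitor
    ([0.5, 0.49, 0.1, 0.1], "ambiguous"),    # cross-fate tie
])
def test_detect_fate_terminal_winner_convention(terminal, expected):
    assert detect_fate(_terminal_traj(terminal), NT) == expected


def test_time_factor_identity_and_rescaling(neural_model, neural_x0,
                                            neural_reference):
    assert time_factor(neural_reference, neural_reference) == pytest.approx(1.0)
    slowed = apply_scalar_prefactor(neural_model, 0.5)
    traj = integrate(slowed, neural_x0, (0, 160))
    assert time_factor(neural_reference, traj) == pytest.approx(2.0, rel=1e-6)


def test_time_factor_unreached_event_is_infinite(neural_reference):
    stuck = _terminal_traj([1.0, 0.0, 0.0, 1.0])
    assert time_factor(neural_reference, stuck) == np.inf
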