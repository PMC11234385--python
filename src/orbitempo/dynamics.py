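"""Numerical integration and geometric post-processing of GRN models.

Separates the two faces of a genetic programme: the *trajectory* (timed
states, carrying tempo) and the *orbit* (the time-free curve traced in
gene-expression space, carrying function).  Orbits are arc-length
parameterised so that curves from systems with different tempos can be
compared point-for-point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (
    DegenerateOrbitError,
    IntegrationError,
    NonConvergenceError,
    NotOscillatoryError,
)
from .models import GRNModel

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_ORBIT_POINTS = 500


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered solution of a model: ``states[k]`` at ``times[k]``."""

    times: np.ndarray
    states: np.ndarray
    model_id: str = ""
    dense: object = None  # scipy OdeSolution, when available

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states, dtype=float)
        if x.ndim != 2 or x.shape[0] != t.shape[0]:
            raise ValueError("states must be (len(times), n_species)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ValueError("trajectory contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    def terminal_state(self) -> np.ndarray:
        return self.states[-1]

    def component(self, index: int) -> np.ndarray:
        return self.states[:, index]

    def window(self, t_min: float, t_max: float = np.inf) -> "Trajectory":
        mask = (self.times >= t_min) & (self.times <= t_max)
        return Trajectory(self.times[mask], self.states[mask],
                          self.model_id, self.dense)

    def value_at(self, t):
        """Interpolated state at time(s) t (dense solution if available)."""
        if self.dense is not None:
            return np.atleast_1d(self.dense(t)).T if np.ndim(t) else self.dense(t)
        t_arr = np.atleast_1d(t)
        out = np.stack([np.interp(t_arr, self.times, self.states[:, j])
                        for j in range(self.n_species)], axis=1)
        return out if np.ndim(t) else out[0]


@dataclass(frozen=True)
class Orbit:
    """Arc-length parameterised curve in gene-expression state space."""

    points: np.ndarray
    cumulative_arclength: np.ndarray
    closed: bool = False
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        al = np.asarray(self.cumulative_arclength, dtype=float)
        if pts.ndim != 2 or al.shape != (pts.shape[0],):
            raise ValueError("points (n, d) and arclength (n,) must align")
        if al[0] != 0 or np.any(np.diff(al) < 0):
            raise ValueError("cumulative arclength must start at 0 and be non-decreasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cumulative_arclength", al)

    @property
    def length(self) -> float:
        return float(self.cumulative_arclength[-1])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    def project(self, columns: Sequence[int]) -> "Orbit":
        """Restrict to a subset of species (arc length recomputed)."""
        pts = self.points[:, list(columns)]
        return orbit_from_points(pts, closed=self.closed,
                                 normalized=self.normalized, meta=dict(self.meta))


def _dedupe(points: np.ndarray, tol: float = 0.0) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], steps > tol])
    return points[keep]


def orbit_from_points(points, closed: bool = False, normalized: bool = False,
                      meta: Optional[dict] = None) -> Orbit:
    """Build an orbit from ordered state vectors (consecutive duplicates dropped)."""
    pts = _dedupe(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise DegenerateOrbitError("orbit needs at least two distinct points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    al = np.concatenate([[0.0], np.cumsum(seg)])
    return Orbit(pts, al, closed=closed, normalized=normalized, meta=meta or {})


def orbit_from_trajectory(traj: Trajectory, closed: bool = False) -> Orbit:
    return orbit_from_points(traj.states, closed=closed)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(model: GRNModel, x0, t_span, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, t_eval=None, method: str = "LSODA",
              dense_output: bool = True, max_points: int = 20000) -> Trajectory:
    """Integrate a model with a stiff-capable adaptive solver.

    Concentrations are kept non-negative at tolerance level: values more
    negative than ``-10 * atol`` raise, smaller undershoots are clipped.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise IntegrationError("initial state must be non-negative")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not np.isfinite(t1 - t0) or t1 <= t0:
        raise IntegrationError(f"invalid time span {t_span}")
    if t_eval is None:
        t_eval = np.linspace(t0, t1, max_points)
    sol = solve_ivp(lambda t, y: model.rate_fn(y, t), (t0, t1), x0,
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval,
                    dense_output=dense_output)
    if not sol.success:
        raise IntegrationError(f"solver failed for {model.name!r}: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise IntegrationError(f"non-finite states produced by {model.name!r}")
    floor = -10.0 * max(atol, 1e-12) * max(1.0, float(np.max(np.abs(states))))
    if np.min(states) < floor:
        raise IntegrationError(
            f"{model.name!r} produced negative concentrations "
            f"(min {np.min(states):.3e})"
        )
    states = np.maximum(states, 0.0)
    return Trajectory(sol.t, states, model_id=model.name,
                      dense=sol.sol if dense_output else None)


def find_steady_state(model: GRNModel, x0, tol: float = 1e-8,
                      max_time: float = 1e5, chunk: float = 50.0,
                      rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> np.ndarray:
    """Integrate until the rate norm stays below ``tol``; return the state.

    Raises :class:`NonConvergenceError` if no convergence within
    ``max_time`` (the caller may treat that as oscillatory behaviour).
    """
    state = np.asarray(x0, dtype=float)
    t_done, span = 0.0, float(chunk)
    while t_done < max_time:
        span = min(span, max_time - t_done)
        traj = integrate(model, state, (0.0, span), rtol=rtol, atol=atol,
                         t_eval=np.linspace(0, span, 64), dense_output=False)
        state = traj.terminal_state()
        # sustained window: rate small both at the end and mid-chunk
        mid = traj.states[len(traj.states) // 2]
        scale = max(1.0, float(np.max(np.abs(state))))
        if (np.linalg.norm(model.rates(state)) < tol * scale
                and np.linalg.norm(model.rates(mid)) < 10 * tol * scale):
            return state
        t_done += span
        span *= 2.0
    raise NonConvergenceError(
        f"{model.name!r}: no steady state within t={max_time} (tol={tol})"
    )


# ---------------------------------------------------------------------------
# periods and limit cycles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodEstimate:
    """Mean inter-crossing interval with its dispersion across cycles."""

    period: float
    cv: float
    n_cycles: int

    def __float__(self):
        return float(self.period)


def _upward_crossings(t: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    idx = np.where((x[:-1] < level) & (x[1:] >= level))[0]
    if idx.size == 0:
        return np.array([])
    frac = (level - x[idx]) / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _refined_crossings(traj: Trajectory, species: int, level: float) -> np.ndarray:
    """Upward crossing times, refined on the dense solution when present."""
    coarse = _upward_crossings(traj.times, traj.component(species), level)
    if traj.dense is None or coarse.size == 0:
        return coarse
    dt = np.median(np.diff(traj.times))
    refined = []
    for tc in coarse:
        a, b = tc - dt, tc + dt
        fa = traj.dense(a)[species] - level
        fb = traj.dense(b)[species] - level
        if fa < 0 <= fb:
            refined.append(brentq(lambda s: traj.dense(s)[species] - level, a, b,
                                  xtol=1e-12 * max(1.0, abs(tc))))
        else:
            refined.append(tc)
    return np.asarray(refined)


def estimate_period(traj: Trajectory, species: int = 0, min_cycles: int = 5,
                    min_relative_amplitude: float = 1e-3) -> PeriodEstimate:
    """Period as the mean inter-crossing interval of a Poincare level.

    The section level is the species mean over the trailing half of the
    trajectory.  The oscillation amplitude must exceed
    ``min_relative_amplitude`` times the species' magnitude — solver noise
    around a fixed point does not count as oscillation.  A coefficient of
    variation above 5% across cycles raises a warning (possible
    non-periodicity).
    """
    x = traj.component(species)
    tail = slice(len(x) // 2, None)
    level = float(np.mean(x[tail]))
    spread = float(np.max(x[tail]) - np.min(x[tail]))
    scale = max(float(np.max(np.abs(x[tail]))), 1e-30)
    if spread <= min_relative_amplitude * scale:
        raise NotOscillatoryError(
            f"amplitude {spread:.2e} below {min_relative_amplitude:.0e} of the "
            f"species magnitude {scale:.2e}; treating as non-oscillatory"
        )
    crossings = _refined_crossings(traj, species, level)
    if crossings.size < min_cycles + 1:
        raise NotOscillatoryError(
            f"only {crossings.size} section crossings; need {min_cycles + 1}"
        )
    intervals = np.diff(crossings)
    period = float(np.mean(intervals))
    cv = float(np.std(intervals) / period)
    if cv > 0.05:
        warnings.warn(f"period estimate CV = {cv:.1%} (> 5%): possible "
                      "non-periodicity", stacklevel=2)
    return PeriodEstimate(period, cv, int(intervals.size))


def find_limit_cycle(model: GRNModel, x0, transient_periods: float = 20.0,
                     total_periods: float = 40.0, section_species: Optional[int] = None,
                     n_points: int = DEFAULT_ORBIT_POINTS, period_guess: Optional[float] = None,
                     rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                     method: str = "LSODA"):
    """Extract one closed orbit and the oscillation period.

    The transient is discarded; one cycle is taken between successive
    upward crossings of a Poincare section (default: the first protein-like
    species through its post-transient mean) and resampled to ``n_points``
    arc-length-uniform points.

    Returns
    -------
    (Orbit, PeriodEstimate)
    """
    x0 = np.asarray(x0, dtype=float)
    if section_species is None:
        # prefer a protein species when the layout is known
        names = model.species_names
        section_species = next((j for j, n in enumerate(names)
                                if n.startswith("p") and not n.startswith("pi")), 0)

    if period_guess is None:
        period_guess = _pilot_period(model, x0, section_species, rtol, atol, method)

    t_end = total_periods * period_guess
    n_eval = max(4000, int(40 * total_periods))
    traj = integrate(model, x0, (0.0, t_end), rtol=rtol, atol=atol,
                     t_eval=np.linspace(0, t_end, n_eval), method=method)
    tail = traj.window(transient_periods * period_guess)
    est = estimate_period(tail, species=section_species, min_cycles=3)

    level = float(np.mean(tail.component(section_species)))
    crossings = _refined_crossings(tail, section_species, level)
    if crossings.size < 3:
        raise NotOscillatoryError("fewer than 3 section crossings after transient")
    t_a, t_b = crossings[-2], crossings[-1]
    ts = np.linspace(t_a, t_b, max(4 * n_points, 512))
    cycle = (tail.dense(ts).T if tail.dense is not None
             else tail.window(t_a, t_b).states)
    # force exact closure: the two crossings bracket one period
    cycle = np.vstack([cycle, cycle[0]])
    orbit = orbit_from_points(cycle, closed=True)
    gap = np.linalg.norm(orbit.points[0] - orbit.points[-1])
    if gap > 1e-6 * max(orbit.length, 1e-30):
        raise NotOscillatoryError(
            f"extracted cycle does not close (gap {gap:.2e} vs length {orbit.length:.2e})"
        )
    return resample_arclength(orbit, n_points), est


def _pilot_period(model, x0, species, rtol, atol, method, t_start: float = 50.0,
                  max_doublings: int = 8) -> float:
    """Bootstrap a period guess by integrating until crossings appear."""
    t_end = t_start
    for _ in range(max_doublings):
        traj = integrate(model, x0, (0.0, t_end), rtol=rtol, atol=atol,
                         t_eval=np.linspace(0, t_end, 4000), dense_output=False)
        tail = traj.window(t_end / 2)
        x = tail.component(species)
        level = float(np.mean(x))
        if np.max(x) - np.min(x) > 1e-3 * max(float(np.max(np.abs(x))), 1e-30):
            crossings = _upward_crossings(tail.times, x, level)
            if crossings.size >= 4:
                return float(np.mean(np.diff(crossings)))
        t_end *= 4.0
    raise NotOscillatoryError(
        f"{model.name!r}: no sustained oscillation detected up to t={t_end}"
    )


# ---------------------------------------------------------------------------
# orbit geometry
# ---------------------------------------------------------------------------

def resample_arclength(orbit: Orbit, n_points: int = DEFAULT_ORBIT_POINTS) -> Orbit:
    """Resample to points equally spaced in cumulative Euclidean arc length."""
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    if orbit.length <= 0:
        raise DegenerateOrbitError("cannot resample a zero-length orbit")
    targets = np.linspace(0.0, orbit.length, n_points)
    pts = np.stack([np.interp(targets, orbit.cumulative_arclength, orbit.points[:, j])
                    for j in range(orbit.dimension)], axis=1)
    return Orbit(pts, targets, closed=orbit.closed, normalized=orbit.normalized,
                 meta=dict(orbit.meta))


def align_cycle_start(orbit: Orbit, reference: Orbit) -> Orbit:
    """Re-cut a closed orbit so it starts at the point nearest the
    reference's start point.

    Two extractions of the same limit cycle through different Poincaré
    sections sample the curve on staggered arc-length grids; the discrete
    Fréchet distance between them is then floored by half the grid spacing
    however similar the curves are.  Re-cutting (with exact projection onto
    the polyline segments) removes the stagger so that residual distances
    reflect genuine orbit differences.
    """
    if not orbit.closed:
        raise ValueError("align_cycle_start requires a closed orbit")
    pts = orbit.points
    if np.array_equal(pts[0], pts[-1]) and len(pts) > 2:
        pts = pts[:-1]
    target = reference.points[0]
    a, b = pts, np.roll(pts, -1, axis=0)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom > 0, denom, 1.0)
    t = np.clip(np.einsum("ij,ij->i", target - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    k = int(np.argmin(np.linalg.norm(proj - target, axis=1)))
    start = proj[k]
    rolled = np.vstack([start, pts[k + 1:], pts[: k + 1], start])
    return orbit_from_points(rolled, closed=True, normalized=orbit.normalized,
                             meta=dict(orbit.meta))


def normalize_orbit(orbit: Orbit, mode: str = "own",
                    reference: Optional[Orbit] = None) -> Orbit:
    """Divide each species by its maximum along the orbit (or a reference).

    ``mode="own"`` uses the orbit's own per-species maxima;
    ``mode="reference"`` uses the maxima of *reference*.  Species with zero
    range are left unscaled and recorded in ``meta["zero_range_species"]``.
    """
    if mode not in ("own", "reference"):
        raise ValueError(f"mode must be 'own' or 'reference', got {mode!r}")
    if mode == "reference":
        if reference is None:
            raise ValueError("mode='reference' requires a reference orbit")
        maxima = np.max(np.abs(reference.points), axis=0)
    else:
        maxima = np.max(np.abs(orbit.points), axis=0)
    zero = maxima <= 0
    safe = np.where(zero, 1.0, maxima)
    meta = dict(orbit.meta)
    if np.any(zero):
        meta["zero_range_species"] = [int(j) for j in np.where(zero)[0]]
    pts = orbit.points / safe
    return orbit_from_points(pts, closed=orbit.closed, normalized=True, meta=meta)


# ---------------------------------------------------------------------------
# fates and event timing
# ---------------------------------------------------------------------------

#: terminal-winner labels for the neural tube convention
NEURAL_TUBE_FATES = {"Pax6": "progenitor", "Irx3": "progenitor",
                     "Olig2": "MN", "Nkx22": "V3"}


def detect_fate(traj: Trajectory, species_labels: Sequence[str],
                fate_map: Optional[dict] = None, tie_tol: float = 0.05) -> str:
    """Label a converged trajectory by its maximal terminal species.

    With the neural tube convention: Nkx2-2 -> ``"V3"``, Olig2 -> ``"MN"``,
    Pax6 or Irx3 (including a Pax6/Irx3 tie) -> ``"progenitor"``.  Any
    other tie within ``tie_tol`` (relative) is ``"ambiguous"``.
    """
    fate_map = fate_map if fate_map is not None else NEURAL_TUBE_FATES
    terminal = traj.terminal_state()
    order = np.argsort(terminal)[::-1]
    top, second = order[0], order[1] if len(order) > 1 else order[0]
    top_label = species_labels[top]
    if len(order) > 1 and terminal[top] > 0:
        rel_gap = (terminal[top] - terminal[second]) / terminal[top]
        if rel_gap < tie_tol:
            labels = {fate_map.get(species_labels[top], species_labels[top]),
                      fate_map.get(species_labels[second], species_labels[second])}
            if labels == {"progenitor"}:
                return "progenitor"
            return "ambiguous"
    return fate_map.get(top_label, top_label)


def time_factor(traj_ref: Trajectory, traj_pert: Trajectory,
                species: int = 2, level_fraction: float = 0.5) -> float:
    """Ratio of event times: perturbed over reference.

    The default event is the given species (Nkx2-2 in the neural tube
    layout) first crossing ``level_fraction`` of the *reference*
    trajectory's terminal level, upward.  Returns ``inf`` when the
    perturbed system never reaches the event (fate failure).
    """
    level = level_fraction * float(traj_ref.terminal_state()[species])
    t_ref = _first_crossing(traj_ref, species, level)
    if not np.isfinite(t_ref):
        raise NonConvergenceError("reference trajectory never reaches the event")
    t_pert = _first_crossing(traj_pert, species, level)
    if not np.isfinite(t_pert):
        return np.inf
    return float(t_pert / t_ref)


def _first_crossing(traj: Trajectory, species: int, level: float) -> float:
    crossings = _refined_crossings(traj, species, level)
    return float(crossings[0]) if crossings.size else np.inf
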