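"""Orbit similarity measures and tempo functionals.

Orbital distance compares the time-free curves of two systems; the
discrete Fréchet distance (a bottleneck measure: the shortest leash
linking a walker on each curve) is the primary choice, with dynamic time
warping (aggregate) and Hausdorff (set-based lower bound) as alternatives.
Tempo along an orbit is the harmonic mean of the local prefactor, written
as a ratio of line integrals; the allochrony deviation measures how far a
tempo field is from a single global (constant) tempo change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.spatial.distance import cdist

from ._frechet import _dtw_dp, _frechet_closed_scan, _frechet_dp_shift, frechet_witness
from .dynamics import Orbit
from .errors import DomainError

ArrayLike = Union[np.ndarray, "Orbit"]


@dataclass(frozen=True)
class OrbitalDistanceResult:
    """Distance between two orbits plus the witness of how it was attained."""

    value: float
    method: str
    alignment: Optional[list] = None
    cyclic_shift: Optional[int] = None
    reversed_b: bool = False

    def __float__(self):
        return float(self.value)


@dataclass(frozen=True)
class TempoResult:
    """Harmonic-mean tempo of a prefactor field along an orbit."""

    mean_tempo: float
    orbit_length: float
    allochrony_deviation: float

    def __float__(self):
        return float(self.mean_tempo)


def _points(curve: ArrayLike) -> np.ndarray:
    pts = curve.points if isinstance(curve, Orbit) else np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise DomainError("curve must be a non-empty (n, d) point array")
    return pts


def _point_pair(a: ArrayLike, b: ArrayLike):
    pa, pb = _points(a), _points(b)
    if pa.shape[1] != pb.shape[1]:
        raise DomainError(
            f"dimension mismatch: {pa.shape[1]} vs {pb.shape[1]}"
        )
    return pa, pb


def _infer_closed(a, b, closed):
    if closed is not None:
        return bool(closed)
    if isinstance(a, Orbit) and isinstance(b, Orbit):
        return a.closed and b.closed
    return False


def frechet_distance(orbit_a: ArrayLike, orbit_b: ArrayLike,
                     closed: Optional[bool] = None,
                     compute_alignment: bool = True) -> OrbitalDistanceResult:
    """Discrete Fréchet distance between two resampled curves.

    For ``closed=True`` the distance is minimised over all cyclic
    re-indexings of the second curve's start point, in both traversal
    directions, so that the value does not depend on where the Poincaré
    section happened to cut each cycle.  When orbits are passed and
    ``closed`` is None, both orbits being closed enables the cyclic search.

    The witness coupling (monotone index pairs) of the optimal alignment is
    returned unless ``compute_alignment=False``.
    """
    pa, pb = _point_pair(orbit_a, orbit_b)
    closed = _infer_closed(orbit_a, orbit_b, closed)
    if closed:
        # drop duplicated endpoint so cyclic shifts act on distinct points
        if np.array_equal(pa[0], pa[-1]) and len(pa) > 2:
            pa = pa[:-1]
        if np.array_equal(pb[0], pb[-1]) and len(pb) > 2:
            pb = pb[:-1]
    C = cdist(pa, pb)
    if not closed:
        value = float(_frechet_dp_shift(C, 0))
        alignment = frechet_witness(C, 0) if compute_alignment else None
        return OrbitalDistanceResult(value, "frechet", alignment=alignment)

    # Hausdorff is a lower bound: once reached, no shift can improve on it
    incumbent = float(_frechet_dp_shift(C, 0))
    best, best_shift = _frechet_closed_scan(C, incumbent)
    best_rev = False
    Cr = C[:, ::-1].copy()
    inc_r = float(_frechet_dp_shift(Cr, 0))
    if inc_r < best:
        best, best_shift, best_rev = inc_r, 0, True
    rev_best, rev_shift = _frechet_closed_scan(Cr, best)
    if rev_best < best:
        best, best_shift, best_rev = rev_best, rev_shift, True
    if best_shift < 0:
        best_shift = 0
    alignment = None
    if compute_alignment:
        Cw = Cr if best_rev else C
        alignment = frechet_witness(Cw, best_shift)
        if best_rev:  # map reversed indices back to the original order
            m = C.shape[1]
            alignment = [(i, (m - 1 - j)) for i, j in alignment]
    return OrbitalDistanceResult(float(best), "frechet", alignment=alignment,
                                 cyclic_shift=int(best_shift), reversed_b=best_rev)


def dtw_distance(orbit_a: ArrayLike, orbit_b: ArrayLike) -> OrbitalDistanceResult:
    """Dynamic time warping with Euclidean local cost (aggregate measure)."""
    pa, pb = _point_pair(orbit_a, orbit_b)
    C = cdist(pa, pb)
    return OrbitalDistanceResult(float(_dtw_dp(C)), "dtw")


def hausdorff_distance(orbit_a: ArrayLike, orbit_b: ArrayLike) -> OrbitalDistanceResult:
    """Symmetric Hausdorff distance on the two point sets.

    Order-free, hence a lower bound for the Fréchet distance; used mainly
    as an independent cross-check.
    """
    pa, pb = _point_pair(orbit_a, orbit_b)
    C = cdist(pa, pb)
    d_ab = float(np.max(np.min(C, axis=1)))
    d_ba = float(np.max(np.min(C, axis=0)))
    return OrbitalDistanceResult(max(d_ab, d_ba), "hausdorff")


# ---------------------------------------------------------------------------
# tempo along an orbit
# ---------------------------------------------------------------------------

def _segment_midpoint_field(orbit: Orbit, mu_field) -> tuple:
    """Evaluate mu at segment midpoints; return (segment lengths, mu values)."""
    pts = orbit.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = seg > 0
    mids = 0.5 * (pts[:-1] + pts[1:])[keep]
    seg = seg[keep]
    if callable(mu_field):
        mu = np.array([float(mu_field(m)) for m in mids])
    else:
        raise DomainError("mu_field must be callable state -> positive scalar")
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        raise DomainError("prefactor field must be strictly positive along the orbit")
    return seg, mu


def tempo_harmonic_mean(orbit: Orbit, mu_field: Callable) -> TempoResult:
    """Relative tempo of a process: harmonic mean of mu along its orbit.

    Discretising the orbit into segments of length ``dl_k`` with prefactor
    ``mu_k`` at midpoints, the mean tempo is ``L / sum(dl_k / mu_k)`` — the
    ratio of line integrals that reduces to ``c`` for a constant prefactor
    ``c`` and is bounded by the extremes of mu along the orbit.
    """
    seg, mu = _segment_midpoint_field(orbit, mu_field)
    L = float(np.sum(seg))
    if L <= 0:
        raise DomainError("orbit has zero length")
    mean_tempo = L / float(np.sum(seg / mu))
    return TempoResult(mean_tempo, L, _allochrony(seg, mu))


def _allochrony(seg, mu) -> float:
    mean = float(np.sum(seg * mu) / np.sum(seg))
    var = float(np.sum(seg * (mu - mean) ** 2) / np.sum(seg))
    return float(np.sqrt(var) / mean)


def allochrony_deviation(orbit: Orbit, mu_field: Callable) -> float:
    """How far a tempo field is from a single global tempo change.

    The arc-length-weighted root-mean-square deviation of mu from its
    arc-length mean, normalised by that mean (dimensionless).  Zero iff mu
    is constant along the orbit (pure allochrony); positive for
    state-dependent (heterochronic) tempo fields.
    """
    seg, mu = _segment_midpoint_field(orbit, mu_field)
    return _allochrony(seg, mu)
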