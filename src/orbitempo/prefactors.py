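"""Per-gene prefactor fields, heterogeneity D_sigma, and molecular predictors.

A model with a declared decomposition ``f = mu * g`` exposes, at every
state, the per-species tempo factors ``mu_i`` and the base-rate components
``g_i`` that shape the orbit.  Heterogeneity of the ``mu_i`` across species
— weighted by how much each species is actually moving — measures how far
a perturbation is from a pure (orbit-preserving) tempo change; its maximum
along an orbit, D_sigma, predicts the orbital (Fréchet) distance a
perturbation will induce without integrating the perturbed system.

For the repressilator, the composed dimer-flux parameters ``r_i`` feed the
prefactor exclusively, so their mean and spread act as purely molecular
predictors of tempo and orbit deformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import Orbit
from .errors import DomainError, ParameterError
from .metrics import TempoResult, tempo_harmonic_mean
from .models import GRNModel
from .parameters import GENES, ParameterSet


@dataclass(frozen=True)
class PrefactorField:
    """Per-species prefactors and velocity weights at one state."""

    mu: np.ndarray
    weights: np.ndarray
    state: np.ndarray
    weights_defined: bool = True


@dataclass(frozen=True)
class HeterogeneityProfile:
    """D_sigma evaluated along an orbit."""

    values: np.ndarray            # D_sigma at every orbit point (NaN if undefined)
    arclength: np.ndarray
    max_value: float              # the orbital prefactor heterogeneity distance
    argmax_arclength: float


def prefactor_components(model: GRNModel, state,
                         reference: Optional[GRNModel] = None) -> PrefactorField:
    """Evaluate ``mu_i`` and velocity weights at a state.

    Weights are the normalised magnitudes of the velocity components,
    ``w_i = |f_i| / sum_j |f_j|``: heterogeneity only matters for species
    that are actually moving at this state.  If *reference* is given (a
    model sharing the same base rates), ``mu`` is the ratio
    ``mu_model / mu_reference`` — the prefactor of the perturbation itself
    — and the weights come from the reference system's velocity.
    """
    x = np.asarray(state, dtype=float)
    mu, base = model.prefactor(x)
    if reference is not None:
        mu_ref, base = reference.prefactor(x)
        velocity = mu_ref * base
        mu = mu / mu_ref
    else:
        velocity = mu * base
    if np.any(mu <= 0) or np.any(~np.isfinite(mu)):
        raise DomainError("prefactor components must be strictly positive")
    denom = float(np.sum(np.abs(velocity)))
    if denom <= 0:
        return PrefactorField(mu, np.full_like(mu, np.nan), x, weights_defined=False)
    return PrefactorField(mu, np.abs(velocity) / denom, x)


def weighted_heterogeneity(field: PrefactorField, weighted_mean: bool = True,
                           relative: bool = False) -> float:
    """D_sigma at one state: sqrt of the weighted variance of the mu_i.

    ``D_sigma^2 = sum_i w_i (mu_i - mu_bar)^2`` with ``mu_bar`` the
    weighted mean of the components (set ``weighted_mean=False`` for the
    unweighted mean).  Zero when all moving species share one prefactor; a
    component attached to a stationary species (zero weight) cannot
    contribute.  With ``relative=True`` the result is divided by
    ``mu_bar`` (a coefficient of variation), making it invariant under a
    uniform tempo scaling of all components — the scale-free form used
    when comparing against the r-heterogeneity predictor.  Returns NaN
    when the weights are undefined (zero velocity).
    """
    if not field.weights_defined:
        return float("nan")
    w, mu = field.weights, field.mu
    mean = float(np.sum(w * mu)) if weighted_mean else float(np.mean(mu))
    dsigma = float(np.sqrt(np.sum(w * (mu - mean) ** 2)))
    return dsigma / mean if relative else dsigma


def orbital_heterogeneity(orbit: Orbit, model: GRNModel,
                          reference: Optional[GRNModel] = None,
                          weighted_mean: bool = True,
                          relative: bool = False) -> HeterogeneityProfile:
    """D_sigma along an orbit and its maximum (the heterogeneity distance).

    Points with undefined weights (zero velocity) are recorded as NaN and
    excluded from the maximum.  For a perturbation expressible as a scalar
    prefactor at every state the profile is identically zero.
    """
    values = np.empty(orbit.n_points)
    for k, point in enumerate(orbit.points):
        field = prefactor_components(model, point, reference=reference)
        values[k] = weighted_heterogeneity(field, weighted_mean=weighted_mean,
                                           relative=relative)
    finite = np.isfinite(values)
    if not np.any(finite):
        raise DomainError("D_sigma undefined at every orbit point")
    idx = int(np.nanargmax(np.where(finite, values, -np.inf)))
    return HeterogeneityProfile(values, orbit.cumulative_arclength.copy(),
                                float(values[idx]),
                                float(orbit.cumulative_arclength[idx]))


def mean_prefactor(orbit: Orbit, model: GRNModel,
                   reference: Optional[GRNModel] = None) -> TempoResult:
    """Arc-length harmonic mean of the velocity-weighted average prefactor.

    At each orbit point the per-species ``mu_i`` are collapsed to their
    velocity-weighted average; the harmonic mean of that scalar field along
    the orbit is the effective tempo of the system (relative to its base
    rates, or to *reference* when given).
    """
    def mu_scalar(state):
        field = prefactor_components(model, state, reference=reference)
        if not field.weights_defined:
            # zero-velocity point: fall back to the unweighted average
            return float(np.mean(field.mu))
        return float(np.sum(field.weights * field.mu))

    return tempo_harmonic_mean(orbit, mu_scalar)


# ---------------------------------------------------------------------------
# molecular predictors from composed dimerisation rates
# ---------------------------------------------------------------------------

def r_statistics(params: ParameterSet) -> tuple:
    """Mean and heterogeneity of the composed dimer-flux parameters r_i.

    ``r_mean`` is the arithmetic mean of ``(r_1, r_2, r_3)``;
    ``r_heterogeneity`` their population standard deviation divided by the
    mean (coefficient of variation), which is invariant under the pure
    tempo scaling used by the design procedure.  Accepts composed or full
    (24-rate) parameter sets.
    """
    if params.model == "repressilator_full":
        from .models import compose_rates

        params = compose_rates(params)
    try:
        r = np.array([params.gene("r", i) for i in GENES])
    except KeyError as exc:
        raise ParameterError(f"missing composed parameter: {exc}")
    if np.any(r <= 0):
        raise ParameterError("composed parameters r_i must be positive")
    r_mean = float(np.mean(r))
    r_het = float(np.std(r) / r_mean)
    return r_mean, r_het


def predictor_fit(table, x_column: str, y_column: str) -> dict:
    """Least-squares line and Pearson correlation between two sweep columns.

    Rows with non-finite values in either column are dropped; at least 20
    finite pairs are required for a meaningful fit.
    """
    x = np.asarray(table[x_column], dtype=float)
    y = np.asarray(table[y_column], dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 20:
        raise DomainError(
            f"need >= 20 finite records for a fit, got {x.size}"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("degenerate variance: cannot fit predictor")
    slope, intercept = np.polyfit(x, y, 1)
    corr = float(np.corrcoef(x, y)[0, 1])
    return {"slope": float(slope), "intercept": float(intercept),
            "pearson_r": corr, "n": int(x.size),
            "x": x_column, "y": y_column}
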