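"""Built-in gene regulatory network ODE models and prefactor transformations.

The central object is :class:`GRNModel`: an autonomous ODE system
``dx/dt = f(x, t)`` over named biochemical species.  Models that arise from a
quasi-steady-state reduction additionally declare a *prefactor
decomposition*: a factorisation ``f(x, t) = mu(x, t) * g(x, t)``
(element-wise) separating the state-dependent tempo factor ``mu_i`` from the
base rates ``g_i`` that shape the orbit.  Two systems related by a strictly
positive *scalar* prefactor share identical orbits (they are orbitally
equivalent) and differ only in tempo; per-species (vector) prefactors may
deform the orbit.

Built-in models
---------------
``bistable``
    Two mutually repressing genes with Hill kinetics; two attracting states.
``neural_tube``
    Four-gene ventral neural tube network (Pax6, Olig2, Nkx2-2, Irx3) with
    cross-repression and Shh activation; produces the progenitor ->
    transient Olig2 -> Nkx2-2 (V3) cascade under high Shh.
``repressilator_full``
    Three-gene cyclic repressor with explicit mRNA, protein monomer,
    protein dimer and promoter occupancy (12 variables, 24 rates).
``repressilator_reduced``
    Six-variable reduction (mRNA + protein per gene) obtained by treating
    the distribution of protein between monomer, free dimer and
    promoter-bound dimer as fast; intermediate steps appear as a prefactor
    ``mu_i(p_i)`` on the protein equation.
``repressilator_qssa``
    Three-variable protein-only model after additionally removing fast
    mRNA; ``mu_i`` multiplies a Hill-type base rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import DomainError, ParameterError, SchemaError
from .parameters import (
    GENES,
    ParameterSet,
    per_gene,
    validate_full_repressilator,
    validate_reduced_repressilator,
)

RateFn = Callable[[np.ndarray, float], np.ndarray]
Decomposition = Callable[[np.ndarray, float], tuple]

# cyclic index helpers (1-based gene labels, 0-based arrays):
# the dimer of gene i silences the promoter of gene i+1, hence the
# promoter of gene i is repressed by the dimer of gene i-1.
_PREV = np.array([2, 0, 1])
_NEXT = np.array([1, 2, 0])


@dataclass(frozen=True)
class GRNModel:
    """An N-species autonomous ODE model of a gene regulatory network.

    Attributes
    ----------
    name:
        Registry name (used for CLI lookup and file metadata).
    species_names:
        Ordered species labels; defines the state-vector layout.
    rate_fn:
        ``f(x, t) -> dx/dt`` with ``len(dx) == n_species``.
    params:
        The :class:`~orbitempo.parameters.ParameterSet` the model was built
        from.
    prefactor_decomposition:
        Optional ``(x, t) -> (mu, base)`` with
        ``mu * base == rate_fn(x, t)`` element-wise.
    """

    name: str
    species_names: tuple
    rate_fn: RateFn
    params: ParameterSet
    prefactor_decomposition: Optional[Decomposition] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def rates(self, x, t: float = 0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.asarray(self.rate_fn(x, t), dtype=float)
        if out.shape != (self.n_species,):
            raise DomainError(
                f"rate_fn returned shape {out.shape}, expected ({self.n_species},)"
            )
        return out

    def prefactor(self, x, t: float = 0.0) -> tuple:
        """Evaluate the declared decomposition ``(mu, base)`` at a state."""
        if self.prefactor_decomposition is None:
            from .errors import UnsupportedModelError

            raise UnsupportedModelError(
                f"model {self.name!r} declares no prefactor decomposition"
            )
        mu, base = self.prefactor_decomposition(np.asarray(x, dtype=float), t)
        return np.asarray(mu, dtype=float), np.asarray(base, dtype=float)


# ---------------------------------------------------------------------------
# bistable switch
# ---------------------------------------------------------------------------

def default_bistable_params() -> ParameterSet:
    """Mutual-repression toggle in its bistable regime."""
    return ParameterSet(
        "bistable",
        {
            "alpha_1": 4.0, "alpha_2": 4.0,
            "beta_1": 1.0, "beta_2": 1.0,
            "K_1": 1.0, "K_2": 1.0,
            "hill": 2.0,
        },
    )


def build_bistable_switch(params: Optional[ParameterSet] = None) -> GRNModel:
    """Two mutually repressing genes; the default parameters are bistable."""
    p = params or default_bistable_params()
    a1, a2 = p["alpha_1"], p["alpha_2"]
    b1, b2 = p["beta_1"], p["beta_2"]
    K1, K2 = p["K_1"], p["K_2"]
    h = p["hill"]

    def rate_fn(x, t):
        x1, x2 = x
        return np.array([
            a1 / (1.0 + (x2 / K1) ** h) - b1 * x1,
            a2 / (1.0 + (x1 / K2) ** h) - b2 * x2,
        ])

    return GRNModel("bistable", ("x1", "x2"), rate_fn, p)


# ---------------------------------------------------------------------------
# ventral neural tube network
# ---------------------------------------------------------------------------

NEURAL_TUBE_SPECIES = ("Pax6", "Olig2", "Nkx22", "Irx3")


def default_neural_tube_params() -> ParameterSet:
    """Calibrated default parameterisation of the neural tube network.

    Levels are expressed relative to the production/degradation scale of
    each gene.  The set is calibrated so that, under high Shh, the network
    runs the progenitor -> transient Olig2 -> Nkx2-2 cascade, and so that
    scaling the degradation rates alone loses the Nkx2-2 fate slightly
    above a twofold increase.
    """
    return ParameterSet(
        "neural_tube",
        {
            # production / degradation
            "alpha_P": 1.0, "alpha_O": 1.1, "alpha_N": 0.9, "alpha_I": 1.0,
            "beta_P": 1.0, "beta_O": 1.0, "beta_N": 1.0, "beta_I": 1.0,
            # repression thresholds K_AB: species A represses species B
            "K_OP": 0.28, "K_NP": 0.28,
            "K_NO": 0.40, "K_IO": 1.2,
            "K_PN": 0.16, "K_ON": 2.5, "K_IN": 0.16,
            "K_OI": 0.30, "K_NI": 0.30,
            # Hill coefficients
            "hill": 5.0, "hill_shh": 2.0,
            # Shh half-activation of Olig2 and Nkx2-2
            "K_SO": 0.30, "K_SN": 0.50,
        },
    )


def build_neural_tube(params: Optional[ParameterSet] = None,
                      shh_level: float = 1.0) -> GRNModel:
    """Four-gene cross-repression network with Shh activation.

    Pax6 and Irx3 are constitutively produced and repressed by Olig2 and
    Nkx2-2; Olig2 and Nkx2-2 additionally require Shh input.  ``shh_level``
    is a dimensionless signal held constant during integration.
    """
    if shh_level < 0:
        raise ParameterError(f"shh_level must be non-negative, got {shh_level}")
    p = params or default_neural_tube_params()
    h = p["hill"]
    hs = p["hill_shh"]

    def act(S, K):
        if S == 0:
            return 0.0
        return S ** hs / (S ** hs + K ** hs)

    gO = act(shh_level, p["K_SO"])
    gN = act(shh_level, p["K_SN"])
    aP, aO, aN, aI = p["alpha_P"], p["alpha_O"], p["alpha_N"], p["alpha_I"]
    bP, bO, bN, bI = p["beta_P"], p["beta_O"], p["beta_N"], p["beta_I"]

    def rep(x, K):
        return 1.0 / (1.0 + (x / K) ** h)

    def rate_fn(x, t):
        P, O, N, I = np.maximum(x, 0.0)
        return np.array([
            aP * rep(O, p["K_OP"]) * rep(N, p["K_NP"]) - bP * P,
            aO * gO * rep(N, p["K_NO"]) * rep(I, p["K_IO"]) - bO * O,
            aN * gN * rep(P, p["K_PN"]) * rep(O, p["K_ON"]) * rep(I, p["K_IN"]) - bN * N,
            aI * rep(O, p["K_OI"]) * rep(N, p["K_NI"]) - bI * I,
        ])

    return GRNModel("neural_tube", NEURAL_TUBE_SPECIES, rate_fn, p,
                    metadata={"shh_level": float(shh_level)})


# ---------------------------------------------------------------------------
# repressilator: full 12-variable mass-action model
# ---------------------------------------------------------------------------

REPRESSILATOR_FULL_SPECIES = tuple(
    f"{stem}{i}" for stem in ("m", "p", "d", "pi") for i in GENES
)

#: promoter copy concentration (single promoter per gene, molecule units)
PROMOTER_COPIES = 1.0


def default_repressilator_full_params() -> ParameterSet:
    """Symmetric oscillatory default for the 12-variable model.

    Degradation sets the slow timescale (delta = 2.5, gamma = 1); the
    reversible dimerisation and promoter (un)binding rates are several
    hundredfold faster, placing the model in the regime where the reduced
    descriptions are valid.  Composed constants: r = 5, s = 2000, with
    protein scale p0 = sigma*alpha/(delta*gamma) = 1000.
    """
    p0 = 1000.0
    r = (5.0, 5.0, 5.0)
    s = (2000.0, 2000.0, 2000.0)
    kdim_minus = 500.0
    kprom_minus = 500.0
    rates = per_gene({
        "alpha": (50.0, 50.0, 50.0),
        "sigma": (50.0, 50.0, 50.0),
        "delta": (2.5, 2.5, 2.5),
        "gamma": (1.0, 1.0, 1.0),
        "kdim_minus": (kdim_minus,) * 3,
        "kdim_plus": tuple(ri * kdim_minus / p0 for ri in r),
        "kprom_minus": (kprom_minus,) * 3,
    })
    # kprom_plus_{i+1} pairs with the dimer of gene i (cyclic pairing)
    for j in GENES:  # promoter j is bound by the dimer of gene j-1
        up = GENES[(j - 2) % 3]
        rates[f"kprom_plus_{j}"] = s[up - 1] * kprom_minus / (r[up - 1] * p0)
    return ParameterSet("repressilator_full", rates)


def build_repressilator_full(params: Optional[ParameterSet] = None) -> GRNModel:
    """Mass-action repressilator with dimerisation and promoter occupancy.

    Variables per gene i: mRNA ``m_i``, protein monomer ``p_i``, free dimer
    ``d_i`` and promoter-active probability ``pi_i``.  The dimer of gene i
    silences the promoter of gene i+1 (indices cyclic).  Dimerisation
    consumes two monomers per dimer, so the monomer balance carries the
    fluxes ``-2 k+ p^2 + 2 k- d``.
    """
    p = params or default_repressilator_full_params()
    validate_full_repressilator(p)
    alpha = np.array([p.gene("alpha", i) for i in GENES])
    sigma = np.array([p.gene("sigma", i) for i in GENES])
    delta = np.array([p.gene("delta", i) for i in GENES])
    gamma = np.array([p.gene("gamma", i) for i in GENES])
    kdp = np.array([p.gene("kdim_plus", i) for i in GENES])
    kdm = np.array([p.gene("kdim_minus", i) for i in GENES])
    kpp = np.array([p.gene("kprom_plus", i) for i in GENES])
    kpm = np.array([p.gene("kprom_minus", i) for i in GENES])

    def rate_fn(x, t):
        m, pr, d, pi = x[0:3], x[3:6], x[6:9], x[9:12]
        dim_fwd = kdp * pr * pr
        dim_bwd = kdm * d
        # binding flux of dimer i onto promoter i+1
        bind = kpp[_NEXT] * d * pi[_NEXT]
        unbind = kpm[_NEXT] * PROMOTER_COPIES * (1.0 - pi[_NEXT])
        dm = alpha * pi - delta * m
        dp = sigma * m - gamma * pr - 2.0 * dim_fwd + 2.0 * dim_bwd
        dd = dim_fwd - dim_bwd - bind + unbind
        dpi = -kpp * d[_PREV] * pi + kpm * PROMOTER_COPIES * (1.0 - pi)
        return np.concatenate([dm, dp, dd, dpi])

    return GRNModel("repressilator_full", REPRESSILATOR_FULL_SPECIES, rate_fn, p)


# ---------------------------------------------------------------------------
# composed parameters and reduced descriptions
# ---------------------------------------------------------------------------

def compose_rates(params: ParameterSet) -> ParameterSet:
    """Collapse the 24 raw repressilator rates into composed constants.

    With the protein scale ``p0_i = sigma_i * alpha_i / (delta_i * gamma_i)``
    (maximum monomer level in the absence of dimerisation), the reduced
    descriptions depend on the raw rates only through, per gene ``i``:

    ``r_i = (kdim_plus_i / kdim_minus_i) * p0_i``
        dimensionless flux strength towards the free dimer; appears only in
        the prefactor ``mu_i``, making it a pure tempo knob,
    ``s_i = (kprom_plus_{i+1} / kprom_minus_{i+1}) * (kdim_plus_i / kdim_minus_i) * p0_i**2``
        repression strength of gene i's dimer on promoter i+1; shapes the
        base rates (and, weakly, the prefactor through promoter
        sequestration),
    ``eta_i = promoter_copies / p0_i``
        weight of the promoter-bound dimer in the protein budget,

    together with the retained timescales ``delta_i`` and ``gamma_i``.
    """
    validate_full_repressilator(params)
    rates = {}
    for i in GENES:
        nxt = GENES[i % 3]
        p0 = (params.gene("sigma", i) * params.gene("alpha", i)
              / (params.gene("delta", i) * params.gene("gamma", i)))
        kd = params.gene("kdim_plus", i) / params.gene("kdim_minus", i)
        kp = params.gene("kprom_plus", nxt) / params.gene("kprom_minus", nxt)
        rates[f"r_{i}"] = kd * p0
        rates[f"s_{i}"] = kp * kd * p0 ** 2
        rates[f"eta_{i}"] = PROMOTER_COPIES / p0
        rates[f"delta_{i}"] = params.gene("delta", i)
        rates[f"gamma_{i}"] = params.gene("gamma", i)
    return ParameterSet("repressilator_reduced", rates)


def default_repressilator_reduced_params() -> ParameterSet:
    """Reference oscillatory parameter set for the reduced repressilator.

    Strong dimer flux (r ~ 25) with mild asymmetry across the genes, sharp
    effective repression (s = 1e5) and mRNA turnover a few-fold faster than
    the effective protein timescale.  This is the reference system used by
    the perturbation sweep and tempo-design experiments.
    """
    return ParameterSet("repressilator_reduced", per_gene({
        "r": (22.0, 25.0, 28.5),
        "s": (1.0e5, 1.0e5, 1.0e5),
        "eta": (1.0e-3, 1.0e-3, 1.0e-3),
        "delta": (2.5, 2.5, 2.5),
        "gamma": (1.0, 1.0, 1.0),
    }))


def _reduced_arrays(params: ParameterSet):
    r = np.array([params.gene("r", i) for i in GENES])
    s = np.array([params.gene("s", i) for i in GENES])
    eta = np.array([params.gene("eta", i) for i in GENES])
    delta = np.array([params.gene("delta", i) for i in GENES])
    gamma = np.array([params.gene("gamma", i) for i in GENES])
    return r, s, eta, delta, gamma


def _coerce_reduced(params: Optional[ParameterSet]) -> ParameterSet:
    if params is None:
        return default_repressilator_reduced_params()
    if params.model == "repressilator_full":
        return compose_rates(params)
    validate_reduced_repressilator(params)
    return params


def repressilator_prefactor(params: ParameterSet, p_tilde) -> np.ndarray:
    """Per-gene tempo prefactor ``mu_i`` at scaled protein levels ``p_tilde``.

    ``mu_i = 1 / (1 + 4 r_i p + 4 eta_i s_i p / (1 + s_i p^2)^2)`` is the
    inverse sensitivity of the total protein pool (monomer + 2 free dimer +
    2 bound dimer) to the monomer level: intermediate reactions buffer the
    monomer, slowing its response without redirecting it.
    """
    r, s, eta, _, _ = _reduced_arrays(_coerce_reduced(params))
    p = np.asarray(p_tilde, dtype=float)
    pc = np.maximum(p, 0.0)
    return 1.0 / (1.0 + 4.0 * r * pc + 4.0 * eta * s * pc / (1.0 + s * pc ** 2) ** 2)


def build_repressilator_reduced(params: Optional[ParameterSet] = None) -> GRNModel:
    """Six-variable mRNA/protein reduction of the repressilator.

    States are non-dimensionalised: ``m_i`` relative to ``alpha_i/delta_i``
    and ``p_i`` relative to ``p0_i``.  The protein equation carries the
    state-dependent prefactor ``mu_i(p_i)``; the base rates (mRNA kinetics
    and ``gamma_i (m_i - p_i)``) involve only ``s``, ``delta`` and
    ``gamma``, so perturbing ``r_i`` alone re-paces the protein response
    without moving the nullclines.
    """
    p = _coerce_reduced(params)
    r, s, eta, delta, gamma = _reduced_arrays(p)

    def decomposition(x, t):
        m, pr = x[0:3], np.maximum(x[3:6], 0.0)
        hill = 1.0 / (1.0 + s[_PREV] * pr[_PREV] ** 2)
        mu_p = 1.0 / (1.0 + 4.0 * r * pr
                      + 4.0 * eta * s * pr / (1.0 + s * pr ** 2) ** 2)
        mu = np.concatenate([np.ones(3), mu_p])
        base = np.concatenate([delta * (hill - m), gamma * (m - pr)])
        return mu, base

    def rate_fn(x, t):
        mu, base = decomposition(x, t)
        return mu * base

    species = tuple(f"m{i}" for i in GENES) + tuple(f"p{i}" for i in GENES)
    return GRNModel("repressilator_reduced", species, rate_fn, p,
                    prefactor_decomposition=decomposition)


def build_repressilator_mrna_qssa(params: Optional[ParameterSet] = None) -> GRNModel:
    """Protein-only repressilator after additionally slaving mRNA.

    ``dp_i/dt = mu_i(p_i) * gamma_i * (H(p_{i-1}) - p_i)`` with the Hill
    base rate ``H(p) = 1 / (1 + s p^2)``.  Valid when mRNA relaxation
    (``delta_i``) is much faster than the effective protein timescale
    (``gamma_i mu_i``).  All intermediate mechanisms are summarised by the
    prefactor ``mu_i``.
    """
    p = _coerce_reduced(params)
    r, s, eta, delta, gamma = _reduced_arrays(p)

    def decomposition(x, t):
        pr = np.maximum(np.asarray(x, dtype=float), 0.0)
        hill = 1.0 / (1.0 + s[_PREV] * pr[_PREV] ** 2)
        mu = 1.0 / (1.0 + 4.0 * r * pr
                    + 4.0 * eta * s * pr / (1.0 + s * pr ** 2) ** 2)
        base = gamma * (hill - pr)
        return mu, base

    def rate_fn(x, t):
        mu, base = decomposition(x, t)
        return mu * base

    species = tuple(f"p{i}" for i in GENES)
    return GRNModel("repressilator_qssa", species, rate_fn, p,
                    prefactor_decomposition=decomposition)


# ---------------------------------------------------------------------------
# prefactor transformations
# ---------------------------------------------------------------------------

def _as_scalar_fn(mu) -> Callable[[np.ndarray, float], float]:
    if callable(mu):
        return mu
    value = float(mu)
    return lambda x, t: value


def apply_scalar_prefactor(model: GRNModel, mu) -> GRNModel:
    """Scale all rates by a strictly positive scalar prefactor.

    ``mu`` may be a constant or a callable ``mu(x, t)``; it may vary
    arbitrarily in time and gene-expression state.  The transformed system
    is orbitally equivalent to the source model: identical orbits, rescaled
    local tempo.
    """
    mu_fn = _as_scalar_fn(mu)

    def rate_fn(x, t):
        m = float(mu_fn(x, t))
        if not np.isfinite(m) or m <= 0:
            raise DomainError(f"scalar prefactor must be positive, got {m}")
        return m * model.rate_fn(x, t)

    decomposition = None
    if model.prefactor_decomposition is not None:
        def decomposition(x, t):
            m = float(mu_fn(x, t))
            if not np.isfinite(m) or m <= 0:
                raise DomainError(f"scalar prefactor must be positive, got {m}")
            mu_vec, base = model.prefactor_decomposition(x, t)
            return m * np.asarray(mu_vec, dtype=float), np.asarray(base, dtype=float)

    return replace(model, name=f"{model.name}*mu", rate_fn=rate_fn,
                   prefactor_decomposition=decomposition)


def apply_vector_prefactor(model: GRNModel, mu_vec) -> GRNModel:
    """Scale rates element-wise (Hadamard product) by a per-species prefactor.

    ``mu_vec`` may be a sequence of positive values or a callable
    ``mu_vec(x, t)`` returning one.  Orbit preservation is *not* guaranteed
    unless the components coincide wherever the corresponding base rates
    are appreciable.
    """
    if callable(mu_vec):
        mu_fn = mu_vec
    else:
        const = np.asarray(mu_vec, dtype=float)
        mu_fn = lambda x, t: const

    def eval_mu(x, t):
        m = np.asarray(mu_fn(x, t), dtype=float)
        if m.shape != (model.n_species,):
            raise DomainError(
                f"vector prefactor has shape {m.shape}, expected ({model.n_species},)"
            )
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            raise DomainError("vector prefactor must be positive componentwise")
        return m

    def rate_fn(x, t):
        return eval_mu(x, t) * model.rate_fn(x, t)

    decomposition = None
    if model.prefactor_decomposition is not None:
        def decomposition(x, t):
            mu0, base = model.prefactor_decomposition(x, t)
            return eval_mu(x, t) * np.asarray(mu0, dtype=float), np.asarray(base, dtype=float)

    return replace(model, name=f"{model.name}*mu_vec", rate_fn=rate_fn,
                   prefactor_decomposition=decomposition)


# ---------------------------------------------------------------------------
# registry and default initial conditions
# ---------------------------------------------------------------------------

MODEL_BUILDERS = {
    "bistable": build_bistable_switch,
    "neural_tube": build_neural_tube,
    "repressilator_full": build_repressilator_full,
    "repressilator_reduced": build_repressilator_reduced,
    "repressilator_qssa": build_repressilator_mrna_qssa,
}

DEFAULT_PARAMS = {
    "bistable": default_bistable_params,
    "neural_tube": default_neural_tube_params,
    "repressilator_full": default_repressilator_full_params,
    "repressilator_reduced": default_repressilator_reduced_params,
    "repressilator_qssa": default_repressilator_reduced_params,
}


def build_model(name: str, params: Optional[ParameterSet] = None, **kwargs) -> GRNModel:
    """Build a registered model by name."""
    try:
        builder = MODEL_BUILDERS[name]
    except KeyError:
        raise SchemaError(
            f"unknown model {name!r}; available: {sorted(MODEL_BUILDERS)}"
        )
    return builder(params, **kwargs) if params is not None or kwargs else builder()


def symmetric_fixed_point_guess(model: GRNModel) -> np.ndarray:
    """Crude interior starting guess used by fixed-point solvers."""
    if model.name.startswith(("repressilator_reduced", "repressilator_qssa")):
        # the symmetric fixed point sits near the root of 1/(1+s p^2) = p
        s_mean = float(np.mean([model.params.gene("s", i) for i in GENES]))
        guess = (1.0 / s_mean) ** (1.0 / 3.0) if s_mean > 1.0 else 0.5
        n = 6 if model.name.startswith("repressilator_reduced") else 3
        return np.full(n, guess)
    if model.name.startswith("repressilator_full"):
        p = model.params
        m0 = p.gene("alpha", 1) / p.gene("delta", 1)
        p0 = p.gene("sigma", 1) * m0 / p.gene("gamma", 1)
        guess = np.empty(12)
        guess[0:3] = 0.05 * m0
        guess[3:6] = 0.05 * p0
        kd = p.gene("kdim_plus", 1) / p.gene("kdim_minus", 1)
        guess[6:9] = kd * guess[3:6] ** 2
        guess[9:12] = 0.5
        return guess
    return np.full(model.n_species, 0.5)


def default_initial_state(model: GRNModel, perturbation: float = 0.2) -> np.ndarray:
    """Reproducible initial condition convention for the built-in models.

    Repressilator variants start from the symmetric fixed point with the
    gene-1 species raised by ``perturbation`` (relative); the neural tube
    starts from the Pax6/Irx3-high state of the Shh = 0 system; the
    bistable switch starts slightly off-centre.
    """
    from scipy.optimize import fsolve

    if model.name.startswith("repressilator"):
        guess = symmetric_fixed_point_guess(model)
        fp = fsolve(lambda x: model.rate_fn(x, 0.0), guess, xtol=1e-12)
        x0 = np.array(fp)
        for j, name in enumerate(model.species_names):
            if name.endswith("1") and not name.startswith("pi"):
                x0[j] *= 1.0 + perturbation
        return x0
    if model.name.startswith("neural_tube"):
        base = build_neural_tube(model.params, shh_level=0.0)
        start = np.array([1.0, 0.0, 0.0, 1.0])
        fp = fsolve(lambda x: base.rate_fn(x, 0.0), start, xtol=1e-12)
        return np.maximum(fp, 0.0)
    if model.name.startswith("bistable"):
        return np.array([1.5, 0.5])
    return np.full(model.n_species, 0.5)
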