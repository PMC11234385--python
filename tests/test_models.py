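"""Model construction, prefactor transformations and reduction structure."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from orbitempo.dynamics import (
    find_steady_state,
    integrate,
    normalize_orbit,
    orbit_from_trajectory,
    resample_arclength,
)
from orbitempo.errors import DomainError, SchemaError, UnsupportedModelError
from orbitempo.metrics import frechet_distance
from orbitempo.models import (
    apply_scalar_prefactor,
    apply_vector_prefactor,
    build_model,
    build_neural_tube,
    build_repressilator_full,
    build_repressilator_mrna_qssa,
    build_repressilator_reduced,
    compose_rates,
    default_initial_state,
    default_neural_tube_params,
    default_repressilator_full_params,
    default_repressilator_reduced_params,
    repressilator_prefactor,
)
from orbitempo.parameters import GENES


# ---------------------------------------------------------------------------
# bistable switch
# ---------------------------------------------------------------------------

def test_bistable_two_basins_reach_distinct_attractors(bistable_model):
    a = find_steady_state(bistable_model, [1.5, 0.5], tol=1e-10)
    b = find_steady_state(bistable_model, [0.5, 1.5], tol=1e-10)
    assert np.linalg.norm(a - b) > 1.0
    # each attractor is a genuine root of the rate function
    for state in (a, b):
        root = fsolve(lambda x: bistable_model.rate_fn(x, 0.0), state, xtol=1e-13)
        assert np.allclose(state, root, atol=1e-8)


def test_bistable_determinism(bistable_model):
    t1 = integrate(bistable_model, [1.0, 0.3], (0, 20))
    t2 = integrate(bistable_model, [1.0, 0.3], (0, 20))
    assert np.array_equal(t1.states, t2.states)


# ---------------------------------------------------------------------------
# neural tube
# ---------------------------------------------------------------------------

def test_neural_tube_cascade_culminates_in_nkx22(neural_reference, neural_model):
    terminal = neural_reference.terminal_state()
    assert neural_model.species_names[int(np.argmax(terminal))] == "Nkx22"
    olig2 = neural_reference.component(1)
    # transient Olig2 pulse: rises well above its terminal value, then falls
    assert olig2.max() > 10 * olig2[-1]
    assert olig2.max() > 0.5


def test_neural_tube_without_shh_keeps_progenitor_state(neural_x0):
    model = build_neural_tube(default_neural_tube_params(), shh_level=0.0)
    traj = integrate(model, neural_x0, (0, 50))
    # Pax6/Irx3 persist; Olig2 and Nkx2-2 never activate
    assert traj.states[:, [1, 2]].max() < 1e-3
    assert np.allclose(traj.terminal_state()[[0, 3]], neural_x0[[0, 3]], atol=1e-3)


def test_neural_tube_strong_degradation_stalls_at_olig2(neural_x0):
    params = default_neural_tube_params()
    beta_keys = [k for k in params if k.startswith("beta_")]
    model = build_neural_tube(params.scaled(beta_keys, 4.0), shh_level=1.0)
    traj = integrate(model, neural_x0, (0, 80))
    terminal = traj.terminal_state()
    assert model.species_names[int(np.argmax(terminal))] == "Olig2"


# ---------------------------------------------------------------------------
# repressilator: structure and reductions
# ---------------------------------------------------------------------------

def test_full_repressilator_symmetric_fixed_point_matches_root_oracle():
    model = build_repressilator_full()
    x0 = default_initial_state(model, perturbation=0.0)
    assert np.linalg.norm(model.rates(x0)) < 1e-6 * np.linalg.norm(x0)
    # symmetry: all three genes share one state
    m, p, d, pi = x0[0:3], x0[3:6], x0[6:9], x0[9:12]
    for block in (m, p, d, pi):
        assert np.allclose(block, block[0], rtol=1e-8)
    assert np.all((pi >= 0) & (pi <= 1))


def test_full_repressilator_promoter_probabilities_stay_in_unit_interval():
    model = build_repressilator_full()
    x0 = default_initial_state(model)
    traj = integrate(model, x0, (0, 60), method="BDF", atol=1e-8)
    pi = traj.states[:, 9:12]
    assert pi.min() >= -1e-9 and pi.max() <= 1 + 1e-9
    assert traj.states[:, 0:9].min() >= 0


def test_full_repressilator_rejects_malformed_parameters():
    params = default_repressilator_full_params()
    with pytest.raises(SchemaError):
        build_repressilator_full(
            params.__class__("repressilator_full",
                             {k: v for k, v in params.rates.items()
                              if k != "sigma_1"}))


@pytest.mark.parametrize("builder", [build_repressilator_reduced,
                                     build_repressilator_mrna_qssa])
def test_prefactor_decomposition_reconstructs_rates(builder, rng):
    """mu * base must equal the full rate vector at random admissible states."""
    model = builder()
    for _ in range(1000):
        x = rng.uniform(0.0, 1.2, size=model.n_species)
        mu, base = model.prefactor(x)
        rates = model.rates(x)
        assert np.allclose(mu * base, rates, rtol=1e-10, atol=1e-300)


def test_compose_rates_matches_closed_forms():
    full = default_repressilator_full_params()
    comp = compose_rates(full)
    p0 = full["sigma_1"] * full["alpha_1"] / (full["delta_1"] * full["gamma_1"])
    kd = full["kdim_plus_1"] / full["kdim_minus_1"]
    assert comp["r_1"] == pytest.approx(kd * p0, rel=1e-12)
    kp = full["kprom_plus_2"] / full["kprom_minus_2"]
    assert comp["s_1"] == pytest.approx(kp * kd * p0 ** 2, rel=1e-12)
    # identical genes -> identical composed triples
    for stem in ("r", "s", "eta", "delta", "gamma"):
        vals = [comp.gene(stem, i) for i in GENES]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])


def test_composed_parameters_invariant_under_joint_fast_rate_scaling():
    """Scaling k+ and k- together changes only how fast the dimer pool
    equilibrates, not the composed constants the reduced model depends on."""
    full = default_repressilator_full_params()
    scaled = full.scaled([f"kdim_plus_{i}" for i in GENES]
                         + [f"kdim_minus_{i}" for i in GENES], 2.0)
    assert compose_rates(full).rates == pytest.approx(compose_rates(scaled).rates)


def test_r_perturbation_touches_only_the_prefactor(rng):
    """r_i appears exclusively in mu_i: base rates and other mu_j unchanged."""
    params = default_repressilator_reduced_params()
    bumped = params.with_updates(r_1=3.0 * params["r_1"])
    a, b = build_repressilator_mrna_qssa(params), build_repressilator_mrna_qssa(bumped)
    for _ in range(50):
        x = rng.uniform(0.0, 1.0, size=3)
        mu_a, base_a = a.prefactor(x)
        mu_b, base_b = b.prefactor(x)
        assert np.allclose(base_a, base_b, rtol=1e-12)
        assert np.allclose(mu_a[1:], mu_b[1:], rtol=1e-12)
        assert mu_b[0] < mu_a[0]  # stronger dimer flux slows gene 1


def test_prefactor_positive_and_identity_without_dimer_flux():
    params = default_repressilator_reduced_params()
    p = np.linspace(0.0, 1.0, 50)
    mu = np.array([repressilator_prefactor(params, np.full(3, v)) for v in p])
    assert np.all(mu > 0) and np.all(mu <= 1)
    assert np.allclose(repressilator_prefactor(params, np.zeros(3)), 1.0)


def test_reduced_model_symmetric_genes_share_prefactor_function():
    params = default_repressilator_reduced_params().with_updates(
        r_1=25.0, r_2=25.0, r_3=25.0)
    mu = repressilator_prefactor(params, np.full(3, 0.3))
    assert mu[0] == pytest.approx(mu[1]) == pytest.approx(mu[2])


# ---------------------------------------------------------------------------
# prefactor transformations
# ---------------------------------------------------------------------------

def test_scalar_prefactor_identity_leaves_trajectories_unchanged(bistable_model):
    scaled = apply_scalar_prefactor(bistable_model, 1.0)
    t1 = integrate(bistable_model, [1.2, 0.4], (0, 10))
    t2 = integrate(scaled, [1.2, 0.4], (0, 10))
    assert np.allclose(t1.states, t2.states, atol=1e-9)


def test_scalar_prefactor_rejects_nonpositive_values(bistable_model):
    bad = apply_scalar_prefactor(bistable_model, lambda x, t: -1.0)
    with pytest.raises(DomainError):
        bad.rates([1.0, 1.0])


def test_vector_prefactor_equal_components_is_scalar_case(bistable_model):
    v = apply_vector_prefactor(bistable_model, [2.0, 2.0])
    s = apply_scalar_prefactor(bistable_model, 2.0)
    x = np.array([0.7, 1.1])
    assert np.allclose(v.rates(x), s.rates(x), rtol=1e-12)


def test_vector_prefactor_validates_shape_and_sign(bistable_model):
    with pytest.raises(DomainError):
        apply_vector_prefactor(bistable_model, [1.0, 2.0, 3.0]).rates([1.0, 1.0])
    with pytest.raises(DomainError):
        apply_vector_prefactor(bistable_model, [1.0, -2.0]).rates([1.0, 1.0])


def test_unequal_vector_prefactor_deforms_bistable_orbit(bistable_model):
    x0 = [1.8, 1.2]
    ref = integrate(bistable_model, x0, (0, 30))
    pert = integrate(apply_vector_prefactor(bistable_model, [4.0, 0.5]),
                     x0, (0, 60))
    orb_a = normalize_orbit(resample_arclength(orbit_from_trajectory(ref), 200))
    orb_b = normalize_orbit(resample_arclength(orbit_from_trajectory(pert), 200))
    assert frechet_distance(orb_a, orb_b, closed=False).value > 0.01


def test_build_model_registry_lookup():
    assert build_model("bistable").name == "bistable"
    with pytest.raises(SchemaError, match="unknown model"):
        build_model("nope")


def test_model_without_decomposition_raises(bistable_model):
    with pytest.raises(UnsupportedModelError):
        bistable_model.prefactor([1.0, 1.0])
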