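"""The package's computational experiments.

Four workflows built on the lower-level modules:

* :func:`degradation_scan` — neural-tube tempo scaling: degradation-only
  versus joint production+degradation rescaling, with time factors, fates
  and orbital distances on a fold grid.
* :func:`perturbation_sweep` — randomly perturb the repressilator's
  composed dimer-flux parameters r_i and measure period, orbital distance,
  prefactor heterogeneity and molecular predictors per system.
* :func:`design_tempo_sets` — design parameter sets that change tempo by an
  order of magnitude while preserving the orbit, by scaling the mean of the
  r_i at fixed heterogeneity.
* :func:`figure_grid_export` — export orbits/trajectories of selected swept
  systems on a (period, orbital distance) grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    detect_fate,
    find_limit_cycle,
    integrate,
    normalize_orbit,
    orbit_from_trajectory,
    resample_arclength,
    time_factor,
)
from .errors import DomainError, NotOscillatoryError, ParameterError
from .metrics import frechet_distance
from .models import (
    GRNModel,
    apply_scalar_prefactor,
    default_initial_state,
    build_neural_tube,
    build_repressilator_mrna_qssa,
    build_repressilator_reduced,
    default_neural_tube_params,
    default_repressilator_reduced_params,
)
from .parameters import GENES, ParameterSet
from .prefactors import mean_prefactor, orbital_heterogeneity, r_statistics

log = logging.getLogger("orbitempo.experiments")

#: normalized Frechet distance below which an orbit counts as preserved
ORBIT_PRESERVATION_THRESHOLD = 0.05

SWEEP_COLUMNS = [
    "params_id", "fold_1", "fold_2", "fold_3", "oscillatory", "period",
    "period_fold", "orbital_distance", "max_dsigma", "mean_prefactor_fold",
    "predicted_period_fold", "r_mean", "r_mean_fold", "r_heterogeneity",
]

SCAN_COLUMNS = ["mu", "strategy", "time_factor", "fate", "orbital_distance"]


@dataclass(frozen=True)
class SweepRecord:
    """One perturbed repressilator system and its measured/predicted metrics."""

    params_id: int
    fold_1: float
    fold_2: float
    fold_3: float
    oscillatory: bool
    period: float
    period_fold: float
    orbital_distance: float
    max_dsigma: float
    mean_prefactor_fold: float
    predicted_period_fold: float
    r_mean: float
    r_mean_fold: float
    r_heterogeneity: float


@dataclass(frozen=True)
class ScanRecord:
    """One neural-tube rate rescaling and its tempo/fate outcome."""

    mu: float
    strategy: str
    time_factor: float
    fate: str
    orbital_distance: float


# ---------------------------------------------------------------------------
# neural tube: scaling production and degradation
# ---------------------------------------------------------------------------

def _neural_tube_reference(params: ParameterSet, shh_level: float,
                           t_end: float, rtol: float, atol: float):
    model = build_neural_tube(params, shh_level=shh_level)
    x0 = default_initial_state(model)
    traj = integrate(model, x0, (0.0, t_end), rtol=rtol, atol=atol)
    orbit = normalize_orbit(resample_arclength(orbit_from_trajectory(traj), 300))
    return model, x0, traj, orbit


def degradation_scan(neural_params: Optional[ParameterSet] = None,
                     fold_grid: Optional[Sequence[float]] = None,
                     shh_level: float = 1.0, t_end: float = 80.0,
                     rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Scan rate fold changes under two tempo-control strategies.

    For each fold ``mu`` on a (default log-spaced, 25-point, [0.25, 5])
    grid and each strategy — scaling degradation rates only, or production
    and degradation together — integrate the neural-tube model from the
    progenitor state, and record the time factor to the Nkx2-2 event, the
    terminal fate, and the Fréchet distance of the (normalized) orbit to
    the unscaled reference.  Joint rescaling is a scalar prefactor, so it
    preserves orbit and fate at any fold; degradation-only rescaling
    deforms the orbit and loses the V3 fate beyond roughly a twofold
    increase.
    """
    params = neural_params or default_neural_tube_params()
    if fold_grid is None:
        fold_grid = np.geomspace(0.25, 5.0, 25)
    fold_grid = np.asarray(fold_grid, dtype=float)
    if np.any(fold_grid <= 0):
        raise ParameterError("fold grid must be positive")

    _, x0, traj_ref, orbit_ref = _neural_tube_reference(
        params, shh_level, t_end, rtol, atol)

    beta_keys = [k for k in params if k.startswith("beta_")]
    records = []
    for mu in fold_grid:
        for strategy in ("degradation_only", "production_and_degradation"):
            if strategy == "production_and_degradation":
                model_mu = apply_scalar_prefactor(
                    build_neural_tube(params, shh_level=shh_level), float(mu))
            else:
                model_mu = build_neural_tube(
                    params.scaled(beta_keys, float(mu)), shh_level=shh_level)
            # slower systems need proportionally longer windows
            horizon = t_end / min(float(mu), 1.0)
            traj = integrate(model_mu, x0, (0.0, horizon), rtol=rtol, atol=atol)
            tf = time_factor(traj_ref, traj, species=2, level_fraction=0.5)
            fate = detect_fate(traj, list(model_mu.species_names))
            orbit = normalize_orbit(
                resample_arclength(orbit_from_trajectory(traj), 300))
            dist = float(frechet_distance(orbit_ref, orbit, closed=False,
                                          compute_alignment=False).value)
            records.append(ScanRecord(float(mu), strategy, float(tf), fate, dist))
    log.info("degradation scan: %d records", len(records))
    return pd.DataFrame([asdict(r) for r in records], columns=SCAN_COLUMNS)


def degradation_ceiling(scan: pd.DataFrame) -> float:
    """Critical degradation-only fold beyond which the V3 fate is lost.

    Geometric midpoint between the largest scanned fold that still reaches
    V3 and the smallest fold (above it) that does not.
    """
    sub = scan[scan.strategy == "degradation_only"].sort_values("mu")
    ok = sub[(sub.fate == "V3") & (sub.mu >= 1.0)]
    lost = sub[(sub.fate != "V3") & (sub.mu >= 1.0)]
    if ok.empty or lost.empty:
        raise DomainError("scan grid does not bracket the fate-loss threshold")
    lo = float(ok.mu.max())
    hi = float(lost[lost.mu > lo].mu.min())
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# repressilator perturbation sweep
# ---------------------------------------------------------------------------

def _reference_cycle(params: ParameterSet, n_orbit_points: int, rtol: float,
                     atol: float):
    model = build_repressilator_reduced(params)
    x0 = default_initial_state(model)
    orbit, period = find_limit_cycle(model, x0, transient_periods=12,
                                     total_periods=28,
                                     n_points=n_orbit_points,
                                     rtol=rtol, atol=atol)
    return model, x0, orbit, float(period.period)


def _protein_columns(model: GRNModel):
    return [j for j, n in enumerate(model.species_names) if n.startswith("p")]


def _analytic_predictors(params_ref: ParameterSet, params_pert: ParameterSet,
                         protein_orbit):
    """Prefactor metrics of a perturbation, without integrating it.

    Evaluated on the protein-only (mRNA-QSSA) representation along the
    reference orbit projected to protein coordinates; the perturbation's
    prefactor is the ratio of perturbed to reference mu_i.  Heterogeneity
    is reported in its scale-free (relative) form so that a uniform tempo
    change across the genes scores zero.
    """
    qssa_ref = build_repressilator_mrna_qssa(params_ref)
    qssa_pert = build_repressilator_mrna_qssa(params_pert)
    het = orbital_heterogeneity(protein_orbit, qssa_pert, reference=qssa_ref,
                                relative=True)
    mpf = mean_prefactor(protein_orbit, qssa_pert, reference=qssa_ref)
    return float(het.max_value), float(mpf.mean_tempo)


def perturbation_sweep(reference_params: Optional[ParameterSet] = None,
                       n_systems: int = 200,
                       fold_range: tuple = (0.2, 5.0), seed: int = 0,
                       distribution: str = "log-uniform",
                       n_orbit_points: int = 200,
                       rtol: float = 1e-7, atol: float = 1e-9) -> pd.DataFrame:
    """Randomly perturb the r_i of a reference repressilator and measure.

    Each system draws an independent fold change per ``r_i`` (log-uniform
    over ``fold_range`` by default, linear-uniform with
    ``distribution="uniform"``).  For every system the analytic predictors
    (max D_sigma and mean-prefactor fold relative to the reference,
    evaluated along the reference orbit) are computed first; the perturbed
    system is then integrated, classified as oscillatory or not, and its
    period and normalized closed-orbit Fréchet distance to the reference
    recorded.  Fully reproducible from *seed*.
    """
    if n_systems < 1:
        raise ParameterError("n_systems must be >= 1")
    lo, hi = map(float, fold_range)
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ParameterError(f"invalid fold range {fold_range}")
    params_ref = reference_params or default_repressilator_reduced_params()

    model_ref, x0, orbit_ref, period_ref = _reference_cycle(
        params_ref, n_orbit_points, rtol, atol)
    pcols = _protein_columns(model_ref)
    protein_orbit = resample_arclength(orbit_ref.project(pcols), n_orbit_points)
    protein_ref_norm = normalize_orbit(protein_orbit)

    rng = np.random.default_rng(seed)
    if distribution == "log-uniform":
        folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_systems, 3)))
    elif distribution == "uniform":
        folds = rng.uniform(lo, hi, size=(n_systems, 3))
    else:
        raise ParameterError(f"unknown distribution {distribution!r}")

    r_keys = [f"r_{i}" for i in GENES]
    r_ref = np.array([params_ref[k] for k in r_keys])
    r_mean_ref, _ = r_statistics(params_ref)
    # perturbed systems start from a state on the reference cycle: the
    # perturbation hits a running system, which selects the attractor that
    # continues the reference behaviour when several coexist
    x0_pert = orbit_ref.points[0].copy()

    records = []
    for sid in range(n_systems):
        f = folds[sid]
        params_pert = params_ref.with_updates(
            **{k: r_ref[j] * f[j] for j, k in enumerate(r_keys)})
        max_ds, mpf = _analytic_predictors(params_ref, params_pert, protein_orbit)
        r_mean, r_het = r_statistics(params_pert)
        oscillatory, period, dist = False, float("nan"), float("nan")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model_pert = build_repressilator_reduced(params_pert)
                orbit_p, per = find_limit_cycle(
                    model_pert, x0_pert, transient_periods=12, total_periods=28,
                    n_points=n_orbit_points,
                    period_guess=period_ref / mpf, rtol=rtol, atol=atol)
            oscillatory = True
            period = float(per.period)
            prot_p = resample_arclength(orbit_p.project(pcols), n_orbit_points)
            prot_p_norm = normalize_orbit(prot_p, mode="reference",
                                          reference=protein_orbit)
            dist = float(frechet_distance(protein_ref_norm, prot_p_norm,
                                          closed=True,
                                          compute_alignment=False).value)
        except NotOscillatoryError:
            pass
        records.append(SweepRecord(
            params_id=sid, fold_1=float(f[0]), fold_2=float(f[1]),
            fold_3=float(f[2]), oscillatory=oscillatory, period=period,
            period_fold=period / period_ref, orbital_distance=dist,
            max_dsigma=max_ds, mean_prefactor_fold=mpf,
            predicted_period_fold=1.0 / mpf, r_mean=r_mean,
            r_mean_fold=r_mean / r_mean_ref, r_heterogeneity=r_het))
        if (sid + 1) % 25 == 0:
            log.info("sweep: %d/%d systems done", sid + 1, n_systems)
    df = pd.DataFrame([asdict(r) for r in records], columns=SWEEP_COLUMNS)
    df.attrs["reference_period"] = period_ref
    df.attrs["seed"] = int(seed)
    return df


# ---------------------------------------------------------------------------
# tempo design at fixed heterogeneity
# ---------------------------------------------------------------------------

def design_tempo_sets(reference_params: Optional[ParameterSet] = None,
                      target_mean_folds: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0),
                      n_orbit_points: int = 200,
                      rtol: float = 1e-7, atol: float = 1e-9):
    """Design orbit-preserving parameter sets spanning a range of tempos.

    Each design multiplies every ``r_i`` by one target fold ``c``, which
    changes the mean of the r_i while keeping their coefficient of
    variation exactly — the prefactor becomes (nearly) uniformly scaled
    across genes, so the orbit is preserved while the period stretches by
    approximately ``c``.  Each design is verified by integration: achieved
    period, normalized Fréchet distance to the reference orbit, and an
    ``orbit_preserved`` flag against the package's preservation threshold.

    Returns
    -------
    (designs, table):
        the list of designed :class:`ParameterSet` objects and a DataFrame
        with one verification row per design.
    """
    params_ref = reference_params or default_repressilator_reduced_params()
    target_mean_folds = [float(c) for c in target_mean_folds]
    if any(c <= 0 for c in target_mean_folds):
        raise ParameterError("target folds must be positive")

    model_ref, x0, orbit_ref, period_ref = _reference_cycle(
        params_ref, n_orbit_points, rtol, atol)
    pcols = _protein_columns(model_ref)
    protein_orbit = resample_arclength(orbit_ref.project(pcols), n_orbit_points)
    protein_ref_norm = normalize_orbit(protein_orbit)
    r_keys = [f"r_{i}" for i in GENES]

    designs, rows = [], []
    for c in target_mean_folds:
        params_c = params_ref.scaled(r_keys, c)
        designs.append(params_c)
        _, mpf = _analytic_predictors(params_ref, params_c, protein_orbit)
        row = {"target_fold": c, "predicted_period_fold": 1.0 / mpf,
               "period": float("nan"), "period_fold": float("nan"),
               "orbital_distance": float("nan"), "orbit_preserved": False,
               "design_failure": False,
               "r_heterogeneity": r_statistics(params_c)[1]}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                orbit_c, per = find_limit_cycle(
                    build_repressilator_reduced(params_c), orbit_ref.points[0],
                    transient_periods=12, total_periods=28,
                    n_points=n_orbit_points, period_guess=period_ref / mpf,
                    rtol=rtol, atol=atol)
            prot_c = resample_arclength(orbit_c.project(pcols), n_orbit_points)
            dist = float(frechet_distance(
                protein_ref_norm,
                normalize_orbit(prot_c, mode="reference", reference=protein_orbit),
                closed=True, compute_alignment=False).value)
            row.update(period=float(per.period),
                       period_fold=float(per.period) / period_ref,
                       orbital_distance=dist,
                       orbit_preserved=dist < ORBIT_PRESERVATION_THRESHOLD)
        except NotOscillatoryError:
            row["design_failure"] = True
            log.warning("design fold %.3g: system is not oscillatory", c)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["reference_period"] = period_ref
    return designs, table


# ---------------------------------------------------------------------------
# grid export of swept systems
# ---------------------------------------------------------------------------

def figure_grid_export(sweep_table: pd.DataFrame, selected_ids: Sequence[int],
                       out_dir, reference_params: Optional[ParameterSet] = None,
                       period_bin_tol: float = 0.02,
                       n_orbit_points: int = 200,
                       rtol: float = 1e-7, atol: float = 1e-9) -> dict:
    """Export orbits and trajectories of selected swept systems.

    Systems are arranged on a grid whose rows share a period bin (relative
    tolerance ``period_bin_tol``) and whose columns are ordered by orbital
    distance to the reference.  Each system is re-integrated
    deterministically from the sweep's fold columns; CSVs are written with
    full float precision.
    """
    from .io import write_orbit_csv, write_trajectory_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params_ref = reference_params or default_repressilator_reduced_params()
    model_ref, _, orbit_ref, _ = _reference_cycle(params_ref, n_orbit_points,
                                                  rtol, atol)
    x0 = orbit_ref.points[0]    # same convention as the sweep
    r_keys = [f"r_{i}" for i in GENES]
    r_ref = np.array([params_ref[k] for k in r_keys])

    table = sweep_table.set_index("params_id")
    missing = [i for i in selected_ids if i not in table.index]
    if missing:
        raise KeyError(f"unknown sweep ids: {missing}")

    entries = []
    for sid in selected_ids:
        row = table.loc[sid]
        folds = np.array([row.fold_1, row.fold_2, row.fold_3])
        params = params_ref.with_updates(
            **{k: r_ref[j] * folds[j] for j, k in enumerate(r_keys)})
        model = build_repressilator_reduced(params)
        period_guess = (float(row.period) if np.isfinite(row.period)
                        else None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            orbit, per = find_limit_cycle(model, x0, transient_periods=12,
                                          total_periods=28,
                                          n_points=n_orbit_points,
                                          period_guess=period_guess,
                                          rtol=rtol, atol=atol)
            t_end = 4.0 * per.period
            traj = integrate(model, x0, (0.0, t_end), rtol=rtol, atol=atol,
                             t_eval=np.linspace(0.0, t_end, 2000))
        orbit_path = out_dir / f"system_{sid:05d}_orbit.csv"
        traj_path = out_dir / f"system_{sid:05d}_trajectory.csv"
        write_orbit_csv(normalize_orbit(orbit), orbit_path,
                        species=model.species_names)
        write_trajectory_csv(traj, traj_path, species=model.species_names)
        entries.append({"params_id": int(sid), "period": float(per.period),
                        "orbital_distance": float(row.orbital_distance),
                        "orbit_csv": orbit_path.name,
                        "trajectory_csv": traj_path.name})

    # assign period bins: greedy grouping within relative tolerance
    entries.sort(key=lambda e: e["period"])
    bin_id, last = -1, -np.inf
    for e in entries:
        if e["period"] > last * (1.0 + period_bin_tol):
            bin_id += 1
        e["period_bin"] = bin_id
        last = e["period"]
    for pb in range(bin_id + 1):
        row_entries = sorted((e for e in entries if e["period_bin"] == pb),
                             key=lambda e: e["orbital_distance"])
        for k, e in enumerate(row_entries):
            e["distance_bin"] = k
    grid = {"period_bin_tol": period_bin_tol,
            "systems": sorted(entries, key=lambda e: e["params_id"])}
    import json

    (out_dir / "grid.json").write_text(json.dumps(grid, indent=2, sort_keys=True) + "\n")
    return grid
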