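"""Uptake-kinetics estimation: RMSE objective, evolutionary programming,
per-case fitting and rate-law selection.

The free parameters of the two-compartment uptake model are estimated from
intracellular IS time series by minimizing the root-mean-square error
between simulated and measured mean concentrations at the nine sampling
times.  The optimizer is classical evolutionary programming: each parent
produces one offspring by Gaussian mutation with self-adaptive step sizes
(on a log10 scale, since the parameters span several decades), and
parents + offspring compete in stochastic round-robin tournaments, the
wins-ranked top half surviving.

Four candidate uptake rate laws are fit; the winner is the one with the
lowest mean RMSE over forward validation at all four initial
concentrations (25, 50, 100, 500 µM), ties resolved toward the simpler
law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    CompartmentGeometry,
    EffluxParameters,
    TransportParameters,
    UptakeCase,
)
from .simulate import fitting_scenario

__all__ = [
    "CaseSelection",
    "EPSettings",
    "FitResult",
    "TimeSeriesDataset",
    "DEFAULT_SAMPLE_TIMES_MIN",
    "ep_optimize",
    "fit_uptake_case",
    "rmse",
    "select_best_case",
    "simulate_uptake_curve",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_TIMES_MIN = (1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 45.0)

#: kf_dissociation (s⁻¹) and carrier density (molecules µm⁻²) held fixed
#: when fitting the Michaelis–Menten uptake variants (cases 2–4).
FIXED_KF_DISSOCIATION = 4.181e-4
FIXED_OAT1_DENSITY = 1.15e7


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------


@dataclass
class TimeSeriesDataset:
    """Replicate intracellular IS measurements for one initial concentration.

    ``replicate_values`` has shape (n_times, n_replicates), µM.
    """

    initial_concentration: float
    sample_times_min: np.ndarray
    replicate_values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_times_min = np.asarray(self.sample_times_min, dtype=float)
        self.replicate_values = np.atleast_2d(
            np.asarray(self.replicate_values, dtype=float)
        )
        if np.any(np.diff(self.sample_times_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.replicate_values.shape[0] != self.sample_times_min.size:
            raise ValueError("replicate_values rows must match sample times")
        if np.any(self.replicate_values < 0):
            raise ValueError("replicate concentrations must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[1]

    @property
    def mean_values(self) -> np.ndarray:
        """Per-time replicate mean, the fitting target."""
        return self.replicate_values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: initial_conc_uM, time_min, replicate, is_cell_uM."""
        n_t, n_r = self.replicate_values.shape
        return pd.DataFrame(
            {
                "initial_conc_uM": np.repeat(self.initial_concentration, n_t * n_r),
                "time_min": np.repeat(self.sample_times_min, n_r),
                "replicate": np.tile(np.arange(1, n_r + 1), n_t),
                "is_cell_uM": self.replicate_values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "list[TimeSeriesDataset]":
        """Parse the tidy schema back into one dataset per initial concentration."""
        out = []
        for conc, grp in df.groupby("initial_conc_uM", sort=True):
            wide = grp.pivot(index="time_min", columns="replicate", values="is_cell_uM")
            out.append(
                cls(
                    initial_concentration=float(conc),
                    sample_times_min=wide.index.to_numpy(),
                    replicate_values=wide.to_numpy(),
                )
            )
        return out


def rmse(experimental: np.ndarray, simulated: np.ndarray) -> float:
    """Root-mean-square error between two aligned series (µM)."""
    experimental = np.asarray(experimental, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if experimental.shape != simulated.shape:
        raise ValueError(
            f"series length mismatch: {experimental.shape} vs {simulated.shape}"
        )
    return float(np.sqrt(np.mean((experimental - simulated) ** 2)))


# --------------------------------------------------------------------------
# forward simulation of the uptake experiment (fast path for the optimizer)
# --------------------------------------------------------------------------


def simulate_uptake_curve(
    transport: TransportParameters,
    initial_conc: float,
    sample_times_min: np.ndarray = np.asarray(DEFAULT_SAMPLE_TIMES_MIN),
    efflux: EffluxParameters | None = None,
    geometry: CompartmentGeometry | None = None,
    rel_tol: float = 1e-8,
) -> np.ndarray:
    """Intracellular IS (µM) of the fitting model at the given times (min).

    Evaluates the solver only at the requested sample times, which keeps a
    single call cheap enough for use inside the optimizer's objective.
    """
    spec = fitting_scenario(initial_conc, transport, efflux, geometry)
    times_s = np.asarray(sample_times_min, dtype=float) * 60.0
    sol = solve_ivp(
        spec.rhs_compiled(),
        (0.0, float(times_s[-1])),
        spec.initial_state.to_array(),
        method="LSODA",
        rtol=rel_tol,
        atol=1e-10,
        t_eval=times_s,
    )
    if not sol.success:
        raise RuntimeError(f"uptake simulation failed: {sol.message}")
    return np.clip(sol.y[3], 0.0, None)


# --------------------------------------------------------------------------
# evolutionary programming
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EPSettings:
    """Evolutionary-programming configuration.

    ``bounds`` maps parameter name → (lower, upper); ``initial_guess``
    maps name → starting value (seeded into the initial population).
    Mutation operates on log10-transformed parameters with self-adaptive
    per-parameter step sizes (initially ``sigma0`` decades); survivor
    selection counts wins against ``tournament_q`` random opponents.
    """

    bounds: dict[str, tuple[float, float]]
    initial_guess: dict[str, float]
    generations: int = 200
    population: int = 20
    seed: int = 1
    runs: int = 1
    tournament_q: int = 10
    sigma0: float = 0.3
    sigma_min: float = 1e-3

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population < 1 or self.runs < 1:
            raise ValueError("generations, population and runs must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 < lower < upper")
            guess = self.initial_guess.get(name)
            if guess is not None and not (lo <= guess <= hi):
                raise ValueError(f"initial guess for {name} outside bounds")


#: Search bounds and initial guesses of the three mass-action parameters.
CASE1_EP_SETTINGS = EPSettings(
    bounds={
        "kf_uptake": (5e-7, 1e-3),
        "kf_dissociation": (5e-5, 1e-3),
        "oat1_density_0": (7e5, 2e7),
    },
    initial_guess={
        "kf_uptake": 1e-4,
        "kf_dissociation": 1e-3,
        "oat1_density_0": 5e6,
    },
)

#: Bounds for the Michaelis–Menten variants.  Vmax units differ per case
#: (molecules µm⁻² s⁻¹ for case 2; s⁻¹ for case 3; s⁻¹ µM⁻¹ for case 4),
#: so the spans are wide enough to cover all three scales.
_MM_BOUNDS = {
    UptakeCase.MICHAELIS_MENTEN: {"vmax_case": (1e-2, 1e8), "km_case": (1e-6, 1e4)},
    UptakeCase.MM_TIMES_OAT1: {"vmax_case": (1e-8, 1e2), "km_case": (1e-6, 1e4)},
    UptakeCase.MM_TIMES_C_OAT1: {"vmax_case": (1e-10, 1e0), "km_case": (1e-6, 1e4)},
}


@dataclass
class FitResult:
    """Outcome of one optimization."""

    parameters: dict[str, float]
    objective: float
    trace: np.ndarray  # best-so-far objective per generation
    run_objectives: list[float]  # best objective of each independent run
    n_failed_evaluations: int = 0
    fittable: bool = True
    case: UptakeCase | None = None
    validation_rmse: dict[float, float] | None = None  # initial conc → RMSE

    @property
    def run_spread(self) -> float:
        """Relative spread of best objectives across repeated runs."""
        best = min(self.run_objectives)
        if best == 0:
            return float(max(self.run_objectives) - best)
        return float((max(self.run_objectives) - best) / best)

    def to_dict(self) -> dict:
        return {
            "case": None if self.case is None else int(self.case),
            "parameters": self.parameters,
            "objective": self.objective,
            "fittable": self.fittable,
            "run_objectives": self.run_objectives,
            "n_failed_evaluations": self.n_failed_evaluations,
            "validation_rmse": self.validation_rmse,
        }


def _evaluate(objective, x_log: np.ndarray, names) -> tuple[float, bool]:
    try:
        value = float(objective(dict(zip(names, 10.0 ** x_log))))
    except Exception as exc:  # integration failure → worst fitness
        logger.debug("objective evaluation failed: %s", exc)
        return np.inf, True
    if not np.isfinite(value):
        return np.inf, True
    return value, False


def _population_axis(xs: np.ndarray) -> np.ndarray:
    """Dominant axis (unit vector) of the population cloud in log space.

    The surviving population stretches along any poorly determined
    direction of the objective, so mutating along this axis lets the
    search slide through narrow curved valleys that axis-aligned steps
    cannot follow.  Degenerate clouds yield a zero vector (no extra
    component).
    """
    if xs.shape[0] < 3:
        return np.zeros(xs.shape[1])
    cov = np.cov(xs.T)
    if not np.all(np.isfinite(cov)):
        return np.zeros(xs.shape[1])
    w, v = np.linalg.eigh(np.atleast_2d(cov))
    return v[:, -1] if w[-1] > 0 else np.zeros(xs.shape[1])


def _ep_run(objective, settings: EPSettings, rng: np.random.Generator):
    names = list(settings.bounds)
    lo = np.log10([settings.bounds[n][0] for n in names])
    hi = np.log10([settings.bounds[n][1] for n in names])
    n_dim = len(names)
    pop = settings.population
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(n_dim))
    tau_prime = 1.0 / np.sqrt(2.0 * n_dim)

    xs = rng.uniform(lo, hi, size=(pop, n_dim))
    guess = np.array([settings.initial_guess.get(n, np.nan) for n in names])
    if not np.any(np.isnan(guess)):
        xs[0] = np.log10(guess)
    sigmas = np.full((pop, n_dim), settings.sigma0)
    axis_sigmas = np.full(pop, settings.sigma0)

    n_failed = 0
    fitness = np.empty(pop)
    for i in range(pop):
        fitness[i], failed = _evaluate(objective, xs[i], names)
        n_failed += failed

    best_idx = int(np.argmin(fitness))
    best_x, best_f = xs[best_idx].copy(), fitness[best_idx]
    trace = np.empty(settings.generations)

    for gen in range(settings.generations):
        # one offspring per parent: per-parameter self-adaptive log-normal
        # step sizes plus a self-adaptive step along the population axis
        axis = _population_axis(xs)
        z_global = rng.standard_normal((pop, 1))
        off_sigmas = np.clip(
            sigmas * np.exp(tau_prime * z_global + tau * rng.standard_normal((pop, n_dim))),
            settings.sigma_min, 1.0,
        )
        off_axis_sigmas = np.clip(
            axis_sigmas * np.exp(tau * rng.standard_normal(pop)),
            settings.sigma_min, 1.0,
        )
        steps = (
            off_sigmas * rng.standard_normal((pop, n_dim))
            + off_axis_sigmas[:, None] * rng.standard_normal((pop, 1)) * axis
        )
        off_xs = np.clip(xs + steps, lo, hi)
        off_fitness = np.empty(pop)
        for i in range(pop):
            off_fitness[i], failed = _evaluate(objective, off_xs[i], names)
            n_failed += failed

        all_xs = np.vstack([xs, off_xs])
        all_sigmas = np.vstack([sigmas, off_sigmas])
        all_axis_sigmas = np.concatenate([axis_sigmas, off_axis_sigmas])
        all_fitness = np.concatenate([fitness, off_fitness])

        # stochastic round-robin: wins against q random opponents
        opponents = rng.integers(0, 2 * pop, size=(2 * pop, settings.tournament_q))
        wins = (all_fitness[:, None] <= all_fitness[opponents]).sum(axis=1)
        order = np.lexsort((all_fitness, -wins))
        keep = order[:pop]
        xs, sigmas, fitness = all_xs[keep], all_sigmas[keep], all_fitness[keep]
        axis_sigmas = all_axis_sigmas[keep]

        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_f = fitness[gen_best]
            best_x = xs[gen_best].copy()
        elif np.min(fitness) > best_f:
            # elitism: never lose the best-so-far to tournament noise
            worst = int(np.argmax(fitness))
            xs[worst], fitness[worst] = best_x, best_f
        trace[gen] = best_f

    return dict(zip(names, 10.0 ** best_x)), float(best_f), trace, n_failed


def ep_optimize(objective, settings: EPSettings) -> FitResult:
    """Minimize ``objective`` (callable on a name→value dict) by EP.

    Deterministic given ``settings.seed``.  With ``runs > 1`` the
    optimization is repeated with independent derived seeds and the best
    run is returned; the per-run best objectives (``run_objectives``)
    expose the run-to-run spread used as a stability check.
    """
    master = np.random.default_rng(settings.seed)
    run_seeds = master.integers(0, 2**31 - 1, size=settings.runs)
    results = [
        _ep_run(objective, settings, np.random.default_rng(s)) for s in run_seeds
    ]
    run_objectives = [r[1] for r in results]
    params, best_f, trace, n_failed = results[int(np.argmin(run_objectives))]
    total_failed = sum(r[3] for r in results)
    fittable = np.isfinite(best_f)
    if not fittable:
        logger.warning("optimization produced no finite objective value")
    return FitResult(
        parameters=params,
        objective=best_f,
        trace=trace,
        run_objectives=run_objectives,
        n_failed_evaluations=total_failed,
        fittable=fittable,
    )


# --------------------------------------------------------------------------
# per-case fitting and selection
# --------------------------------------------------------------------------


def _case_transport(case: UptakeCase, params: dict[str, float]) -> TransportParameters:
    if case is UptakeCase.MASS_ACTION:
        return TransportParameters(
            kf_uptake=params["kf_uptake"],
            kf_dissociation=params["kf_dissociation"],
            oat1_density_0=params["oat1_density_0"],
        )
    return TransportParameters(
        kf_uptake=0.0,
        kf_dissociation=FIXED_KF_DISSOCIATION,
        oat1_density_0=FIXED_OAT1_DENSITY,
        uptake_case=case,
        vmax_case=params["vmax_case"],
        km_case=params["km_case"],
    )


def fit_uptake_case(
    case: UptakeCase | int,
    dataset: TimeSeriesDataset,
    settings: EPSettings | None = None,
    sim_rel_tol: float = 1e-8,
) -> FitResult:
    """Fit one uptake rate law to a single-concentration dataset.

    Case 1 frees the three mass-action parameters; cases 2–4 free
    (Vmax, Km) with the dissociation rate and carrier density held at
    their case-1 values.  The objective is the RMSE between the
    replicate-mean intracellular IS and the simulated curve at the
    dataset's sample times.
    """
    case = UptakeCase(case)
    if settings is None:
        settings = CASE1_EP_SETTINGS
    if case is not UptakeCase.MASS_ACTION:
        settings = replace(
            settings,
            bounds=_MM_BOUNDS[case],
            initial_guess={
                "vmax_case": float(np.sqrt(np.prod(_MM_BOUNDS[case]["vmax_case"]))),
                "km_case": 1.0,
            },
        )
    target = dataset.mean_values
    times = dataset.sample_times_min

    def objective(params: dict[str, float]) -> float:
        transport = _case_transport(case, params)
        sim = simulate_uptake_curve(
            transport, dataset.initial_concentration, times, rel_tol=sim_rel_tol
        )
        return rmse(target, sim)

    result = ep_optimize(objective, settings)
    result.case = case
    if not result.fittable:
        logger.warning("case %s could not be fitted", int(case))
    return result


@dataclass
class CaseSelection:
    """Per-case validation RMSE table and overall ranking."""

    table: pd.DataFrame  # columns: case, initial_conc_uM, rmse_uM
    mean_rmse: dict[int, float]
    ranking: list[int]  # fittable cases, best first

    @property
    def best_case(self) -> int:
        return self.ranking[0]


def select_best_case(
    fits: dict[UptakeCase | int, FitResult],
    validation_datasets: list[TimeSeriesDataset],
    sim_rel_tol: float = 1e-8,
) -> CaseSelection:
    """Rank fitted rate laws by mean validation RMSE.

    Each fit is forward-simulated at every validation concentration and
    scored against the replicate means; unfittable cases are excluded
    from the ranking.  Ties resolve toward the lower case index
    (simpler kinetics).
    """
    if not fits:
        raise ValueError("no fits to select from")
    rows = []
    mean_rmse: dict[int, float] = {}
    for case, fit in sorted(fits.items(), key=lambda kv: int(kv[0])):
        case = UptakeCase(case)
        if not fit.fittable:
            continue
        transport = _case_transport(case, fit.parameters)
        per_conc: dict[float, float] = {}
        for ds in validation_datasets:
            try:
                sim = simulate_uptake_curve(
                    transport, ds.initial_concentration, ds.sample_times_min,
                    rel_tol=sim_rel_tol,
                )
                err = rmse(ds.mean_values, sim)
            except RuntimeError:
                err = np.inf
            per_conc[ds.initial_concentration] = err
            rows.append(
                {"case": int(case), "initial_conc_uM": ds.initial_concentration,
                 "rmse_uM": err}
            )
        fit.validation_rmse = per_conc
        mean_rmse[int(case)] = float(np.mean(list(per_conc.values())))
    if not mean_rmse:
        raise ValueError("all cases were unfittable")
    return CaseSelection(pd.DataFrame(rows), mean_rmse, rank_cases(mean_rmse))


def rank_cases(mean_rmse: dict[int, float]) -> list[int]:
    """Order cases by mean RMSE; exact ties go to the lower case index."""
    return sorted(mean_rmse, key=lambda c: (mean_rmse[c], c))
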