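"""Baseline maximum-likelihood parameter estimation and identifiability.

The measurement noise is Gaussian with variance
``sigma^2(x) = sigma_b^2 + sigma_s^2 x^2`` evaluated at the model
prediction ``x`` (that is how the data were generated), so maximising the
likelihood is weighted least squares and goodness of fit is

.. math:: \\chi^2 = \\sum_i (y_i - x_i)^2 / \\sigma^2(x_i)

over all purchased data points.  The pipeline is:

1. closed-form initial guesses from steady-state relations
   (:func:`steady_state_init`, :func:`solve_regulation`);
2. multistart local optimisation from Latin-hypercube starting points in
   log-parameter space (:func:`fit_multistart`);
3. profile likelihood for identifiability and confidence intervals
   (:func:`profile_likelihood`);
4. experiment ranking by ensemble prediction spread per credit
   (:func:`rank_experiments`).

Optimisation works on log10-transformed parameters: positivity is built in
and a factor-x mismatch is the same step everywhere, matching the
geometry of the challenge parameter distance.  Derivatives use finite
differences of the integrated trajectories (no forward sensitivity system
is implemented; the least-squares structure makes the Gauss-Newton
approximation of the Hessian implicit in the trust-region solver).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import qmc

from .lab import (
    Dataset,
    MeasurementRequest,
    NoiseModel,
    Perturbation,
    PriceTable,
    apply_perturbation,
)
from .model import (
    MRNA_PROTEIN,
    IntegrationError,
    ModelInstance,
    ParameterSet,
    TimeGrid,
    mrna_species,
    parameter_ids,
    promoter_id,
    protein_species,
    rbs_id,
    simulate,
    PROTEIN_DEGRADATION,
)

__all__ = [
    "Objective",
    "FitResult",
    "StartResult",
    "ProfileResult",
    "RegulationFit",
    "RankedExperiment",
    "chi2",
    "steady_state_init",
    "solve_regulation",
    "fit_multistart",
    "profile_likelihood",
    "rank_experiments",
]


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _dataset_residuals(
    model: ModelInstance,
    ds: Dataset,
    nm: NoiseModel,
    rtol: float,
    atol: float,
    max_steps: int = 100_000,
) -> np.ndarray:
    perturbed = model
    for p in ds.perturbations:
        perturbed = apply_perturbation(perturbed, p)
    try:
        traj = simulate(
            perturbed, ds.grid, rtol=rtol, atol=atol, max_steps=max_steps
        ).subset(ds.species)
    except IntegrationError as err:
        raise IntegrationError(
            f"while fitting dataset ({ds.technology}, "
            f"perturbations={[p.kind + ':' + p.target for p in ds.perturbations]}): {err}"
        ) from err
    x = traj.values
    if not np.all(np.isfinite(x)):
        raise IntegrationError(
            f"non-finite trajectory for dataset ({ds.technology})"
        )
    sigma = np.sqrt(nm.variance(x))
    return ((ds.values - x) / sigma).ravel()


def chi2(
    model: ModelInstance,
    datasets: Sequence[Dataset],
    nm: NoiseModel | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Weighted least-squares statistic of the model against the datasets.

    Additive over datasets and invariant under permuting data points.
    Equals -2 log L up to the additive constant sum(log 2 pi sigma^2).
    """
    nm = nm or NoiseModel()
    total = 0.0
    for ds in datasets:
        r = _dataset_residuals(model, ds, nm, rtol, atol)
        total += float(np.dot(r, r))
    return total


class Objective:
    """chi-square objective over free parameters in log10 space.

    ``model`` supplies the network, the fixed parameters and initial
    conditions; ``free_params`` (default: all) are replaced by the
    optimisation vector ``x = log10(theta)``.
    """

    def __init__(
        self,
        model: ModelInstance,
        datasets: Sequence[Dataset],
        nm: NoiseModel | None = None,
        free_params: Sequence[str] | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-8,
        max_steps: int = 5000,
    ):
        self.model = model
        self.datasets = tuple(datasets)
        self.nm = nm or NoiseModel()
        self.free = tuple(free_params or parameter_ids(model.spec))
        unknown = set(self.free) - set(model.params)
        if unknown:
            raise ValueError(f"free parameters not in the model: {sorted(unknown)}")
        self.rtol = rtol
        self.atol = atol
        self.max_steps = max_steps

    def params_from_vector(self, x: np.ndarray) -> ParameterSet:
        return self.model.params.replace(
            **{k: 10.0 ** xi for k, xi in zip(self.free, x)}
        )

    def vector_from_params(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array([math.log10(params[k]) for k in self.free])

    def residuals(self, x: np.ndarray) -> np.ndarray:
        model = self.model.with_params(self.params_from_vector(x))
        return np.concatenate(
            [
                _dataset_residuals(
                    model, ds, self.nm, self.rtol, self.atol, self.max_steps
                )
                for ds in self.datasets
            ]
        )

    def chi2(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# steady-state initialisation
# ---------------------------------------------------------------------------

def _approach_shape(t: np.ndarray, delta: float) -> np.ndarray:
    """p(t)/p_ss for induction from zero with mRNA rate 1 and protein rate
    delta: 1 - e^(-dt) - d (e^(-t) - e^(-dt)) / (d - 1), continuous at d=1."""
    if abs(delta - 1.0) < 1e-6:
        return 1.0 - np.exp(-t) * (1.0 + t)
    return (
        1.0
        - np.exp(-delta * t)
        - delta * (np.exp(-t) - np.exp(-delta * t)) / (delta - 1.0)
    )


def _steady_value(values: np.ndarray) -> float:
    # average the last quarter of the course to damp noise
    n = max(1, len(values) // 4)
    return float(np.mean(values[-n:]))


def steady_state_init(
    datasets: Sequence[Dataset], spec, min_level: float = 1e-6
) -> tuple[dict[str, float], list[str]]:
    """Closed-form parameter guesses from wildtype near-steady data.

    Uses the steady-state relations ``m_ss = pro * (regulatory terms)`` and
    ``delta_p * p_ss = rbs * m_ss`` (mRNA degradation is 1).  The shared
    protein degradation rate is fitted to the relaxation of an unregulated
    gene's protein course; promoter strengths assume unit regulatory terms
    where the regulation is unknown.  Returns (guess, warnings); quantities
    that cannot be estimated are simply left out of the guess.
    """
    if spec.model_class != MRNA_PROTEIN:
        raise ValueError("steady-state initialisation targets mrna_protein models")
    warnings: list[str] = []
    wildtype = [ds for ds in datasets if not ds.perturbations]
    if not wildtype:
        return {}, ["no wildtype dataset available"]
    m_ss: dict[str, float] = {}
    p_course: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ds in wildtype:
        for g in spec.gene_ids:
            ms, ps = mrna_species(g), protein_species(g)
            if ms in ds.species:
                m_ss[g] = _steady_value(ds.get(ms))
            if ps in ds.species:
                p_course[g] = (ds.grid.times, ds.get(ps))
    guess: dict[str, float] = {}
    delta = None
    for g in spec.unregulated_genes():
        if g in p_course:
            t, p = p_course[g]
            p_ss = _steady_value(p)
            if p_ss <= min_level:
                continue
            res = minimize_scalar(
                lambda logd: float(
                    np.sum((p - p_ss * _approach_shape(t, 10.0**logd)) ** 2)
                ),
                bounds=(-3.0, 3.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            delta = 10.0**res.x
            guess[PROTEIN_DEGRADATION] = delta
            break
    if delta is None:
        warnings.append(
            "no unregulated gene with measured protein course: "
            "protein degradation rate left unset"
        )
    for g in spec.gene_ids:
        if g in m_ss and m_ss[g] > min_level:
            # unit regulatory terms assumed for regulated genes
            guess[promoter_id(g)] = m_ss[g]
        if delta is not None and g in p_course and g in m_ss and m_ss[g] > min_level:
            p_ss = _steady_value(p_course[g][1])
            if p_ss > min_level:
                guess[rbs_id(g)] = delta * p_ss / m_ss[g]
    if not guess:
        warnings.append("no usable (non-zero) steady-state levels in the data")
    return guess, warnings


@dataclass(frozen=True)
class RegulationFit:
    Kd: float
    h: float
    well_determined: bool
    message: str = ""


def solve_regulation(
    points: Sequence[tuple[float, float]], sign: str = "-"
) -> RegulationFit:
    """Fit (Kd, h) of a Hill regulation from (regulator, term) steady points.

    The Hill relation is linear on the double-log scale: for repression
    ``log((1-f)/f) = h (log P - log Kd)`` and symmetrically for activation,
    so three or more points determine both unknowns by least squares.  The
    fit is flagged poorly determined when the regulator concentrations do
    not bracket the fitted Kd (terms all nearly saturated carry almost no
    information, exactly the regime where a direct gel-shift measurement is
    the only option).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 steady-state points")
    P = np.array([p for p, _ in points], dtype=float)
    f = np.array([v for _, v in points], dtype=float)
    if np.any(P <= 0):
        raise ValueError("regulator concentrations must be > 0")
    if len(np.unique(P)) < 3:
        raise ValueError("regulator concentrations must be distinct")
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("regulatory terms must lie strictly inside (0, 1)")
    y = np.log((1.0 - f) / f) if sign == "-" else np.log(f / (1.0 - f))
    A = np.column_stack([np.log(P), np.ones_like(P)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    if slope <= 0:
        return RegulationFit(
            float("nan"), float(slope), False, "non-positive fitted Hill slope"
        )
    h = float(slope)
    Kd = float(np.exp(-intercept / slope))
    ok = P.min() <= Kd <= P.max()
    msg = "" if ok else (
        f"regulator range [{P.min():.3g}, {P.max():.3g}] does not bracket Kd={Kd:.3g}"
    )
    return RegulationFit(Kd, h, ok, msg)


# ---------------------------------------------------------------------------
# multistart fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StartResult:
    x0: np.ndarray
    x: np.ndarray
    chi2: float
    status: int
    message: str


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    chi2: float
    starts: tuple[StartResult, ...]
    free_params: tuple[str, ...]
    bounds: tuple[float, float]

    @property
    def x(self) -> np.ndarray:
        return np.array([math.log10(self.params[k]) for k in self.free_params])


def _local_fit(
    objective: Objective,
    x0: np.ndarray,
    log_bounds: tuple[np.ndarray, np.ndarray],
    max_nfev: int,
) -> StartResult:
    try:
        res = least_squares(
            objective.residuals,
            np.clip(x0, log_bounds[0], log_bounds[1]),
            bounds=log_bounds,
            method="trf",
            max_nfev=max_nfev,
            x_scale="jac",
            diff_step=1e-3,
        )
        return StartResult(
            x0=np.asarray(x0), x=res.x, chi2=float(2 * res.cost), status=res.status,
            message=res.message,
        )
    except (IntegrationError, ValueError) as err:
        return StartResult(
            x0=np.asarray(x0), x=np.asarray(x0), chi2=float("inf"), status=-1,
            message=str(err),
        )


def fit_multistart(
    model: ModelInstance,
    datasets: Sequence[Dataset],
    nm: NoiseModel | None = None,
    n_starts: int = 50,
    bounds: tuple[float, float] = (1e-3, 1e3),
    rng: np.random.Generator | None = None,
    free_params: Sequence[str] | None = None,
    extra_starts: Sequence[Mapping[str, float]] = (),
    max_nfev: int = 8,
    refine_top: int = 3,
    refine_max_nfev: int = 250,
    rtol: float = 1e-5,
    atol: float = 1e-7,
) -> FitResult:
    """Latin-hypercube multistart minimisation of chi-square.

    ``n_starts`` points are drawn by Latin-hypercube sampling in log10
    parameter space inside ``bounds`` (each parameter's starts occupy
    distinct equal-probability strata).  Every start runs a bounded
    trust-region least-squares pass capped at ``max_nfev`` residual
    evaluations; the best ``refine_top`` are then polished with a larger
    budget.  ``extra_starts`` (e.g. a steady-state initial guess) are
    prepended and also refined when competitive.  Fully deterministic for a
    seeded ``rng``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if not (0 < bounds[0] < bounds[1]):
        raise ValueError("bounds must be finite, positive and increasing")
    rng = rng or np.random.default_rng()
    objective = Objective(
        model, datasets, nm, free_params=free_params, rtol=rtol, atol=atol
    )
    d = len(objective.free)
    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    log_bounds = (np.full(d, lo), np.full(d, hi))
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    x0s = [lo + (hi - lo) * row for row in sampler.random(n=n_starts)]
    for extra in extra_starts:
        merged = dict(model.params)
        merged.update(extra)
        x0s.insert(0, objective.vector_from_params(merged))
    starts = [_local_fit(objective, x0, log_bounds, max_nfev) for x0 in x0s]
    order = np.argsort([s.chi2 for s in starts])
    refined: list[StartResult] = []
    for i in order[: max(1, refine_top)]:
        if math.isfinite(starts[i].chi2):
            refined.append(
                _local_fit(objective, starts[i].x, log_bounds, refine_max_nfev)
            )
    all_results = starts + refined
    finite = [s for s in all_results if math.isfinite(s.chi2)]
    if not finite:
        raise IntegrationError(
            "all starts failed; first message: " + all_results[0].message
        )
    best = min(finite, key=lambda s: s.chi2)
    return FitResult(
        params=objective.params_from_vector(best.x),
        chi2=best.chi2,
        starts=tuple(all_results),
        free_params=objective.free,
        bounds=bounds,
    )


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileResult:
    param_id: str
    values: np.ndarray  # parameter values (linear scale), ascending
    chi2_profile: np.ndarray
    chi2_min: float
    threshold: float
    ci: tuple[float, float]  # nan end(s) when unbounded within the box
    identifiable: bool
    failures: tuple[int, ...] = ()


def _interp_crossing(v0, c0, v1, c1, level):
    """Parameter value where the profile crosses ``level`` between 2 points."""
    if c1 == c0:
        return v1
    w = (level - c0) / (c1 - c0)
    return 10 ** (math.log10(v0) + w * (math.log10(v1) - math.log10(v0)))


def profile_likelihood(
    model: ModelInstance,
    datasets: Sequence[Dataset],
    fit: FitResult,
    param_id: str,
    nm: NoiseModel | None = None,
    n_points: int = 21,
    span_decades: float = 2.0,
    threshold: float = 3.84,
    max_nfev: int = 100,
    max_extra: int = 8,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> ProfileResult:
    """Profile chi-square of one parameter around a converged fit.

    Walks a log10 grid of fixed values outward from the optimum,
    re-optimising all other free parameters at each point (warm-started
    from the neighbouring solution), and extends each side until the
    profile exceeds ``chi2_min + threshold`` or the parameter bound is hit.
    The default threshold 3.84 is the 95% quantile of chi-square with one
    degree of freedom, giving a pointwise 95% confidence interval.  A side
    whose profile stays below threshold all the way to the bound marks the
    parameter non-identifiable (flat or one-sided profile).
    """
    if param_id not in fit.free_params:
        raise ValueError(f"{param_id!r} was not a free parameter of the fit")
    other = [k for k in fit.free_params if k != param_id]
    base_model = model.with_params(fit.params)
    objective = Objective(
        base_model, datasets, nm, free_params=other, rtol=rtol, atol=atol
    )
    lo, hi = math.log10(fit.bounds[0]), math.log10(fit.bounds[1])
    center = math.log10(fit.params[param_id])
    step = 2 * span_decades / (n_points - 1)
    x_center = objective.vector_from_params(fit.params)
    d = len(other)
    log_bounds = (np.full(d, lo), np.full(d, hi))

    def profile_point(logv: float, warm: np.ndarray) -> tuple[float, np.ndarray, bool]:
        fixed = base_model.with_params(
            fit.params.replace(**{param_id: 10.0**logv})
        )
        obj = Objective(fixed, datasets, nm, free_params=other, rtol=rtol, atol=atol)
        if not other:
            return obj.chi2(warm), warm, True
        try:
            res = least_squares(
                obj.residuals, warm, bounds=log_bounds, method="trf",
                max_nfev=max_nfev, x_scale="jac",
            )
            return float(2 * res.cost), res.x, True
        except IntegrationError:
            return float("inf"), warm, False

    sides: dict[int, list[tuple[float, float, bool]]] = {+1: [], -1: []}
    for direction in (+1, -1):
        warm = x_center.copy()
        k = 1
        while True:
            logv = center + direction * k * step
            at_bound = logv <= lo or logv >= hi
            logv = min(max(logv, lo), hi)
            c, warm, ok = profile_point(logv, warm)
            sides[direction].append((10.0**logv, c, ok))
            crossed = c > fit.chi2 + threshold
            past_grid = k >= (n_points - 1) // 2
            if crossed or at_bound or (past_grid and k >= (n_points - 1) // 2 + max_extra):
                break
            k += 1

    pts = (
        [(v, c, ok) for v, c, ok in reversed(sides[-1])]
        + [(fit.params[param_id], fit.chi2, True)]
        + sides[+1]
    )
    values = np.array([v for v, _, _ in pts])
    profile = np.array([c for _, c, _ in pts])
    failures = tuple(i for i, (_, _, ok) in enumerate(pts) if not ok)
    # numerical guard: the profile can never be below the global optimum
    chi2_min = min(fit.chi2, float(np.nanmin(profile)))
    level = chi2_min + threshold

    center_idx = int(np.argmin(np.abs(values - fit.params[param_id])))
    ci_lo = float("nan")
    for i in range(center_idx, 0, -1):
        if profile[i - 1] > level >= profile[i]:
            ci_lo = _interp_crossing(values[i - 1], profile[i - 1], values[i], profile[i], level)
            break
    ci_hi = float("nan")
    for i in range(center_idx, len(values) - 1):
        if profile[i + 1] > level >= profile[i]:
            ci_hi = _interp_crossing(values[i], profile[i], values[i + 1], profile[i + 1], level)
            break
    identifiable = math.isfinite(ci_lo) and math.isfinite(ci_hi)
    return ProfileResult(
        param_id=param_id,
        values=values,
        chi2_profile=profile,
        chi2_min=chi2_min,
        threshold=threshold,
        ci=(ci_lo, ci_hi),
        identifiable=identifiable,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# experiment ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedExperiment:
    perturbations: tuple[Perturbation, ...]
    request: MeasurementRequest
    spread: float
    cost: int
    spread_per_credit: float


def rank_experiments(
    model: ModelInstance,
    ensemble: Sequence[Mapping[str, float]],
    candidates: Sequence[tuple[Sequence[Perturbation], MeasurementRequest]],
    prices: PriceTable | None = None,
    t_end: float = 20.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> list[RankedExperiment]:
    """Rank candidate purchases by ensemble prediction spread per credit.

    ``ensemble`` holds parameter vectors consistent with the current data
    (e.g. collected along profile-likelihood curves).  For each candidate
    the perturbed model is simulated for every ensemble member on the
    technology grid; the spread is the maximum over measured species and
    time points of the ensemble standard deviation.  Experiments whose
    outcome the ensemble already agrees on rank last: measuring them cannot
    reduce uncertainty.
    """
    if not candidates:
        raise ValueError("no candidate experiments")
    if not ensemble:
        raise ValueError("empty parameter ensemble")
    prices = prices or PriceTable()
    from .lab import _measured_species  # shared species resolution

    ranked = []
    for perturbations, request in candidates:
        species = _measured_species(model, request)
        grid = TimeGrid(0.0, t_end, request.step)
        runs = []
        for member in ensemble:
            m = model.with_params(model.params.replace(**dict(member)))
            for p in perturbations:
                m = apply_perturbation(m, p)
            runs.append(simulate(m, grid, rtol=rtol, atol=atol).subset(species).values)
        spread = float(np.max(np.std(np.stack(runs), axis=0)))
        cost = prices.experiment_cost(tuple(perturbations), request)
        ranked.append(
            RankedExperiment(
                tuple(perturbations), request, spread, cost, spread / cost
            )
        )
    return sorted(ranked, key=lambda r: -r.spread_per_credit)
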