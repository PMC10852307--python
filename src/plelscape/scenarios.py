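"""2030 land-demand scenarios: Markov projection, GM(1,1), GMOP programs.

Four demand scenarios are supported:

* **NLD** (natural development): a Markov chain estimated from the latest
  observed transition matrix, applied for the required number of 5-year
  steps.
* **ECD** (economic development): linear program maximizing the economic
  objective F1 subject to per-class area bounds, a total-area equality and
  a population-capacity constraint.
* **ELD** (ecological development): the same constraint set with the
  ecological objective F2.
* **EED** (ecological–economic): weighted-sum scalarization of F1 and F2,
  each normalized by its single-objective optimum (a seeded genetic
  algorithm is available as an alternative solver).

The LP solver is HiGHS via :func:`scipy.optimize.linprog`.  For specs with
strictly ordered positive coefficients the optimum is the greedy vertex:
classes are filled to their upper bounds in decreasing coefficient order
and the residual area falls to the cheapest classes; this property backs
the brute-force oracle used in the tests.

GM(1,1) grey forecasting is included as a utility for constructing demand
bounds from short positive series: first-order accumulation (AGO), a
background series z(k) = 0.5(x¹(k)+x¹(k−1)), least-squares estimation of
the development coefficient a and grey input b, and the exponential
time-response forecast.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linprog

from .plel_core import PLEL_NAMES

DEMAND_TOL = 1e-4


# ---------------------------------------------------------------------------
# Markov projection (NLD)


def estimate_markov(areas_t1: pd.Series, transition: pd.DataFrame) -> pd.DataFrame:
    """Row-stochastic transition probabilities from an area transition matrix.

    Rows with zero area become identity rows (with a warning): a class that
    is absent cannot move.
    """
    P = transition.to_numpy(float).copy()
    rows = P.sum(axis=1)
    for i, s in enumerate(rows):
        if s <= 0:
            warnings.warn(
                f"zero-area row for class {transition.index[i]}; using identity row"
            )
            P[i] = 0.0
            P[i, i] = 1.0
        else:
            P[i] /= s
    return pd.DataFrame(P, index=transition.index, columns=transition.columns)


def project_demand(areas: pd.Series, P: pd.DataFrame, steps: int = 1) -> pd.Series:
    """Project areas forward: demand = areas · Pˢ.  Total area is conserved."""
    a = areas.to_numpy(float)
    M = np.linalg.matrix_power(P.to_numpy(float), steps)
    out = a @ M
    return pd.Series(out, index=areas.index, name=f"demand_{steps}steps")


# ---------------------------------------------------------------------------
# GM(1,1)


@dataclass
class GreyModel:
    """Fitted GM(1,1): development coefficient ``a`` and grey input ``b``."""

    a: float
    b: float
    x0_first: float

    def forecast(self, n_fit: int, horizon: int) -> np.ndarray:
        """Fitted + forecast values of the original series (length
        ``n_fit + horizon``, first entry the observed first value)."""
        k = np.arange(n_fit + horizon)
        if abs(self.a) < 1e-10:
            # degenerate exponential: constant increments b
            x1 = self.x0_first + self.b * k
        else:
            x1 = (self.x0_first - self.b / self.a) * np.exp(-self.a * k) + self.b / self.a
        x0 = np.empty_like(x1)
        x0[0] = self.x0_first
        x0[1:] = np.diff(x1)
        return x0


def gm11_fit(series: np.ndarray) -> GreyModel:
    """Fit GM(1,1) to a strictly positive series of length ≥ 4."""
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1 or len(x0) < 4:
        raise ValueError("GM(1,1) needs a 1-D series of length >= 4")
    if np.any(x0 <= 0):
        raise ValueError("GM(1,1) requires strictly positive values")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z, np.ones(len(z))])
    Y = x0[1:]
    (a, b), *_ = np.linalg.lstsq(B, Y, rcond=None)
    return GreyModel(a=float(a), b=float(b), x0_first=float(x0[0]))


def gm11_forecast(series: np.ndarray, horizon: int) -> np.ndarray:
    """Forecast ``horizon`` steps beyond a positive series via GM(1,1)."""
    model = gm11_fit(series)
    full = model.forecast(len(series), horizon)
    return full[len(series):]


# ---------------------------------------------------------------------------
# Scenario specifications and LP solving


@dataclass
class ScenarioSpec:
    """One GMOP scenario: objective, box bounds, equality and population cap."""

    name: str
    objective: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    total_area: float
    population_coeff: dict[str, float] = field(default_factory=dict)
    population_cap: float | None = None
    classes: tuple[str, ...] = PLEL_NAMES

    def __post_init__(self) -> None:
        for cls in self.classes:
            lo, hi = self.bounds.get(cls, (0.0, np.inf))
            if lo > hi:
                raise ValueError(f"bound lo > hi for class {cls}")
        lo_sum = sum(self.bounds.get(c, (0.0, np.inf))[0] for c in self.classes)
        hi_sum = sum(self.bounds.get(c, (0.0, np.inf))[1] for c in self.classes)
        if not (lo_sum - DEMAND_TOL <= self.total_area <= hi_sum + DEMAND_TOL):
            raise ValueError("total area outside the reachable [sum lo, sum hi] band")

    def vectors(self) -> tuple[np.ndarray, list[tuple[float, float]], np.ndarray]:
        c = np.array([self.objective.get(k, 0.0) for k in self.classes])
        b = [tuple(self.bounds.get(k, (0.0, np.inf))) for k in self.classes]
        p = np.array([self.population_coeff.get(k, 0.0) for k in self.classes])
        return c, b, p


def load_default_spec(objective: str = "economic", name: str | None = None) -> ScenarioSpec:
    """The shipped scenario specification (economic or ecological objective)."""
    ref = importlib.resources.files("plelscape").joinpath("data/scenario_defaults.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return spec_from_config(cfg, objective=objective, name=name)


def spec_from_config(cfg: dict, objective: str = "economic", name: str | None = None) -> ScenarioSpec:
    classes = tuple(cfg["classes"])
    return ScenarioSpec(
        name=name or ("ECD" if objective == "economic" else "ELD"),
        objective=dict(cfg["objectives"][objective]),
        bounds={k: tuple(v) for k, v in cfg["bounds"].items()},
        total_area=float(cfg["total_area"]),
        population_coeff=dict(cfg["population"]["coefficients"]),
        population_cap=float(cfg["population"]["cap"]),
        classes=classes,
    )


def solve_scenario_lp(spec: ScenarioSpec) -> tuple[pd.Series, float]:
    """Exact LP optimum of a scenario: maximize cᵀx subject to Σx = total,
    box bounds and the population constraint.  Returns (demand, objective).
    """
    c, bounds, p = spec.vectors()
    n = len(c)
    A_ub, b_ub = None, None
    if spec.population_cap is not None and np.any(p != 0):
        A_ub, b_ub = [p], [spec.population_cap]
    res = linprog(
        -c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=[np.ones(n)],
        b_eq=[spec.total_area],
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise ValueError(
            f"scenario {spec.name} infeasible under its constraint set: {res.message}"
        )
    demand = pd.Series(res.x, index=list(spec.classes), name=spec.name)
    return demand, float(-res.fun)


def population_slack(spec: ScenarioSpec, demand: pd.Series) -> float:
    """Slack of the population constraint at a demand vector (≥ 0 when met)."""
    _, _, p = spec.vectors()
    if spec.population_cap is None:
        return np.inf
    return float(spec.population_cap - p @ demand.reindex(list(spec.classes)).to_numpy())


def greedy_lp_oracle(spec: ScenarioSpec) -> pd.Series:
    """Independent greedy solution for single-equality + box specs with an
    inactive population constraint: fill classes to upper bounds in
    decreasing coefficient order, then drain back to lower bounds in
    increasing order until the equality holds.  Used as a test oracle."""
    c, bounds, _ = spec.vectors()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x = lo.copy()
    residual = spec.total_area - lo.sum()
    for i in np.argsort(-c, kind="stable"):
        take = min(residual, hi[i] - lo[i])
        x[i] += take
        residual -= take
        if residual <= 1e-9:
            break
    return pd.Series(x, index=list(spec.classes), name=f"{spec.name}_greedy")


def solve_eed(
    f1_spec: ScenarioSpec,
    f2_spec: ScenarioSpec,
    weights: tuple[float, float] = (0.5, 0.5),
) -> tuple[pd.Series, dict]:
    """Weighted-sum scalarization of the two objectives over the shared
    constraint set, each normalized by its single-objective optimum.

    Returns the demand vector and a report with both objective values at
    the EED solution and at the two single-objective extremes.
    """
    d1, f1_star = solve_scenario_lp(f1_spec)
    d2, f2_star = solve_scenario_lp(f2_spec)
    c1, _, _ = f1_spec.vectors()
    c2, _, _ = f2_spec.vectors()
    w1, w2 = weights
    combo = ScenarioSpec(
        name="EED",
        objective={
            k: w1 * f1_spec.objective.get(k, 0.0) / f1_star
            + w2 * f2_spec.objective.get(k, 0.0) / f2_star
            for k in f1_spec.classes
        },
        bounds=f1_spec.bounds,
        total_area=f1_spec.total_area,
        population_coeff=f1_spec.population_coeff,
        population_cap=f1_spec.population_cap,
        classes=f1_spec.classes,
    )
    demand, _ = solve_scenario_lp(combo)
    x = demand.to_numpy()
    report = {
        "F1_at_EED": float(c1 @ x),
        "F2_at_EED": float(c2 @ x),
        "F1_star": f1_star,
        "F2_star": f2_star,
        "F1_at_ELD": float(c1 @ d2.to_numpy()),
        "F2_at_ECD": float(c2 @ d1.to_numpy()),
    }
    return demand, report


def solve_eed_ga(
    f1_spec: ScenarioSpec,
    f2_spec: ScenarioSpec,
    weights: tuple[float, float] = (0.5, 0.5),
    population: int = 80,
    generations: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Seeded real-coded genetic algorithm for the scalarized EED problem.

    Candidates live in the box; the total-area equality is enforced by a
    projection repair (shift shared equally, then clip and re-shift) and
    the population constraint by a quadratic penalty.  Provided for parity
    with GA-based solvers; the LP scalarization is the reference route.
    """
    rng = np.random.default_rng(seed)
    _, f1_star = solve_scenario_lp(f1_spec)
    _, f2_star = solve_scenario_lp(f2_spec)
    c1, bounds, p = f1_spec.vectors()
    c2, _, _ = f2_spec.vectors()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([min(b[1], f1_spec.total_area) for b in bounds])
    w1, w2 = weights
    cap = f1_spec.population_cap or np.inf

    def repair(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, lo, hi)
        for _ in range(50):
            gap = f1_spec.total_area - x.sum()
            if abs(gap) < 1e-6:
                break
            room = (hi - x) if gap > 0 else (x - lo)
            total_room = room.sum()
            if total_room <= 0:
                break
            x = np.clip(x + gap * room / total_room, lo, hi)
        return x

    def fitness(x: np.ndarray) -> float:
        f = w1 * (c1 @ x) / f1_star + w2 * (c2 @ x) / f2_star
        viol = max(0.0, p @ x - cap)
        return f - 1e-6 * viol**2

    pop = np.array([repair(rng.uniform(lo, hi)) for _ in range(population)])
    fit = np.array([fitness(x) for x in pop])
    sigma = 0.1 * (hi - lo + 1e-9)
    for _ in range(generations):
        order = np.argsort(-fit)
        elites = pop[order[: population // 4]]
        children = []
        while len(children) < population - len(elites):
            i, j = rng.integers(0, len(elites), size=2)
            alpha = rng.random()
            child = alpha * elites[i] + (1 - alpha) * elites[j]
            child = child + rng.normal(0, sigma) * (rng.random(len(child)) < 0.3)
            children.append(repair(child))
        pop = np.vstack([elites, children])
        fit = np.array([fitness(x) for x in pop])
        sigma *= 0.985
    best = pop[np.argmax(fit)]
    return pd.Series(best, index=list(f1_spec.classes), name="EED_ga")
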