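"""Driver-based suitability and a patch-growing CA spatial allocator.

This is a reduced-fidelity land-use change allocator in the spirit of
patch-generating CA simulators: a pluggable classifier (random forest by
default) learns per-class conversion suitability from two observed epochs
and a driver stack, oversampling expansion cells (cells whose class
changed), and a cellular automaton then grows and shrinks classes until
per-class areas converge to a demand vector.

Per cell and candidate class the CA score multiplies suitability by the
3×3 neighborhood density of the class (plus a floor so isolated seeds stay
possible) under a geometrically decreasing acceptance threshold; with a
small probability new patches are seeded at suitability-weighted random
cells.  Restricted cells (e.g. a lake protection zone) never change, and a
boolean transition matrix can forbid specific conversions.  Accuracy
against a reference raster is summarized by a confusion matrix with
overall accuracy and Cohen's kappa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .plel_core import (
    CategoricalRaster,
    CODE_TO_NAME,
    PLEL_CODES,
    cross_tabulate,
    tabulate_areas,
)
from .synthetic_data import DriverStack

logger = logging.getLogger(__name__)


@dataclass
class SuitabilityMaps:
    """Per-class conversion probability rasters (normalized per cell)."""

    probabilities: dict[int, np.ndarray]  # class code -> 2-D probability

    def stack(self) -> np.ndarray:
        return np.stack([self.probabilities[c] for c in PLEL_CODES])


def fit_suitability(
    t1: CategoricalRaster,
    t2: CategoricalRaster,
    drivers: DriverStack,
    seed: int = 0,
    n_samples: int = 20_000,
    expansion_boost: float = 3.0,
    classifier: str = "random_forest",
) -> SuitabilityMaps:
    """Learn class suitability from the t1→t2 change and the drivers.

    Training cells are sampled under the shared mask with labels from t2;
    expansion cells (t2 ≠ t1) are oversampled by ``expansion_boost``.  A
    class absent from the training labels receives a uniform prior with a
    warning.  Per-cell probabilities over the 8 classes sum to 1.
    """
    if not t1.same_grid(t2):
        raise ValueError("epoch rasters are not aligned")
    rng = np.random.default_rng(seed)
    mask = t1.mask & t2.mask
    X_all = drivers.feature_matrix(mask)
    y_all = t2.values[mask]
    changed = (t2.values != t1.values)[mask]
    w = np.where(changed, expansion_boost, 1.0)
    n = min(n_samples, len(y_all))
    idx = rng.choice(len(y_all), size=n, replace=False, p=w / w.sum())
    X, y = X_all[idx], y_all[idx]
    if classifier == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=60, min_samples_leaf=5, random_state=seed, n_jobs=1
        )
    elif classifier == "logistic":
        clf = LogisticRegression(max_iter=500, random_state=seed)
    else:
        raise ValueError("classifier must be 'random_forest' or 'logistic'")
    clf.fit(X, y)
    proba = clf.predict_proba(X_all)
    probs: dict[int, np.ndarray] = {}
    trained = set(int(c) for c in clf.classes_)
    missing = [c for c in PLEL_CODES if c not in trained]
    if missing:
        warnings.warn(
            f"classes {missing} absent from training; assigning uniform prior"
        )
    full = np.zeros((len(X_all), len(PLEL_CODES)))
    for j, c in enumerate(PLEL_CODES):
        if c in trained:
            full[:, j] = proba[:, list(clf.classes_).index(c)]
        else:
            # spatially uniform floor, small enough not to distort the
            # calibrated probabilities of the classes that were seen
            full[:, j] = 1e-3
    full /= full.sum(axis=1, keepdims=True)
    for j, c in enumerate(PLEL_CODES):
        grid = np.zeros(t1.shape)
        grid[mask] = full[:, j]
        probs[c] = grid
    return SuitabilityMaps(probabilities=probs)


@dataclass
class CAParams:
    patch_seed_prob: float = 0.02
    decay: float = 0.9
    max_iter: int = 200
    tolerance: float = 0.005  # relative per-class area tolerance
    seed: int = 0
    neighborhood: int = 3
    neighborhood_weight: float = 3.0  # exponent on the density term
    suitability_weight: float = 1.0  # exponent on the suitability term
    temperature: float = 1.0  # scale of the stochastic selection noise
    density_floor: float = 0.02  # keeps isolated seeds possible
    transition_allowed: np.ndarray | None = None  # 8x8 boolean, rows=from


def _density(values: np.ndarray, code: int, size: int) -> np.ndarray:
    return ndimage.uniform_filter((values == code).astype(float), size=size, mode="nearest")


def _plan_flows(
    counts: np.ndarray,
    target: np.ndarray,
    allowed: np.ndarray,
    tol_cells: np.ndarray,
    transition_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Integer i→j conversion plan reaching ``target`` from ``counts``.

    Without ``transition_probs`` the plan is the minimal net flow (donors
    with surplus feed growers with deficits, largest first).  With a
    row-stochastic matrix, gross flows start from the Markov expectation
    counts_i·P_ij — reproducing offsetting exchanges, as a CA–Markov
    allocator does — and are then trimmed/topped up to hit the target.
    """
    flow = np.zeros((8, 8), dtype=int)
    if transition_probs is not None:
        P = np.asarray(transition_probs, dtype=float)
        flow = np.floor(counts[:, None] * P).astype(int)
        np.fill_diagonal(flow, 0)
        flow[~allowed] = 0
        # trim inflows of classes that would overshoot their target
        end = counts - flow.sum(axis=1) + flow.sum(axis=0)
        for j in range(8):
            excess = end[j] - target[j]
            for i in np.argsort(-flow[:, j]):
                if excess < 1.0 or flow[i, j] == 0:
                    break
                cut = int(min(excess, flow[i, j]))
                flow[i, j] -= cut
                excess -= cut
    # close remaining gaps with net flows, largest shortage first
    end = counts - flow.sum(axis=1) + flow.sum(axis=0)
    surplus = np.maximum(end - target, 0.0)
    shortage = np.maximum(target - end, 0.0)
    for j in np.argsort(-shortage):
        need = shortage[j]
        for i in np.argsort(-surplus):
            if need < 1.0 or surplus[i] < 1.0 or not allowed[i, j]:
                continue
            f = int(min(need, surplus[i]))
            flow[i, j] += f
            need -= f
            surplus[i] -= f
        if need > tol_cells[j] and shortage[j] > 0:
            logger.warning(
                "demand for %s short by %.0f cells: no allowed donor",
                CODE_TO_NAME[PLEL_CODES[j]], need,
            )
    return flow


def allocate(
    base: CategoricalRaster,
    demand: pd.Series,
    suitability: SuitabilityMaps,
    restricted: np.ndarray | None = None,
    params: CAParams | None = None,
    transition_probs: np.ndarray | None = None,
) -> CategoricalRaster:
    """Grow/shrink classes from ``base`` until areas match ``demand``.

    ``demand`` is indexed by class name in hm² and must total the valid
    area of ``base`` (±0.5%); a demand below the immutable restricted area
    of a class is rejected before iteration.  ``transition_probs`` (an
    8×8 row-stochastic matrix, e.g. the estimated Markov matrix) switches
    the conversion plan from minimal net flows to Markov-expected gross
    flows.  The run is deterministic under a fixed ``params.seed``.
    """
    params = params or CAParams()
    rng = np.random.default_rng(params.seed)
    if restricted is None:
        restricted = np.zeros(base.shape, dtype=bool)
    cell_area = base.cell_area_hm2
    target_cells = np.array(
        [demand[CODE_TO_NAME[c]] / cell_area for c in PLEL_CODES]
    )
    n_valid = int(base.mask.sum())
    if abs(target_cells.sum() - n_valid) > max(0.005 * n_valid, 1.0):
        raise ValueError(
            f"demand total {target_cells.sum() * cell_area:.1f} hm2 does not match "
            f"valid area {n_valid * cell_area:.1f} hm2"
        )
    # Restricted feasibility: immutable cells put a floor under each class.
    frozen = restricted & base.mask
    for j, c in enumerate(PLEL_CODES):
        locked = int(((base.values == c) & frozen).sum())
        if target_cells[j] + 0.5 < locked:
            raise ValueError(
                f"demand for {CODE_TO_NAME[c]} ({demand[CODE_TO_NAME[c]]:.1f} hm2) is below "
                f"its immutable restricted area ({locked * cell_area:.1f} hm2)"
            )
    allowed = params.transition_allowed
    if allowed is None:
        allowed = np.ones((8, 8), dtype=bool)
    suit = suitability.stack()
    values = base.values.copy()
    tol_cells = np.maximum(params.tolerance * np.maximum(target_cells, 1.0), 0.5)
    # One transportation plan up front (donors with surplus feed growers with
    # deficits), executed over rounds with a geometric acceptance schedule:
    # round t converts a (1 - decay^t) share of each remaining flow, with the
    # neighborhood density recomputed in between so conversions grow patches.
    # A converted cell is frozen for the rest of the run, so no cell is
    # shuffled through a chain of classes.
    counts = np.array([((values == c) & base.mask).sum() for c in PLEL_CODES], float)
    flow = _plan_flows(counts, target_cells, allowed, tol_cells, transition_probs)
    done = np.zeros(base.shape, dtype=bool)
    threshold = params.decay
    for _ in range(params.max_iter):
        if flow.sum() == 0:
            break
        frac = 1.0 - threshold
        for i in rng.permutation(8):
            for j in rng.permutation(8):
                if flow[i, j] == 0:
                    continue
                code_i, code_j = PLEL_CODES[i], PLEL_CODES[j]
                pool = np.flatnonzero(
                    ((values == code_i) & base.mask & ~frozen & ~done).ravel()
                )
                if pool.size == 0:
                    flow[i, j] = 0
                    continue
                take = min(max(int(flow[i, j] * frac), 1), pool.size, flow[i, j])
                dens = _density(values, code_j, params.neighborhood).ravel()[pool]
                s = suit[j].ravel()[pool]
                score = (
                    s ** params.suitability_weight
                    * (dens + params.density_floor) ** params.neighborhood_weight
                )
                key = np.log(score + 1e-12) + params.temperature * rng.gumbel(size=pool.size)
                # a small share of conversions seed new patches at
                # suitability-weighted cells, ignoring the neighborhood
                n_seed = rng.binomial(take, params.patch_seed_prob)
                n_grow = take - n_seed
                if take >= pool.size:
                    chosen = pool
                else:
                    grow = pool[np.argpartition(key, -n_grow)[-n_grow:]] if n_grow else pool[:0]
                    if n_seed:
                        seed_key = np.log(s + 1e-12) + rng.gumbel(size=pool.size)
                        seed_sel = pool[np.argpartition(seed_key, -n_seed)[-n_seed:]]
                        chosen = np.unique(np.concatenate([grow, seed_sel]))
                    else:
                        chosen = grow
                values.ravel()[chosen] = code_j
                done.ravel()[chosen] = True
                flow[i, j] -= len(chosen)
        threshold *= params.decay
    counts = np.array([((values == c) & base.mask).sum() for c in PLEL_CODES], float)
    if np.any(np.abs(target_cells - counts) > tol_cells):
        logger.warning("CA finished outside demand tolerance")
    return base.copy(values=values, epoch_label=f"{base.epoch_label}+alloc")


def confusion_kappa(
    pred: CategoricalRaster, truth: CategoricalRaster
) -> tuple[pd.DataFrame, float, float]:
    """Confusion matrix (rows = truth, cols = predicted), OA and kappa.

    OA = trace/total; kappa = (p_o − p_e)/(1 − p_e) with p_e from the
    row×column marginal products.
    """
    if not pred.same_grid(truth):
        raise ValueError("rasters are not aligned")
    mask = pred.mask & truth.mask
    k = len(PLEL_CODES)
    t = truth.values[mask] - 1
    p = pred.values[mask] - 1
    cm = np.bincount(t * k + p, minlength=k * k).reshape(k, k).astype(float)
    total = cm.sum()
    po = np.trace(cm) / total
    pe = (cm.sum(axis=1) @ cm.sum(axis=0)) / total**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    names = [CODE_TO_NAME[c] for c in PLEL_CODES]
    return pd.DataFrame(cm, index=names, columns=names), float(po), float(kappa)


def self_validation(
    series: list[CategoricalRaster],
    drivers: DriverStack,
    restricted: np.ndarray | None = None,
    seed: int = 0,
    params: CAParams | None = None,
) -> dict:
    """Hindcast check: fit suitability on epochs 0→1, allocate the observed
    epoch-2 demand starting from epoch 1, and score against the true epoch
    2 and a persistence (no-change) baseline."""
    if len(series) < 3:
        raise ValueError("need at least 3 epochs")
    t0, t1, t2 = series[0], series[1], series[2]
    suit = fit_suitability(t0, t1, drivers, seed=seed)
    demand = tabulate_areas(t2)
    params = params or CAParams(seed=seed)
    xt = cross_tabulate(t0, t1).to_numpy()
    rows = xt.sum(axis=1, keepdims=True)
    P_est = np.where(rows > 0, xt / np.where(rows == 0, 1, rows), np.eye(8))
    sim = allocate(
        t1, demand, suit, restricted=restricted, params=params,
        transition_probs=P_est,
    )
    _, oa_sim, kappa_sim = confusion_kappa(sim, t2)
    _, oa_base, kappa_base = confusion_kappa(t1, t2)
    return {
        "kappa_sim": kappa_sim,
        "oa_sim": oa_sim,
        "kappa_persistence": kappa_base,
        "oa_persistence": oa_base,
        "simulated": sim,
    }
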