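"""Coupling coordination of production / living / ecological tier risks.

For each evaluation unit the tier risks U1 (production), U2 (living) and
U3 (ecological) are combined into

    coupling degree      C = [1 − sqrt(((U3−U1)² + (U3−U2)² + (U2−U1)²)/3)]
                             × (Ua/Umax) × (Ub/Umax)
    comprehensive index  T = α1·U1 + α2·U2 + α3·U3     (α = 0.3 each)
    coordination degree  D = sqrt(C·T)

where Umax is the largest of the three risks and Ua, Ub the other two, so
both ratio factors are ≤ 1 and C ∈ [0, 1]: C is 1 when the three risks are
equal and positive, and 0 when any tier is absent.  The α weights are kept
at 0.3/0.3/0.3 (summing to 0.9) as printed.  D is classified into five
coordination levels with upper-inclusive breaks:

    severe disorder        D ≤ 0.0093
    moderate disorder      0.0093 < D ≤ 0.017
    basic coordination     0.017 < D ≤ 0.025
    moderate coordination  0.025 < D ≤ 0.034
    high coordination      D > 0.034

``coordination_degree`` also offers ``form="product"`` (D = C·T); at the
risk magnitudes this analysis produces (U ≈ 0.001–0.01) the product form
cannot reach the upper coordination classes, which is why the root form is
the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_ALPHA = (0.3, 0.3, 0.3)
DEFAULT_CCD_THRESHOLDS = (0.0093, 0.017, 0.025, 0.034)
CCD_LABELS = (
    "severe disorder",
    "moderate disorder",
    "basic coordination",
    "moderate coordination",
    "high coordination",
)


def coupling_degree(u1: float, u2: float, u3: float, denominator: str = "max") -> float:
    """Coupling degree C of the three tier risks, clamped to [0, 1].

    ``denominator="max"`` (default) divides the two smaller risks by the
    largest, making C symmetric in its arguments; ``"ecological"`` divides
    by the literal U3.
    """
    u = np.asarray([u1, u2, u3], dtype=float)
    if np.any(u < 0):
        raise ValueError("tier risks must be nonnegative")
    if np.all(u == 0):
        return 0.0
    disp = np.sqrt(((u[2] - u[0]) ** 2 + (u[2] - u[1]) ** 2 + (u[1] - u[0]) ** 2) / 3.0)
    if denominator == "max":
        den = u.max()
        others = np.sort(u)[:2]
    elif denominator == "ecological":
        den = u[2]
        others = u[:2]
    else:
        raise ValueError("denominator must be 'max' or 'ecological'")
    if den == 0:
        return 0.0
    c = (1.0 - disp) * (others[0] / den) * (others[1] / den)
    return float(np.clip(c, 0.0, 1.0))


def comprehensive_index(
    u1: float, u2: float, u3: float, alpha: tuple[float, float, float] = DEFAULT_ALPHA
) -> float:
    """Comprehensive security index T = α1·U1 + α2·U2 + α3·U3."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0):
        raise ValueError("alpha weights must be nonnegative")
    return float(a[0] * u1 + a[1] * u2 + a[2] * u3)


def coordination_degree(c: float, t: float, form: str = "sqrt") -> float:
    """Coordination degree D from coupling C and comprehensive index T."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    if t < 0:
        raise ValueError("T must be nonnegative")
    if form == "sqrt":
        return float(np.sqrt(c * t))
    if form == "product":
        return float(c * t)
    raise ValueError("form must be 'sqrt' or 'product'")


def classify_ccd(
    d: float,
    thresholds: tuple[float, ...] = DEFAULT_CCD_THRESHOLDS,
    labels: tuple[str, ...] = CCD_LABELS,
) -> str:
    """Coordination level of D; boundaries are upper-inclusive."""
    t = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    idx = int(np.searchsorted(t, d, side="left"))
    return labels[idx]


def compute_ccd_table(
    unit_table: pd.DataFrame,
    alpha: tuple[float, float, float] = DEFAULT_ALPHA,
    form: str = "sqrt",
    denominator: str = "max",
    thresholds: tuple[float, ...] = DEFAULT_CCD_THRESHOLDS,
) -> pd.DataFrame:
    """Per-unit C, T, D and coordination level from a unit risk table.

    Expects columns U1, U2, U3 (tier risks); centroid columns, when
    present, are carried through so the D field can be kriged like ERI.
    """
    recs = []
    for uid, row in unit_table.iterrows():
        c = coupling_degree(row["U1"], row["U2"], row["U3"], denominator=denominator)
        t = comprehensive_index(row["U1"], row["U2"], row["U3"], alpha=alpha)
        d = coordination_degree(c, t, form=form)
        recs.append(
            {
                "unit_id": uid,
                "U1": row["U1"], "U2": row["U2"], "U3": row["U3"],
                "C": c, "T": t, "D": d,
                "level": classify_ccd(d, thresholds=thresholds),
            }
        )
    df = pd.DataFrame(recs).set_index("unit_id")
    for col in ("centroid_x", "centroid_y"):
        if col in unit_table.columns:
            df[col] = unit_table[col]
    return df
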