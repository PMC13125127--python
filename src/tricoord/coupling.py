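"""Coupling degree, coordination index and coupling coordination degree (CCD).

For three subsystem development indices U1, U2, U3 in [0, 1]:

    C = 3 * (U1*U2*U3)^(1/3) / (U1 + U2 + U3)       coupling degree
    T = alpha*U1 + beta*U2 + lam*U3                 coordination index
    D = sqrt(C * T)                                 coupling coordination degree

C measures how similar in magnitude the three scores are (AM-GM: C = 1 iff
all equal, 0 if any score is 0); T measures their overall level; D combines
both and is classified into ten named intervals from "Extreme imbalance"
(D < 0.1) to "Excellent coordination" (D >= 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CompletenessError, InvalidConfigError, UndefinedCouplingError

#: Ten-level classification of D: left-closed, right-open intervals; the top
#: interval is closed at 1 so that the attainable maximum D = 1 classifies.
LEVELS: list[tuple[float, float, str]] = [
    (0.0, 0.1, "Extreme imbalance"),
    (0.1, 0.2, "Severe imbalance"),
    (0.2, 0.3, "Moderate imbalance"),
    (0.3, 0.4, "Mild imbalance"),
    (0.4, 0.5, "Borderline imbalance"),
    (0.5, 0.6, "Barely coordinated"),
    (0.6, 0.7, "Basic coordination"),
    (0.7, 0.8, "Intermediate coordination"),
    (0.8, 0.9, "Good coordination"),
    (0.9, 1.0, "Excellent coordination"),
]

_CUTS = np.array([hi for _, hi, _ in LEVELS[:-1]])
_LABELS = np.array([label for _, _, label in LEVELS])

TRAJECTORY_GROUPS = ("Leading", "Advantageous", "CatchingUp", "Lagging")


@dataclass
class CouplingConfig:
    """Weights of the coordination index T; default equal thirds."""

    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    lam: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        w = np.array([self.alpha, self.beta, self.lam], dtype=float)
        if (w < 0).any():
            raise InvalidConfigError("coordination weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-10:
            raise InvalidConfigError(
                f"coordination weights must sum to 1, got {w.sum()!r}"
            )


def coupling_degree(u1, u2, u3):
    """Coupling degree C = 3 (U1 U2 U3)^(1/3) / (U1+U2+U3).

    Accepts scalars or arrays. C = 0 whenever any score is zero; the
    all-zero case (0/0) is undefined and raises.
    """
    u1, u2, u3 = np.asarray(u1, float), np.asarray(u2, float), np.asarray(u3, float)
    if (u1 < 0).any() or (u2 < 0).any() or (u3 < 0).any():
        raise InvalidConfigError("subsystem scores must be nonnegative")
    total = u1 + u2 + u3
    if np.any(total == 0):
        raise UndefinedCouplingError("coupling undefined: all subsystem scores zero")
    c = 3.0 * np.cbrt(u1 * u2 * u3) / total
    return c if c.ndim else float(c)


def coordination_degree(u1, u2, u3, cfg: CouplingConfig | None = None) -> pd.DataFrame:
    """Full coupling record: C, T, D and the ten-level label."""
    cfg = cfg or CouplingConfig()
    u1, u2, u3 = np.atleast_1d(u1), np.atleast_1d(u2), np.atleast_1d(u3)
    c = np.atleast_1d(coupling_degree(u1, u2, u3))
    t = cfg.alpha * u1 + cfg.beta * u2 + cfg.lam * u3
    d = np.sqrt(c * t)
    return pd.DataFrame({"C": c, "T": t, "D": d, "level": classify_level(d)})


def classify_level(d):
    """Map D in [0, 1] to its ten-level label (left-closed intervals)."""
    arr = np.atleast_1d(np.asarray(d, float))
    if (arr < 0).any() or (arr > 1).any():
        raise InvalidConfigError(f"D outside [0, 1]: {arr[(arr < 0) | (arr > 1)]}")
    idx = np.searchsorted(_CUTS, arr, side="right")
    labels = _LABELS[idx]
    return labels if np.ndim(d) else str(labels[0])


def average_annual_growth(first: float, last: float, n_intervals: int) -> float:
    """Geometric average annual growth rate in percent (CAGR).

    100 * ((last/first)^(1/n_intervals) - 1) over ``n_intervals`` year
    steps (a 2013-2023 series has 10 intervals).
    """
    if first <= 0:
        raise InvalidConfigError("growth rate needs a positive starting value")
    if n_intervals < 1:
        raise InvalidConfigError("n_intervals must be >= 1")
    return 100.0 * ((last / first) ** (1.0 / n_intervals) - 1.0)


def trajectory_groups(
    ccd: pd.DataFrame,
    year_first: int,
    year_last: int,
    rule=None,
) -> pd.Series:
    """Group units into Leading / Advantageous / CatchingUp / Lagging.

    Default rule: quartiles of final-year D — the top quartile of units is
    Leading, then Advantageous, then CatchingUp, bottom quartile Lagging.
    Ties broken deterministically by unit id (ascending id wins the higher
    group). ``rule`` may be a callable (DataFrame indexed by unit with
    columns D_first, D_last) -> Series of labels, replacing the default.

    ``ccd`` is a DataFrame with (unit, year) index or columns and a column D.
    """
    tbl = ccd.reset_index() if "unit" not in ccd.columns else ccd.copy()
    need = {"unit", "year", "D"}
    if not need <= set(tbl.columns):
        raise InvalidConfigError(f"ccd panel must have columns {sorted(need)}")
    units = sorted(tbl["unit"].unique())
    frame = {}
    for tag, year in (("D_first", year_first), ("D_last", year_last)):
        snap = tbl.loc[tbl["year"] == year].set_index("unit")["D"]
        missing = set(units) - set(snap.index)
        if missing:
            raise CompletenessError(
                f"units missing year {year}: {sorted(missing)}"
            )
        frame[tag] = snap.reindex(units)
    snap = pd.DataFrame(frame)
    if rule is not None:
        return rule(snap)
    order = snap.sort_values(["D_last", "unit"], ascending=[False, True]).index
    chunks = np.array_split(np.arange(len(order)), 4)
    labels = pd.Series(index=order, dtype=object, name="group")
    for chunk, name in zip(chunks, TRAJECTORY_GROUPS):
        labels.iloc[chunk] = name
    return labels.reindex(units)


class CouplingCoordination(BaseEstimator, TransformerMixin):
    """Transformer: subsystem scores (U1..U3) -> coupling records.

    Stateless apart from its T-weights; ``transform`` returns a DataFrame
    with columns C, T, D, level aligned to the input index. Input columns
    must be the three subsystem scores in (healthcare, insurance, pharma)
    order.
    """

    def __init__(self, alpha: float = 1 / 3, beta: float = 1 / 3, lam: float = 1 / 3):
        self.alpha = alpha
        self.beta = beta
        self.lam = lam

    def fit(self, X, y=None):
        self.config_ = CouplingConfig(self.alpha, self.beta, self.lam)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != 3:
            raise InvalidConfigError("expected exactly three subsystem score columns")
        rec = coordination_degree(arr[:, 0], arr[:, 1], arr[:, 2], self.config_)
        rec.index = X.index if hasattr(X, "index") else rec.index
        return rec
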