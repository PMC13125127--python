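"""Composite subsystem development indices.

Indicators of each health subsystem (healthcare delivery, medical insurance,
pharmaceutical sector) are min-max standardized with their direction applied
(negative-direction indicators are reflected so that larger always means
better), weighted objectively, and aggregated into one development index per
subsystem and unit-year:

    U_i = sum_j W_j * X'_ij,    sum_j W_j = 1 within the subsystem block.

The default weighting is CRITIC: an indicator's weight is proportional to its
information capacity I_j = sigma_j * c_j, the product of its contrast
intensity (sample standard deviation of the standardized column) and its
conflict with the other indicators of the block, c_j = sum_k (1 - r_jk) over
Pearson correlations. Entropy weighting is provided as a robustness
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateIndicatorError, InvalidConfigError, UndefinedWeightsError

SUBSYSTEMS = ("healthcare", "insurance", "pharma")

PANEL_COLUMNS = ["unit", "year", "indicator", "value"]


@dataclass
class IndicatorSchema:
    """Maps each indicator id to its subsystem, dimension and direction."""

    table: pd.DataFrame  # columns: indicator, subsystem, dimension, direction

    def __post_init__(self) -> None:
        required = {"indicator", "subsystem", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidConfigError(f"schema missing columns: {sorted(missing)}")
        if self.table["indicator"].duplicated().any():
            dupes = self.table.loc[self.table["indicator"].duplicated(), "indicator"]
            raise InvalidConfigError(f"duplicate indicator ids: {list(dupes)}")
        bad_dir = ~self.table["direction"].isin(["+", "-"])
        if bad_dir.any():
            raise InvalidConfigError(
                f"directions must be '+' or '-', got "
                f"{sorted(self.table.loc[bad_dir, 'direction'].unique())}"
            )
        bad_sub = ~self.table["subsystem"].isin(SUBSYSTEMS)
        if bad_sub.any():
            raise InvalidConfigError(
                f"unknown subsystems: {sorted(self.table.loc[bad_sub, 'subsystem'].unique())}"
            )

    @property
    def indicators(self) -> list[str]:
        return list(self.table["indicator"])

    def direction(self, indicator: str) -> str:
        return self.table.set_index("indicator").loc[indicator, "direction"]

    def block(self, subsystem: str) -> list[str]:
        sel = self.table["subsystem"] == subsystem
        return list(self.table.loc[sel, "indicator"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndicatorSchema":
        return cls(pd.read_csv(path, comment="#"))


def panel_to_wide(panel: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (unit, year, indicator, value) panel to unit-year rows."""
    wide = panel.pivot_table(
        index=["unit", "year"], columns="indicator", values="value", aggfunc="first"
    )
    wide.columns.name = None
    return wide.sort_index()


def standardize(
    panel: pd.DataFrame,
    schema: IndicatorSchema,
    pool: str = "panel",
) -> pd.DataFrame:
    """Min-max standardize every indicator with its direction applied.

    Positive-direction indicators map through (x - min) / (max - min),
    negative-direction ones through (max - x) / (max - min), so the
    standardized value is always "larger is better" and spans exactly [0, 1]
    within the pool.

    Parameters
    ----------
    panel : long-format DataFrame with columns unit, year, indicator, value.
    schema : indicator metadata providing the direction of each indicator.
    pool : "panel" standardizes each indicator over all units and years
        jointly (scores comparable over time, the default); "year"
        standardizes within each year separately.

    Returns
    -------
    Wide DataFrame indexed by (unit, year) of standardized values in [0, 1].
    """
    if pool not in ("panel", "year"):
        raise InvalidConfigError(f"pool must be 'panel' or 'year', got {pool!r}")
    wide = panel_to_wide(panel)
    missing = set(wide.columns) - set(schema.indicators)
    if missing:
        raise InvalidConfigError(f"indicators absent from schema: {sorted(missing)}")
    out = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)

    def _std_block(block: pd.DataFrame) -> pd.DataFrame:
        lo = block.min(axis=0)
        hi = block.max(axis=0)
        rng = hi - lo
        degenerate = rng <= 0
        if degenerate.any():
            names = list(block.columns[degenerate])
            raise DegenerateIndicatorError(
                f"constant indicator(s) within pool: {names}"
            )
        res = (block - lo) / rng
        for ind in block.columns:
            if schema.direction(ind) == "-":
                res[ind] = 1.0 - res[ind]
        return res

    if pool == "panel":
        out.loc[:, :] = _std_block(wide)
    else:
        for year, grp in wide.groupby(level="year"):
            out.loc[grp.index, :] = _std_block(grp).values
    return out


@dataclass
class CriticDiagnostics:
    """Per-indicator weight computation artifacts for one subsystem block.

    ``info`` is exactly ``sigma * conflict`` and ``weights`` is ``info``
    normalized to sum to one over the block.
    """

    sigma: pd.Series
    corr: pd.DataFrame
    conflict: pd.Series
    info: pd.Series
    weights: pd.Series
    method: str = "critic"
    warnings_: list = field(default_factory=list)


def critic_weights(std: pd.DataFrame, block: list[str] | None = None) -> CriticDiagnostics:
    """CRITIC objective weights for one indicator block.

    sigma_j is the sample standard deviation (m-1 denominator) of the
    standardized column; conflict c_j sums (1 - r_jk) over every indicator of
    the block including j itself (the self term contributes zero); the weight
    is I_j / sum I_j with I_j = sigma_j * c_j.
    """
    cols = list(block) if block is not None else list(std.columns)
    X = std[cols]
    if len(cols) == 1:
        w = pd.Series([1.0], index=cols)
        msg = f"single-indicator block {cols[0]!r}: weight fixed at 1"
        warnings.warn(msg, stacklevel=2)
        sig = X.std(ddof=1)
        one = pd.Series([0.0], index=cols)
        return CriticDiagnostics(
            sigma=sig, corr=pd.DataFrame(1.0, index=cols, columns=cols),
            conflict=one, info=one, weights=w, warnings_=[msg],
        )
    sigma = X.std(ddof=1)
    corr = X.corr(method="pearson")
    if corr.isna().any().any():
        bad = list(corr.columns[corr.isna().any()])
        raise DegenerateIndicatorError(
            f"zero-variance column(s) in block break correlations: {bad}"
        )
    conflict = (1.0 - corr).sum(axis=0)
    info = sigma * conflict
    total = info.sum()
    if not np.isfinite(total) or total <= 0:
        raise UndefinedWeightsError(
            "all indicators in the block carry zero information capacity"
        )
    weights = info / total
    return CriticDiagnostics(sigma=sigma, corr=corr, conflict=conflict,
                             info=info, weights=weights)


def entropy_weights(
    std: pd.DataFrame, block: list[str] | None = None, offset: float = 1e-6
) -> CriticDiagnostics:
    """Entropy-method weights (robustness alternative to CRITIC).

    Shares p_ij are computed from standardized values shifted by a small
    offset (entropy is undefined at zero); entropy e_j = -(1/ln m) sum p ln p
    and the weight is proportional to the divergence 1 - e_j.
    """
    cols = list(block) if block is not None else list(std.columns)
    X = std[cols].to_numpy(dtype=float) + offset
    m = X.shape[0]
    p = X / X.sum(axis=0, keepdims=True)
    entropy = -(p * np.log(p)).sum(axis=0) / np.log(m)
    diver = 1.0 - entropy
    diver = np.where(np.abs(diver) < 1e-15, 0.0, diver)
    total = diver.sum()
    if total <= 0:
        raise UndefinedWeightsError("all indicators have unit entropy; weights undefined")
    w = pd.Series(diver / total, index=cols)
    ent = pd.Series(entropy, index=cols)
    return CriticDiagnostics(
        sigma=ent,  # entropy stored in the dispersion slot for inspection
        corr=pd.DataFrame(np.nan, index=cols, columns=cols),
        conflict=pd.Series(diver, index=cols),
        info=pd.Series(diver, index=cols),
        weights=w,
        method="entropy",
    )


def composite_scores(
    std: pd.DataFrame,
    schema: IndicatorSchema,
    diagnostics: dict[str, CriticDiagnostics],
) -> pd.DataFrame:
    """Aggregate standardized indicators into per-subsystem indices U1..U3.

    Each subsystem score is the weight-weighted sum of its standardized
    indicators, a convex combination, hence in [0, 1].
    """
    out = {}
    for sub in SUBSYSTEMS:
        block = schema.block(sub)
        if not block:
            continue
        diag = diagnostics.get(sub)
        if diag is None or set(diag.weights.index) != set(block):
            raise InvalidConfigError(
                f"weights for subsystem {sub!r} do not cover its indicators"
            )
        w = diag.weights.reindex(block)
        out[sub] = std[block].to_numpy() @ w.to_numpy()
    return pd.DataFrame(out, index=std.index)


class SubsystemIndex(BaseEstimator, TransformerMixin):
    """Transformer: indicator panel -> subsystem development indices.

    ``fit`` standardizes its input panel and learns the per-subsystem-block
    objective weights; ``transform`` standardizes the given panel (with the
    configured pool) and aggregates it with the fitted weights to one score
    per subsystem and unit-year. The usual call is ``fit_transform`` on the
    whole study panel.

    Parameters
    ----------
    schema : IndicatorSchema
    method : {"critic", "entropy"}
    pool : {"panel", "year"} standardization pool.

    Attributes
    ----------
    diagnostics_ : dict of subsystem -> CriticDiagnostics
    weights_ : Series of per-indicator weights (block-normalized)
    std_ : standardized training panel (wide, unit-year index)
    scores_ : subsystem scores of the training panel
    """

    def __init__(self, schema: IndicatorSchema | None = None,
                 method: str = "critic", pool: str = "panel"):
        self.schema = schema
        self.method = method
        self.pool = pool

    def fit(self, X: pd.DataFrame, y=None) -> "SubsystemIndex":
        if self.schema is None:
            raise InvalidConfigError("SubsystemIndex requires a schema")
        if self.method not in ("critic", "entropy"):
            raise InvalidConfigError(f"unknown weighting method {self.method!r}")
        std = standardize(X, self.schema, pool=self.pool)
        weigh = critic_weights if self.method == "critic" else entropy_weights
        self.diagnostics_ = {
            sub: weigh(std, self.schema.block(sub))
            for sub in SUBSYSTEMS
            if self.schema.block(sub)
        }
        self.weights_ = pd.concat([d.weights for d in self.diagnostics_.values()])
        self.std_ = std
        self.scores_ = composite_scores(std, self.schema, self.diagnostics_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "diagnostics_"):
            raise EstimationErrorNotFitted()
        std = standardize(X, self.schema, pool=self.pool)
        return composite_scores(std, self.schema, self.diagnostics_)

    def weight_table(self) -> pd.DataFrame:
        """Per-indicator weight table in the published layout."""
        rows = []
        meta = self.schema.table.set_index("indicator")
        for sub, diag in self.diagnostics_.items():
            for ind, w in diag.weights.items():
                rows.append({
                    "subsystem": sub,
                    "dimension": meta.loc[ind].get("dimension", ""),
                    "indicator": ind,
                    "weight": w,
                    "direction": meta.loc[ind, "direction"],
                })
        return pd.DataFrame(rows)


class EstimationErrorNotFitted(RuntimeError):
    def __init__(self):
        super().__init__("SubsystemIndex is not fitted; call fit first")
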