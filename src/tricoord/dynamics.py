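"""Distribution dynamics of the CCD: kernel density and Markov-chain mobility.

Two complementary views of how the cross-section of coupling-coordination
scores evolves:

* Gaussian kernel density estimates of the CCD distribution per year reveal
  shifts in location, spread and modality (polarization).
* Tier-transition Markov chains: unit-years are partitioned into four tiers
  (I-IV) at the pooled quartiles of the CCD, and year-over-year transition
  probabilities are estimated by maximum likelihood (row-normalized counts).
  The spatial variant conditions each transition on the tier of the unit's
  spatial lag (neighborhood average) at the start of the transition,
  revealing neighborhood-dependent mobility such as club convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import EstimationError, InvalidConfigError, PartitionError
from .weights import SpatialWeights

TIER_LABELS = ("I", "II", "III", "IV")


@dataclass
class KdeResult:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    values = np.asarray(values, float)
    n = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise EstimationError("cannot pick a bandwidth for constant data")
    return 0.9 * spread * n ** (-0.2)


def gaussian_kde(
    values,
    h: float | None = None,
    grid_size: int = 512,
    grid=None,
    allow_single: bool = False,
) -> KdeResult:
    """Gaussian kernel density estimate f(x) = (1/Nh) sum K((X_i - x)/h).

    ``h`` defaults to Silverman's rule; the evaluation grid spans the data
    range extended by 4h on each side (so the density mass inside the grid
    is essentially 1).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 and not allow_single:
        raise EstimationError("need at least 2 observations (allow_single=False)")
    if h is not None and h <= 0:
        raise InvalidConfigError(f"bandwidth must be positive, got {h}")
    if h is None:
        h = silverman_bandwidth(values)
    if grid is None:
        lo, hi = values.min() - 4 * h, values.max() + 4 * h
        grid = np.linspace(lo, hi, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (values[:, None] - grid[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=0) / (values.size * h * np.sqrt(2 * np.pi))
    return KdeResult(grid=grid, density=dens, bandwidth=float(h), n=values.size)


@dataclass
class TierPartition:
    """Quartile cut points and the I-IV tier of every unit-year."""

    cuts: np.ndarray  # three interior cut points
    tiers: pd.Series  # integer tiers 1..4, index (unit, year)
    scheme: str = "pooled"

    def labels(self) -> pd.Series:
        return self.tiers.map(lambda t: TIER_LABELS[t - 1])


def _tiers_from_cuts(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    # boundary ties go to the lower tier: v == cut stays below it
    return 1 + np.searchsorted(cuts, values, side="left")


def assign_tiers(ccd: pd.Series, scheme: str = "pooled") -> TierPartition:
    """Partition CCD values into four tiers at the quartiles.

    ``scheme`` is "pooled" (cut points from all unit-years jointly, the
    default) or "per-year" (cut points recomputed within each year).
    Percentiles use linear interpolation; values equal to a cut point land
    in the lower tier.
    """
    if scheme not in ("pooled", "per-year"):
        raise InvalidConfigError(f"unknown tier scheme {scheme!r}")
    values = ccd.to_numpy(dtype=float)
    if np.unique(values).size < 4:
        raise PartitionError("need at least 4 distinct values to form quartile tiers")
    if scheme == "pooled":
        cuts = np.percentile(values, [25, 50, 75])
        tiers = _tiers_from_cuts(values, cuts)
    else:
        tiers = np.empty(len(ccd), dtype=int)
        years = ccd.index.get_level_values("year")
        cuts = np.percentile(values, [25, 50, 75])  # pooled cuts still reported
        for year in np.unique(years):
            mask = years == year
            sub = values[mask]
            if np.unique(sub).size < 4:
                raise PartitionError(f"year {year} has fewer than 4 distinct values")
            tiers[mask] = _tiers_from_cuts(sub, np.percentile(sub, [25, 50, 75]))
    return TierPartition(cuts=np.asarray(cuts, float),
                         tiers=pd.Series(tiers, index=ccd.index, name="tier"),
                         scheme=scheme)


@dataclass
class TransitionMatrixSet:
    """Unconditional and neighborhood-conditioned tier transition matrices."""

    counts: np.ndarray                      # 4x4
    probs: np.ndarray                       # 4x4, rows with visits sum to 1
    row_totals: np.ndarray                  # visits per starting tier
    conditional_counts: np.ndarray | None = None   # (4, 4, 4) by lag tier
    conditional_probs: np.ndarray | None = None
    conditional_row_totals: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long table: chain type, lag type, from-tier, to-tier probs, N."""
        rows = []
        for i, lab in enumerate(TIER_LABELS):
            rows.append({"chain": "traditional", "lag": "none", "from": lab,
                         **{TIER_LABELS[j]: self.probs[i, j] for j in range(4)},
                         "N": int(self.row_totals[i])})
        if self.conditional_probs is not None:
            for g, glab in enumerate(TIER_LABELS):
                for i, lab in enumerate(TIER_LABELS):
                    rows.append({"chain": "spatial", "lag": glab, "from": lab,
                                 **{TIER_LABELS[j]: self.conditional_probs[g, i, j]
                                    for j in range(4)},
                                 "N": int(self.conditional_row_totals[g, i])})
        return pd.DataFrame(rows)


def _pairs_from_tiers(tiers: pd.Series) -> pd.DataFrame:
    """Consecutive-year (from, to) tier pairs per unit."""
    df = tiers.rename("tier").reset_index()
    df = df.sort_values(["unit", "year"])
    frm = df.groupby("unit")["tier"].shift(0)
    nxt = df.groupby("unit")["tier"].shift(-1)
    keep = nxt.notna()
    pairs = pd.DataFrame({
        "unit": df.loc[keep, "unit"],
        "year": df.loc[keep, "year"],
        "from": frm[keep].astype(int),
        "to": nxt[keep].astype(int),
    })
    return pairs.reset_index(drop=True)


def _count_matrix(frm: np.ndarray, to: np.ndarray, k: int = 4) -> np.ndarray:
    counts = np.zeros((k, k))
    np.add.at(counts, (frm - 1, to - 1), 1.0)
    return counts


def _normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    totals = counts.sum(axis=1)
    probs = np.divide(counts, totals[:, None], where=totals[:, None] > 0,
                      out=np.zeros_like(counts))
    return probs, totals


def transition_matrix(tiers: pd.Series | TierPartition) -> TransitionMatrixSet:
    """Maximum-likelihood transition matrix over all year-over-year pairs."""
    if isinstance(tiers, TierPartition):
        tiers = tiers.tiers
    pairs = _pairs_from_tiers(tiers)
    if pairs.empty:
        raise EstimationError("no consecutive-year transitions to estimate from")
    counts = _count_matrix(pairs["from"].to_numpy(), pairs["to"].to_numpy())
    probs, totals = _normalize(counts)
    return TransitionMatrixSet(counts=counts, probs=probs, row_totals=totals)


def spatial_lag(y: pd.Series, w: SpatialWeights) -> pd.Series:
    """Neighborhood average Lag_i = sum_j W_ij y_j per year.

    ``y`` is indexed by (unit, year); W must be row-standardized so a
    constant surface maps to itself.
    """
    mat = w.matrix
    out = []
    for year, grp in y.groupby(level="year"):
        vec = grp.droplevel("year").reindex(w.ids)
        if vec.isna().any():
            raise InvalidConfigError(
                f"year {year}: units missing from panel or W mismatch"
            )
        lag = mat @ vec.to_numpy(dtype=float)
        out.append(pd.Series(lag, index=pd.MultiIndex.from_product(
            [w.ids, [year]], names=["unit", "year"])))
    res = pd.concat(out).sort_index()
    res.name = "lag"
    return res.reindex(y.sort_index().index)


def spatial_transition_matrices(
    tiers: pd.Series | TierPartition,
    lag_tiers: pd.Series | TierPartition,
) -> TransitionMatrixSet:
    """Transition matrices conditioned on the spatial-lag tier at time t.

    The four conditioned count matrices partition the unconditional counts:
    their cell-wise sum reproduces the traditional chain exactly.
    """
    if isinstance(tiers, TierPartition):
        tiers = tiers.tiers
    if isinstance(lag_tiers, TierPartition):
        lag_tiers = lag_tiers.tiers
    pairs = _pairs_from_tiers(tiers)
    if pairs.empty:
        raise EstimationError("no consecutive-year transitions to estimate from")
    lag_at_t = lag_tiers.reindex(
        pd.MultiIndex.from_frame(pairs[["unit", "year"]]))
    if lag_at_t.isna().any():
        missing = pairs.loc[np.asarray(lag_at_t.isna()), ["unit", "year"]]
        raise EstimationError(
            f"lag tier missing for transitions starting at: {missing.values.tolist()[:5]}"
        )
    counts = _count_matrix(pairs["from"].to_numpy(), pairs["to"].to_numpy())
    probs, totals = _normalize(counts)
    cond_counts = np.zeros((4, 4, 4))
    lag_arr = lag_at_t.to_numpy(dtype=int)
    for g in range(1, 5):
        sel = lag_arr == g
        cond_counts[g - 1] = _count_matrix(
            pairs.loc[sel, "from"].to_numpy(), pairs.loc[sel, "to"].to_numpy())
    cond_probs = np.zeros_like(cond_counts)
    cond_totals = np.zeros((4, 4))
    for g in range(4):
        cond_probs[g], cond_totals[g] = _normalize(cond_counts[g])
    return TransitionMatrixSet(
        counts=counts, probs=probs, row_totals=totals,
        conditional_counts=cond_counts, conditional_probs=cond_probs,
        conditional_row_totals=cond_totals,
    )


class MarkovTierChain(BaseEstimator):
    """Estimator: CCD panel -> tier partition and transition matrices.

    Parameters
    ----------
    scheme : quartile pool for tiers, "pooled" or "per-year".
    weights : optional SpatialWeights; when given, the spatially conditioned
        transition matrices are estimated as well (lag tiers from the pooled
        quartiles of the spatial-lag values).

    Attributes
    ----------
    partition_ : TierPartition of the CCD values
    lag_partition_ : TierPartition of the spatial-lag values (if weights)
    matrices_ : TransitionMatrixSet
    """

    def __init__(self, scheme: str = "pooled", weights: SpatialWeights | None = None):
        self.scheme = scheme
        self.weights = weights

    def fit(self, X: pd.Series, y=None) -> "MarkovTierChain":
        """``X`` is a CCD Series indexed by (unit, year)."""
        self.partition_ = assign_tiers(X, scheme=self.scheme)
        if self.weights is not None:
            lag = spatial_lag(X, self.weights)
            self.lag_partition_ = assign_tiers(lag, scheme=self.scheme)
            self.matrices_ = spatial_transition_matrices(
                self.partition_, self.lag_partition_)
        else:
            self.lag_partition_ = None
            self.matrices_ = transition_matrix(self.partition_)
        return self
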