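"""Global and local Moran's I spatial autocorrelation statistics.

Global Moran's I for a cross-section y with weight matrix W:

    I = (n / S0) * (z' W z) / (z' z),      z = y - mean(y),  S0 = sum W_ij

Inference defaults to the randomization-moments z-test: E(I) = -1/(n-1) and
SD(I) from the permutation (randomization) variance formula, which accounts
for the sample kurtosis. A seeded permutation pseudo-p is available as a
cross-check. Local Moran's I_i = (z_i / S2) * sum_j W_ij z_j with
S2 = z'z / n, so that sum_i I_i = n * I for a row-standardized W; LISA
classes (HH, LL, HL, LH) come from the signs of z_i and its spatial lag,
gated on a conditional-permutation pseudo-p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InvalidConfigError
from .weights import SpatialWeights


@dataclass
class MoranResult:
    I: float
    expected: float
    sd: float
    z: float
    p: float
    inference: str
    n_permutations: int | None = None


def _validate(y, w: SpatialWeights) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size != w.n:
        raise InvalidConfigError(f"y has {y.size} values but W has {w.n} units")
    if np.ptp(y) == 0:
        raise EstimationError("Moran's I undefined for a constant variable")
    return y


def _moran_stat(z: np.ndarray, w: np.ndarray, s0: float) -> float:
    return float(z.size / s0 * (z @ w @ z) / (z @ z))


def _randomization_sd(y: np.ndarray, w: np.ndarray) -> float:
    """SD of I under random relabelling (randomization moments)."""
    n = y.size
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    z = y - y.mean()
    b2 = n * (z ** 4).sum() / (z ** 2).sum() ** 2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var = num / den - 1.0 / (n - 1) ** 2
    return float(np.sqrt(var))


def global_moran(
    y,
    w: SpatialWeights,
    inference: str = "analytic",
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with randomization-analytic or permutation inference.

    ``inference`` "analytic" gives the two-sided z-test against the
    randomization moments; "permutation" additionally computes a two-sided
    pseudo-p from seeded shuffles of y.
    """
    y = _validate(y, w)
    n = y.size
    z = y - y.mean()
    stat = _moran_stat(z, w.matrix, w.s0)
    expected = -1.0 / (n - 1)
    sd = _randomization_sd(y, w.matrix)
    zscore = (stat - expected) / sd
    p_analytic = 2.0 * stats.norm.sf(abs(zscore))
    if inference == "analytic":
        return MoranResult(stat, expected, sd, zscore, float(p_analytic), "analytic")
    if inference != "permutation":
        raise InvalidConfigError(f"unknown inference {inference!r}")
    rng = np.random.default_rng(seed)
    sims = np.empty(n_permutations)
    for b in range(n_permutations):
        zp = rng.permutation(z)
        sims[b] = _moran_stat(zp, w.matrix, w.s0)
    hi = (sims >= stat).sum()
    lo = (sims <= stat).sum()
    p_perm = min(1.0, 2.0 * (1 + min(hi, lo)) / (n_permutations + 1))
    return MoranResult(stat, expected, sd, zscore, float(p_perm),
                       "permutation", n_permutations)


@dataclass
class LisaResult:
    table: pd.DataFrame  # unit, Ii, p, cluster
    alpha: float
    n_permutations: int

    def classes(self) -> pd.Series:
        return self.table.set_index("unit")["cluster"]


def local_moran(
    y,
    w: SpatialWeights,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = None,
) -> LisaResult:
    """Local Moran's I with conditional-permutation pseudo-p values.

    For each unit i the remaining n-1 values are permuted among the other
    locations, holding y_i fixed; the pseudo-p is the one-sided permutation
    probability of an I_i at least as extreme in the direction of the
    observed statistic. Units with pseudo-p > alpha are
    "ns"; otherwise the class is HH/LL (z_i and lag share sign, I_i > 0) or
    HL/LH (opposite signs, I_i < 0).
    """
    y = _validate(y, w)
    n = y.size
    z = y - y.mean()
    s2 = (z @ z) / n
    lag = w.matrix @ z
    ii = z * lag / s2
    rng = np.random.default_rng(seed)
    pvals = np.empty(n)
    others = np.arange(n)
    for i in range(n):
        wi = w.matrix[i]
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pool = z[mask]
        wnb = wi[mask]
        # permute the other values; lag_i only needs the values that land on
        # positive-weight positions
        sims = np.empty(n_permutations)
        for b in range(n_permutations):
            sims[b] = wnb @ rng.permutation(pool)
        sim_ii = z[i] * sims / s2
        extreme = (sim_ii >= ii[i]).sum() if ii[i] >= 0 else (sim_ii <= ii[i]).sum()
        pvals[i] = (1 + extreme) / (n_permutations + 1)
    cluster = np.where(
        pvals > alpha, "ns",
        np.where(z > 0, np.where(lag > 0, "HH", "HL"),
                 np.where(lag > 0, "LH", "LL")))
    table = pd.DataFrame({"unit": list(w.ids), "Ii": ii, "p": pvals,
                          "cluster": cluster})
    return LisaResult(table=table, alpha=alpha, n_permutations=n_permutations)
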