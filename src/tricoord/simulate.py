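"""Synthetic provincial panel generator with known ground truth.

Emulates the statistical structure the analysis chain assumes: 31 units in
three regional tiers (east > central > west level offsets), 11 years of
upward drift, a ~29-indicator schema mixing positive- and negative-direction
indicators across three subsystems, covariates in realistic published
ranges, positive spatial autocorrelation, and configurable spatial-Durbin
and threshold-regression generating processes whose true parameters are
recorded for recovery testing.

Construction: each unit-year has a latent quality per subsystem

    L[i, t, s] = region_offset[region(i), s] + drift[s] * t + u_i + e_it

with u_i a spatially autocorrelated unit effect, (I - rho W)^-1 eta, constant
over time. Indicators are noisy affine transforms of the latent quality;
negative-direction indicators get a sign flip before noise, so higher raw
values correspond to worse latent quality.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import weights as wmod
from .errors import InvalidConfigError
from .weights import SpatialWeights

REGIONS = ("east", "central", "west")

#: Table-3-magnitude covariate ranges: per-capita GDP (yuan), government
#: health expenditure share of GDP (%), urbanization rate (%), education
#: human capital (%), old-age dependency ratio (%).
DEFAULT_COVARIATE_RANGES = {
    "GDP": (22_400.0, 216_700.0),
    "GHI": (3.97, 13.93),
    "Urb": (23.97, 89.58),
    "Edu": (0.89, 4.37),
    "Old": (7.01, 30.6),
}

DEFAULT_REGION_OFFSETS = {
    "east": {"healthcare": 0.55, "insurance": 0.50, "pharma": 0.35},
    "central": {"healthcare": 0.45, "insurance": 0.42, "pharma": 0.22},
    "west": {"healthcare": 0.38, "insurance": 0.36, "pharma": 0.12},
}

DEFAULT_DRIFT = {"healthcare": 0.012, "insurance": 0.014, "pharma": 0.010}

#: Default threshold DGP: old-age dependency threshold with a steeper slope
#: in the high-aging regime.
DEFAULT_THRESHOLD_DGP = (15.06, 0.006, 0.011)


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2^31 (crc32 of "seed:stage")."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2 ** 31)


def default_schema_table() -> pd.DataFrame:
    """29-indicator schema: 10 healthcare (2 negative), 11 insurance
    (2 negative), 8 pharma (all positive)."""
    rows = []

    def add(sub, dim, n_pos, n_neg=0):
        base = len([r for r in rows if r["subsystem"] == sub]) + 1
        for j in range(n_pos):
            rows.append({"indicator": f"{sub[:3]}_{base + j:02d}",
                         "subsystem": sub, "dimension": dim, "direction": "+"})
        for j in range(n_neg):
            rows.append({"indicator": f"{sub[:3]}_{base + n_pos + j:02d}",
                         "subsystem": sub, "dimension": dim, "direction": "-"})

    add("healthcare", "resources", 4)
    add("healthcare", "service_scale", 2)
    add("healthcare", "service_efficiency", 2)
    add("healthcare", "disease_control", 0, 2)
    add("insurance", "funding", 2, 2)
    add("insurance", "compensation", 3)
    add("insurance", "coverage", 2)
    add("insurance", "sustainability", 2)
    add("pharma", "enterprise_scale", 2)
    add("pharma", "economic_benefit", 3)
    add("pharma", "innovation", 3)
    return pd.DataFrame(rows)


def default_geography(n_units: int = 31):
    """Synthetic centroids on an 8x5 grid in three longitudinal bands.

    Columns 0-2 are the western band (12 units), 3-4 central (8 units),
    5-7 eastern (11 units); 9 grid cells are dropped deterministically to
    reach 31. Returns (centroids DataFrame indexed by unit with x, y,
    region; adjacency DataFrame of queen-contiguous pairs).
    """
    if n_units != 31:
        raise InvalidConfigError("default geography is defined for 31 units")
    cells = []
    # drop cells at band corners to get 12 / 8 / 11 per band
    dropped = {(0, 4), (2, 0), (2, 4), (3, 0), (4, 4), (5, 0), (5, 4), (7, 0), (7, 4)}
    for col in range(8):
        for row in range(5):
            if (col, row) in dropped:
                continue
            region = "west" if col <= 2 else ("central" if col <= 4 else "east")
            cells.append((col, row, region))
    assert len(cells) == 31
    counters = {"east": 0, "central": 0, "west": 0}
    recs = []
    for col, row, region in sorted(cells, key=lambda c: ({"east": 0, "central": 1, "west": 2}[c[2]], c[0], c[1])):
        counters[region] += 1
        recs.append({"unit": f"{region[0].upper()}{counters[region]:02d}",
                     "x": float(col), "y": float(row), "region": region,
                     "col": col, "row": row})
    cent = pd.DataFrame(recs).set_index("unit")
    pairs = []
    bycell = {(r["col"], r["row"]): u for u, r in cent.iterrows()}
    for (c, r), u in bycell.items():
        for dc in (-1, 0, 1):
            for dr in (-1, 0, 1):
                if dc == dr == 0:
                    continue
                v = bycell.get((c + dc, r + dr))
                if v is not None and u < v:
                    pairs.append({"unit_a": u, "unit_b": v})
    adjacency = pd.DataFrame(pairs)
    return cent[["x", "y", "region"]], adjacency


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_units: int = 31
    n_years: int = 11
    start_year: int = 2013
    region_assignment: dict | None = None        # unit -> region
    indicator_schema: pd.DataFrame | None = None  # indicator, subsystem, dimension, direction
    region_level_offsets: dict = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_REGION_OFFSETS.items()})
    annual_drift: dict = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    noise_sd: float = 0.05
    spatial_rho_dgp: float = 0.4
    spatial_effect_sd: float = 0.03
    covariate_ranges: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_COVARIATE_RANGES.items()})
    covariate_ar: float = 0.8
    threshold_dgp: tuple | None = DEFAULT_THRESHOLD_DGP  # (gamma, beta_low, beta_high)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units <= 0 or self.n_years <= 0:
            raise InvalidConfigError("n_units and n_years must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not -1 < self.spatial_rho_dgp < 1:
            raise InvalidConfigError("spatial_rho_dgp must lie in (-1, 1)")
        if self.indicator_schema is None:
            self.indicator_schema = default_schema_table()
        if any(v <= 0 for v in self.annual_drift.values()):
            raise InvalidConfigError("annual drift must be positive per subsystem")
        if self.region_assignment is None:
            if self.n_units == 31:
                cent, _ = default_geography()
                self.region_assignment = dict(cent["region"])
            else:
                units = [f"U{i + 1:02d}" for i in range(self.n_units)]
                thirds = np.array_split(units, 3)
                self.region_assignment = {}
                for reg, chunk in zip(REGIONS, thirds):
                    self.region_assignment.update({u: reg for u in chunk})
        seen = set(self.region_assignment.values()) - set(REGIONS)
        if seen:
            raise InvalidConfigError(f"unknown regions: {sorted(seen)}")
        if len(self.region_assignment) != self.n_units:
            raise InvalidConfigError(
                f"region assignment covers {len(self.region_assignment)} units, "
                f"expected {self.n_units}")

    @property
    def units(self) -> list[str]:
        return list(self.region_assignment)

    @property
    def years(self) -> list[int]:
        return [self.start_year + t for t in range(self.n_years)]


@dataclass
class GroundTruth:
    """Exact generator parameters, for recovery tests; JSON round-trippable."""

    true_rho: float | None = None
    true_betas: list | None = None
    true_theta: list | None = None
    true_sigma: float | None = None
    true_gamma: float | None = None
    true_regime_betas: list | None = None
    region_means: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        data = asdict(self)
        for k, v in asdict(other).items():
            if v is not None:
                data[k] = v
        return GroundTruth(**data)


def _latent_quality(cfg: SimulationConfig, w: SpatialWeights | None,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent subsystem quality, shape (n_units, n_years) per subsystem."""
    n, T = cfg.n_units, cfg.n_years
    units = cfg.units
    out = {}
    for sub in ("healthcare", "insurance", "pharma"):
        base = np.array([cfg.region_level_offsets[cfg.region_assignment[u]][sub]
                         for u in units])
        drift = cfg.annual_drift[sub] * np.arange(T)
        if w is not None and cfg.spatial_effect_sd > 0:
            eta = rng.normal(0.0, cfg.spatial_effect_sd, size=n)
            ueff = np.linalg.solve(np.eye(n) - cfg.spatial_rho_dgp * w.matrix, eta)
        else:
            ueff = np.zeros(n)
        out[sub] = base[:, None] + drift[None, :] + ueff[:, None]
    return out


def generate_indicator_panel(
    cfg: SimulationConfig,
    w: SpatialWeights | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format indicator panel (unit, year, indicator, value).

    Deterministic given cfg.seed. Positive-direction indicators are
    increasing affine transforms of the latent quality; negative-direction
    indicators are decreasing transforms (higher raw value = worse quality),
    both with Gaussian observation noise of sd cfg.noise_sd.
    """
    rng = np.random.default_rng(child_seed(cfg.seed, "indicators"))
    if w is None and cfg.n_units == 31:
        cent, adj = default_geography()
        w = wmod.from_adjacency(adj, list(cent.index), row_standardize=True,
                                centroids=cent)
    latent = _latent_quality(cfg, w, rng)
    schema = cfg.indicator_schema
    rows = []
    units, years = cfg.units, cfg.years
    region_means = {
        sub: {reg: float(np.mean([latent[sub][i] for i, u in enumerate(units)
                                  if cfg.region_assignment[u] == reg]))
              for reg in REGIONS}
        for sub in latent
    }
    for _, spec in schema.iterrows():
        sub = spec["subsystem"]
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(0.5, 1.5)
        L = latent[sub]
        noise = (rng.normal(0.0, cfg.noise_sd, size=L.shape)
                 if cfg.noise_sd > 0 else 0.0)
        if spec["direction"] == "+":
            vals = a + b * L + noise
        else:
            vals = a - b * L + noise
        for i, u in enumerate(units):
            for t, yr in enumerate(years):
                rows.append((u, yr, spec["indicator"], vals[i, t]))
    panel = pd.DataFrame(rows, columns=["unit", "year", "indicator", "value"])
    return panel, GroundTruth(region_means=region_means)


def generate_covariates(cfg: SimulationConfig) -> pd.DataFrame:
    """Covariate panel with Table-3-magnitude ranges and AR(1) persistence.

    Each unit draws a level uniformly inside the covariate range, then
    follows a mean-reverting AR(1); the old-age dependency ratio also drifts
    upward (populations age), guaranteeing within-unit variation of the
    threshold variable. Values are clipped to the stated ranges.
    """
    rng = np.random.default_rng(child_seed(cfg.seed, "covariates"))
    n, T = cfg.n_units, cfg.n_years
    region_rank = {"east": 0.75, "central": 0.5, "west": 0.25}
    recs = []
    for name, (lo, hi) in cfg.covariate_ranges.items():
        width = hi - lo
        # richer regions sit higher in the range for GDP/Urb/Edu
        if name in ("GDP", "Urb", "Edu"):
            centers = np.array([lo + width * np.clip(
                region_rank[cfg.region_assignment[u]] + rng.normal(0, 0.12), 0.05, 0.95)
                for u in cfg.units])
        else:
            centers = lo + width * rng.uniform(0.15, 0.85, size=n)
        drift = width * 0.025 if name == "Old" else 0.0
        innov_sd = width * 0.03
        x = np.empty((n, T))
        x[:, 0] = centers + rng.normal(0, innov_sd, size=n)
        for t in range(1, T):
            x[:, t] = (centers + drift * t
                       + cfg.covariate_ar * (x[:, t - 1] - centers - drift * (t - 1))
                       + rng.normal(0, innov_sd, size=n))
        x = np.clip(x, lo, hi)
        for i, u in enumerate(cfg.units):
            for t, yr in enumerate(cfg.years):
                recs.append((u, yr, name, x[i, t]))
    cov = pd.DataFrame(recs, columns=["unit", "year", "covariate", "value"])
    wide = cov.pivot_table(index=["unit", "year"], columns="covariate",
                           values="value", aggfunc="first")
    wide.columns.name = None
    return wide[list(cfg.covariate_ranges)].sort_index()


def generate_sdm_outcome(
    w: SpatialWeights,
    X: pd.DataFrame,
    rho: float,
    betas,
    theta,
    sigma: float,
    seed: int,
    intercept: float = 0.0,
) -> tuple[pd.Series, GroundTruth]:
    """Spatial-Durbin outcome y = (I - rho W)^-1 (a + X b + W X t + eps).

    ``X`` is a covariate panel indexed by (unit, year) in W's unit order
    within each year; eps ~ N(0, sigma^2) iid per observation. Raises when
    (I - rho W) is numerically singular, naming the offending rho.
    """
    betas = np.asarray(betas, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = w.n
    eig = np.linalg.eigvals(w.matrix)
    margin = np.min(np.abs(1.0 - rho * eig))
    if margin < 1e-10:
        raise InvalidConfigError(
            f"(I - rho W) is singular for rho={rho}; choose |rho| inside the "
            "spectral bounds of W")
    A_inv = np.linalg.inv(np.eye(n) - rho * w.matrix)
    rng = np.random.default_rng(seed)
    out = []
    years = X.index.get_level_values("year").unique().sort_values()
    for yr in years:
        Xt = X.xs(yr, level="year").reindex(w.ids).to_numpy(dtype=float)
        mean = intercept + Xt @ betas + w.matrix @ Xt @ theta
        eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        yt = A_inv @ (mean + eps)
        out.append(pd.Series(yt, index=pd.MultiIndex.from_product(
            [w.ids, [yr]], names=["unit", "year"])))
    y = pd.concat(out).sort_index()
    y.name = "y"
    gt = GroundTruth(true_rho=float(rho), true_betas=list(map(float, betas)),
                     true_theta=list(map(float, theta)), true_sigma=float(sigma))
    return y, gt


def generate_threshold_outcome(
    q: pd.Series,
    gamma: float,
    beta_low: float,
    beta_high: float,
    controls: pd.DataFrame | None,
    sigma: float,
    seed: int,
    control_betas=None,
    unit_effect_sd: float = 0.05,
) -> tuple[pd.Series, GroundTruth]:
    """Regime-switching panel outcome with fixed unit effects.

    y_it = mu_i + controls @ delta + beta_low * q * 1(q <= gamma)
         + beta_high * q * 1(q > gamma) + eps,  eps ~ N(0, sigma^2).

    ``gamma`` must lie strictly inside the observed range of q.
    """
    qv = q.to_numpy(dtype=float)
    if not qv.min() < gamma < qv.max():
        raise InvalidConfigError(
            f"gamma={gamma} outside the observed range "
            f"[{qv.min():.4g}, {qv.max():.4g}] of the threshold variable")
    rng = np.random.default_rng(seed)
    units = q.index.get_level_values("unit")
    uniq = units.unique()
    mu = pd.Series(rng.normal(0.0, unit_effect_sd, size=len(uniq)), index=uniq)
    y = mu.reindex(units).to_numpy()
    low = qv <= gamma
    y = y + np.where(low, beta_low * qv, beta_high * qv)
    if controls is not None and len(controls.columns):
        cb = (np.asarray(control_betas, dtype=float) if control_betas is not None
              else np.full(len(controls.columns), 0.01))
        y = y + controls.reindex(q.index).to_numpy(dtype=float) @ cb
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(y))
    ys = pd.Series(y, index=q.index, name="y")
    gt = GroundTruth(true_gamma=float(gamma),
                     true_regime_betas=[float(beta_low), float(beta_high)])
    return ys, gt
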