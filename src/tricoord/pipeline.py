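"""End-to-end pipeline: simulate -> weight -> score -> classify -> dynamics
-> spatial statistics -> SDM -> threshold, as a configured, logged, resumable
run writing the analysis tables as CSV.

Every output CSV carries a commented provenance header (config hash and
seed); a persisted config re-runs to byte-identical outputs given the same
seed, because the single run seed fans out to per-stage child seeds by
stable hashing of stage names — enabling or disabling one stage never
perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composite, coupling, dynamics, moran, sdm, simulate, threshold, weights
from .composite import IndicatorSchema, SubsystemIndex
from .coupling import CouplingCoordination, average_annual_growth, trajectory_groups
from .dynamics import MarkovTierChain, gaussian_kde
from .errors import DependencyError, InvalidConfigError
from .simulate import SimulationConfig, GroundTruth, child_seed

log = logging.getLogger(__name__)

STAGES = ["simulate", "validate", "weights", "ccd", "kde", "markov",
          "moran", "lisa", "sdm", "threshold", "report"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    n_units: int = 31
    n_years: int = 11
    start_year: int = 2013
    noise_sd: float = 0.05
    weighting: str = "critic"
    pool: str = "panel"
    w_moran: str = "contiguity"          # Moran / LISA / Markov conditioning
    w_sdm: str = "inverse_distance"      # SDM per the distance-matrix choice
    quartile_scheme: str = "pooled"
    n_permutations: int = 999
    alpha: float = 0.05
    sdm_effects: str = "random"
    sdm_rho_dgp: float = 0.4
    sdm_betas: list = field(default_factory=lambda: [1.0, -0.5])
    sdm_theta: list = field(default_factory=lambda: [0.5, 0.2])
    sdm_sigma: float = 0.1
    threshold_gamma: float = 15.06
    threshold_betas: list = field(default_factory=lambda: [0.006, 0.011])
    threshold_sigma: float = 0.05
    n_bootstrap: int = 300
    trim: float = 0.05
    max_candidates: int | None = 100

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        data = dataclasses.asdict(self)
        data.pop("out_dir")  # storage location, not a scientific parameter
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tricoord config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, index=index)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise DependencyError(f"missing upstream artifact {path.name}; "
                              "run its producing stage first")
    return pd.read_csv(path, comment="#", **kw)


def validate_inputs(panel: pd.DataFrame, schema,
                    centroids: pd.DataFrame | None = None,
                    adjacency: pd.DataFrame | None = None) -> list[str]:
    """Collect (not fail-fast) structural problems of the inputs.

    ``schema`` may be an IndicatorSchema or a raw schema DataFrame (the raw
    form lets malformed direction labels be reported instead of raised).
    """
    issues: list[str] = []
    need = {"unit", "year", "indicator", "value"}
    if not need <= set(panel.columns):
        issues.append(f"panel missing columns {sorted(need - set(panel.columns))}")
        return issues
    units = panel["unit"].unique()
    years = panel["year"].unique()
    inds = panel["indicator"].unique()
    counts = panel.groupby(["unit", "year"])["indicator"].nunique()
    full = pd.MultiIndex.from_product([units, years])
    missing = full.difference(counts.index)
    for unit, year in missing:
        issues.append(f"balance violation: unit {unit} missing year {year}")
    short = counts[counts < len(inds)]
    for (unit, year), c in short.items():
        issues.append(f"unit {unit} year {year} has {c}/{len(inds)} indicators")
    tab = schema.table if isinstance(schema, IndicatorSchema) else schema
    schema_inds = set(tab["indicator"])
    for ind in set(inds) - schema_inds:
        issues.append(f"schema violation: indicator {ind} not in schema")
    for _, row in tab.iterrows():
        if row["direction"] not in ("+", "-"):
            issues.append(f"schema violation: indicator {row['indicator']} "
                          f"direction {row['direction']!r} not in {{+, -}}")
    if centroids is not None:
        missing_geo = set(units) - set(centroids.index)
        if missing_geo:
            issues.append(f"geography missing units: {sorted(missing_geo)}")
    if adjacency is not None:
        known = set(units)
        bad = set(adjacency["unit_a"]) | set(adjacency["unit_b"]) - known
        for u in sorted(bad - known):
            issues.append(f"adjacency references unknown unit {u}")
    return issues


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return a report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in set(cfg.stages)]
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")
    report: dict = {"config": cfg.digest(), "seed": cfg.seed, "stages": {}}
    timings = {}

    schema = IndicatorSchema(simulate.default_schema_table())
    if cfg.n_units == 31:
        centroids, adjacency = simulate.default_geography()
    else:
        raise InvalidConfigError("pipeline default geography requires 31 units")
    w_queen = weights.from_adjacency(adjacency, list(centroids.index),
                                     row_standardize=True, centroids=centroids)
    w_dist = weights.from_centroids(centroids, kind="inverse_distance",
                                    row_standardize=True)
    w_for = {"contiguity": w_queen, "inverse_distance": w_dist}

    for stage in requested:
        t0 = time.perf_counter()
        log.info("stage %s", stage)
        if stage == "simulate":
            sim = SimulationConfig(n_units=cfg.n_units, n_years=cfg.n_years,
                                   start_year=cfg.start_year,
                                   noise_sd=cfg.noise_sd,
                                   spatial_rho_dgp=cfg.sdm_rho_dgp,
                                   seed=cfg.seed)
            panel, gt = simulate.generate_indicator_panel(sim, w=w_queen)
            cov = simulate.generate_covariates(sim)
            # dedicated DGP outcomes for recovery of the spatial and
            # threshold parameters
            covs_sdm = cov[["Urb", "Edu"]] / 100.0
            y_sdm, gt_sdm = simulate.generate_sdm_outcome(
                w_dist, covs_sdm, cfg.sdm_rho_dgp,
                cfg.sdm_betas, cfg.sdm_theta, cfg.sdm_sigma,
                seed=child_seed(cfg.seed, "sdm_dgp"))
            y_thr, gt_thr = simulate.generate_threshold_outcome(
                cov["Old"], cfg.threshold_gamma, *cfg.threshold_betas,
                controls=cov[["Urb"]] / 100.0, sigma=cfg.threshold_sigma,
                seed=child_seed(cfg.seed, "threshold_dgp"))
            gt = gt.merged(gt_sdm).merged(gt_thr)
            _write_csv(panel, out / "indicators.csv", cfg, index=False)
            _write_csv(cov.reset_index(), out / "covariates.csv", cfg, index=False)
            _write_csv(centroids.reset_index(), out / "centroids.csv", cfg, index=False)
            _write_csv(adjacency, out / "adjacency.csv", cfg, index=False)
            _write_csv(schema.table, out / "schema.csv", cfg, index=False)
            _write_csv(y_sdm.reset_index(), out / "sdm_outcome.csv", cfg, index=False)
            _write_csv(y_thr.reset_index(), out / "threshold_outcome.csv", cfg,
                       index=False)
            gt.to_json(out / "ground_truth.json")
        elif stage == "validate":
            panel = _read_csv(out / "indicators.csv")
            issues = validate_inputs(panel, schema, centroids, adjacency)
            report["stages"]["validate"] = {"issues": issues}
            (out / "validation.json").write_text(json.dumps(issues, indent=2))
        elif stage == "weights":
            panel = _read_csv(out / "indicators.csv")
            indexer = SubsystemIndex(schema, method=cfg.weighting, pool=cfg.pool)
            indexer.fit(panel)
            _write_csv(indexer.weight_table(), out / "weight_table.csv", cfg,
                       index=False)
        elif stage == "ccd":
            panel = _read_csv(out / "indicators.csv")
            indexer = SubsystemIndex(schema, method=cfg.weighting, pool=cfg.pool)
            scores = indexer.fit(panel).scores_
            rec = CouplingCoordination().fit(scores).transform(scores)
            tbl = scores.join(rec)
            tbl.columns = ["U1", "U2", "U3", "C", "T", "D", "level"]
            _write_csv(tbl.reset_index(), out / "ccd.csv", cfg, index=False)
            # entropy-weighted variant for downstream robustness
            alt = SubsystemIndex(schema, method="entropy", pool=cfg.pool)
            alt_scores = alt.fit(panel).scores_
            alt_rec = CouplingCoordination().fit(alt_scores).transform(alt_scores)
            _write_csv(alt_rec.reset_index()[["unit", "year", "D"]],
                       out / "ccd_entropy.csv", cfg, index=False)
            groups = trajectory_groups(tbl.reset_index(), cfg.start_year,
                                       cfg.start_year + cfg.n_years - 1)
            _write_csv(groups.rename("group").reset_index()
                       .rename(columns={"index": "unit"}),
                       out / "trajectory_groups.csv", cfg, index=False)
        elif stage == "kde":
            ccd = _read_csv(out / "ccd.csv")
            frames = []
            for year, grp in ccd.groupby("year"):
                kde = gaussian_kde(grp["D"].to_numpy())
                frames.append(pd.DataFrame({"year": year, "x": kde.grid,
                                            "density": kde.density,
                                            "bandwidth": kde.bandwidth}))
            _write_csv(pd.concat(frames), out / "kde.csv", cfg, index=False)
        elif stage == "markov":
            ccd = _read_csv(out / "ccd.csv").set_index(["unit", "year"])
            chain = MarkovTierChain(scheme=cfg.quartile_scheme,
                                    weights=w_for[cfg.w_moran])
            chain.fit(ccd["D"])
            _write_csv(chain.matrices_.to_frame(), out / "markov.csv", cfg,
                       index=False)
        elif stage == "moran":
            ccd = _read_csv(out / "ccd.csv").set_index(["unit", "year"])
            w = w_for[cfg.w_moran]
            rows = []
            for year, grp in ccd["D"].groupby(level="year"):
                res = moran.global_moran(
                    grp.droplevel("year").reindex(w.ids), w)
                rows.append({"year": year, "I": res.I, "E(I)": res.expected,
                             "SD(I)": res.sd, "z": res.z, "p": res.p})
            _write_csv(pd.DataFrame(rows), out / "moran.csv", cfg, index=False)
        elif stage == "lisa":
            ccd = _read_csv(out / "ccd.csv").set_index(["unit", "year"])
            w = w_for[cfg.w_moran]
            last = cfg.start_year + cfg.n_years - 1
            frames = []
            for year in (cfg.start_year, last):
                y = ccd["D"].xs(year, level="year").reindex(w.ids)
                res = moran.local_moran(y, w, alpha=cfg.alpha,
                                        n_permutations=cfg.n_permutations,
                                        seed=child_seed(cfg.seed, f"lisa{year}"))
                tab = res.table.assign(year=year)
                frames.append(tab)
            _write_csv(pd.concat(frames), out / "lisa.csv", cfg, index=False)
        elif stage == "sdm":
            cov = _read_csv(out / "covariates.csv").set_index(["unit", "year"])
            y = _read_csv(out / "sdm_outcome.csv").set_index(["unit", "year"])["y"]
            X = cov[["Urb", "Edu"]] / 100.0
            w = w_for[cfg.w_sdm]
            res = sdm.fit_sdm(X, y, w, effects=cfg.sdm_effects)
            tests = sdm.lm_tests(X, y, w)
            battery, _ = sdm.lr_wald_hausman(X, y, w, effects=cfg.sdm_effects)
            vifs, mean_vif = sdm.vif(cov)
            tbl = res.table()
            tbl.loc["R2"] = [res.r2, np.nan, np.nan]
            tbl.loc["log_likelihood"] = [res.llf, np.nan, np.nan]
            tbl.loc["N"] = [res.n * res.T, np.nan, np.nan]
            _write_csv(tbl, out / "sdm.csv", cfg)
            spec_tbl = pd.concat([
                tests.to_frame(), battery.to_frame(),
                pd.DataFrame({"statistic": [f"VIF_{k}" for k in vifs.index]
                              + ["mean_VIF"],
                              "value": list(vifs) + [mean_vif]}),
            ])
            _write_csv(spec_tbl, out / "sdm_tests.csv", cfg, index=False)
            report["stages"]["sdm"] = {"rho": res.rho, "r2": res.r2}
        elif stage == "threshold":
            cov = _read_csv(out / "covariates.csv").set_index(["unit", "year"])
            y = _read_csv(out / "threshold_outcome.csv").set_index(
                ["unit", "year"])["y"]
            single, double = threshold.sequential_thresholds(
                y, cov["Old"], controls=cov[["Urb"]] / 100.0,
                trim=cfg.trim, max_candidates=cfg.max_candidates,
                n_bootstrap=cfg.n_bootstrap,
                random_state=child_seed(cfg.seed, "threshold_boot"))
            rows = []
            for name, fitres in (("single", single), ("double", double)):
                if fitres is None:
                    continue
                rows.append({
                    "model": name,
                    "threshold": fitres.gammas[-1] if name == "double" else fitres.gamma,
                    "thresholds": ";".join(f"{g:g}" for g in fitres.gammas),
                    "RSS": fitres.rss, "MSE": fitres.mse,
                    "F": fitres.f_stat, "p": fitres.bootstrap_p,
                    "crit10": fitres.critical_values[0.10],
                    "crit5": fitres.critical_values[0.05],
                    "crit1": fitres.critical_values[0.01],
                })
            _write_csv(pd.DataFrame(rows), out / "threshold_tests.csv", cfg,
                       index=False)
            _write_csv(single.regime_coefs, out / "threshold_coefs.csv", cfg)
            report["stages"]["threshold"] = {"gamma": single.gamma,
                                             "p": single.bootstrap_p}
        elif stage == "report":
            ccd = _read_csv(out / "ccd.csv")
            first = cfg.start_year
            last = cfg.start_year + cfg.n_years - 1
            nat = ccd.groupby("year")["D"].mean()
            growth = average_annual_growth(nat[first], nat[last],
                                           cfg.n_years - 1)
            summary = {
                "mean_ccd": float(ccd["D"].mean()),
                "national_ccd_first": float(nat[first]),
                "national_ccd_last": float(nat[last]),
                "national_ccd_cagr_pct": float(growth),
            }
            gt_path = out / "ground_truth.json"
            if gt_path.exists():
                summary["ground_truth"] = json.loads(gt_path.read_text())
            (out / "report.json").write_text(json.dumps(summary, indent=2))
            report["stages"]["report"] = summary
        timings[stage] = round(time.perf_counter() - t0, 3)
    report["timings"] = timings
    return report
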