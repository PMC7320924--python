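"""Readers, writers, run configuration and the end-to-end pipeline.

Tables travel as plain CSV (documented headers), geography as a GeoJSON
FeatureCollection plus a two-column adjacency CSV. Readers validate the
schema up front: unknown stage labels and unknown area ids are named
errors with row numbers, while unstageable tumour records and records
without a resolvable area are *excluded and tallied* (real registry
extractions lose a handful of cases the same way).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._schema import AGE_GROUPS, CASE_COLUMNS, SEXES, STAGES
from .bym import BYMSmoother, PriorSpec
from .geography import Geography, generate_geography
from .regression import EcologicalRegression, LateStageLogistic
from .scan import KulldorffScan, compare_signal_sets
from .signals import COLOUR_HEX, classify_signals, concordance
from .standardise import (StandardPopulation, compute_sir,
                          direct_standardised_rates, expected_counts,
                          observed_counts)
from .synthetic import (RiskModelParams, UnstageableError, generate_population,
                        recode_stage, simulate_cases)

logger = logging.getLogger(__name__)

__all__ = ["read_cases", "read_population", "read_geography",
           "write_signals_geojson", "RunConfig", "run_pipeline"]


def read_cases(path, geo: Geography | None = None) -> tuple[pd.DataFrame, dict]:
    """Read and validate a case table.

    Returns ``(cases, exclusions)``. Rows whose stage is missing are
    recoded from raw tumour fields (``breslow_mm``, ``ulceration``,
    ``nodal_or_distant``) when present; rows that still cannot be staged
    are excluded and counted under ``exclusions["unstageable"]``. Rows
    with a missing area id are excluded as ``ungeocodable``. A *known but
    wrong* label — a stage outside {I, II, III-IV} or an area id absent
    from the geography — is an error naming the offending row.
    """
    df = pd.read_csv(path, dtype={"area_id": str})
    excl = {"retrieved": int(len(df)), "unstageable": 0, "ungeocodable": 0}

    geocoded = df["area_id"].notna() & (df["area_id"].astype(str).str.len() > 0)
    excl["ungeocodable"] = int((~geocoded).sum())
    df = df[geocoded]
    if geo is not None:
        unknown = ~df["area_id"].isin(set(geo.area_ids))
        if unknown.any():
            row = df.index[unknown][0]
            raise ValueError(
                f"case row {row} references area {df.loc[row, 'area_id']!r} "
                "absent from the geography")

    if "stage" not in df.columns:
        df["stage"] = np.nan
    need = df["stage"].isna()
    if need.any():
        raw_cols = {"breslow_mm", "ulceration", "nodal_or_distant"}
        if raw_cols <= set(df.columns):
            staged = []
            for row, rec in df.loc[need].iterrows():
                try:
                    staged.append(recode_stage(
                        rec["breslow_mm"],
                        bool(rec["ulceration"]) if pd.notna(rec["ulceration"]) else False,
                        bool(rec["nodal_or_distant"]) if pd.notna(rec["nodal_or_distant"]) else False))
                except UnstageableError:
                    staged.append(np.nan)
            df.loc[need, "stage"] = staged
        unstageable = df["stage"].isna()
        excl["unstageable"] = int(unstageable.sum())
        df = df[~unstageable]
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(f"case row {row} has unknown stage label "
                         f"{df.loc[row, 'stage']!r}; expected one of {STAGES}")
    bad_age = ~df["age_group"].isin(AGE_GROUPS)
    if bad_age.any():
        row = df.index[bad_age][0]
        raise ValueError(f"case row {row} has unknown age group "
                         f"{df.loc[row, 'age_group']!r}")
    excl["analytic"] = int(len(df))
    logger.info("case table: %d retrieved, %d unstageable, %d not geocodable, "
                "%d analytic", excl["retrieved"], excl["unstageable"],
                excl["ungeocodable"], excl["analytic"])
    keep = [c for c in CASE_COLUMNS if c in df.columns]
    return df[keep].reset_index(drop=True), excl


def read_population(path, geo: Geography | None = None) -> pd.DataFrame:
    """Read and validate stratified person-years."""
    df = pd.read_csv(path, dtype={"area_id": str})
    dup = df.duplicated(["area_id", "sex", "age_group", "year"])
    if dup.any():
        raise ValueError(f"duplicate population strata at rows {list(df.index[dup])[:5]}")
    if (df["person_years"] < 0).any():
        row = df.index[df["person_years"] < 0][0]
        raise ValueError(f"negative person-years at row {row}")
    if not set(df["sex"]) <= set(SEXES):
        raise ValueError(f"unknown sex labels {set(df['sex']) - set(SEXES)}")
    per_ay = df.groupby(["area_id", "year"], observed=False)["age_group"].nunique()
    if (per_ay < len(AGE_GROUPS)).any():
        missing = per_ay.index[per_ay < len(AGE_GROUPS)][0]
        raise ValueError(f"area-year {missing} does not cover all 13 age bands")
    if geo is not None:
        unknown = set(df["area_id"]) - set(geo.area_ids)
        if unknown:
            raise ValueError(f"population references unknown areas {sorted(unknown)[:5]}")
    return df


def read_geography(geojson_path, adjacency_path) -> Geography:
    return Geography.read(geojson_path, adjacency_path)


def write_signals_geojson(geo: Geography, signals: pd.DataFrame, path) -> None:
    """GeoJSON overlay with signal class and fill colour per area."""
    gj = geo.to_geojson()
    for feat in gj["features"]:
        aid = feat["properties"]["area_id"]
        if aid in signals.index:
            rec = signals.loc[aid]
            feat["properties"].update(
                pp=float(rec["pp"]), signal_class=rec["class"],
                colour=rec["colour"], fill=COLOUR_HEX[rec["colour"]])
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable).

    Either ``simulate`` holds generator settings, or the three input
    paths must point at existing files. ``comparison`` selects the
    indirect-standardisation reference: ``"region"`` (whole study area)
    or the name of a subarea defined in the geography.
    """
    out_dir: str = "stagemap_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    comparison: str = "region"
    simulate: dict | None = None
    cases_path: str | None = None
    population_path: str | None = None
    geojson_path: str | None = None
    adjacency_path: str | None = None
    mcmc: dict = field(default_factory=lambda: {
        "n_iter": 20000, "burn_in": 10000, "thin": 5, "n_chains": 4})
    priors: dict = field(default_factory=dict)
    cutoffs: list[float] = field(default_factory=lambda: [0.90, 0.80, 0.20, 0.10])
    standard_population: dict | None = None
    scan: dict = field(default_factory=lambda: {"max_fraction": 0.5, "n_sim": 999})
    late_definitions: list[str] = field(default_factory=lambda: ["II-IV", "III-IV"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r} in config")
        c = self.cutoffs
        if not (c[0] > c[1] and c[2] > c[3]):
            raise ValueError("cut-offs must be strictly decreasing within each side")
        if self.simulate is None:
            for p in (self.cases_path, self.population_path,
                      self.geojson_path, self.adjacency_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file missing: {p}")


def _simulated_inputs(cfg: RunConfig):
    sim = dict(cfg.simulate or {})
    n_rows = sim.get("n_rows", 45)
    n_cols = sim.get("n_cols", 45)
    sub = None
    if sim.get("urban_block"):
        r0, r1, c0, c1 = sim["urban_block"]
        sub = {sim.get("urban_name", "urban"): (slice(r0, r1), slice(c0, c1))}
    geo = generate_geography(n_rows, n_cols,
                             income_spatial_trend=sim.get("income_spatial_trend", 0.5),
                             seed=cfg.seed, subareas=sub)
    pop = generate_population(geo, mean_area_pop=sim.get("mean_area_pop", 1600),
                              n_years=sim.get("n_years", 9), seed=cfg.seed + 1)
    effects = {s: np.asarray(v, dtype=float) for s, v in sim.get(
        "quintile_log_effects",
        {"I": [0, .1, .1, .17, .3], "II": [0, 0, 0, 0, .04],
         "III-IV": [0, 0, 0, 0, 0]}).items()}
    params = RiskModelParams(
        quintile_log_effects=effects,
        tau_u={s: sim.get("tau_u", 15.0) for s in STAGES},
        tau_v={s: sim.get("tau_v", 200.0) for s in STAGES},
        seed=cfg.seed + 2)
    cases = simulate_cases(pop, geo, params)
    return geo, pop, cases


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artifacts.

    simulate/ingest -> direct standardisation -> per-stage expected
    counts, SIRs, BYM smoothing, signal classification -> cross-stage
    concordance -> ecological regression -> case-level logistic ->
    spatial scan; plus a JSON manifest (seed, versions, timings).
    Deterministic for a fixed seed.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": list(config.stages),
                      "python": platform.python_version(),
                      "timings": {}, "completed": []}

    def _stage_done(name):
        manifest["completed"].append(name)
        manifest["timings"][name] = round(time.time() - t0, 2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        if config.simulate is not None:
            geo, pop, cases = _simulated_inputs(config)
            geo.write(out / "geography.geojson", out / "adjacency.csv")
            pop.to_csv(out / "population.csv", index=False)
            cases.to_csv(out / "cases.csv", index=False)
            exclusions = {"retrieved": len(cases), "analytic": len(cases),
                          "unstageable": 0, "ungeocodable": 0}
        else:
            geo = read_geography(config.geojson_path, config.adjacency_path)
            cases, exclusions = read_cases(config.cases_path, geo)
            pop = read_population(config.population_path, geo)
        manifest["exclusions"] = exclusions
        _stage_done("ingest")

        if config.comparison == "region":
            scope_ids = geo.area_ids
            quintile = geo.areas["quintile"]
        else:
            if config.comparison not in geo.subareas:
                raise ValueError(f"unknown comparison subarea {config.comparison!r}")
            scope_ids = geo.subareas[config.comparison]
            quintile = geo.quintiles(config.comparison)

        std = StandardPopulation(config.standard_population)
        rates = direct_standardised_rates(cases, pop, std)
        rates.to_csv(out / "rates.csv", index=False)
        _stage_done("standardise")

        mcmc = dict(config.mcmc)
        priors = PriorSpec(**config.priors) if config.priors else PriorSpec()
        smoothed: dict[str, BYMSmoother] = {}
        signal_maps: dict[str, pd.DataFrame] = {}
        for stage in config.stages:
            O = observed_counts(cases, stage, scope_ids)
            E = expected_counts(cases, pop, scope_ids, stage, areas=scope_ids)
            sir = compute_sir(O, E, stage=stage)
            sir.to_csv(out / f"sir_{_slug(stage)}.csv")
            fit = BYMSmoother(priors=priors, random_state=config.seed,
                              **mcmc).fit(sir[["O", "E"]], geo)
            fit.summary_table(stage).to_csv(out / f"smoothed_{_slug(stage)}.csv")
            smoothed[stage] = fit
            sig = classify_signals(fit.pp_, tuple(config.cutoffs))
            sig.insert(0, "stage", stage)
            sig.to_csv(out / f"signals_{_slug(stage)}.csv")
            write_signals_geojson(geo, sig, out / f"signals_{_slug(stage)}.geojson")
            signal_maps[stage] = sig
            _stage_done(f"smooth_{_slug(stage)}")

        conc = {}
        pairs = [(a, b) for a, b in zip(config.stages[1:], config.stages[:-1])]
        for a, b in pairs:
            for direction in ("elevated", "lowered"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    conc[f"{a}_vs_{b}_{direction}"] = concordance(
                        signal_maps[a], smoothed[b].theta_, direction)
        with open(out / "concordance.json", "w") as fh:
            json.dump(conc, fh, indent=2)
        _stage_done("concordance")

        eco_rows = []
        for stage, fit in smoothed.items():
            var = fit.var_log_sir_
            reg = EcologicalRegression().fit(np.log(fit.theta_), quintile,
                                             sample_weight=1.0 / var)
            tab = reg.summary_table().reset_index()
            tab.insert(0, "stage", stage)
            tab["any_elevated_signal"] = bool(
                (signal_maps[stage]["class"] == "strong_elevated").any()
                or (signal_maps[stage]["class"] == "moderate_elevated").any())
            eco_rows.append(tab)
        pd.concat(eco_rows, ignore_index=True).to_csv(out / "ecoreg.csv", index=False)
        _stage_done("ecological_regression")

        logi_rows = []
        for late in config.late_definitions:
            fitl = LateStageLogistic(late_definition=late).fit(cases, quintile=quintile)
            tab = fitl.summary_table()
            tab.insert(0, "late_definition", late)
            logi_rows.append(tab)
        pd.concat(logi_rows, ignore_index=True).to_csv(out / "logistic.csv", index=False)
        _stage_done("logistic")

        for stage in config.stages:
            sir = smoothed[stage].summary_table()[["O", "E"]]
            scan = KulldorffScan(random_state=config.seed,
                                 **config.scan).fit(sir, geo.centroids())
            sc = scan.clusters_.copy()
            sc["areas"] = sc["areas"].map(lambda xs: ";".join(xs))
            sc.to_csv(out / f"scan_{_slug(stage)}.csv", index=False)
            manifest[f"scan_overlap_{_slug(stage)}"] = compare_signal_sets(
                scan, signal_maps[stage])
            _stage_done(f"scan_{_slug(stage)}")
    except Exception as err:
        manifest["failed"] = {"stage": _next_stage_name(manifest), "error": str(err)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    manifest["wall_time_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _slug(stage: str) -> str:
    return stage.replace("-", "").replace("+", "").lower()


def _next_stage_name(manifest: dict) -> str:
    done = manifest.get("completed", [])
    return f"after:{done[-1]}" if done else "ingest"
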