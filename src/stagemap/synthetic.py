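"""Synthetic stage-stratified cancer incidence data.

The simulator is the generative mirror of the smoothing model used
downstream: stage-specific stratum counts are Poisson with intensity

    person_years * baseline_rate(sex, age, stage)
                 * exp(alpha + quintile_effect + u_i + v_i)

where ``u`` is a spatially structured intrinsic-CAR (ICAR) field on the
area adjacency graph and ``v`` is unstructured Gaussian noise. It targets
the study conditions of a regional melanoma mapping: ~2,000 areas of
600-2,600 residents, 13 adult age bands, two sexes, 9 calendar years, and
stage-specific baselines of roughly 20 / 5 / 2 per 100,000 person-years
for stage I / II / III-IV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._schema import AGE_GROUPS, DEFAULT_AGE_PYRAMID, QUINTILES, SEXES, STAGES
from .geography import Geography

__all__ = [
    "RiskModelParams", "default_baseline_rates", "generate_population",
    "simulate_cases", "sample_icar", "recode_stage", "UnstageableError",
]


class UnstageableError(ValueError):
    """Raised when a tumour record cannot be assigned a clinical stage."""


def recode_stage(breslow_mm: float | None, ulceration: bool,
                 nodal_or_distant: bool) -> str:
    """Clinical stage from Breslow thickness, ulceration and spread.

    Stage I: thickness <= 1.0 mm, or 1.1-2.0 mm without ulceration.
    Stage II: 1.1-2.0 mm with ulceration, or any tumour > 2.0 mm.
    Stage III-IV: regional nodal involvement or distant metastasis
    (pooled because stage IV is rare).

    Records with no nodal/distant spread and a missing or non-positive
    thickness cannot be staged and raise :class:`UnstageableError`.
    """
    if nodal_or_distant:
        return "III-IV"
    if breslow_mm is None or not np.isfinite(breslow_mm) or breslow_mm <= 0:
        raise UnstageableError(
            "cannot stage a localised tumour without a positive Breslow thickness")
    if breslow_mm <= 1.0:
        return "I"
    if breslow_mm <= 2.0:
        return "II" if ulceration else "I"
    return "II"


def default_baseline_rates(stage_rates: Mapping[str, float] | None = None,
                           age_gradient: float = 1.0) -> pd.DataFrame:
    """Baseline incidence per person-year by (sex, age_group, stage).

    ``stage_rates`` are overall rates per person-year (defaults: stage I
    20e-5, stage II 5e-5, stage III-IV 2e-5). Within each stage the rate
    rises with age, more steeply for later stages, so that the late-stage
    share of cases increases with age — the qualitative pattern seen in
    registry data. ``age_gradient`` scales the log-linear age slopes
    (0 = flat rates). Rates are renormalised so that, under the default
    age pyramid, each stage's population-average rate equals its
    ``stage_rates`` entry.
    """
    stage_rates = dict(stage_rates or {"I": 20e-5, "II": 5e-5, "III-IV": 2e-5})
    # log-linear slope per 5-year band, by stage
    slopes = {"I": 0.06 * age_gradient, "II": 0.22 * age_gradient,
              "III-IV": 0.14 * age_gradient}
    pyramid = np.array([DEFAULT_AGE_PYRAMID[a] for a in AGE_GROUPS])
    rows = []
    for stage in STAGES:
        shape = np.exp(slopes[stage] * np.arange(len(AGE_GROUPS)))
        shape *= stage_rates[stage] / float(pyramid @ shape)
        for sex in SEXES:
            for a, r in zip(AGE_GROUPS, shape):
                rows.append({"sex": sex, "age_group": a, "stage": stage,
                             "rate": float(r)})
    return pd.DataFrame(rows)


@dataclass
class RiskModelParams:
    """Generative parameters of the stage-specific incidence model.

    Attributes
    ----------
    baseline_rates : DataFrame (sex, age_group, stage, rate)
        Rate per person-year in each stratum; non-negative.
    quintile_log_effects : mapping stage -> length-5 array
        Log relative risks for Q1..Q5; the reference (Q1) entry must be 0.
    alpha : mapping stage -> float
        Global log-offset per stage.
    tau_u, tau_v : mapping stage -> float
        Precisions of the structured (ICAR) and unstructured random
        effects; must be positive. Large values mean weak heterogeneity.
    seed : int
    """
    baseline_rates: pd.DataFrame = field(default_factory=default_baseline_rates)
    quintile_log_effects: Mapping[str, np.ndarray] = field(
        default_factory=lambda: {s: np.zeros(5) for s in STAGES})
    alpha: Mapping[str, float] = field(default_factory=lambda: {s: 0.0 for s in STAGES})
    tau_u: Mapping[str, float] = field(default_factory=lambda: {s: 10.0 for s in STAGES})
    tau_v: Mapping[str, float] = field(default_factory=lambda: {s: 100.0 for s in STAGES})
    seed: int = 0

    def __post_init__(self):
        if (self.baseline_rates["rate"] < 0).any():
            raise ValueError("baseline rates must be non-negative")
        for s, eff in self.quintile_log_effects.items():
            eff = np.asarray(eff, dtype=float)
            if eff.shape != (5,):
                raise ValueError(f"quintile effects for stage {s} must have length 5")
            if eff[0] != 0.0:
                raise ValueError("reference quintile (Q1) effect must be fixed at 0")
        for name, taus in (("tau_u", self.tau_u), ("tau_v", self.tau_v)):
            for s, t in taus.items():
                if not t > 0:
                    raise ValueError(f"{name}[{s}] must be positive")


def generate_population(geo: Geography, mean_area_pop: float = 1600.0,
                        n_years: int = 9, seed: int = 0, *, start_year: int = 2008,
                        age_pyramid: Mapping[str, float] | None = None,
                        dispersion: float = 0.45) -> pd.DataFrame:
    """Person-years stratified by area, sex, 5-year age band and year.

    Area base sizes are uniform on ``mean_area_pop * (1 ± dispersion)``
    with ±3% i.i.d. yearly wobble, so the default (mean 1,600, dispersion
    0.45) keeps every area-year total inside the 600-2,600 band typical of
    the emulated small-area system. Strata split the total by a fixed age
    pyramid and an even sex ratio, with mild multiplicative noise; all
    13 x 2 strata are present for every area-year.
    """
    if mean_area_pop <= 0:
        raise ValueError("mean_area_pop must be positive")
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    pyramid = dict(age_pyramid or DEFAULT_AGE_PYRAMID)
    if set(pyramid) != set(AGE_GROUPS):
        raise ValueError("age pyramid must cover exactly the 13 age bands")
    w = np.array([pyramid[a] for a in AGE_GROUPS], dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    n = geo.n_areas
    base = mean_area_pop * rng.uniform(1.0 - dispersion, 1.0 + dispersion, size=n)
    years = np.arange(start_year, start_year + n_years)
    frames = []
    for yi, year in enumerate(years):
        tot = base * np.clip(rng.normal(1.0, 0.01, size=n), 0.97, 1.03)
        # stratum shares: pyramid x even sex split, jittered then renormalised
        shares = np.outer(np.ones(n), np.repeat(w / 2.0, 2))
        noise = rng.gamma(400.0, 1.0 / 400.0, size=shares.shape)
        shares = shares * noise
        shares /= shares.sum(axis=1, keepdims=True)
        py = shares * tot[:, None]
        frame = pd.DataFrame({
            "area_id": np.repeat(geo.area_ids, len(AGE_GROUPS) * 2),
            "age_group": np.tile(np.repeat(AGE_GROUPS, 2), n),
            "sex": np.tile(list(SEXES), n * len(AGE_GROUPS)),
            "year": year,
            "person_years": py.ravel(),
        })
        frames.append(frame)
    pop = pd.concat(frames, ignore_index=True)
    return pop[["area_id", "sex", "age_group", "year", "person_years"]]


def _icar_basis(graph: nx.Graph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the graph Laplacian restricted to its row space."""
    L = nx.laplacian_matrix(graph, nodelist=nodes).toarray().astype(float)
    evals, evecs = np.linalg.eigh(L)
    keep = evals > 1e-9 * max(evals.max(), 1.0)
    return evals[keep], evecs[:, keep]


def sample_icar(graph: nx.Graph, tau: float, rng: np.random.Generator,
                nodes: list[str] | None = None,
                basis: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Draw one ICAR field u ~ N(0, (tau*L)^+) constrained to sum to zero.

    The intrinsic CAR density is improper along constants; we sample the
    proper Gaussian on the orthogonal complement of the null space of the
    Laplacian L (for a connected graph: the sum-to-zero subspace), via the
    eigen-decomposition L = V diag(lambda) V'. This is the simulation
    convention matched by the fitter's sum-to-zero constraint.
    """
    if nodes is None:
        nodes = list(graph.nodes)
    if basis is None:
        basis = _icar_basis(graph, nodes)
    evals, evecs = basis
    z = rng.standard_normal(evals.size) / np.sqrt(tau * evals)
    return evecs @ z


def simulate_cases(pop: pd.DataFrame, geo: Geography,
                   params: RiskModelParams,
                   balance_fields_on: pd.Series | None = None) -> pd.DataFrame:
    """Simulate a case table from stratified person-years and risk fields.

    For each stage a fresh ICAR field ``u`` (precision ``tau_u``) and
    i.i.d. Gaussian field ``v`` (precision ``tau_v``) are drawn, the
    stratum intensity assembled as documented in the module docstring, and
    Poisson counts expanded into one row per case. Deterministic for a
    fixed ``params.seed``.

    ``balance_fields_on`` (optional per-area labels, e.g. deprivation
    quintiles) recentres each random field to mean zero within every
    label group. Use this in effect-recovery experiments: it removes the
    realised confounding between the nuisance fields and the group
    contrast, so the nominal group effects are exactly the area-level
    estimand. Leave unset to emulate observational data, where nuisance
    spatial structure is not balanced across deprivation groups.
    """
    missing = set(pop["area_id"].astype(str)) - set(geo.area_ids)
    if missing:
        raise ValueError(f"population areas absent from geography: {sorted(missing)[:5]}")
    if not geo.is_connected():
        raise ValueError("adjacency graph must be connected for ICAR simulation")
    rng = np.random.default_rng(params.seed)
    nodes = geo.area_ids
    basis = _icar_basis(geo.graph, nodes)
    area_pos = {a: i for i, a in enumerate(nodes)}
    if "quintile" in geo.areas:
        qidx = geo.areas["quintile"].map(
            {q: i for i, q in enumerate(QUINTILES)}).to_numpy()
    else:  # toy geographies (< 5 areas) carry no quintiles: all reference
        qidx = np.zeros(geo.n_areas, dtype=int)

    rates = params.baseline_rates.set_index(["sex", "age_group", "stage"])["rate"]
    strata = pop.copy()
    strata["area_id"] = strata["area_id"].astype(str)
    ai = strata["area_id"].map(area_pos).to_numpy()

    balance_idx = None
    if balance_fields_on is not None:
        labels = pd.Series(balance_fields_on).reindex(nodes)
        if labels.isna().any():
            raise ValueError("balance_fields_on must label every area")
        balance_idx = labels.to_numpy()

    out = []
    case_counter = 0
    for stage in STAGES:
        u = sample_icar(geo.graph, params.tau_u[stage], rng, nodes, basis)
        v = rng.standard_normal(len(nodes)) / np.sqrt(params.tau_v[stage])
        if balance_idx is not None:
            for field in (u, v):
                s = pd.Series(field, index=balance_idx)
                field -= s.groupby(level=0).transform("mean").to_numpy()
        qeff = np.asarray(params.quintile_log_effects[stage], dtype=float)
        log_rr = params.alpha[stage] + qeff[qidx] + u + v
        base = rates.reindex(
            pd.MultiIndex.from_arrays(
                [strata["sex"], strata["age_group"], np.repeat(stage, len(strata))])
        ).to_numpy()
        if np.isnan(base).any():
            raise ValueError("baseline_rates must cover every (sex, age_group) stratum")
        mu = strata["person_years"].to_numpy() * base * np.exp(log_rr[ai])
        counts = rng.poisson(mu)
        nz = np.nonzero(counts)[0]
        if nz.size:
            reps = counts[nz]
            block = strata.iloc[np.repeat(nz, reps)][
                ["area_id", "sex", "age_group", "year"]].copy()
            block["stage"] = stage
            out.append(block)
            case_counter += int(reps.sum())
    if not out:
        return pd.DataFrame(columns=["case_id", "area_id", "sex", "age_group",
                                     "year", "stage"])
    cases = pd.concat(out, ignore_index=True)
    cases.insert(0, "case_id", [f"C{i:07d}" for i in range(len(cases))])
    return cases
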