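"""Age standardisation and standardised incidence ratios (SIRs).

Two classical procedures:

* **Direct standardisation** for time trends: a weighted average of
  age-specific rates using an external standard population (default: the
  2013 European Standard Population restricted to ages 30+), reported per
  100,000 person-years.
* **Indirect standardisation** for small-area mapping: expected counts
  ``E_i`` from sex- and age-specific rates of a comparison population
  (the whole region for regional maps, the urban subarea for local maps),
  and the SIR ``O_i / E_i``. When the comparison population is the mapped
  population itself, the expected counts calibrate exactly:
  ``sum(E_i) == sum(O_i)``.

Plus the late-stage case-proportion tabulation (counts, column
percentages and proportion of late-stage cases per age band or
deprivation quintile) that motivates incidence-based mapping in the
first place.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._schema import AGE_GROUPS, STAGES

logger = logging.getLogger(__name__)

__all__ = [
    "StandardPopulation", "ESP2013_30PLUS", "direct_standardised_rates",
    "expected_counts", "observed_counts", "compute_sir",
    "stage_proportions", "stage_proportions_from_counts",
]

#: 2013 European Standard Population, ages 30-34 ... 90+, per 100,000.
ESP2013_30PLUS: dict[str, float] = {
    "30-34": 7000, "35-39": 7000, "40-44": 7000, "45-49": 7000,
    "50-54": 6500, "55-59": 6000, "60-64": 5500, "65-69": 5000,
    "70-74": 4000, "75-79": 2500, "80-84": 1500, "85-89": 800, "90+": 200,
}


class StandardPopulation:
    """Weights per 5-year age band used for direct standardisation.

    Defaults to the 2013 European Standard Population restricted to the
    thirteen adult bands. Weights only matter up to a constant factor.
    """

    def __init__(self, weights: Mapping[str, float] | None = None):
        weights = dict(weights if weights is not None else ESP2013_30PLUS)
        if set(weights) != set(AGE_GROUPS):
            raise ValueError("standard population must cover exactly the 13 age bands")
        w = pd.Series(weights, dtype=float).reindex(AGE_GROUPS)
        if (w < 0).any():
            raise ValueError("standard weights must be non-negative")
        if not (w > 0).any():
            raise ValueError("standard weights must have at least one positive entry")
        self.weights = w

    @property
    def normalised(self) -> pd.Series:
        return self.weights / self.weights.sum()


def direct_standardised_rates(cases: pd.DataFrame, pop: pd.DataFrame,
                              std: StandardPopulation | None = None,
                              by_sex: bool = False) -> pd.DataFrame:
    """Directly age-standardised rates per 100,000 person-years.

    Rates are computed per (year, stage); age-specific rates are pooled
    over sex by default (``by_sex=True`` stratifies). Bands with zero
    person-years and zero cases contribute rate 0 (logged); a band with
    cases but no person-years is a data inconsistency.
    """
    std = std or StandardPopulation()
    w = std.normalised
    sex_levels = [None]
    if by_sex:
        sex_levels = sorted(pop["sex"].unique())
    rows = []
    for sex in sex_levels:
        p = pop if sex is None else pop[pop["sex"] == sex]
        c = cases if sex is None else cases[cases["sex"] == sex]
        py = p.groupby(["year", "age_group"], observed=False)["person_years"].sum()
        obs = c.groupby(["year", "stage", "age_group"], observed=False).size()
        for year in sorted(p["year"].unique()):
            for stage in STAGES:
                rate = 0.0
                for a in AGE_GROUPS:
                    o = float(obs.get((year, stage, a), 0.0))
                    d = float(py.get((year, a), 0.0))
                    if d <= 0.0:
                        if o > 0:
                            raise ValueError(
                                f"cases observed in empty stratum (year={year}, "
                                f"age={a}, sex={sex})")
                        logger.warning("empty stratum year=%s age=%s contributes rate 0",
                                       year, a)
                        continue
                    rate += w[a] * o / d
                row = {"year": year, "stage": stage, "rate": 1e5 * rate}
                if sex is not None:
                    row["sex"] = sex
                rows.append(row)
    return pd.DataFrame(rows)


def observed_counts(cases: pd.DataFrame, stage: str,
                    area_ids: Iterable[str]) -> pd.Series:
    """Observed case count per area for one stage (zero-filled)."""
    sub = cases[cases["stage"] == stage]
    o = sub.groupby("area_id", observed=False).size()
    return o.reindex(list(area_ids), fill_value=0).astype(int)


def expected_counts(cases: pd.DataFrame, pop: pd.DataFrame,
                    comparison: Iterable[str], stage: str,
                    areas: Iterable[str] | None = None) -> pd.Series:
    """Indirectly standardised expected counts ``E_i`` per area.

    Reference rates per (sex, age band) are the stage-specific incidences
    of the *comparison* population, pooled over the study years; each
    area's expectation sums its person-years against those rates. With
    ``comparison`` equal to the mapped areas this is internal
    standardisation and ``sum(E) == sum(O)`` exactly.
    """
    comparison = set(map(str, comparison))
    if not comparison:
        raise ValueError("comparison area set must be non-empty")
    pop = pop.assign(area_id=pop["area_id"].astype(str))
    case_areas = set(cases["area_id"].astype(str))
    missing = case_areas - set(pop["area_id"])
    if missing:
        raise ValueError(f"cases reference areas absent from population: {sorted(missing)[:5]}")
    sub = cases[cases["stage"] == stage]
    comp_cases = sub[sub["area_id"].astype(str).isin(comparison)]
    comp_pop = pop[pop["area_id"].isin(comparison)]
    o_ref = comp_cases.groupby(["sex", "age_group"], observed=False).size()
    py_ref = comp_pop.groupby(["sex", "age_group"], observed=False)["person_years"].sum()
    rate = pd.Series(0.0, index=py_ref.index)
    pos = py_ref > 0
    rate[pos] = o_ref.reindex(py_ref.index, fill_value=0)[pos] / py_ref[pos]
    bad = (~pos) & (o_ref.reindex(py_ref.index, fill_value=0) > 0)
    if bad.any():
        raise ValueError("comparison stratum has cases but zero person-years: "
                         f"{list(py_ref.index[bad])[:5]}")
    tgt = pop if areas is None else pop[pop["area_id"].isin(set(map(str, areas)))]
    py_i = tgt.groupby(["area_id", "sex", "age_group"], observed=False)[
        "person_years"].sum().reset_index()
    py_i["rate"] = rate.reindex(
        pd.MultiIndex.from_arrays([py_i["sex"], py_i["age_group"]]),
        fill_value=0.0).to_numpy()
    e = (py_i["person_years"] * py_i["rate"]).groupby(py_i["area_id"]).sum()
    e.name = "E"
    if areas is not None:
        e = e.reindex(list(map(str, areas)), fill_value=0.0)
    return e


def compute_sir(observed: pd.Series, expected: pd.Series,
                stage: str | None = None) -> pd.DataFrame:
    """Raw SIR table: O, E and O/E per area.

    ``E = 0`` with ``O = 0`` yields a missing SIR (flagged, excluded from
    smoothing input upstream with a warning); ``E = 0`` with ``O > 0`` is
    an inconsistency and raises.
    """
    o = observed.astype(float)
    e = expected.reindex(o.index).astype(float)
    if (e < 0).any():
        raise ValueError("expected counts must be non-negative")
    impossible = (e == 0) & (o > 0)
    if impossible.any():
        raise ValueError(f"O > 0 with E = 0 in areas {list(o.index[impossible])[:5]}")
    sir = np.divide(o, e, out=np.full(len(o), np.nan), where=e > 0)
    tab = pd.DataFrame({"O": observed.astype(int), "E": e, "sir": sir},
                       index=o.index)
    tab.index.name = "area_id"
    if stage is not None:
        tab.insert(0, "stage", stage)
    if tab["sir"].isna().any():
        logger.warning("%d areas have O = E = 0; SIR undefined there",
                       int(tab["sir"].isna().sum()))
    return tab


def stage_proportions_from_counts(counts: pd.DataFrame,
                                  late_definition: str = "II-IV") -> pd.DataFrame:
    """Late-stage tabulation from a pre-aggregated group x stage table.

    Parameters
    ----------
    counts : DataFrame
        One row per group, columns named after the stages ("I", "II",
        "III-IV") holding case counts.
    late_definition : {"II-IV", "III-IV"}
        Which stages count as a late diagnosis.

    Returns
    -------
    DataFrame with per-stage counts, per-stage column percentages
    (``pct_<stage>``, each stage column summing to 100 across groups),
    group totals and the late-stage proportion.
    """
    if late_definition not in ("II-IV", "III-IV"):
        raise ValueError("late_definition must be 'II-IV' or 'III-IV'")
    out = counts[list(STAGES)].copy()
    tot_by_stage = out.sum(axis=0)
    for s in STAGES:
        denom = tot_by_stage[s]
        out[f"pct_{s}"] = 100.0 * out[s] / denom if denom > 0 else np.nan
    out["total"] = counts[list(STAGES)].sum(axis=1)
    late = out["II"] + out["III-IV"] if late_definition == "II-IV" else out["III-IV"]
    out["prop_late"] = late / out["total"]
    return out


def stage_proportions(cases: pd.DataFrame, by: str | pd.Series,
                      late_definition: str = "II-IV") -> pd.DataFrame:
    """Late-stage tabulation of a case table.

    ``by`` is either a column of the case table (e.g. ``"age_group"``) or
    a per-area label series (e.g. quintiles for some scope) indexed by
    area_id; in the latter case the tabulation is restricted to cases in
    labelled areas.
    """
    if cases["stage"].isna().any() or (~cases["stage"].isin(STAGES)).any():
        raise ValueError("every case must carry one of the three stage labels")
    if isinstance(by, str):
        groups = cases[by]
    else:
        groups = cases["area_id"].astype(str).map(by)
        cases = cases[groups.notna()]
        groups = groups.dropna()
    counts = (pd.crosstab(groups, cases["stage"])
              .reindex(columns=list(STAGES), fill_value=0))
    return stage_proportions_from_counts(counts, late_definition)
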