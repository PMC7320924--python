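"""Bundled reference tables.

`load_cmm_stage_counts` returns the published stage-at-diagnosis counts
for first invasive cutaneous malignant melanoma (ages 30+) in south-west
Sweden, 2008-2016, cross-tabulated by 5-year age band and by small-area
deprivation quintile (region-wide and within the Gothenburg and Malmoe
urban areas). These margins are the canonical fixture for the late-stage
proportion tabulation: 10,302 analytic cases split 7,302 / 2,273 / 727
across stages I / II / III-IV.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cmm_stage_counts", "CMM_CASE_FLOW"]

#: Case-flow margins of the same study window: cases retrieved from the
#: registry, excluded as unstageable or not geocodable, and the analytic n.
CMM_CASE_FLOW: dict[str, int] = {
    "retrieved": 10607,
    "unstageable": 300,
    "ungeocodable": 5,
    "analytic": 10302,
}


def load_cmm_stage_counts(grouping: str | None = None) -> pd.DataFrame:
    """Stage-specific case counts by age band and deprivation quintile.

    Parameters
    ----------
    grouping : optional
        One of ``"age_group"``, ``"region_quintile"``,
        ``"gothenburg_quintile"``, ``"malmoe_quintile"`` to select a
        single margin; by default all rows are returned.

    Returns
    -------
    DataFrame with columns ``grouping``, ``level`` and per-stage counts
    (``I``, ``II``, ``III-IV``); indexed by ``level`` when a single
    grouping is selected.
    """
    with resources.files("stagemap.data").joinpath("cmm_stage_counts.csv").open() as fh:
        tab = pd.read_csv(fh)
    if grouping is None:
        return tab
    known = tab["grouping"].unique()
    if grouping not in known:
        raise ValueError(f"grouping must be one of {sorted(known)}")
    return tab[tab["grouping"] == grouping].set_index("level")[["I", "II", "III-IV"]]
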