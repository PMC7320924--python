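"""Purely spatial Poisson scan statistic (Kulldorff-style).

Candidate clusters are circular windows: for each area centroid, the
windows are the nested sets of nearest areas whose combined expected
count stays below ``max_fraction`` of the total. Each window's evidence
is the Poisson log-likelihood ratio

    LLR = O_in * ln(O_in/E_in) + O_out * ln(O_out/E_out)   if O_in/E_in > O_out/E_out,
          0 otherwise,

with expected counts calibrated so that their total equals the total
observed count (the conditional formulation). Significance is Monte
Carlo: the total count is redistributed multinomially with probabilities
proportional to E, and the maximum LLR over all windows recomputed per
replicate; p = (1 + #{replicates >= observed}) / (n_sim + 1).

This is the sensitivity cross-check to exceedance-probability signals:
scan clusters and red/light-red signal sets can be compared by their
overlap (:func:`compare_signal_sets`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["KulldorffScan", "kulldorff_scan", "compare_signal_sets"]


def _llr(o_in, e_in, o_tot, e_tot):
    """Vectorised conditional Poisson scan LLR (0 for low-risk windows)."""
    o_out = o_tot - o_in
    e_out = e_tot - e_in
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(o_in > 0, o_in * np.log(o_in / e_in), 0.0)
        t2 = np.where(o_out > 0, o_out * np.log(o_out / e_out), 0.0)
    llr = t1 + t2
    high = o_in * e_out > o_out * e_in  # O_in/E_in > O_out/E_out
    return np.where(high, llr, 0.0)


class KulldorffScan(BaseEstimator):
    """Spatial scan for clusters of elevated incidence.

    Parameters
    ----------
    max_fraction : float in (0, 0.5]
        Maximum share of the total expected count inside a window.
    n_sim : int >= 19
        Monte Carlo replicates for the p-value.
    random_state : int

    Attributes (after fit)
    ----------------------
    clusters_ : DataFrame of non-overlapping candidate clusters sorted by
        decreasing LLR: member areas, O_in, E_in, relative risks inside
        and outside, LLR, Monte Carlo p-value (the p-value is computed
        against the null distribution of the *maximum* LLR, so it is
        conservative for secondary clusters).
    """

    def __init__(self, max_fraction: float = 0.5, n_sim: int = 999,
                 random_state: int = 0):
        self.max_fraction = max_fraction
        self.n_sim = n_sim
        self.random_state = random_state

    def fit(self, sir: pd.DataFrame, centroids: pd.DataFrame):
        """Scan a per-area (O, E) table.

        ``centroids`` must have columns ``x``, ``y`` indexed by area_id.
        Areas must all have E > 0.
        """
        if not 0 < self.max_fraction <= 0.5:
            raise ValueError("max_fraction must be in (0, 0.5]")
        if self.n_sim < 19:
            raise ValueError("need at least 19 Monte Carlo replicates")
        tab = sir.copy()
        if "area_id" in tab.columns:
            tab = tab.set_index("area_id")
        tab.index = tab.index.astype(str)
        if (tab["E"] <= 0).any():
            raise ValueError("every scanned area needs E > 0")
        ids = np.array(tab.index)
        O = tab["O"].to_numpy(dtype=float)
        E = tab["E"].to_numpy(dtype=float)
        o_tot = O.sum()
        E = E * (o_tot / E.sum())  # conditional calibration
        xy = centroids.loc[ids, ["x", "y"]].to_numpy(dtype=float)
        n = ids.size

        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        order = np.argsort(d2, axis=1, kind="stable")  # row j: areas by distance from j
        e_cum = np.cumsum(E[order], axis=1)
        o_cum = np.cumsum(O[order], axis=1)
        valid = e_cum <= self.max_fraction * E.sum() + 1e-12
        valid[:, 0] = True  # single-area windows always admissible
        llr = np.where(valid, _llr(o_cum, e_cum, o_tot, E.sum()), -np.inf)

        rng = np.random.default_rng(self.random_state)
        p = E / E.sum()
        null_max = np.empty(self.n_sim)
        for s in range(self.n_sim):
            o_sim = rng.multinomial(int(round(o_tot)), p).astype(float)
            oc = np.cumsum(o_sim[order], axis=1)
            null_max[s] = np.where(valid, _llr(oc, e_cum, o_tot, E.sum()), -np.inf).max()

        flat = np.argsort(llr, axis=None)[::-1]
        taken = np.zeros(n, dtype=bool)
        rows = []
        for f in flat:
            j, k = divmod(f, n)
            if not np.isfinite(llr[j, k]) or llr[j, k] <= 0:
                break
            members = order[j, :k + 1]
            if taken[members].any():
                continue
            taken[members] = True
            o_in, e_in = o_cum[j, k], e_cum[j, k]
            o_out, e_out = o_tot - o_in, E.sum() - e_in
            rows.append({
                "areas": list(ids[members]),
                "n_areas": k + 1,
                "O_in": int(o_in), "E_in": float(e_in),
                "rr_inside": o_in / e_in if e_in > 0 else np.nan,
                "rr_outside": o_out / e_out if e_out > 0 else np.nan,
                "llr": float(llr[j, k]),
                "p_value": float((1 + np.sum(null_max >= llr[j, k] - 1e-12))
                                 / (self.n_sim + 1)),
            })
        self.clusters_ = pd.DataFrame(
            rows, columns=["areas", "n_areas", "O_in", "E_in", "rr_inside",
                           "rr_outside", "llr", "p_value"])
        self.null_max_llr_ = null_max
        self.area_ids_ = list(ids)
        return self

    @property
    def top_cluster_(self) -> pd.Series:
        if self.clusters_.empty:
            return pd.Series(dtype=object)
        return self.clusters_.iloc[0]


def kulldorff_scan(sir: pd.DataFrame, centroids: pd.DataFrame,
                   max_fraction: float = 0.5, n_sim: int = 999,
                   seed: int = 0) -> KulldorffScan:
    return KulldorffScan(max_fraction=max_fraction, n_sim=n_sim,
                         random_state=seed).fit(sir, centroids)


def compare_signal_sets(scan: KulldorffScan, signals: pd.DataFrame) -> dict:
    """Overlap between the top scan cluster and the elevated signal set.

    The signal set is the red + light-red areas (PP > the moderate
    cut-off). Returns the Jaccard index and the 2x2 contingency counts
    over the common area universe.
    """
    universe = set(scan.area_ids_)
    if set(signals.index) != universe:
        raise ValueError("scan and signal map must cover the same areas")
    cluster = set(scan.top_cluster_["areas"]) if not scan.clusters_.empty else set()
    signal = set(signals.index[signals["class"].isin(
        ["strong_elevated", "moderate_elevated"])])
    inter = cluster & signal
    union = cluster | signal
    return {
        "jaccard": len(inter) / len(union) if union else float("nan"),
        "n_both": len(inter),
        "n_cluster_only": len(cluster - signal),
        "n_signal_only": len(signal - cluster),
        "n_neither": len(universe - union),
    }
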