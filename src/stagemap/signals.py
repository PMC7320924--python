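"""Posterior-probability signal classes and cross-stage concordance.

Areas are classified by the posterior probability PP = Pr(SIR > 1 | data)
into five bands, rendered as map colours:

    PP > 0.90          red         strong signal, elevated incidence
    0.90 >= PP > 0.80  light red   moderate signal, elevated incidence
    0.80 >= PP > 0.20  yellow      no signal
    0.20 >= PP > 0.10  light green moderate signal, lowered incidence
    0.10 >= PP         green       strong signal, lowered incidence

Boundary values belong to the lower band (PP = 0.90 is light red). The
upper cut-offs follow published simulation work on exceedance-probability
signalling; the lower ones mirror them symmetrically.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["SignalClassifier", "classify_signals", "concordance",
           "CLASS_ORDER", "CLASS_COLOURS", "COLOUR_HEX"]

CLASS_ORDER = ("strong_elevated", "moderate_elevated", "neutral",
               "moderate_lowered", "strong_lowered")

CLASS_COLOURS = {
    "strong_elevated": "red",
    "moderate_elevated": "light_red",
    "neutral": "yellow",
    "moderate_lowered": "light_green",
    "strong_lowered": "green",
}

#: Default choropleth fill colours.
COLOUR_HEX = {"red": "#d73027", "light_red": "#fc8d59", "yellow": "#ffffbf",
              "light_green": "#91cf60", "green": "#1a9850"}


class SignalClassifier(BaseEstimator):
    """Map PP values to the five signal classes.

    Parameters
    ----------
    cutoffs : four decreasing values in (0, 1), default (0.90, 0.80,
        0.20, 0.10): the strong/moderate elevated and moderate/strong
        lowered boundaries.
    """

    def __init__(self, cutoffs: Sequence[float] = (0.90, 0.80, 0.20, 0.10)):
        self.cutoffs = cutoffs

    def fit(self, pp=None, y=None):
        c = tuple(self.cutoffs)
        if len(c) != 4 or not all(1 > a > b > 0 for a, b in zip(c, c[1:])):
            raise ValueError("cutoffs must be four strictly decreasing values in (0, 1)")
        self.cutoffs_ = c
        return self

    def transform(self, pp: pd.Series | np.ndarray) -> pd.DataFrame:
        """Classify; returns a frame with pp, class and colour per area."""
        if not hasattr(self, "cutoffs_"):
            self.fit()
        vals = np.asarray(pd.Series(pp), dtype=float)
        if np.any((vals < 0) | (vals > 1) | ~np.isfinite(vals)):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        hi, mhi, mlo, lo = self.cutoffs_
        cls = np.select(
            [vals > hi, vals > mhi, vals > mlo, vals > lo],
            ["strong_elevated", "moderate_elevated", "neutral", "moderate_lowered"],
            default="strong_lowered")
        index = pp.index if isinstance(pp, pd.Series) else pd.RangeIndex(len(vals))
        out = pd.DataFrame({"pp": vals, "class": cls}, index=index)
        out["colour"] = out["class"].map(CLASS_COLOURS)
        out.index.name = "area_id"
        return out

    def fit_transform(self, pp, y=None):
        return self.fit().transform(pp)


def classify_signals(pp: pd.Series,
                     cutoffs: Sequence[float] = (0.90, 0.80, 0.20, 0.10)) -> pd.DataFrame:
    """Functional wrapper around :class:`SignalClassifier`."""
    return SignalClassifier(cutoffs=cutoffs).fit_transform(pp)


def concordance(signals_a: pd.DataFrame, sir_b: pd.Series,
                direction: str = "elevated",
                signal_threshold: float = 0.80) -> dict:
    """Cross-stage agreement between signals for stage A and SIRs for stage B.

    Selects areas whose stage-A posterior probability signals an elevated
    (PP > threshold) or lowered (PP < 1 - threshold) incidence, and counts
    how many of them have a stage-B smoothed SIR on the same side of 1.
    The threshold defaults to 0.80, i.e. strong + moderate signals count;
    it is a free parameter because published usage leaves it open.

    Returns ``{"n_signalling", "n_concordant", "fraction"}``; the fraction
    is NaN (with a warning) when no area signals.
    """
    if direction not in ("elevated", "lowered"):
        raise ValueError("direction must be 'elevated' or 'lowered'")
    pp = signals_a["pp"]
    sir_b = sir_b.reindex(pp.index)
    if sir_b.isna().any():
        raise ValueError("stage-B SIRs must cover every stage-A area")
    if direction == "elevated":
        sel = pp > signal_threshold
        conc = sir_b[sel] > 1.0
    else:
        sel = pp < 1.0 - signal_threshold
        conc = sir_b[sel] < 1.0
    n_sig = int(sel.sum())
    n_conc = int(conc.sum())
    if n_sig == 0:
        warnings.warn("no signalling areas; concordance fraction undefined")
        return {"n_signalling": 0, "n_concordant": 0, "fraction": float("nan")}
    return {"n_signalling": n_sig, "n_concordant": n_conc,
            "fraction": n_conc / n_sig}
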