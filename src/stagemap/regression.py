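"""Deprivation-incidence regressions.

Two complementary analyses:

* :class:`EcologicalRegression` — the area-level estimate of inequality
  in stage-specific incidence: weighted least squares of log smoothed SIR
  on deprivation quintile (Q1 reference), with inverse posterior
  variances of log SIR as weights. exp(coefficients) are "ratios between
  average-level incidences" per quintile.
* :class:`LateStageLogistic` — the case-level analysis of the odds of a
  late-stage diagnosis given age band, sex and quintile. This mirrors the
  conventional proportion-based assessment whose pitfalls motivate
  incidence-based mapping: a rising late-stage *proportion* in deprived
  areas can reflect deficit early-stage incidence rather than excess
  late-stage incidence.

Both delegate the ordinary fits to statsmodels (WLS, and GLM-Binomial
whose fitting algorithm is iteratively reweighted least squares) and
report Wald 95% confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._schema import AGE_GROUPS, QUINTILES, SEXES

__all__ = ["EcologicalRegression", "LateStageLogistic",
           "ecological_regression", "late_stage_logistic"]


class EcologicalRegression(BaseEstimator):
    """WLS of log smoothed SIR on deprivation quintile.

    Fit on per-area values; weights are inverse variances of log SIR
    (only their ratios matter). Fitted attributes:

    ratios_ : Series over Q1..Q5 — exp(coefficients), Q1 fixed at 1.
    conf_int_ : DataFrame (low, high) of exp-scale Wald 95% CIs.
    coef_, se_ : log-scale estimates and standard errors (Q2..Q5).
    resid_var_ : weighted residual variance (fit diagnostic).
    """

    def __init__(self, reference: str = "Q1"):
        self.reference = reference

    def fit(self, log_sir: pd.Series, quintile: pd.Series,
            sample_weight: pd.Series | np.ndarray | None = None):
        quintile = quintile.reindex(log_sir.index)
        if quintile.isna().any():
            raise ValueError("quintile labels must cover every area in the SIR input")
        present = set(quintile)
        missing = [q for q in QUINTILES if q not in present]
        if missing:
            raise ValueError(f"no areas in quintile(s) {missing}")
        counts = quintile.value_counts()
        if (counts < 2).any():
            raise ValueError("need at least 2 areas per quintile")
        if sample_weight is None:
            w = np.ones(len(log_sir))
        else:
            w = np.asarray(pd.Series(sample_weight).reindex(log_sir.index)
                           if isinstance(sample_weight, pd.Series) else sample_weight,
                           dtype=float)
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise ValueError("weights must be positive and finite")
        levels = [self.reference] + [q for q in QUINTILES if q != self.reference]
        X = pd.get_dummies(pd.Categorical(quintile, categories=levels),
                           drop_first=True, dtype=float)
        X = sm.add_constant(X)
        res = sm.WLS(np.asarray(log_sir, dtype=float), X, weights=w).fit()
        self.result_ = res
        names = list(X.columns[1:])
        coef = pd.Series(res.params[1:], index=names)
        se = pd.Series(res.bse[1:], index=names)
        ci = res.conf_int()
        ratios = {self.reference: 1.0}
        lo = {self.reference: 1.0}
        hi = {self.reference: 1.0}
        for name in names:
            ratios[str(name)] = float(np.exp(coef[name]))
            row = ci.loc[name] if hasattr(ci, "loc") else ci[list(X.columns).index(name)]
            lo[str(name)] = float(np.exp(row[0]))
            hi[str(name)] = float(np.exp(row[1]))
        order = [q for q in QUINTILES]
        self.coef_ = coef
        self.se_ = se
        self.ratios_ = pd.Series({q: ratios[q] for q in order}, name="ratio")
        self.conf_int_ = pd.DataFrame({"low": [lo[q] for q in order],
                                       "high": [hi[q] for q in order]}, index=order)
        self.resid_var_ = float(res.mse_resid)
        return self

    def summary_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({"estimate": self.ratios_,
                            "ci_low": self.conf_int_["low"],
                            "ci_high": self.conf_int_["high"]})
        tab.index.name = "quintile"
        return tab

    def propagate_draws(self, theta_draws: np.ndarray, quintile: pd.Series,
                        sample_weight=None, max_draws: int = 200):
        """Posterior-propagated interval estimates (Rubin's rules).

        The plain Wald CIs from :meth:`fit` treat the smoothed SIRs as
        fixed data, ignoring their correlated posterior uncertainty and
        hence understating interval width. Here the WLS is refitted to
        each retained posterior draw of log theta and the results
        combined as for multiple imputation: total variance = mean
        within-fit variance + (1 + 1/M) between-fit variance, with
        Rubin's degrees of freedom and t quantiles.

        Sets ``ratios_propagated_`` and ``conf_int_propagated_``.
        """
        from scipy import stats

        quintile = pd.Series(quintile)
        levels = [self.reference] + [q for q in QUINTILES if q != self.reference]
        X = pd.get_dummies(pd.Categorical(quintile, categories=levels),
                           drop_first=True, dtype=float)
        names = list(X.columns)
        X = sm.add_constant(X).to_numpy(dtype=float)
        n, p = X.shape
        w = (np.ones(n) if sample_weight is None
             else np.asarray(pd.Series(sample_weight).reindex(quintile.index)
                             if isinstance(sample_weight, pd.Series)
                             else sample_weight, dtype=float))
        draws = np.asarray(theta_draws, dtype=float)
        if draws.shape[0] > max_draws:
            draws = draws[:: draws.shape[0] // max_draws + 1]
        Y = np.log(draws)
        XtW = X.T * w
        G = np.linalg.inv(XtW @ X)
        A = G @ XtW                       # (p, n) projector
        B = Y @ A.T                       # (M, p) per-draw coefficients
        R = Y - B @ X.T
        sig2 = (w * R**2).sum(axis=1) / (n - p)
        within = sig2.mean() * np.diag(G)
        M = B.shape[0]
        qbar = B.mean(axis=0)
        between = B.var(axis=0, ddof=1)
        total = within + (1 + 1 / M) * between
        with np.errstate(divide="ignore"):
            r = (1 + 1 / M) * between / within
            dof = (M - 1) * (1 + 1 / np.where(r > 0, r, np.inf))**2
        tq = stats.t.ppf(0.975, np.clip(dof, 2.0, None))
        lo = qbar - tq * np.sqrt(total)
        hi = qbar + tq * np.sqrt(total)
        order = list(QUINTILES)
        ratios = {self.reference: 1.0}
        los = {self.reference: 1.0}
        his = {self.reference: 1.0}
        for j, name in enumerate(names, start=1):
            ratios[str(name)] = float(np.exp(qbar[j]))
            los[str(name)] = float(np.exp(lo[j]))
            his[str(name)] = float(np.exp(hi[j]))
        self.ratios_propagated_ = pd.Series({q: ratios[q] for q in order})
        self.conf_int_propagated_ = pd.DataFrame(
            {"low": [los[q] for q in order], "high": [his[q] for q in order]},
            index=order)
        return self


class LateStageLogistic(BaseEstimator):
    """Multivariable logistic regression of late-stage odds.

    Case-level outcome: stage in the late set ("II-IV": stages II and
    III-IV; "III-IV": stage III-IV only). Covariates: age band, sex and
    deprivation quintile of the case's area, treatment-coded with
    reference levels age 30-34, female, and the wealthiest quintile Q5.

    Fitted attributes: ``odds_ratios_`` and ``conf_int_`` (exp scale),
    ``coef_``/``se_`` (log-odds scale), indexed by "<variable>:<level>".
    """

    def __init__(self, late_definition: str = "II-IV",
                 reference: dict | None = None, max_iter: int = 100):
        self.late_definition = late_definition
        self.reference = reference
        self.max_iter = max_iter

    def fit(self, cases: pd.DataFrame, quintile: pd.Series | None = None,
            scope: list[str] | None = None):
        """Fit on a case table.

        ``quintile``: per-area labels (indexed by area_id); required when
        the case table has no ``quintile`` column. ``scope`` restricts to
        cases resident in the given areas (e.g. one urban subarea).
        """
        if self.late_definition not in ("II-IV", "III-IV"):
            raise ValueError("late_definition must be 'II-IV' or 'III-IV'")
        ref = {"age_group": "30-34", "sex": "F", "quintile": "Q5"}
        ref.update(self.reference or {})
        df = cases.copy()
        if scope is not None:
            df = df[df["area_id"].astype(str).isin(set(map(str, scope)))]
        if quintile is not None:
            df["quintile"] = df["area_id"].astype(str).map(quintile)
            df = df[df["quintile"].notna()]
        late_set = {"II", "III-IV"} if self.late_definition == "II-IV" else {"III-IV"}
        y = df["stage"].isin(late_set).astype(float).to_numpy()
        cols = {}
        self._terms = []
        for var, levels in (("age_group", AGE_GROUPS), ("sex", SEXES),
                            ("quintile", QUINTILES)):
            if var not in df:
                continue
            present = [lv for lv in levels if (df[var] == lv).any()]
            if ref[var] not in present:
                raise ValueError(f"reference level {ref[var]!r} of {var} has no cases")
            for lv in present:
                if lv == ref[var]:
                    continue
                cols[f"{var}:{lv}"] = (df[var] == lv).astype(float).to_numpy()
                self._terms.append((var, lv))
        X = sm.add_constant(pd.DataFrame(cols, index=df.index))
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=self.max_iter, tol=1e-10)
        except Exception as err:  # pragma: no cover - statsmodels raises rarely
            raise RuntimeError(f"logistic fit failed: {err}") from err
        if not res.converged:
            raise RuntimeError("IRLS did not converge; check for sparse strata")
        se = pd.Series(res.bse[1:], index=list(cols))
        if (se > 50).any():
            raise RuntimeError(
                "quasi-complete separation suspected (enormous standard errors); "
                f"inspect levels {list(se.index[se > 50])}; consider pooling strata")
        self.result_ = res
        self.coef_ = pd.Series(res.params[1:], index=list(cols))
        self.se_ = se
        self.odds_ratios_ = np.exp(self.coef_).rename("or")
        ci = res.conf_int()
        ci = pd.DataFrame(np.asarray(ci)[1:], index=list(cols), columns=["low", "high"])
        self.conf_int_ = np.exp(ci)
        self.reference_ = ref
        self.n_cases_ = int(len(df))
        return self

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for var, lv in self._terms:
            key = f"{var}:{lv}"
            rows.append({"term": var, "level": lv,
                         "estimate": float(self.odds_ratios_[key]),
                         "ci_low": float(self.conf_int_.loc[key, "low"]),
                         "ci_high": float(self.conf_int_.loc[key, "high"])})
        for var, lv in self.reference_.items():
            rows.append({"term": var, "level": lv, "estimate": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan})
        return pd.DataFrame(rows)


def ecological_regression(smoothed_sir: pd.Series, var_log_sir: pd.Series,
                          quintile: pd.Series) -> EcologicalRegression:
    """Weighted ecological regression of ln(smoothed SIR) on quintile.

    ``var_log_sir`` are posterior variances of log SIR; weights are their
    inverses.
    """
    var = var_log_sir.reindex(smoothed_sir.index)
    if (var <= 0).any() or var.isna().any():
        raise ValueError("log-SIR variances must be positive for every area")
    return EcologicalRegression().fit(np.log(smoothed_sir), quintile,
                                      sample_weight=1.0 / var)


def late_stage_logistic(cases: pd.DataFrame, late_definition: str = "II-IV",
                        quintile: pd.Series | None = None,
                        scope: list[str] | None = None) -> LateStageLogistic:
    return LateStageLogistic(late_definition=late_definition).fit(
        cases, quintile=quintile, scope=scope)
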