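"""Competing-risk cumulative incidence and censoring weights on the age scale.

The cohort is an illness-death system: a healthy twin can first experience
the case event (arthroplasty) or die; administrative window end and
emigration are the only true censoring mechanisms. The cause-specific
cumulative incidence is estimated by the Aalen-Johansen estimator with
delayed entry (individuals enter the risk set at their age at the window
start); its pointwise variance uses the standard delta-method estimator.

Inverse-probability-of-censoring weights reweight individuals who are fully
observed to a horizon age by 1/G(t-), where G is the Kaplan-Meier estimate
of the censoring distribution. Death before the horizon without a case event
is a fully observed non-case (an outcome state), not censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.base import BaseEstimator

__all__ = [
    "CIFCurve",
    "AalenJohansenEstimator",
    "estimate_cif",
    "CensoringWeighter",
    "censoring_weights",
]


@dataclass
class CIFCurve:
    age_grid: np.ndarray
    cif: dict          # cause -> array over the grid
    se: dict           # cause -> array over the grid
    n_at_risk: np.ndarray
    cause_labels: tuple = ("case", "death")

    def survival(self):
        return 1.0 - sum(self.cif[c] for c in self.cause_labels)


class AalenJohansenEstimator(BaseEstimator):
    """Nonparametric cause-specific cumulative incidence with delayed entry.

    fit() consumes entry ages, exit ages and exit causes ('case', 'death',
    'censored'); evaluate() returns the step functions on an age grid.
    """

    causes = ("case", "death")

    def fit(self, entry, exit_age, cause):
        entry = np.asarray(entry, float)
        exit_age = np.asarray(exit_age, float)
        cause = np.asarray(cause)
        if np.any(exit_age < entry):
            raise ValueError("exit_age before entry age")

        is_event = cause != "censored"
        times = np.unique(exit_age[is_event])
        # risk set: entered strictly before t, not yet exited (entry < t <= exit)
        n_entered = np.searchsorted(np.sort(entry), times, side="left")
        n_exited = np.searchsorted(np.sort(exit_age), times, side="left")
        n_risk = n_entered - n_exited
        d = {c: np.zeros(times.size) for c in self.causes}
        for c in self.causes:
            t_c, cnt = np.unique(exit_age[cause == c], return_counts=True)
            d[c][np.searchsorted(times, t_c)] += cnt
        d_all = sum(d.values())

        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(n_risk > 0, d_all / n_risk, 0.0)
        surv_after = np.cumprod(1.0 - frac)            # S(t_j)
        surv_before = np.concatenate([[1.0], surv_after[:-1]])  # S(t_j-)

        self.event_times_ = times
        self.n_at_risk_ = n_risk
        self.d_ = d
        self.d_all_ = d_all
        self.surv_before_ = surv_before
        self.surv_ = surv_after
        self.cif_ = {}
        for c in self.causes:
            with np.errstate(divide="ignore", invalid="ignore"):
                inc = np.where(n_risk > 0, surv_before * d[c] / n_risk, 0.0)
            self.cif_[c] = np.cumsum(inc)
        self.all_censored_ = times.size == 0
        if self.all_censored_:
            import warnings
            warnings.warn("no events observed; cumulative incidence is identically zero")
        return self

    def _variance_at(self, c, idx):
        """Delta-method variance of CIF_c at event-time index (inclusive).

        The Marubini-Valsecchi form with three cumulative pieces; vectorised
        over the prefix via cumulative sums.
        """
        n = self.n_at_risk_.astype(float)
        d_all = self.d_all_
        dc = self.d_[c]
        F = self.cif_[c]
        S = self.surv_before_
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where((n > 0) & (n > d_all), d_all / (n * (n - d_all)), 0.0)
            b = np.where(n > 0, S ** 2 * (n - dc) / n * dc / n ** 2, 0.0)
            g = np.where(n > 0, S * dc / n ** 2, 0.0)
        ca, cFa, cF2a = np.cumsum(a), np.cumsum(F * a), np.cumsum(F ** 2 * a)
        cb = np.cumsum(b)
        cg, cFg = np.cumsum(g), np.cumsum(F * g)
        Ft = F[idx]
        var = (Ft ** 2 * ca[idx] - 2 * Ft * cFa[idx] + cF2a[idx]
               + cb[idx]
               - 2 * (Ft * cg[idx] - cFg[idx]))
        return np.maximum(var, 0.0)

    def evaluate(self, age_grid) -> CIFCurve:
        age_grid = np.asarray(age_grid, float)
        if self.all_censored_:
            zero = np.zeros_like(age_grid)
            return CIFCurve(age_grid=age_grid,
                            cif={c: zero.copy() for c in self.causes},
                            se={c: zero.copy() for c in self.causes},
                            n_at_risk=zero.copy())
        idx = np.searchsorted(self.event_times_, age_grid, side="right") - 1
        cif, se = {}, {}
        for c in self.causes:
            vals = np.where(idx >= 0, self.cif_[c][np.maximum(idx, 0)], 0.0)
            cif[c] = vals
            v = np.zeros_like(age_grid)
            pos = idx >= 0
            if np.any(pos):
                v[pos] = self._variance_at(c, idx[pos])
            se[c] = np.sqrt(v)
        n_risk = np.where(idx >= 0, self.n_at_risk_[np.maximum(idx, 0)], 0)
        return CIFCurve(age_grid=age_grid, cif=cif, se=se, n_at_risk=n_risk)


def estimate_cif(cohort: pd.DataFrame, by_sex: bool = False, age_grid=None):
    """Aalen-Johansen cumulative incidence of the case and death states.

    Returns a CIFCurve, or a {'M': ..., 'F': ...} dict with ``by_sex``.
    """
    if age_grid is None:
        age_grid = np.arange(30.0, 101.0, 1.0)
    if by_sex:
        return {s: estimate_cif(cohort[cohort["sex"] == s], age_grid=age_grid)
                for s in ("M", "F")}
    est = AalenJohansenEstimator().fit(
        np.minimum(cohort["entry_age"].to_numpy(), cohort["exit_age"].to_numpy()),
        cohort["exit_age"].to_numpy(), cohort["exit_cause"].to_numpy())
    return est.evaluate(age_grid)


class CensoringWeighter(BaseEstimator):
    """IPCW transformer: per-individual response and weight at a horizon age.

    G is the Kaplan-Meier estimator of the censoring distribution on the age
    scale with delayed entry (censoring is the "event"; case and death exits
    are censored observations of the censoring time). An individual fully
    observed to the horizon — case or death before it, or still under
    observation at it — receives weight 1/G(min(exit, horizon)-), capped at
    ``cap``; an individual censored before the horizon receives weight 0.

    Parameters
    ----------
    horizon_age : age by which "affected" is evaluated.
    stratify_by_sex : estimate G separately per sex.
    cap : upper bound on weights (tail instability of 1/G); capped count is
        reported in ``n_capped_``.
    g_method : how censoring is handled. 'auto' selects 'administrative'
        when the known potential administrative censoring age (column
        ``admin_censor_age``) is present, else 'km'. Under 'administrative',
        the censoring age is a known covariate, so weighting by a marginal G
        would mix individuals with zero probability of being observed at the
        horizon into the target population; instead the analysis is
        restricted to the positivity region (admin_censor_age >= horizon,
        where status at the horizon is observable regardless of outcome) and
        the remaining genuinely random censoring (emigration) is handled by
        a delayed-entry Kaplan-Meier G within that subcohort. 'km' is the
        classic marginal Kaplan-Meier IPCW, appropriate when censoring ages
        are random and independent of the outcome.
    """

    def __init__(self, horizon_age: float = 85.0, stratify_by_sex: bool = False,
                 cap: float = 20.0, g_method: str = "auto"):
        self.horizon_age = horizon_age
        self.stratify_by_sex = stratify_by_sex
        self.cap = cap
        self.g_method = g_method

    def fit(self, cohort: pd.DataFrame, y=None):
        method = self.g_method
        if method == "auto":
            method = "administrative" if "admin_censor_age" in cohort.columns else "km"
        if method == "administrative" and "admin_censor_age" not in cohort.columns:
            raise ValueError("g_method='administrative' requires an admin_censor_age column")
        self.g_method_ = method
        if method == "administrative":
            cohort = cohort[cohort["admin_censor_age"] >= float(self.horizon_age)]
            if not len(cohort):
                raise ValueError(
                    "no individual can be observed to the horizon; lower the horizon")
        self.km_ = {}
        for key, sub in self._groups(cohort):
            # prevalent cases (exit before entry) carry no censoring information
            sub = sub[sub["exit_age"] >= sub["entry_age"]]
            kmf = KaplanMeierFitter()
            try:
                kmf.fit(sub["exit_age"].to_numpy(float),
                        (sub["exit_cause"] == "censored").to_numpy(),
                        entry=sub["entry_age"].to_numpy(float), label="G")
            except Exception as err:  # lifelines StatError: S(t) hits 0
                raise ValueError(
                    "censoring survival reaches 0 before the horizon; "
                    "lower the horizon or rely on the weight cap") from err
            sf = kmf.survival_function_["G"]
            self.km_[key] = (sf.index.to_numpy(float), sf.to_numpy(float))
        return self

    def _groups(self, cohort):
        if self.stratify_by_sex:
            return [(s, cohort[cohort["sex"] == s]) for s in ("M", "F")]
        return [("all", cohort)]

    def _g_left(self, key, t):
        """Left limit G(t-) of the fitted censoring survival."""
        times, surv = self.km_[key]
        idx = np.searchsorted(times, t, side="left") - 1
        return np.where(idx >= 0, surv[np.maximum(idx, 0)], 1.0)

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        h = float(self.horizon_age)
        exit_age = cohort["exit_age"].to_numpy(float)
        cause = cohort["exit_cause"].to_numpy()
        fully_observed = (exit_age >= h) | (cause != "censored")
        if self.g_method_ == "administrative":
            # positivity: status at the horizon must be observable a priori
            fully_observed &= cohort["admin_censor_age"].to_numpy(float) >= h
        response = (cause == "case") & (exit_age <= h)
        t_eval = np.minimum(exit_age, h)

        weight = np.zeros(len(cohort))
        n_capped = 0
        for key, sub in self._groups(cohort):
            m = cohort.index.isin(sub.index)
            g = self._g_left(key, t_eval[m])
            obs = fully_observed[m]
            if np.any(obs & (g <= 0)):
                raise ValueError(
                    "censoring survival reaches 0 before the horizon; "
                    "lower the horizon or rely on the weight cap")
            w = np.where(obs, 1.0 / np.where(g > 0, g, np.nan), 0.0)
            n_capped += int(np.sum(w > self.cap))
            weight[m] = np.minimum(w, self.cap)
        self.n_capped_ = n_capped

        out = cohort[["person_id", "pair_id", "sex", "zygosity"]].copy()
        out["horizon_age"] = h
        out["response"] = response.astype(int)
        out["weight"] = weight
        out["fully_observed"] = fully_observed
        out.attrs["weight_scheme"] = (
            f"ipcw(horizon={h},cap={self.cap},by_sex={self.stratify_by_sex})")
        return out

    def fit_transform(self, cohort, y=None):
        return self.fit(cohort).transform(cohort)


def censoring_weights(cohort: pd.DataFrame, horizon_age: float,
                      stratify_by_sex: bool = False, cap: float = 20.0) -> pd.DataFrame:
    """Functional wrapper around CensoringWeighter."""
    return CensoringWeighter(horizon_age=horizon_age,
                             stratify_by_sex=stratify_by_sex,
                             cap=cap).fit_transform(cohort)
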