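"""Liability-threshold variance-component models for twin pair data.

The binary outcome of each twin is modelled as the dichotomisation of a
latent standard-normal liability at a probit threshold; within-pair liability
correlation is structured by zygosity. The saturated model frees one
correlation per zygosity group; the biometric submodels constrain

    rMZ = a2 + d2 + c2,      rDZ = a2/2 + d2/4 + c2,

with the components of the chosen decomposition (ACE, ADE, AE, CE) living on
the unit simplex. Fitting maximises the (optionally IPCW-weighted) sum over
pairs of the log bivariate-probit likelihood; with weights, a pair enters
only when both members are fully observed and its weight is the product of
the member weights.

ACDE is rejected: with MZ and DZ pairs only, D and C are not jointly
identifiable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import approx_fprime, minimize
from scipy.special import expit, logit
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from ._bvn import cell_probs, ndtr, ndtri

__all__ = [
    "make_pair_table",
    "LiabilityVarianceModel",
    "fit_saturated",
    "fit_components",
    "compare_models",
    "heritability",
]

_GROUPS = ("MZ", "DZSS", "DZOS")


def make_pair_table(cohort: pd.DataFrame, horizon_age=None,
                    weighted_outcomes: pd.DataFrame | None = None,
                    complete_pairs_only: bool = True,
                    weight_policy: str = "shared") -> pd.DataFrame:
    """Collapse an individual-level cohort into one row per pair.

    Returns columns pair_id, zygosity, sex1, sex2, y1, y2, w. Unweighted
    (``weighted_outcomes is None``): y is "case by horizon", w = 1, and the
    complete-pairs convention drops pairs with a death during follow-up.
    With a WeightedOutcome frame from censoring weights: y is its response
    and only pairs with both members fully observed are retained.

    weight_policy controls the pair-level IPC weight. "shared" (default)
    uses max(w1, w2) = 1/G(max(u1, u2)-): twins share a birth date, hence a
    common administrative censoring age, so the probability that the pair is
    fully observed is governed by the later of the two evaluation times.
    "product" uses w1*w2, the independent-censoring rule, appropriate when
    members are censored independently.
    """
    horizon = np.inf if horizon_age is None else float(horizon_age)
    df = cohort[["person_id", "pair_id", "member_index", "sex", "zygosity",
                 "exit_age", "exit_cause"]].copy()
    if weighted_outcomes is not None:
        w = weighted_outcomes[["person_id", "response", "weight"]]
        df = df.merge(w, on="person_id", how="inner")
        df["y"] = df["response"].astype(int)
    else:
        df["y"] = ((df["exit_cause"] == "case") & (df["exit_age"] <= horizon)).astype(int)
        df["weight"] = 1.0

    # order members so that opposite-sex pairs are (male, female)
    df["_ord"] = np.where(df["zygosity"] == "DZOS",
                          np.where(df["sex"] == "M", 0, 1),
                          df["member_index"] - 1)
    df = df.sort_values(["pair_id", "_ord"])
    g = df.groupby("pair_id", sort=True)
    n_members = g.size()
    first = g.head(1).set_index("pair_id")
    second = g.tail(1).set_index("pair_id")
    if weight_policy == "shared":
        w_pair = np.maximum(first["weight"], second["weight"])
        w_pair = w_pair.where((first["weight"] > 0) & (second["weight"] > 0), 0.0)
    elif weight_policy == "product":
        w_pair = first["weight"] * second["weight"]
    else:
        raise ValueError("weight_policy must be 'shared' or 'product'")
    pairs = pd.DataFrame({
        "zygosity": first["zygosity"],
        "sex1": first["sex"], "sex2": second["sex"],
        "y1": first["y"], "y2": second["y"],
        "w": w_pair.astype(float),
    }).loc[n_members[n_members == 2].index]

    if weighted_outcomes is not None:
        pairs = pairs[pairs["w"] > 0]
        scheme = weighted_outcomes.attrs.get("weight_scheme", "ipcw") + f"|{weight_policy}"
    else:
        if complete_pairs_only:
            any_dead = (df.assign(dead=df["exit_cause"] == "death")
                        .groupby("pair_id")["dead"].any())
            pairs = pairs[~any_dead.reindex(pairs.index, fill_value=False)]
        scheme = "unweighted"
    pairs = pairs.reset_index()
    pairs.attrs["weight_scheme"] = scheme
    pairs.attrs["horizon_age"] = horizon
    return pairs


class LiabilityVarianceModel(BaseEstimator):
    """Bivariate-probit liability model over zygosity groups.

    Parameters
    ----------
    model : 'saturated', 'ACE', 'ADE', 'AE' or 'CE'.
    sex_mode : 'adjusted' fits sex-specific thresholds with shared variance
        components on all pairs (opposite-sex pairs contribute a
        mixed-threshold bivariate term); 'stratified' fits one sex's same-sex
        pairs with per-zygosity thresholds (opposite-sex pairs are dropped).
    sex : which sex to keep in stratified mode.
    pool_dz : saturated model only — share one correlation between same-sex
        and opposite-sex DZ pairs instead of freeing them separately.
    """

    def __init__(self, model: str = "ACE", sex_mode: str = "adjusted",
                 sex: str | None = None, pool_dz: bool = False,
                 max_restarts: int = 5, gtol: float = 1e-8, random_state: int = 0):
        self.model = model
        self.sex_mode = sex_mode
        self.sex = sex
        self.pool_dz = pool_dz
        self.max_restarts = max_restarts
        self.gtol = gtol
        self.random_state = random_state

    # ---- parameter mapping -------------------------------------------------
    def _n_rho_params(self):
        if self.model == "saturated":
            if self.sex_mode == "stratified":
                return 2
            return 2 if self.pool_dz else 3
        return {"ACE": 2, "ADE": 2, "AE": 1, "CE": 1}[self.model]

    def _components_from(self, x):
        """Map unconstrained stick-breaking parameters to (a2, d2, c2, e2)."""
        if self.model == "ACE":
            a2 = expit(x[0]); c2 = (1 - a2) * expit(x[1])
            return a2, 0.0, c2, 1 - a2 - c2
        if self.model == "ADE":
            a2 = expit(x[0]); d2 = (1 - a2) * expit(x[1])
            return a2, d2, 0.0, 1 - a2 - d2
        if self.model == "AE":
            a2 = expit(x[0])
            return a2, 0.0, 0.0, 1 - a2
        if self.model == "CE":
            c2 = expit(x[0])
            return 0.0, 0.0, c2, 1 - c2
        raise AssertionError

    def _rho_by_group(self, x):
        """Correlation for (MZ, DZSS, DZOS) from the rho-block parameters."""
        if self.model == "saturated":
            z = np.tanh(x)
            if self.sex_mode == "stratified":
                return np.array([z[0], z[1], np.nan])
            if self.pool_dz:
                return np.array([z[0], z[1], z[1]])
            return np.array([z[0], z[1], z[2]])
        a2, d2, c2, _ = self._components_from(x)
        rmz = a2 + d2 + c2
        rdz = 0.5 * a2 + 0.25 * d2 + c2
        return np.array([rmz, rdz, rdz])

    # ---- fitting -----------------------------------------------------------
    def fit(self, pairs: pd.DataFrame, y=None):
        if self.model == "ACDE":
            raise ValueError("ACDE is not identifiable in the classical twin design")
        if self.model not in ("saturated", "ACE", "ADE", "AE", "CE"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.sex_mode not in ("adjusted", "stratified"):
            raise ValueError("sex_mode must be 'adjusted' or 'stratified'")
        if self.sex_mode == "stratified":
            if self.sex not in ("M", "F"):
                raise ValueError("stratified mode requires sex='M' or 'F'")
            pairs = pairs[(pairs["zygosity"] != "DZOS") & (pairs["sex1"] == self.sex)]
        if not len(pairs):
            raise ValueError("no pairs to fit")

        cells = (pairs.groupby(["zygosity", "sex1", "sex2", "y1", "y2"])["w"]
                 .sum().reset_index())
        grp = cells["zygosity"].map({g: i for i, g in enumerate(_GROUPS)}).to_numpy()
        s1 = (cells["sex1"] == "F").astype(int).to_numpy()
        s2 = (cells["sex2"] == "F").astype(int).to_numpy()
        y1 = cells["y1"].to_numpy().astype(bool)
        y2 = cells["y2"].to_numpy().astype(bool)
        w = cells["w"].to_numpy(float)

        n_thr = 2 if self.sex_mode == "adjusted" else 2  # (M,F) or (MZ,DZ)
        n_rho = self._n_rho_params()

        if self.sex_mode == "adjusted":
            thr_idx1, thr_idx2 = s1, s2
        else:
            thr_idx1 = thr_idx2 = np.minimum(grp, 1)  # MZ -> 0, DZSS -> 1

        def nll(theta):
            thr = theta[:n_thr]
            rho = self._rho_by_group(theta[n_thr:])[grp]
            h1 = thr[thr_idx1]
            h2 = thr[thr_idx2]
            p11, p10, p01, p00 = cell_probs(h1, h2, rho)
            p = np.where(y1 & y2, p11,
                         np.where(y1 & ~y2, p10, np.where(~y1 & y2, p01, p00)))
            return -float(np.sum(w * np.log(p)))

        # threshold start from the weighted marginal prevalence
        q = (np.sum(w * (y1 + y2)) / (2 * np.sum(w)))
        q = min(max(q, 1e-6), 1 - 1e-6)
        t0 = ndtri(1 - q)
        if self.model == "saturated":
            x0_rho = np.full(n_rho, np.arctanh(0.3))
        elif self.model in ("ACE", "ADE"):
            x0_rho = np.array([logit(0.4), logit(0.4)])
        else:
            x0_rho = np.array([logit(0.5)])
        theta0 = np.concatenate([np.full(n_thr, t0), x0_rho])

        rng = np.random.default_rng(self.random_state)
        best = None
        for attempt in range(self.max_restarts + 1):
            start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, theta0.size)
            res = minimize(nll, start, method="L-BFGS-B",
                           options={"ftol": 1e-13, "gtol": self.gtol, "maxiter": 500})
            gnorm = float(np.max(np.abs(
                approx_fprime(res.x, nll, 1e-6 * np.maximum(1.0, np.abs(res.x))))))
            ok = res.success or gnorm < 1e-4
            if best is None or res.fun < best[0].fun - 1e-9:
                best = (res, gnorm, ok)
            if ok and attempt == 0:
                break
            if best[2] and attempt >= 1:
                break
        res, gnorm, ok = best
        theta = res.x

        self.converged_ = bool(ok)
        self.gradient_norm_ = gnorm
        self.loglik_ = float(-res.fun)
        self.n_free_params_ = int(theta.size)
        self.aic_ = 2 * self.n_free_params_ - 2 * self.loglik_
        self.n_pairs_ = int(len(pairs))
        self.sum_weights_ = float(np.sum(w))
        self.weight_scheme_id_ = pairs.attrs.get("weight_scheme", "unweighted")

        thr = theta[:n_thr]
        if self.sex_mode == "adjusted":
            self.thresholds_ = {"M": float(thr[0]), "F": float(thr[1])}
        else:
            self.thresholds_ = {"MZ": float(thr[0]), "DZ": float(thr[1])}
        self.prevalences_ = {k: float(1 - ndtr(v)) for k, v in self.thresholds_.items()}

        rho = self._rho_by_group(theta[n_thr:])
        if self.model == "saturated":
            self.correlations_ = {"MZ": float(rho[0]), "DZSS": float(rho[1])}
            if self.sex_mode == "adjusted":
                self.correlations_["DZOS"] = float(rho[2])
            self.components_ = None
            self.implied_rmz_ = float(rho[0])
            self.implied_rdz_ = self._pooled_rdz(pairs, rho)
        else:
            a2, d2, c2, e2 = self._components_from(theta[n_thr:])
            self.components_ = {"a2": float(a2), "d2": float(d2),
                                "c2": float(c2), "e2": float(e2)}
            self.correlations_ = None
            self.implied_rmz_ = float(rho[0])
            self.implied_rdz_ = float(rho[1])
        self.h2_broad_ = (None if self.components_ is None
                          else self.components_["a2"] + self.components_["d2"])

        self._delta_cis(theta, nll, n_thr)
        return self

    def _pooled_rdz(self, pairs, rho):
        """Count-weighted DZ correlation for moment-style summaries."""
        n_ss = int((pairs["zygosity"] == "DZSS").sum())
        n_os = int((pairs["zygosity"] == "DZOS").sum())
        if self.sex_mode == "stratified" or n_os == 0:
            return float(rho[1])
        return float((n_ss * rho[1] + n_os * rho[2]) / (n_ss + n_os))

    def _delta_cis(self, theta, nll, n_thr):
        """Delta-method 95% CIs from the observed information."""
        k = theta.size
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        H = np.empty((k, k))
        f0 = nll(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll(theta + ei + ej) - nll(theta + ei - ej)
                        - nll(theta - ei + ej) + nll(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        self.param_cov_ = cov

        def outputs(th):
            rho = self._rho_by_group(th[n_thr:])
            out = {}
            if self.model == "saturated":
                out["rMZ"] = rho[0]
                out["rDZSS"] = rho[1]
                if self.sex_mode == "adjusted":
                    out["rDZOS"] = rho[2]
            else:
                a2, d2, c2, e2 = self._components_from(th[n_thr:])
                out.update(a2=a2, d2=d2, c2=c2, e2=e2, h2=a2 + d2)
            return out

        names = list(outputs(theta))
        vals = outputs(theta)
        J = np.zeros((len(names), k))
        for i in range(k):
            step = np.zeros(k); step[i] = 1e-5 * max(1.0, abs(theta[i]))
            up = outputs(theta + step)
            dn = outputs(theta - step)
            for r, nm in enumerate(names):
                J[r, i] = (up[nm] - dn[nm]) / (2 * step[i])
        var = np.einsum("ri,ij,rj->r", J, cov, J)
        var = np.where(var > 0, var, np.nan)
        se = np.sqrt(var)
        self.ci95_ = {}
        for r, nm in enumerate(names):
            v = vals[nm]
            if np.isnan(se[r]):
                lo, hi = (0.0, 1.0) if nm not in ("rMZ", "rDZSS", "rDZOS") else (-1.0, 1.0)
            else:
                lo, hi = v - 1.96 * se[r], v + 1.96 * se[r]
            if nm in ("a2", "d2", "c2", "e2", "h2"):
                lo, hi = max(0.0, lo), min(1.0, hi)
            else:
                lo, hi = max(-1.0, lo), min(1.0, hi)
            self.ci95_[nm] = (float(lo), float(hi))
        if self.components_ is not None:
            self.h2_ci95_ = self.ci95_["h2"]


def fit_saturated(pairs, weights=None, sex_mode="adjusted", sex=None,
                  pool_dz=False, **kw) -> LiabilityVarianceModel:
    """Saturated fit: free correlation per zygosity group (spec thresholds)."""
    pairs = _as_pairs(pairs, weights, kw.pop("horizon_age", None))
    return LiabilityVarianceModel(model="saturated", sex_mode=sex_mode, sex=sex,
                                  pool_dz=pool_dz, **kw).fit(pairs)


def fit_components(pairs, model_tag, weights=None, sex_mode="adjusted",
                   sex=None, **kw) -> LiabilityVarianceModel:
    """Biometric submodel fit (ACE / ADE / AE / CE)."""
    pairs = _as_pairs(pairs, weights, kw.pop("horizon_age", None))
    return LiabilityVarianceModel(model=model_tag, sex_mode=sex_mode,
                                  sex=sex, **kw).fit(pairs)


def _as_pairs(obj, weights=None, horizon_age=None):
    if "y1" in getattr(obj, "columns", ()):
        return obj
    return make_pair_table(obj, horizon_age=horizon_age, weighted_outcomes=weights)


def compare_models(fit_restricted: LiabilityVarianceModel,
                   fit_general: LiabilityVarianceModel) -> dict:
    """Likelihood-ratio test of a nested pair plus AIC ranking.

    chi2 = 2 (LL_general - LL_restricted); df = difference in free
    parameters; the p-value uses the plain chi-square reference (no boundary
    mixture correction).
    """
    if fit_restricted.weight_scheme_id_ != fit_general.weight_scheme_id_:
        raise ValueError("fits use different weight schemes; LRT is not comparable")
    df = fit_general.n_free_params_ - fit_restricted.n_free_params_
    if df <= 0:
        raise ValueError("restricted model must have fewer free parameters")
    chi2 = max(0.0, 2.0 * (fit_general.loglik_ - fit_restricted.loglik_))
    return {
        "chi2": chi2,
        "df": df,
        "p": float(chi2_dist.sf(chi2, df)),
        "aic_restricted": fit_restricted.aic_,
        "aic_general": fit_general.aic_,
        "preferred_by_aic": ("restricted" if fit_restricted.aic_ <= fit_general.aic_
                             else "general"),
    }


def heritability(fit: LiabilityVarianceModel) -> dict:
    """Broad-sense heritability H2 = a2 + d2 with its delta-method CI.

    For a saturated fit without a component decomposition the moment-based
    2 (rMZ - rDZ) is returned instead, labelled as such.
    """
    if not fit.converged_:
        raise ValueError("fit did not converge")
    if fit.components_ is not None:
        return {"h2": fit.h2_broad_, "ci95": fit.h2_ci95_, "basis": "components"}
    h2 = 2.0 * (fit.implied_rmz_ - fit.implied_rdz_)
    lo_mz, hi_mz = fit.ci95_["rMZ"]
    rdz_keys = [k for k in ("rDZSS", "rDZOS") if k in fit.ci95_]
    se_mz = (hi_mz - lo_mz) / (2 * 1.96)
    se_dz = np.mean([(fit.ci95_[k][1] - fit.ci95_[k][0]) / (2 * 1.96) for k in rdz_keys])
    se = 2.0 * float(np.hypot(se_mz, se_dz))
    return {"h2": float(np.clip(h2, 0, 1)),
            "ci95": (float(max(0, h2 - 1.96 * se)), float(min(1, h2 + 1.96 * se))),
            "basis": "moment"}
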