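"""Pair concordance tables, concordance rates and tetrachoric correlations.

A 2x2 pair table of a dichotomous trait in an exchangeable twin stratum is
summarised by (n_cc, n_cd, n_dd): pairs with both, one, or neither member
affected. The tetrachoric correlation is the ML correlation of a bivariate
standard normal dichotomised at a single shared threshold that reproduces
the table; it measures within-pair similarity on the liability scale.

Two concordance notions are kept deliberately distinct: the count-based
pairwise/proband-wise rates computed directly from a table, and the
model-based case-wise concordance implied by a (rho, prevalence) pair under
the liability model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._bvn import bvn_upper, cell_probs, ndtr, ndtri

__all__ = [
    "PairContingency",
    "pair_contingency",
    "concordance_rates",
    "TetrachoricCorrelation",
    "tetrachoric",
    "model_casewise",
]

STRATA = {"MZM": ("MZ", "M"), "MZF": ("MZ", "F"),
          "DZM": ("DZSS", "M"), "DZF": ("DZSS", "F"),
          "OSDZ": ("DZOS", None)}


@dataclass(frozen=True)
class PairContingency:
    n_cc: int
    n_cd: int
    n_dd: int
    stratum: str = "pooled"
    complete_pairs_only: bool = True

    def __post_init__(self):
        if min(self.n_cc, self.n_cd, self.n_dd) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_cc + self.n_cd + self.n_dd

    @property
    def prevalence(self) -> float:
        """Per-individual prevalence q = (2 n_cc + n_cd) / (2 total)."""
        return (2 * self.n_cc + self.n_cd) / (2 * self.total)


def pair_contingency(cohort: pd.DataFrame, stratum: str,
                     horizon_age: Optional[float] = None,
                     complete_pairs_only: bool = True) -> PairContingency:
    """Build the pair table for one zygosity/sex stratum.

    ``affected`` means a case event by ``horizon_age`` (by end of follow-up
    when omitted). With ``complete_pairs_only`` pairs with a member dead
    before follow-up end are dropped, the convention for raw registry
    concordance tables.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; one of {sorted(STRATA)}")
    zyg, sex = STRATA[stratum]
    sub = cohort[cohort["zygosity"] == zyg]
    if sex is not None:
        pair_sex = sub.groupby("pair_id")["sex"].agg(lambda s: s.iloc[0])
        sub = sub[sub["pair_id"].isin(pair_sex[pair_sex == sex].index)]

    horizon = np.inf if horizon_age is None else float(horizon_age)
    affected = (sub["exit_cause"].to_numpy() == "case") & (sub["exit_age"].to_numpy() <= horizon)
    g = pd.DataFrame({"pair_id": sub["pair_id"].to_numpy(),
                      "affected": affected,
                      "dead": sub["exit_cause"].to_numpy() == "death"}).groupby("pair_id")
    n_aff = g["affected"].sum()
    n_members = g.size()
    any_dead = g["dead"].any()

    keep = n_members == 2
    if complete_pairs_only:
        keep &= ~any_dead
    n_aff = n_aff[keep]
    return PairContingency(int((n_aff == 2).sum()), int((n_aff == 1).sum()),
                           int((n_aff == 0).sum()), stratum=stratum,
                           complete_pairs_only=complete_pairs_only)


def concordance_rates(tab: PairContingency) -> dict:
    """Pairwise and proband-wise concordance from a pair table.

    pairwise = n_cc / (n_cc + n_cd); probandwise = 2 n_cc / (2 n_cc + n_cd)
    (complete-ascertainment convention). Both are None, with ``defined`` set
    False, when there is no affected pair to condition on.
    """
    if tab.total <= 0:
        raise ValueError("empty table")
    denom = tab.n_cc + tab.n_cd
    if denom == 0:
        return {"pairwise": None, "probandwise": None, "defined": False}
    return {"pairwise": tab.n_cc / denom,
            "probandwise": 2 * tab.n_cc / (2 * tab.n_cc + tab.n_cd),
            "defined": True}


class TetrachoricCorrelation(BaseEstimator):
    """ML tetrachoric correlation of an exchangeable twin pair table.

    Maximises the double-entered symmetric bivariate-normal likelihood with a
    single threshold shared by both pair members; the discordant mass is
    split evenly across the two off-diagonal cells. Confidence intervals are
    delta-method on the atanh scale, guaranteeing the interval contains the
    estimate.

    Parameters
    ----------
    continuity_correction : add 0.5 to every cell before fitting (off by
        default); degenerate tables (a zero margin) otherwise return a
        boundary flag instead of an estimate at +-1.
    """

    def __init__(self, continuity_correction: bool = False):
        self.continuity_correction = continuity_correction

    def fit(self, X, y=None, sample_weight=None):
        """Fit from a PairContingency, an (n_cc, n_cd, n_dd) triple, or an
        (n, 2) binary pair matrix (optionally weighted)."""
        if isinstance(X, PairContingency):
            counts = np.array([X.n_cc, X.n_cd, X.n_dd], float)
        else:
            X = np.asarray(X, float)
            if X.ndim == 2 and X.shape[1] == 2:
                w = np.ones(len(X)) if sample_weight is None else np.asarray(sample_weight, float)
                s = X.sum(axis=1)
                counts = np.array([w[s == 2].sum(), w[s == 1].sum(), w[s == 0].sum()])
            elif X.shape == (3,):
                counts = X
            else:
                raise ValueError("X must be a pair table, a count triple, or an (n,2) binary matrix")
        if self.continuity_correction:
            counts = counts + 0.5

        n_cc, n_cd, n_dd = counts
        total = counts.sum()
        n_affected = 2 * n_cc + n_cd
        # zero margin: nothing above (or below) the threshold
        if n_affected == 0 or 2 * n_dd + n_cd == 0:
            self.boundary_ = True
            self.rho_ = None
            self.threshold_ = None
            self.ci95_ = None
            self.loglik_ = 0.0
            return self

        q = n_affected / (2.0 * total)

        def nll(p):
            tau, z = p
            rho = np.tanh(z)
            p11, p10, p01, p00 = cell_probs(tau, tau, rho)
            return -(n_cc * np.log(p11) + n_cd * np.log(p10 + p01) + n_dd * np.log(p00))

        # crude moment start for rho from the concordant-affected cell
        tau0 = float(ndtri(1.0 - q))
        res = minimize(nll, [tau0, np.arctanh(0.2)], method="L-BFGS-B",
                       options={"ftol": 1e-14, "gtol": 1e-10})
        tau, z = res.x
        self.rho_ = float(np.tanh(z))
        self.boundary_ = bool(abs(self.rho_) > 1 - 1e-7)
        self.threshold_ = float(tau)
        self.loglik_ = float(-res.fun)
        self.converged_ = bool(res.success)

        # delta-method CI on the atanh scale from the observed information
        h = 1e-5
        grid = np.array([[tau, z - h], [tau, z], [tau, z + h],
                         [tau - h, z], [tau + h, z],
                         [tau - h, z - h], [tau + h, z + h],
                         [tau - h, z + h], [tau + h, z - h]])
        f = np.array([nll(p) for p in grid])
        d2z = (f[0] - 2 * f[1] + f[2]) / h ** 2
        d2t = (f[3] - 2 * f[1] + f[4]) / h ** 2
        dtz = (f[6] + f[5] - f[7] - f[8]) / (4 * h ** 2)
        # observed information of (tau, z); invert for var(z)
        info = np.array([[d2t, dtz], [dtz, d2z]])
        try:
            var_z = np.linalg.inv(info)[1, 1]
        except np.linalg.LinAlgError:
            var_z = np.nan
        if np.isfinite(var_z) and var_z > 0:
            se_z = np.sqrt(var_z)
            self.ci95_ = (float(np.tanh(z - 1.96 * se_z)), float(np.tanh(z + 1.96 * se_z)))
        else:
            self.ci95_ = (-1.0, 1.0)
        return self


def tetrachoric(tab, continuity_correction: bool = False) -> TetrachoricCorrelation:
    """Functional wrapper: fitted TetrachoricCorrelation for a pair table."""
    return TetrachoricCorrelation(continuity_correction=continuity_correction).fit(tab)


def model_casewise(rho: float, q: float) -> float:
    """Model-based case-wise concordance under the liability model.

    P(twin affected | co-twin affected) = Phi2_upper(z, z; rho) / q with
    z = Phi^-1(1 - q).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("prevalence q must lie in (0, 1)")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    z = ndtri(1.0 - q)
    return float(bvn_upper(z, z, rho) / q)
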