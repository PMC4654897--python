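"""Pair tables, concordance rates and the tetrachoric ML estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr
from scipy.optimize import minimize_scalar

from twinliab import (PairContingency, TetrachoricCorrelation,
                      concordance_rates, model_casewise, pair_contingency,
                      tetrachoric)


def make_pairs_cohort(cells, zygosity="MZ", sex="M"):
    """Cohort frame from a list of (y1, y2, n_pairs) cells."""
    rows = []
    pid = 0
    for y1, y2, n in cells:
        for _ in range(n):
            pid += 1
            for j, y in ((1, y1), (2, y2)):
                rows.append({"person_id": 2 * pid - 2 + j, "pair_id": pid,
                             "member_index": j, "sex": sex, "zygosity": zygosity,
                             "entry_age": 30.0,
                             "exit_age": 60.0 if y else 80.0,
                             "exit_cause": "case" if y else "censored"})
    return pd.DataFrame(rows)


class TestPairContingency:
    def test_all_concordant(self):
        cohort = make_pairs_cohort([(1, 1, 100)])
        tab = pair_contingency(cohort, "MZM")
        assert (tab.n_cc, tab.n_cd, tab.n_dd) == (100, 0, 0)

    def test_margins_arithmetic(self):
        tab = PairContingency(10, 57, 4558, stratum="MZM")
        assert tab.total == 4625
        assert tab.prevalence == pytest.approx(77 / 9250)

    def test_empty_stratum_is_zero_table(self):
        cohort = make_pairs_cohort([(1, 0, 3)], zygosity="MZ", sex="M")
        tab = pair_contingency(cohort, "MZF")
        assert tab.total == 0

    def test_unknown_stratum(self):
        with pytest.raises(ValueError, match="stratum"):
            pair_contingency(make_pairs_cohort([(0, 0, 1)]), "XX")

    def test_complete_pairs_drop_deaths(self):
        cohort = make_pairs_cohort([(1, 0, 5), (0, 0, 5)])
        cohort.loc[cohort["person_id"] == 2, "exit_cause"] = "death"
        tab = pair_contingency(cohort, "MZM")
        assert tab.total == 9
        tab_all = pair_contingency(cohort, "MZM", complete_pairs_only=False)
        assert tab_all.total == 10

    def test_horizon_restricts_cases(self):
        cohort = make_pairs_cohort([(1, 0, 4)])  # cases at age 60
        assert pair_contingency(cohort, "MZM", horizon_age=50.0).n_cd == 0
        assert pair_contingency(cohort, "MZM", horizon_age=65.0).n_cd == 4


class TestConcordanceRates:
    def test_printed_count_example(self):
        r = concordance_rates(PairContingency(10, 57, 4558))
        assert r["pairwise"] == pytest.approx(0.149, abs=5e-4)
        assert r["probandwise"] == pytest.approx(0.260, abs=5e-4)

    @pytest.mark.parametrize("tab,pw,prob", [
        (PairContingency(5, 0, 10), 1.0, 1.0),
        (PairContingency(0, 7, 10), 0.0, 0.0),
    ])
    def test_degenerate_corners(self, tab, pw, prob):
        r = concordance_rates(tab)
        assert (r["pairwise"], r["probandwise"]) == (pw, prob)

    def test_no_affected_pair_is_flagged(self):
        r = concordance_rates(PairContingency(0, 0, 10))
        assert not r["defined"] and r["pairwise"] is None

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(ncc=st.integers(0, 300), ncd=st.integers(0, 300),
           ndd=st.integers(0, 3000))
    def test_probandwise_dominates_pairwise(self, ncc, ncd, ndd):
        if ncc + ncd == 0:
            return
        r = concordance_rates(PairContingency(ncc, ncd, ndd))
        assert r["probandwise"] >= r["pairwise"]
        if ncc * ncd == 0:
            assert r["probandwise"] == r["pairwise"]
        else:
            assert r["probandwise"] > r["pairwise"]


_GL_NODES = np.polynomial.legendre.leggauss(220)


def profile_loglik_oracle(counts, rho):
    """Profile log-likelihood over the threshold at fixed rho.

    Independent numerics: the concordant-affected orthant is integrated with
    Gauss-Legendre quadrature of phi(x) * Phibar((tau - rho x)/sqrt(1-rho^2))
    rather than any closed form, and the threshold profile uses Brent search.
    """
    ncc, ncd, ndd = counts
    nodes, weights = _GL_NODES

    def upper_orthant(tau):
        lo, hi = tau, 9.0
        x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * weights
        phi = np.exp(-0.5 * x ** 2) / np.sqrt(2 * np.pi)
        inner = 1.0 - ndtr((tau - rho * x) / np.sqrt(1 - rho ** 2))
        return float(np.sum(w * phi * inner))

    def nll(tau):
        p11 = upper_orthant(tau)
        pbar = 1.0 - ndtr(tau)
        p_disc = 2.0 * max(pbar - p11, 1e-300)
        p00 = max(1.0 - 2 * pbar + p11, 1e-300)
        return -(ncc * np.log(max(p11, 1e-300)) + ncd * np.log(p_disc)
                 + ndd * np.log(p00))

    res = minimize_scalar(nll, bracket=(1.0, 2.5), method="brent",
                          options={"xtol": 1e-10})
    return -res.fun


@pytest.mark.parametrize("counts", [(10, 57, 4558), (30, 100, 2000)])
def test_ml_matches_grid_search_oracle(counts):
    """ML solution against a rho-grid oracle with independent quadrature.

    The oracle profiles the threshold by Brent search at each grid rho and
    integrates the orthant with Gauss-Legendre quadrature (no closed form).
    Checks: (a) the likelihood function itself agrees with the quadrature
    oracle to 1e-6 at the oracle's best grid point, (b) the ML optimum
    dominates every grid value, and (c) the gap to the best grid value is
    bounded by the quadratic grid-quantisation term.
    """
    est = TetrachoricCorrelation().fit(np.array(counts, float))
    grid = np.arange(-0.999, 0.9995, 1e-3)
    # profile the neighbourhood of the optimum densely and the rest coarsely:
    # the loglik is smooth and unimodal, so far-away rho cannot beat the
    # local profile
    coarse = grid[::25]
    ll_coarse = np.array([profile_loglik_oracle(counts, r) for r in coarse])
    top = coarse[np.argmax(ll_coarse)]
    local = grid[np.abs(grid - top) <= 0.03]
    ll_local = {r: profile_loglik_oracle(counts, r) for r in local}
    best_rho = max(ll_local, key=ll_local.get)
    best = max(ll_local[best_rho], ll_coarse.max())

    # (a) same likelihood value at the oracle's best rho, computed by our
    # closed-form cells with our own threshold profile
    from twinliab._bvn import cell_probs
    from twinliab._bvn import ndtri as _ndtri

    def own_profile(rho):
        ncc, ncd, ndd = counts

        def nll(tau):
            p11, p10, p01, p00 = cell_probs(tau, tau, rho)
            return -(ncc * np.log(p11) + ncd * np.log(p10 + p01)
                     + ndd * np.log(p00))
        res = minimize_scalar(nll, bracket=(1.0, 2.5), method="brent",
                              options={"xtol": 1e-10})
        return -res.fun

    assert own_profile(best_rho) == pytest.approx(ll_local[best_rho], abs=1e-6)
    # (b) ML dominates the grid; (c) quantisation gap only
    assert est.loglik_ >= best - 1e-9
    assert est.loglik_ - best < 1e-4


class TestTetrachoric:
    def test_independence_limit(self):
        q = 0.3
        n = 10_000
        ncc = int(round(q * q * n))
        ncd = int(round(2 * q * (1 - q) * n))
        tab = PairContingency(ncc, ncd, n - ncc - ncd)
        est = tetrachoric(tab)
        assert abs(est.rho_) < 0.02
        assert est.ci95_[0] <= est.rho_ <= est.ci95_[1]

    def test_recovers_known_rho_from_sampled_tables(self):
        from twinliab._bvn import bvn_upper, ndtri
        rng = np.random.default_rng(5)
        rho, q, n = 0.6, 0.1, 20_000
        tau = ndtri(1 - q)
        p11 = float(bvn_upper(tau, tau, rho))
        p_disc = 2 * (q - p11)
        for _ in range(5):
            ncc, ncd, ndd = rng.multinomial(n, [p11, p_disc, 1 - p11 - p_disc])
            est = tetrachoric(PairContingency(ncc, ncd, ndd))
            se = (est.ci95_[1] - est.ci95_[0]) / (2 * 1.96)
            assert abs(est.rho_ - rho) < 3 * se

    def test_boundary_table_is_flagged(self):
        est = tetrachoric(PairContingency(0, 0, 100))
        assert est.boundary_ and est.rho_ is None

    def test_continuity_correction_moves_off_boundary(self):
        est = tetrachoric(PairContingency(5, 0, 95), continuity_correction=True)
        assert est.rho_ is not None and abs(est.rho_) < 1

    def test_accepts_pair_matrix_with_weights(self):
        X = np.array([[1, 1]] * 10 + [[1, 0]] * 57 + [[0, 0]] * 4558)
        est = TetrachoricCorrelation().fit(X)
        ref = tetrachoric(PairContingency(10, 57, 4558))
        assert est.rho_ == pytest.approx(ref.rho_, abs=1e-9)


class TestModelCasewise:
    def test_independence_returns_prevalence(self):
        assert model_casewise(0.0, 0.06) == pytest.approx(0.06, abs=1e-9)

    def test_comonotone_limit(self):
        assert model_casewise(0.9999, 0.06) > 0.97

    def test_strictly_increasing_in_rho(self):
        vals = [model_casewise(r, 0.06) for r in np.linspace(-0.5, 0.95, 30)]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("bad_q", [0.0, 1.0, -0.1])
    def test_invalid_prevalence(self, bad_q):
        with pytest.raises(ValueError):
            model_casewise(0.5, bad_q)
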