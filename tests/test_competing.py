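"""Aalen-Johansen cumulative incidence and censoring weights."""

import numpy as np
import pandas as pd
import pytest
from lifelines import AalenJohansenFitter, KaplanMeierFitter

from twinliab import (AalenJohansenEstimator, CensoringWeighter,
                      censoring_weights, default_params, estimate_cif,
                      simulate_cohort)
from twinliab.simulate import GompertzMortality

# 8-record toy; Aalen-Johansen values worked out by hand before implementation
TOY_EXIT = np.array([50, 55, 60, 62, 65, 70, 72, 80], float)
TOY_CAUSE = np.array(["censored", "case", "death", "case",
                      "censored", "case", "death", "censored"])


def toy_cohort():
    return pd.DataFrame({
        "person_id": np.arange(8), "pair_id": np.arange(8) // 2,
        "sex": ["M"] * 8, "zygosity": ["MZ"] * 8,
        "entry_age": np.zeros(8), "exit_age": TOY_EXIT, "exit_cause": TOY_CAUSE})


def test_hand_computed_aalen_johansen_fixture():
    est = AalenJohansenEstimator().fit(np.zeros(8), TOY_EXIT, TOY_CAUSE)
    curve = est.evaluate([58.0, 75.0])
    assert curve.cif["case"][0] == pytest.approx(1 / 7, abs=1e-12)
    assert curve.cif["case"][1] == pytest.approx(10 / 21, abs=1e-12)
    assert curve.cif["death"][1] == pytest.approx(1 / 3, abs=1e-12)
    assert curve.survival()[1] == pytest.approx(4 / 21, abs=1e-12)
    assert (curve.se["case"] > 0).all()


def test_matches_lifelines_without_truncation():
    rng = np.random.default_rng(2)
    n = 400
    t_case = rng.exponential(40, n)
    t_death = rng.exponential(60, n)
    t_cens = rng.uniform(5, 80, n)
    exit_age = np.minimum.reduce([t_case, t_death, t_cens])
    cause = np.where(t_case == exit_age, "case",
                     np.where(t_death == exit_age, "death", "censored"))
    est = AalenJohansenEstimator().fit(np.zeros(n), exit_age, cause)

    aj = AalenJohansenFitter(calculate_variance=True, seed=0)
    codes = np.where(cause == "case", 1, np.where(cause == "death", 2, 0))
    aj.fit(exit_age, codes, event_of_interest=1)
    grid = [10.0, 25.0, 50.0, 70.0]
    ours = est.evaluate(grid)
    theirs = aj.cumulative_density_.reindex(
        aj.cumulative_density_.index.union(grid)).ffill().loc[grid].iloc[:, 0]
    assert np.allclose(ours.cif["case"], theirs.to_numpy(), atol=1e-10)
    vars_ = aj.variance_.reindex(
        aj.variance_.index.union(grid)).ffill().loc[grid]
    assert np.allclose(ours.se["case"] ** 2, vars_.to_numpy(), rtol=1e-6)


def test_no_death_no_censoring_cif_is_the_ecdf(complete_cohort):
    cohort, _ = complete_cohort
    sub = cohort.sample(6000, random_state=1)
    curve = estimate_cif(sub, age_grid=[60.0, 75.0, 90.0])
    cases = sub[sub["exit_cause"] == "case"]
    for i, age in enumerate([60.0, 75.0, 90.0]):
        ecdf = (cases["exit_age"] <= age).sum() / len(sub)
        assert curve.cif["case"][i] == pytest.approx(ecdf, abs=1e-10)


def test_single_cause_cif_is_one_minus_km():
    rng = np.random.default_rng(3)
    n = 500
    t = rng.weibull(2, n) * 50
    c = rng.uniform(10, 70, n)
    exit_age = np.minimum(t, c)
    cause = np.where(t <= c, "case", "censored")
    est = AalenJohansenEstimator().fit(np.zeros(n), exit_age, cause)
    kmf = KaplanMeierFitter().fit(exit_age, cause == "case")
    grid = [20.0, 35.0, 55.0]
    ours = est.evaluate(grid)
    km = kmf.survival_function_at_times(grid).to_numpy()
    assert np.allclose(ours.cif["case"], 1 - km, atol=1e-10)


def test_monotone_and_conserving_on_registry_cohort(paper_cohort):
    for sex, curve in estimate_cif(paper_cohort, by_sex=True).items():
        for c in ("case", "death"):
            assert np.all(np.diff(curve.cif[c]) >= -1e-12)
            assert np.all(curve.cif[c] >= 0)
        total = curve.survival() + curve.cif["case"] + curve.cif["death"]
        assert np.allclose(total, 1.0, atol=1e-10)


def test_disjoint_halves_agree(paper_cohort):
    half1 = paper_cohort[paper_cohort["pair_id"] % 2 == 0]
    half2 = paper_cohort[paper_cohort["pair_id"] % 2 == 1]
    grid = np.arange(55.0, 91.0, 5.0)
    c1 = estimate_cif(half1, age_grid=grid)
    c2 = estimate_cif(half2, age_grid=grid)
    se = np.sqrt(c1.se["case"] ** 2 + c2.se["case"] ** 2)
    assert np.all(np.abs(c1.cif["case"] - c2.cif["case"]) < 3 * np.maximum(se, 1e-6))


def test_all_censored_warns_and_returns_zero():
    cohort = pd.DataFrame({"entry_age": [0.0, 0.0], "exit_age": [50.0, 60.0],
                           "exit_cause": ["censored", "censored"],
                           "sex": ["M", "M"]})
    with pytest.warns(UserWarning, match="no events"):
        curve = estimate_cif(cohort, age_grid=[55.0])
    assert curve.cif["case"][0] == 0.0


def test_fourfold_increase_from_age_60_to_85(paper_cohort):
    """The case CIF rises steeply late in life: CIF(85)/CIF(60) in [3, 6]."""
    for sex, curve in estimate_cif(paper_cohort, by_sex=True,
                                   age_grid=[60.0, 85.0]).items():
        ratio = curve.cif["case"][1] / curve.cif["case"][0]
        assert 3.0 <= ratio <= 6.0, (sex, ratio)


class TestCensoringWeights:
    def test_hand_computed_km_weight_fixture(self):
        """4 individuals, horizon 75; weights worked out by hand (KM G)."""
        cohort = pd.DataFrame({
            "person_id": [1, 2, 3, 4], "pair_id": [1, 1, 2, 2],
            "sex": ["M", "M", "F", "F"], "zygosity": ["MZ"] * 4,
            "entry_age": [0.0] * 4,
            "exit_age": [60.0, 65.0, 70.0, 78.0],
            "exit_cause": ["case", "censored", "death", "censored"]})
        w = censoring_weights(cohort, 75.0).set_index("person_id")
        assert w.loc[1, "weight"] == pytest.approx(1.0)
        assert w.loc[2, "weight"] == 0.0 and not w.loc[2, "fully_observed"]
        assert w.loc[3, "weight"] == pytest.approx(1.5)
        assert w.loc[4, "weight"] == pytest.approx(1.5)
        assert w.loc[1, "response"] == 1
        assert w.loc[3, "response"] == 0  # death is an observed non-case

    def test_no_censoring_gives_unit_weights(self):
        rng = np.random.default_rng(4)
        n = 200
        cohort = pd.DataFrame({
            "person_id": np.arange(n), "pair_id": np.arange(n) // 2,
            "sex": ["M"] * n, "zygosity": ["MZ"] * n,
            "entry_age": np.zeros(n),
            "exit_age": rng.uniform(40, 90, n),
            "exit_cause": rng.choice(["case", "death"], n)})
        w = censoring_weights(cohort, 85.0)
        assert np.allclose(w["weight"], 1.0)

    def test_weighted_mean_recovers_latent_prevalence(self):
        """IPCW undoes censoring: weighted response mean ~= K(horizon)."""
        p = default_params(n_pairs=20_000, seed=43, emit_prevalent=True,
                           mortality=GompertzMortality(1e-12, 1e-12, 0.05),
                           emigration_rate=0.0)
        cohort = simulate_cohort(p)
        h = 75.0
        w = censoring_weights(cohort, h)
        k_true = float(p.threshold.cum_onset(h))
        obs = w[w["weight"] > 0]
        est = np.sum(obs["weight"] * obs["response"]) / np.sum(obs["weight"])
        n_eff = np.sum(obs["weight"]) ** 2 / np.sum(obs["weight"] ** 2)
        se = np.sqrt(k_true * (1 - k_true) / n_eff)
        assert abs(est - k_true) < 4 * se
        naive = (cohort["exit_cause"] == "case").mean()
        assert naive < k_true - 4 * se  # unweighted underestimates

    def test_weight_sum_tracks_eligible_count(self, paper_cohort):
        w = censoring_weights(paper_cohort, 70.0)
        n_eligible = int((paper_cohort["admin_censor_age"] >= 70.0).sum())
        assert abs(w["weight"].sum() / n_eligible - 1.0) < 0.05

    def test_horizon_beyond_observation_errors(self):
        cohort = pd.DataFrame({
            "person_id": [1, 2], "pair_id": [1, 1], "sex": ["M", "M"],
            "zygosity": ["MZ"] * 2, "entry_age": [50.0, 50.0],
            "exit_age": [60.0, 61.0], "exit_cause": ["censored", "censored"],
            "admin_censor_age": [60.0, 61.0]})
        with pytest.raises(ValueError, match="horizon"):
            censoring_weights(cohort, 80.0)

    def test_km_mode_g_hits_zero_errors(self):
        cohort = pd.DataFrame({
            "person_id": np.arange(6), "pair_id": np.arange(6) // 2,
            "sex": ["M"] * 6, "zygosity": ["MZ"] * 6,
            "entry_age": [0.0] * 5 + [62.0],
            "exit_age": [60.0] * 5 + [70.0],
            "exit_cause": ["censored"] * 5 + ["death"]})
        # G hits 0 at 60, but the late entrant's death at 70 needs G beyond it
        with pytest.raises(ValueError, match="lower the horizon|cap"):
            censoring_weights(cohort, 75.0)

    def test_cap_is_applied_and_counted(self):
        cohort = pd.DataFrame({
            "person_id": np.arange(20), "pair_id": np.arange(20) // 2,
            "sex": ["M"] * 20, "zygosity": ["MZ"] * 20,
            "entry_age": np.zeros(20),
            "exit_age": [60.0] * 18 + [70.0, 72.0],
            "exit_cause": ["censored"] * 18 + ["case", "death"]})
        cw = CensoringWeighter(horizon_age=75.0, cap=3.0).fit(cohort)
        w = cw.transform(cohort)
        assert w["weight"].max() <= 3.0
        assert cw.n_capped_ >= 1
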