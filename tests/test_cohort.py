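"""Exclusions, endpoints, splitting, screening, BH, incidence, logistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hedratio import (
    CohortError,
    FitError,
    apply_exclusions,
    baseline_table,
    bh_adjust,
    cumulative_incidence,
    derive_endpoints,
    final_model,
    immune_logistic,
    simulate_cohort,
    stratified_split,
    stratify,
    univariate_screen,
)
from hedratio.cohort import _design, _fit_cox


def brute_force_bh(p):
    """Literal step-up definition: adj_i = min over ranks >= rank(i)."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(
            min(p[j] * m / r for r, j in enumerate(order, start=1) if r >= rank),
            1.0,
        )
    return adj


def toy_cohort(n=40, seed=0):
    rng = np.random.default_rng(seed)
    death = np.where(rng.random(n) < 0.5, rng.uniform(20, 900, n).round(), np.nan)
    relapse = np.where(rng.random(n) < 0.3, rng.uniform(15, 500, n).round(), np.nan)
    followup = np.fmax(np.fmax(death, relapse), rng.uniform(100, 1500, n).round())
    followup = np.where(np.isnan(death), followup, death)
    relapse = np.where(relapse <= followup, relapse, np.nan)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "death_day": death, "relapse_day": relapse,
        "last_followup_day": followup,
    })


class TestExclusions:
    def test_492_with_22_early_deaths_leaves_470(self):
        df = toy_cohort(492, seed=1)
        df["death_day"] = np.nan
        df.loc[: 21, "death_day"] = 5.0       # exactly 22 early deaths
        df.loc[22:59, "death_day"] = 200.0    # later deaths retained
        df["last_followup_day"] = df["death_day"].fillna(900.0)
        out = apply_exclusions(df)
        assert len(df) == 492 and len(out) == 470

    def test_death_on_day_14_is_retained(self):
        df = pd.DataFrame({"subject_id": ["a", "b"],
                           "death_day": [14.0, 13.0],
                           "last_followup_day": [14.0, 13.0]})
        out = apply_exclusions(df)
        assert list(out["subject_id"]) == ["a"]

    def test_no_early_deaths_unchanged(self):
        df = toy_cohort(30, seed=2)
        df["death_day"] = df["death_day"].clip(lower=20)
        assert len(apply_exclusions(df)) == 30

    def test_negative_death_day_rejected(self):
        df = pd.DataFrame({"subject_id": ["a"], "death_day": [-1.0],
                           "last_followup_day": [10.0]})
        with pytest.raises(CohortError, match="negative"):
            apply_exclusions(df)


class TestEndpoints:
    @pytest.mark.parametrize("death,relapse,fup,expected", [
        (400.0, 100.0, 400.0, dict(dfs=(100.0, 1), os=(400.0, 1))),
        (np.nan, np.nan, 900.0, dict(dfs=(900.0, 0), os=(900.0, 0))),
        (50.0, np.nan, 50.0, dict(dfs=(50.0, 1), os=(50.0, 1))),
    ])
    def test_definitions(self, death, relapse, fup, expected):
        df = pd.DataFrame({"subject_id": ["x"], "death_day": [death],
                           "relapse_day": [relapse], "last_followup_day": [fup]})
        out = derive_endpoints(df).iloc[0]
        assert (out["dfs_time"], out["dfs_event"]) == expected["dfs"]
        assert (out["os_time"], out["os_event"]) == expected["os"]

    def test_missing_followup_rejected(self):
        df = pd.DataFrame({"subject_id": ["x"], "death_day": [np.nan],
                           "relapse_day": [np.nan], "last_followup_day": [np.nan]})
        with pytest.raises(CohortError, match="follow"):
            derive_endpoints(df)


@pytest.fixture(scope="module")
def cohort():
    return apply_exclusions(simulate_cohort(seed=3).cohort)


class TestSplit:
    STRATA = ["disease_status", "hct_number", "conditioning", "hla_match",
              "hct_period"]

    def test_partition_disjoint_exhaustive(self, cohort):
        train, test = stratified_split(cohort, self.STRATA, 338 / 470, seed=5)
        assert set(train.subject_id).isdisjoint(test.subject_id)
        assert len(train) + len(test) == len(cohort)

    def test_train_size_near_target(self, cohort):
        train, _ = stratified_split(cohort, self.STRATA, 338 / 470, seed=5)
        n_cells = cohort.groupby(self.STRATA).ngroups
        assert abs(len(train) - 338) <= n_cells / 2 + 1

    def test_same_seed_reproduces_partition(self, cohort):
        a = stratified_split(cohort, self.STRATA, 0.7, seed=9)[0]
        b = stratified_split(cohort, self.STRATA, 0.7, seed=9)[0]
        assert list(a.subject_id) == list(b.subject_id)

    def test_stratum_proportions_preserved(self, cohort):
        train, _ = stratified_split(cohort, self.STRATA, 0.72, seed=1)
        for status, frac in cohort["disease_status"].value_counts(
                normalize=True).items():
            got = (train["disease_status"] == status).mean()
            assert got == pytest.approx(frac, abs=0.05)

    def test_complementary_fraction_swaps_sizes_on_balanced_strata(self):
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(200)],
            "g": ["a", "b"] * 100,
        })
        t1, _ = stratified_split(df, ["g"], 0.25, seed=2)
        t2, _ = stratified_split(df, ["g"], 0.75, seed=2)
        assert len(t1) == 50 and len(t2) == 150

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortError):
            stratified_split(pd.DataFrame(columns=["g", "subject_id"]), ["g"], 0.5, 0)


class TestBaseline:
    def test_identical_sets_give_p_one(self):
        df = simulate_cohort(seed=4, n_subjects=200).cohort
        table = baseline_table(df, df.copy(), {
            "age": "continuous", "conditioning": "categorical",
            "hla_match": "categorical"})
        assert (table["p"].dropna() > 0.999).all()

    def test_large_shift_detected(self):
        df = simulate_cohort(seed=4, n_subjects=200).cohort
        shifted = df.copy()
        shifted["age"] = shifted["age"] + 30
        table = baseline_table(df, shifted, {"age": "continuous"})
        assert table["p"].iloc[0] < 1e-10

    def test_null_pvalues_roughly_uniform(self):
        # two halves of the same generating distribution, many replicates
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            x = pd.DataFrame({"v": rng.normal(size=60)})
            y = pd.DataFrame({"v": rng.normal(size=60)})
            pvals.append(baseline_table(x, y, {"v": "continuous"})["p"].iloc[0])
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBH:
    def test_hand_computed_stepup(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])
        got = bh_adjust([0.005, 0.04, 0.03])
        # ranks: 0.005*3/1=0.015, 0.03*3/2=0.045, 0.04*3/3=0.04 -> cummin
        assert np.allclose(got, [0.015, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == 0.123

    def test_all_equal_stay_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(CohortError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(CohortError):
            bh_adjust([-0.1])

    @settings(max_examples=100, deadline=None)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce_and_is_monotone(self, p):
        got = bh_adjust(p)
        assert np.array_equal(got, brute_force_bh(p))
        order = np.argsort(p, kind="stable")
        assert (np.diff(got[order]) >= -1e-15).all()
        assert ((got >= np.asarray(p) - 1e-15) & (got <= 1.0)).all()


class TestCumulativeIncidence:
    def test_no_competing_equals_one_minus_km(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(100, 200).round() + 1
        s = (rng.random(200) < 0.6).astype(int)
        aj = cumulative_incidence(t, s)["all"]
        km = cumulative_incidence(t, s, mode="one-minus-km")["all"]
        assert np.allclose(aj["cif"], km["cif"], atol=1e-9)
        # cross-check against lifelines' Kaplan-Meier estimator
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(t, s)
        at = kmf.survival_function_at_times(aj["time"]).to_numpy()
        assert np.allclose(aj["cif"], 1 - at, atol=1e-9)

    def test_toy_hand_computed_aalen_johansen(self):
        # times [2,3,5,7,9], status [event, competing, event, censor, event]
        curves = cumulative_incidence([2, 3, 5, 7, 9], [1, 2, 1, 0, 1])
        got = curves["all"]
        expected = [(0.0, 0.0), (2.0, 0.2), (5.0, 0.4), (9.0, 0.8)]
        assert list(map(tuple, got.to_numpy())) == expected

    def test_all_events_reach_one(self):
        curves = cumulative_incidence([1, 2, 3, 4], [1, 1, 1, 1])
        assert curves["all"]["cif"].iloc[-1] == pytest.approx(1.0)

    def test_curves_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(50, 300).round()
        s = rng.choice([0, 1, 2], 300, p=[0.3, 0.4, 0.3])
        g = rng.choice(["x", "y"], 300)
        for curve in cumulative_incidence(t, s, g).values():
            c = curve["cif"].to_numpy()
            assert (np.diff(c) >= 0).all() and c[-1] <= 1.0
        # both competing events together never exceed total probability 1
        ev = cumulative_incidence(t, s)["all"]["cif"].iloc[-1]
        comp = cumulative_incidence(t, np.where(s == 2, 1, np.where(s == 1, 2, 0))
                                    )["all"]["cif"].iloc[-1]
        assert ev + comp <= 1.0 + 1e-12

    def test_competing_lowers_incidence_vs_naive(self):
        t = [2, 3, 5, 7, 9]
        s = [1, 2, 1, 0, 1]
        aj = cumulative_incidence(t, s)["all"]["cif"].iloc[-1]
        naive = cumulative_incidence(t, s, mode="one-minus-km")["all"]["cif"].iloc[-1]
        assert aj < naive


def _prepared(seed, n, log_hr=0.0):
    res = simulate_cohort(seed=seed, n_subjects=n, score1_log_hr=log_hr)
    c = derive_endpoints(apply_exclusions(res.cohort))
    c["score1_group"] = stratify(c["score1"], "median")
    return c


class TestModels:
    def test_removal_threshold_one_keeps_full_model(self):
        c = _prepared(21, 400)
        full = final_model(c, "score1_group", "DFS", removal_threshold=1.0)
        direct, mapping, _ = _fit_cox(
            c, "dfs_time", "dfs_event",
            ["score1_group", *("disease_status", "hct_number", "conditioning",
                               "tbi", "hla_match", "graft_source")])
        assert len(full) == len(direct.summary)
        got = full.set_index("coefficient")["hr"]
        for name, row in direct.summary.iterrows():
            assert got[name] == pytest.approx(row["exp(coef)"], rel=1e-9)

    def test_single_level_exposure_rejected(self):
        c = _prepared(22, 300)
        c["score1_group"] = "high"
        with pytest.raises(CohortError, match="single group"):
            final_model(c, "score1_group", "DFS")

    def test_univariate_screen_empty_candidates(self):
        c = _prepared(23, 300)
        selected, table = univariate_screen(c, [])
        assert selected == [] and table.empty

    def test_univariate_screen_detects_strong_covariate(self):
        c = _prepared(24, 470)
        selected, table = univariate_screen(
            c, ["disease_status", "gender"])
        # the generator gives advanced disease a strong hazard increase and
        # gender no effect at all
        assert "disease_status" in selected

    def test_no_events_is_degenerate(self):
        c = _prepared(25, 200)
        c["dfs_event"] = 0
        with pytest.raises(FitError, match="no events"):
            _fit_cox(c, "dfs_time", "dfs_event", ["conditioning"])

    def test_design_missing_group_label_is_nan(self):
        df = pd.DataFrame({"g": ["low", "high", "missing", "low"]})
        X, mapping = _design(df, ["g"])
        col = X[mapping["g"][0]]
        assert np.isnan(col.iloc[2])
        assert mapping["g"] == ["g[high]"]


class TestImmuneLogistic:
    def test_constant_exposure_rejected(self):
        c = _prepared(26, 300)
        c["classI_mean_group"] = "high"
        with pytest.raises(CohortError, match="constant"):
            immune_logistic(c, 12, ["NK"])

    def test_reports_or_per_subset(self):
        c = _prepared(27, 492)
        c["classI_mean_group"] = stratify(c["classI_mean"], "median")
        table = immune_logistic(c, 12, ["NK", "CD4"])
        assert set(table["subset"]) == {"NK", "CD4"}
        ok = table[~table["unstable"]]
        assert (ok["ci_lower"] <= ok["or"]).all()
        assert (ok["or"] <= ok["ci_upper"]).all()
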