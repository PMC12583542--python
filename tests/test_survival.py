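import numpy as np
import pandas as pd
import pytest

import cellniche as cn
from tests.conftest import make_survival_spot_rows


def cindex_oracle(risk, times, event):
    """O(n^2) pair enumeration of Harrell's c."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # admissible: the earlier time is an observed event
            if times[i] < times[j] and event[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestSelectCohort:
    def test_toy_table_rule_by_rule(self):
        patients = pd.DataFrame(
            dict(
                patient_id=[f"P{i}" for i in range(6)],
                center="A",
                subtype="LUAD",
                uicc8=[4, 2, 1, 2, 1, 3],
                r_status=["0", "1", "0", "0", "0", "0"],
                adjuvant=[False, False, True, False, False, False],
                os_months=[20.0, 30.0, 15.0, 2.0, 40.0, 25.0],
                event=[1, 0, 1, 1, 0, 1],
            )
        )
        kept, exclusions = cn.select_cohort(patients)
        assert sorted(kept["patient_id"]) == ["P4", "P5"]
        assert exclusions == dict(stage=1, r_status=1, adjuvant=1, min_followup=1)

    def test_empty_and_identity(self):
        empty = pd.DataFrame(columns=["patient_id", "subtype", "uicc8", "r_status",
                                      "adjuvant", "os_months", "event"])
        kept, _ = cn.select_cohort(empty)
        assert kept.empty
        eligible = pd.DataFrame(dict(patient_id=["P0"], subtype=["LUAD"], uicc8=[1],
                                     r_status=["0"], adjuvant=[False], os_months=[12.0], event=[1]))
        kept, exclusions = cn.select_cohort(eligible)
        assert len(kept) == 1 and sum(exclusions.values()) == 0

    def test_unknown_rule_errors(self):
        with pytest.raises(ValueError):
            cn.select_cohort(pd.DataFrame(), rules=("stage", "nonsense"))


class TestPropensityMatch:
    def _meta(self, n, seed=0, stage_pool=(1, 2, 3)):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            dict(
                patient_id=[f"P{seed}_{i}" for i in range(n)],
                uicc8=rng.choice(stage_pool, n),
                os_months=rng.uniform(3, 100, n),
                event=rng.integers(0, 2, n),
            )
        )

    def test_duplicated_cohort_perfect_matching(self):
        test = self._meta(30, seed=1)
        train = pd.concat([test, self._meta(30, seed=2)], ignore_index=True)
        matched = cn.propensity_match(train, test, seed=0)
        assert len(matched) == len(test)
        assert matched["patient_id"].is_unique

    def test_determinism(self):
        train, test = self._meta(50, 1), self._meta(20, 2)
        a = cn.propensity_match(train, test, seed=3)
        b = cn.propensity_match(train, test, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_removes_distributional_shift(self):
        """With an extra all-stage-3 block in the training cohort, matching
        drops it: the matched subset's stage distribution mirrors the test's."""
        test = self._meta(60, seed=4, stage_pool=(1, 2))
        extra = self._meta(60, seed=5, stage_pool=(3,))
        train = pd.concat([self._meta(60, seed=6, stage_pool=(1, 2)), extra], ignore_index=True)
        matched = cn.propensity_match(train, test, seed=0)
        assert (matched["uicc8"] == 3).mean() < 0.1

    def test_train_smaller_than_test_errors(self):
        with pytest.raises(ValueError):
            cn.propensity_match(self._meta(5), self._meta(10))


class TestConcordance:
    def test_perfect_and_tied(self):
        assert cn.concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
        assert cn.concordance_index([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            n = 50
            risk = rng.normal(size=n)
            times = rng.exponential(20, n)  # continuous: no tied event times
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            assert cn.concordance_index(risk, times, event) == pytest.approx(
                cindex_oracle(risk, times, event)
            )

    def test_antisymmetry_without_ties(self, rng):
        risk = rng.normal(size=40)
        times = rng.permutation(40).astype(float) + 1
        event = np.ones(40, dtype=int)
        c = cn.concordance_index(risk, times, event)
        assert c + cn.concordance_index(-risk, times, event) == pytest.approx(1.0)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            cn.concordance_index([1, 2], [3, 4], [0, 0])


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "c_model,c_baseline,expected_pct",
        [(0.644, 0.633, 8), (0.674, 0.630, 34), (0.5001, 0.5001, 0)],
    )
    def test_reported_arithmetic(self, c_model, c_baseline, expected_pct):
        ratio = cn.relative_improvement(c_model, c_baseline)
        assert round((ratio - 1) * 100) == expected_pct

    def test_baseline_at_chance_errors(self):
        with pytest.raises(ValueError):
            cn.relative_improvement(0.7, 0.5)


class TestMRMR:
    def test_single_candidate(self, rng):
        f = pd.DataFrame({"a": rng.normal(size=30)})
        t = rng.exponential(10, 30)
        assert cn.mrmr_survival_select(f, t, np.ones(30, int), 1) == ["a"]

    def test_first_pick_is_max_relevance(self, rng):
        n = 120
        strong = rng.normal(size=n)
        times = np.exp(-strong + rng.normal(0, 0.3, n)) * 20
        noise = rng.normal(size=n)
        feats = pd.DataFrame({"noise": noise, "strong": strong})
        sel = cn.mrmr_survival_select(feats, times, np.ones(n, int), 2)
        assert sel[0] == "strong"

    def test_duplicate_feature_deprioritized(self, rng):
        """A, a copy A', and a weaker independent B: redundancy pushes the
        copy behind B, giving selection order [A, B, A']."""
        n = 150
        a = rng.normal(size=n)
        b = 0.5 * a + rng.normal(0, 1.0, n)
        times = np.exp(-a + rng.normal(0, 0.2, n)) * 20
        feats = pd.DataFrame({"A": a, "A_copy": a.copy(), "B": b})
        sel = cn.mrmr_survival_select(feats, times, np.ones(n, int), 3)
        assert sel == ["A", "B", "A_copy"]

    def test_constant_feature_is_chance_relevance(self, rng):
        n = 60
        feats = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        sel = cn.mrmr_survival_select(feats, rng.exponential(10, n), np.ones(n, int), 2)
        assert set(sel) == {"const", "x"}

    def test_max_k_too_large_errors(self, rng):
        feats = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            cn.mrmr_survival_select(feats, np.ones(10), np.ones(10, int), 2)


class TestRiskModel:
    def test_perfect_feature_high_training_cindex(self, rng):
        n = 60
        x = rng.normal(size=n)
        rows = pd.DataFrame(
            dict(patient_id=[f"P{i}" for i in range(n)], spot_id=[f"S{i}" for i in range(n)],
                 os_months=np.exp(-x) * 10, event=1, f=x)
        )
        model = cn.fit_risk_model(rows, ["f"], max_k=1, alpha=0.01)
        risk = model.predict_spot_risk(rows)
        c = cn.concordance_index(risk.to_numpy(), rows["os_months"].to_numpy(),
                                 rows["event"].to_numpy())
        assert c >= 0.95

    def test_ridge_shrinkage_monotone_limit(self):
        rows = make_survival_spot_rows(60, betas=[0, 3.0, 0, 0.3], seed=2)
        feats = [f"niche_{j}" for j in (1, 2, 3)] + ["uicc8"]
        small = cn.fit_risk_model(rows, feats, alpha=0.01)
        large = cn.fit_risk_model(rows, feats, alpha=1e4)
        assert max(abs(v) for v in large.coefficients.values()) < 0.05
        assert max(abs(v) for v in large.coefficients.values()) < max(
            abs(v) for v in small.coefficients.values()
        )

    def test_model_json_round_trip(self, tmp_path):
        rows = make_survival_spot_rows(40, betas=[0, 2.0, 0, 0.3], seed=3)
        feats = [f"niche_{j}" for j in (1, 2, 3)] + ["uicc8"]
        model = cn.fit_risk_model(rows, feats, max_k=2, alpha=0.1)
        model.to_json(tmp_path / "model.json")
        loaded = cn.RiskModel.from_json(tmp_path / "model.json")
        pd.testing.assert_series_equal(
            loaded.predict_spot_risk(rows), model.predict_spot_risk(rows)
        )

    def test_zero_variance_feature_dropped_with_warning(self):
        rows = make_survival_spot_rows(40, betas=[0, 2.0, 0, 0.3], seed=4)
        rows["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = cn.fit_risk_model(rows, ["flat", "niche_1", "niche_2"], alpha=0.1)
        assert "flat" not in model.candidate_features


class TestPatientPooling:
    def test_max_pooling(self):
        rows = make_survival_spot_rows(10, betas=[0, 2.0, 0, 0.3], seed=5)
        feats = [f"niche_{j}" for j in (1, 2, 3)] + ["uicc8"]
        model = cn.fit_risk_model(rows, feats, alpha=0.1)
        spot_risk = model.predict_spot_risk(rows)
        patient_risk = cn.predict_patient_risk(model, rows)
        for pid, r in patient_risk.items():
            assert r == pytest.approx(spot_risk[rows.patient_id == pid].max())
            assert (r >= spot_risk[rows.patient_id == pid] - 1e-12).all()

    def test_mean_pooling_mode(self):
        rows = make_survival_spot_rows(6, betas=[0, 2.0, 0, 0.3], seed=6)
        feats = [f"niche_{j}" for j in (1, 2, 3)] + ["uicc8"]
        model = cn.fit_risk_model(rows, feats, alpha=0.1)
        spot_risk = model.predict_spot_risk(rows)
        mean_risk = cn.predict_patient_risk(model, rows, pooling="mean")
        for pid, r in mean_risk.items():
            assert r == pytest.approx(spot_risk[rows.patient_id == pid].mean())


class TestTuning:
    def test_single_combo_grid(self):
        rows = make_survival_spot_rows(40, betas=[0, 2.0, 0, 0.3], seed=7)
        feats = [f"niche_{j}" for j in (1, 2, 3)] + ["uicc8"]
        k, a, table = cn.tune_hyperparams(rows, feats, max_k_grid=(2,), alpha_grid=(0.1,),
                                          n_folds=3)
        assert (k, a) == (2, 0.1)
        assert len(table) == 1

    def test_patient_level_folds(self):
        """No patient's spots may straddle a train/validation split."""
        from sklearn.model_selection import GroupKFold

        rows = make_survival_spot_rows(30, betas=[0, 2.0, 0, 0.3], seed=8)
        groups = rows["patient_id"].to_numpy()
        for tr, va in GroupKFold(n_splits=3).split(rows, groups=groups):
            assert set(groups[tr]).isdisjoint(groups[va])

    def test_planted_informative_niche_selected(self):
        rows = make_survival_spot_rows(150, betas=[0, 3.0, 0, 0.2], seed=9)
        feats = [f"niche_{j}" for j in (1, 2, 3)] + ["uicc8"]
        k, a, _ = cn.tune_hyperparams(rows, feats, max_k_grid=(2, 4), alpha_grid=(0.1,),
                                      n_folds=3)
        model = cn.fit_risk_model(rows, feats, max_k=k, alpha=a)
        assert "niche_2" in model.feature_names


class TestStratification:
    def test_nine_distinct_risks(self):
        labels = cn.stratify_tertiles(pd.Series(np.arange(1.0, 10.0)))
        assert list(labels) == ["RS1"] * 3 + ["RS2"] * 3 + ["RS3"] * 3

    def test_all_equal_collapses_to_rs1(self):
        with pytest.warns(UserWarning):
            labels = cn.stratify_tertiles(pd.Series(np.ones(6)))
        assert set(labels) == {"RS1"}

    def test_balanced_groups_property(self, rng):
        for _ in range(10):
            risks = rng.normal(size=int(rng.integers(9, 40)))
            labels = cn.stratify_tertiles(pd.Series(risks))
            sizes = labels.value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_too_few_patients_errors(self):
        with pytest.raises(ValueError):
            cn.stratify_tertiles(pd.Series([1.0, 2.0]))


class TestKMLogrank:
    def test_identical_groups_no_separation(self, rng):
        times = rng.exponential(20, 30)
        events = np.ones(30, int)
        groups = np.r_[np.zeros(15), np.ones(15)]
        times2 = np.r_[times[:15], times[:15]]
        curves, stat, p = cn.km_logrank(groups, times2, np.ones(30, int))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert set(curves) == {"0.0", "1.0"}

    def test_clearly_separated_groups(self, rng):
        times = np.r_[rng.uniform(1, 5, 30), rng.uniform(50, 100, 30)]
        groups = np.r_[np.zeros(30), np.ones(30)]
        _, _, p = cn.km_logrank(groups, times, np.ones(60, int))
        assert p <= 0.01

    def test_km_without_censoring_is_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        curves, _, _ = cn.km_logrank(np.r_[np.zeros(4), np.ones(4)],
                                     np.r_[times, times], np.ones(8, int))
        sf = curves["0.0"].iloc[:, 0]
        # no censoring: KM equals the empirical survival function
        assert sf.loc[1.0] == pytest.approx(0.75)
        assert sf.loc[2.0] == pytest.approx(0.5)
        assert sf.loc[4.0] == pytest.approx(0.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            cn.km_logrank(np.zeros(5), np.arange(5.0) + 1, np.ones(5, int))


class TestBootstrapCompare:
    def test_identical_models_p_one(self, rng):
        risk = rng.normal(size=60)
        times = rng.exponential(20, 60)
        events = np.ones(60, int)
        bm, bb, p = cn.bootstrap_compare(risk, risk.copy(), times, events, n_boot=100, seed=0)
        np.testing.assert_array_equal(bm, bb)
        assert p == 1.0

    def test_strong_vs_chance_predictor(self, rng):
        n = 150
        times = rng.exponential(20, n)
        events = np.ones(n, int)
        strong = -times + rng.normal(0, 1.0, n)
        chance = rng.normal(size=n)
        _, _, p = cn.bootstrap_compare(strong, chance, times, events, n_boot=500, seed=0)
        assert p <= 0.001

    def test_seed_determinism(self, rng):
        risk = rng.normal(size=40)
        base = rng.normal(size=40)
        times = rng.exponential(10, 40)
        events = np.ones(40, int)
        a = cn.bootstrap_compare(risk, base, times, events, n_boot=100, seed=5)
        b = cn.bootstrap_compare(risk, base, times, events, n_boot=100, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_min_boot_enforced(self):
        with pytest.raises(ValueError):
            cn.bootstrap_compare(np.ones(5), np.ones(5), np.ones(5), np.ones(5, int), n_boot=10)


class TestRestratification:
    def test_no_upstaging(self):
        table, summary = cn.restratification_table([1, 1, 1], ["RS1", "RS1", "RS1"])
        assert summary["stage1_upstaged_fraction"] == 0.0

    def test_toy_upstaging_fraction(self):
        _, summary = cn.restratification_table([1, 1, 1, 1], ["RS1", "RS2", "RS2", "RS3"])
        assert summary["stage1_upstaged_fraction"] == pytest.approx(0.75)

    def test_row_sums_conserved(self, rng):
        stages = rng.choice([1, 2, 3], 60)
        rs = rng.choice(["RS1", "RS2", "RS3"], 60)
        table, _ = cn.restratification_table(stages, rs)
        for s in np.unique(stages):
            assert table.loc[s].sum() == (stages == s).sum()
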