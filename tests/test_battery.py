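import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import trialpower as tp
from trialpower import battery


def _flat(groups_dict):
    y = np.concatenate([np.asarray(v, float) for v in groups_dict.values()])
    g = np.concatenate([[k] * len(v) for k, v in groups_dict.items()])
    return y, g


class TestOnewayAnova:
    def test_identical_groups(self):
        y, g = _flat({"A": (1, 2, 3), "B": (1, 2, 3)})
        res = tp.oneway_anova(y, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups(self):
        # df2 = 2 caps how small p can get with two observations per group
        y, g = _flat({"A": (1, 2), "B": (101, 102)})
        assert tp.oneway_anova(y, g).p_value < 1e-4
        y, g = _flat({"A": (1, 2, 1.5), "B": (101, 102, 101.5), "C": (201, 202, 201.5)})
        assert tp.oneway_anova(y, g).p_value < 1e-6

    def test_matches_sums_of_squares_oracle(self):
        data = {
            "A": (6, 8, 4, 5, 3, 4),
            "B": (8, 12, 9, 11, 6, 8),
            "C": (13, 9, 11, 8, 7, 12),
        }
        y, g = _flat(data)
        res = tp.oneway_anova(y, g)
        # independent from-scratch decomposition
        grand = y.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in data.values())
        ssw = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in data.values())
        F = (ssb / 2) / (ssw / 15)
        assert res.statistic == pytest.approx(F, rel=1e-12)
        assert res.p_value == pytest.approx(stats.f.sf(F, 2, 15), rel=1e-12)
        assert (res.df1, res.df2) == (2, 15)

    def test_degenerate_data_rejected(self):
        y, g = _flat({"A": (1, 1, 1), "B": (2, 2, 2)})
        with pytest.raises(ValueError, match="degenerate"):
            tp.oneway_anova(y, g)


class TestWelchAnova:
    def test_two_group_equal_variance_equals_anova(self):
        # exact algebraic identity at g=2 with equal sample variances
        a = np.array([1.0, 2.0, 3.0, 4.0])
        y, g = _flat({"A": a, "B": a + 10})
        w, f = tp.welch_anova(y, g), tp.oneway_anova(y, g)
        assert w.statistic == pytest.approx(f.statistic, abs=1e-10)
        assert w.p_value == pytest.approx(f.p_value, abs=1e-10)
        assert w.df2 <= len(y) - 2 + 1e-9

    def test_multi_group_correction_factor(self):
        # for g>2 Welch divides by B > 1 even under equal sample variances
        a = np.array([1.0, 2.0, 3.0, 4.0])
        y, g = _flat({"A": a, "B": a + 1, "C": a + 2, "D": a + 3})
        w, f = tp.welch_anova(y, g), tp.oneway_anova(y, g)
        n, gg = 4.0, 4.0
        H = gg * (1 - 1 / gg) ** 2 / (n - 1)
        B = 1 + 2 * (gg - 2) / (gg**2 - 1) * H
        assert w.statistic == pytest.approx(f.statistic / B, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pingouin_oracle(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        y = rng.normal(size=40) * np.repeat([1, 2, 1, 3], 10)
        g = np.repeat(list("abcd"), 10)
        mine = tp.welch_anova(y, g)
        ref = pg.welch_anova(dv="y", between="g", data=pd.DataFrame({"y": y, "g": g}))
        assert mine.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert mine.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert mine.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_separated_groups(self):
        y, g = _flat({"A": (1, 2), "B": (101, 102)})
        assert tp.welch_anova(y, g).p_value < 1e-4

    def test_zero_variance_group_rejected(self):
        y, g = _flat({"A": (1, 1), "B": (2, 3)})
        with pytest.raises(ValueError, match="zero variance"):
            tp.welch_anova(y, g)

    def test_size_robust_under_heteroscedasticity(self):
        """Small, more-variable group: Welch holds its size, ANOVA does not."""
        rng = np.random.default_rng(2024)
        sizes, sds = (6, 12, 12, 12), (np.sqrt(5.0), 1.0, 1.0, 1.0)
        g = np.concatenate([[k] * n for k, n in zip("abcd", sizes)])
        rej_w = rej_a = 0
        n_reps = 2000
        for _ in range(n_reps):
            y = np.concatenate(
                [rng.normal(0, sd, size=n) for n, sd in zip(sizes, sds)]
            )
            rej_w += tp.welch_anova(y, g).p_value < 0.05
            rej_a += tp.oneway_anova(y, g).p_value < 0.05
        assert 0.03 <= rej_w / n_reps <= 0.07
        assert rej_a / n_reps > 0.07


class TestAffineAndRelabelInvariance:
    @given(
        a=st.floats(min_value=0.1, max_value=50).flatmap(
            lambda x: st.sampled_from([x, -x])
        ),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(12)
        y = rng.normal(size=24)
        g = np.repeat(list("abc"), 8)
        for fn in (tp.oneway_anova, tp.welch_anova):
            base = fn(y, g)
            trans = fn(a * y + b, g)
            assert trans.statistic == pytest.approx(base.statistic, rel=1e-8, abs=1e-10)
            assert trans.p_value == pytest.approx(base.p_value, rel=1e-8, abs=1e-12)

    def test_group_relabel_invariance(self, params18):
        trial = tp.sample_trial(tp.ScenarioSpec(8, 0.5, "normal", 2.0), params18, 3)
        relabeled = {"control": "dose2", "dose2": "control", "dose1": "dose3", "dose3": "dose1"}
        g2 = np.array([relabeled[g] for g in trial.group])
        y = trial.values[:, 0]
        assert tp.oneway_anova(y, g2).statistic == pytest.approx(
            tp.oneway_anova(y, trial.group).statistic, rel=1e-12
        )
        assert tp.welch_anova(y, g2).statistic == pytest.approx(
            tp.welch_anova(y, trial.group).statistic, rel=1e-12
        )
        m1 = tp.manova_endpoint(trial, "neuroscore")
        t2 = tp.TrialDataset(trial.values, g2, trial.subject_id, trial.labels)
        m2 = tp.manova_endpoint(t2, "neuroscore")
        assert m2.wilks_lambda == pytest.approx(m1.wilks_lambda, rel=1e-10)


class TestLmmMainEffect:
    def test_balanced_engine_matches_mixedlm(self, params18):
        trial = tp.sample_trial(tp.ScenarioSpec(10, 0.5, "normal", 1.0), params18, 21)
        for ep in trial.endpoints[:3]:
            fast = tp.lmm_main_effect(trial, ep, df_method="balanced")
            full = tp.lmm_main_effect(trial, ep, df_method="containment")
            assert fast.statistic == pytest.approx(full.statistic, rel=1e-2)
            assert fast.p_value == pytest.approx(full.p_value, abs=5e-3)
            assert (fast.df1, fast.df2) == (full.df1, full.df2)

    def test_zero_subject_variance_matches_twoway_anova(self):
        """With no between-subject variance the mixed model collapses to the
        two-way fixed-effects ANOVA treatment test."""
        rng = np.random.default_rng(2)
        n, g, T = 10, 4, 3
        labels = tp.make_labels(("e",), ("day1", "day7", "day14"))
        effects = np.repeat([0.0, 0.5, 1.0, 1.5], n)
        values = effects[:, None] + rng.normal(size=(n * g, T))
        trial = tp.TrialDataset(
            values=values,
            group=np.repeat(["control", "dose1", "dose2", "dose3"], n),
            subject_id=np.arange(n * g),
            labels=labels,
        )
        res = tp.lmm_main_effect(trial, "e", df_method="containment")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        long = trial.to_long()
        ols = smf.ols("value ~ C(group) + C(time)", data=long).fit()
        F_fixed = float(anova_lm(ols).loc["C(group)", "F"])
        assert res.statistic == pytest.approx(F_fixed, rel=0.01)

    def test_null_calibration(self, params18):
        """d=0, n=20: pooled LMM rejection rate stays near the nominal 5%."""
        (summary,) = tp.run_scenario(
            tp.ScenarioSpec(20, 0.0, "normal", 1.0),
            params18,
            methods=["lmm"],
            n_reps=1000,
            base_seed=77,
        )
        assert 0.035 <= summary.rate <= 0.065

    def test_huge_shift_detected(self, params18):
        scen = tp.ScenarioSpec(10, 10.0, "normal", 1.0)
        trial = tp.sample_trial(scen, params18, 1)
        for ep in trial.endpoints:
            assert tp.lmm_main_effect(trial, ep).p_value < 1e-6

    def test_single_time_point_redirects(self, params18):
        trial = tp.sample_trial(tp.ScenarioSpec(5, 0.0, "normal", 1.0), params18, 0)
        single = tp.TrialDataset(
            trial.values[:, :1], trial.group, trial.subject_id, (trial.labels[0],)
        )
        with pytest.raises(ValueError, match="oneway_anova"):
            tp.lmm_main_effect(single, "neuroscore")


class TestPcaScoresAnova:
    def test_two_variable_retention(self):
        # eigenvalues of a 2x2 correlation matrix are 1 +/- rho
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        w, V = tp.kaiser_components(R)
        assert np.allclose(w, [1.8])
        assert V.shape == (2, 1)

    def test_identity_retains_nothing(self, params4):
        trial = tp.sample_trial(tp.ScenarioSpec(10, 0.0, "normal", 1.0), params4, 2)
        with pytest.warns(UserWarning, match="no components"):
            out = tp.pca_scores_anova(trial, np.eye(4))
        assert out == []

    def test_eigenvector_sign_convention(self, params18):
        w, V = tp.kaiser_components(params18.corr)
        for k in range(V.shape[1]):
            j = np.argmax(np.abs(V[:, k]))
            assert V[j, k] > 0
        assert np.all(np.diff(w) <= 0)

    def test_variance_pooling_beats_median_univariate(self, params4):
        """Effects on all variables: the first component concentrates them."""
        scen = tp.ScenarioSpec(10, 0.4, "normal", 1.0)
        wins = 0
        for r in range(500):
            trial = tp.sample_trial(scen, params4, 40_000 + r)
            pcs = tp.pca_scores_anova(trial, params4.corr)
            p_univ = np.median(
                [tp.oneway_anova(trial.values[:, j], trial.group).p_value for j in range(4)]
            )
            wins += pcs[0].p_value < p_univ
        assert wins >= 0.6 * 500


class TestInteractionPosthoc:
    def test_table_shape(self, params18):
        trial = tp.sample_trial(tp.ScenarioSpec(5, 2.0, "normal", 1.0), params18, 8)
        total = 0
        for ep in trial.endpoints:
            tab = tp.lmm_interaction_posthoc(trial, ep)
            assert set(tab.contrasts["time"]) == {"day1", "day7", "day14"}
            assert len(tab.contrasts) == 9  # 3 times x 3 doses
            total += len(tab.contrasts)
        assert total == 54  # 18 variables x 3 contrasts

    def test_day1_only_effects_detected(self, params18):
        signs = tuple(1 if j % 3 == 0 else 0 for j in range(18))  # day1 columns
        scen = tp.ScenarioSpec(10, 3.0, "normal", 1.0, effect_sign=signs)
        hits = 0
        for r in range(200):
            trial = tp.sample_trial(scen, params18, 60_000 + r)
            tab = tp.lmm_interaction_posthoc(trial, "neuroscore")
            day1 = tab.contrasts[tab.contrasts["time"] == "day1"]
            hits += bool((day1["p_value"] < 0.01).all())
        assert hits >= 0.95 * 200

    def test_null_calibration(self, params18):
        scen = tp.ScenarioSpec(10, 0.0, "normal", 1.0)
        pvals = []
        for r in range(200):
            trial = tp.sample_trial(scen, params18, 70_000 + r)
            tab = tp.lmm_interaction_posthoc(trial, "lesion_volume")
            pvals.extend(tab.contrasts["p_value"])
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert abs(rate - 0.05) <= 0.03

    def test_adjustments_are_monotone(self, params18):
        trial = tp.sample_trial(tp.ScenarioSpec(6, 1.0, "normal", 1.0), params18, 4)
        raw = tp.lmm_interaction_posthoc(trial, "neuroscore", adjust="none")
        bonf = tp.lmm_interaction_posthoc(trial, "neuroscore", adjust="bonferroni")
        sidak = tp.lmm_interaction_posthoc(trial, "neuroscore", adjust="sidak")
        assert np.all(bonf.contrasts["p_value"] >= raw.contrasts["p_value"] - 1e-12)
        assert np.all(sidak.contrasts["p_value"] >= raw.contrasts["p_value"] - 1e-12)
        assert np.all(bonf.contrasts["p_value"] >= sidak.contrasts["p_value"] - 1e-12)
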