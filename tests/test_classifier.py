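"""Differential methylation, penalized fits, consensus protocol, prediction."""

import numpy as np
import pandas as pd
import pytest

from epiclonal import (
    ClassifierModel,
    consensus_refinement,
    differential_probes,
    fit_multinomial_elasticnet,
    predict,
    top_mean_diff_probes,
)
from epiclonal.cohort import generate_signal_matrix

GROUPS = {"normal": 8, "non_aggressive": 8, "aggressive": 10}


def _two_group_beta(n_probes=400, n1=10, n2=10, planted=None, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0.5, noise, (n_probes, n1 + n2))
    if planted:
        for idx, diff in planted.items():
            X[idx, n1:] += diff
    probes = [f"p{i:04d}" for i in range(n_probes)]
    cols = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    beta = pd.DataFrame(np.clip(X, 0, 1), index=probes, columns=cols)
    groups = {"g1": cols[:n1], "g2": cols[n1:]}
    return beta, groups


class TestDifferentialProbes:
    def test_planted_difference_flagged_at_strict_fdr(self):
        beta, groups = _two_group_beta(planted={7: 0.5})
        table = differential_probes(beta, groups, fdr=0.05)
        assert table.loc["p0007", "significant"]
        assert table["significant"].sum() == 1

    def test_null_has_calibrated_raw_p_and_no_fdr_hits(self):
        beta, groups = _two_group_beta(n_probes=2000, seed=1)
        table = differential_probes(beta, groups, fdr=0.05)
        frac_raw = (table["p"] < 0.05).mean()
        assert 0.03 < frac_raw < 0.07
        assert table["significant"].sum() <= 2

    def test_single_sample_group_rejected(self):
        beta, groups = _two_group_beta(n1=1)
        groups["g1"] = groups["g1"][:1]
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_probes(beta, groups)

    def test_zero_variance_equal_means_p_one(self):
        beta = pd.DataFrame(
            0.5, index=["p0"], columns=["a1", "a2", "b1", "b2"]
        )
        t = differential_probes(beta, {"g1": ["a1", "a2"], "g2": ["b1", "b2"]})
        assert t.loc["p0", "p"] == 1.0
        assert t.loc["p0", "t"] == 0.0


class TestTopMeanDiff:
    def test_planted_probes_lead_the_ranking(self):
        beta, groups = _two_group_beta(planted={i: 0.4 for i in range(10)}, noise=0.01)
        top = top_mean_diff_probes(beta, groups["g1"], groups["g2"], k=10)
        assert set(top) == {f"p{i:04d}" for i in range(10)}

    def test_matches_brute_force_on_toy(self):
        beta, groups = _two_group_beta(n_probes=100, seed=2)
        top = top_mean_diff_probes(beta, groups["g1"], groups["g2"], k=100)
        diff = (beta[groups["g1"]].mean(axis=1) - beta[groups["g2"]].mean(axis=1)).abs()
        expected = sorted(beta.index, key=lambda p: (-diff[p], list(beta.index).index(p)))
        assert top == expected

    def test_k_larger_than_available_fails(self):
        beta, groups = _two_group_beta(n_probes=50)
        with pytest.raises(ValueError, match="exceeds"):
            top_mean_diff_probes(beta, groups["g1"], groups["g2"], k=51)


class TestFit:
    def test_separable_signal_recovered_with_full_training_accuracy(self):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=3)
        fit = fit_multinomial_elasticnet(beta, labels, seed=4)
        assert set(fit.selected_probes) & set(beta.index[:5])
        model = ClassifierModel(
            probes=fit.probes, class_order=fit.classes, coef=fit.coef, intercept=fit.intercept
        )
        res = predict(model, beta)
        assert (res.frame["predicted"] == labels.loc[res.frame.index]).all()

    def test_extreme_penalty_gives_intercept_only_class_frequencies(self):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=5)
        fit = fit_multinomial_elasticnet(beta, labels, C=1e-6)
        assert fit.selected_probes == []
        model = ClassifierModel(
            probes=fit.probes, class_order=fit.classes, coef=fit.coef, intercept=fit.intercept
        )
        res = predict(model, beta)
        freq = labels.value_counts(normalize=True)
        for cls in fit.classes:
            np.testing.assert_allclose(res.frame[f"p_{cls}"], freq[cls], atol=0.02)

    def test_same_seed_identical_selection(self):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=6)
        f1 = fit_multinomial_elasticnet(beta, labels, seed=7)
        f2 = fit_multinomial_elasticnet(beta, labels, seed=7)
        assert f1.selected_probes == f2.selected_probes
        np.testing.assert_array_equal(f1.coef, f2.coef)

    def test_single_class_rejected(self):
        beta, labels = generate_signal_matrix({"aggressive": 6}, n_probes=500, seed=8)
        with pytest.raises(ValueError, match="classes"):
            fit_multinomial_elasticnet(beta, labels)


class TestConsensus:
    def test_union_is_monotone_in_restarts(self):
        from epiclonal.classifier import _prepare, _fit_path, _cv_choose

        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=9)
        design = _prepare(beta, labels)
        path = _fit_path(design, 1.0, 16, 600, 1e-3)
        selections = []
        for s in range(6):
            j, _ = _cv_choose(design, path, s, 3, "1se", 1.0, 600, 1e-3)
            nz = np.any(np.abs(path.coefs[j]) > 1e-8, axis=0)
            selections.append({p for p, m in zip(design.probes, nz) if m})
        u3 = set().union(*selections[:3])
        u6 = set().union(*selections)
        assert u3 <= u6

    def test_single_restart_equals_fit_then_refit(self):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=10)
        states = np.random.SeedSequence(11).generate_state(2) % (2**31)
        model = consensus_refinement(beta, labels, n_restarts=1, seed=11)
        fit = fit_multinomial_elasticnet(beta, labels, seed=int(states[0]))
        union = [p for p in beta.index if p in set(fit.selected_probes)]
        refit = fit_multinomial_elasticnet(
            beta.loc[union], labels, seed=int(states[1]), max_iter=5000, tol=1e-4
        )
        assert model.probes == refit.selected_probes

    def test_recovery_and_holdout_accuracy_single_replicate(self):
        from sklearn.metrics import balanced_accuracy_score

        sizes = {"normal": 12, "non_aggressive": 10, "aggressive": 31}
        beta, labels = generate_signal_matrix(sizes, seed=12, baseline_seed=12)
        model = consensus_refinement(beta, labels, n_restarts=5, seed=13)
        assert set(beta.index[:5]) <= set(model.probes) | set(beta.index[5:])  # sanity
        planted_found = len(set(model.probes) & set(beta.index[:5]))
        assert planted_found >= 3
        held, y = generate_signal_matrix(sizes, seed=1200, baseline_seed=12)
        res = predict(model, held)
        assert balanced_accuracy_score(y.loc[res.frame.index], res.frame["predicted"]) >= 0.9

    def test_sample_order_permutation_does_not_change_panel(self):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=14)
        rng = np.random.default_rng(15)
        perm = rng.permutation(beta.columns)
        m1 = consensus_refinement(beta, labels, n_restarts=3, seed=16)
        m2 = consensus_refinement(beta[perm], labels.loc[perm], n_restarts=3, seed=16)
        assert m1.probes == m2.probes
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_pure_noise_input_fails_clearly(self):
        rng = np.random.default_rng(17)
        beta = pd.DataFrame(
            rng.normal(0.5, 0.02, (300, 24)),
            index=[f"p{i}" for i in range(300)],
            columns=[f"s{i}" for i in range(24)],
        )
        labels = pd.Series(
            ["normal"] * 8 + ["non_aggressive"] * 8 + ["aggressive"] * 8, index=beta.columns
        )
        with pytest.raises(ValueError, match="no discriminative probes"):
            consensus_refinement(beta, labels, n_restarts=2, seed=18)


def _manual_model(intercepts):
    return ClassifierModel(
        probes=["p0"],
        class_order=["normal", "non_aggressive", "aggressive"],
        coef=np.zeros((3, 1)),
        intercept=np.log(np.asarray(intercepts)),
    )


class TestPredict:
    def test_confidence_threshold_is_strict(self):
        beta = pd.DataFrame({"s1": [0.5]}, index=["p0"])
        res = predict(_manual_model([0.68, 0.20, 0.12]), beta)
        row = res.frame.loc["s1"]
        assert row["predicted"] == "normal"
        assert bool(row["confident"])
        res2 = predict(_manual_model([0.67, 0.20, 0.13]), beta)
        assert not bool(res2.frame.loc["s1", "confident"])

    def test_exact_tie_breaks_by_class_order(self):
        beta = pd.DataFrame({"s1": [0.5]}, index=["p0"])
        res = predict(_manual_model([1 / 3, 1 / 3, 1 / 3]), beta)
        assert res.frame.loc["s1", "predicted"] == "normal"
        assert not bool(res.frame.loc["s1", "confident"])

    def test_probabilities_sum_to_one(self):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=19)
        fit = fit_multinomial_elasticnet(beta, labels, seed=20)
        model = ClassifierModel(
            probes=fit.probes, class_order=fit.classes, coef=fit.coef, intercept=fit.intercept
        )
        res = predict(model, beta)
        sums = res.frame[[f"p_{c}" for c in fit.classes]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_missing_values_reject_sample_with_reason(self):
        beta = pd.DataFrame({"ok": [0.5], "bad": [np.nan]}, index=["p0"])
        res = predict(_manual_model([0.5, 0.3, 0.2]), beta)
        assert "ok" in res.frame.index
        assert res.rejected == {"bad": "missing values among model probes"}

    def test_absent_model_probe_raises(self):
        beta = pd.DataFrame({"s": [0.5]}, index=["other"])
        with pytest.raises(KeyError, match="p0"):
            predict(_manual_model([0.5, 0.3, 0.2]), beta)


class TestSerialization:
    def test_json_round_trip_bit_identical(self, tmp_path):
        beta, labels = generate_signal_matrix(GROUPS, n_probes=500, seed=21)
        model = consensus_refinement(beta, labels, n_restarts=2, seed=22)
        path = tmp_path / "model.json"
        s1 = model.to_json(path)
        back = ClassifierModel.from_json(path)
        assert back.probes == model.probes
        assert back.class_order == model.class_order
        np.testing.assert_array_equal(back.coef, model.coef)
        np.testing.assert_array_equal(back.intercept, model.intercept)
        assert back.to_json() == s1
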