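"""CPM pipeline: elementary operations against brute-force oracles,
leakage-freedom, masked mode, permutation behavior and anatomical
summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from socialcpm import (
    CPMConfig,
    CPMRegressor,
    EdgeIndexMap,
    EdgeMask,
    PlantedSignalSpec,
    fit_strength_model,
    lobewise_summary,
    network_strength,
    permutation_test,
    residualize,
    robust_edges,
    run_cpm,
    select_edges,
    simulate_cpm_dataset,
)
from socialcpm.cpm import make_folds
from socialcpm.synthio import synthetic_atlas

from test_synthio import pearson_null_tail


class TestResidualize:
    def test_intercept_only_mean_centers(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        np.testing.assert_allclose(residualize(y), y - y.mean())

    def test_exact_linear_target_vanishes(self):
        c = np.arange(10.0)
        np.testing.assert_allclose(residualize(3 * c + 2, c), 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        A = np.column_stack([np.ones(40), C])
        beta = np.linalg.solve(A.T @ A, A.T @ y)  # closed-form oracle
        np.testing.assert_allclose(residualize(y, C), y - A @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(30, 3))
        r = residualize(rng.normal(size=30), C)
        assert np.all(np.abs(C.T @ r) < 1e-8)

    def test_collinear_confounds_named(self):
        C = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.random.default_rng(2).normal(size=10), C)


class TestSelectEdges:
    def test_strong_edge_lands_in_positive_tail(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        X = rng.normal(size=(50, 5))
        X[:, 2] = y + 0.3 * rng.normal(size=50)
        mask = select_edges(X, y, 0.2)
        assert 2 in mask.positive

    def test_extreme_threshold_gives_empty_mask(self):
        rng = np.random.default_rng(4)
        mask = select_edges(rng.normal(size=(30, 20)), rng.normal(size=30), 0.999)
        assert mask.n_edges == 0

    def test_null_selection_rate_matches_analytic_tail(self):
        hits = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = rng.normal(size=(200, 400)), rng.normal(size=200)
            mask = select_edges(X, y, 0.2)
            hits += mask.n_edges
            total += 400
        p = pearson_null_tail(0.2, 200)
        band = 4 * np.sqrt(p * (1 - p) / total)
        assert hits / total == pytest.approx(p, abs=band + 0.002)

    def test_overlapping_tails_impossible(self):
        with pytest.raises(ValueError, match="disjoint"):
            EdgeMask(np.array([1, 2]), np.array([2, 3]))


class TestStrengthModel:
    def test_empty_mask_gives_zero_strengths(self):
        mask = EdgeMask(np.empty(0, int), np.empty(0, int))
        assert network_strength(np.arange(5.0), mask) == (0.0, 0.0)

    def test_singleton_mask_picks_edge_value(self):
        mask = EdgeMask(np.array([3]), np.empty(0, int))
        assert network_strength(np.arange(5.0), mask) == (3.0, 0.0)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        pos = rng.choice(30, 8, replace=False)
        neg = np.setdiff1d(np.arange(30), pos)[:5]
        mask = EdgeMask(pos, neg)
        sp, sn = network_strength(x, mask)
        assert sp == pytest.approx(sum(x[k] for k in mask.positive), abs=1e-12)
        assert sn == pytest.approx(sum(x[k] for k in mask.negative), abs=1e-12)

    def test_exact_linear_fit_recovered(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=20)
        coef = fit_strength_model(s[:, None], 2 * s + 1)
        np.testing.assert_allclose(coef, [1.0, 2.0], atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        S = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        A = np.column_stack([np.ones(25), S])
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit_strength_model(S, y), expected, atol=1e-10)


class TestCPMRegressor:
    def test_sklearn_protocol(self):
        est = CPMRegressor(threshold=0.3, model_mode="positive")
        assert clone(est).get_params() == est.get_params()

    def test_fit_predict_consistent_with_elementary_ops(self, planted_dataset):
        d = planted_dataset
        est = CPMRegressor().fit(d.edges, d.behavior)
        mask = select_edges(d.edges, d.behavior, 0.2)
        np.testing.assert_array_equal(est.mask_.positive, mask.positive)
        np.testing.assert_array_equal(est.mask_.negative, mask.negative)
        strengths = np.array([network_strength(x, mask) for x in d.edges])
        coef = fit_strength_model(strengths, d.behavior)
        np.testing.assert_allclose(
            est.predict(d.edges), coef[0] + strengths @ coef[1:], atol=1e-10
        )

    def test_rejects_bad_mode(self):
        with pytest.raises(ValueError, match="model_mode"):
            CPMRegressor(model_mode="both_tails").fit(np.ones((5, 3)), np.arange(5.0))


class TestRunCPM:
    def test_engine_matches_per_fold_estimator(self, planted_dataset):
        """The vectorized CV engine must reproduce an explicit per-fold
        residualize/select/fit/predict loop exactly."""
        d = planted_dataset
        cfg = CPMConfig(n_iterations=1, seed=13)
        res = run_cpm(d, cfg, confounds=["fd_rms"])
        C = d.confounds.to_numpy()
        folds = make_folds(d.n_subjects, 10, np.random.default_rng(13))
        expected = np.empty(d.n_subjects)
        for te in folds:
            tr = np.setdiff1d(np.arange(d.n_subjects), te)
            A_tr = np.column_stack([np.ones(tr.size), C[tr]])
            beta = np.linalg.lstsq(A_tr, d.behavior[tr], rcond=None)[0]
            r_tr = d.behavior[tr] - A_tr @ beta
            est = CPMRegressor().fit(d.edges[tr], r_tr)
            expected[te] = est.predict(d.edges[te])
        np.testing.assert_allclose(res.predictions[0], expected, atol=1e-10)

    def test_no_test_set_leakage(self, planted_dataset):
        """Replacing held-out subjects' behavior must not change their
        predictions."""
        d = planted_dataset
        cfg = CPMConfig(n_iterations=1, seed=21)
        res = run_cpm(d, cfg)
        folds = make_folds(d.n_subjects, 10, np.random.default_rng(21))
        te = folds[0]
        tampered = simulate_cpm_dataset(
            PlantedSignalSpec(n_subjects=60, n_nodes=20,
                              signal_edges=tuple(d.signal_edges), effect_size=0.5, seed=7)
        )
        tampered.behavior = tampered.behavior.copy()
        tampered.behavior[te] = 999.0 + np.arange(te.size)
        res2 = run_cpm(tampered, cfg)
        np.testing.assert_allclose(res.predictions[0][te], res2.predictions[0][te], atol=1e-10)

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = make_folds(67, 10, np.random.default_rng(0))
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) == {6, 7}
        assert sum(sizes) == 67

    def test_masked_mode_ignores_outside_edges(self, planted_dataset):
        d = planted_dataset
        mask = EdgeMask(d.signal_edges[:8], np.empty(0, int))
        cfg = CPMConfig(n_iterations=2, seed=5)
        res = run_cpm(d, cfg, feature_mask=mask)
        zeroed = simulate_cpm_dataset(
            PlantedSignalSpec(n_subjects=60, n_nodes=20,
                              signal_edges=tuple(d.signal_edges), effect_size=0.5, seed=7)
        )
        outside = np.setdiff1d(np.arange(d.n_edges), mask.union)
        zeroed.edges = zeroed.edges.copy()
        zeroed.edges[:, outside] = 0.0
        res2 = run_cpm(zeroed, cfg, feature_mask=mask)
        np.testing.assert_allclose(res.predictions, res2.predictions, atol=1e-10)
        assert res.pos_frequency[outside].sum() == 0.0

    def test_accuracy_monotone_in_effect_size(self):
        medians = []
        for effect in (0.0, 0.2, 0.4, 0.6):
            accs = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                signal = tuple(sorted(rng.choice(435, size=15, replace=False)))
                d = simulate_cpm_dataset(
                    PlantedSignalSpec(n_subjects=80, n_nodes=30, signal_edges=signal,
                                      effect_size=effect, seed=seed)
                )
                cfg = CPMConfig(n_iterations=3, seed=seed)
                accs.append(run_cpm(d, cfg).median_accuracy)
            medians.append(np.mean(accs))
        assert all(b >= a - 0.05 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0]

    def test_null_accuracy_centers_on_zero(self, null_dataset):
        cfg = CPMConfig(n_iterations=5, seed=2)
        res = run_cpm(null_dataset, cfg)
        assert abs(res.median_accuracy) < 0.35

    def test_separate_tails_returns_both_models(self, planted_dataset):
        cfg = CPMConfig(n_iterations=2, model_mode="separate_tails", seed=3)
        res = run_cpm(planted_dataset, cfg)
        assert res.positive.accuracies.shape == (2,)
        assert res.negative.accuracies.shape == (2,)
        # planted signal is positive, so the positive-tail model should win
        assert res.positive.median_accuracy > res.negative.median_accuracy

    def test_too_few_subjects_rejected(self):
        d = simulate_cpm_dataset(PlantedSignalSpec(n_subjects=8, n_nodes=10, seed=0))
        with pytest.raises(ValueError, match="folds"):
            run_cpm(d, CPMConfig(k_folds=10, n_iterations=1))


class TestPermutation:
    def test_boundary_p_values(self, planted_dataset):
        cfg = CPMConfig(n_iterations=2, n_permutations=50, seed=8)
        res = run_cpm(planted_dataset, cfg)
        perm = permutation_test(planted_dataset, cfg, res)
        assert 0 < perm.p_value <= 1
        assert perm.null_accuracies.shape == (50,)
        # planted signal at effect 0.5 on n=60 beats every null here
        assert perm.p_value == pytest.approx(1 / 51)

    def test_paper_counting_convention(self, planted_dataset):
        cfg = CPMConfig(n_iterations=2, n_permutations=50, seed=8)
        res = run_cpm(planted_dataset, cfg)
        perm = permutation_test(planted_dataset, cfg, res, counting="paper")
        count = int((perm.null_accuracies >= res.median_accuracy).sum())
        expected = count / 50 if count else 1 / 51
        assert perm.p_value == pytest.approx(expected)

    def test_independent_splits_agree_distributionally(self, null_dataset):
        cfg = CPMConfig(n_iterations=2, n_permutations=30, seed=4)
        res = run_cpm(null_dataset, cfg)
        shared = permutation_test(null_dataset, cfg, res)
        indep = permutation_test(null_dataset, cfg, res, independent_splits=True)
        # same null scale, not identical draws
        assert abs(shared.null_accuracies.std() - indep.null_accuracies.std()) < 0.1


class TestRobustEdges:
    def test_fraction_zero_keeps_all_ever_selected(self, planted_dataset):
        cfg = CPMConfig(n_iterations=2, seed=1)
        res = run_cpm(planted_dataset, cfg)
        mask = robust_edges(res, fraction=0.0)
        ever = np.flatnonzero((res.pos_frequency > 0) | (res.neg_frequency > 0))
        np.testing.assert_array_equal(np.sort(mask.union), ever)

    def test_always_selected_edge_survives_fraction_one(self, planted_dataset):
        cfg = CPMConfig(n_iterations=3, seed=1)
        res = run_cpm(planted_dataset, cfg)
        always = np.flatnonzero(res.pos_frequency == 1.0)
        assert always.size > 0  # effect 0.5 at n=60 selects planted edges everywhere
        mask = robust_edges(res, fraction=1.0)
        assert np.all(np.isin(always, mask.positive))


class TestLobewise:
    def test_two_lobe_enumeration(self):
        atlas = synthetic_atlas(4, seed=0)
        atlas["lobe"] = ["Occipital", "Occipital", "Cerebellum", "Cerebellum"]
        imap = EdgeIndexMap(4)
        # one within-Occipital edge and one Occipital-Cerebellum edge
        mask = EdgeMask(np.array([imap.to_index(0, 1), imap.to_index(1, 2)]),
                        np.empty(0, int))
        out = lobewise_summary(mask, atlas, imap)
        pos = out.pair_counts[out.pair_counts["tail"] == "positive"]
        counts = {(r["lobe_a"], r["lobe_b"]): r["count"] for _, r in pos.iterrows()}
        assert counts[("Occipital", "Occipital")] == 1
        assert counts[("Cerebellum", "Occipital")] == 1
        assert counts[("Cerebellum", "Cerebellum")] == 0

    def test_empty_mask_gives_zeros(self):
        atlas = synthetic_atlas(6, seed=0)
        out = lobewise_summary(
            EdgeMask(np.empty(0, int), np.empty(0, int)), atlas, EdgeIndexMap(6)
        )
        assert (out.pair_counts["count"] == 0).all()
        assert (out.degrees[["K_positive", "K_negative"]] == 0).all().all()

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(9)
        imap = EdgeIndexMap(20)
        atlas = synthetic_atlas(20, seed=3)
        pos = rng.choice(imap.n_edges, 25, replace=False)
        neg = np.setdiff1d(rng.choice(imap.n_edges, 40, replace=False), pos)[:15]
        mask = EdgeMask(pos, neg)
        out = lobewise_summary(mask, atlas, imap)
        lobes = atlas.sort_values("node_id")["lobe"].tolist()
        for tail, idx in (("positive", mask.positive), ("negative", mask.negative)):
            brute = {}
            for k in idx:
                i, j = imap.to_pair(int(k))
                key = tuple(sorted((lobes[i], lobes[j])))
                brute[key] = brute.get(key, 0) + 1
            tab = out.pair_counts[out.pair_counts["tail"] == tail]
            for _, r in tab.iterrows():
                assert r["count"] == brute.get((r["lobe_a"], r["lobe_b"]), 0)
        # degrees by brute force
        deg = np.zeros(20, int)
        for k in mask.positive:
            i, j = imap.to_pair(int(k))
            deg[i] += 1
            deg[j] += 1
        np.testing.assert_array_equal(out.degrees["K_positive"].to_numpy(), deg)

    def test_standardization_uses_possible_pairs(self):
        atlas = synthetic_atlas(4, seed=0)
        atlas["lobe"] = ["Occipital", "Occipital", "Occipital", "Cerebellum"]
        imap = EdgeIndexMap(4)
        mask = EdgeMask(np.array([imap.to_index(0, 1)]), np.empty(0, int))
        out = lobewise_summary(mask, atlas, imap)
        row = out.pair_counts[
            (out.pair_counts.lobe_a == "Occipital")
            & (out.pair_counts.lobe_b == "Occipital")
            & (out.pair_counts["tail"] == "positive")
        ].iloc[0]
        assert row["possible"] == 3
        assert row["standardized"] == pytest.approx(1 / 3)
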