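"""CPM edge statistics, LOOCV prediction, and FDR control."""

import numpy as np
import pandas as pd
import pytest

import oracles
from connfp.behavior import (
    EdgeStats,
    edge_behavior_corr,
    fdr_correct,
    loocv_predict,
    network_strength,
    run_matrix_of_models,
    select_edges,
    subnetwork_edge_indices,
)
from connfp.connectomes import ConnMatrix, GroupingScheme, devectorize_edges
from connfp.synthetic import CohortConfig, generate_fc_cohort, generate_traits


class TestEdgeBehaviorCorr:
    def test_matches_bruteforce_oracle(self, rng):
        x = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        stats_ = edge_behavior_corr(x, y)
        for e in range(2):
            r_o = oracles.pearson_two_pass(x[:, e], y)
            assert stats_.r[e] == pytest.approx(r_o, abs=1e-12)
            assert stats_.p[e] == pytest.approx(
                oracles.pearson_p_two_sided(r_o, 5), abs=1e-12)

    def test_perfect_predictor_edge(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = np.column_stack([2.0 * y, np.ones(5)])
        stats_ = edge_behavior_corr(x, y)
        assert stats_.r[0] == pytest.approx(1.0, abs=1e-14)
        assert 0 < stats_.p[0] < 1e-15  # driven to the floor, never exactly 0
        assert stats_.r[1] == 0.0  # constant edge carries no association

    def test_type_one_error_calibration(self, rng):
        """Independent trait: ~5% of null edges pass p < 0.05."""
        x = rng.normal(size=(50, 1000))
        y = rng.normal(size=50)
        stats_ = edge_behavior_corr(x, y)
        frac = (stats_.p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_missing_traits_dropped_pairwise(self, rng):
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        y[3] = np.nan
        stats_ = edge_behavior_corr(x, y)
        assert stats_.n_used == 9 and stats_.n_dropped == 1
        keep = np.isfinite(y)
        manual = oracles.pearson_two_pass(x[keep, 0], y[keep])
        assert stats_.r[0] == pytest.approx(manual, abs=1e-12)

    def test_constant_trait_and_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edge_behavior_corr(rng.normal(size=(6, 2)), np.ones(6))
        with pytest.raises(ValueError, match="4 subjects"):
            edge_behavior_corr(rng.normal(size=(3, 2)), np.arange(3.0))


class TestSelectEdges:
    def test_direct_filter(self):
        stats_ = EdgeStats(r=np.array([0.5, 0.4, -0.2]),
                           p=np.array([0.005, 0.02, 0.5]), n_used=20)
        pos, neg = select_edges(stats_, 0.01)
        assert pos.tolist() == [0] and neg.tolist() == []

    def test_degenerate_threshold_splits_by_sign(self, rng):
        r = rng.normal(size=50)
        stats_ = EdgeStats(r=r, p=rng.uniform(0.0001, 0.9, size=50), n_used=20)
        pos, neg = select_edges(stats_, 1 - 1e-12)
        assert set(pos) == set(np.nonzero(r > 0)[0])
        assert set(neg) == set(np.nonzero(r < 0)[0])

    def test_union_is_threshold_set_and_disjoint(self, rng):
        x = rng.normal(size=(30, 200))
        y = rng.normal(size=30)
        stats_ = edge_behavior_corr(x, y)
        pos, neg = select_edges(stats_, 0.1)
        assert set(pos) & set(neg) == set()
        assert set(pos) | set(neg) == set(np.nonzero(stats_.p < 0.1)[0])

    def test_null_selection_poisson_band(self, rng):
        x = rng.normal(size=(100, 1000))
        y = rng.normal(size=100)
        pos, neg = select_edges(edge_behavior_corr(x, y), 0.01)
        total = len(pos) + len(neg)
        assert total <= 10 + 4 * np.sqrt(10)  # ~Poisson(10) upper band
        assert total >= 1


class TestNetworkStrength:
    def test_singleton_and_sum(self):
        v = np.array([0.1, 0.2, 0.3, 0.9])
        assert network_strength(v, np.array([2])) == pytest.approx(0.3)
        assert network_strength(v, np.array([0, 1, 2])) == pytest.approx(0.6)
        assert network_strength(v, np.arange(4)) == pytest.approx(v.sum())

    def test_empty_set_zero(self):
        assert network_strength(np.arange(3.0), np.array([], dtype=int)) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            network_strength(np.arange(3.0), np.array([5]))


class TestLoocvPredict:
    def test_noiseless_affine_recovery(self, rng):
        # the informative edge is the only non-constant one, so every fold
        # selects exactly it and OLS recovers the affine map
        x = np.column_stack([np.zeros(30), rng.normal(size=30), np.ones(30)])
        y = 3.0 * x[:, 1] - 1.0
        res = loocv_predict(x, y, p_threshold=0.05, sign="positive")
        assert res.r_pred == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(res.predictions, y, atol=1e-8)
        assert res.empty_folds == 0

    def test_trait_affine_invariance(self, rng):
        x = rng.normal(size=(25, 8))
        y = x[:, 0] + rng.normal(scale=0.5, size=25)
        a = loocv_predict(x, y, p_threshold=0.1)
        b = loocv_predict(x, 4.0 * y + 10.0, p_threshold=0.1)
        assert b.r_pred == pytest.approx(a.r_pred, abs=1e-10)
        assert np.allclose(b.predictions, 4.0 * a.predictions + 10.0, atol=1e-8)

    def test_planted_cohort_recovers_correlation(self):
        """Signal:noise 1 cohort: r_pred near the sqrt(1/2) population value."""
        from connfp.experiments import planted_cpm_config
        r = []
        for b in range(5):
            cfg = planted_cpm_config(n_subjects=200, seed=300 + b)
            cohort = generate_fc_cohort(cfg)
            traits = generate_traits(cohort, cfg)
            res = loocv_predict(cohort.edge_vectors(), traits.iloc[:, 0].to_numpy(),
                                p_threshold=0.01, sign="positive")
            r.append(res.r_pred)
        # within the Monte-Carlo band (500-replicate oracle: 0.655 +/- 0.079)
        assert abs(np.mean(r) - np.sqrt(0.5)) < 2 * 0.079

    def test_null_cohort_no_model_calibration(self):
        """beta = 0: majority-empty folds yield no-model, r_pred ~ 0."""
        rs, sig = [], 0
        for b in range(25):
            cfg = CohortConfig(n_subjects=40, n_parcels=8, beta=0.0,
                               sigma_trait=1.0, seed=700 + b)
            cohort = generate_fc_cohort(cfg)
            traits = generate_traits(cohort, cfg)
            res = loocv_predict(cohort.edge_vectors(), traits.iloc[:, 0].to_numpy(),
                                p_threshold=0.01, sign="positive")
            rs.append(res.r_pred)
            sig += res.p_pred < 0.05
        assert abs(np.mean(rs)) < 0.15
        assert sig <= 0.2 * 25

    def test_constant_training_fold_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        y = np.array([1.0, 1.0, 1.0, 1.0, 5.0])  # constant once subject 4 left out
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fold"):
                loocv_predict(x, y, p_threshold=0.5)


class TestLoocvPermutationP:
    def test_strong_effect_small_p_null_large(self, rng):
        from connfp.behavior import loocv_permutation_p
        x = rng.normal(size=(20, 3))
        y = x[:, 0] + rng.normal(scale=0.2, size=20)
        p_sig = loocv_permutation_p(x, y, p_threshold=0.1, n_perm=39, seed=3)
        y_null = rng.normal(size=20)
        p_null = loocv_permutation_p(x, y_null, p_threshold=0.1, n_perm=39, seed=3)
        assert p_sig == pytest.approx(1 / 40)
        assert p_null > 0.1


class TestFdrCorrect:
    def test_hand_step_up_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
        reject, p_adj = fdr_correct(p, q=0.05)
        assert reject.tolist() == [True, True, True, True, False]
        assert p_adj[0] == pytest.approx(0.05)

    def test_all_ones_no_rejection(self):
        reject, _ = fdr_correct(np.ones(5), q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_test(self):
        reject, p_adj = fdr_correct(np.array([0.04]), q=0.05)
        assert reject.tolist() == [True] and p_adj[0] == pytest.approx(0.04)

    def test_matches_bruteforce_bh_on_random_vectors(self, rng):
        """1,000 random p-vectors against the step-up definition."""
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.uniform(1e-6, 1.0, size=m)
            q = rng.uniform(0.01, 0.2)
            reject, p_adj = fdr_correct(p, q=q)
            rej_o, adj_o = oracles.bh_step_up(p.tolist(), q)
            assert reject.tolist() == rej_o
            assert np.allclose(p_adj, adj_o, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            fdr_correct(np.array([1.5]))


class TestRunMatrixOfModels:
    def _cohort_mats(self, cohort):
        return [ConnMatrix(np.mean([m.weights for m in subj], axis=0),
                           subj[0].parcel_labels, "FCz")
                for subj in cohort.fc_matrices]

    def test_single_cell_reduces_to_loocv_predict(self):
        cfg = CohortConfig(n_subjects=30, n_parcels=6, beta=1.0, sigma_trait=0.05,
                           effect_edges_pos=(0,), seed=21)
        cohort = generate_fc_cohort(cfg)
        traits = generate_traits(cohort, cfg)
        mats = self._cohort_mats(cohort)
        table = run_matrix_of_models({"FCz": mats}, None, traits,
                                     p_threshold=0.05, signs=("positive",))
        assert len(table) == 1
        direct = loocv_predict(cohort.edge_vectors(), traits.iloc[:, 0].to_numpy(),
                               p_threshold=0.05, sign="positive")
        assert table.loc[0, "r_pred"] == pytest.approx(direct.r_pred)
        assert table.loc[0, "group"] == "whole-brain"

    def test_planted_subnetwork_detected_null_not(self):
        """Effect confined to group A edges: A significant, B not, mostly."""
        hits_a, hits_b = 0, 0
        n_rep = 10
        for b in range(n_rep):
            cfg = CohortConfig(n_subjects=80, n_parcels=8, beta=1.0,
                               sigma_trait=0.05, effect_edges_pos=(0,),  # edge (P1,P2)
                               seed=900 + b)
            cohort = generate_fc_cohort(cfg)
            traits = generate_traits(cohort, cfg)
            g = GroupingScheme("halves", {f"P{i + 1:03d}": ("A" if i < 4 else "B")
                                          for i in range(8)})
            table = run_matrix_of_models({"FCz": self._cohort_mats(cohort)}, g, traits,
                                         p_threshold=0.01, signs=("positive",),
                                         include_whole_brain=False)
            row_a = table[table.group == "A"].iloc[0]
            row_b = table[table.group == "B"].iloc[0]
            hits_a += bool(row_a.significant)
            hits_b += bool(row_b.significant)
        assert hits_a >= 0.9 * n_rep
        assert hits_b <= 0.2 * n_rep

    def test_trait_battery_row_count(self):
        """A 29-trait battery yields 29 rows per group x sign x weight kind."""
        cfg = CohortConfig(n_subjects=20, n_parcels=5, seed=33)
        cohort = generate_fc_cohort(cfg)
        rng = np.random.default_rng(0)
        traits = pd.DataFrame(rng.normal(size=(20, 29)),
                              columns=[f"measure_{i:02d}" for i in range(29)],
                              index=cohort.subject_ids)
        table = run_matrix_of_models({"FCz": self._cohort_mats(cohort)}, None,
                                     traits, signs=("positive", "negative"))
        assert len(table) == 29 * 2  # whole-brain only, both signs
        assert set(table.trait) == set(traits.columns)

    def test_subnetwork_edge_indices_within_block(self):
        labels = ["a", "b", "c", "d"]
        g = GroupingScheme("g", {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        # canonical order: ab, ac, ad, bc, bd, cd -> X edges {0}, Y edges {5}
        assert subnetwork_edge_indices(labels, g, "X").tolist() == [0]
        assert subnetwork_edge_indices(labels, g, "Y").tolist() == [5]
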