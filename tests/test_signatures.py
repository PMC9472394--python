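from itertools import combinations

import numpy as np
import pytest

from seqlift import (ExpressionMatrix, batch_signatures, bridge_null,
                     bridge_walk, characteristic_direction,
                     fold_change_signature, reverse_search,
                     simulate_perturbation_study)
from seqlift.signatures import _shrunk_inverse_apply


def group(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(values,
                            gene_ids=[f"g{i}" for i in range(values.shape[0])],
                            sample_ids=[f"s{j}" for j in range(values.shape[1])])


def brute_force_walk(ranked, gene_set):
    """Independent running-sum reference: plain python loop over the
    cumulative hit/miss counts."""
    n = len(ranked)
    m = sum(1 for g in ranked if g in gene_set)
    hits, misses, path = 0, 0, []
    for g in ranked:
        if g in gene_set:
            hits += 1
        else:
            misses += 1
        path.append(hits / m - misses / (n - m))
    return path


class TestCharacteristicDirection:
    def test_gamma_zero_is_normalized_mean_difference(self):
        ctrl = group([[0.0, 0.0], [0.0, 0.0]])
        treat = group([[3.0, 3.0], [4.0, 4.0]])
        b = characteristic_direction(ctrl, treat, gamma=0.0)
        np.testing.assert_allclose(b, [0.6, 0.8], atol=1e-12)

    def test_unit_norm_for_random_inputs(self):
        rng = np.random.default_rng(0)
        ctrl = group(rng.normal(5, 1, size=(10, 6)))
        treat = group(rng.normal(6, 1, size=(10, 6)))
        b = characteristic_direction(ctrl, treat, gamma=0.5)
        assert abs(np.linalg.norm(b) - 1.0) < 1e-8

    def test_matches_dense_closed_form(self):
        """The returned direction equals normalize((gamma*S + (1-gamma)I)^-1 d)
        computed independently with numpy linear algebra."""
        rng = np.random.default_rng(1)
        ctrl = group(rng.normal(5, 1, size=(8, 12)))
        treat = group(rng.normal(5.5, 1, size=(8, 12)))
        gamma = 0.7
        b = characteristic_direction(ctrl, treat, gamma=gamma)
        mu_c, mu_t = ctrl.values.mean(1), treat.values.mean(1)
        centered = np.hstack([ctrl.values - mu_c[:, None],
                              treat.values - mu_t[:, None]])
        sigma = centered @ centered.T / (12 + 12 - 2)
        ref = np.linalg.solve(gamma * sigma + (1 - gamma) * np.eye(8),
                              mu_t - mu_c)
        ref = ref / np.linalg.norm(ref)
        if np.dot(ref, b) < 0:
            ref = -ref
        np.testing.assert_allclose(b, ref, atol=1e-8)

    def test_data_span_inverse_agrees_with_dense_solve(self):
        rng = np.random.default_rng(2)
        centered = rng.normal(size=(40, 6))  # p >> n regime
        delta = rng.normal(size=40)
        gamma, dof = 0.6, 4
        sigma = centered @ centered.T / dof
        dense = np.linalg.solve(gamma * sigma + (1 - gamma) * np.eye(40), delta)
        woodbury = _shrunk_inverse_apply(centered, dof, gamma, delta)
        np.testing.assert_allclose(woodbury, dense, atol=1e-8)

    def test_single_sample_groups_fall_back_to_mean_difference(self):
        ctrl = group([[1.0], [1.0]])
        treat = group([[4.0], [5.0]])
        b = characteristic_direction(ctrl, treat, gamma=0.9)
        np.testing.assert_allclose(b, np.array([3.0, 4.0]) / 5.0, atol=1e-12)

    def test_zero_signal_rejected(self):
        m = group([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="no differential signal"):
            characteristic_direction(m, m, gamma=0.0)

    def test_sign_convention_follows_strongest_gene(self):
        ctrl = group([[5.0, 5.0], [5.0, 5.0]])
        treat = group([[1.0, 1.0], [5.1, 5.1]])  # dominant gene goes down
        b = characteristic_direction(ctrl, treat, gamma=0.0)
        assert b[np.argmax(np.abs(b))] < 0


class TestFoldChange:
    def test_equal_groups_give_zero(self):
        m = group([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(fold_change_signature(m, m), 0.0)

    def test_mean_difference(self):
        ctrl = group([[3.0, 3.0]])
        treat = group([[5.0, 5.0]])
        np.testing.assert_array_equal(fold_change_signature(ctrl, treat), [2.0])

    def test_constant_shift_moves_all_fold_changes(self):
        rng = np.random.default_rng(3)
        ctrl = group(rng.uniform(0, 5, size=(6, 4)))
        treat = group(rng.uniform(0, 5, size=(6, 4)))
        base = fold_change_signature(ctrl, treat)
        shifted = fold_change_signature(ctrl, treat.with_values(treat.values + 1.5))
        np.testing.assert_allclose(shifted - base, 1.5)


class TestBatchSignatures:
    def test_one_signature_per_qualifying_batch(self, tiny_study):
        sigs = batch_signatures(tiny_study.profiles, tiny_study.metadata,
                                "drugA", method="cd")
        assert len(sigs) == len(tiny_study.batches)
        for sig in sigs:
            assert sig.n_treatment == 4 and sig.n_control == 4

    def test_batch_without_controls_skipped(self, tiny_study):
        meta = [r for r in tiny_study.metadata]
        # make batch01 all-treatment
        for r in meta:
            if r.batch == "batch01":
                r.perturbagen = "drugA"
        sigs = batch_signatures(tiny_study.profiles, meta, "drugA")
        assert len(sigs) == len(tiny_study.batches) - 1

    def test_spiked_effect_recovered_in_fold_changes(self, tiny_study):
        sigs = batch_signatures(tiny_study.profiles, tiny_study.metadata,
                                "drugA", method="fold_change")
        fc = np.mean([s.log2_fold_changes for s in sigs], axis=0)
        gene_ids = tiny_study.profiles.gene_ids
        t_idx = [gene_ids.index(g) for g in tiny_study.target_set]
        o_idx = [i for i in range(len(gene_ids)) if i not in set(t_idx)]
        assert abs(fc[t_idx].mean() - tiny_study.effect_size) < 0.5
        assert abs(fc[o_idx].mean()) < 0.25

    def test_unknown_perturbagen_rejected(self, tiny_study):
        with pytest.raises(ValueError, match="absent"):
            batch_signatures(tiny_study.profiles, tiny_study.metadata, "nope")


class TestBridgeWalk:
    def test_set_at_top_peaks_at_one(self):
        ranked = list("ABCDEFGH")
        res = bridge_walk(ranked, {"A", "B"})
        assert res.peak == 1.0
        assert res.peak_rank == 2

    def test_walk_ends_at_zero(self):
        rng = np.random.default_rng(4)
        ranked = [f"g{i}" for i in range(57)]
        gene_set = set(rng.choice(ranked, size=9, replace=False))
        res = bridge_walk(ranked, gene_set)
        assert abs(res.running_sum[-1]) < 1e-9

    def test_set_at_bottom_never_positive(self):
        ranked = list("ABCDEF")
        res = bridge_walk(ranked, {"E", "F"})
        assert res.peak <= 1e-9
        assert np.all(res.running_sum[:-2] < 0)

    def test_exhaustive_enumeration_of_all_placements(self):
        """bridge_walk agrees bit-for-bit with an independent loop-based
        running sum over every C(6,2) placement, and the mean peaks match."""
        genes = list("ABCDEF")
        peaks, oracle_peaks = [], []
        for idx in combinations(range(6), 2):
            gene_set = {genes[i] for i in idx}
            res = bridge_walk(genes, gene_set)
            path = brute_force_walk(genes, gene_set)
            np.testing.assert_array_equal(res.running_sum, path)
            peaks.append(res.peak)
            oracle_peaks.append(max(path))
        assert np.mean(peaks) == np.mean(oracle_peaks)

    @pytest.mark.parametrize("n,m", [(5, 1), (6, 3), (7, 2)])
    def test_exhaustive_agreement_small_rankings(self, n, m):
        genes = [f"g{i}" for i in range(n)]
        for idx in combinations(range(n), m):
            gene_set = {genes[i] for i in idx}
            res = bridge_walk(genes, gene_set)
            np.testing.assert_array_equal(res.running_sum,
                                          brute_force_walk(genes, gene_set))

    def test_weighted_walk_is_bridge_with_peak_in_unit_interval(self):
        rng = np.random.default_rng(5)
        ranked = [f"g{i}" for i in range(40)]
        gene_set = set(rng.choice(ranked, size=8, replace=False))
        weights = rng.uniform(0, 3, size=40)
        res = bridge_walk(ranked, gene_set, weights=weights)
        assert abs(res.running_sum[-1]) < 1e-9
        assert 0.0 <= res.peak <= 1.0

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bridge_walk(list("ABC"), {"X"})
        with pytest.raises(ValueError, match="degenerate"):
            bridge_walk(list("ABC"), {"A", "B", "C"})


class TestBridgeNull:
    def test_seeded_null_reproducible(self):
        ranked = [f"g{i}" for i in range(30)]
        gene_set = {f"g{i}" for i in range(5)}
        a = bridge_null(ranked, gene_set, 50, seed=9)
        b = bridge_null(ranked, gene_set, 50, seed=9)
        assert a.p_value == b.p_value
        assert a.permutation_mean_peak == b.permutation_mean_peak

    def test_extreme_ranking_attains_minimum_p(self):
        ranked = [f"g{i}" for i in range(200)]
        gene_set = {f"g{i}" for i in range(10)}  # all at the very top
        res = bridge_null(ranked, gene_set, 99, seed=1)
        assert res.p_value == 1 / 100

    def test_p_value_bounded(self):
        ranked = [f"g{i}" for i in range(20)]
        res = bridge_null(ranked, {"g19"}, 20, seed=2)
        assert 0 < res.p_value <= 1


class TestReverseSearch:
    def test_dominant_signature_ranks_first(self, tiny_world):
        study = simulate_perturbation_study(tiny_world, n_batches=4,
                                            treat_per_batch=4,
                                            control_per_batch=4,
                                            target_set_size=6,
                                            effect_size=2.0, seed=33)
        sigs = batch_signatures(study.profiles, study.metadata, "drugA")
        query = sorted(study.target_set)[0]
        up, down, volcano = reverse_search(query, sigs)
        assert set(up.columns) >= {"signature_id", "log2fc", "cd_coefficient",
                                   "rank", "discordant"}
        # every signature spikes the target set, so top hits must be positive
        assert up.iloc[0].log2fc > 0
        assert len(volcano) == len(sigs)
        np.testing.assert_array_equal(volcano["abs_cd"],
                                      volcano["cd_coefficient"].abs())

    def test_upregulating_batch_found(self, tiny_world):
        null = simulate_perturbation_study(tiny_world, n_batches=3,
                                           treat_per_batch=4,
                                           control_per_batch=4,
                                           target_set_size=0,
                                           effect_size=0.0, seed=44)
        active = simulate_perturbation_study(tiny_world, n_batches=1,
                                             treat_per_batch=4,
                                             control_per_batch=4,
                                             target_set_size=5,
                                             effect_size=2.0, seed=45)
        sigs = batch_signatures(null.profiles, null.metadata, "drugA")
        active_sigs = batch_signatures(active.profiles, active.metadata, "drugA")
        active_sigs[0].signature_id = "ACTIVE"
        query = sorted(active.target_set)[0]
        up, _, _ = reverse_search(query, sigs + active_sigs)
        assert up.iloc[0].signature_id == "ACTIVE"

    def test_cell_line_filter_can_empty_results(self, tiny_study):
        sigs = batch_signatures(tiny_study.profiles, tiny_study.metadata, "drugA")
        up, down, _ = reverse_search(tiny_study.profiles.gene_ids[0], sigs,
                                     cell_line="NOPE")
        assert up.empty and down.empty

    def test_absent_gene_rejected(self, tiny_study):
        sigs = batch_signatures(tiny_study.profiles, tiny_study.metadata, "drugA")
        with pytest.raises(ValueError, match="ZZZ"):
            reverse_search("ZZZ", sigs)
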