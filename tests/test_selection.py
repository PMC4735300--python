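"""Subset fitness, greedy forward selection, and odorant clustering."""

import numpy as np
import pytest

import orscreen as o
from orscreen.descriptors import DescriptorMatrix
from orscreen.selection import FITNESS_REGISTRY

from conftest import pairs_auc


def toy_matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    return DescriptorMatrix([f"m{i}" for i in range(values.shape[0])], names, values)


def fitness_oracle(m, labels, subset):
    """Independent LOO nearest-positive AUC: explicit loops + pair counts."""
    x = m.columns(subset)
    labels = np.asarray(labels, dtype=bool)
    scores = []
    for i in range(len(x)):
        d = [
            np.linalg.norm(x[i] - x[j])
            for j in range(len(x))
            if labels[j] and j != i
        ]
        scores.append(min(d))
    return pairs_auc(-np.asarray(scores), labels)


class TestSubsetFitness:
    def test_perfect_separation(self):
        m = toy_matrix([[0.0], [0.1], [10.0], [10.1]])
        assert o.subset_fitness(m, [1, 1, 0, 0], ["d0"]) == 1.0

    def test_matches_all_pairs_oracle_on_hand_instance(self):
        rng = np.random.default_rng(42)
        m = toy_matrix(rng.normal(size=(6, 2)))
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        got = o.subset_fitness(m, labels, ["d0", "d1"])
        assert got == fitness_oracle(m, labels, ["d0", "d1"])

    def test_permutation_null_is_chance(self, panel1):
        _, _, work, labels, _, truth = panel1
        subset = [f"D{j:04d}" for j in truth.informative_idx]
        rng = np.random.default_rng(0)
        vals = [
            o.subset_fitness(work, rng.permutation(labels), subset)
            for _ in range(200)
        ]
        assert 0.45 <= np.mean(vals) <= 0.55

    def test_requires_two_per_class(self):
        m = toy_matrix(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError):
            o.subset_fitness(m, [1, 0, 0, 0], ["d0"])

    def test_empty_subset_rejected(self):
        m = toy_matrix(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError):
            o.subset_fitness(m, [1, 1, 0, 0], [])


class TestFisherSeparation:
    def test_informative_dimension_scores_higher(self, panel1):
        _, _, work, labels, _, truth = panel1
        planted = f"D{truth.informative_idx[0]:04d}"
        noise = next(
            n for j, n in enumerate(work.descriptor_names)
            if j not in set(truth.informative_idx) | set(truth.kinetics_idx)
        )
        assert o.fisher_separation(work, labels, [planted]) > o.fisher_separation(
            work, labels, [noise]
        )

    def test_registry_contains_both_fitnesses(self):
        assert {"fisher_separation", "loo_nearest_positive_auc"} <= set(FITNESS_REGISTRY)


class TestSFS:
    @pytest.mark.parametrize("fitness", ["fisher_separation", "loo_nearest_positive_auc"])
    def test_each_step_is_exhaustive_argmax(self, fitness):
        fn = FITNESS_REGISTRY[fitness]
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = toy_matrix(rng.normal(size=(14, 8)))
            labels = np.zeros(14, dtype=bool)
            labels[rng.choice(14, 5, replace=False)] = True
            got = o.sfs_select(m, labels, target_size=3, fitness=fitness)
            selected = []
            for step in range(3):
                cands = [n for n in m.descriptor_names if n not in selected]
                scores = [fn(m, labels, selected + [c]) for c in cands]
                selected.append(cands[int(np.argmax(scores))])
            assert got.selected == selected

    def test_recovers_planted_subspace(self, panel1):
        _, _, work, labels, _, truth = panel1
        subset = o.sfs_select(work, labels, target_size=3)
        assert set(subset.selected) == {f"D{j:04d}" for j in truth.informative_idx}

    def test_target_size_13(self, panel1):
        _, _, work, labels, _, _ = panel1
        subset = o.sfs_select(work, labels, target_size=13)
        assert len(subset.selected) == 13
        assert len(subset.fitness_trajectory) == 13

    def test_plateau_trajectory_monotone(self, panel1):
        _, _, work, labels, _, _ = panel1
        subset = o.sfs_select(work, labels, target_size=20, stop_rule="plateau",
                              plateau_tol=1e-4)
        traj = subset.fitness_trajectory
        assert all(b - a >= 1e-4 for a, b in zip(traj, traj[1:]))
        assert len(subset.selected) < 20  # plateaued before the cap

    def test_tie_breaks_to_lowest_column_index(self):
        col = np.array([0.0, 0.2, 5.0, 5.2, 5.1, 0.1])
        m = toy_matrix(np.column_stack([col, col]), names=["d0", "d1"])
        labels = np.array([1, 1, 0, 0, 0, 1], dtype=bool)
        got = o.sfs_select(m, labels, target_size=1)
        assert got.selected == ["d0"]

    def test_target_exceeding_width_rejected(self):
        m = toy_matrix(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError):
            o.sfs_select(m, [1, 1, 0, 0], target_size=5)

    def test_save_load_roundtrip(self, tmp_path, panel1):
        _, _, work, labels, _, _ = panel1
        subset = o.sfs_select(work, labels, target_size=3)
        p = tmp_path / "s.json"
        subset.save(p)
        back = o.DescriptorSubset.load(p)
        assert back.selected == subset.selected
        assert back.fitness_trajectory == subset.fitness_trajectory


class TestKineticsSubset:
    def test_recovers_planted_kinetics_dims_seed1(self, panel1):
        records, _, work, _, _, truth = panel1
        subset = o.kinetics_subset(work, [r.kinetics_label for r in records],
                                   target_size=2)
        assert set(subset.selected) == {f"D{j:04d}" for j in truth.kinetics_idx}

    def test_recovery_rate_over_seeds(self):
        hits = 0
        for s in range(25):
            records, matrix, truth = o.gen_training_set(o.ChemSimConfig(seed=s))
            work = o.scale_matrix(o.clean_matrix(matrix))
            subset = o.kinetics_subset(work, [r.kinetics_label for r in records],
                                       target_size=2)
            hits += set(subset.selected) == {f"D{j:04d}" for j in truth.kinetics_idx}
        # 4 prolonged vs 10 transient positives: exact recovery is
        # information-limited, but must clearly beat chance
        assert hits >= 15

    def test_all_prolonged_is_error(self, panel1):
        _, _, work, _, _, _ = panel1
        labels = ["prolonged"] * work.n_molecules
        with pytest.raises(ValueError, match="transient"):
            o.kinetics_subset(work, labels)

    def test_selected_beats_full_matrix(self, panel1):
        records, _, work, _, _, _ = panel1
        kin_labels = [r.kinetics_label for r in records]
        subset = o.kinetics_subset(work, kin_labels, target_size=2)
        rows = [i for i, lab in enumerate(kin_labels) if lab != "unknown"]
        sub = work.take_rows(rows)
        lab = np.array([kin_labels[i] == "prolonged" for i in rows])
        assert o.fisher_separation(sub, lab, subset.selected) >= o.fisher_separation(
            sub, lab, sub.descriptor_names
        )


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        m = toy_matrix([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        dend = o.cluster_odorants(m, ["d0", "d1"])
        assert dend.merge_heights[0] == 0.0

    def test_average_linkage_hand_instance(self):
        # 1-D points {0, 1, 4, 10}: merges at 1, 3.5, 25/3
        m = toy_matrix([[0.0], [1.0], [4.0], [10.0]])
        dend = o.cluster_odorants(m, ["d0"])
        np.testing.assert_allclose(dend.merge_heights, [1.0, 3.5, 25.0 / 3.0])

    def test_two_cluster_cut_isolates_actives(self, panel1, fitted1):
        records, _, work, labels, _, _ = panel1
        subset, _ = fitted1
        dend = o.cluster_odorants(work, subset)
        cut = dend.cut(2)
        lab = {r.id: r.active_label == "active" for r in records}
        leaf_lab = np.array([lab[i] for i in dend.leaf_ids])
        best = max(
            (cut == c)[leaf_lab].sum() / leaf_lab.sum() for c in np.unique(cut)
        )
        assert best >= 0.9

    def test_newick_roundtrips_through_skbio(self, panel1, fitted1):
        import io

        from skbio.tree import TreeNode

        _, _, work, _, _, _ = panel1
        subset, _ = fitted1
        dend = o.cluster_odorants(work, subset)
        tree = TreeNode.read(io.StringIO(dend.to_newick()))
        tips = {t.name for t in tree.tips()}
        assert tips == set(dend.leaf_ids)

    def test_deterministic_under_row_shuffle(self, panel1, fitted1):
        _, _, work, _, _, _ = panel1
        subset, _ = fitted1
        rng = np.random.default_rng(0)
        shuffled = work.take_rows(rng.permutation(work.n_molecules))
        a = o.cluster_odorants(work, subset)
        b = o.cluster_odorants(shuffled, subset)
        np.testing.assert_array_equal(a.merges, b.merges)
        assert a.leaf_ids == b.leaf_ids

    def test_empty_subset_rejected(self, panel1):
        _, _, work, _, _, _ = panel1
        with pytest.raises(ValueError):
            o.cluster_odorants(work, [])
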