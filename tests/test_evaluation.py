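import numpy as np
import pytest

from strokemrs.core import ValidationError
from strokemrs.evaluate import (
    ConfusionMatrix3,
    SweepRow,
    ber,
    bootstrap_ccc_matrix,
    chronological_split,
    dichotomize,
    feature_sweep,
    roc_auc,
    select_model_size,
)

from conftest import make_matrix_cohort


def cm(counts, names=("c1", "c2", "c3")):
    return ConfusionMatrix3(np.array(counts), list(names))


class TestBer:
    def test_diagonal_is_zero(self):
        assert ber(cm([[5, 0, 0], [0, 7, 0], [0, 0, 3]])) == 0.0

    def test_printed_example(self):
        """Class sizes (16, 7, 5) with (1, 0, 1) misclassified -> 8.75%."""
        m = cm([[15, 1, 0], [0, 7, 0], [0, 1, 4]])
        assert ber(m) == pytest.approx((1 / 16 + 0 + 1 / 5) / 3 * 100)
        assert ber(m) == pytest.approx(8.75)

    def test_uniformly_wrong_is_100(self):
        assert ber(cm([[0, 3, 0], [0, 0, 4], [5, 0, 0]])) == 100.0

    def test_matches_direct_formula_on_random_matrices(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 20, size=(3, 3))
            counts += np.diag([1, 1, 1])  # keep every row non-empty
            m = cm(counts)
            per_class = [
                (row.sum() - row[i]) / row.sum() for i, row in enumerate(counts)
            ]
            assert ber(m) == pytest.approx(np.mean(per_class) * 100)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            ber(cm([[0, 0, 0], [0, 5, 0], [0, 0, 5]]))


class TestDichotomize:
    def test_counts_partition_total(self, rng):
        counts = rng.integers(0, 15, size=(3, 3))
        m = cm(counts)
        for target in m.class_names:
            d = dichotomize(m, target)
            assert d.tp + d.fn + d.fp + d.tn == m.total

    def test_perfect_matrix_all_100(self):
        d = dichotomize(cm([[5, 0, 0], [0, 7, 0], [0, 0, 3]]), "c2")
        assert (d.sensitivity, d.specificity, d.ppv, d.npv) == (100, 100, 100, 100)

    def test_zero_denominator_is_nan(self):
        # nothing predicted as c3 -> PPV undefined, not 0
        d = dichotomize(cm([[5, 0, 0], [0, 7, 0], [3, 0, 0]]), "c3")
        assert np.isnan(d.ppv)
        assert d.sensitivity == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        auc, se = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert (auc, se) == (1.0, 0.0)

    def test_identical_score_distributions_give_half(self):
        auc, _ = roc_auc([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_pair_counting(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        auc, _ = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestBootstrap:
    def test_separable_classes_score_100(self, gaussian_blobs):
        X, y = gaussian_blobs
        mean, sd = bootstrap_ccc_matrix(X, y, ["a", "b", "c"], n_boot=50, seed=1)
        assert mean == 100.0
        assert sd == 0.0

    def test_fixed_seed_reproducible_bitwise(self, rng):
        X = rng.normal(size=(30, 4))
        X[:10] += 2.0
        y = np.repeat(["a", "b", "c"], 10)
        a = bootstrap_ccc_matrix(X, y, ["a", "b", "c"], n_boot=200, seed=7)
        b = bootstrap_ccc_matrix(X, y, ["a", "b", "c"], n_boot=200, seed=7)
        assert a == b

    def test_seed_changes_resamples_but_not_level(self, rng):
        X = rng.normal(size=(60, 4))
        X[:20] += 2.5
        X[20:40] += np.array([0, 2.5, 0, 0])
        y = np.repeat(["a", "b", "c"], 20)
        m1, _ = bootstrap_ccc_matrix(X, y, ["a", "b", "c"], n_boot=1000, seed=1)
        m2, _ = bootstrap_ccc_matrix(X, y, ["a", "b", "c"], n_boot=1000, seed=2)
        assert m1 != m2
        assert abs(m1 - m2) < 0.5  # Monte-Carlo stability at n_boot=1000


class TestModelSizeRule:
    def rows(self, bers):
        return [SweepRow(k, np.nan, np.nan, b) for k, b in enumerate(bers, start=2)]

    def test_first_local_minimum(self):
        assert select_model_size(self.rows([20, 10, 12, 5, 15])) == 3

    def test_monotone_decreasing_picks_last(self):
        assert select_model_size(self.rows([20, 15, 10, 5])) == 5

    def test_global_minimum_mode(self):
        assert select_model_size(self.rows([20, 10, 12, 5, 15]), rule="global_min") == 5

    def test_flat_start_picks_smallest(self):
        assert select_model_size(self.rows([10, 10, 12])) == 2


class TestChronologicalSplit:
    def test_three_animals_two_spectra_each(self, rng):
        X = rng.normal(size=(6, 4))
        y = ["a", "b"] * 3
        cohort = make_matrix_cohort(X, y, animal_ids=[1, 1, 2, 2, 3, 3])
        out = chronological_split(cohort, 2 / 3)
        by_animal = {r.animal_id: r.split for r in out.records}
        assert by_animal == {"1": "train", "2": "train", "3": "test"}

    def test_no_animal_straddles_and_sets_disjoint(self, rng):
        for trial in range(5):
            n = 30
            animals = rng.integers(1, 9, size=n)
            X = rng.normal(size=(n, 3))
            y = rng.choice(["a", "b", "c"], size=n).tolist()
            cohort = make_matrix_cohort(X, y, animal_ids=animals)
            out = chronological_split(cohort)
            for a in set(r.animal_id for r in out.records):
                splits = {r.split for r in out.records if r.animal_id == a}
                assert len(splits) == 1
            train_ids = {r.spectrum_id for r in out.records if r.split == "train"}
            test_ids = {r.spectrum_id for r in out.records if r.split == "test"}
            assert not train_ids & test_ids
            assert train_ids and test_ids

    def test_single_animal_rejected(self, rng):
        cohort = make_matrix_cohort(rng.normal(size=(4, 3)), ["a"] * 4, animal_ids=[1] * 4)
        with pytest.raises(ValidationError):
            chronological_split(cohort)


class TestFeatureSweep:
    def _split_cohort(self, rng, n_per=12, p=15):
        y = np.repeat(["a", "b", "c"], n_per)
        X = rng.normal(0, 1, size=(3 * n_per, p))
        X[:, 2] += np.repeat([0, 3, 6], n_per)
        X[:, 9] += np.repeat([0, 4, 0], n_per)
        splits = (["train"] * (2 * n_per // 3) + ["test"] * (n_per - 2 * n_per // 3)) * 3
        return make_matrix_cohort(X, y, splits=splits)

    def test_row_count_covers_k_range(self, rng):
        cohort = self._split_cohort(rng)
        sweep = feature_sweep(
            cohort.subset("train"), cohort.subset("test"), 2, 8, n_boot=10, seed=0
        )
        assert [r.k for r in sweep.rows] == list(range(2, 9))
        assert sweep.selected_k in range(2, 9)

    def test_selected_k_no_worse_than_k_min(self, rng):
        cohort = self._split_cohort(rng)
        sweep = feature_sweep(
            cohort.subset("train"), cohort.subset("test"), 2, 8, n_boot=0, seed=0
        )
        by_k = {r.k: r.test_ber for r in sweep.rows}
        assert by_k[sweep.selected_k] <= by_k[2]

    def test_overlapping_split_rejected(self, rng):
        cohort = self._split_cohort(rng)
        with pytest.raises(ValidationError):
            feature_sweep(cohort.subset("train"), cohort.subset("train"), 2, 4, 0, 0)
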