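import itertools

import numpy as np
import pytest

from strokemrs.select import (
    cfs_merit,
    feature_class_correlation,
    recommended_feature_cap,
    sffs_select,
    sffs_select_matrix,
)

from conftest import make_matrix_cohort


def _toy(rng, n=60, p=8, informative=(0, 3)):
    y = np.array(["a"] * (n // 3) + ["b"] * (n // 3) + ["c"] * (n - 2 * (n // 3)))
    X = rng.normal(0, 1, size=(n, p))
    shifts = {"a": 0.0, "b": 2.5, "c": 5.0}
    for j in informative:
        X[:, j] += [shifts[c] for c in y]
    return X, y


def _merit_direct(subset, X, y):
    """Independent direct evaluation of the CFS formula (Pearson encoding)."""
    k = len(subset)
    classes = np.unique(y)
    rcf = []
    for j in subset:
        rs = []
        for c in classes:
            ind = (y == c).astype(float)
            rs.append(abs(np.corrcoef(X[:, j], ind)[0, 1]))
        rcf.append(np.mean(rs))
    r_cf = np.mean(rcf)
    if k == 1:
        return r_cf
    r_ff = np.mean(
        [abs(np.corrcoef(X[:, a], X[:, b])[0, 1]) for a, b in itertools.combinations(subset, 2)]
    )
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


class TestCfsMerit:
    def test_singleton_equals_class_correlation(self, rng):
        X, y = _toy(rng)
        rcf = feature_class_correlation(X, y, correlation="pearson")
        for j in range(X.shape[1]):
            assert cfs_merit([j], X, y, correlation="pearson") == pytest.approx(rcf[j])

    def test_duplicated_feature_gains_nothing(self, rng):
        """An exact duplicate of a feature leaves the merit unchanged."""
        X, y = _toy(rng)
        Xdup = np.column_stack([X, X[:, 0]])
        single = cfs_merit([0], Xdup, y, correlation="pearson")
        paired = cfs_merit([0, Xdup.shape[1] - 1], Xdup, y, correlation="pearson")
        assert paired == pytest.approx(single)

    def test_matches_direct_formula_exhaustively(self, rng):
        """All C(8,3) subsets agree with an independent formula evaluation."""
        X, y = _toy(rng)
        for subset in itertools.combinations(range(8), 3):
            assert cfs_merit(list(subset), X, y, correlation="pearson") == pytest.approx(
                _merit_direct(subset, X, y), abs=1e-12
            )

    def test_affine_rescaling_invariance(self, rng):
        X, y = _toy(rng)
        scale = rng.uniform(0.1, 10.0, X.shape[1])
        offset = rng.normal(0, 5, X.shape[1])
        subset = [0, 2, 5]
        a = cfs_merit(subset, X, y, correlation="pearson")
        b = cfs_merit(subset, X * scale + offset, y, correlation="pearson")
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_subset_rejected(self, rng):
        X, y = _toy(rng)
        with pytest.raises(ValueError):
            cfs_merit([], X, y)

    def test_constant_feature_scores_zero(self, rng):
        X, y = _toy(rng)
        X[:, 7] = 1.0
        assert cfs_merit([7], X, y, correlation="pearson") == 0.0
        assert cfs_merit([7], X, y, correlation="spearman") == 0.0


class TestSffs:
    @pytest.mark.parametrize("correlation", ["pearson", "spearman"])
    def test_greedy_path_matches_bruteforce(self, rng, correlation):
        """The incremental search equals step-by-step argmax over explicit merits."""
        X, y = _toy(rng, p=10, informative=(1, 4, 7))
        selected, trace = sffs_select_matrix(X, y, 5, correlation=correlation)
        chosen = []
        for _ in range(5):
            best_j, best_m = None, -np.inf
            for j in range(10):
                if j in chosen:
                    continue
                m = cfs_merit(chosen + [j], X, y, correlation=correlation)
                if m > best_m:
                    best_j, best_m = j, m
            chosen.append(best_j)
        assert selected == chosen
        assert [s.merit for s in trace.steps] == pytest.approx(
            [cfs_merit(chosen[: i + 1], X, y, correlation=correlation) for i in range(5)]
        )

    def test_dominant_feature_selected_first(self, rng):
        """A perfectly class-separating feature gets selection order 1."""
        n = 30
        y = np.repeat(["a", "b", "c"], 10)
        X = rng.normal(0, 1, size=(n, 6))
        X[:, 4] = np.repeat([0.0, 10.0, 20.0], 10) + rng.normal(0, 0.01, n)
        for corr in ("pearson", "spearman", "su"):
            selected, _ = sffs_select_matrix(X, y, 1, correlation=corr)
            assert selected[0] == 4, corr

    def test_deterministic(self, rng):
        X, y = _toy(rng, p=10)
        a, _ = sffs_select_matrix(X, y, 6)
        b, _ = sffs_select_matrix(X, y, 6)
        assert a == b

    def test_cohort_wrapper_reports_ppm(self, rng):
        X, y = _toy(rng, p=12)
        cohort = make_matrix_cohort(X, y)
        fs, trace = sffs_select(cohort, 4)
        assert len(fs) == 4
        assert [e.selection_order for e in fs.entries] == [1, 2, 3, 4]
        assert np.allclose(fs.ppms, cohort.axis[fs.indices])

    def test_floating_mode_runs(self, rng):
        X, y = _toy(rng, p=10, informative=(0, 5))
        selected, _ = sffs_select_matrix(X, y, 4, floating=True)
        assert 2 <= len(selected) <= 4
        assert len(set(selected)) == len(selected)


class TestRecommendedCap:
    @pytest.mark.parametrize(
        "sizes,expected", [((30, 20, 9), 3), ((40, 30, 22), 7), ((10, 8, 3), 2)]
    )
    def test_one_third_of_smallest_class(self, rng, sizes, expected):
        y = np.concatenate([[f"c{i}"] * s for i, s in enumerate(sizes)])
        X = rng.normal(size=(len(y), 4))
        cohort = make_matrix_cohort(X, y)
        assert recommended_feature_cap(cohort) == expected
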