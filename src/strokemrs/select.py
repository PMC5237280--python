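"""Sequential forward selection of spectral datapoints under the
correlation-based feature-subset (CFS) merit.

The merit of a k-feature subset is

    merit = k * r_cf / sqrt(k + k*(k-1) * r_ff)

where r_cf is the mean feature-class correlation over the subset and
r_ff the mean absolute pairwise feature-feature correlation.  A subset
scores well when its features correlate with the class but not with
each other.

Three correlation encodings are provided:

``spearman`` (default)
    Rank-transformed point-biserial correlation; the class correlation
    of one feature is the mean, over the three one-vs-rest class
    indicators, of the absolute correlation.  Chosen as the default
    because the normalized peak heights are strongly non-normal
    (heavy-tailed, as the cohort's own normality checks show), where a
    linear correlation understates the class association of the most
    skewed biomarkers.

``pearson``
    The same construction on the raw heights.

``su``
    Symmetric uncertainty on features discretized by the Fayyad-Irani
    MDL criterion, as in Hall's original formulation; the class enters
    directly as a nominal variable (no one-vs-rest encoding).

Constant features have all correlations defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .core import Cohort, FeatureEntry, FeatureSet

__all__ = [
    "MeritStep",
    "MeritTrace",
    "cfs_merit",
    "sffs_select",
    "sffs_select_matrix",
    "recommended_feature_cap",
    "feature_class_correlation",
]

DEFAULT_CORRELATION = "spearman"


@dataclass(frozen=True)
class MeritStep:
    k: int
    chosen_index: int
    merit: float


@dataclass
class MeritTrace:
    steps: list
    criterion: str = "cfs"
    correlation: str = DEFAULT_CORRELATION


def _encode(X: np.ndarray, correlation: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if correlation == "pearson":
        return X
    if correlation == "spearman":
        return np.apply_along_axis(scipy.stats.rankdata, 0, X)
    raise ValueError(f"unknown correlation encoding {correlation!r}")


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _class_corr_encoded(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean over one-vs-rest indicators of |r| on an already-encoded matrix."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    sx = X.std(axis=0)
    classes = np.unique(y)
    acc = np.zeros(p)
    for c in classes:
        ind = (y == c).astype(float)
        si = ind.std()
        if si == 0:
            continue
        cov = (Xc * (ind - ind.mean())[:, None]).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(sx > 0, cov / (sx * si), 0.0)
        acc += np.abs(r)
    return acc / len(classes)


def feature_class_correlation(
    X: np.ndarray, y: np.ndarray, correlation: str = DEFAULT_CORRELATION
) -> np.ndarray:
    """Per-feature class correlation under the chosen encoding."""
    if correlation == "su":
        D, ycode = _discretize_all(np.asarray(X, dtype=float), np.asarray(y))
        return np.array([_symmetric_uncertainty(D[:, j], ycode) for j in range(D.shape[1])])
    return _class_corr_encoded(_encode(X, correlation), np.asarray(y))


def _abs_corr_with(X: np.ndarray, j: int) -> np.ndarray:
    """|Pearson correlation| of column j with every column (0 where degenerate)."""
    Xc = X - X.mean(axis=0)
    sx = X.std(axis=0)
    cov = (Xc * Xc[:, [j]]).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((sx > 0) & (sx[j] > 0), cov / (sx * sx[j]), 0.0)
    return np.abs(r)


# ---------------------------------------------------------------------------
# symmetric uncertainty on MDL-discretized features (Hall's formulation)


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    return float(-(p * np.log2(p)).sum())


def _symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ha, hb = _entropy(a), _entropy(b)
    if ha == 0.0 or hb == 0.0:
        return 0.0
    joint = a.astype(np.int64) * (b.max() + 1) + b.astype(np.int64)
    mi = ha + hb - _entropy(joint)
    return float(2.0 * mi / (ha + hb))


def _mdl_cuts(x: np.ndarray, y: np.ndarray) -> list:
    """Fayyad-Irani recursive binary MDL discretization cut points."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 4:
            return
        labs = ys[lo:hi]
        e_full = _entropy(labs)
        best, best_gain, best_info = None, 0.0, None
        for i in range(lo + 1, hi):
            if xs[i] == xs[i - 1]:
                continue
            left, right = ys[lo:i], ys[i:hi]
            gain = e_full - (left.size * _entropy(left) + right.size * _entropy(right)) / n
            if gain > best_gain:
                best_gain, best = gain, i
                best_info = (
                    _entropy(left),
                    _entropy(right),
                    np.unique(left).size,
                    np.unique(right).size,
                )
        if best is None:
            return
        k = np.unique(labs).size
        el, er, kl, kr = best_info
        delta = np.log2(3.0**k - 2.0) - (k * e_full - kl * el - kr * er)
        if best_gain > (np.log2(n - 1) + delta) / n:
            cuts.append(0.5 * (xs[best - 1] + xs[best]))
            recurse(lo, best)
            recurse(best, hi)

    recurse(0, xs.size)
    return sorted(cuts)


def _discretize_all(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ycode = np.unique(y, return_inverse=True)[1]
    D = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        cuts = _mdl_cuts(X[:, j], ycode)
        D[:, j] = np.digitize(X[:, j], cuts) if cuts else 0
    return D, ycode


# ---------------------------------------------------------------------------
# merit and greedy search


def cfs_merit(
    subset, X: np.ndarray, y: np.ndarray, correlation: str = DEFAULT_CORRELATION
) -> float:
    """CFS merit of an explicit feature subset (direct formula)."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty feature subset")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    k = len(subset)
    if correlation == "su":
        D, ycode = _discretize_all(X[:, subset], y)
        rcf = np.array([_symmetric_uncertainty(D[:, j], ycode) for j in range(k)])
        pair = [
            _symmetric_uncertainty(D[:, a], D[:, b])
            for a in range(k)
            for b in range(a + 1, k)
        ]
    else:
        E = _encode(X[:, subset], correlation)
        rcf = _class_corr_encoded(E, y)
        pair = [
            abs(_safe_pearson(E[:, a], E[:, b]))
            for a in range(k)
            for b in range(a + 1, k)
        ]
    r_cf = float(rcf.mean())
    if k == 1:
        return r_cf
    r_ff = float(np.mean(pair))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def sffs_select_matrix(
    X: np.ndarray,
    y: np.ndarray,
    max_features: int,
    floating: bool = False,
    correlation: str = DEFAULT_CORRELATION,
) -> tuple[list, MeritTrace]:
    """Greedy forward search maximizing CFS merit; returns ordered indices.

    At each step the candidate datapoint maximizing the merit of the
    augmented subset is added; merit ties break toward the lower
    datapoint index (higher ppm).  With `floating=True`, after each
    addition any earlier feature whose removal improves merit is
    dropped (conditional exclusion) before the search continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if not 1 <= max_features <= p:
        raise ValueError(f"max_features {max_features} outside [1, {p}]")

    if correlation == "su":
        D, ycode = _discretize_all(X, y)
        rcf = np.array([_symmetric_uncertainty(D[:, j], ycode) for j in range(p)])

        def corr_with(j: int) -> np.ndarray:
            return np.array([_symmetric_uncertainty(D[:, j], D[:, q]) for q in range(p)])

    else:
        E = _encode(X, correlation)
        rcf = _class_corr_encoded(E, y)

        def corr_with(j: int) -> np.ndarray:
            return _abs_corr_with(E, j)

    selected: list[int] = []
    in_subset = np.zeros(p, dtype=bool)
    ff_sum = np.zeros(p)  # sum over selected of |corr(feature, selected)|
    pair_sum = 0.0  # sum of |corr| over selected pairs
    rcf_sum = 0.0
    best_at_size: dict[int, float] = {}
    steps: list[MeritStep] = []

    def rebuild() -> None:
        nonlocal pair_sum, rcf_sum, ff_sum
        in_subset[:] = False
        in_subset[selected] = True
        rcf_sum = float(rcf[selected].sum())
        ff_sum[:] = 0.0
        pair_sum = 0.0
        for a in selected:
            ca = corr_with(a)
            pair_sum += float(sum(ca[b] for b in selected if b != a)) / 2.0
            ff_sum += ca

    while len(selected) < max_features:
        k = len(selected) + 1
        if k == 1:
            m = rcf.copy()
        else:
            # merit = k * mean(rcf) / sqrt(k + k(k-1)*mean(|rff|)); the k in the
            # numerator cancels the 1/k of the mean, leaving the plain sum.
            rff = 2.0 * (pair_sum + ff_sum) / (k * (k - 1))
            m = (rcf_sum + rcf) / np.sqrt(k + k * (k - 1) * rff)
        m[in_subset] = -np.inf
        j = int(np.argmax(m))  # argmax returns the first (lowest) index on ties
        if not np.isfinite(m[j]):
            warnings.warn("no informative datapoints left; returning shorter selection")
            break
        corr_j = corr_with(j)
        pair_sum += ff_sum[j]
        ff_sum += corr_j
        selected.append(j)
        in_subset[j] = True
        rcf_sum += rcf[j]
        steps.append(MeritStep(len(selected), j, float(m[j])))

        best_at_size[len(selected)] = max(
            best_at_size.get(len(selected), -np.inf), float(m[j])
        )
        if floating and len(selected) > 2:
            # conditional exclusion: drop an earlier feature only when the
            # reduced subset strictly beats the best subset already seen at
            # that size — the standard guard that keeps the search finite
            improved = True
            while improved and len(selected) > 2:
                improved = False
                for drop in list(selected[:-1]):
                    trial = [s for s in selected if s != drop]
                    merit_trial = cfs_merit(trial, X, y, correlation)
                    if merit_trial > best_at_size.get(len(trial), -np.inf) + 1e-12:
                        selected = trial
                        best_at_size[len(trial)] = merit_trial
                        improved = True
                        break
            rebuild()
    return selected, MeritTrace(steps, correlation=correlation)


def sffs_select(
    train: Cohort,
    max_features: int,
    floating: bool = False,
    correlation: str = DEFAULT_CORRELATION,
) -> tuple[FeatureSet, MeritTrace]:
    """Run forward CFS selection on a normalized training cohort."""
    X, y = train.matrix()
    selected, trace = sffs_select_matrix(
        X, y, max_features, floating=floating, correlation=correlation
    )
    axis = train.axis
    fs = FeatureSet(
        [FeatureEntry(i + 1, j, float(axis[j])) for i, j in enumerate(selected)]
    )
    return fs, trace


def recommended_feature_cap(train: Cohort) -> int:
    """Rule of thumb for model size: one third of the smallest class, at least 2."""
    sizes = [v for v in train.class_sizes().values() if v > 0]
    if not sizes:
        raise ValueError("empty cohort")
    return max(2, min(sizes) // 3)
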