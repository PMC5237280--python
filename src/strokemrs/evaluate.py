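"""Classifier evaluation: balanced error rate, bootstrap accuracy,
one-vs-rest diagnostic metrics, ROC/AUC, the feature-count sweep with
its model-size selection rule, and the chronological train/test split.

BER is the unweighted mean over classes of the per-class
misclassification proportion, expressed as a percentage, so a class
with five cases weighs as much as one with fifty.  CCC (correctly
classified cases, %) is estimated on the training set by refitting the
discriminant on bootstrap resamples (sampling cases with replacement)
and scoring each refit on the full original training set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Cohort, FeatureSet, ValidationError
from .lda import fit_fisher_lda_matrix, predict
from .select import sffs_select

__all__ = [
    "ConfusionMatrix3",
    "DichotomizedMetrics",
    "SweepRow",
    "SweepResult",
    "ber",
    "ccc",
    "bootstrap_ccc",
    "bootstrap_ccc_matrix",
    "dichotomize",
    "roc_auc",
    "ovr_scores",
    "feature_sweep",
    "select_model_size",
    "chronological_split",
]


@dataclass
class ConfusionMatrix3:
    """Class-by-class counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_names)
        if self.counts.shape != (C, C):
            raise ValidationError(f"confusion shape {self.counts.shape} != ({C},{C})")
        if (self.counts < 0).any():
            raise ValidationError("negative confusion counts")

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_names) -> "ConfusionMatrix3":
        class_names = list(class_names)
        pos = {c: i for i, c in enumerate(class_names)}
        counts = np.zeros((len(class_names), len(class_names)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[pos[t], pos[p]] += 1
        return cls(counts, class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


def ber(confusion: ConfusionMatrix3) -> float:
    """Balanced error rate (%): mean over classes of misclassified/total."""
    totals = confusion.row_sums
    if (totals == 0).any():
        raise ValidationError("BER undefined: a class has no cases")
    correct = np.diag(confusion.counts)
    per_class = (totals - correct) / totals
    return float(per_class.mean() * 100.0)


def ccc(confusion: ConfusionMatrix3) -> float:
    """Correctly classified cases (%) over all cases pooled."""
    return float(np.diag(confusion.counts).sum() / confusion.total * 100.0)


@dataclass(frozen=True)
class DichotomizedMetrics:
    """One-vs-rest counts and diagnostic percentages for one target class.

    Metrics with a zero denominator are reported as NaN (undefined),
    never as 0.  `auc`/`auc_se` are filled only when continuous scores
    are available.
    """

    target_class: str
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: Optional[float] = None
    auc_se: Optional[float] = None


def _pct(num: int, den: int) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def dichotomize(confusion: ConfusionMatrix3, target: str) -> DichotomizedMetrics:
    """Collapse a 3-class confusion to target-vs-rest diagnostic metrics."""
    names = confusion.class_names
    if target not in names:
        raise ValidationError(f"unknown class {target!r}")
    i = names.index(target)
    c = confusion.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return DichotomizedMetrics(
        target_class=target,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        ppv=_pct(tp, tp + fp),
        npv=_pct(tn, tn + fn),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """AUC by the rank (Mann-Whitney) formulation, SE by Hanley-McNeil.

    `labels` are binary (1 = target class); higher scores should favour
    the target class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc needs both label values present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(auc), float(math.sqrt(max(var, 0.0)))


def ovr_scores(model, X: np.ndarray, target: str) -> np.ndarray:
    """One-vs-rest continuous score: distance to the nearest other
    centroid minus distance to the target centroid (higher = more
    target-like)."""
    Z = model.transform(np.asarray(X, dtype=float))
    D = np.sqrt(((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2))
    i = model.class_names.index(target)
    others = [j for j in range(len(model.class_names)) if j != i]
    return D[:, others].min(axis=1) - D[:, i]


def bootstrap_ccc_matrix(
    X: np.ndarray,
    y: np.ndarray,
    class_names,
    n_boot: int = 1000,
    seed: int = 0,
    out_of_bag: bool = False,
) -> tuple[float, float]:
    """Bootstrap the training-set CCC of the discriminant on fixed features.

    Each replicate resamples cases with replacement, refits the LDA, and
    scores CCC on the full original training set (or only on cases left
    out of the replicate when `out_of_bag`).  Replicates missing a class
    or with a degenerate class (fewer than 2 cases) are redrawn.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vals = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            counts = {c: int((y[idx] == c).sum()) for c in class_names}
            if min(counts.values()) >= 2:
                break
            redraws += 1
        model = fit_fisher_lda_matrix(X[idx], y[idx], class_names)
        if out_of_bag:
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size == 0:
                vals[b] = np.nan
                continue
            Xs, ys = X[oob], y[oob]
        else:
            Xs, ys = X, y
        labels, _ = predict(model, Xs)
        vals[b] = 100.0 * np.mean(np.asarray(labels) == ys)
    if redraws:
        warnings.warn(f"redrew {redraws} bootstrap replicates missing a class")
    return float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))


def bootstrap_ccc(
    train: Cohort,
    features: FeatureSet,
    n_boot: int = 1000,
    seed: int = 0,
    out_of_bag: bool = False,
) -> tuple[float, float]:
    """Cohort-level wrapper around :func:`bootstrap_ccc_matrix`."""
    X, y = train.matrix()
    return bootstrap_ccc_matrix(
        X[:, features.indices], y, list(train.class_labels), n_boot, seed, out_of_bag
    )


@dataclass(frozen=True)
class SweepRow:
    k: int
    ccc_mean: float
    ccc_sd: float
    test_ber: float


@dataclass
class SweepResult:
    rows: list
    selected_k: int
    features: FeatureSet = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [r.k for r in self.rows],
                "ccc_mean": [r.ccc_mean for r in self.rows],
                "ccc_sd": [r.ccc_sd for r in self.rows],
                "test_ber": [r.test_ber for r in self.rows],
            }
        )


def select_model_size(rows: Sequence[SweepRow], rule: str = "first_local_min") -> int:
    """Model-size rule on the test-set BER curve.

    `first_local_min` (default): the smallest k whose BER is no larger
    than both neighbours — larger models risk overtraining even when a
    marginally lower BER appears later.  `global_min`: smallest k
    attaining the overall minimum.
    """
    bers = [r.test_ber for r in rows]
    ks = [r.k for r in rows]
    if rule == "global_min":
        return ks[int(np.argmin(bers))]
    if rule != "first_local_min":
        raise ValueError(f"unknown rule {rule!r}")
    for i in range(len(bers)):
        left_ok = i == 0 or bers[i] <= bers[i - 1]
        right_ok = i == len(bers) - 1 or bers[i] <= bers[i + 1]
        if left_ok and right_ok:
            return ks[i]
    return ks[int(np.argmin(bers))]


def feature_sweep(
    train: Cohort,
    test: Cohort,
    k_min: int = 2,
    k_max: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
    rule: str = "first_local_min",
) -> SweepResult:
    """Sweep the number of selected features and pick the model size.

    Runs the forward CFS selection once to `k_max` on the training set;
    for each k the first k features are refit with Fisher LDA, the
    bootstrap CCC is scored on the training set (skipped when
    `n_boot` == 0) and the BER on the independent test set.  The
    selected k follows `rule` on the test-BER curve.
    """
    train_ids = {r.spectrum_id for r in train.records}
    if train_ids & {r.spectrum_id for r in test.records}:
        raise ValidationError("train and test sets overlap")
    from .select import recommended_feature_cap

    cap = recommended_feature_cap(train)
    if k_max > cap:
        warnings.warn(
            f"k_max={k_max} exceeds the 1/3-smallest-class guideline ({cap})"
        )
    features, _ = sffs_select(train, k_max)
    if len(features) < k_max:
        k_max = len(features)
    Xtr, ytr = train.matrix()
    Xte, yte = test.matrix()
    rows = []
    for k in range(k_min, k_max + 1):
        idx = features.indices[:k]
        model = fit_fisher_lda_matrix(Xtr[:, idx], ytr, list(train.class_labels))
        labels, _ = predict(model, Xte[:, idx])
        cm = ConfusionMatrix3.from_predictions(yte, labels, list(train.class_labels))
        test_ber = ber(cm)
        if n_boot > 0:
            sub_seed = int(
                np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31)
            )
            m, s = bootstrap_ccc_matrix(
                Xtr[:, idx], ytr, list(train.class_labels), n_boot, sub_seed
            )
        else:
            m, s = float("nan"), float("nan")
        rows.append(SweepRow(k, m, s, test_ber))
    return SweepResult(rows, select_model_size(rows, rule), features)


def chronological_split(cohort: Cohort, train_fraction: float = 2.0 / 3.0) -> Cohort:
    """Assign whole animals to train/test in animal-ID order.

    Animals are sorted by numeric ID (earlier = lower = enrolled first)
    and assigned to the training set until it holds at least
    `train_fraction` of all spectra; every remaining animal goes to the
    test set.  No animal ever straddles the split.
    """
    animals: dict[str, list] = {}
    for r in cohort.records:
        animals.setdefault(r.animal_id, []).append(r)
    if len(animals) < 2:
        raise ValidationError("cannot split a cohort with fewer than 2 animals")

    def sort_key(a: str):
        try:
            return (0, float(a))
        except ValueError:
            return (1, a)

    quota = train_fraction * len(cohort.records)
    train_animals = set()
    cum = 0
    for a in sorted(animals, key=sort_key):
        if cum >= quota:
            break
        train_animals.add(a)
        cum += len(animals[a])
    if len(train_animals) == len(animals):
        train_animals.discard(max(animals, key=sort_key))
    new_records = [
        r.copy_with(split="train" if r.animal_id in train_animals else "test")
        for r in cohort.records
    ]
    return Cohort(new_records, list(cohort.class_labels), dict(cohort.contralateral_map))
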