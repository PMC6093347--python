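"""Pairwise category decoding with exemplar-generalization cross-validation.

Protocol per category pair: trials are folded so that all trials of a given
stimulus exemplar land entirely in either the training or the test set
(decoding therefore measures category generalization across exemplars, not
image memorization).  Within each fold the training set is balanced to equal
class sizes (fixing chance at 50%), z-scored with training statistics, the
top-k features by one-way F statistic are selected, and a linear SVM
(C = 1) is trained; accuracy is pooled over folds as percent correct.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.svm import SVC

from .features import FeatureTable
from .stimuli import (DECODED_COARSE, IDENTITY_LABELS, SPECIES_LABELS,
                      VIEW_LABELS)

N_PAIRS_PER_LEVEL = {"coarse": 3, "species": 1, "view": 3, "identity": 10}


def level_pairs(level: str) -> list[tuple[str, str]]:
    """All decoded label pairs of a hierarchy level (3/1/3/10 pairs)."""
    labels = {"coarse": DECODED_COARSE, "species": SPECIES_LABELS,
              "view": VIEW_LABELS, "identity": IDENTITY_LABELS}[level]
    return list(combinations(labels, 2))


@dataclass
class DecodeSpec:
    level: str
    pair: tuple[str, str]
    n_selected_features: int = 100
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair members must be distinct")
        if self.pair[0] not in dict.fromkeys(sum(level_pairs(self.level), ())):
            raise ValueError(f"{self.pair[0]!r} is not a {self.level} label")


@dataclass
class FoldResult:
    n_test: int
    n_correct: int
    selected_features: np.ndarray
    weight_hash: str


@dataclass
class DecodeResult:
    folds: list[FoldResult]
    accuracy_pct: float
    ci95_pct: tuple[float, float]

    @property
    def n_test_total(self) -> int:
        return sum(f.n_test for f in self.folds)

    @property
    def n_correct_total(self) -> int:
        return sum(f.n_correct for f in self.folds)


def binomial_ci(n_correct: int, n_total: int) -> tuple[float, float]:
    """Two-sided 95% Clopper-Pearson CI on percent correct."""
    ci = stats.binomtest(n_correct, n_total).proportion_ci(0.95)
    return 100.0 * ci.low, 100.0 * ci.high


def zscore_by_train(train: np.ndarray,
                    test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-transform both sets using mean/SD of the training set.

    Zero-SD (constant) training columns are centered but not scaled.
    """
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training trials")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    # constant columns (incl. rounding-dust SDs) are centered, not scaled
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    sd = np.where(constant, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def select_features_F(train: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest one-way F statistics (stable index ties).

    If the table has <= k features, all are retained.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 trials")
    if train.shape[1] <= k:
        return np.arange(train.shape[1])
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns get F = 0 below
        f_vals, _ = f_classif(train, y)
    f_vals = np.nan_to_num(f_vals, nan=0.0, posinf=np.inf)
    order = np.argsort(-f_vals, kind="stable")
    return np.sort(order[:k])


def exemplar_folds(
    stimulus_ids: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Exemplar-grouped folds: no stimulus appears in both train and test.

    N = the smaller category's exemplar count; the larger category is
    randomly subsampled to N exemplars; each fold's test set holds all
    trials of exactly one exemplar per category.
    """
    exemplars = []
    for label in pair:
        ex = np.unique(stimulus_ids[labels == label])
        if len(ex) < 2:
            raise ValueError("cannot form generalization folds: "
                             f"category {label!r} has < 2 exemplars")
        exemplars.append(ex)
    n = min(len(e) for e in exemplars)
    chosen = [rng.permutation(e)[:n] for e in exemplars]
    kept = np.isin(stimulus_ids, np.concatenate(chosen))
    folds = []
    for k in range(n):
        test_stims = {chosen[0][k], chosen[1][k]}
        is_test = np.isin(stimulus_ids, list(test_stims))
        folds.append((np.flatnonzero(kept & ~is_test),
                      np.flatnonzero(is_test)))
    return folds


def balance_classes(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset (majority class subsampled)."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() == 0:
        raise ValueError("both classes must be non-empty")
    n = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n:
            idx = rng.permutation(idx)[:n]
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _decode_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    spec: DecodeSpec,
    rng: np.random.Generator,
) -> FoldResult:
    bal = balance_classes(y[train_idx], rng)
    tr = train_idx[bal]
    X_tr, X_te = zscore_by_train(X[tr], X[test_idx])
    sel = select_features_F(X_tr, y[tr], spec.n_selected_features)
    clf = SVC(kernel="linear", C=spec.svm_c)
    clf.fit(X_tr[:, sel], y[tr])
    pred = clf.predict(X_te[:, sel])
    weight_hash = hashlib.sha256(
        np.ascontiguousarray(clf.coef_).tobytes()
        + np.ascontiguousarray(clf.intercept_).tobytes()
    ).hexdigest()
    return FoldResult(
        n_test=len(test_idx),
        n_correct=int((pred == y[test_idx]).sum()),
        selected_features=sel,
        weight_hash=weight_hash,
    )


def pairwise_decode(spec: DecodeSpec, features: FeatureTable) -> DecodeResult:
    """Run the full pairwise decoding protocol; fully seeded by spec.seed."""
    labels = features.labels(spec.level)
    in_pair = np.isin(labels, list(spec.pair))
    if not all((labels == m).any() for m in spec.pair):
        raise ValueError(f"features do not cover both members of {spec.pair}")
    sub = features.subset_trials(np.flatnonzero(in_pair))
    y = sub.labels(spec.level)
    sids = sub.trial_meta["stimulus_id"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    folds = exemplar_folds(sids, y, spec.pair, rng)
    # assert exemplar disjointness on every emitted fold
    for tr, te in folds:
        if set(sids[tr]) & set(sids[te]):
            raise AssertionError("exemplar leakage between train and test")
    results = [_decode_fold(sub.values, y, tr, te, spec, rng)
               for tr, te in folds]
    n_correct = sum(f.n_correct for f in results)
    n_test = sum(f.n_test for f in results)
    return DecodeResult(
        folds=results,
        accuracy_pct=100.0 * n_correct / n_test,
        ci95_pct=binomial_ci(n_correct, n_test),
    )


def permute_labels(features: FeatureTable,
                   rng: np.random.Generator) -> FeatureTable:
    """Randomly reassign trials to stimuli (and hence category labels).

    Permutes the trial-metadata rows against the feature rows, preserving
    the exemplar/fold structure while destroying any feature-label
    association — the null used for chance calibration.
    """
    perm = rng.permutation(features.n_trials)
    return FeatureTable(features.values, features.feature_meta,
                        features.trial_meta.iloc[perm])


def level_accuracy(level: str, results: dict) -> float:
    """Trial-weighted pooled percent correct over all pairs of a level."""
    expected = N_PAIRS_PER_LEVEL[level]
    if len(results) != expected:
        raise ValueError(
            f"{level} level needs {expected} pair results, got {len(results)}"
        )
    n_correct = sum(r.n_correct_total for r in results.values())
    n_test = sum(r.n_test_total for r in results.values())
    return 100.0 * n_correct / n_test


def timecourse_decode(spec: DecodeSpec,
                      features: FeatureTable) -> tuple[np.ndarray, list]:
    """Decoding accuracy as a function of time (one window per point).

    ``features`` must carry a sliding-window grid (e.g. the 25-point,
    25-ms-step timecourse scheme); each time point uses only that window's
    features across all channels.
    """
    windows = np.unique(features.feature_meta["window"])
    results = []
    for w in windows:
        results.append(pairwise_decode(spec, features.select(window=int(w))))
    return windows, results


def frequency_decode(spec: DecodeSpec, features_by_band: dict) -> dict:
    """One decoding result per frequency band plus the pooled-band condition.

    Requires the per-band feature count (before selection) to be identical
    across single bands; the same k applies to every condition including
    "all".
    """
    single = {b: t for b, t in features_by_band.items() if b != "all"}
    counts = {b: t.n_features for b, t in single.items()}
    if len(set(counts.values())) > 1:
        raise ValueError(f"per-band feature counts differ: {counts}")
    if "all" not in features_by_band:
        features_by_band = dict(features_by_band)
        features_by_band["all"] = FeatureTable.concat_features(
            list(single.values())
        )
    return {band: pairwise_decode(spec, table)
            for band, table in features_by_band.items()}
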