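"""Spatial- and trial-shuffle controls on decoding.

Spatial shuffling permutes channel assignments within contiguous subareas of
the electrode grid independently on every trial, erasing spatial structure
at scales up to the subarea size while preserving the per-trial multiset of
channel responses.  Decoding accuracy versus subarea size is summarized by
the decay fit y = A exp(-B x) + C (A > 0, B > 0, C > 50; B is the decay
constant).  Trial shuffling permutes trials within stimulus independently
per channel, preserving per-channel marginals but destroying cross-channel
trial covariance; it is applied to the training set only, or to training
and test data, and conditions are compared by chi-squared tests on pooled
correct counts with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .decoding import DecodeResult, DecodeSpec, FoldResult, binomial_ci, \
    balance_classes, exemplar_folds, select_features_F, zscore_by_train
from .features import FeatureTable


# ---------------------------------------------------------------------------
# spatial shuffle

def _divisors(n: int) -> list[int]:
    return [d for d in range(1, n + 1) if n % d == 0]


def subarea_blocks(grid_rows: int, grid_cols: int,
                   subarea_size: int) -> list[np.ndarray]:
    """Tile the grid into contiguous rectangular blocks of ~subarea_size.

    The block shape is the divisor pair (rows x cols) whose channel count is
    closest to ``subarea_size`` (ties broken toward square blocks), so the
    tiling is exact with no remainder channels.  Returns channel-index
    arrays (row-major channel order).
    """
    n_channels = grid_rows * grid_cols
    if subarea_size > n_channels:
        raise ValueError("subarea_size exceeds channel count")
    if subarea_size < 1:
        raise ValueError("subarea_size must be >= 1")
    best = None
    for br in _divisors(grid_rows):
        for bc in _divisors(grid_cols):
            score = (abs(br * bc - subarea_size), abs(br - bc))
            if best is None or score < best[0]:
                best = (score, br, bc)
    _, br, bc = best
    blocks = []
    for r0 in range(0, grid_rows, br):
        for c0 in range(0, grid_cols, bc):
            rr, cc = np.meshgrid(np.arange(r0, r0 + br),
                                 np.arange(c0, c0 + bc), indexing="ij")
            blocks.append((rr * grid_cols + cc).ravel())
    return blocks


def spatial_shuffle(
    features: FeatureTable,
    subarea_size: int,
    grid_rows: int,
    grid_cols: int,
    seed: int = 0,
    return_permutations: bool = False,
):
    """Permute channel labels within subareas, independently per trial.

    All features of a channel (every window/band) move together.  The sorted
    multiset of channel response vectors within each (trial, subarea) is
    unchanged; ``subarea_size == 1`` is the identity.
    """
    blocks = subarea_blocks(grid_rows, grid_cols, subarea_size)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    channels = features.feature_meta["channel"].to_numpy()
    col_of = {}  # channel -> feature column indices (in stable order)
    for ch in np.unique(channels):
        col_of[ch] = np.flatnonzero(channels == ch)
    values = features.values.copy()
    perms = []
    for t in range(features.n_trials):
        perm = np.arange(grid_rows * grid_cols)
        for block in blocks:
            perm[block] = block[rng.permutation(len(block))]
        perms.append(perm)
        for ch in col_of:
            src = perm[ch]
            if src != ch:
                values[t, col_of[ch]] = features.values[t, col_of[src]]
    out = FeatureTable(values, features.feature_meta, features.trial_meta)
    if return_permutations:
        return out, np.asarray(perms)
    return out


# ---------------------------------------------------------------------------
# decay fit

@dataclass
class DecayFit:
    A: float
    B: float
    C: float
    residuals: np.ndarray
    no_decay: bool  # A at its lower boundary (flat curve)


def fit_decay(sizes: np.ndarray, accuracies: np.ndarray,
              n_starts: int = 5, seed: int = 0) -> DecayFit:
    """Constrained least-squares fit of y = A exp(-B x) + C.

    Bounds A > 0, B > 0, C > 50; multistart (seeded) to avoid the boundary
    trap where A or B collapses.  Raises on non-convergence, attaching the
    last iterate to the exception.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 points to fit the decay curve")

    def resid(p):
        a, b, c = p
        return a * np.exp(-b * x) + c - y

    lo = np.array([1e-9, 1e-9, 50.0 + 1e-9])
    hi = np.array([200.0, 10.0, 100.0])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    amp0 = max(y.max() - y.min(), 1e-3)
    starts = [np.array([amp0, 1.0 / max(x.mean(), 1e-6),
                        np.clip(y.min(), 50.01, 99.0)])]
    for _ in range(n_starts - 1):
        starts.append(np.array([
            amp0 * rng.uniform(0.2, 2.0),
            rng.uniform(0.01, 1.0),
            np.clip(y.min() * rng.uniform(0.9, 1.05), 50.01, 99.9),
        ]))
    best = None
    last = None
    for p0 in starts:
        sol = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        last = sol
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        err = RuntimeError("decay fit did not converge")
        err.last_iterate = last.x if last is not None else None
        raise err
    a, b, c = best.x
    # A below half a percentage point of accuracy means no resolvable decay
    return DecayFit(A=float(a), B=float(b), C=float(c),
                    residuals=resid(best.x), no_decay=bool(a < 0.5))


@dataclass
class ShuffleCurve:
    sizes: np.ndarray
    accuracies_pct: np.ndarray
    fit: DecayFit
    max_drop_pct: float  # accuracy(no shuffle) - accuracy(full-grid shuffle)


def shuffle_curve(
    spec: DecodeSpec,
    features: FeatureTable,
    grid_rows: int,
    grid_cols: int,
    sizes=(4, 10, 20, 30, 60),
    seed: int = 0,
    fit: bool = True,
) -> ShuffleCurve:
    """Decoding accuracy versus spatial-shuffle subarea size, with decay fit."""
    from .decoding import pairwise_decode

    baseline = pairwise_decode(spec, features).accuracy_pct
    accs = []
    for k, size in enumerate(sizes):
        shuffled = spatial_shuffle(features, int(size), grid_rows, grid_cols,
                                   seed=seed + k)
        accs.append(pairwise_decode(spec, shuffled).accuracy_pct)
    accs = np.asarray(accs)
    decay = fit_decay(np.asarray(sizes, float), accs, seed=seed) if fit else None
    full = accs[np.argmax(np.asarray(sizes))]
    return ShuffleCurve(np.asarray(sizes), accs, decay, baseline - full)


# ---------------------------------------------------------------------------
# trial shuffle

def trial_shuffle(features: FeatureTable, seed: int = 0,
                  trial_mask: np.ndarray | None = None) -> FeatureTable:
    """Shuffle trials within stimulus, independently per channel.

    Per-channel, per-stimulus marginal distributions are preserved exactly;
    cross-channel trial covariance is destroyed.  Raises if any stimulus in
    the shuffled set has a single trial (the shuffle would be the identity).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    channels = features.feature_meta["channel"].to_numpy()
    sids = features.trial_meta["stimulus_id"].to_numpy()
    mask = np.ones(features.n_trials, bool) if trial_mask is None \
        else np.asarray(trial_mask, bool)
    values = features.values.copy()
    uniq_ch = np.unique(channels)
    for sid in np.unique(sids[mask]):
        rows = np.flatnonzero(mask & (sids == sid))
        if len(rows) < 2:
            raise ValueError(
                f"stimulus {sid!r} has a single trial; shuffle is the identity"
            )
        for ch in uniq_ch:
            cols = np.flatnonzero(channels == ch)
            perm = rng.permutation(len(rows))
            values[np.ix_(rows, cols)] = features.values[np.ix_(rows[perm], cols)]
    return FeatureTable(values, features.feature_meta, features.trial_meta)


def decode_with_trial_shuffle(
    spec: DecodeSpec,
    features: FeatureTable,
    mode: str,
    seed: int = 0,
) -> DecodeResult:
    """Run the decoding protocol under a trial-shuffle condition.

    ``mode='train-only'``: the training data of every fold are shuffled
    (fresh permutation per fold) while test data stay original.
    ``mode='train+test'``: the whole data set is shuffled once up front and
    processed normally.
    """
    from .decoding import _decode_fold

    if mode == "train+test":
        shuffled = trial_shuffle(features, seed=seed)
        from .decoding import pairwise_decode
        return pairwise_decode(spec, shuffled)
    if mode != "train-only":
        raise ValueError(f"unknown mode {mode!r}")

    labels = features.labels(spec.level)
    sub = features.subset_trials(np.flatnonzero(np.isin(labels, list(spec.pair))))
    y = sub.labels(spec.level)
    sids = sub.trial_meta["stimulus_id"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    folds = exemplar_folds(sids, y, spec.pair, rng)
    results = []
    for k, (tr, te) in enumerate(folds):
        train_mask = np.zeros(sub.n_trials, bool)
        train_mask[tr] = True
        shuffled = trial_shuffle(sub, seed=seed * 1000 + k,
                                 trial_mask=train_mask)
        X = shuffled.values.copy()
        X[te] = sub.values[te]  # test data stay original
        results.append(_decode_fold(X, y, tr, te, spec, rng))
    n_correct = sum(f.n_correct for f in results)
    n_test = sum(f.n_test for f in results)
    return DecodeResult(results, 100.0 * n_correct / n_test,
                        binomial_ci(n_correct, n_test))


@dataclass
class ConditionComparison:
    pair: tuple[str, str]
    chi2: float
    p_raw: float
    p_bonferroni: float
    continuity_corrected: bool


def compare_conditions(results: dict) -> list[ConditionComparison]:
    """Pairwise chi-squared comparison of pooled correct/incorrect counts.

    ``results`` maps condition name -> DecodeResult.  P-values are
    Bonferroni-multiplied by the number of comparisons (capped at 1).  Cells
    with zero counts fall back to the continuity-corrected variant, flagged.
    """
    from itertools import combinations as _comb

    names = list(results)
    comparisons = list(_comb(names, 2))
    out = []
    for a, b in comparisons:
        ra, rb = results[a], results[b]
        table = np.array([
            [ra.n_correct_total, ra.n_test_total - ra.n_correct_total],
            [rb.n_correct_total, rb.n_test_total - rb.n_correct_total],
        ])
        if np.array_equal(table[0], table[1]) or (table.sum(axis=0) == 0).any():
            # identical counts, or a degenerate all-correct/all-wrong margin
            chi2, p, corrected = 0.0, 1.0, False
        else:
            corrected = bool((table == 0).any())
            res = stats.chi2_contingency(table, correction=corrected)
            chi2, p = res.statistic, res.pvalue
        out.append(ConditionComparison(
            pair=(a, b), chi2=float(chi2), p_raw=float(p),
            p_bonferroni=float(min(p * len(comparisons), 1.0)),
            continuity_corrected=corrected,
        ))
    return out
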