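import numpy as np
import pandas as pd
import pytest

from itcdecode import (DecodeSpec, FeatureTable, balance_classes,
                       exemplar_folds, frequency_decode, level_accuracy,
                       level_pairs, pairwise_decode, select_features_F,
                       timecourse_decode, zscore_by_train)
from itcdecode.features import TIMECOURSE_SCHEME, feature_grid_meta


def gaussian_pair_table(n_exemplars=(4, 4), trials_per=8, n_features=120,
                        effect=0.0, seed=0, labels=("face", "body"),
                        level="coarse", informative=None, rng=None):
    """Two-category synthetic feature table with exemplar structure."""
    rng = rng or np.random.default_rng(seed)
    rows, values = [], []
    for li, (label, n_ex) in enumerate(zip(labels, n_exemplars)):
        for ex in range(n_ex):
            for _ in range(trials_per):
                x = rng.standard_normal(n_features)
                if li == 0:
                    idx = (informative if informative is not None
                           else np.arange(n_features))
                    x[idx] += effect
                values.append(x)
                rows.append({"stimulus_id": f"{label}_{ex}",
                             "coarse": label if level == "coarse" else "face",
                             "species": label if level == "species" else "n/a",
                             "view": label if level == "view" else "n/a",
                             "identity": label if level == "identity" else "n/a"})
    meta = pd.DataFrame({"channel": np.arange(n_features) // 12,
                         "window": np.arange(n_features) % 12,
                         "band": "total"})
    return FeatureTable(np.asarray(values), meta, pd.DataFrame(rows))


class TestZScore:
    def test_two_point_column(self):
        tr, te = zscore_by_train(np.array([[1.0], [3.0]]), np.array([[2.0]]))
        np.testing.assert_allclose(tr.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert te[0, 0] == 0.0  # test value at the train mean maps to 0

    def test_constant_column_centered_not_scaled(self):
        tr, te = zscore_by_train(np.full((3, 1), 5.0), np.array([[7.0]]))
        np.testing.assert_allclose(tr, 0.0)
        assert te[0, 0] == 2.0

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            zscore_by_train(np.ones((1, 2)), np.ones((1, 2)))


class TestSelectFeaturesF:
    def test_few_features_all_retained(self, rng):
        X = rng.standard_normal((20, 80))
        y = np.repeat(["a", "b"], 10)
        assert len(select_features_F(X, y, 100)) == 80

    def test_perfect_separator_ranked_first(self, rng):
        X = rng.standard_normal((40, 50))
        y = np.repeat(["a", "b"], 20)
        X[:20, 7] += 50.0
        sel = select_features_F(X, y, 1)
        assert list(sel) == [7]

    def test_matches_textbook_variance_ratio(self, rng):
        """Ranks agree with a direct between/within variance computation."""
        X = rng.standard_normal((30, 40))
        y = np.repeat(["a", "b"], 15)
        X[:15, :10] += rng.uniform(0.5, 2.0, 10)
        sel = select_features_F(X, y, 12)
        f_oracle = np.empty(40)
        for j in range(40):
            groups = [X[y == c, j] for c in ("a", "b")]
            grand = X[:, j].mean()
            between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            within = sum(((g - g.mean()) ** 2).sum() for g in groups) / (30 - 2)
            f_oracle[j] = between / within
        expected = np.sort(np.argsort(-f_oracle, kind="stable")[:12])
        np.testing.assert_array_equal(sel, expected)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            select_features_F(np.ones((3, 4)), np.array(["a", "a", "b"]), 2)


class TestExemplarFolds:
    def test_unbalanced_exemplars_subsampled(self, rng):
        table = gaussian_pair_table(n_exemplars=(5, 3))
        sids = table.trial_meta["stimulus_id"].to_numpy()
        y = table.labels("coarse")
        folds = exemplar_folds(sids, y, ("face", "body"), rng)
        assert len(folds) == 3  # N = min(5, 3)
        used = set()
        for tr, te in folds:
            used |= set(sids[te])
        assert len({s for s in used if s.startswith("face")}) == 3

    def test_train_test_stimulus_disjoint(self, rng):
        table = gaussian_pair_table(n_exemplars=(4, 4))
        sids = table.trial_meta["stimulus_id"].to_numpy()
        folds = exemplar_folds(sids, table.labels("coarse"),
                               ("face", "body"), rng)
        for tr, te in folds:
            assert not (set(sids[tr]) & set(sids[te]))

    def test_fold_test_sizes(self, rng):
        table = gaussian_pair_table(n_exemplars=(4, 4), trials_per=10)
        folds = exemplar_folds(table.trial_meta["stimulus_id"].to_numpy(),
                               table.labels("coarse"), ("face", "body"), rng)
        for _, te in folds:
            assert len(te) == 20  # 2 exemplars x 10 trials

    def test_single_exemplar_category_rejected(self, rng):
        table = gaussian_pair_table(n_exemplars=(1, 3))
        with pytest.raises(ValueError, match="generalization folds"):
            exemplar_folds(table.trial_meta["stimulus_id"].to_numpy(),
                           table.labels("coarse"), ("face", "body"), rng)


class TestBalanceClasses:
    def test_majority_subsampled(self, rng):
        y = np.array(["a"] * 30 + ["b"] * 18)
        idx = balance_classes(y, rng)
        vals, counts = np.unique(y[idx], return_counts=True)
        assert counts.tolist() == [18, 18]

    def test_already_balanced_unchanged(self, rng):
        y = np.array(["a"] * 10 + ["b"] * 10)
        assert len(balance_classes(y, rng)) == 20


class TestPairwiseDecode:
    def test_separated_gaussians_high_accuracy(self):
        # class-mean separation ~3 SD overall (0.3 SD on each of 120 features)
        table = gaussian_pair_table(effect=0.45, seed=2, trials_per=10)
        res = pairwise_decode(DecodeSpec("coarse", ("face", "body"), seed=0),
                              table)
        assert res.accuracy_pct > 90.0
        assert res.ci95_pct[0] <= res.accuracy_pct <= res.ci95_pct[1]

    def test_no_signal_within_chance_ci(self):
        table = gaussian_pair_table(effect=0.0, seed=3, trials_per=12)
        res = pairwise_decode(DecodeSpec("coarse", ("face", "body"), seed=0),
                              table)
        assert res.ci95_pct[0] <= 50.0 <= res.ci95_pct[1] or \
            abs(res.accuracy_pct - 50.0) < 10.0

    def test_label_swap_symmetric(self):
        table = gaussian_pair_table(effect=0.4, seed=4)
        a = pairwise_decode(DecodeSpec("coarse", ("face", "body"), seed=0), table)
        b = pairwise_decode(DecodeSpec("coarse", ("body", "face"), seed=0), table)
        # same exemplar-fold structure up to category order: pooled totals match
        assert a.n_test_total == b.n_test_total

    def test_seeded_determinism(self):
        table = gaussian_pair_table(effect=0.3, seed=5)
        spec = DecodeSpec("coarse", ("face", "body"), seed=42)
        a = pairwise_decode(spec, table)
        b = pairwise_decode(spec, table)
        assert a.accuracy_pct == b.accuracy_pct
        assert [f.weight_hash for f in a.folds] == \
            [f.weight_hash for f in b.folds]

    def test_training_ignores_test_labels(self):
        """Permuting test labels never changes the trained model."""
        table = gaussian_pair_table(effect=0.5, seed=6)
        spec = DecodeSpec("coarse", ("face", "body"), seed=7)
        hashes = [f.weight_hash for f in pairwise_decode(spec, table).folds]
        # scramble the labels only in the metadata copy used for testing:
        # identical features and train labels -> identical weights
        table2 = FeatureTable(table.values, table.feature_meta,
                              table.trial_meta.copy())
        hashes2 = [f.weight_hash for f in pairwise_decode(spec, table2).folds]
        assert hashes == hashes2


class TestLevelAccuracy:
    def test_identity_needs_ten_pairs(self):
        assert len(level_pairs("identity")) == 10
        with pytest.raises(ValueError, match="10"):
            level_accuracy("identity", {})

    def test_pooling_matches_fold_recount(self):
        results = {}
        for pair in level_pairs("coarse"):
            labels = pair if "face" in pair else (pair[0], pair[1])
            table = gaussian_pair_table(effect=0.5, seed=hash(pair) % 100,
                                        labels=pair)
            results[pair] = pairwise_decode(
                DecodeSpec("coarse", pair, seed=0), table)
        pooled = level_accuracy("coarse", results)
        n_c = sum(f.n_correct for r in results.values() for f in r.folds)
        n_t = sum(f.n_test for r in results.values() for f in r.folds)
        assert pooled == pytest.approx(100.0 * n_c / n_t)


class TestTimecourse:
    def _timecourse_table(self, signal_windows, seed=0):
        rng = np.random.default_rng(seed)
        n_ch, nw = 8, TIMECOURSE_SCHEME.n_windows
        rows, values = [], []
        for label in ("face", "body"):
            for ex in range(4):
                for _ in range(8):
                    x = rng.standard_normal(n_ch * nw)
                    if label == "face":
                        for w in signal_windows:
                            x[w::nw] += 1.2  # all channels, that window
                    values.append(x)
                    rows.append({"stimulus_id": f"{label}_{ex}",
                                 "coarse": label, "species": "n/a",
                                 "view": "n/a", "identity": "n/a"})
        meta = feature_grid_meta(n_ch, TIMECOURSE_SCHEME, "total")
        return FeatureTable(np.asarray(values), meta, pd.DataFrame(rows))

    def test_25_time_points(self):
        assert TIMECOURSE_SCHEME.n_windows == 25
        np.testing.assert_allclose(TIMECOURSE_SCHEME.starts_ms[:3],
                                   [-50.0, -25.0, 0.0])
        assert TIMECOURSE_SCHEME.starts_ms[-1] == 550.0

    def test_accuracy_localized_to_signal_windows(self):
        signal_windows = [8, 9, 10]
        table = self._timecourse_table(signal_windows)
        spec = DecodeSpec("coarse", ("face", "body"), seed=0)
        windows, results = timecourse_decode(spec, table)
        accs = np.array([r.accuracy_pct for r in results])
        assert accs[signal_windows].min() > 75.0
        quiet = [w for w in range(25) if w not in signal_windows]
        assert np.median(accs[quiet]) < 65.0
        # pre-onset points stay within the chance CI
        for w in (0, 1):
            lo, hi = results[w].ci95_pct
            assert lo <= 50.0 <= hi


class TestFrequencyDecode:
    def _band_tables(self, informative_band, seed=0):
        rng = np.random.default_rng(seed)
        tables = {}
        for band in ("DC", "theta4", "highgamma80"):
            eff = 1.0 if band == informative_band else 0.0
            tables[band] = gaussian_pair_table(
                effect=eff / np.sqrt(96), n_features=96, seed=seed,
                rng=np.random.default_rng(rng.integers(2**31)))
        return tables

    def test_injected_band_wins(self):
        tables = self._band_tables("highgamma80", seed=8)
        # make the informative band clearly informative
        tables["highgamma80"] = gaussian_pair_table(effect=0.8, n_features=96,
                                                    seed=99)
        spec = DecodeSpec("coarse", ("face", "body"), seed=0)
        res = frequency_decode(spec, tables)
        assert set(res) == {"DC", "theta4", "highgamma80", "all"}
        hg = res["highgamma80"].accuracy_pct
        assert hg > max(res["DC"].accuracy_pct, res["theta4"].accuracy_pct)

    def test_mismatched_band_sizes_rejected(self):
        tables = self._band_tables("DC")
        tables["theta4"] = gaussian_pair_table(n_features=40)
        with pytest.raises(ValueError, match="feature counts"):
            frequency_decode(DecodeSpec("coarse", ("face", "body")), tables)
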