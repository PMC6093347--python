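import numpy as np
import pytest
from scipy import stats

from itcdecode import (DecodeSpec, compare_conditions, fit_decay,
                       pairwise_decode, spatial_shuffle, trial_shuffle)
from itcdecode.decoding import DecodeResult, FoldResult
from itcdecode.shuffle import decode_with_trial_shuffle, subarea_blocks
from test_decoding import gaussian_pair_table


class TestSpatialShuffle:
    def test_size_one_is_identity(self):
        table = gaussian_pair_table(effect=0.3, seed=1)
        out = spatial_shuffle(table, 1, 6, 10, seed=0)
        np.testing.assert_array_equal(out.values, table.values)

    def test_multiset_preserved_per_trial_subarea(self):
        table = gaussian_pair_table(effect=0.3, seed=2, n_features=60 * 2)
        # 60 channels x 2 windows
        import pandas as pd
        meta = pd.DataFrame({"channel": np.repeat(np.arange(60), 2),
                             "window": np.tile([0, 1], 60), "band": "total"})
        table = type(table)(table.values, meta, table.trial_meta)
        out = spatial_shuffle(table, 10, 6, 10, seed=3)
        blocks = subarea_blocks(6, 10, 10)
        ch = meta["channel"].to_numpy()
        for t in (0, 5):
            for block in blocks:
                cols = np.flatnonzero(np.isin(ch, block))
                a = np.sort(table.values[t, cols].reshape(len(block), 2), axis=0)
                b = np.sort(out.values[t, cols].reshape(len(block), 2), axis=0)
                np.testing.assert_array_equal(a, b)

    def test_stored_permutation_reproduces_output(self):
        table = gaussian_pair_table(effect=0.3, seed=4, n_features=60)
        import pandas as pd
        meta = pd.DataFrame({"channel": np.arange(60),
                             "window": 0, "band": "total"})
        table = type(table)(table.values, meta, table.trial_meta)
        out, perms = spatial_shuffle(table, 20, 6, 10, seed=5,
                                     return_permutations=True)
        rebuilt = np.stack([table.values[t, perms[t]]
                            for t in range(table.n_trials)])
        np.testing.assert_array_equal(out.values, rebuilt)

    def test_oversized_subarea_rejected(self):
        table = gaussian_pair_table()
        with pytest.raises(ValueError):
            spatial_shuffle(table, 61, 6, 10)

    def test_block_tiling_exact(self):
        for size in (4, 10, 20, 30, 60):
            blocks = subarea_blocks(6, 10, size)
            flat = np.concatenate(blocks)
            assert sorted(flat) == list(range(60))

    def test_homogeneous_map_more_shuffle_robust(self):
        """Shuffling hurts decoding less when the informative channels are
        everywhere (homogeneous) than when information is spatially local."""
        import pandas as pd
        rng = np.random.default_rng(11)
        drops = {}
        for kind in ("homogeneous", "clustered"):
            n_ch = 60
            if kind == "homogeneous":
                informative = np.arange(n_ch)
                eff = 0.35
            else:
                informative = np.arange(12)  # one corner block of channels
                eff = 0.35 * np.sqrt(60 / 12)  # match total contrast energy
            meta = pd.DataFrame({"channel": np.arange(n_ch),
                                 "window": 0, "band": "total"})
            table = gaussian_pair_table(n_features=n_ch, effect=eff, seed=12,
                                        informative=informative, trials_per=10)
            table = type(table)(table.values, meta, table.trial_meta)
            spec = DecodeSpec("coarse", ("face", "body"), seed=0)
            base = pairwise_decode(spec, table).accuracy_pct
            shuf = pairwise_decode(
                spec, spatial_shuffle(table, 60, 6, 10, seed=13)).accuracy_pct
            drops[kind] = base - shuf
        assert drops["homogeneous"] < drops["clustered"]


class TestFitDecay:
    def test_exact_recovery_on_model_class(self):
        x = np.array([4, 10, 20, 30, 45, 60], float)
        y = 20.0 * np.exp(-0.1 * x) + 55.0
        fit = fit_decay(x, y)
        assert fit.A == pytest.approx(20.0, abs=1e-6)
        assert fit.B == pytest.approx(0.1, abs=1e-6)
        assert fit.C == pytest.approx(55.0, abs=1e-6)
        assert not fit.no_decay

    def test_flat_curve_flagged_no_decay(self):
        x = np.array([4, 10, 30, 60], float)
        fit = fit_decay(x, np.full(4, 75.0))
        assert fit.no_decay
        assert fit.C == pytest.approx(75.0, abs=0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(np.array([1, 2, 3.0]), np.array([60, 55, 52.0]))

    def test_noisy_recovery_of_decay_constant(self):
        """Monte-Carlo recovery of B under accuracy noise.

        Exponential decay constants are weakly identified from noisy decay
        curves; at 0.5% noise most seeds recover B within 25%, and at 1%
        noise the median relative error stays below 25%.
        """
        x = np.linspace(4, 60, 13)
        true_b = 0.08
        n_seeds = 40
        errs = {0.5: [], 1.0: []}
        for noise, bucket in errs.items():
            for seed in range(n_seeds):
                rng = np.random.default_rng(seed)
                y = (18.0 * np.exp(-true_b * x) + 56.0
                     + rng.normal(0, noise, len(x)))
                fit = fit_decay(x, y, seed=seed)
                bucket.append(abs(fit.B - true_b) / true_b)
        assert np.mean(np.asarray(errs[0.5]) < 0.25) >= 0.85
        assert np.median(errs[1.0]) < 0.25

    def test_low_noise_bias_small(self):
        x = np.linspace(4, 60, 13)
        bs = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            y = 18.0 * np.exp(-0.08 * x) + 56.0 + rng.normal(0, 0.5, len(x))
            bs.append(fit_decay(x, y, seed=seed).B)
        assert abs(np.mean(bs) - 0.08) / 0.08 < 0.10


class TestTrialShuffle:
    def test_marginals_preserved(self):
        table = gaussian_pair_table(effect=0.4, seed=6)
        out = trial_shuffle(table, seed=7)
        sids = table.trial_meta["stimulus_id"].to_numpy()
        ch = table.feature_meta["channel"].to_numpy()
        for sid in np.unique(sids):
            rows = sids == sid
            for c in np.unique(ch)[:3]:
                cols = ch == c
                np.testing.assert_allclose(
                    np.sort(table.values[np.ix_(rows, cols)], axis=0),
                    np.sort(out.values[np.ix_(rows, cols)], axis=0))

    def test_single_trial_stimulus_rejected(self):
        table = gaussian_pair_table(trials_per=1)
        with pytest.raises(ValueError, match="single trial"):
            trial_shuffle(table)

    def test_independent_channels_decoding_unchanged(self):
        # channels independent by construction: nothing to destroy
        table = gaussian_pair_table(effect=0.45, seed=8, trials_per=10)
        spec = DecodeSpec("coarse", ("face", "body"), seed=0)
        a = pairwise_decode(spec, table)
        b = decode_with_trial_shuffle(spec, table, "train-only", seed=9)
        # difference stays inside the joint binomial uncertainty
        se = np.sqrt(2) * 100 * np.sqrt(0.25 / a.n_test_total)
        assert abs(a.accuracy_pct - b.accuracy_pct) < 3 * se + 5

    def test_shared_noise_shuffle_hurts(self):
        """Destroying cross-channel covariance lowers accuracy when the
        discriminative signal rides on shared trial noise."""
        rng = np.random.default_rng(10)
        import pandas as pd
        n_ch, trials_per = 40, 12
        rows, values = [], []
        for label in ("face", "body"):
            for ex in range(4):
                for _ in range(trials_per):
                    shared = rng.standard_normal()  # common across channels
                    x = 1.2 * shared + 0.4 * rng.standard_normal(n_ch)
                    if label == "face":
                        x[: n_ch // 2] += 0.5  # signal on half the channels:
                        # a channel contrast cancels the shared noise only
                        # while the trial covariance is intact
                    values.append(x)
                    rows.append({"stimulus_id": f"{label}_{ex}",
                                 "coarse": label, "species": "n/a",
                                 "view": "n/a", "identity": "n/a"})
        meta = pd.DataFrame({"channel": np.arange(n_ch), "window": 0,
                             "band": "total"})
        table = gaussian_pair_table().__class__(
            np.asarray(values), meta, pd.DataFrame(rows))
        spec = DecodeSpec("coarse", ("face", "body"), seed=0)
        orig = pairwise_decode(spec, table)
        shuf = decode_with_trial_shuffle(spec, table, "train-only", seed=1)
        assert shuf.accuracy_pct < orig.accuracy_pct


def _result(n_correct, n_test):
    return DecodeResult([FoldResult(n_test, n_correct, np.array([]), "")],
                        100.0 * n_correct / n_test, (0.0, 100.0))


class TestCompareConditions:
    def test_identical_counts_p_one(self):
        res = compare_conditions({"a": _result(150, 200), "b": _result(150, 200)})
        assert res[0].p_raw == 1.0

    def test_strong_difference_matches_fisher(self):
        out = compare_conditions({"a": _result(180, 200),
                                  "b": _result(120, 200)})[0]
        assert out.p_bonferroni < 0.001
        _, p_fisher = stats.fisher_exact([[180, 20], [120, 80]])
        # chi-squared agrees with the exact hypergeometric computation in
        # order of magnitude at these counts
        assert abs(np.log10(out.p_raw) - np.log10(p_fisher)) < 1.0

    def test_bonferroni_over_three_comparisons(self):
        res = compare_conditions({"a": _result(150, 200),
                                  "b": _result(140, 200),
                                  "c": _result(130, 200)})
        assert len(res) == 3
        for c in res:
            assert c.p_bonferroni == pytest.approx(min(c.p_raw * 3, 1.0))
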