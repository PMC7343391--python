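"""ROC preference, inclusion criteria, pseudopopulation decoding, and the
synthetic spike-count generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flexcat as fc
from flexcat.neural import (
    BinnedSpikeTable,
    DecodeConfig,
    SpikeCountTable,
    apply_inclusion,
    neuron_preferences,
    pseudopopulation_decode,
    read_spike_table,
    roc_preference,
    sliding_window,
    sliding_window_bins,
    synth_spike_table,
    write_spike_table,
)


def _pair_oracle(a, b):
    """Exhaustive all-pairs auROC: P(b > a) + 0.5 P(b == a)."""
    wins = sum((y > x) + 0.5 * (y == x) for x in a for y in b)
    return 2 * (wins / (len(a) * len(b)) - 0.5)


class TestROCPreference:
    def test_identical_distributions_give_zero(self):
        assert roc_preference([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_small_example_with_tie(self):
        # 4 pairs: (1,2)+, (1,3)+, (2,2) tie, (2,3)+ -> auROC 3.5/4
        assert roc_preference([1, 2], [2, 3]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_preference([0, 1], [5, 6]) == 1.0
        assert roc_preference([5, 6], [0, 1]) == -1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_preference([], [1])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=12),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=12),
    )
    def test_matches_exhaustive_pair_oracle(self, a, b):
        assert roc_preference(a, b) == pytest.approx(_pair_oracle(a, b), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=10),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=10),
    )
    def test_antisymmetry(self, a, b):
        assert roc_preference(a, b) == pytest.approx(-roc_preference(b, a), abs=1e-12)


def _table_with_counts(n_per, rate_hz=2.0, window=(0.0, 700.0), seed=0):
    """Table with exactly n_per trials for each (period, correct, class)."""
    rng = np.random.default_rng(seed)
    rows = []
    for period in ("stable", "switching"):
        for correct in (True, False):
            for choice in ("left", "right"):
                for _ in range(n_per):
                    rows.append((choice, "low" if choice == "left" else "high",
                                 period, correct))
    labels = pd.DataFrame(rows, columns=["choice", "prev_stim_class", "period", "correct"])
    dur = (window[1] - window[0]) / 1000
    counts = rng.poisson(rate_hz * dur, size=(1, len(labels))).astype(float)
    return SpikeCountTable(counts, labels, window)


class TestInclusion:
    def test_too_few_trials_excluded(self):
        t10 = _table_with_counts(10)
        t9 = _table_with_counts(9)
        keep10, _ = apply_inclusion(t10, "choice")
        keep9, _ = apply_inclusion(t9, "choice")
        assert len(keep10) == 1 and len(keep9) == 0

    def test_low_rate_everywhere_excluded(self):
        t = _table_with_counts(12, rate_hz=0.4, seed=1)
        t.counts[:] = 0.3  # 0.43 spikes/s in every condition, below threshold
        keep, rep = apply_inclusion(t, "choice")
        assert len(keep) == 0 and not rep["rate_ok"].iloc[0]

    def test_rate_above_threshold_in_one_condition_suffices(self):
        t = _table_with_counts(12, rate_hz=0.4, seed=2)
        stable_correct = (t.labels["period"] == "stable") & t.labels["correct"]
        t.counts[0, stable_correct.to_numpy()] = 3.0  # ~4.3 spikes/s there
        keep, _ = apply_inclusion(t, "choice")
        assert len(keep) == 1


class TestDecoding:
    def test_separable_classes_decode_above_90_percent(self):
        table = synth_spike_table(n_neurons=20, n_trials=240, base_rate=10.0,
                                  choice_gain=1.0, history_gain=0.0, seed=3)
        cfg = DecodeConfig(n_resamples=20, cv_repeats=10, seed=0)
        acc = pseudopopulation_decode(table, "choice", condition=None, cfg=cfg)
        assert acc.shape == (20,)
        assert acc.mean() > 0.9

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(5)
        table = synth_spike_table(n_neurons=20, n_trials=240, base_rate=10.0,
                                  choice_gain=1.0, history_gain=0.0, seed=3)
        # destroy the label-response association independently per neuron
        for i in range(table.n_neurons):
            table.counts[i] = rng.permutation(table.counts[i])
        cfg = DecodeConfig(n_resamples=30, cv_repeats=10, seed=1)
        acc = pseudopopulation_decode(table, "choice", condition=None, cfg=cfg)
        # chance 0.5; each resample tests 6 pseudotrials, so allow 3 sigma of
        # the binomial spread of the mean over resamples
        n_test = 2 * cfg.n_trials_per_class - 2 * int(round(0.75 * cfg.n_trials_per_class))
        sigma = np.sqrt(0.25 / (n_test * cfg.n_resamples))
        assert abs(acc.mean() - 0.5) < 4 * sigma + 0.05

    def test_seed_makes_decoding_reproducible(self):
        table = synth_spike_table(n_neurons=10, n_trials=200, seed=7,
                                  choice_gain=0.5)
        cfg = DecodeConfig(n_resamples=5, cv_repeats=5, seed=9)
        a = pseudopopulation_decode(table, "choice", None, cfg)
        b = pseudopopulation_decode(table, "choice", None, cfg)
        assert np.array_equal(a, b)

    def test_insufficient_trials_error_names_neuron(self):
        table = _table_with_counts(9)
        with pytest.raises(ValueError, match="n0"):
            pseudopopulation_decode(table, "choice", ("stable", True),
                                    DecodeConfig(n_resamples=2, cv_repeats=2))

    def test_zscore_of_training_features(self):
        """Within the decoder, each neuron's training features are
        standardized; replicate the transform here on one resample draw."""
        table = synth_spike_table(n_neurons=5, n_trials=100, seed=0)
        X = table.counts[:, :20].T.copy()
        mu, sd = X.mean(0), X.std(0)
        sd[sd == 0] = 1
        Z = (X - mu) / sd
        assert np.allclose(Z.mean(0), 0, atol=1e-12)
        assert np.allclose(Z.std(0)[sd > 1e-12], 1, atol=1e-12)


class TestSlidingWindow:
    def test_default_span_gives_35_bins(self):
        starts = sliding_window_bins((0.0, 900.0), 50.0, 25.0)
        assert len(starts) == 35
        assert starts[0] == 0.0 and starts[-1] == 850.0

    def test_constant_rate_neurons_have_near_zero_preferences(self):
        binned = synth_spike_table(n_neurons=15, n_trials=300, base_rate=8.0,
                                   choice_gain=0.0, history_gain=0.0, seed=2,
                                   n_bins=6)
        out = sliding_window("preference_correlation", binned)
        assert len(out) == 6
        prefs = neuron_preferences(binned.window(0))
        assert np.abs(prefs["choice_pref"]).max() < 0.35
        assert np.abs(prefs["choice_pref"]).mean() < 0.12

    def test_decoding_rises_after_onset(self):
        binned = synth_spike_table(n_neurons=15, n_trials=200, base_rate=20.0,
                                   choice_gain=1.0, seed=4, n_bins=4, onset_bin=2)
        cfg = DecodeConfig(n_resamples=5, cv_repeats=5, seed=0)
        out = sliding_window("decode", binned, target_label="choice", cfg=cfg)
        pre = out["accuracy"][:2].mean()
        post = out["accuracy"][2:].mean()
        assert pre < 0.65 and post > 0.8


class TestSynthGenerator:
    def test_zero_gain_gives_flat_choice_preference(self):
        table = synth_spike_table(n_neurons=40, n_trials=400, choice_gain=0.0,
                                  history_gain=0.5, seed=6)
        prefs = neuron_preferences(table)
        assert np.abs(prefs["choice_pref"]).mean() < 0.08
        assert np.abs(prefs["prev_stim_pref"]).mean() > 0.15

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coupled_loadings_correlate_preferences(self, seed):
        table = synth_spike_table(n_neurons=100, n_trials=400, choice_gain=0.4,
                                  history_gain=0.4, coupling=0.9, seed=seed)
        prefs = neuron_preferences(table)
        r = np.corrcoef(prefs["choice_pref"], prefs["prev_stim_pref"])[0, 1]
        assert r > 0.6

    def test_fixed_seed_bit_identical(self):
        a = synth_spike_table(seed=11)
        b = synth_spike_table(seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert a.labels.equals(b.labels)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            synth_spike_table(choice_gain=-1)
        with pytest.raises(ValueError):
            synth_spike_table(coupling=1.5)

    def test_csv_round_trip(self, tmp_path):
        table = synth_spike_table(n_neurons=6, n_trials=50, seed=1)
        write_spike_table(table, tmp_path / "c.csv", tmp_path / "l.csv")
        back = read_spike_table(tmp_path / "c.csv", tmp_path / "l.csv")
        assert np.array_equal(back.counts, table.counts)
        assert back.labels["choice"].equals(table.labels["choice"])
        assert back.labels["correct"].dtype == bool
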