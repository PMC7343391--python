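"""ROC-based selectivity and pseudopopulation decoding of spike counts.

Selectivity between two trial conditions is quantified as the ROC
preference 2*(auROC - 0.5) in [-1, 1], computed exactly through the
rank/Mann-Whitney identity (ties count 0.5). Decoding assembles a
pseudopopulation — trials resampled independently per neuron, since units
were not recorded simultaneously — z-scores each neuron, and classifies
upcoming choice or previous-stimulus class with a linear maximum-margin
(support-vector) classifier under repeated 75/25 splits.

A Poisson generator with per-neuron choice/history loadings stands in for
recorded units; it is synthetic data for exercising the analyses, not a
model of any recorded population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

__all__ = [
    "SpikeCountTable",
    "BinnedSpikeTable",
    "DecodeConfig",
    "roc_preference",
    "apply_inclusion",
    "pseudopopulation_decode",
    "sliding_window",
    "sliding_window_bins",
    "synth_spike_table",
    "read_spike_table",
    "write_spike_table",
]


@dataclass
class SpikeCountTable:
    """Spike counts of ``n_neurons x n_trials`` in one counting window.

    ``labels`` has one row per trial with columns choice ('left'/'right'),
    prev_stim_class ('low'/'high'/'reversing'), period ('stable'/
    'switching'), correct (bool). ``counts`` may contain NaN for trials a
    neuron was not recorded on (pseudopopulation neurons need not share
    trials).
    """

    counts: np.ndarray
    labels: pd.DataFrame
    window_ms: tuple = (0.0, 700.0)
    neuron_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (neurons x trials)")
        if self.counts.shape[1] != len(self.labels):
            raise ValueError("labels must align with the trial axis")
        if self.window_ms[1] <= self.window_ms[0]:
            raise ValueError("window end must exceed start")
        if np.nanmin(self.counts) < 0:
            raise ValueError("spike counts must be nonnegative")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(self.counts.shape[0])]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def mean_rates(self, trial_mask=None) -> np.ndarray:
        """Per-neuron mean firing rate (spikes/s) over (masked) trials."""
        c = self.counts if trial_mask is None else self.counts[:, trial_mask]
        dur_s = (self.window_ms[1] - self.window_ms[0]) / 1000.0
        return np.nanmean(c, axis=1) / dur_s


@dataclass
class BinnedSpikeTable:
    """Per-bin spike counts (neurons x trials x bins) for sliding-window
    analyses; ``bin_centers_ms`` stamps each bin at its center."""

    counts: np.ndarray
    labels: pd.DataFrame
    bin_centers_ms: np.ndarray
    bin_width_ms: float = 50.0

    def window(self, b: int) -> SpikeCountTable:
        c = self.bin_centers_ms[b]
        return SpikeCountTable(self.counts[:, :, b], self.labels,
                               (c - self.bin_width_ms / 2, c + self.bin_width_ms / 2))


@dataclass(frozen=True)
class DecodeConfig:
    """Pseudopopulation decoding protocol (study defaults: 10 trials per
    class per neuron, 1500 resamples — 100 for sliding windows — and 100
    repeats of the 75/25 split)."""

    n_trials_per_class: int = 10
    n_resamples: int = 1500
    cv_repeats: int = 100
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_class < 2:
            raise ValueError("n_trials_per_class must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def roc_preference(counts_a, counts_b) -> float:
    """Signed selectivity 2*(auROC - 0.5) between two response groups.

    auROC = P(draw from b > draw from a) + 0.5 P(tie), computed exactly via
    the rank-sum (Mann-Whitney U) identity. Positive values mean higher
    firing in group b; by this package's convention group a is left-choice
    (or previous-low) trials and group b right-choice (previous-high).
    """
    a = np.asarray(counts_a, dtype=float).ravel()
    b = np.asarray(counts_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))
    u_b = ranks[len(a):].sum() - len(b) * (len(b) + 1) / 2.0
    auroc = u_b / (len(a) * len(b))
    return float(2.0 * (auroc - 0.5))


def _condition_mask(labels: pd.DataFrame, condition) -> np.ndarray:
    """Boolean trial mask for a (period, correctness) condition; either
    element may be None to pool over it."""
    mask = np.ones(len(labels), dtype=bool)
    if condition is None:
        return mask
    period, correct = condition
    if period is not None:
        mask &= (labels["period"] == period).to_numpy()
    if correct is not None:
        mask &= labels["correct"].to_numpy(dtype=bool) == bool(correct)
    return mask


def _class_values(target_label: str):
    if target_label == "choice":
        return "choice", ["left", "right"]
    if target_label == "prev_stim":
        return "prev_stim_class", ["low", "high"]
    raise ValueError("target_label must be 'choice' or 'prev_stim'")


def apply_inclusion(table: SpikeCountTable, target_label: str = "choice",
                    conditions=None, min_trials: int = 10,
                    min_rate: float = 0.5):
    """Neuron-inclusion filter for ROC/decoding analyses.

    A neuron is kept if it has at least ``min_trials`` trials of each target
    class under EVERY condition and fires above ``min_rate`` spikes/s in at
    least one condition. Returns (included neuron indices, per-neuron report
    DataFrame).
    """
    if conditions is None:
        conditions = [("stable", True), ("switching", True),
                      ("stable", False), ("switching", False)]
    col, classes = _class_values(target_label)
    ok_trials = np.ones(table.n_neurons, dtype=bool)
    ok_rate = np.zeros(table.n_neurons, dtype=bool)
    report = {}
    for cond in conditions:
        cmask = _condition_mask(table.labels, cond)
        for cls in classes:
            sel = cmask & (table.labels[col] == cls).to_numpy()
            n_per = np.sum(~np.isnan(table.counts[:, sel]), axis=1)
            ok_trials &= n_per >= min_trials
            report[f"n[{cond}][{cls}]"] = n_per
        ok_rate |= table.mean_rates(cmask) > min_rate
    keep = np.nonzero(ok_trials & ok_rate)[0]
    rep = pd.DataFrame(report, index=table.neuron_ids)
    rep["enough_trials"] = ok_trials
    rep["rate_ok"] = ok_rate
    rep["included"] = ok_trials & ok_rate
    return keep, rep


def pseudopopulation_decode(table: SpikeCountTable, target_label: str = "choice",
                            condition=("switching", True),
                            cfg: DecodeConfig | None = None,
                            neurons=None) -> np.ndarray:
    """Decode a binary trial label from resampled pseudopopulations.

    Per resample, ``n_trials_per_class`` trials per class are drawn without
    replacement independently for each neuron to build a pseudopopulation
    matrix; per repeat, a stratified 75/25 split is z-scored on the training
    part (statistics applied to the test part) and classified with a linear
    SVM (C = 1); the repeat-averaged accuracy is one sample. Returns
    ``cfg.n_resamples`` accuracy values.
    """
    cfg = cfg or DecodeConfig()
    col, classes = _class_values(target_label)
    cmask = _condition_mask(table.labels, condition)
    if neurons is None:
        neurons = np.arange(table.n_neurons)
    neurons = np.asarray(neurons)
    trial_pools = []
    for cls in classes:
        sel = cmask & (table.labels[col] == cls).to_numpy()
        pools = []
        for i in neurons:
            idx = np.nonzero(sel & ~np.isnan(table.counts[i]))[0]
            if len(idx) < cfg.n_trials_per_class:
                raise ValueError(
                    f"neuron {table.neuron_ids[i]} has {len(idx)} < "
                    f"{cfg.n_trials_per_class} '{cls}' trials under {condition}")
            pools.append(idx)
        trial_pools.append(pools)

    rng = np.random.default_rng(cfg.seed)
    n_cls = cfg.n_trials_per_class
    y = np.repeat([0, 1], n_cls)
    n_train_per_cls = max(1, int(round(cfg.train_fraction * n_cls)))
    accuracies = np.empty(cfg.n_resamples)
    for r in range(cfg.n_resamples):
        X = np.empty((2 * n_cls, len(neurons)))
        for c, pools in enumerate(trial_pools):
            for j, idx in enumerate(pools):
                take = rng.choice(idx, size=n_cls, replace=False)
                X[c * n_cls:(c + 1) * n_cls, j] = table.counts[neurons[j], take]
        acc = 0.0
        for _ in range(cfg.cv_repeats):
            train = np.zeros(2 * n_cls, dtype=bool)
            for c in (0, 1):  # stratified split
                pick = rng.choice(n_cls, size=n_train_per_cls, replace=False)
                train[c * n_cls + pick] = True
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[train] - mu) / sd
            Xte = (X[~train] - mu) / sd
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(Xtr, y[train])
            acc += float(np.mean(clf.predict(Xte) == y[~train]))
        accuracies[r] = acc / cfg.cv_repeats
    return accuracies


def sliding_window_bins(span_ms=(0.0, 900.0), bin_ms: float = 50.0,
                        step_ms: float = 25.0) -> np.ndarray:
    """Bin start times for a sliding-window analysis; bins extending past
    the span are dropped. Default span/width/step give 35 bins."""
    starts = np.arange(span_ms[0], span_ms[1] - bin_ms + 1e-9, step_ms)
    return starts


def sliding_window(analysis: str, binned: BinnedSpikeTable, *,
                   target_label: str = "choice", condition=None,
                   cfg: DecodeConfig | None = None, neurons=None) -> pd.DataFrame:
    """Apply an analysis per time bin.

    analysis="preference_correlation": per-bin Pearson correlation across
    neurons between choice preference and previous-stimulus preference
    (both as ROC preferences). analysis="decode": per-bin mean decoding
    accuracy. Rows are stamped at the bin center (ms).
    """
    rows = []
    for b, center in enumerate(binned.bin_centers_ms):
        tab = binned.window(b)
        if analysis == "preference_correlation":
            prefs = neuron_preferences(tab, condition=condition, neurons=neurons)
            r = float(np.corrcoef(prefs["choice_pref"], prefs["prev_stim_pref"])[0, 1])
            rows.append({"time_ms": center, "correlation": r})
        elif analysis == "decode":
            acc = pseudopopulation_decode(tab, target_label, condition, cfg, neurons)
            rows.append({"time_ms": center, "accuracy": float(acc.mean())})
        else:
            raise ValueError("analysis must be 'preference_correlation' or 'decode'")
    return pd.DataFrame(rows)


def neuron_preferences(table: SpikeCountTable, condition=None, neurons=None) -> pd.DataFrame:
    """Per-neuron ROC preferences for upcoming choice (left vs right) and
    previous stimulus class (low vs high)."""
    cmask = _condition_mask(table.labels, condition)
    if neurons is None:
        neurons = np.arange(table.n_neurons)
    ch = table.labels["choice"].to_numpy()
    pv = table.labels["prev_stim_class"].to_numpy()
    rows = []
    for i in neurons:
        valid = cmask & ~np.isnan(table.counts[i])
        c = table.counts[i]
        rows.append({
            "neuron": table.neuron_ids[i],
            "choice_pref": roc_preference(c[valid & (ch == "left")], c[valid & (ch == "right")]),
            "prev_stim_pref": roc_preference(c[valid & (pv == "low")], c[valid & (pv == "high")]),
        })
    return pd.DataFrame(rows)


def synth_spike_table(n_neurons: int = 60, n_trials: int = 400,
                      base_rate: float = 5.0, choice_gain: float = 0.3,
                      history_gain: float = 0.3, coupling: float = 0.0,
                      seed: int = 0, window_ms=(0.0, 700.0),
                      n_bins: int | None = None, onset_bin: int = 0):
    """Synthetic Poisson spike-count table with choice/history tuning.

    Per-neuron log rate: log(base_rate) + choice_gain * c_i * x_choice +
    history_gain * h_i * x_prev, with trial labels x in {-1, +1} (choice:
    right = +1; previous stimulus: high = +1) and per-neuron loadings
    (c_i, h_i) standard-normal with correlation ``coupling`` — so the two
    ROC-preference vectors correlate across neurons with the sign of
    ``coupling``. Trials carry period and correctness labels balanced at
    random. With ``n_bins`` set, returns a :class:`BinnedSpikeTable` whose
    tuning switches on at ``onset_bin`` (rates before it are untuned).
    """
    if choice_gain < 0 or history_gain < 0:
        raise ValueError("gains must be >= 0")
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, coupling], [coupling, 1.0]])
    load = rng.multivariate_normal([0.0, 0.0], cov, size=n_neurons)
    c_i, h_i = load[:, 0], load[:, 1]

    x_choice = rng.choice([-1, 1], size=n_trials)
    x_prev = rng.choice([-1, 1], size=n_trials)
    labels = pd.DataFrame({
        "choice": np.where(x_choice > 0, "right", "left"),
        "prev_stim_class": np.where(x_prev > 0, "high", "low"),
        "period": rng.choice(["stable", "switching"], size=n_trials),
        "correct": rng.choice([True, False], size=n_trials, p=[0.7, 0.3]),
    })
    dur_s = (window_ms[1] - window_ms[0]) / 1000.0
    log_mod = (choice_gain * np.outer(c_i, x_choice)
               + history_gain * np.outer(h_i, x_prev))
    if n_bins is None:
        lam = base_rate * dur_s * np.exp(log_mod)
        counts = rng.poisson(lam).astype(float)
        return SpikeCountTable(counts, labels, window_ms)
    bin_w = (window_ms[1] - window_ms[0]) / n_bins
    counts = np.empty((n_neurons, n_trials, n_bins))
    for b in range(n_bins):
        mod = log_mod if b >= onset_bin else 0.0
        lam = base_rate * (bin_w / 1000.0) * np.exp(mod)
        counts[:, :, b] = rng.poisson(lam * np.ones_like(log_mod))
    centers = window_ms[0] + bin_w * (np.arange(n_bins) + 0.5)
    return BinnedSpikeTable(counts, labels, centers, bin_w)


def write_spike_table(table: SpikeCountTable, counts_path, labels_path) -> None:
    """Write counts (neurons as rows, trials as columns) and trial labels
    as two CSVs."""
    pd.DataFrame(table.counts, index=table.neuron_ids).to_csv(counts_path)
    table.labels.to_csv(labels_path, index=False)


def read_spike_table(counts_path, labels_path, window_ms=(0.0, 700.0)) -> SpikeCountTable:
    counts = pd.read_csv(counts_path, index_col=0)
    labels = pd.read_csv(labels_path)
    if "correct" in labels.columns:
        labels["correct"] = labels["correct"].astype(bool)
    return SpikeCountTable(counts.to_numpy(dtype=float), labels, window_ms,
                           list(counts.index.astype(str)))
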