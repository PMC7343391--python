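"""Task data model: stimuli, blocks, periods, and trial-table I/O.

The task is a two-alternative forced-choice categorization of grating
spatial frequency (SF) with a boundary that alternates between blocks.
Seven log-spaced SFs are shown; the middle one (the *reversing stimulus*)
changes its correct side between low-boundary and high-boundary blocks,
while the stimulus statistics concentrate 90% of trials on the two
block-frequent SFs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "BehaviorDataset",
    "normalize_sf",
    "normalize_sf01",
    "correct_side",
    "label_periods",
    "read_trials",
    "write_trials",
    "validate_dataset",
    "DEFAULT_SF_VALUES",
    "RECORDING_SF_VALUES",
]

#: SF sets used in the task (cycles/degree). The first is the behavioral
#: cohort's set; the second was used for recording/inactivation cohorts.
DEFAULT_SF_VALUES = (0.03, 0.044, 0.065, 0.095, 0.139, 0.204, 0.3)
RECORDING_SF_VALUES = (0.06, 0.073, 0.09, 0.11, 0.134, 0.164, 0.2)

TRIAL_COLUMNS = [
    "session_id",
    "block_index",
    "block_type",
    "trial_in_block",
    "sf",
    "sf_norm",
    "sf_norm01",
    "is_reversing",
    "choice",
    "rewarded",
    "period",
]

REQUIRED_INPUT_COLUMNS = ["session_id", "block_index", "block_type", "sf", "choice", "rewarded"]


class TaskError(ValueError):
    """Raised for invalid stimuli, malformed trial tables, or inconsistent labels."""


@dataclass(frozen=True)
class TaskConfig:
    """Static description of the boundary-switching categorization task.

    Parameters
    ----------
    sf_values
        Ordered spatial frequencies (cycles/degree); 7 values, strictly
        increasing, approximately log-spaced. The 4th is the reversing SF.
    reversing_index
        Index of the reversing SF within ``sf_values`` (default 3, the middle
        of 7).
    frequent_prob
        Joint probability mass of the two block-frequent SFs (0.90).
    min_block_trials
        Minimum trials per block before a boundary switch is allowed (60).
    switch_window
        Number of most recent reversing-stimulus trials over which the switch
        criterion is evaluated (10).
    switch_criterion
        Fraction correct on the reversing stimulus required to trigger a
        switch (0.70 for the behavioral cohort, 0.80 for others).
    period_length
        Length of the stable (pre-switch) and switching (post-switch)
        analysis periods, in trials (15).
    max_block_trials
        Safety cap: a simulated block is force-switched at this length.
    """

    sf_values: tuple = DEFAULT_SF_VALUES
    reversing_index: int = 3
    frequent_prob: float = 0.90
    min_block_trials: int = 60
    switch_window: int = 10
    switch_criterion: float = 0.70
    period_length: int = 15
    max_block_trials: int = 500

    def __post_init__(self):
        sf = np.asarray(self.sf_values, dtype=float)
        if sf.ndim != 1 or len(sf) < 3:
            raise TaskError("sf_values must be a 1-D sequence of at least 3 SFs")
        if np.any(sf <= 0) or np.any(np.diff(sf) <= 0):
            raise TaskError("sf_values must be positive and strictly increasing")
        if not (0 <= self.reversing_index < len(sf)):
            raise TaskError("reversing_index out of range")
        # the reversing SF should be the geometric middle of a log-spaced set
        logsf = np.log(sf)
        mid = 0.5 * (logsf[0] + logsf[-1])
        span = logsf[-1] - logsf[0]
        if abs(logsf[self.reversing_index] - mid) > 0.05 * span:
            raise TaskError("reversing SF is not the geometric middle of the set")
        if not (0.0 < self.switch_criterion < 1.0):
            raise TaskError("switch_criterion must be in (0, 1)")
        if self.period_length > self.min_block_trials:
            raise TaskError("period_length must not exceed min_block_trials")
        if self.max_block_trials < self.min_block_trials:
            raise TaskError("max_block_trials must be >= min_block_trials")

    @property
    def reversing_sf(self) -> float:
        return float(self.sf_values[self.reversing_index])

    def frequent_sfs(self, block_type: str) -> tuple:
        """The two SFs shown on 90% of trials in a block of the given type."""
        if block_type == "low":
            return (float(self.sf_values[0]), self.reversing_sf)
        if block_type == "high":
            return (self.reversing_sf, float(self.sf_values[-1]))
        raise TaskError(f"unknown block_type {block_type!r}")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sf_values": list(map(float, self.sf_values)),
            "reversing_index": self.reversing_index,
            "frequent_prob": self.frequent_prob,
            "min_block_trials": self.min_block_trials,
            "switch_window": self.switch_window,
            "switch_criterion": self.switch_criterion,
            "period_length": self.period_length,
            "max_block_trials": self.max_block_trials,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "sf_values" in d:
            d["sf_values"] = tuple(d["sf_values"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "TaskConfig":
        """Load from a YAML or JSON file (decided by extension)."""
        text = open(path).read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


def normalize_sf(sf: float, config: TaskConfig) -> float:
    """Map an SF (cycles/degree) to the signed log-frequency scale in [-1, 1].

    Returns ``(log sf - log sf_rev) / (log sf_max - log sf_rev)``: 0 for the
    reversing stimulus, -1/+1 at the extremes, negative for lower SFs. For an
    exactly log-spaced 7-SF set this is ``(i - 3)/3`` for 0-based index ``i``.
    """
    i = _sf_index(sf, config)
    logsf = math.log(config.sf_values[i])
    logrev = math.log(config.reversing_sf)
    logmax = math.log(config.sf_values[-1])
    return (logsf - logrev) / (logmax - logrev)


def normalize_sf01(sf: float, config: TaskConfig) -> float:
    """Map an SF to [0, 1] (lowest SF -> 0, highest -> 1), log scale.

    This is the stimulus convention of the reinforcement-learning model.
    """
    i = _sf_index(sf, config)
    logsf = math.log(config.sf_values[i])
    logmin = math.log(config.sf_values[0])
    logmax = math.log(config.sf_values[-1])
    return (logsf - logmin) / (logmax - logmin)


def _sf_index(sf: float, config: TaskConfig) -> int:
    arr = np.asarray(config.sf_values, dtype=float)
    hits = np.nonzero(np.isclose(arr, float(sf), rtol=1e-6, atol=0.0))[0]
    if len(hits) != 1:
        raise TaskError(f"stimulus {sf!r} is not in the configured SF set {tuple(arr)}")
    return int(hits[0])


def correct_side(sf_norm: float, block_type: str) -> str:
    """Correct response port for a normalized stimulus in a given block type.

    In a low-boundary block the boundary sits below the reversing SF, so the
    reversing stimulus (``sf_norm == 0``) is "high" and rewarded on the
    right; in a high-boundary block it is "low" and rewarded on the left.
    """
    if block_type == "low":
        return "right" if sf_norm >= 0 else "left"
    if block_type == "high":
        return "left" if sf_norm <= 0 else "right"
    raise TaskError(f"unknown block_type {block_type!r}")


@dataclass
class BehaviorDataset:
    """Ordered trial-level behavioral data, grouped by session then block.

    ``trials`` is a DataFrame with one row per trial and columns
    ``session_id, block_index, block_type, trial_in_block, sf, sf_norm,
    sf_norm01, is_reversing, choice, rewarded, period`` (plus optional
    latent-trajectory columns for simulated data).
    """

    trials: pd.DataFrame
    config: TaskConfig = field(default_factory=TaskConfig)
    provenance: str = "observed"  # or "simulated"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_blocks(self) -> int:
        return len(self.trials.groupby(["session_id", "block_index"], sort=False))

    def blocks(self):
        """Iterate over ``((session_id, block_index), block_frame)`` in order."""
        return self.trials.groupby(["session_id", "block_index"], sort=False)

    def session_ids(self) -> list:
        return list(dict.fromkeys(self.trials["session_id"]))

    def subset(self, mask) -> "BehaviorDataset":
        return replace(self, trials=self.trials.loc[mask].reset_index(drop=True))


def _recompute_derived(df: pd.DataFrame, config: TaskConfig) -> pd.DataFrame:
    df = df.copy()
    df["sf"] = df["sf"].astype(float)
    norm, norm01 = [], []
    for row_i, x in enumerate(df["sf"]):
        try:
            norm.append(normalize_sf(x, config))
            norm01.append(normalize_sf01(x, config))
        except TaskError as e:
            raise TaskError(f"row {row_i}: {e}") from None
    df["sf_norm"] = norm
    df["sf_norm01"] = norm01
    df["is_reversing"] = np.isclose(df["sf_norm"], 0.0)
    df["rewarded"] = df["rewarded"].astype(int).astype(bool)
    if "trial_in_block" not in df.columns:
        df["trial_in_block"] = df.groupby(["session_id", "block_index"], sort=False).cumcount()
    return df


def validate_dataset(dataset: BehaviorDataset, strict_block_length: bool | None = None) -> None:
    """Check structural invariants; raise :class:`TaskError` on violation.

    ``strict_block_length`` enforces >= ``min_block_trials`` per completed
    block; it defaults to True except for period-restricted simulated data
    (which contains only the 2 x period_length analyzed trials per block).
    """
    df = dataset.trials
    cfg = dataset.config
    if strict_block_length is None:
        strict_block_length = not (
            dataset.provenance == "simulated" and df.attrs.get("sim_mode") == "period_reset"
        )
    for col in ["session_id", "block_index", "block_type", "sf", "choice", "rewarded"]:
        if col not in df.columns:
            raise TaskError(f"missing required column {col!r}")
    bad_bt = set(df["block_type"]) - {"low", "high"}
    if bad_bt:
        raise TaskError(f"unknown block_type values {sorted(bad_bt)}")
    bad_choice = set(df["choice"]) - {"left", "right"}
    if bad_choice:
        raise TaskError(f"unknown choice values {sorted(bad_choice)}")
    for row_i, (sfv,) in enumerate(zip(df["sf"])):
        try:
            _sf_index(sfv, cfg)
        except TaskError as e:
            raise TaskError(f"row {row_i}: {e}") from None
    # reward consistency with the block's category rule
    exp = [
        correct_side(sn, bt) == ch
        for sn, bt, ch in zip(df["sf_norm"], df["block_type"], df["choice"])
    ]
    mism = np.nonzero(np.asarray(exp) != df["rewarded"].to_numpy())[0]
    if len(mism):
        raise TaskError(
            f"rewarded flag inconsistent with the category rule at row {mism[0]} "
            f"({len(mism)} rows total)"
        )
    for sid, sess in df.groupby("session_id", sort=False):
        bt = [g["block_type"].iloc[0] for _, g in sess.groupby("block_index", sort=False)]
        if any(a == b for a, b in zip(bt, bt[1:])):
            raise TaskError(f"session {sid!r}: block_type does not alternate")
        lengths = sess.groupby("block_index", sort=False).size()
        # every block except the session's last must be complete
        if strict_block_length and len(lengths) > 1:
            short = lengths.iloc[:-1][lengths.iloc[:-1] < cfg.min_block_trials]
            if len(short):
                raise TaskError(
                    f"session {sid!r}: completed block {short.index[0]} has "
                    f"{short.iloc[0]} < {cfg.min_block_trials} trials"
                )
        for bi, g in sess.groupby("block_index", sort=False):
            tib = g["trial_in_block"].to_numpy()
            if not np.array_equal(tib, np.arange(len(tib))):
                raise TaskError(f"session {sid!r} block {bi}: trial_in_block not contiguous from 0")


def label_periods(dataset: BehaviorDataset, config: TaskConfig | None = None) -> BehaviorDataset:
    """Label each trial stable / switching / other.

    The last ``period_length`` trials of every block *followed by* a switch
    are stable; the first ``period_length`` trials of every block *preceded
    by* a switch are switching; everything else (the first block's opening
    trials, the final incomplete block's tail) is other. If a short block
    makes the two windows overlap, switching wins.
    """
    cfg = config or dataset.config
    df = dataset.trials.copy()
    period = np.full(len(df), "other", dtype=object)
    pos = 0
    for sid, sess in df.groupby("session_id", sort=False):
        blocks = list(sess.groupby("block_index", sort=False))
        for k, (bi, g) in enumerate(blocks):
            n = len(g)
            start = pos
            followed_by_switch = k < len(blocks) - 1
            preceded_by_switch = k > 0
            if followed_by_switch:
                period[start + max(0, n - cfg.period_length) : start + n] = "stable"
            if preceded_by_switch:  # applied second: switching wins on overlap
                period[start : start + min(cfg.period_length, n)] = "switching"
            pos += n
    df["period"] = period
    return replace(dataset, trials=df)


def read_trials(path, config: TaskConfig | None = None, validate: bool = True) -> BehaviorDataset:
    """Read a CSV trial table, recompute derived columns, and validate.

    Required columns: session_id, block_index, block_type, sf, choice,
    rewarded. Derived columns present in the file (sf_norm, period, ...) are
    recomputed and checked for consistency.
    """
    cfg = config or TaskConfig()
    raw = pd.read_csv(path)
    missing = [c for c in REQUIRED_INPUT_COLUMNS if c not in raw.columns]
    if missing:
        raise TaskError(f"{path}: missing required column(s) {missing}")
    had_sf_norm = "sf_norm" in raw.columns
    old_norm = raw["sf_norm"].to_numpy(dtype=float) if had_sf_norm else None
    df = _recompute_derived(raw, cfg)
    if had_sf_norm and not np.allclose(old_norm, df["sf_norm"].to_numpy(), atol=1e-6):
        raise TaskError(f"{path}: stored sf_norm disagrees with recomputed normalization")
    ds = BehaviorDataset(trials=df, config=cfg, provenance="observed")
    ds = label_periods(ds)
    if validate:
        validate_dataset(ds)
    return ds


def write_trials(dataset: BehaviorDataset, path) -> None:
    """Write the trial table as UTF-8 CSV (bit-exact round trip of all fields)."""
    df = dataset.trials.copy()
    df["rewarded"] = df["rewarded"].astype(int)
    df["is_reversing"] = df["is_reversing"].astype(int)
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False, encoding="utf-8")
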