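"""Behavioral metrics: psychometric curves with lapse rates, reversal
dynamics (trials to reverse choice), and history-conditioned choice bias.

The psychometric function is the 4-parameter logistic

    Psi(x) = lapse_low + (1 - lapse_low - lapse_high) / (1 + exp(-(x - threshold)/slope))

fitted by direct binomial maximum likelihood on per-SF right-choice counts
with x in log-SF units (the stimuli are log-spaced). Reversal dynamics fit
the saturating exponential f(n) = A (1 - exp(-n/tau)) + I to the
switch-aligned correct rate for the reversing stimulus; trials-to-reverse
is the analytic crossing of f with 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.special import expit

from .task import BehaviorDataset

__all__ = [
    "PsychometricFit",
    "ReversalFit",
    "psychometric_counts",
    "fit_psychometric",
    "reversal_curve",
    "fit_reversal",
    "trials_to_reverse",
    "right_choice_bias",
]


@dataclass
class PsychometricFit:
    """4-parameter psychometric fit. ``threshold`` (log-SF units) is the
    subjective category boundary; ``slope`` is the logistic scale;
    ``lapse_low``/``lapse_high`` are the lower/upper asymptote offsets."""

    lapse_low: float
    lapse_high: float
    threshold: float
    slope: float
    nll: float = float("nan")
    degenerate: bool = False  # all-0 or all-1 data: boundary at infinity

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.lapse_low + (1.0 - self.lapse_low - self.lapse_high) * expit(
            (x - self.threshold) / self.slope)


@dataclass
class ReversalFit:
    """Exponential reversal fit f(n) = A (1 - exp(-n/tau)) + I.

    ``1 - I`` is the pre-switch performance for the reversing stimulus;
    ``A`` the asymptotic gain; ``tau`` the time constant in (reversing)
    trials; ``n_reverse`` the fitted curve's 50%-correct crossing, or NaN
    with ``crossing_defined=False`` when the curve never crosses 0.5.
    """

    A: float
    tau: float
    I: float
    n_reverse: float = float("nan")
    crossing_defined: bool = True

    def predict(self, n):
        n = np.asarray(n, dtype=float)
        return self.A * (1.0 - np.exp(-n / self.tau)) + self.I


def psychometric_counts(dataset: BehaviorDataset, block_type: str | None = None,
                        exclude_after_switch: int = 30) -> pd.DataFrame:
    """Per-SF (x, n_right, n_total) counts for psychometric fitting.

    Trials within ``exclude_after_switch`` trials after a boundary switch
    (i.e. the opening trials of every block except each session's first)
    are excluded, so the counts reflect the adapted state.
    """
    df = dataset.trials
    keep = (df["block_index"] == df.groupby("session_id")["block_index"].transform("min")) | (
        df["trial_in_block"] >= exclude_after_switch)
    df = df[keep]
    if block_type is not None:
        df = df[df["block_type"] == block_type]
    g = df.assign(right=(df["choice"] == "right")).groupby("sf")["right"]
    sfs = np.array(sorted(g.groups))
    out = pd.DataFrame({
        "x": np.log(sfs),
        "sf": sfs,
        "n_right": g.sum().reindex(sfs).to_numpy(dtype=int),
        "n_total": g.size().reindex(sfs).to_numpy(dtype=int),
    })
    return out.reset_index(drop=True)


def _psy_nll(theta, x, n_right, n_total):
    gl, gh, a, b = theta
    p = gl + (1.0 - gl - gh) * expit((x - a) / b)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(n_right * np.log(p) + (n_total - n_right) * np.log(1.0 - p))


def fit_psychometric(counts: pd.DataFrame, max_lapse: float = 0.5) -> PsychometricFit:
    """Binomial ML fit of the 4-parameter psychometric function.

    ``counts`` needs columns x (log-SF), n_right, n_total with >= 4 distinct
    x values. Degenerate data (every response the same) is flagged instead
    of fitted.
    """
    x = counts["x"].to_numpy(dtype=float)
    nr = counts["n_right"].to_numpy(dtype=float)
    nt = counts["n_total"].to_numpy(dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("psychometric fit needs >= 4 distinct stimulus values")
    if np.any(nt <= 0):
        raise ValueError("n_total must be positive for every stimulus")
    if nr.sum() == 0 or (nt - nr).sum() == 0:
        return PsychometricFit(0.0, 0.0, math.inf if nr.sum() == 0 else -math.inf,
                               1.0, degenerate=True)
    span = x.max() - x.min()
    best = None
    for a0 in np.quantile(x, [0.3, 0.5, 0.7]):
        for b0 in (span / 8, span / 3):
            res = minimize(
                _psy_nll, np.array([0.02, 0.02, a0, b0]),
                args=(x, nr, nt), method="L-BFGS-B",
                bounds=[(0.0, max_lapse), (0.0, max_lapse),
                        (x.min() - 2 * span, x.max() + 2 * span),
                        (1e-4, 10 * span)],
            )
            if best is None or res.fun < best.fun:
                best = res
    gl, gh, a, b = best.x
    return PsychometricFit(float(gl), float(gh), float(a), float(b), nll=float(best.fun))


def reversal_curve(dataset: BehaviorDataset, max_trials: int = 60) -> pd.DataFrame:
    """Switch-aligned correct rate for the reversing stimulus.

    For every block preceded by a switch, reversing-stimulus trials are
    indexed by their post-switch ordinal n = 1, 2, ...; the correct rate is
    averaged across all switches (all blocks, all sessions). Returns columns
    n, correct_rate, n_obs for n <= ``max_trials``.
    """
    recs = []
    for sid, sess in dataset.trials.groupby("session_id", sort=False):
        blocks = list(sess.groupby("block_index", sort=False))
        for k, (_, g) in enumerate(blocks):
            if k == 0:
                continue  # no preceding switch
            rev = g[g["is_reversing"]]
            for ordinal, (_, row) in enumerate(rev.iterrows(), start=1):
                if ordinal > max_trials:
                    break
                recs.append({"n": ordinal, "correct": bool(row["rewarded"])})
    if not recs:
        raise ValueError("reversal_curve needs at least one boundary switch")
    df = pd.DataFrame(recs)
    g = df.groupby("n")["correct"]
    return pd.DataFrame({"n": g.mean().index, "correct_rate": g.mean().to_numpy(),
                         "n_obs": g.size().to_numpy()})


def fit_reversal(curve: pd.DataFrame) -> ReversalFit:
    """Least-squares fit of f(n) = A (1 - exp(-n/tau)) + I to the
    switch-aligned correct-rate curve, then the analytic 50% crossing."""
    n = curve["n"].to_numpy(dtype=float)
    y = curve["correct_rate"].to_numpy(dtype=float)

    def f(n, A, tau, I):
        return A * (1.0 - np.exp(-n / tau)) + I

    p0 = (max(y.max() - y.min(), 0.1), max(len(n) / 5.0, 1.0), max(y.min(), 0.0))
    popt, _ = curve_fit(f, n, y, p0=p0, bounds=([0.0, 1e-3, 0.0], [1.5, 1e3, 1.0]),
                        maxfev=20000)
    A, tau, I = map(float, popt)
    fit = ReversalFit(A=A, tau=tau, I=I)
    fit.n_reverse, fit.crossing_defined = _crossing(A, tau, I)
    return fit


def _crossing(A, tau, I):
    frac = (0.5 - I) / A if A > 0 else math.inf
    if not (0.0 < frac < 1.0):
        return float("nan"), False
    return -tau * math.log(1.0 - frac), True


def trials_to_reverse(fit: ReversalFit) -> float:
    """Trials needed for the fitted reversal curve to cross 50% correct:
    n* = -tau ln(1 - (0.5 - I)/A). NaN (flagged on the fit) if the curve
    never crosses 0.5."""
    n_rev, ok = _crossing(fit.A, fit.tau, fit.I)
    fit.n_reverse, fit.crossing_defined = n_rev, ok
    return n_rev


def right_choice_bias(dataset: BehaviorDataset, period: str = "switching"):
    """History-conditioned right-choice bias on reversing-stimulus trials.

    For reversing-stimulus trials in the given period whose previous trial
    (same session) showed a non-reversing stimulus, the bias after a low
    (high) previous stimulus is P(right | prev low (high)) minus the
    unconditional P(right) over reversing-stimulus trials of the same block
    type in the same period, matched per trial. Returns
    (bias_after_low, bias_after_high, difference); raises if either
    condition has no qualifying trials.
    """
    df = dataset.trials
    if "period" not in df.columns:
        raise ValueError("dataset must be period-labeled")
    prev_norm = df.groupby("session_id", sort=False)["sf_norm"].shift(1)
    in_period = df["period"] == period
    rev = df["is_reversing"] & in_period

    if rev.sum() == 0:
        raise ValueError(f"no reversing-stimulus trials in period={period}")
    # block-type-matched unconditional right rate over reversing trials in
    # the period; a baseline exists for every block type a conditional
    # trial can come from (the trial itself is part of the baseline)
    uncond = {
        bt: float((df.loc[rev & (df["block_type"] == bt), "choice"] == "right").mean())
        for bt in df.loc[rev, "block_type"].unique()
    }

    out = {}
    counts = {}
    for label, cond in (("low", prev_norm < 0), ("high", prev_norm > 0)):
        sel = rev & cond & prev_norm.notna()
        counts[label] = int(sel.sum())
        if counts[label] == 0:
            raise ValueError(
                f"no reversing-stimulus trials with previous {label} stimulus in "
                f"period={period} (counts: {counts})")
        right = (df.loc[sel, "choice"] == "right").to_numpy(dtype=float)
        base = df.loc[sel, "block_type"].map(uncond).to_numpy(dtype=float)
        out[label] = float(np.mean(right - base))
    return out["low"], out["high"], out["low"] - out["high"]
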