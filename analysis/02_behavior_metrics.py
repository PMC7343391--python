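#!/usr/bin/env python
"""Behavioral metrics of the simulated median agent.

Fits psychometric curves separately for low- and high-boundary blocks
(the subjective boundary shifts between block types for an adaptive
agent), fits the exponential reversal curve for the reversing stimulus and
reports trials-to-reverse, and computes the history-conditioned right-
choice bias in the stable and switching periods.
"""

import json
from pathlib import Path

import flexcat as fc
from flexcat.metrics import (
    fit_psychometric,
    fit_reversal,
    psychometric_counts,
    reversal_curve,
    right_choice_bias,
    trials_to_reverse,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

trials = OUT / "sim_m4_trials.csv"
if trials.exists():
    ds = fc.read_trials(trials)
else:
    ds = fc.simulate_agent("m4", fc.M4_MEDIANS, fc.SimConfig(n_blocks_per_type=50, seed=101))

report = {}
for bt in ("low", "high"):
    pf = fit_psychometric(psychometric_counts(ds, bt))
    report[f"psychometric_{bt}"] = {"threshold_logsf": pf.threshold, "slope": pf.slope,
                                    "lapse_low": pf.lapse_low, "lapse_high": pf.lapse_high}
    print(f"{bt}-boundary blocks: subjective boundary {pf.threshold:.3f} log-SF "
          f"(slope {pf.slope:.3f})")
shift = report["psychometric_high"]["threshold_logsf"] - report["psychometric_low"]["threshold_logsf"]
print(f"boundary shift between block types: {shift:.3f} log-SF units "
      f"({'adaptive' if shift > 0 else 'NOT adaptive'})")

rf = fit_reversal(reversal_curve(ds))
n_rev = trials_to_reverse(rf)
report["reversal"] = {"A": rf.A, "tau": rf.tau, "I": rf.I, "trials_to_reverse": n_rev}
print(f"reversal fit: A={rf.A:.3f}, tau={rf.tau:.2f}, I={rf.I:.3f} -> "
      f"{n_rev:.2f} reversing trials to cross 50%")

for period in ("stable", "switching"):
    lo, hi, diff = right_choice_bias(ds, period)
    report[f"bias_{period}"] = {"after_low": lo, "after_high": hi, "difference": diff}
    print(f"{period} period: right-choice bias after low {lo:+.3f}, "
          f"after high {hi:+.3f}, difference {diff:+.3f}")

(OUT / "behavior_metrics.json").write_text(json.dumps(report, indent=1))
print(f"wrote {OUT / 'behavior_metrics.json'}")
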