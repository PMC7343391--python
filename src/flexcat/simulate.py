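"""Generative engine: run any fitted choice model as an agent through the
boundary-switching task.

This is the synthetic-data source for every downstream stage (fitting,
recovery, behavioral metrics). In ``all_trials`` mode the task is closed
loop: stimuli are drawn from the block statistics, the agent's choice is
sampled from its model probability, reward follows the category rule, and
the block ends at the first trial where the block has at least
``min_block_trials`` trials AND the agent was correct on at least
``switch_criterion`` of the last ``switch_window`` reversing-stimulus
trials — exactly the rule the animals experienced. In ``period_reset``
mode only the analyzed stable/switching segments are generated, each from
its criterion-rate initial state, with no adaptive stopping rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import (
    DynamicDCParams,
    InitPolicy,
    RLParams,
    RLState,
    choice_prob_right,
    get_variant,
    rl_step,
    rl_update,
    stable_init_dc,
    switching_init_dc,
    update_dc,
)
from .task import BehaviorDataset, TaskConfig, correct_side, label_periods, normalize_sf, normalize_sf01

__all__ = ["SimConfig", "simulate_agent", "sample_stimulus", "stimulus_probs", "apply_inactivation"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol.

    n_blocks_per_type : blocks of each boundary type per run (study: 50).
    mode              : "all_trials" (closed-loop task) or "period_reset"
                        (stable/switching segments only).
    seed              : base seed; block-order, stimulus and choice draws
                        use separate child streams so the streams are
                        documented and portable.
    task              : the task configuration.
    inactivation_scale: optional {param: multiplier} applied to the agent's
                        parameters before simulation (emulates a
                        manipulation such as chemogenetic silencing that
                        scales the history weight).
    """

    n_blocks_per_type: int = 50
    mode: str = "all_trials"
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    inactivation_scale: dict | None = None

    def __post_init__(self):
        if self.n_blocks_per_type < 1:
            raise ValueError("n_blocks_per_type must be >= 1")
        if self.mode not in ("all_trials", "period_reset"):
            raise ValueError("mode must be 'all_trials' or 'period_reset'")
        if self.inactivation_scale:
            for v in self.inactivation_scale.values():
                if not np.isfinite(v):
                    raise ValueError("inactivation multipliers must be finite")


def stimulus_probs(block_type: str, config: TaskConfig) -> np.ndarray:
    """Per-SF presentation probabilities for a block type.

    The two block-frequent SFs split the frequent mass equally (0.45 each
    for the default 90%); the remaining SFs split the rest equally.
    """
    sf = np.asarray(config.sf_values, dtype=float)
    probs = np.full(len(sf), (1.0 - config.frequent_prob) / (len(sf) - 2))
    freq = config.frequent_sfs(block_type)
    for f in freq:
        i = int(np.argmin(np.abs(sf - f)))
        probs[i] = config.frequent_prob / 2.0
    return probs


def sample_stimulus(block_type: str, config: TaskConfig, rng: np.random.Generator) -> float:
    """Draw one SF from the block's presentation statistics."""
    probs = stimulus_probs(block_type, config)
    return float(rng.choice(np.asarray(config.sf_values, dtype=float), p=probs))


def apply_inactivation(variant, params, scale_map: dict):
    """Multiplicatively scale named free parameters; constraints re-checked.

    Raises if a key is not a free parameter of the variant or if the scaled
    vector violates a constraint (e.g. gamma1 < 0).
    """
    variant = get_variant(variant)
    if not scale_map:
        return params
    bad = [k for k in scale_map if k not in variant.free_names]
    if bad:
        raise ValueError(f"{bad} not free parameter(s) of variant {variant.id}")
    return replace(params, **{k: getattr(params, k) * m for k, m in scale_map.items()})


class _DCAgent:
    def __init__(self, params: DynamicDCParams, dc_init: float):
        self.params = params
        self.dc = dc_init

    def p_right(self, s: float, s01: float) -> float:
        return choice_prob_right(self.params.gamma1, s, self.dc)

    def observe(self, *, is_reversing, choice, rewarded, sf_norm):
        self.dc = update_dc(self.params, self.dc, is_reversing=is_reversing,
                            choice=choice, rewarded=rewarded, sf_norm=sf_norm)

    def latent(self) -> dict:
        return {"dc": self.dc}

    def reset(self, dc_init: float):
        self.dc = dc_init


class _RLAgent:
    def __init__(self, params: RLParams, v0: float):
        self.params = params
        self.v0 = v0
        self.state = RLState(v_left=v0, v_right=v0)

    def p_right(self, s: float, s01: float) -> float:
        self.state = rl_step(self.params, self.state, s01)
        return self.state.p_right

    def observe(self, *, is_reversing, choice, rewarded, sf_norm):
        self.state = rl_update(self.params, self.state, choice, rewarded)

    def latent(self) -> dict:
        st = self.state
        return {"v_left": st.v_left, "v_right": st.v_right, "p_model": st.p_right}

    def reset(self, dc_init: float):
        self.state = RLState(v_left=self.v0, v_right=self.v0)


def simulate_agent(variant, params, sim: SimConfig,
                   policy: InitPolicy | None = None) -> BehaviorDataset:
    """Simulate one session of the block-switching task with a model agent.

    Returns a labeled, validated :class:`BehaviorDataset` whose trial table
    carries the latent trajectory columns (``dc`` and ``p_right`` for the
    DC family; value traces for RL). ``dataset.trials.attrs`` records the
    simulation mode and the number of force-switched blocks.
    """
    variant = get_variant(variant)
    policy = policy or InitPolicy(mode=sim.mode)
    if policy.mode != sim.mode:
        raise ValueError("policy.mode must match sim.mode")
    params = variant.apply_mask(params)
    if sim.inactivation_scale:
        params = apply_inactivation(variant, params, sim.inactivation_scale)
    cfg = sim.task
    ss = np.random.SeedSequence(sim.seed)
    rng_block, rng_stim, rng_choice = (np.random.default_rng(c) for c in ss.spawn(3))

    first = "low" if rng_block.random() < 0.5 else "high"
    order = [first, "high" if first == "low" else "low"] * sim.n_blocks_per_type

    if variant.family == "rl":
        agent = _RLAgent(params, policy.rl_v0)
    else:
        agent = _DCAgent(params, policy.session_init)

    rows: list[dict] = []
    forced_switches = 0

    def run_trial(block_index, block_type, t_in_block, period=""):
        sf = sample_stimulus(block_type, cfg, rng_stim)
        s = normalize_sf(sf, cfg)
        s01 = normalize_sf01(sf, cfg)
        p = agent.p_right(s, s01)
        choice = "right" if rng_choice.random() < p else "left"
        correct = correct_side(s, block_type)
        rewarded = choice == correct
        rows.append({
            "session_id": "sim0",
            "block_index": block_index,
            "block_type": block_type,
            "trial_in_block": t_in_block,
            "sf": sf,
            "sf_norm": s,
            "sf_norm01": s01,
            "is_reversing": s == 0.0,
            "choice": choice,
            "rewarded": rewarded,
            "p_right": p,
            **agent.latent(),
        })
        agent.observe(is_reversing=(s == 0.0), choice=choice, rewarded=rewarded, sf_norm=s)
        return s == 0.0, rewarded

    if sim.mode == "all_trials":
        for bi, bt in enumerate(order):
            rev_correct: list[bool] = []
            t = 0
            while True:
                was_rev, rewarded = run_trial(bi, bt, t)
                if was_rev:
                    rev_correct.append(rewarded)
                t += 1
                if (t >= cfg.min_block_trials and len(rev_correct) >= cfg.switch_window
                        and np.mean(rev_correct[-cfg.switch_window:]) >= cfg.switch_criterion):
                    break
                if t >= cfg.max_block_trials:
                    forced_switches += 1
                    break
    else:  # period_reset: generate the analyzed segments directly
        for bi, bt in enumerate(order):
            for period in ("switching", "stable"):
                if variant.family == "rl":
                    agent.reset(0.0)
                else:
                    init = (switching_init_dc(bt, cfg.switch_criterion) if period == "switching"
                            else stable_init_dc(bt, cfg.switch_criterion))
                    agent.reset(init)
                base = 0 if period == "switching" else cfg.period_length
                for t in range(cfg.period_length):
                    run_trial(bi, bt, base + t, period)

    df = pd.DataFrame(rows)
    df.attrs["sim_mode"] = sim.mode
    df.attrs["forced_switches"] = forced_switches
    if forced_switches:
        warnings.warn(
            f"{forced_switches} block(s) hit max_block_trials={cfg.max_block_trials} "
            "without meeting the switch criterion and were force-switched"
        )
    ds = BehaviorDataset(trials=df, config=cfg, provenance="simulated", seed=sim.seed)
    ds = label_periods(ds)
    if sim.mode == "period_reset":
        # period labels follow construction, not block-edge inference
        per = np.where(ds.trials["trial_in_block"] < cfg.period_length, "switching", "stable")
        ds.trials["period"] = per
        ds.trials.attrs["sim_mode"] = sim.mode
        ds.trials.attrs["forced_switches"] = forced_switches
    return ds
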