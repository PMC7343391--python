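"""Trial-wise likelihood machinery for the dynamic decision-criterion model
family (variants m1-m7) and the stimulus-weighted reinforcement-learning
alternative.

The dynamic-DC model states that the animal compares the (weighted) current
stimulus against a latent decision criterion DC that moves trial by trial:

    p_right(t) = logistic(gamma1 * S(t) - DC(t))

After a reversing-stimulus trial the criterion moves by +/- alpha1 (rewarded)
or -/+ alpha2 (unrewarded) depending on the chosen side; after a
non-reversing trial it moves by gamma2 * S(t-1); in both cases it first
decays by the drift factor (1 - beta). The RL alternative instead learns
left/right action values updated by reward-prediction errors and weights
them by the stimulus through a softmax.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .task import BehaviorDataset, TaskConfig

__all__ = [
    "DynamicDCParams",
    "RLParams",
    "ModelVariant",
    "VARIANTS",
    "get_variant",
    "DCTrajectory",
    "RLState",
    "InitPolicy",
    "choice_prob_right",
    "update_dc",
    "dc_nll",
    "rl_step",
    "rl_update",
    "rl_nll",
    "stable_init_dc",
    "switching_init_dc",
    "prepare_arrays",
]

PARAM_NAMES = ("alpha1", "alpha2", "beta", "gamma1", "gamma2")


@dataclass(frozen=True)
class DynamicDCParams:
    """Parameter vector of the dynamic-DC model.

    alpha1 : criterion shift after a rewarded reversing-stimulus trial
             (positive = win-stay).
    alpha2 : criterion shift after an unrewarded reversing-stimulus trial
             (positive = lose-shift).
    beta   : drift of the criterion toward 0 (0 < beta < 1) or away from it
             (beta < 0); constrained beta <= 1.
    gamma1 : weight of the current stimulus, constrained >= 0.
    gamma2 : weight of the previous (non-reversing) stimulus.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    beta: float = 0.0
    gamma1: float = 1.0
    gamma2: float = 0.0

    def __post_init__(self):
        if self.gamma1 < 0:
            raise ValueError("gamma1 must be >= 0")
        if self.beta > 1:
            raise ValueError("beta must be <= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.beta, self.gamma1, self.gamma2])

    @classmethod
    def from_array(cls, x) -> "DynamicDCParams":
        return cls(*map(float, x))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}


@dataclass(frozen=True)
class RLParams:
    """Parameters of the stimulus-weighted RL model.

    alpha : learning rate, constrained to (0, 1).
    gamma : weight of the current stimulus in the expected values.
    """

    alpha: float = 0.5
    gamma: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.gamma])

    @classmethod
    def from_array(cls, x) -> "RLParams":
        return cls(float(x[0]), float(x[1]))

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "gamma": self.gamma}


@dataclass(frozen=True)
class ModelVariant:
    """A model identity plus the mask of parameters fixed to constants.

    Dynamic-DC variants: m1 (full), m2 (alpha1=0), m3 (alpha2=0),
    m4 (alpha1=alpha2=0), m5 (beta=0), m6 (gamma1=1), m7 (gamma2=0).
    ``rl`` is the 2-parameter RL model (no mask).
    """

    id: str
    fixed: dict = field(default_factory=dict)

    @property
    def family(self) -> str:
        return "rl" if self.id == "rl" else "dc"

    @property
    def param_names(self) -> tuple:
        return ("alpha", "gamma") if self.family == "rl" else PARAM_NAMES

    @property
    def free_names(self) -> tuple:
        return tuple(n for n in self.param_names if n not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def apply_mask(self, params):
        """Force fixed entries of a parameter object to their mask values."""
        if self.fixed:
            return replace(params, **self.fixed)
        return params

    def embed(self, free_values) -> np.ndarray:
        """Build the full parameter array from free values + fixed mask."""
        out = []
        it = iter(free_values)
        for n in self.param_names:
            out.append(self.fixed[n] if n in self.fixed else float(next(it)))
        return np.array(out)

    def make_params(self, free_values):
        full = self.embed(free_values)
        return RLParams.from_array(full) if self.family == "rl" else DynamicDCParams.from_array(full)

    def to_json(self, params=None) -> str:
        d = {"variant": self.id, "fixed": self.fixed}
        if params is not None:
            d["params"] = params.to_dict()
        return json.dumps(d, indent=1)

    @staticmethod
    def from_json(text: str):
        d = json.loads(text)
        v = get_variant(d["variant"])
        if "params" in d:
            cls = RLParams if v.family == "rl" else DynamicDCParams
            return v, cls(**d["params"])
        return v


#: all-mice median parameters of the full and reduced dynamic-DC models,
#: the canonical operating points for simulation and recovery experiments
M1_MEDIANS = DynamicDCParams(alpha1=-0.13, alpha2=0.13, beta=0.22, gamma1=3.64, gamma2=0.42)
M4_MEDIANS = DynamicDCParams(alpha1=0.0, alpha2=0.0, beta=0.21, gamma1=3.61, gamma2=0.36)

VARIANTS = {
    "m1": ModelVariant("m1", {}),
    "m2": ModelVariant("m2", {"alpha1": 0.0}),
    "m3": ModelVariant("m3", {"alpha2": 0.0}),
    "m4": ModelVariant("m4", {"alpha1": 0.0, "alpha2": 0.0}),
    "m5": ModelVariant("m5", {"beta": 0.0}),
    "m6": ModelVariant("m6", {"gamma1": 1.0}),
    "m7": ModelVariant("m7", {"gamma2": 0.0}),
    "rl": ModelVariant("rl", {}),
}


def get_variant(vid) -> ModelVariant:
    if isinstance(vid, ModelVariant):
        return vid
    try:
        return VARIANTS[vid]
    except KeyError:
        raise ValueError(f"unknown model variant {vid!r}; known: {sorted(VARIANTS)}") from None


@dataclass
class DCTrajectory:
    """Latent trace of a dynamic-DC run: criterion, decision variable,
    and right-choice probability per trial."""

    dc: np.ndarray
    z: np.ndarray
    p_right: np.ndarray

    def __len__(self):
        return len(self.dc)


@dataclass
class RLState:
    """One-trial RL state: left/right values, stimulus-weighted expected
    values and the softmax right-choice probability."""

    v_left: float = 1.0
    v_right: float = 1.0
    q_left: float = 0.0
    q_right: float = 0.0
    p_right: float = 0.5


# --- initialization policies -------------------------------------------


def stable_init_dc(block_type: str, criterion: float = 0.70) -> float:
    """Criterion value giving the switch-criterion correct rate on the
    reversing stimulus at the start of a stable segment.

    With S = 0, p_right = logistic(-dc); a 70% correct rate on the reversing
    stimulus means p_right = 0.70 in a low-boundary block (right is correct)
    and 0.30 in a high-boundary block, i.e. dc = -/+ ln(7/3).
    """
    v = math.log(criterion / (1.0 - criterion))
    return -v if block_type == "low" else v


def switching_init_dc(block_type: str, criterion: float = 0.70) -> float:
    """Criterion at the start of a switching segment: the complementary
    correct rate (1 - criterion), i.e. the sign-flipped stable value."""
    return -stable_init_dc(block_type, criterion)


@dataclass(frozen=True)
class InitPolicy:
    """Where the latent state (re)starts along the trial sequence.

    mode="all_trials": the criterion starts at 0 at each session start and
    is never reset afterwards (it carries across block boundaries).
    mode="period_reset": the trial sequence is restricted to stable /
    switching periods and the criterion restarts at every period boundary,
    at the value implied by the task's switch criterion (see
    :func:`stable_init_dc` / :func:`switching_init_dc`).

    ``rl_reset_at_segments`` controls whether RL values also reset to
    ``rl_v0`` at period starts in period_reset mode (default True).
    """

    mode: str = "all_trials"
    session_init: float = 0.0
    rl_v0: float = 1.0
    rl_reset_at_segments: bool = True

    def __post_init__(self):
        if self.mode not in ("all_trials", "period_reset"):
            raise ValueError("mode must be 'all_trials' or 'period_reset'")


# --- pure-Python step functions (reference arithmetic) ------------------


def choice_prob_right(gamma1: float, s: float, dc: float) -> float:
    """p(right) = logistic(gamma1 * s - dc)."""
    z = gamma1 * s - dc
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def update_dc(params: DynamicDCParams, dc_prev: float, *, is_reversing: bool,
              choice: str, rewarded: bool, sf_norm: float) -> float:
    """One criterion update given the PREVIOUS trial's events."""
    decayed = (1.0 - params.beta) * dc_prev
    if is_reversing:
        if rewarded:
            return decayed + (params.alpha1 if choice == "left" else -params.alpha1)
        return decayed + (-params.alpha2 if choice == "left" else params.alpha2)
    return decayed + params.gamma2 * sf_norm


def rl_step(params: RLParams, state: RLState, s01: float) -> RLState:
    """Compute Q values and the softmax choice probability for stimulus s01."""
    ql = params.gamma * (1.0 - s01) * state.v_left
    qr = params.gamma * s01 * state.v_right
    m = max(ql, qr)
    er = math.exp(qr - m)
    el = math.exp(ql - m)
    return RLState(state.v_left, state.v_right, ql, qr, er / (el + er))


def rl_update(params: RLParams, state: RLState, choice: str, rewarded: bool) -> RLState:
    """Update the chosen side's value with the reward-prediction error."""
    r = 1.0 if rewarded else 0.0
    if choice == "right":
        v_right = state.v_right + params.alpha * (r - state.q_right)
        return replace(state, v_right=v_right)
    v_left = state.v_left + params.alpha * (r - state.q_left)
    return replace(state, v_left=v_left)


# --- sequence preparation ----------------------------------------------


def prepare_arrays(dataset: BehaviorDataset, policy: InitPolicy,
                   config: TaskConfig | None = None) -> dict:
    """Flatten a dataset into the arrays the likelihood kernels consume.

    Returns a dict with per-trial arrays (s, s01, is_rev, choice_right,
    rewarded, seg_start, dc0) plus the row index of the retained trials. In
    period_reset mode only stable/switching trials are retained and segments
    restart at each (session, block, period) boundary with the
    criterion-rate initial value.
    """
    cfg = config or dataset.config
    df = dataset.trials
    if policy.mode == "period_reset":
        if "period" not in df.columns:
            raise ValueError("period labels required for period_reset policy")
        df = df[df["period"].isin(["stable", "switching"])]
        if len(df) == 0:
            raise ValueError("no stable/switching trials in dataset")
        seg_key = list(
            zip(df["session_id"], df["block_index"], df["period"])
        )
    else:
        seg_key = list(df["session_id"])
    if len(df) == 0:
        raise ValueError("empty trial sequence")
    n = len(df)
    seg_start = np.zeros(n, dtype=np.bool_)
    seg_start[0] = True
    for t in range(1, n):
        seg_start[t] = seg_key[t] != seg_key[t - 1]
    dc0 = np.zeros(n)
    if policy.mode == "period_reset":
        bt = df["block_type"].to_numpy()
        per = df["period"].to_numpy()
        for t in np.nonzero(seg_start)[0]:
            if per[t] == "stable":
                dc0[t] = stable_init_dc(bt[t], cfg.switch_criterion)
            else:
                dc0[t] = switching_init_dc(bt[t], cfg.switch_criterion)
    else:
        dc0[seg_start] = policy.session_init
    return {
        "index": df.index.to_numpy(),
        "s": df["sf_norm"].to_numpy(dtype=float),
        "s01": df["sf_norm01"].to_numpy(dtype=float),
        "is_rev": df["is_reversing"].to_numpy(dtype=np.bool_),
        "choice_right": (df["choice"].to_numpy() == "right"),
        "rewarded": df["rewarded"].to_numpy(dtype=np.bool_),
        "seg_start": seg_start,
        "dc0": dc0,
    }


def _full_mask(arrs, mask):
    if mask is None:
        return np.ones(len(arrs["s"]), dtype=np.bool_)
    return np.asarray(mask, dtype=np.bool_)


def dc_nll(variant, params: DynamicDCParams, dataset_or_arrays, policy: InitPolicy | None = None,
           mask=None, config: TaskConfig | None = None):
    """Average negative log-likelihood (nats/trial) of observed choices
    under the dynamic-DC model, plus the latent trajectory.

    ``dataset_or_arrays`` is a :class:`BehaviorDataset` (converted with
    ``policy``) or a dict from :func:`prepare_arrays`. ``mask`` restricts
    which trials enter the average (the recursion always runs over all
    retained trials); used for cross-validation scoring.
    """
    variant = get_variant(variant)
    if variant.family != "dc":
        raise ValueError("dc_nll requires a dynamic-DC variant")
    params = variant.apply_mask(params)
    arrs = (dataset_or_arrays if isinstance(dataset_or_arrays, dict)
            else prepare_arrays(dataset_or_arrays, policy or InitPolicy(), config))
    dc, p_right = _kernels.dc_recursion(
        arrs["s"], arrs["is_rev"], arrs["choice_right"], arrs["rewarded"],
        arrs["seg_start"], arrs["dc0"],
        params.alpha1, params.alpha2, params.beta, params.gamma1, params.gamma2,
    )
    nll = _kernels.nll_from_p(p_right, arrs["choice_right"], _full_mask(arrs, mask))
    return float(nll), DCTrajectory(dc=dc, z=params.gamma1 * arrs["s"] - dc, p_right=p_right)


def rl_nll(params: RLParams, dataset_or_arrays, policy: InitPolicy | None = None,
           mask=None, config: TaskConfig | None = None):
    """Average negative log-likelihood under the RL model, plus the value
    traces (per-trial v/q/p arrays as a dict)."""
    policy = policy or InitPolicy()
    arrs = (dataset_or_arrays if isinstance(dataset_or_arrays, dict)
            else prepare_arrays(dataset_or_arrays, policy, config))
    seg_start = arrs["seg_start"]
    if not policy.rl_reset_at_segments:
        seg_start = np.zeros_like(seg_start)
        seg_start[0] = True
    vl, vr, ql, qr, p_right = _kernels.rl_recursion(
        arrs["s01"], arrs["choice_right"], arrs["rewarded"], seg_start,
        params.alpha, params.gamma, policy.rl_v0,
    )
    nll = _kernels.nll_from_p(p_right, arrs["choice_right"], _full_mask(arrs, mask))
    traces = {"v_left": vl, "v_right": vr, "q_left": ql, "q_right": qr, "p_right": p_right}
    return float(nll), traces
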