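"""Likelihood machinery: logistic choice rule, criterion updates, RL value
updates, and the sequence NLLs against independent hand evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flexcat as fc
from flexcat.models import (
    InitPolicy,
    RLState,
    dc_nll,
    prepare_arrays,
    rl_nll,
    rl_step,
    rl_update,
    stable_init_dc,
    switching_init_dc,
)

LN2 = math.log(2.0)


class TestChoiceProbRight:
    def test_symmetric_point_is_half(self):
        assert fc.choice_prob_right(1.0, 0.0, 0.0) == 0.5

    def test_printed_median_gain_at_extremes(self):
        # logistic(3.64) and its complement, closed form
        p = fc.choice_prob_right(3.64, 1.0, 0.0)
        assert p == pytest.approx(1 / (1 + math.exp(-3.64)))
        assert p == pytest.approx(0.9744, abs=1e-4)
        assert fc.choice_prob_right(3.64, -1.0, 0.0) == pytest.approx(1 - p)

    @settings(deadline=None, derandomize=True)
    @given(g=st.floats(0, 20), s=st.floats(-1, 1), dc=st.floats(-30, 30))
    def test_logistic_antisymmetry(self, g, s, dc):
        assert fc.choice_prob_right(g, s, dc) + fc.choice_prob_right(g, -s, -dc) \
            == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(g=st.floats(0.1, 20), dc=st.floats(-5, 5))
    def test_monotone_in_stimulus(self, g, dc):
        ps = [fc.choice_prob_right(g, s, dc) for s in np.linspace(-1, 1, 7)]
        assert np.all(np.diff(ps) > 0)


class TestUpdateDC:
    def test_rewarded_left_reversing_with_printed_medians(self):
        p = fc.DynamicDCParams(alpha1=-0.13, alpha2=0.13, beta=0.22, gamma1=3.64, gamma2=0.42)
        out = fc.update_dc(p, 1.0, is_reversing=True, choice="left",
                           rewarded=True, sf_norm=0.0)
        assert out == pytest.approx(0.78 * 1.0 + (-0.13))

    def test_reward_and_side_signs(self):
        p = fc.DynamicDCParams(alpha1=0.3, alpha2=0.2, beta=0.0, gamma1=1.0, gamma2=0.0)
        kw = dict(is_reversing=True, sf_norm=0.0)
        assert fc.update_dc(p, 0.0, choice="left", rewarded=True, **kw) == 0.3
        assert fc.update_dc(p, 0.0, choice="right", rewarded=True, **kw) == -0.3
        assert fc.update_dc(p, 0.0, choice="left", rewarded=False, **kw) == -0.2
        assert fc.update_dc(p, 0.0, choice="right", rewarded=False, **kw) == 0.2

    def test_previous_stimulus_term(self):
        p = fc.DynamicDCParams(beta=0.0, gamma1=1.0, gamma2=0.42)
        out = fc.update_dc(p, 0.0, is_reversing=False, choice="left",
                           rewarded=True, sf_norm=-1.0)
        assert out == pytest.approx(-0.42)

    def test_m4_reversing_update_is_pure_drift(self):
        p = fc.VARIANTS["m4"].apply_mask(
            fc.DynamicDCParams(alpha1=0.5, alpha2=0.5, beta=0.3, gamma1=2.0, gamma2=0.4))
        for choice in ("left", "right"):
            for rewarded in (True, False):
                assert fc.update_dc(p, 1.0, is_reversing=True, choice=choice,
                                    rewarded=rewarded, sf_norm=0.0) == pytest.approx(0.7)

    def test_drift_geometry_over_100_steps(self):
        # with no history input, dc decays geometrically for beta in (0,1)
        # and grows for beta < 0
        for beta, growing in ((0.2, False), (-0.1, True)):
            p = fc.DynamicDCParams(beta=beta, gamma1=1.0, gamma2=0.0)
            dc = 1.0
            trace = []
            for _ in range(100):
                dc = fc.update_dc(p, dc, is_reversing=False, choice="left",
                                  rewarded=True, sf_norm=0.5 * 0)  # S=0 input
                trace.append(dc)
            assert trace[-1] == pytest.approx((1 - beta) ** 100)
            ratios = np.diff(np.log(np.abs(trace)))
            assert np.allclose(ratios, math.log(abs(1 - beta)))
            assert (abs(trace[-1]) > 1.0) == growing


def _dataset_from_rows(rows, cfg):
    df = pd.DataFrame(rows)
    df["sf_norm01"] = (df["sf_norm"] + 1) / 2
    df["is_reversing"] = df["sf_norm"] == 0.0
    df["trial_in_block"] = range(len(df))
    return fc.BehaviorDataset(trials=df, config=cfg)


def _hand_rows(cfg):
    """5 hand-constructed trials in one low-boundary block."""
    spec = [  # (sf_norm, choice)
        (0.0, "right"), (-1.0, "left"), (0.0, "left"), (1 / 3, "right"), (0.0, "right"),
    ]
    sfs = {0.0: 0.095, -1.0: 0.03, 1 / 3: 0.139}
    return [dict(session_id="s", block_index=0, block_type="low", sf=sfs[s],
                 sf_norm=s, choice=c, rewarded=fc.correct_side(s, "low") == c)
            for s, c in spec]


class TestDCNLL:
    def test_uninformative_model_gives_ln2(self, m4_small):
        p = fc.DynamicDCParams(alpha1=0, alpha2=0, beta=0, gamma1=0, gamma2=0)
        nll, _ = dc_nll("m1", p, m4_small, InitPolicy())
        assert nll == pytest.approx(LN2, abs=1e-12)

    def test_five_trial_brute_force_oracle(self, cfg):
        """Sequential hand evaluation of the 5-step recursion."""
        ds = _dataset_from_rows(_hand_rows(cfg), cfg)
        p = fc.DynamicDCParams(alpha1=-0.13, alpha2=0.13, beta=0.22, gamma1=3.64, gamma2=0.42)
        # hand recursion, independent of the kernel implementation
        dc = 0.0
        logps = []
        prev = None
        for _, row in ds.trials.iterrows():
            if prev is not None:
                if prev["is_reversing"]:
                    if prev["rewarded"]:
                        step = -p.alpha1 if prev["choice"] == "right" else p.alpha1
                    else:
                        step = p.alpha2 if prev["choice"] == "right" else -p.alpha2
                else:
                    step = p.gamma2 * prev["sf_norm"]
                dc = (1 - p.beta) * dc + step
            pr = 1 / (1 + math.exp(-(p.gamma1 * row["sf_norm"] - dc)))
            logps.append(math.log(pr if row["choice"] == "right" else 1 - pr))
            prev = row
        expect = -np.mean(logps)
        nll, traj = dc_nll("m1", p, ds, InitPolicy())
        assert nll == pytest.approx(expect, abs=1e-12)
        assert len(traj) == 5
        assert traj.p_right == pytest.approx(1 / (1 + np.exp(-traj.z)))

    def test_deterministic_choices_saturate(self, cfg):
        # choices generated from the model at huge gain are near-deterministic
        p = fc.DynamicDCParams(gamma1=50.0)
        ds = fc.simulate_agent("m7", p, fc.SimConfig(n_blocks_per_type=2, seed=3, task=cfg))
        nonrev = ds.subset(~ds.trials["is_reversing"])
        nonrev.trials["block_index"] = 0
        nonrev.trials["trial_in_block"] = range(len(nonrev.trials))
        nll, _ = dc_nll("m7", p, nonrev, InitPolicy())
        assert nll < 0.01

    def test_segment_decomposition_consistency(self, m4_small):
        """NLL over the dataset equals the trial-count-weighted average of
        per-session NLLs under the same policy."""
        ds = m4_small
        half = len(ds.trials) // 2
        # split into two pseudo-sessions at a block boundary
        blocks = ds.trials.groupby("block_index").size().cumsum()
        cut_block = int((blocks <= half).sum())
        t = ds.trials.copy()
        t.loc[t.block_index >= cut_block, "session_id"] = "s1"
        ds2 = fc.BehaviorDataset(trials=t, config=ds.config)
        p = fc.M4_MEDIANS
        whole, _ = dc_nll("m4", p, ds2, InitPolicy())
        parts = []
        for sid, g in t.groupby("session_id"):
            sub = fc.BehaviorDataset(trials=g.reset_index(drop=True), config=ds.config)
            n, _ = dc_nll("m4", p, sub, InitPolicy())
            parts.append((n, len(g)))
        weighted = sum(n * w for n, w in parts) / sum(w for _, w in parts)
        assert whole == pytest.approx(weighted, abs=1e-12)

    def test_empty_sequence_rejected(self, cfg):
        ds = fc.BehaviorDataset(trials=pd.DataFrame(columns=["session_id", "sf_norm"]),
                                config=cfg)
        with pytest.raises(ValueError):
            dc_nll("m1", fc.M1_MEDIANS, ds, InitPolicy())


class TestInitPolicy:
    def test_stable_init_matches_criterion_rate(self):
        # logistic(-dc) must equal the 70% criterion on the reversing stimulus
        dc_low = stable_init_dc("low", 0.70)
        assert dc_low == pytest.approx(-math.log(7 / 3))
        assert fc.choice_prob_right(3.6, 0.0, dc_low) == pytest.approx(0.70)
        assert stable_init_dc("high", 0.70) == pytest.approx(math.log(7 / 3))

    def test_switching_init_is_complementary(self):
        assert switching_init_dc("low", 0.70) == pytest.approx(math.log(7 / 3))
        assert fc.choice_prob_right(3.6, 0.0, switching_init_dc("low", 0.70)) \
            == pytest.approx(0.30)

    def test_80_percent_criterion(self):
        assert stable_init_dc("low", 0.80) == pytest.approx(-math.log(4))

    def test_period_reset_arrays_start_at_criterion_values(self):
        ds = fc.simulate_agent("m4", fc.M4_MEDIANS,
                               fc.SimConfig(n_blocks_per_type=3, seed=5, mode="period_reset"))
        arrs = prepare_arrays(ds, InitPolicy(mode="period_reset"))
        starts = np.nonzero(arrs["seg_start"])[0]
        assert len(starts) == 12  # 6 blocks x 2 periods
        df = ds.trials.iloc[arrs["index"]]
        for t in starts:
            bt = df.iloc[t]["block_type"]
            per = df.iloc[t]["period"]
            expect = (stable_init_dc(bt) if per == "stable" else switching_init_dc(bt))
            assert arrs["dc0"][t] == pytest.approx(expect)
            # the simulator stored the same latent start
            assert df.iloc[t]["dc"] == pytest.approx(expect)


class TestRL:
    def test_symmetric_q_gives_half(self):
        st_ = rl_step(fc.RLParams(alpha=0.2, gamma=2.0), RLState(1.0, 1.0), 0.5)
        assert st_.p_right == 0.5
        assert st_.q_left == st_.q_right == pytest.approx(1.0)

    def test_rewarded_update_arithmetic(self):
        st_ = RLState(v_left=1.0, v_right=1.0, q_left=0.0, q_right=0.4)
        out = rl_update(fc.RLParams(alpha=0.2, gamma=1.0), st_, "right", True)
        assert out.v_right == pytest.approx(1 + 0.2 * (1 - 0.4))
        assert out.v_left == 1.0

    def test_unrewarded_update_arithmetic(self):
        st_ = RLState(v_left=1.0, v_right=1.0, q_left=0.4, q_right=0.0)
        out = rl_update(fc.RLParams(alpha=0.2, gamma=1.0), st_, "left", False)
        assert out.v_left == pytest.approx(1 + 0.2 * (0 - 0.4))

    def test_zero_stimulus_weight_gives_ln2(self, m4_small):
        nll, _ = rl_nll(fc.RLParams(alpha=0.5, gamma=0.0), m4_small, InitPolicy())
        assert nll == pytest.approx(LN2, abs=1e-12)

    def test_five_trial_hand_oracle(self, cfg):
        ds = _dataset_from_rows(_hand_rows(cfg), cfg)
        params = fc.RLParams(alpha=0.3, gamma=2.0)
        policy = InitPolicy()
        # independent sequential evaluation with the pure step functions
        state = RLState(v_left=policy.rl_v0, v_right=policy.rl_v0)
        logps = []
        for _, row in ds.trials.iterrows():
            s01 = row["sf_norm01"]
            state = rl_step(params, state, s01)
            pr = state.p_right
            logps.append(math.log(pr if row["choice"] == "right" else 1 - pr))
            state = rl_update(params, state, row["choice"], row["rewarded"])
        expect = -np.mean(logps)
        nll, traces = rl_nll(params, ds, policy)
        assert nll == pytest.approx(expect, abs=1e-12)
        assert traces["p_right"][0] == pytest.approx(
            1 / (1 + math.exp(-(2.0 * 0.5 - 2.0 * 0.5))))

    def test_softmax_identity_on_traces(self, m4_small):
        nll, tr = rl_nll(fc.RLParams(alpha=0.3, gamma=2.0), m4_small, InitPolicy())
        expect = np.exp(tr["q_right"]) / (np.exp(tr["q_left"]) + np.exp(tr["q_right"]))
        assert tr["p_right"] == pytest.approx(expect)


class TestVariants:
    def test_free_parameter_counts(self):
        expect = {"m1": 5, "m2": 4, "m3": 4, "m4": 3, "m5": 4, "m6": 4, "m7": 4, "rl": 2}
        for vid, n in expect.items():
            assert fc.VARIANTS[vid].n_free == n

    def test_mask_forces_fixed_values(self):
        p = fc.VARIANTS["m4"].apply_mask(
            fc.DynamicDCParams(alpha1=0.7, alpha2=-0.7, beta=0.2, gamma1=3.0, gamma2=0.1))
        assert p.alpha1 == 0.0 and p.alpha2 == 0.0
        assert p.beta == 0.2

    def test_constraint_violations_rejected(self):
        with pytest.raises(ValueError):
            fc.DynamicDCParams(gamma1=-0.1)
        with pytest.raises(ValueError):
            fc.DynamicDCParams(beta=1.2)
        with pytest.raises(ValueError):
            fc.RLParams(alpha=0.0)

    def test_json_round_trip(self):
        v = fc.VARIANTS["m4"]
        text = v.to_json(fc.M4_MEDIANS)
        v2, p2 = fc.ModelVariant.from_json(text)
        assert v2.id == "m4" and p2 == fc.M4_MEDIANS
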