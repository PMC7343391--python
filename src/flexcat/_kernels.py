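"""JIT-compiled per-trial likelihood recursions.

The sequential latent-state recursions (decision criterion, RL values) are
the hot path of constrained ML fitting: every objective evaluation walks the
full trial sequence. They are compiled with numba; the pure-Python step
functions in :mod:`flexcat.models` define the same arithmetic and are the
reference the tests compare against.
"""

import numpy as np
from numba import njit

P_CLIP = 1e-12  # probability floor keeping log-likelihoods finite


@njit(cache=True)
def dc_recursion(s, is_rev, choice_right, rewarded, seg_start, dc0,
                 a1, a2, beta, g1, g2):
    """Run the decision-criterion recursion; return (dc, p_right) per trial.

    ``seg_start[t]`` flags trials where the criterion is (re)initialized to
    ``dc0[t]``; elsewhere DC(t) = (1-beta) DC(t-1) + update(trial t-1).
    """
    n = s.shape[0]
    dc = np.empty(n)
    p_right = np.empty(n)
    d = 0.0
    for t in range(n):
        if seg_start[t]:
            d = dc0[t]
        else:
            if is_rev[t - 1]:
                if rewarded[t - 1]:
                    upd = -a1 if choice_right[t - 1] else a1
                else:
                    upd = a2 if choice_right[t - 1] else -a2
            else:
                upd = g2 * s[t - 1]
            d = (1.0 - beta) * d + upd
        dc[t] = d
        z = g1 * s[t] - d
        p_right[t] = 1.0 / (1.0 + np.exp(-z))
    return dc, p_right


@njit(cache=True)
def nll_from_p(p_right, choice_right, mask):
    """Average negative log-likelihood (nats/trial) over masked trials."""
    ll = 0.0
    cnt = 0
    for t in range(p_right.shape[0]):
        if mask[t]:
            p = p_right[t] if choice_right[t] else 1.0 - p_right[t]
            if p < P_CLIP:
                p = P_CLIP
            elif p > 1.0 - P_CLIP:
                p = 1.0 - P_CLIP
            ll += np.log(p)
            cnt += 1
    return -ll / cnt


@njit(cache=True)
def rl_recursion(s01, choice_right, rewarded, seg_start, alpha, gamma, v0):
    """Run the stimulus-weighted RL recursion.

    Returns per-trial (v_left, v_right, q_left, q_right, p_right). Values
    reset to ``v0`` at segment starts; after the choice of trial t, the
    chosen side's value is updated with alpha * (reward - Q_chosen(t)).
    """
    n = s01.shape[0]
    vl_tr = np.empty(n)
    vr_tr = np.empty(n)
    ql_tr = np.empty(n)
    qr_tr = np.empty(n)
    p_right = np.empty(n)
    vl = v0
    vr = v0
    for t in range(n):
        if seg_start[t]:
            vl = v0
            vr = v0
        ql = gamma * (1.0 - s01[t]) * vl
        qr = gamma * s01[t] * vr
        # softmax over the two Q values
        m = ql if ql > qr else qr
        el = np.exp(ql - m)
        er = np.exp(qr - m)
        p = er / (el + er)
        vl_tr[t] = vl
        vr_tr[t] = vr
        ql_tr[t] = ql
        qr_tr[t] = qr
        p_right[t] = p
        r = 1.0 if rewarded[t] else 0.0
        if choice_right[t]:
            vr = vr + alpha * (r - qr)
        else:
            vl = vl + alpha * (r - ql)
    return vl_tr, vr_tr, ql_tr, qr_tr, p_right
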