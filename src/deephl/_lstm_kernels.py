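"""Numba-compiled LSTM forward/backward kernels.

The time recurrence cannot be vectorized across steps, so the per-step gate
arithmetic is fused into compiled loops.  Gate order in the fused weight
matrices is input, forget, cell, output; initial hidden/cell states are zero.
Output buffers are allocated by the caller (which also fixes the dtype; numba
specializes per dtype).  The backward pass is the standard BPTT recursion;
both kernels are checked against finite differences in the test suite.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def lstm_forward(xW, Wh, i_s, f_s, g_s, o_s, c_s, tc_s, h_s):
    """xW: (B, T, 4H) input projections + bias; Wh: (H, 4H).

    Fills the (B, T, H) gate/state caches needed for backward and the hidden
    sequence h_s.
    """
    B, T, H4 = xW.shape
    H = H4 // 4
    h = np.zeros((B, H), xW.dtype)
    c = np.zeros((B, H), xW.dtype)
    for t in range(T):
        z = xW[:, t] + h @ Wh
        for bb in range(B):
            for j in range(H):
                ii = 1.0 / (1.0 + math.exp(-z[bb, j]))
                ff = 1.0 / (1.0 + math.exp(-z[bb, H + j]))
                gg = math.tanh(z[bb, 2 * H + j])
                oo = 1.0 / (1.0 + math.exp(-z[bb, 3 * H + j]))
                cc = ff * c[bb, j] + ii * gg
                tc = math.tanh(cc)
                i_s[bb, t, j] = ii
                f_s[bb, t, j] = ff
                g_s[bb, t, j] = gg
                o_s[bb, t, j] = oo
                c_s[bb, t, j] = cc
                tc_s[bb, t, j] = tc
                h_s[bb, t, j] = oo * tc
                c[bb, j] = cc
                h[bb, j] = oo * tc
    return h_s


@njit(cache=True)
def lstm_forward_nograd(xW, Wh, h_s):
    """Hidden sequence only; no caches (for evaluation-mode passes)."""
    B, T, H4 = xW.shape
    H = H4 // 4
    h = np.zeros((B, H), xW.dtype)
    c = np.zeros((B, H), xW.dtype)
    for t in range(T):
        z = xW[:, t] + h @ Wh
        for bb in range(B):
            for j in range(H):
                ii = 1.0 / (1.0 + math.exp(-z[bb, j]))
                ff = 1.0 / (1.0 + math.exp(-z[bb, H + j]))
                gg = math.tanh(z[bb, 2 * H + j])
                oo = 1.0 / (1.0 + math.exp(-z[bb, 3 * H + j]))
                cc = ff * c[bb, j] + ii * gg
                c[bb, j] = cc
                h[bb, j] = oo * math.tanh(cc)
                h_s[bb, t, j] = h[bb, j]
    return h_s


@njit(cache=True)
def lstm_backward(g, i_s, f_s, g_s, o_s, c_s, tc_s, Wh, dZ):
    """g: (B, T, H) gradient w.r.t. the hidden sequence.

    Fills dZ (B, T, 4H), the gradient w.r.t. the pre-activation gates;
    weight/input gradients follow from dZ by plain matrix products.
    """
    B, T, H = g.shape
    WhT = Wh.T.copy()
    dh_next = np.zeros((B, H), g.dtype)
    dc_next = np.zeros((B, H), g.dtype)
    for t in range(T - 1, -1, -1):
        for bb in range(B):
            for j in range(H):
                ii = i_s[bb, t, j]
                ff = f_s[bb, t, j]
                gg = g_s[bb, t, j]
                oo = o_s[bb, t, j]
                tc = tc_s[bb, t, j]
                c_prev = c_s[bb, t - 1, j] if t > 0 else 0.0
                dh = g[bb, t, j] + dh_next[bb, j]
                do = dh * tc
                dc = dh * oo * (1.0 - tc * tc) + dc_next[bb, j]
                dZ[bb, t, j] = dc * gg * ii * (1.0 - ii)
                dZ[bb, t, H + j] = dc * c_prev * ff * (1.0 - ff)
                dZ[bb, t, 2 * H + j] = dc * ii * (1.0 - gg * gg)
                dZ[bb, t, 3 * H + j] = do * oo * (1.0 - oo)
                dc_next[bb, j] = dc * ff
        dh_next = dZ[:, t] @ WhT
    return dZ
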