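"""JIT-compiled trial loops for the learning models.

Model fitting evaluates the full trial-by-trial recursion thousands of times
per participant, so the per-run loops live here as numba kernels.  The
readable single-step reference semantics are in :mod:`traitlearn.models`
(``predict``/``update``); both paths are asserted equal in the test suite.

All kernels take runs in packed form: ``orders`` is (R, T) item indices,
``feedbacks`` is (R, N) item-indexed feedback per profile.  State is
re-initialized at the start of every run (models never share learning across
profiles) and is never clipped to the rating scale.  Reference-point models
blend at prediction time: the expressed prediction is
``gamma * RP(item) + (1 - gamma) * state``, the prediction error is taken
from that expressed prediction, and the stored state keeps the pure
delta-rule update.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def series_coarse(orders, feedbacks, factor_idx, n_factors, rp,
                  a_pos, a_neg, gamma, start, use_rp):
    """Predictions of the coarse-granularity models (one value per factor)."""
    R, T = orders.shape
    preds = np.empty((R, T))
    for r in range(R):
        state = np.full(n_factors, start)
        for t in range(T):
            i = orders[r, t]
            f = factor_idx[i]
            if use_rp:
                p = gamma * rp[i] + (1.0 - gamma) * state[f]
            else:
                p = state[f]
            preds[r, t] = p
            pe = feedbacks[r, i] - p
            a = a_neg if pe < 0.0 else a_pos
            state[f] = state[f] + a * pe
    return preds


@njit(cache=True)
def series_fine(orders, feedbacks, sim, rp, a_pos, a_neg, gamma, start, use_rp):
    """Predictions of the fine-granularity models (one value per item).

    Every trial updates all items in proportion to their signed correlation
    with the current item.
    """
    R, T = orders.shape
    n = sim.shape[0]
    preds = np.empty((R, T))
    for r in range(R):
        state = np.full(n, start)
        for t in range(T):
            i = orders[r, t]
            if use_rp:
                p = gamma * rp[i] + (1.0 - gamma) * state[i]
            else:
                p = state[i]
            preds[r, t] = p
            pe = feedbacks[r, i] - p
            a = a_neg if pe < 0.0 else a_pos
            upd = a * pe
            for j in range(n):
                state[j] = state[j] + upd * sim[j, i]
    return preds
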