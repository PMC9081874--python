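"""Numba-compiled inner loop for Euler-Maruyama network integration.

The kernel integrates one chunk of steps with pre-drawn Gaussian increments
so that random-number consumption (and hence seed reproducibility) is owned
by numpy's Generator outside the compiled code.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def em_chunk(E, I, A, G,
             tau_e, tau_i, a_e, a_i, w_ee, w_ei, w_ie, w_ii, B_e, B_i, h,
             dt, sqrt_dt_s, noise,
             out_E, out_I, store_every, step_offset):
    """Advance the network state through ``noise.shape[0]`` steps in place.

    Parameters are per-region 1-d arrays; ``noise`` is (steps, 2, N) with
    standard-normal entries (ignored when ``sqrt_dt_s`` is 0).  Stored
    samples go to ``out_E/out_I`` every ``store_every`` global steps.

    Returns (n_clipped, blow_step, blow_region); blow_step is -1 unless the
    pre-clip state left [-10, 10], which aborts integration.
    """
    n_steps = noise.shape[0]
    n = E.shape[0]
    n_clipped = 0
    for k in range(n_steps):
        # external drive J_e = G * A @ E
        for a in range(n):
            j = 0.0
            for b in range(n):
                j += A[a, b] * E[b]
            j *= G
            v_e = a_e[a] * w_ee[a] * E[a] - w_ei[a] * I[a] - B_e[a] + j
            v_i = a_i[a] * w_ie[a] * E[a] - w_ii[a] * I[a] - B_i[a]
            s_e = h[a] / (1.0 + np.exp(-v_e))
            s_i = h[a] / (1.0 + np.exp(-v_i))
            dE = (-E[a] + (1.0 - E[a]) * s_e) / tau_e[a]
            dI = (-I[a] + (1.0 - I[a]) * s_i) / tau_i[a]
            # write into the noise buffer so the update is synchronous
            noise[k, 0, a] = E[a] + dE * dt + sqrt_dt_s * noise[k, 0, a]
            noise[k, 1, a] = I[a] + dI * dt + sqrt_dt_s * noise[k, 1, a]
        for a in range(n):
            e_new = noise[k, 0, a]
            i_new = noise[k, 1, a]
            if abs(e_new) > 10.0 or abs(i_new) > 10.0:
                return n_clipped, step_offset + k, a
            if e_new < 0.0:
                e_new = 0.0
                n_clipped += 1
            elif e_new > 1.0:
                e_new = 1.0
                n_clipped += 1
            if i_new < 0.0:
                i_new = 0.0
                n_clipped += 1
            elif i_new > 1.0:
                i_new = 1.0
                n_clipped += 1
            E[a] = e_new
            I[a] = i_new
        gstep = step_offset + k + 1
        if gstep % store_every == 0:
            idx = gstep // store_every - 1
            for a in range(n):
                out_E[idx, a] = E[a]
                out_I[idx, a] = I[a]
    return n_clipped, -1, -1
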