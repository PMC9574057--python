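"""Numba inner loop of the time-driven simulation.

The loop advances all neurons on a fixed grid (default dt = 0.05 ms) with
the exact propagator of the linear sub-threshold dynamics, while the
plasticity state of each excitatory-to-excitatory synapse is advanced
event-wise in closed form only when its presynaptic neuron fires.  Spike
deliveries are queued in a circular buffer indexed by arrival step.

Order of operations within one step (covering (t, t+dt]):
  1. on 1 ms boundaries, redraw the piecewise-constant external currents;
  2. add the deliveries due this step to the synaptic currents;
  3. advance (V, I_exc, I_inh) with the propagator (V clamped while
     refractory);
  4. threshold check at the step boundary: reset, schedule deliveries at
     t + delay with the STP-modulated efficacy computed at emission time.

Everything is scalar arithmetic on flat arrays so numba compiles it to a
single tight loop; the RNG is numba's global NumPy-compatible generator,
seeded once at entry, which makes runs bit-for-bit reproducible for a given
(configuration, seed) pair.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_SPIKE_OVERFLOW = 1
STATUS_NONFINITE = 2


@njit(cache=True)
def run_kernel(
    n_steps,
    dt,
    steps_per_ms,
    n_exc,
    # per-neuron propagator coefficients
    pV, pVe, pVi, pVx, dec_e, dec_i,
    V_th, V_reset, ref_steps,
    V0,
    # connectivity (CSR by source neuron)
    indptr, conn_target, conn_delay_steps, conn_jump, conn_plastic,
    # STP state and constants
    u, x, t_last, U, tau_f, tau_d, variant_post,
    # compiled protocol: segment bounds in ms and per-neuron (mu, sigma)
    seg_bounds_ms, seg_mu, seg_sigma,
    seed,
    # spike record (preallocated)
    spikes_step, spikes_id,
    # STP trace sampling: stride in steps (0 = off), connection indices per
    # traced population (CSR), outputs (n_samples, n_traced)
    trace_stride, trace_indptr, trace_conn, trace_u, trace_x,
):
    np.random.seed(seed)
    n = V0.shape[0]
    V = V0.copy()
    I_exc = np.zeros(n)
    I_inh = np.zeros(n)
    I_ext = np.zeros(n)
    ref_until = np.full(n, -1, dtype=np.int64)

    L = 1
    for k in range(conn_delay_steps.shape[0]):
        if conn_delay_steps[k] + 1 > L:
            L = conn_delay_steps[k] + 1
    buf_e = np.zeros((L, n))
    buf_i = np.zeros((L, n))

    n_spikes = 0
    cap = spikes_step.shape[0]
    seg = 0
    n_seg = seg_mu.shape[0]
    n_traced = trace_indptr.shape[0] - 1

    for step in range(n_steps):
        # 1. refresh external currents on the 1 ms noise grid
        if step % steps_per_ms == 0:
            ms = step // steps_per_ms
            while seg + 1 < n_seg and ms >= seg_bounds_ms[seg + 1]:
                seg += 1
            for j in range(n):
                I_ext[j] = seg_mu[seg, j] + seg_sigma[seg, j] * np.random.standard_normal()

        # 2-3. deliver due spikes and propagate: branchless so the loop
        # vectorizes (refractory neurons keep their clamped V via select).
        slot = step % L
        for j in range(n):
            Ie = I_exc[j] + buf_e[slot, j]
            Ii = I_inh[j] + buf_i[slot, j]
            buf_e[slot, j] = 0.0
            buf_i[slot, j] = 0.0
            Vn = (pV[j] * V[j] + pVe[j] * Ie
                  + pVi[j] * Ii + pVx[j] * I_ext[j])
            V[j] = Vn if step >= ref_until[j] else V[j]
            I_exc[j] = Ie * dec_e[j]
            I_inh[j] = Ii * dec_i[j]

        # 4. threshold detection at the step boundary.  A spike scheduled
        # here lands at least one step ahead (delays >= 1 step), so
        # scheduling cannot affect the slot consumed above.
        t_now = (step + 1) * dt
        for j in range(n):
            if V[j] >= V_th and step >= ref_until[j]:
                if n_spikes >= cap:
                    return (n_spikes, STATUS_SPIKE_OVERFLOW, step, j)
                spikes_step[n_spikes] = step + 1
                spikes_id[n_spikes] = j
                n_spikes += 1
                V[j] = V_reset
                ref_until[j] = step + 1 + ref_steps
                for k in range(indptr[j], indptr[j + 1]):
                    amp = conn_jump[k]
                    if conn_plastic[k]:
                        dtl = t_now - t_last[k]
                        um = U + (u[k] - U) * np.exp(-dtl / tau_f)
                        xm = 1.0 + (x[k] - 1.0) * np.exp(-dtl / tau_d)
                        up = um + U * (1.0 - um)
                        if variant_post:
                            amp = amp * up * xm
                        else:
                            amp = amp * um * xm
                        u[k] = up
                        x[k] = xm - up * xm
                        t_last[k] = t_now
                    s2 = (step + conn_delay_steps[k]) % L
                    tg = conn_target[k]
                    if j < n_exc:
                        buf_e[s2, tg] += amp
                    else:
                        buf_i[s2, tg] += amp

        # periodic numerical health check
        if step % 200 == 0:
            for j in range(n):
                if not np.isfinite(V[j]):
                    return (n_spikes, STATUS_NONFINITE, step, j)

        # 5. sample STP traces (left limits at t_now)
        if trace_stride > 0 and (step + 1) % trace_stride == 0:
            s_idx = (step + 1) // trace_stride - 1
            if s_idx < trace_u.shape[0]:
                for p in range(n_traced):
                    su = 0.0
                    sx = 0.0
                    m = trace_indptr[p + 1] - trace_indptr[p]
                    for q in range(trace_indptr[p], trace_indptr[p + 1]):
                        k = trace_conn[q]
                        dtl = t_now - t_last[k]
                        su += U + (u[k] - U) * np.exp(-dtl / tau_f)
                        sx += 1.0 + (x[k] - 1.0) * np.exp(-dtl / tau_d)
                    if m > 0:
                        trace_u[s_idx, p] = su / m
                        trace_x[s_idx, p] = sx / m

    return (n_spikes, STATUS_OK, n_steps - 1, -1)
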