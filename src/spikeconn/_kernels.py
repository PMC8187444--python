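"""Compiled inner loops (numba) for the simulator and correlograms."""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_chunk(seed, step0, nsteps, cap, v, h1, h2, g_se, g_si,
                   ge_bg, gi_bg, last_spike,
                   tau_m, omega, alpha1, alpha2,
                   group, amp, phase, omega_freq,
                   out_ptr, out_tgt, out_G, out_dsteps, edge_exc,
                   buf_e, buf_i, consts, ksub):
    """Integrate one chunk of the MAT network; mutates all state arrays.

    Returns (spike_steps, spike_units, n_spikes); n_spikes is -1 on
    numerical blow-up and -2 on spike-capacity overflow.  ``seed >= 0``
    seeds the compiled RNG (first chunk only); later chunks pass -1 and
    continue the stream.
    """
    if seed >= 0:
        np.random.seed(seed)
    de_bg, se_bg = consts[0], consts[1]
    di_bg, si_bg = consts[2], consts[3]
    ge0, gi0 = consts[4], consts[5]
    Ee, Ei, gL = consts[6], consts[7], consts[8]
    dec_se, dec_si = consts[9], consts[10]
    d1, d2 = consts[11], consts[12]
    VL, VE, VI = consts[13], consts[14], consts[15]
    refrac, sqdt, dt = consts[16], consts[17], consts[18]
    clip = consts[19] > 0.5
    N = v.shape[0]
    D = buf_e.shape[0]
    times = np.empty(cap, np.int64)
    units = np.empty(cap, np.int32)
    nsp = 0
    for s in range(nsteps):
        step = step0 + s
        t = step * dt
        slot = step % D
        bg_step = step % ksub == 0  # background sample path on a coarser grid
        for n in range(N):
            if bg_step:
                # background OU conductances (exact stationary update)
                ge = ge0 + (ge_bg[n] - ge0) * de_bg + se_bg * np.random.standard_normal()
                if group[n] >= 0:
                    # amplitude-modulated extra white noise (slow rhythm)
                    ge += (amp[n] * np.sin(omega_freq[n] * t + phase[n])
                           * sqdt * np.random.standard_normal())
                gi = gi0 + (gi_bg[n] - gi0) * di_bg + si_bg * np.random.standard_normal()
                if clip:
                    if ge < 0.0:
                        ge = 0.0
                    if gi < 0.0:
                        gi = 0.0
                ge_bg[n] = ge
                gi_bg[n] = gi
            else:
                ge = ge_bg[n]
                gi = gi_bg[n]
            # synaptic conductances: exact decay plus delayed jumps
            gse = g_se[n] * dec_se + buf_e[slot, n]
            gsi = g_si[n] * dec_si + buf_i[slot, n]
            buf_e[slot, n] = 0.0
            buf_i[slot, n] = 0.0
            g_se[n] = gse
            g_si[n] = gsi
            # membrane (forward Euler); no reset at spike
            vm = v[n]
            RI = (ge * (vm - Ee) + gi * (vm - Ei)) / gL
            vm += dt * ((-(vm - VL) - RI) / tau_m[n]
                        - gse * (vm - VE) - gsi * (vm - VI))
            v[n] = vm
            # adaptive threshold
            h1[n] *= d1
            h2[n] *= d2
            if vm >= omega[n] + h1[n] + h2[n] and (t - last_spike[n]) >= refrac:
                if nsp >= cap:
                    return times, units, -2
                times[nsp] = step
                units[nsp] = n
                nsp += 1
                last_spike[n] = t
                h1[n] += alpha1[n]
                h2[n] += alpha2[n]
                for k in range(out_ptr[n], out_ptr[n + 1]):
                    dslot = (step + out_dsteps[k]) % D
                    if edge_exc[k]:
                        buf_e[dslot, out_tgt[k]] += out_G[k]
                    else:
                        buf_i[dslot, out_tgt[k]] += out_G[k]
    for n in range(N):
        if not np.isfinite(v[n]) or np.abs(v[n]) > 1000.0:
            return times, units, -1
    return times, units, nsp


@njit(cache=True)
def ccg_counts(ref, tgt, W, delta):
    """Histogram of lags (tgt - ref) in [-W, W), bin width delta.

    Both spike trains must be sorted ascending and share units with W
    and delta (milliseconds here).  Bins are half-open, lower edge
    inclusive, so an exact coincidence falls in the first positive bin.
    """
    nbins = int(round(2.0 * W / delta))
    counts = np.zeros(nbins, np.int64)
    j_lo = 0
    for i in range(ref.shape[0]):
        t = ref[i]
        lo = t - W
        hi = t + W
        while j_lo < tgt.shape[0] and tgt[j_lo] < lo:
            j_lo += 1
        j = j_lo
        while j < tgt.shape[0] and tgt[j] < hi:
            k = int(np.floor((tgt[j] - t + W) / delta))
            if 0 <= k < nbins:
                counts[k] += 1
            j += 1
    return counts
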