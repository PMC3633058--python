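"""Compiled inner loop of the direct-method SSA.

Everything here operates on the flat CSR-style arrays produced by
ssa.compile_model.  Semantics match the reference operations in ssa.py:
exact combinatorial propensities, declaration-order immediate cascades run
to quiescence after every firing, last-value-carried-forward sampling.

The RNG is numba's internal per-thread generator, seeded once per run via
set_seed; a fixed seed therefore gives bit-identical trajectories.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def quiesce(x, tptr, tidx, tcoe, qptr, qidx, qcoe, fir_imm, cap):
    """Fire immediates in declaration order until none is satisfiable.

    Rescans from the first immediate after every firing.  Returns the
    number of firings, or -1 if the cascade exceeds ``cap``.
    """
    n = tptr.shape[0] - 1
    total = 0
    i = 0
    while i < n:
        ok = True
        for k in range(tptr[i], tptr[i + 1]):
            if x[tidx[k]] < tcoe[k]:
                ok = False
                break
        if ok:
            total += 1
            if total > cap:
                return -1
            for k in range(tptr[i], tptr[i + 1]):
                x[tidx[k]] -= tcoe[k]
            for k in range(qptr[i], qptr[i + 1]):
                x[qidx[k]] += qcoe[k]
            fir_imm[i] += 1
            i = 0
        else:
            i += 1
    return total


@njit(cache=True)
def _flush(t_limit, x, fir_kin, fir_imm, sample_times, spos, counts_out, fir_out):
    """Record the current state at every sample time <= t_limit (LVCF)."""
    nk = fir_kin.shape[0]
    n = sample_times.shape[0]
    while spos < n and sample_times[spos] <= t_limit:
        counts_out[spos, :] = x
        fir_out[spos, :nk] = fir_kin
        fir_out[spos, nk:] = fir_imm
        spos += 1
    return spos


@njit(cache=True)
def run_segment(x, t, c,
                rptr, ridx, rcoe, pptr, pidx, pcoe,
                tptr, tidx, tcoe, qptr, qidx, qcoe,
                t_stop, sample_times, spos, counts_out, fir_out,
                fir_kin, fir_imm, max_events, imm_cap, n_events):
    """Advance the SSA from t to t_stop.

    Returns (t, spos, n_events, status); status 0 = reached t_stop,
    1 = max_events exhausted, 2 = immediate cascade overflow.
    """
    R = c.shape[0]
    a = np.empty(R, dtype=np.float64)
    nk = fir_kin.shape[0]
    eps = 1e-12 * (1.0 + abs(t_stop))
    while True:
        a0 = 0.0
        for j in range(R):
            aj = c[j]
            if aj > 0.0:
                for k in range(rptr[j], rptr[j + 1]):
                    xi = x[ridx[k]]
                    nu = rcoe[k]
                    if xi < nu:
                        aj = 0.0
                        break
                    if nu == 1:
                        aj *= xi
                    else:
                        comb = 1.0
                        for m in range(nu):
                            comb *= (xi - m)
                        for m in range(2, nu + 1):
                            comb /= m
                        aj *= comb
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            spos = _flush(t_stop + eps, x, fir_kin, fir_imm,
                          sample_times, spos, counts_out, fir_out)
            return t_stop, spos, n_events, 0
        tau = -np.log(np.random.random()) / a0
        t_new = t + tau
        if t_new > t_stop:
            # discard the draw: memorylessness makes stopping at t_stop exact
            spos = _flush(t_stop + eps, x, fir_kin, fir_imm,
                          sample_times, spos, counts_out, fir_out)
            return t_stop, spos, n_events, 0
        # samples strictly before the firing time see the old state
        npts = sample_times.shape[0]
        while spos < npts and sample_times[spos] < t_new:
            counts_out[spos, :] = x
            fir_out[spos, :nk] = fir_kin
            fir_out[spos, nk:] = fir_imm
            spos += 1
        # pick reaction j with probability a_j / a0
        u = np.random.random() * a0
        acc = 0.0
        j = R - 1
        for jj in range(R):
            acc += a[jj]
            if u <= acc:
                j = jj
                break
        for k in range(rptr[j], rptr[j + 1]):
            x[ridx[k]] -= rcoe[k]
        for k in range(pptr[j], pptr[j + 1]):
            x[pidx[k]] += pcoe[k]
        fir_kin[j] += 1
        if quiesce(x, tptr, tidx, tcoe, qptr, qidx, qcoe, fir_imm, imm_cap) < 0:
            return t_new, spos, n_events, 2
        t = t_new
        n_events += 1
        if n_events >= max_events:
            spos = _flush(t, x, fir_kin, fir_imm,
                          sample_times, spos, counts_out, fir_out)
            return t, spos, n_events, 1
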