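"""Fused numba kernel stepping both reservoir modules jointly.

The public per-operation functions in :mod:`comodal.reservoir` and
:mod:`comodal.model` define the semantics; this kernel is the same math
fused into one compiled loop (dynamics, sliding-window output
normalization, teaching signals, RLS readout updates and the Hebbian
association layer) so that desk-scale experiments run in minutes.  A test
asserts step-for-step agreement with the composed numpy operations.

Variant codes: 0 original (cross-fed teaching), 1 A1 (reservoir-to-reservoir
input), 2 A2 (cross feedback from partner readouts), 3 A3 (all-to-all
readout coupling).  For variants 1-3 the teaching signal is module-local.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _soft_wta(zhat, gamma, beta, out):
    """f_i = [tanh((zhat_i - gamma * sum_{j != i} zhat_j) / beta)]_+"""
    total = 0.0
    for j in range(zhat.shape[0]):
        total += zhat[j]
    for i in range(zhat.shape[0]):
        u = (zhat[i] - gamma * (total - zhat[i])) / beta
        v = np.tanh(u)
        out[i] = v if v > 0.0 else 0.0


@njit(cache=True)
def _push_stats(buf, ssum, ssumsq, count, pos, z):
    win = buf.shape[0]
    for i in range(z.shape[0]):
        if count >= win:
            old = buf[pos, i]
            ssum[i] += z[i] - old
            ssumsq[i] += z[i] * z[i] - old * old
        else:
            ssum[i] += z[i]
            ssumsq[i] += z[i] * z[i]
        buf[pos, i] = z[i]


@njit(cache=True)
def _refresh_stats(buf, ssum, ssumsq):
    # periodic exact recomputation kills float drift of the running sums
    win, O = buf.shape
    for i in range(O):
        s = 0.0
        q = 0.0
        for t in range(win):
            s += buf[t, i]
            q += buf[t, i] * buf[t, i]
        ssum[i] = s
        ssumsq[i] = q


@njit(cache=True)
def _normalize(ssum, ssumsq, n, sigma_floor, z, out):
    for i in range(z.shape[0]):
        mu = ssum[i] / n
        var = ssumsq[i] / n - mu * mu
        if var < 0.0:
            var = 0.0
        sd = np.sqrt(var)
        out[i] = 0.0 if sd < sigma_floor else (z[i] - mu) / sd


@njit(cache=True)
def _rls(W_out, P, support, r, e):
    O, S = support.shape
    for i in range(O):
        rs = np.empty(S)
        for s in range(S):
            rs[s] = r[support[i, s]]
        Pr = P[i] @ rs
        c = 0.0
        for s in range(S):
            c += rs[s] * Pr[s]
        a = 1.0 / (1.0 + c)
        for u in range(S):
            pu = a * Pr[u]
            for v in range(S):
                P[i, u, v] -= pu * Pr[v]
            W_out[i, support[i, u]] -= e[i] * pu


@njit(cache=True)
def _csr_matvec_add(indptr, indices, data, v, out):
    for row in range(out.shape[0]):
        acc = 0.0
        for k in range(indptr[row], indptr[row + 1]):
            acc += data[k] * v[indices[k]]
        out[row] += acc


@njit(cache=True)
def run_block(
    # module states (updated in place)
    x1, r1, x2, r2,
    # module 1 weights
    W1, in_idx1, in_w1, Wback1, Wout1, P1, supp1,
    # module 2 weights
    W2, in_idx2, in_w2, Wback2, Wout2, P2, supp2,
    # block inputs
    u1, u2, noise1, noise2,
    # sliding-window readout statistics (shared counters)
    buf1, sum1, sumsq1, buf2, sum2, sumsq2, counters,
    # scalar parameters
    dt, tau1, tau2, g1, g2, k1, k2,
    beta, gamma, sigma_floor, delta, hebb_eta,
    variant, learn, force_interval, t0, warm_min, pretrain_zero,
    # cross-module structures (size-0 dummies when unused)
    a1_indptr1, a1_indices1, a1_data1,
    a1_indptr2, a1_indices2, a1_data2,
    wbi1, wbi2, R1, R2,
    w_assoc1, w_assoc2,
    # per-step records
    z1_out, z2_out, f1_out, f2_out, o_out,
    # strided reservoir-rate snapshots (rec_stride 0 disables)
    r1_rec, r2_rec, rec_stride,
):
    B = u1.shape[0]
    O = Wout1.shape[0]
    win = buf1.shape[0]
    zh1 = np.empty(O)
    zh2 = np.empty(O)
    f1 = np.zeros(O)
    f2 = np.zeros(O)
    o = np.zeros(O)
    for t in range(B):
        gt = t0 + t
        # readouts from the rates entering this step
        z1 = Wout1 @ r1
        z2 = Wout2 @ r2
        if variant == 3:
            z1c = z1 + R1 @ z2
            z2c = z2 + R2 @ z1
            z1, z2 = z1c, z2c
        # sliding-window statistics (push both modules, shared counters)
        pos = counters[1]
        _push_stats(buf1, sum1, sumsq1, counters[0], pos, z1)
        _push_stats(buf2, sum2, sumsq2, counters[0], pos, z2)
        counters[0] += 1
        counters[1] = (pos + 1) % win
        if counters[1] == 0 and counters[0] >= win:
            _refresh_stats(buf1, sum1, sumsq1)
            _refresh_stats(buf2, sum2, sumsq2)
        warm = counters[0] >= warm_min
        # teaching signals
        for i in range(O):
            f1[i] = 0.0
            f2[i] = 0.0
        if warm:
            n_eff = win if counters[0] >= win else counters[0]
            _normalize(sum1, sumsq1, n_eff, sigma_floor, z1, zh1)
            _normalize(sum2, sumsq2, n_eff, sigma_floor, z2, zh2)
            if variant == 0:
                _soft_wta(zh2, gamma, beta, f1)
                _soft_wta(zh1, gamma, beta, f2)
            else:
                _soft_wta(zh1, gamma, beta, f1)
                _soft_wta(zh2, gamma, beta, f2)
        # FORCE / RLS readout updates
        if learn and (warm or pretrain_zero) and gt % force_interval == 0:
            _rls(Wout1, P1, supp1, r1, z1 - f1)
            _rls(Wout2, P2, supp2, r2, z2 - f2)
        # association layer
        if variant == 0:
            for i in range(O):
                o[i] = delta * (z1[i] + z2[i])
        else:
            o = w_assoc1 @ z1 + w_assoc2 @ z2
            if learn and warm:
                mz1 = 0.0
                mz2 = 0.0
                for j in range(O):
                    mz1 += z1[j]
                    mz2 += z2[j]
                mz1 /= O
                mz2 /= O
                for i in range(O):
                    for j in range(O):
                        w_assoc1[i, j] += dt * hebb_eta * o[i] * (z1[j] - mz1)
                        w_assoc2[i, j] += dt * hebb_eta * o[i] * (z2[j] - mz2)
        # records
        for i in range(O):
            z1_out[t, i] = z1[i]
            z2_out[t, i] = z2[i]
            f1_out[t, i] = f1[i]
            f2_out[t, i] = f2[i]
            o_out[t, i] = o[i]
        if rec_stride > 0 and gt % rec_stride == 0:
            row = counters[2]
            for nn in range(r1.shape[0]):
                r1_rec[row, nn] = r1[nn]
            for nn in range(r2.shape[0]):
                r2_rec[row, nn] = r2[nn]
            counters[2] = row + 1
        # leaky Euler dynamics (both drives from pre-update rates)
        drive1 = g1 * (W1 @ r1) + Wback1 @ z1
        drive2 = g2 * (W2 @ r2) + Wback2 @ z2
        row1 = u1[t]
        row2 = u2[t]
        for nn in range(x1.shape[0]):
            drive1[nn] += in_w1[nn] * row1[in_idx1[nn]] + k1 * noise1[t, nn]
        for nn in range(x2.shape[0]):
            drive2[nn] += in_w2[nn] * row2[in_idx2[nn]] + k2 * noise2[t, nn]
        if variant == 1:
            _csr_matvec_add(a1_indptr1, a1_indices1, a1_data1, r2, drive1)
            _csr_matvec_add(a1_indptr2, a1_indices2, a1_data2, r1, drive2)
        elif variant == 2:
            drive1 += wbi1 @ z2
            drive2 += wbi2 @ z1
        for nn in range(x1.shape[0]):
            x1[nn] += (dt / tau1) * (drive1[nn] - x1[nn])
            r1[nn] = np.tanh(x1[nn])
        for nn in range(x2.shape[0]):
            x2[nn] += (dt / tau2) * (drive2[nn] - x2[nn])
            r2[nn] = np.tanh(x2[nn])
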