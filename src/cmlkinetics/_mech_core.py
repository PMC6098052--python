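"""Numba kernel for the affinity-binned clonal-competition simulation.

The stem-cell pool is a set of grouped cohorts keyed by (clone, state,
affinity bin, TKI status).  Normal cells are propagated as mean-field
expectations (float counts); leukemic cells are integer counts updated with
binomial draws, so the demographic noise that matters for the peripheral
readout is retained.  Affinity bins are geometric with ratio equal to the
per-step regeneration/differentiation factor, so the affinity update is a
one-bin shift: up in quiescence (A), down in cycle (Omega); cells shifted
below the lowest bin differentiate out of the pool and feed the mature
compartment.
"""
import numpy as np
from numba import njit

# state-vector layout helpers are kept in plain arrays for numba's benefit


@njit(cache=True)
def _sig(n, lo, hi, half, hill):
    if hi <= lo:
        return lo
    return lo + (hi - lo) / (1.0 + (n / half) ** hill)


@njit(cache=True)
def run_core(nA, nO, lA, lO, xA, xO, mat,
             inv_a, rel_a,
             fw_lo, fw_hi, fw_half, fw_hill,
             fa_lo, fa_hi, fa_half, fa_hill,
             fw_leuk, f_omega_cml, f_alpha_cml,
             r_deg, r_trans, kill_quiescent,
             p_div_n, p_div_l, dt, mat_decay, amp,
             n_steps, record_steps, out_n1, out_n2, out_lsc,
             seed, tallies):
    """Advance the state n_steps; record mature counts and leukemic stem
    counts at the step indices in record_steps.  tallies (len 6) accumulates
    [activations, deactivations, divisions, kills, differentiations,
    conversions] for the leukemic clone (bookkeeping tests)."""
    np.random.seed(seed)
    K = nA.shape[0]
    p_tr = 1.0 - np.exp(-r_trans * dt)
    rec = 0
    n_rec = record_steps.shape[0]
    act_l = np.zeros(K, dtype=np.int64)
    dea_l = np.zeros(K, dtype=np.int64)
    act_x = np.zeros(K, dtype=np.int64)
    dea_x = np.zeros(K, dtype=np.int64)
    # mature counts are reported as the running average since the previous
    # sample: a variance-reduced estimate of the slowly varying mean
    # readout (single differentiation events make the instantaneous
    # compartment spiky when few leukemic stem cells remain)
    acc_n = 0.0
    acc_l = 0.0
    n_acc = 0
    for istep in range(n_steps + 1):
        if rec < n_rec and istep == record_steps[rec]:
            lsc = 0
            for k in range(K):
                lsc += lA[k] + lO[k] + xA[k] + xO[k]
            if n_acc > 0:
                out_n1[rec] = acc_l / n_acc
                out_n2[rec] = acc_n / n_acc
            else:
                out_n1[rec] = mat[1]
                out_n2[rec] = mat[0]
            out_lsc[rec] = lsc
            acc_n = 0.0
            acc_l = 0.0
            n_acc = 0
            rec += 1
        if istep == n_steps:
            break

        n_a_tot = 0.0
        n_o_tot = 0.0
        for k in range(K):
            n_a_tot += nA[k] + lA[k] + xA[k]
            n_o_tot += nO[k] + lO[k] + xO[k]
        fw = _sig(n_o_tot, fw_lo, fw_hi, fw_half, fw_hill)
        fa = _sig(n_a_tot, fa_lo, fa_hi, fa_half, fa_hill)

        # (a) transition attempts -------------------------------------------
        for k in range(K):
            pa = 1.0 - np.exp(-fa * rel_a[k] * dt)
            pw_l = 1.0 - np.exp(-fw_leuk * inv_a[k] * dt)
            pw_x = 1.0 - np.exp(-fw_leuk * f_omega_cml * inv_a[k] * dt)
            pa_x = 1.0 - np.exp(-fa * f_alpha_cml * rel_a[k] * dt)
            a = np.random.binomial(lA[k], pw_l) if lA[k] > 0 else 0
            d = np.random.binomial(lO[k], pa) if lO[k] > 0 else 0
            act_l[k] = a
            dea_l[k] = d
            a2 = np.random.binomial(xA[k], pw_x) if xA[k] > 0 else 0
            d2 = np.random.binomial(xO[k], pa_x) if xO[k] > 0 else 0
            act_x[k] = a2
            dea_x[k] = d2
            tallies[0] += a + a2
            tallies[1] += d + d2
        for k in range(K):
            lA[k] += dea_l[k] - act_l[k]
            lO[k] += act_l[k] - dea_l[k]
            xA[k] += dea_x[k] - act_x[k]
            xO[k] += act_x[k] - dea_x[k]
        # normal clone, mean-field
        for k in range(K):
            pw = 1.0 - np.exp(-fw * inv_a[k] * dt)
            pa = 1.0 - np.exp(-fa * rel_a[k] * dt)
            a_f = nA[k] * pw
            d_f = nO[k] * pa
            nA[k] += d_f - a_f
            nO[k] += a_f - d_f

        # (b) affinity update: A shifts up (clipped at a_max), Omega shifts
        # down; Omega cells leaving the lowest bin differentiate out (d)
        flux_n = nO[0]
        flux_l = float(lO[0])
        flux_x = float(xO[0])
        nA[K - 1] += nA[K - 2]
        lA[K - 1] += lA[K - 2]
        xA[K - 1] += xA[K - 2]
        for k in range(K - 2, 0, -1):
            nA[k] = nA[k - 1]
            lA[k] = lA[k - 1]
            xA[k] = xA[k - 1]
        nA[0] = 0.0
        lA[0] = 0
        xA[0] = 0
        for k in range(0, K - 1):
            nO[k] = nO[k + 1]
            lO[k] = lO[k + 1]
            xO[k] = xO[k + 1]
        nO[K - 1] = 0.0
        lO[K - 1] = 0
        xO[K - 1] = 0
        tallies[4] += int(flux_l + flux_x)

        # (c) division in Omega
        for k in range(K):
            nO[k] += nO[k] * p_div_n
            if lO[k] > 0:
                nd = np.random.binomial(lO[k], p_div_l)
                lO[k] += nd
                tallies[2] += nd
            if xO[k] > 0:
                nd = np.random.binomial(xO[k], p_div_l)
                xO[k] += nd
                tallies[2] += nd

        # (e) gradual TKI onset: naive -> affected
        if p_tr > 0.0:
            for k in range(K):
                if lA[k] > 0:
                    c = np.random.binomial(lA[k], p_tr)
                    lA[k] -= c
                    xA[k] += c
                    tallies[5] += c
                if lO[k] > 0:
                    c = np.random.binomial(lO[k], p_tr)
                    lO[k] -= c
                    xO[k] += c
                    tallies[5] += c

        # (f) cytotoxic TKI effect on affected leukemic cells in cycle
        if r_deg > 0.0:
            for k in range(K):
                if xO[k] > 0:
                    kd = np.random.binomial(xO[k], r_deg)
                    xO[k] -= kd
                    tallies[3] += kd
                if kill_quiescent and xA[k] > 0:
                    kd = np.random.binomial(xA[k], r_deg)
                    xA[k] -= kd
                    tallies[3] += kd

        # (g) mature-compartment bookkeeping
        mat[0] = mat[0] * mat_decay + amp * flux_n
        mat[1] = mat[1] * mat_decay + amp * (flux_l + flux_x)
        acc_n += mat[0]
        acc_l += mat[1]
        n_acc += 1
    return rec
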