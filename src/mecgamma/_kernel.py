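"""Fixed-step network integration kernel (numba-compiled).

State update scheme per time step (dt = 0.025 ms by default):

1. synaptic conductance states decay exponentially (exact factors);
2. readout clamp currents and requested voltages are recorded;
3. gating variables advance by exponential Euler at the old voltage, then
   the membrane potential advances by exponential Euler on the linearized
   (conductance-form) membrane equation -- unconditionally stable for
   HH-type channel densities at this dt;
4. upward 0 mV crossings (2 ms refractory) are registered as spikes and the
   corresponding synaptic increments are applied, taking effect on the next
   time step (zero-delay event queue).

For speed, the voltage-dependent gate quantities (steady state and per-step
exponential-Euler decay factor) are evaluated from lookup tables sampled on
a 0.05 mV grid with linear interpolation; the tables are built per run from
the exact rate functions, so interpolation error in the gates is O(1e-6).

All conductances in nS, capacitances in pF, potentials in mV, times in ms,
currents in pA.  The Ornstein-Uhlenbeck drive noise is generated in-kernel
per interneuron from the seeded numba RNG, so a (network, config) pair maps
deterministically to one realization.
"""

import numpy as np
from numba import njit

from . import rates

SPIKE_THRESH = 0.0
REFRAC_MS = 2.0
BLOWUP_MV = 200.0

V_TABLE_MIN = -130.0
V_TABLE_MAX = 70.0
V_TABLE_STEP = 0.05


def build_tables(dt: float, fs_params, st_params):
    """Gate steady-state and decay-factor tables for both cell types.

    Returns (v_min, inv_step, T) where T has one row per tabulated quantity:
    rows 0-4: WB m_inf, h_inf, h_fac, n_inf, n_fac;
    rows 5-13: stellate m_inf, m_fac, h_inf, h_fac, n_inf, n_fac (with the
    per-gate voltage shifts applied), NaP m_inf, HCN r_inf, r_fac.
    """
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2, V_TABLE_STEP)
    phi_i = fs_params.phi
    vi = v - fs_params.v_shift
    ah, bh = rates.wb_h_alpha(vi), rates.wb_h_beta(vi)
    an, bn = rates.wb_n_alpha(vi), rates.wb_n_beta(vi)
    rows = [
        rates.wb_m_inf(vi),
        ah / (ah + bh), -np.expm1(-dt * phi_i * (ah + bh)),
        an / (an + bn), -np.expm1(-dt * phi_i * (an + bn)),
    ]
    phi_e = st_params.phi
    vg = v - st_params.v_shift
    vn = v - st_params.v_shift_k
    am, bm = rates.hh_m_alpha(vg), rates.hh_m_beta(vg)
    ah, bh = rates.hh_h_alpha(vg), rates.hh_h_beta(vg)
    an, bn = rates.hh_n_alpha(vn), rates.hh_n_beta(vn)
    tr = rates.h_r_tau(v)
    rows += [
        am / (am + bm), -np.expm1(-dt * phi_e * (am + bm)),
        ah / (ah + bh), -np.expm1(-dt * phi_e * (ah + bh)),
        an / (an + bn), -np.expm1(-dt * phi_e * (an + bn)),
        rates.nap_m_inf(v),
        rates.h_r_inf(v), -np.expm1(-dt / tr),
    ]
    T = np.ascontiguousarray(np.vstack(rows))
    return V_TABLE_MIN, 1.0 / V_TABLE_STEP, T


@njit(cache=True, inline="always")
def _lut(T, row, v, v_min, inv_step):
    u = (v - v_min) * inv_step
    if u < 0.0:
        u = 0.0
    i = int(u)
    nmax = T.shape[1] - 2
    if i > nmax:
        i = nmax
    w = u - i
    return T[row, i] + (T[row, i + 1] - T[row, i]) * w


@njit(cache=True)
def advance_network(
        n_steps, dt, noise_seed,
        v_min, inv_step, T,
        # I population state + parameters
        v_i, h_i, nn_i, gna_i, gk_i, gl_i,
        ena_i, ek_i, el_i, cm_i,
        # E population state + parameters
        v_e, m_e, he_e, nn_e, r_e, gna_e, gk_e, gl_e, gnap_e, gh_e,
        ena_e, ek_e, el_e, eh_e, cm_e,
        # drive
        th_i, th_e, e_drive, ou_a, ou_b, x_ou,
        # synapse kinetics
        f_ampa, e_ampa, f_g2d, f_g2r, f_g3d, f_g3r,
        # adjacency (CSR, targets include readouts)
        ei_indptr, ei_post, ei_w,
        ii_indptr, ii_post, ii_wn, ii_wne,
        ie_indptr, ie_post, ie_wn, e_gaba_ie,
        # synaptic state (I targets then E targets)
        s_ampa, s2_d, s2_r, s2e_d, s2e_r, s3_d, s3_r,
        # readouts + recording
        n_ro_i, n_ro_e, v_clamp, rec_stride,
        rec_ro_i, rec_ro_e, rec_idx_i, rec_idx_e, rec_v_i, rec_v_e,
        # spike output
        spike_t, spike_gid):
    np.random.seed(noise_seed)
    n_i = v_i.shape[0]
    n_e = v_e.shape[0]
    last_i = np.full(n_i, -1e9)
    last_e = np.full(n_e, -1e9)
    n_sp = 0
    cap = spike_t.shape[0]
    err = 0
    for k in range(n_steps):
        # 1. synaptic decay to time t_k
        for j in range(s_ampa.shape[0]):
            s_ampa[j] *= f_ampa
            s2_d[j] *= f_g2d
            s2_r[j] *= f_g2r
            s2e_d[j] *= f_g2d
            s2e_r[j] *= f_g2r
        for j in range(s3_d.shape[0]):
            s3_d[j] *= f_g3d
            s3_r[j] *= f_g3r
        # 2. record
        if k % rec_stride == 0:
            kr = k // rec_stride
            for j in range(n_ro_i):
                jj = n_i + j
                g_g = s2_d[jj] - s2_r[jj]
                ge_g = s2e_d[jj] - s2e_r[jj]
                rec_ro_i[j, kr] = (s_ampa[jj] * (v_clamp - e_ampa)
                                   + g_g * v_clamp - ge_g
                                   + th_i[k] * (v_clamp - e_drive))
            for j in range(n_ro_e):
                jj = n_e + j
                g_g = s3_d[jj] - s3_r[jj]
                rec_ro_e[j, kr] = (g_g * (v_clamp - e_gaba_ie)
                                   + th_e[k] * (v_clamp - e_drive))
            for j in range(rec_idx_i.shape[0]):
                rec_v_i[j, kr] = v_i[rec_idx_i[j]]
            for j in range(rec_idx_e.shape[0]):
                rec_v_e[j, kr] = v_e[rec_idx_e[j]]
        # 3. integrate populations
        t_next = (k + 1) * dt
        for i in range(n_i):
            x_ou[i] = ou_a * x_ou[i] + ou_b * np.random.standard_normal()
            vk = v_i[i]
            h_i[i] += (_lut(T, 1, vk, v_min, inv_step) - h_i[i]) \
                * _lut(T, 2, vk, v_min, inv_step)
            nn_i[i] += (_lut(T, 3, vk, v_min, inv_step) - nn_i[i]) \
                * _lut(T, 4, vk, v_min, inv_step)
            m = _lut(T, 0, vk, v_min, inv_step)
            g_na = gna_i[i] * m * m * m * h_i[i]
            g_k = gk_i[i] * nn_i[i] ** 4
            g_drv = th_i[k] + x_ou[i]
            if g_drv < 0.0:
                g_drv = 0.0
            g_g = s2_d[i] - s2_r[i]
            ge_g = s2e_d[i] - s2e_r[i]
            g_tot = g_na + g_k + gl_i[i] + g_drv + s_ampa[i] + g_g
            num = (g_na * ena_i + g_k * ek_i + gl_i[i] * el_i
                   + g_drv * e_drive + s_ampa[i] * e_ampa + ge_g)
            v_inf = num / g_tot
            v_new = v_inf + (vk - v_inf) * np.exp(-dt * g_tot / cm_i)
            v_i[i] = v_new
            if v_new >= SPIKE_THRESH and vk < SPIKE_THRESH \
                    and t_next - last_i[i] >= REFRAC_MS:
                last_i[i] = t_next
                if n_sp >= cap:
                    err = 2
                    break
                spike_t[n_sp] = t_next
                spike_gid[n_sp] = i
                n_sp += 1
                for q in range(ii_indptr[i], ii_indptr[i + 1]):
                    tgt = ii_post[q]
                    s2_d[tgt] += ii_wn[q]
                    s2_r[tgt] += ii_wn[q]
                    s2e_d[tgt] += ii_wne[q]
                    s2e_r[tgt] += ii_wne[q]
                for q in range(ie_indptr[i], ie_indptr[i + 1]):
                    tgt = ie_post[q]
                    s3_d[tgt] += ie_wn[q]
                    s3_r[tgt] += ie_wn[q]
            if v_new > BLOWUP_MV or v_new < -BLOWUP_MV:
                err = 1
                break
        if err:
            break
        for i in range(n_e):
            vk = v_e[i]
            m_e[i] += (_lut(T, 5, vk, v_min, inv_step) - m_e[i]) \
                * _lut(T, 6, vk, v_min, inv_step)
            he_e[i] += (_lut(T, 7, vk, v_min, inv_step) - he_e[i]) \
                * _lut(T, 8, vk, v_min, inv_step)
            nn_e[i] += (_lut(T, 9, vk, v_min, inv_step) - nn_e[i]) \
                * _lut(T, 10, vk, v_min, inv_step)
            r_e[i] += (_lut(T, 12, vk, v_min, inv_step) - r_e[i]) \
                * _lut(T, 13, vk, v_min, inv_step)
            g_na = gna_e[i] * m_e[i] ** 3 * he_e[i]
            g_k = gk_e[i] * nn_e[i] ** 4
            g_nap = gnap_e[i] * _lut(T, 11, vk, v_min, inv_step)
            g_h = gh_e[i] * r_e[i]
            g_g = s3_d[i] - s3_r[i]
            g_tot = g_na + g_k + gl_e[i] + g_nap + g_h + th_e[k] + g_g
            num = (g_na * ena_e + g_k * ek_e + gl_e[i] * el_e + g_nap * ena_e
                   + g_h * eh_e + th_e[k] * e_drive + g_g * e_gaba_ie)
            v_inf = num / g_tot
            v_new = v_inf + (vk - v_inf) * np.exp(-dt * g_tot / cm_e)
            v_e[i] = v_new
            if v_new >= SPIKE_THRESH and vk < SPIKE_THRESH \
                    and t_next - last_e[i] >= REFRAC_MS:
                last_e[i] = t_next
                if n_sp >= cap:
                    err = 2
                    break
                spike_t[n_sp] = t_next
                spike_gid[n_sp] = n_i + i
                n_sp += 1
                for q in range(ei_indptr[i], ei_indptr[i + 1]):
                    s_ampa[ei_post[q]] += ei_w[q]
            if v_new > BLOWUP_MV or v_new < -BLOWUP_MV:
                err = 1
                break
        if err:
            break
    return n_sp, err
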