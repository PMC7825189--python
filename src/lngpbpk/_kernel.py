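"""Compiled right-hand side of the whole-body system.

Numerically identical to :func:`lngpbpk.engine` 's pure-Python reference
RHS (asserted by the engine test suite on random states); exists only to
remove Python-level overhead from the inner integration loop.

Driver encoding for interaction terms: kind 0 = victim unbound plasma
concentration, kind 1 = perpetrator unbound plasma concentration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rhs_kernel", "fast_fu_nb"]


@njit(cache=True)
def fast_fu_nb(cp_nm, alb_ratio, shbg_nm, kd_shbg_nm):
    """Closed-form unbound fraction (albumin excess, SHBG depletable)."""
    if kd_shbg_nm <= 0.0 or not np.isfinite(kd_shbg_nm):
        return 1.0 / (1.0 + alb_ratio)
    if cp_nm <= 0.0:
        return 1.0 / (1.0 + alb_ratio + shbg_nm / kd_shbg_nm)
    b = (1.0 + alb_ratio) * kd_shbg_nm + shbg_nm - cp_nm
    disc = b * b + 4.0 * (1.0 + alb_ratio) * cp_nm * kd_shbg_nm
    free = (-b + np.sqrt(disc)) / (2.0 * (1.0 + alb_ratio))
    return free / cp_nm


@njit(cache=True)
def rhs_kernel(
    y,
    dy,
    # layout
    n_gi,
    per_victim,
    v_off,
    p_off,
    i_gut,
    i_liver,
    i_spleen,
    i_shbg,
    i_el,
    i_eg,
    # physiology
    vp,
    vols,
    q_ha,
    q_gut,
    q_spl,
    q_hv,
    kt,
    lumen_v,
    # victims
    v_mode,
    v_fu_const,
    v_alb_ratio,
    v_kd_shbg_nm,
    v_inv_fu_scale,
    v_kpu,
    v_qx,
    v_sat,
    v_kabs,
    v_kdiss,
    v_clint_cyp_l,
    v_clint_other,
    v_clint_cyp_g,
    v_clint_total,
    # perpetrators
    p_ka,
    p_cl,
    p_v,
    p_fu,
    # pools
    kdeg_shbg,
    shbg0,
    kdeg_el,
    kdeg_eg,
    # interactions
    comp_kind,
    comp_idx,
    comp_ki,
    ci_kind,
    ci_idx,
    ci_emax,
    ci_ec50,
    mb_kind,
    mb_idx,
    mb_kinact,
    mb_ki,
    si_kind,
    si_idx,
    si_emax,
    si_ec50,
):
    nv = v_off.shape[0]
    npp = p_off.shape[0]
    n_org = vols.shape[0]
    dy[:] = 0.0

    # --- perpetrators ------------------------------------------------------
    for j in range(npp):
        b = p_off[j]
        a_g = max(y[b], 0.0)
        a_c = max(y[b + 1], 0.0)
        dy[b] = -p_ka[j] * a_g
        dy[b + 1] = p_ka[j] * a_g - p_cl[j] * a_c / p_v[j]

    shbg = max(y[i_shbg], 0.0)
    e_l = max(y[i_el], 0.0)
    e_g = max(y[i_eg], 0.0)

    # --- victim plasma concentrations and unbound fractions ----------------
    fu_v = np.empty(nv)
    cp_v = np.empty(nv)
    for k in range(nv):
        cp = max(y[v_off[k] + 2 * n_gi], 0.0) / vp
        cp_v[k] = cp
        if v_mode[k] == 0:
            fu_v[k] = v_fu_const[k]
        else:
            fu_v[k] = fast_fu_nb(
                cp * 1e3, v_alb_ratio[k], shbg * v_inv_fu_scale[k], v_kd_shbg_nm[k]
            )

    # --- competitive CYP3A4 inhibition factor ------------------------------
    s = 0.0
    for n in range(comp_kind.shape[0]):
        if comp_kind[n] == 0:
            c = fu_v[comp_idx[n]] * cp_v[comp_idx[n]]
        else:
            j = comp_idx[n]
            c = p_fu[j] * max(y[p_off[j] + 1], 0.0) / p_v[j]
        s += c / comp_ki[n]
    phi = 1.0 / (1.0 + s)

    # --- regulation pools ---------------------------------------------------
    m_shbg = 1.0
    for n in range(si_kind.shape[0]):
        if si_kind[n] == 0:
            c = fu_v[si_idx[n]] * cp_v[si_idx[n]]
        else:
            j = si_idx[n]
            c = p_fu[j] * max(y[p_off[j] + 1], 0.0) / p_v[j]
        m_shbg *= 1.0 + (si_emax[n] - 1.0) * c / (si_ec50[n] + c)
    dy[i_shbg] = kdeg_shbg * shbg0 * m_shbg - kdeg_shbg * shbg

    m_cyp = 1.0
    for n in range(ci_kind.shape[0]):
        if ci_kind[n] == 0:
            c = fu_v[ci_idx[n]] * cp_v[ci_idx[n]]
        else:
            j = ci_idx[n]
            c = p_fu[j] * max(y[p_off[j] + 1], 0.0) / p_v[j]
        m_cyp *= 1.0 + (ci_emax[n] - 1.0) * c / (ci_ec50[n] + c)
    mbi = 0.0
    for n in range(mb_kind.shape[0]):
        if mb_kind[n] == 0:
            c = fu_v[mb_idx[n]] * cp_v[mb_idx[n]]
        else:
            j = mb_idx[n]
            c = p_fu[j] * max(y[p_off[j] + 1], 0.0) / p_v[j]
        mbi += mb_kinact[n] * c / (mb_ki[n] + c)
    dy[i_el] = kdeg_el * m_cyp - (kdeg_el + mbi) * e_l
    dy[i_eg] = kdeg_eg * m_cyp - (kdeg_eg + mbi) * e_g

    # --- victims ------------------------------------------------------------
    for k in range(nv):
        base = v_off[k]
        cp = cp_v[k]
        fu_t = fu_v[k]

        # GI cascade
        absorbed = 0.0
        prev_sol = 0.0
        prev_dis = 0.0
        for g in range(n_gi):
            sol = max(y[base + g], 0.0)
            dis = max(y[base + n_gi + g], 0.0)
            c_l = dis / lumen_v[g]
            # smooth solubility limit; negative values = precipitation back
            # to solid under transient supersaturation
            cap = 1.0 - c_l / v_sat[k, g]
            r_diss = v_kdiss[k] * sol * cap
            r_abs = v_kabs[k, g] * dis
            dy[base + g] = -r_diss - kt[g] * sol + prev_sol
            dy[base + n_gi + g] = r_diss - kt[g] * dis - r_abs + prev_dis
            prev_sol = kt[g] * sol
            prev_dis = kt[g] * dis
            absorbed += r_abs
        fecal = kt[n_gi - 1] * (
            max(y[base + n_gi - 1], 0.0) + max(y[base + 2 * n_gi - 1], 0.0)
        )

        # metabolism
        t0 = base + 2 * n_gi + 1
        a_liv = max(y[t0 + i_liver], 0.0)
        a_gut = max(y[t0 + i_gut], 0.0)
        cu_liver = a_liv / vols[i_liver] / v_kpu[k, i_liver]
        cu_gut = a_gut / vols[i_gut] / v_kpu[k, i_gut]
        if v_clint_total[k] > 0.0:
            met_liver = v_clint_total[k] * cu_liver
            met_gut = 0.0
        else:
            met_liver = (v_clint_cyp_l[k] * e_l * phi + v_clint_other[k]) * cu_liver
            met_gut = v_clint_cyp_g[k] * e_g * phi * cu_gut

        # circulation
        plasma_in = 0.0
        plasma_out = 0.0
        c_out_gut = 0.0
        c_out_spl = 0.0
        c_out_liv = 0.0
        for i in range(n_org):
            kp = fu_t * v_kpu[k, i]
            if kp < 1e-12:
                kp = 1e-12
            a_t = max(y[t0 + i], 0.0)
            c_out = a_t / vols[i] / kp
            if i == i_gut:
                c_out_gut = c_out
            elif i == i_spleen:
                c_out_spl = c_out
            elif i == i_liver:
                c_out_liv = c_out
            else:
                dy[t0 + i] = v_qx[k, i] * (cp - c_out)
                plasma_out += v_qx[k, i] * cp
                plasma_in += v_qx[k, i] * c_out
        dy[t0 + i_spleen] = q_spl * (cp - c_out_spl)
        dy[t0 + i_gut] = q_gut * (cp - c_out_gut) + absorbed - met_gut
        dy[t0 + i_liver] = (
            q_ha * cp
            + q_gut * c_out_gut
            + q_spl * c_out_spl
            - q_hv * c_out_liv
            - met_liver
        )
        plasma_out += (q_ha + q_gut + q_spl) * cp
        plasma_in += q_hv * c_out_liv
        dy[base + 2 * n_gi] = plasma_in - plasma_out
        dy[base + per_victim - 2] = met_liver + met_gut
        dy[base + per_victim - 1] = fecal
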