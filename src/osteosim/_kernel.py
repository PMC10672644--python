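"""Compiled daily-step kernel for one material site.

This is the inner loop of the simulation engine: a straight transcription
of the module-level model (tissue composition, stimulus, focal balance,
activation, windowed formation/resorption integrals, LIFO layer turnover,
accommodation) into flat arrays so that multi-decade daily runs and
calibration sweeps stay fast.  Semantics are defined by the public modules
(`tissue`, `kinetics`, `stimulus`); the test suite cross-checks the kernel
trace against them.

Day-d bookkeeping (state recorded at the start of day d, i.e. the end of
day d-1):

1. layer-stack summary -> v_b, mean v_m, mean ash fraction
2. elastic modulus from (v_b, alpha)
3. strains and daily stimulus zeta (with the scenario load factor)
4. focal balance from zeta - zeta_ref, scaled by kappa_fbb(d)
5. activation frequency from zeta with f_bio * kappa_fbio(d)
6. origination rate f_or * S_v(porosity)
7. formation / resorption rates from history windows (excluding today)
8. LIFO turnover (resorb youngest-first, deposit fresh layer)
9. accommodation step on zeta_ref
10. push today's origination rate and focal balance into the history

Histories are padded with the equilibrium origination rate and f_bb = 1 so
the run starts at steady state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# output column indices of simulate_site
N_OUT = 9
(
    COL_VB,
    COL_VM,
    COL_ALPHA,
    COL_ZETA,
    COL_ZETA_REF,
    COL_FOR,
    COL_NDOT,
    COL_VFDOT,
    COL_VRDOT,
) = range(N_OUT)


@njit(cache=True)
def _sv_poly(p, coeffs):
    """Evaluate the specific-surface polynomial at porosity p (clamped)."""
    if p < 0.0:
        p = 0.0
    elif p > 1.0:
        p = 1.0
    acc = 0.0
    for k in range(len(coeffs) - 1, -1, -1):
        acc = acc * p + coeffs[k]
    if acc < 0.0:
        acc = 0.0
    return acc


@njit(cache=True)
def _focal_balance(x, fbb_min, fbb_max, w, v):
    if x <= -(w + v):
        return fbb_min
    if x < -w:
        return 1.0 + (1.0 - fbb_min) * (x + w) / v
    if x <= w:
        return 1.0
    if x < w + v:
        return 1.0 + (fbb_max - 1.0) * (x - w) / v
    return fbb_max


@njit(cache=True)
def simulate_site(
    n_days,
    # initial state
    vb0,
    init_age_days,
    zeta_ref0,
    # tissue constants
    rho_m,
    rho_o,
    rho_w,
    v_o,
    # specific-surface polynomial, lowest order first
    sv_coeffs,
    # BMU parameters
    t_r,
    t_i,
    t_f,
    a_bmu,
    v_bmu,
    f_bio,
    fbb_min,
    fbb_max,
    w_zone,
    v_zone,
    # mineralization law
    alpha_0,
    alpha_max,
    tau_min,
    # stimulus
    m_exp,
    phi,
    cycles,
    sigma,
    # per-day modifier arrays (length n_days)
    kappa_fbio,
    kappa_fbb,
    load_factor,
    # numerics
    coalesce_gap,
):
    """Simulate one site for n_days daily steps; returns (out, flags).

    out has shape (n_days, N_OUT); flags[0] counts clamped (over-resorbed)
    days, flags[1] is 1 if the site degenerated to zero volume.
    """
    W = t_r + t_i + t_f
    out = np.zeros((n_days, N_OUT))
    flags = np.zeros(2, dtype=np.int64)

    # --- layer stack: thickness + deposition day (day index; initial layer
    # deposited in the past), youngest at index n_layers-1.
    cap = n_days + 8
    th = np.zeros(cap)
    dep = np.zeros(cap)
    th[0] = vb0
    dep[0] = -init_age_days
    n_layers = 1
    total_vb = vb0

    # --- histories. ndot[o_nd + d] is the origination rate of day d, with
    # days -2W..-1 prefilled at the equilibrium rate; nact[o_w + d] is the
    # active-BMU density of day d (lifespan-window sum of ndot); fbb likewise.
    o_nd = 2 * W
    o_w = W
    alpha_init = alpha_max - (alpha_max - alpha_0) * np.exp(-init_age_days / tau_min)
    e0 = 84370.0 * vb0**2.58 * alpha_init**2.74
    zeta_eq = 0.0
    for i in range(len(cycles)):
        zeta_eq += cycles[i] * (sigma[i] / e0) ** m_exp
    zeta_eq = zeta_eq ** (1.0 / m_exp)
    c_eq = f_bio * (zeta_ref0 / (zeta_eq + zeta_ref0)) * _sv_poly(1.0 - vb0, sv_coeffs)

    ndot = np.empty(n_days + 2 * W)
    ndot[: 2 * W] = c_eq
    nact = np.empty(n_days + W)
    nact[:W] = c_eq * W
    fbbh = np.empty(n_days + W)
    fbbh[:W] = 1.0

    zeta_ref = zeta_ref0
    dead = False

    for d in range(n_days):
        if dead:
            # degenerate site: no tissue left, freeze at zero
            out[d, COL_ZETA_REF] = zeta_ref
            continue

        # (1) stack summary
        vb = 0.0
        vm_sum = 0.0
        al_sum = 0.0
        for i in range(n_layers):
            age = d - dep[i]
            al = alpha_max - (alpha_max - alpha_0) * np.exp(-age / tau_min)
            vm = rho_o * v_o * al / (rho_m * (1.0 - al))
            vb += th[i]
            vm_sum += th[i] * vm
            al_sum += th[i] * al
        if vb <= 0.0 or n_layers == 0:
            dead = True
            flags[1] = 1
            out[d, COL_ZETA_REF] = zeta_ref
            continue
        vm_mean = vm_sum / vb
        alpha_mean = al_sum / vb

        # (2) elastic modulus
        e_mod = 84370.0 * vb**2.58 * alpha_mean**2.74

        # (3) daily stimulus with scenario load factor
        zeta = 0.0
        for i in range(len(cycles)):
            eps = load_factor[d] * sigma[i] / e_mod
            zeta += cycles[i] * eps**m_exp
        zeta = zeta ** (1.0 / m_exp)

        # (4) focal balance under kappa_fbb
        fbb_now = kappa_fbb[d] * _focal_balance(
            zeta - zeta_ref, fbb_min, fbb_max, w_zone, v_zone
        )
        if fbb_now < 0.0:
            fbb_now = 0.0

        # (5) activation frequency under kappa_fbio
        f_or = f_bio * kappa_fbio[d] * zeta_ref / (zeta + zeta_ref)

        # (6) origination rate on the free surface
        ndot_now = f_or * _sv_poly(1.0 - vb, sv_coeffs)

        # (7) formation / resorption from the history windows
        acc = 0.0
        for k in range(t_r):
            acc += nact[o_w + d - 1 - k]
        vr_dot = a_bmu * v_bmu / t_r * acc
        acc = 0.0
        for k in range(t_f):
            j = o_w + d - W + k  # days t-W .. t-T_R-T_I-1
            acc += nact[j] * fbbh[j]
        vf_dot = a_bmu * v_bmu / t_f * acc

        # record start-of-day state and today's rates
        out[d, COL_VB] = vb
        out[d, COL_VM] = vm_mean
        out[d, COL_ALPHA] = alpha_mean
        out[d, COL_ZETA] = zeta
        out[d, COL_ZETA_REF] = zeta_ref
        out[d, COL_FOR] = f_or
        out[d, COL_NDOT] = ndot_now
        out[d, COL_VFDOT] = vf_dot
        out[d, COL_VRDOT] = vr_dot

        # (8) LIFO turnover: resorb youngest-first, then deposit
        remaining = vr_dot
        while remaining > 0.0 and n_layers > 0:
            if th[n_layers - 1] <= remaining + 1e-18:
                remaining -= th[n_layers - 1]
                n_layers -= 1
            else:
                th[n_layers - 1] -= remaining
                remaining = 0.0
        if remaining > 1e-15:
            flags[0] += 1
        # deposition bookkeeping: a layer pushed at the end of day d first
        # appears in the day d+1 summary at age 0, matching the pure-Python
        # step_site ordering (turnover advances ages before depositing).
        born = d + 1.0
        if vf_dot > 0.0:
            if n_layers > 0 and (born - dep[n_layers - 1]) < coalesce_gap:
                t_old = th[n_layers - 1]
                dep[n_layers - 1] = (dep[n_layers - 1] * t_old + born * vf_dot) / (
                    t_old + vf_dot
                )
                th[n_layers - 1] = t_old + vf_dot
            else:
                th[n_layers] = vf_dot
                dep[n_layers] = born
                n_layers += 1

        # (9) accommodation
        zeta_ref = zeta_ref + phi * (zeta - zeta_ref)

        # (10) push history
        ndot[o_nd + d] = ndot_now
        fbbh[o_w + d] = fbb_now
        na = nact[o_w + d - 1] + ndot_now - ndot[o_nd + d - W]
        if na < 0.0:
            na = 0.0
        nact[o_w + d] = na

    return out, flags
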