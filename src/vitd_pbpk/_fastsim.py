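"""Compiled fixed-grid TR-BDF2 integrator for the QSS-reduced PBPK system.

This backend exists for the inner loops of SAEM estimation and
virtual-population simulation, where the model is solved tens of
thousands of times. It integrates the reduced (QSS) system with the
one-step, L-stable TR-BDF2 scheme (trapezoidal stage to t + gamma*h,
BDF2 stage to t + h, gamma = 2 - sqrt(2)), using a geometric step plan
restarted at every dose event: small steps through the absorption
transient, growing to a capped maximum through the slow inter-dose
decline. A chord-Newton iteration with a segment-frozen Jacobian and a
hand-rolled LU factorisation keep the per-trajectory cost around a
millisecond. Accuracy against the SciPy reference integrator is part of
the test suite (well below 1% on 3-year weekly regimens).

State layout (reduced): [GI, D_pool, D_liver, 25art, 25ven, 25liv,
25fm|25rb, (25lm)] — the vitamin D pool lumps venous + arterial + rest
of body, split algebraically by the QSS relations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import HOURS_PER_YEAR
from .errors import SolverError
from .pbpk import PbpkParameters, PhysiologyPlan
from .physiology import PhysiologySet, fat_mass_fraction

_GAMMA = 2.0 - np.sqrt(2.0)

# parameter-vector indices
_KA, _CLH, _KPL, _KPRB, _FM, _CLMAX, _C50, _GAM = range(8)
_KP25L, _KP25FM, _KP25LM, _KP25RB, _ENDOG, _WTREF, _EXPO = range(8, 15)
# plan-vector indices: wt0, slope/h, f_art, f_ven, f_liv, f_fm, f_lm, f_rb,
# q_co per kg, liver flow fraction, split flag
_W0, _SL, _FA, _FV, _FL, _FFM, _FLM, _FRB, _QKG, _LFF, _SPL = range(11)


def _param_vector(p: PbpkParameters) -> np.ndarray:
    return np.array(
        [
            p.ka, p.cl_h, p.kp_l, p.kp_rb, p.f_m, p.clmax, p.c50, p.gamma,
            p.kp25_l, p.kp25_fm, p.kp25_lm, p.kp25_rb, p.endog,
            p.clmax_wt_ref, p.clmax_exponent,
        ],
        dtype=np.float64,
    )


def _plan_vector(phys) -> np.ndarray:
    if isinstance(phys, PhysiologyPlan):
        cfg = phys.config
        wt0 = phys.trajectory.wt0
        slope_h = phys.trajectory.slope_per_year(cfg) / HOURS_PER_YEAR
        fa, fv, fl = cfg.frac_arterial, cfg.frac_venous, cfg.frac_liver
        frb = 1.0 / cfg.density - fa - fv - fl
        if phys.split:
            ffm = fat_mass_fraction(phys.zbmi)
            flm = frb - ffm / cfg.density
        else:
            ffm = flm = 0.0
        qkg = cfg.cardiac_output_ref / cfg.weight_ref
        lff = cfg.liver_flow_fraction
        split = 1.0 if phys.split else 0.0
    elif isinstance(phys, PhysiologySet):
        wt0 = phys.total_volume
        slope_h = 0.0
        fa, fv, fl = phys.v_art / wt0, phys.v_ven / wt0, phys.v_liver / wt0
        frb = phys.v_rb / wt0
        ffm, flm = phys.v_fm / wt0, phys.v_lm / wt0
        qkg = phys.q_co / wt0
        lff = phys.q_liver / phys.q_co
        split = 1.0 if phys.split else 0.0
    else:  # pragma: no cover
        raise TypeError("phys must be PhysiologySet or PhysiologyPlan")
    return np.array(
        [wt0, slope_h, fa, fv, fl, ffm, flm, frb, qkg, lff, split], dtype=np.float64
    )


@njit(cache=True, fastmath=False)
def _rhs(t, y, pv, pl, dy):
    wt = pl[_W0] + pl[_SL] * t
    split = pl[_SPL] > 0.5
    v_art = pl[_FA] * wt
    v_ven = pl[_FV] * wt
    v_liv = pl[_FL] * wt
    v_rb = pl[_FRB] * wt
    q_co = pl[_QKG] * wt
    q_l = pl[_LFF] * q_co
    q_rb = q_co - q_l
    clmax_t = pv[_CLMAX] * (wt / pv[_WTREF]) ** pv[_EXPO]

    r = q_co / (q_l + q_rb)
    denom = 1.0 + r * (v_art + v_rb * pv[_KPRB]) / v_ven
    a_dven = y[1] / denom
    c_dven = a_dven / v_ven
    c_dart = r * c_dven
    c_dliv = y[2] / v_liv
    dy[0] = -pv[_KA] * y[0]
    dy[2] = (
        q_l * (c_dart - c_dliv / pv[_KPL])
        + pv[_KA] * y[0]
        - pv[_CLH] * c_dliv / pv[_KPL]
    )
    dy[1] = pv[_ENDOG] + q_l * (c_dliv / pv[_KPL] - c_dart)

    prod25 = pv[_FM] * pv[_CLH] * c_dliv / pv[_KPL]
    c25a = y[3] / v_art
    c25v = y[4] / v_ven
    c25l = y[5] / v_liv
    dy[3] = q_co * (c25v - c25a)
    dy[5] = q_l * (c25a - c25l / pv[_KP25L]) + prod25
    if split:
        v_fm = pl[_FFM] * wt
        v_lm = pl[_FLM] * wt
        q_fm = q_rb * v_fm / (v_fm + v_lm)
        q_lm = q_rb - q_fm
        c25fm = y[6] / v_fm
        c25lm = y[7] / v_lm
        dy[6] = q_fm * (c25a - c25fm / pv[_KP25FM])
        dy[7] = q_lm * (c25a - c25lm / pv[_KP25LM])
        ret = q_fm * c25fm / pv[_KP25FM] + q_lm * c25lm / pv[_KP25LM]
    else:
        c25rb = y[6] / v_rb
        dy[6] = q_rb * (c25a - c25rb / pv[_KP25RB])
        ret = q_rb * c25rb / pv[_KP25RB]
    cpos = c25v if c25v > 0.0 else 0.0
    cg = cpos ** pv[_GAM]
    cl25 = clmax_t * cg / (pv[_C50] ** pv[_GAM] + cg) if cg > 0.0 else 0.0
    dy[4] = q_l * c25l / pv[_KP25L] + ret - q_co * c25v - cl25 * y[4]


@njit(cache=True)
def _jacobian(t, y, pv, pl, f0, J, ftmp, ypert):
    n = y.size
    for j in range(n):
        ypert[j] = y[j]
    for j in range(n):
        eps = 1e-6 * (abs(y[j]) if abs(y[j]) > 1.0 else 1.0)
        ypert[j] = y[j] + eps
        _rhs(t, ypert, pv, pl, ftmp)
        for i in range(n):
            J[i, j] = (ftmp[i] - f0[i]) / eps
        ypert[j] = y[j]


@njit(cache=True)
def _lu_factor(M, piv):
    """In-place LU with partial pivoting; returns False if singular."""
    n = M.shape[0]
    for k in range(n):
        pmax = abs(M[k, k])
        prow = k
        for i in range(k + 1, n):
            if abs(M[i, k]) > pmax:
                pmax = abs(M[i, k])
                prow = i
        if pmax == 0.0:
            return False
        piv[k] = prow
        if prow != k:
            for j in range(n):
                tmp = M[k, j]
                M[k, j] = M[prow, j]
                M[prow, j] = tmp
        inv = 1.0 / M[k, k]
        for i in range(k + 1, n):
            lik = M[i, k] * inv
            M[i, k] = lik
            for j in range(k + 1, n):
                M[i, j] -= lik * M[k, j]
    return True


@njit(cache=True)
def _lu_solve(M, piv, b):
    """Solve in place using the factorisation from :func:`_lu_factor`."""
    n = M.shape[0]
    for k in range(n):
        prow = piv[k]
        if prow != k:
            tmp = b[k]
            b[k] = b[prow]
            b[prow] = tmp
        for i in range(k + 1, n):
            b[i] -= M[i, k] * b[k]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= M[i, j] * b[j]
        b[i] = s / M[i, i]


@njit(cache=True)
def _newton(t_stage, a, rhs_const, z, pv, pl, LU, piv, f, res):
    """Chord Newton for z - a*f(t_stage, z) = rhs_const with frozen LU."""
    n = z.size
    nrm = 1.0
    for _ in range(15):
        _rhs(t_stage, z, pv, pl, f)
        for i in range(n):
            res[i] = z[i] - a * f[i] - rhs_const[i]
        _lu_solve(LU, piv, res)
        nrm = 0.0
        for i in range(n):
            z[i] -= res[i]
            sc = abs(z[i]) if abs(z[i]) > 1.0 else 1.0
            v = abs(res[i]) / sc
            if v > nrm:
                nrm = v
        if nrm < 1e-9:
            return True
        if not np.isfinite(nrm):
            return False
    return nrm < 1e-7


@njit(cache=True)
def _drive(y0, pv, pl, brk, dose_amt, obs_idx, dt0, dtmax, growth, out_conc, out_states):
    n = y0.size
    y = y0.copy()
    f0 = np.empty(n)
    f = np.empty(n)
    ftmp = np.empty(n)
    ypert = np.empty(n)
    res = np.empty(n)
    rhs_c = np.empty(n)
    z = np.empty(n)
    ynew = np.empty(n)
    J = np.empty((n, n))
    LU1 = np.empty((n, n))
    LU2 = np.empty((n, n))
    piv1 = np.empty(n, dtype=np.int64)
    piv2 = np.empty(n, dtype=np.int64)
    g = _GAMMA
    w1 = 1.0 / (g * (2.0 - g))
    w0 = (1.0 - g) ** 2 / (g * (2.0 - g))

    # breakpoint 0 (t = brk[0] = 0): record obs, then dose
    wt = pl[_W0] + pl[_SL] * brk[0]
    if obs_idx[0] >= 0:
        out_conc[obs_idx[0]] = y[4] / (pl[_FV] * wt)
        for i in range(n):
            out_states[obs_idx[0], i] = y[i]
    y[0] += dose_amt[0]

    h_base = dt0
    have_jac = False
    h_jac = -1.0
    for k in range(brk.size - 1):
        ta = brk[k]
        tb = brk[k + 1]
        if dose_amt[k] > 0.0:
            h_base = dt0  # restart step plan through the absorption transient
            have_jac = False
        t = ta
        while t < tb - 1e-9:
            h = h_base if h_base < tb - t else tb - t
            _rhs(t, y, pv, pl, f0)
            attempts = 0
            while True:
                if not have_jac or h != h_jac:
                    if not have_jac:
                        _jacobian(t, y, pv, pl, f0, J, ftmp, ypert)
                        have_jac = True
                    a1 = 0.5 * g * h
                    a2 = (1.0 - g) / (2.0 - g) * h
                    for i in range(n):
                        for j in range(n):
                            LU1[i, j] = -a1 * J[i, j]
                            LU2[i, j] = -a2 * J[i, j]
                        LU1[i, i] += 1.0
                        LU2[i, i] += 1.0
                    ok = _lu_factor(LU1, piv1) and _lu_factor(LU2, piv2)
                    h_jac = h
                else:
                    a1 = 0.5 * g * h
                    a2 = (1.0 - g) / (2.0 - g) * h
                    ok = True
                if ok:
                    # TR stage to t + g*h
                    for i in range(n):
                        rhs_c[i] = y[i] + a1 * f0[i]
                        z[i] = y[i] + g * h * f0[i]
                    ok = _newton(t + g * h, a1, rhs_c, z, pv, pl, LU1, piv1, f, res)
                if ok:
                    # BDF2 stage to t + h
                    for i in range(n):
                        rhs_c[i] = w1 * z[i] - w0 * y[i]
                        ynew[i] = z[i]
                    ok = _newton(t + h, a2, rhs_c, ynew, pv, pl, LU2, piv2, f, res)
                if ok:
                    break
                attempts += 1
                if attempts > 8:
                    return False
                h *= 0.25
                have_jac = False
            for i in range(n):
                # amounts are physically non-negative; clip the small
                # undershoot a stiff decay can leave on a large step
                y[i] = ynew[i] if ynew[i] > 0.0 else 0.0
            t += h
            h_next = h_base * growth
            h_base = h_next if h_next < dtmax else dtmax
        wt = pl[_W0] + pl[_SL] * tb
        if obs_idx[k + 1] >= 0:
            out_conc[obs_idx[k + 1]] = y[4] / (pl[_FV] * wt)
            for i in range(n):
                out_states[obs_idx[k + 1], i] = y[i]
        y[0] += dose_amt[k + 1]
    return True


def integrate_fast(
    p: PbpkParameters,
    phys,
    doses,
    obs_times: np.ndarray,
    y0: np.ndarray,
    dt0: float = 1.5,
    dtmax: float = 60.0,
    growth: float = 2.5,
    return_states: bool = False,
):
    """Python wrapper: build event tables, run the compiled driver.

    Observation times must be unique; an observation coinciding with a
    dose time is recorded before the dose is applied (pre-dose sample).
    """
    pv = _param_vector(p)
    pl = _plan_vector(phys)
    obs_times = np.asarray(obs_times, dtype=np.float64)
    dose_times = np.array([d.time_h for d in doses], dtype=np.float64)
    dose_amts = np.array([d.amount_nmol for d in doses], dtype=np.float64)
    order = np.argsort(dose_times, kind="stable")
    dose_times, dose_amts = dose_times[order], dose_amts[order]

    brk = np.union1d(np.union1d(dose_times, obs_times), np.array([0.0]))
    dose_amt = np.zeros(brk.size)
    idx = np.searchsorted(brk, dose_times)
    for i, amt in zip(idx, dose_amts):
        dose_amt[i] += amt
    obs_idx = np.full(brk.size, -1, dtype=np.int64)
    obs_idx[np.searchsorted(brk, obs_times)] = np.arange(obs_times.size)

    out_conc = np.empty(obs_times.size)
    out_states = np.empty((obs_times.size, y0.size))
    ok = _drive(
        np.asarray(y0, dtype=np.float64), pv, pl, brk, dose_amt, obs_idx,
        dt0, dtmax, growth, out_conc, out_states,
    )
    if not ok:
        raise SolverError(
            "TR-BDF2 Newton iteration failed to converge (after step refinement); "
            f"parameters clmax={p.clmax:.4g}, c50={p.c50:.4g}"
        )
    if return_states:
        return out_conc, out_states
    return out_conc
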