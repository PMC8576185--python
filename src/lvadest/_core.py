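"""Jitted fixed-step integration core of the closed-loop 0D model.

The circulation, four cardiac chambers, carotid baroreflex (with pure
efferent delays held in ring buffers) and the pump are advanced together by
classical RK4 at a fixed step that divides the output grid exactly.  The
fixed step keeps runs bit-deterministic and makes the neural delays exact;
a 30 s run takes ~0.1 s once compiled.

Parameter packing: the Python layer (cvs0d) assembles a flat float64 vector
whose layout is defined by ``PARAM_NAMES`` below; index constants ``I_*``
are generated from the same list, so the two can never drift apart.
"""

import numpy as np
from numba import njit

PARAM_NAMES = (
    # systemic arteries (branch split toward the two peripheral beds)
    "c_sa", "v0_sa", "r_sasp", "l_sasp", "r_saep", "l_saep",
    # peripheral and venous systemic compartments
    "c_sp", "v0_sp", "c_ep", "v0_ep",
    "c_sv", "r_sv", "c_ev", "r_ev",
    # pulmonary compartments
    "c_pa", "v0_pa", "r_pa", "l_pa",
    "c_pp", "v0_pp", "r_pp",
    "c_pv", "v0_pv", "r_pv",
    # atria and ventricles
    "c_la", "v0_la", "r_la", "c_ra", "v0_ra", "r_ra",
    "p0_lv", "ke_lv", "v0_lv", "kr_lv",
    "p0_rv", "ke_rv", "v0_rv", "kr_rv",
    # cardiac timing
    "tsys0", "ksys", "t0",
    "v_total",
    # baroreflex afferent + efferent statics
    "tau_p", "tau_zp", "f_min", "f_max", "p_n", "k_a",
    "f_es_inf", "f_es_0", "k_es", "f_es_min",
    "f_ev_0", "f_ev_inf", "f_cs_0", "k_ev",
    # effectors: gain, time constant, delay, offset
    "g_emaxlv", "tau_emaxlv", "d_emaxlv", "emax_lv0",
    "g_emaxrv", "tau_emaxrv", "d_emaxrv", "emax_rv0",
    "g_rsp", "tau_rsp", "d_rsp", "rsp0",
    "g_rep", "tau_rep", "d_rep", "rep0",
    "g_vusv", "tau_vusv", "d_vusv", "vusv0",
    "g_vuev", "tau_vuev", "d_vuev", "vuev0",
    "g_ts", "tau_ts", "d_ts",
    "g_tv", "tau_tv", "d_tv",
)

for _i, _name in enumerate(PARAM_NAMES):
    globals()["I_" + _name.upper()] = _i
N_PARAMS = len(PARAM_NAMES)

# state layout
STATE_NAMES = (
    "v_sa", "v_sp", "v_ep", "v_sv", "v_ev", "v_pa", "v_pp", "v_pv",
    "v_la", "v_lv", "v_ra", "v_rv",
    "q_sasp", "q_saep", "q_pa",
    "p_cs",
    "x_elv", "x_erv", "x_rsp", "x_rep", "x_vusv", "x_vuev", "x_ts", "x_tv",
    "xi",
)
N_STATES = len(STATE_NAMES)

# auxiliary output layout (per evaluated instant)
AUX_NAMES = ("p_sa", "p_pa", "p_lv", "v_lv", "q_av", "q_pump", "p_pv", "v_tot",
             "period")
N_AUX = len(AUX_NAMES)

_MIN_PERIOD = 0.3
_MAX_PERIOD = 2.0
_MIN_ELASTANCE = 0.02
_MIN_R_PER = 0.05


@njit(cache=True)
def _pulsed_speed(t, rpm_set, pulse_on, anchor):
    if not pulse_on:
        return rpm_set
    phase = (t - anchor) % 2.0
    if phase < 0.15:
        return rpm_set - 2000.0
    if phase < 0.35:
        return rpm_set + 2000.0
    return rpm_set


@njit(cache=True)
def _bilinear(speeds, dps, flows, rpm, dp):
    """Bilinear table lookup; dp clamped to the table domain."""
    if dp < dps[0]:
        dp = dps[0]
    elif dp > dps[-1]:
        dp = dps[-1]
    # uniform-ish grids: locate by scan (grids are short)
    i = np.searchsorted(speeds, rpm) - 1
    if i < 0:
        i = 0
    elif i > speeds.size - 2:
        i = speeds.size - 2
    j = np.searchsorted(dps, dp) - 1
    if j < 0:
        j = 0
    elif j > dps.size - 2:
        j = dps.size - 2
    ts = (rpm - speeds[i]) / (speeds[i + 1] - speeds[i])
    td = (dp - dps[j]) / (dps[j + 1] - dps[j])
    return ((1 - ts) * (1 - td) * flows[i, j]
            + ts * (1 - td) * flows[i + 1, j]
            + (1 - ts) * td * flows[i, j + 1]
            + ts * td * flows[i + 1, j + 1])


@njit(cache=True)
def _firing(p_cs, pp):
    """Afferent firing and efferent sympathetic/vagal activities."""
    z = (p_cs - pp[I_P_N]) / pp[I_K_A]
    if z > 50.0:
        z = 50.0
    elif z < -50.0:
        z = -50.0
    e = np.exp(z)
    f_cs = (pp[I_F_MIN] + pp[I_F_MAX] * e) / (1.0 + e)
    f_es = pp[I_F_ES_INF] + (pp[I_F_ES_0] - pp[I_F_ES_INF]) * np.exp(
        -pp[I_K_ES] * f_cs)
    z2 = (f_cs - pp[I_F_CS_0]) / pp[I_K_EV]
    if z2 > 50.0:
        z2 = 50.0
    elif z2 < -50.0:
        z2 = -50.0
    e2 = np.exp(z2)
    f_ev = (pp[I_F_EV_0] + pp[I_F_EV_INF] * e2) / (1.0 + e2)
    return f_es, f_ev


@njit(cache=True)
def _drive(f_es, f_es_min):
    d = f_es - f_es_min
    if d < 0.0:
        d = 0.0
    return np.log(1.0 + d)


@njit(cache=True)
def _rhs(t, y, pp, spd, dps, flw, pump_on, rpm_set, pulse_on, anchor,
         fes_d_e, fes_d_r, fes_d_vu, fes_d_ts, fev_d_tv,
         t_onset, t_beat, tsys, dy, aux):
    # pressures from volumes (Eq. V = C*P + V0)
    p_sa = (y[0] - pp[I_V0_SA]) / pp[I_C_SA]
    p_sp = (y[1] - pp[I_V0_SP]) / pp[I_C_SP]
    p_ep = (y[2] - pp[I_V0_EP]) / pp[I_C_EP]
    vu_sv = pp[I_VUSV0] + y[20]
    vu_ev = pp[I_VUEV0] + y[21]
    p_sv = (y[3] - vu_sv) / pp[I_C_SV]
    p_ev = (y[4] - vu_ev) / pp[I_C_EV]
    p_pa = (y[5] - pp[I_V0_PA]) / pp[I_C_PA]
    p_pp = (y[6] - pp[I_V0_PP]) / pp[I_C_PP]
    p_pv = (y[7] - pp[I_V0_PV]) / pp[I_C_PV]
    p_la = (y[8] - pp[I_V0_LA]) / pp[I_C_LA]
    p_ra = (y[10] - pp[I_V0_RA]) / pp[I_C_RA]

    # ventricular activation
    u = t - t_onset
    phi = 0.0
    if 0.0 <= u < tsys:
        s = np.sin(np.pi * u / tsys)
        phi = s * s

    e_lv = pp[I_EMAX_LV0] + y[16]
    if e_lv < _MIN_ELASTANCE:
        e_lv = _MIN_ELASTANCE
    e_rv = pp[I_EMAX_RV0] + y[17]
    if e_rv < _MIN_ELASTANCE:
        e_rv = _MIN_ELASTANCE

    # left ventricle: isovolumic pressure, viscous loss, aortic valve, pump
    v_lv = y[9]
    p_max_lv = (phi * e_lv * (v_lv - pp[I_V0_LV])
                + (1.0 - phi) * pp[I_P0_LV] * (np.exp(pp[I_KE_LV] * v_lv) - 1.0))
    r_lv = pp[I_KR_LV] * (p_max_lv if p_max_lv > 0.0 else 0.0) + 1e-6
    q_av = 0.0
    if p_max_lv > p_sa:
        q_av = (p_max_lv - p_sa) / r_lv
    q_pump = 0.0
    if pump_on:
        p_lv_est = p_max_lv - r_lv * q_av
        rpm = _pulsed_speed(t, rpm_set, pulse_on, anchor)
        q_pump = _bilinear(spd, dps, flw, rpm, p_sa - p_lv_est)
        if q_pump < 0.0:
            q_pump = 0.0
    p_lv = p_max_lv - r_lv * (q_av + q_pump)
    q_mi = 0.0
    if p_la > p_lv:
        q_mi = (p_la - p_lv) / pp[I_R_LA]

    # right ventricle and tricuspid/pulmonary valves
    v_rv = y[11]
    p_max_rv = (phi * e_rv * (v_rv - pp[I_V0_RV])
                + (1.0 - phi) * pp[I_P0_RV] * (np.exp(pp[I_KE_RV] * v_rv) - 1.0))
    r_rv = pp[I_KR_RV] * (p_max_rv if p_max_rv > 0.0 else 0.0) + 1e-6
    q_po = 0.0
    if p_max_rv > p_pa:
        q_po = (p_max_rv - p_pa) / r_rv
    p_rv = p_max_rv - r_rv * q_po
    q_tri = 0.0
    if p_ra > p_rv:
        q_tri = (p_ra - p_rv) / pp[I_R_RA]

    # controlled peripheral resistances
    r_sp = pp[I_RSP0] + y[18]
    if r_sp < _MIN_R_PER:
        r_sp = _MIN_R_PER
    r_ep = pp[I_REP0] + y[19]
    if r_ep < _MIN_R_PER:
        r_ep = _MIN_R_PER

    q_sp_out = (p_sp - p_sv) / r_sp
    q_ep_out = (p_ep - p_ev) / r_ep
    q_sv = (p_sv - p_ra) / pp[I_R_SV]
    q_ev = (p_ev - p_ra) / pp[I_R_EV]
    q_pp = (p_pp - p_pv) / pp[I_R_PP]
    q_pv = (p_pv - p_la) / pp[I_R_PV]

    # volumes (mass conservation) and inertial flows (momentum)
    dy[0] = q_av + q_pump - y[12] - y[13]
    dy[1] = y[12] - q_sp_out
    dy[2] = y[13] - q_ep_out
    dy[3] = q_sp_out - q_sv
    dy[4] = q_ep_out - q_ev
    dy[5] = q_po - y[14]
    dy[6] = y[14] - q_pp
    dy[7] = q_pp - q_pv
    dy[8] = q_pv - q_mi
    dy[9] = q_mi - q_av - q_pump
    dy[10] = q_sv + q_ev - q_tri
    dy[11] = q_tri - q_po
    dy[12] = (p_sa - p_sp - pp[I_R_SASP] * y[12]) / pp[I_L_SASP]
    dy[13] = (p_sa - p_ep - pp[I_R_SAEP] * y[13]) / pp[I_L_SAEP]
    dy[14] = (p_pa - p_pp - pp[I_R_PA] * y[14]) / pp[I_L_PA]

    # carotid afferent filter (uses dP_sa/dt = dV_sa/dt / C_sa)
    dp_sa = dy[0] / pp[I_C_SA]
    dy[15] = (p_sa + pp[I_TAU_ZP] * dp_sa - y[15]) / pp[I_TAU_P]

    # effector first-order dynamics toward delayed static characteristics
    fmin = pp[I_F_ES_MIN]
    dy[16] = (pp[I_G_EMAXLV] * _drive(fes_d_e, fmin) - y[16]) / pp[I_TAU_EMAXLV]
    dy[17] = (pp[I_G_EMAXRV] * _drive(fes_d_e, fmin) - y[17]) / pp[I_TAU_EMAXRV]
    dy[18] = (pp[I_G_RSP] * _drive(fes_d_r, fmin) - y[18]) / pp[I_TAU_RSP]
    dy[19] = (pp[I_G_REP] * _drive(fes_d_r, fmin) - y[19]) / pp[I_TAU_REP]
    dy[20] = (pp[I_G_VUSV] * _drive(fes_d_vu, fmin) - y[20]) / pp[I_TAU_VUSV]
    dy[21] = (pp[I_G_VUEV] * _drive(fes_d_vu, fmin) - y[21]) / pp[I_TAU_VUEV]
    dy[22] = (pp[I_G_TS] * _drive(fes_d_ts, fmin) - y[22]) / pp[I_TAU_TS]
    dy[23] = (pp[I_G_TV] * fev_d_tv - y[23]) / pp[I_TAU_TV]

    # cardiac phase clock (instantaneous regulated period)
    period = pp[I_T0] + y[22] + y[23]
    if period < _MIN_PERIOD:
        period = _MIN_PERIOD
    elif period > _MAX_PERIOD:
        period = _MAX_PERIOD
    dy[24] = 1.0 / period

    aux[0] = p_sa
    aux[1] = p_pa
    aux[2] = p_lv
    aux[3] = v_lv
    aux[4] = q_av
    aux[5] = q_pump
    aux[6] = p_pv
    v_tot = 0.0
    for i in range(12):
        v_tot += y[i]
    aux[7] = v_tot
    aux[8] = period


@njit(cache=True)
def integrate(pp, y0, spd, dps, flw, pump_on, rpm_set, pulse_on, anchor,
              T, N, n_sub):
    """Advance the full model over (0, T); sample N+1 uniform output points.

    Returns (out, onsets, n_onsets, ok) where ``out`` is (N+1, N_AUX).
    """
    dt = T / N / n_sub
    n_steps = N * n_sub
    y = y0.copy()
    dy = np.empty(N_STATES)
    aux = np.empty(N_AUX)
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    ytmp = np.empty(N_STATES)

    fes_buf = np.empty(n_steps + 1)
    fev_buf = np.empty(n_steps + 1)
    f_es, f_ev = _firing(y[15], pp)
    fes_buf[0] = f_es
    fev_buf[0] = f_ev

    d_e = int(round(pp[I_D_EMAXLV] / dt))
    d_r = int(round(pp[I_D_RSP] / dt))
    d_vu = int(round(pp[I_D_VUSV] / dt))
    d_ts = int(round(pp[I_D_TS] / dt))
    d_tv = int(round(pp[I_D_TV] / dt))

    out = np.empty((N + 1, N_AUX))
    onsets = np.empty(256)
    n_onsets = 0

    # per-beat bookkeeping
    t_onset = 0.0
    period = pp[I_T0] + y[22] + y[23]
    if period < _MIN_PERIOD:
        period = _MIN_PERIOD
    elif period > _MAX_PERIOD:
        period = _MAX_PERIOD
    t_beat = period
    tsys = pp[I_TSYS0] - pp[I_KSYS] / t_beat
    onsets[0] = 0.0
    n_onsets = 1

    # record initial sample
    _rhs(0.0, y, pp, spd, dps, flw, pump_on, rpm_set, pulse_on, anchor,
         fes_buf[0], fes_buf[0], fes_buf[0], fes_buf[0], fev_buf[0],
         t_onset, t_beat, tsys, dy, aux)
    out[0, :] = aux

    ok = True
    for step in range(n_steps):
        t = step * dt
        i_e = step - d_e
        if i_e < 0:
            i_e = 0
        i_r = step - d_r
        if i_r < 0:
            i_r = 0
        i_vu = step - d_vu
        if i_vu < 0:
            i_vu = 0
        i_ts = step - d_ts
        if i_ts < 0:
            i_ts = 0
        i_tv = step - d_tv
        if i_tv < 0:
            i_tv = 0
        fe = fes_buf[i_e]
        fr = fes_buf[i_r]
        fvu = fes_buf[i_vu]
        fts = fes_buf[i_ts]
        ftv = fev_buf[i_tv]

        _rhs(t, y, pp, spd, dps, flw, pump_on, rpm_set, pulse_on, anchor,
             fe, fr, fvu, fts, ftv, t_onset, t_beat, tsys, k1, aux)
        for i in range(N_STATES):
            ytmp[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(t + 0.5 * dt, ytmp, pp, spd, dps, flw, pump_on, rpm_set,
             pulse_on, anchor, fe, fr, fvu, fts, ftv,
             t_onset, t_beat, tsys, k2, aux)
        for i in range(N_STATES):
            ytmp[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(t + 0.5 * dt, ytmp, pp, spd, dps, flw, pump_on, rpm_set,
             pulse_on, anchor, fe, fr, fvu, fts, ftv,
             t_onset, t_beat, tsys, k3, aux)
        for i in range(N_STATES):
            ytmp[i] = y[i] + dt * k3[i]
        _rhs(t + dt, ytmp, pp, spd, dps, flw, pump_on, rpm_set,
             pulse_on, anchor, fe, fr, fvu, fts, ftv,
             t_onset, t_beat, tsys, k4, aux)
        for i in range(N_STATES):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # new beat when the phase clock wraps
        if y[24] >= 1.0:
            y[24] -= 1.0
            t_onset = t + dt
            period = pp[I_T0] + y[22] + y[23]
            if period < _MIN_PERIOD:
                period = _MIN_PERIOD
            elif period > _MAX_PERIOD:
                period = _MAX_PERIOD
            t_beat = period
            tsys = pp[I_TSYS0] - pp[I_KSYS] / t_beat
            if n_onsets < onsets.size:
                onsets[n_onsets] = t_onset
                n_onsets += 1

        f_es, f_ev = _firing(y[15], pp)
        fes_buf[step + 1] = f_es
        fev_buf[step + 1] = f_ev

        # sanity: finite state, nonnegative volumes
        for i in range(12):
            if not np.isfinite(y[i]) or y[i] < -1.0:
                ok = False
        if not ok:
            break

        if (step + 1) % n_sub == 0:
            m = (step + 1) // n_sub
            _rhs(t + dt, y, pp, spd, dps, flw, pump_on, rpm_set, pulse_on,
                 anchor, fes_buf[step + 1 - d_e if step + 1 > d_e else 0],
                 fes_buf[step + 1 - d_r if step + 1 > d_r else 0],
                 fes_buf[step + 1 - d_vu if step + 1 > d_vu else 0],
                 fes_buf[step + 1 - d_ts if step + 1 > d_ts else 0],
                 fev_buf[step + 1 - d_tv if step + 1 > d_tv else 0],
                 t_onset, t_beat, tsys, dy, aux)
            out[m, :] = aux

    return out, onsets[:n_onsets], n_onsets, ok
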