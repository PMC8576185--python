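"""Closed-loop 0D cardiovascular model with carotid baroreflex and LVAD.

Eight vascular compartments (systemic arteries; splanchnic/extrasplanchnic
peripheral and venous beds; pulmonary arteries, peripheral bed and veins),
four cardiac chambers (passive atria, time-varying-elastance ventricles with
ideal diode valves), carotid baroreflex afferent/efferent pathways, and an
apex-to-aorta continuous-flow pump.  Governing relations per compartment:

    dV/dt = Q_in - Q_out                      (mass)
    L dQ_out/dt = P_in - P_out - R Q_out      (momentum, large arteries only)
    V = C P + V0                              (pressure-volume)

The ventricular pressure blends an active elastance term with a passive
exponential end-diastolic curve through the activation waveform
``sin^2(pi t / T_sys)``; the baroreflex modulates peripheral resistances,
venous unstressed volumes, heart period and ventricular elastances through
delayed first-order effectors driven by sympathetic/vagal firing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from ._core import PARAM_NAMES, N_PARAMS
from .config import HeartFailureParams, ModelConfig, default_config
from .pump import PumpCurveTable, PumpSetting, default_pump_table

__all__ = [
    "SimulationFailure",
    "SimulationResult",
    "passive_ventricular_pressure",
    "instantaneous_elastance",
    "valve_flow",
    "compartment_volume",
    "compartment_pressure",
    "volume_derivative",
    "inertial_flow_derivative",
    "afferent_firing",
    "effector_target",
    "simulate_effector",
    "pack_params",
    "initial_state",
    "simulate",
]

log = logging.getLogger(__name__)


class SimulationFailure(RuntimeError):
    """Raised when the integrator produced a non-physical state."""


# ---------------------------------------------------------------------------
# elementary constitutive relations (mirrored inside the jitted kernel)
# ---------------------------------------------------------------------------

def passive_ventricular_pressure(V, k_E, P_0):
    """End-diastolic (passive) ventricular pressure P0*(exp(kE*V) - 1)."""
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("ventricular volume must be nonnegative")
    if not (k_E > 0 and P_0 > 0):
        raise ValueError("k_E and P_0 must be positive")
    out = P_0 * np.expm1(k_E * V)
    return out if out.ndim else float(out)

def instantaneous_elastance(phase, heart_period, E_max_eff,
                            Tsys0=0.5, ksys=0.075):
    """Activation u(t) in [0, 1] and the active elastance contribution.

    The activation is ``sin^2(pi*phase/T_sys)`` during systole
    (``T_sys = Tsys0 - ksys/heart_period``) and zero in diastole, so the
    ventricular pressure is the u-weighted blend of the active branch
    ``E_max_eff*(V - V0)`` and the passive curve.
    """
    phase = np.asarray(phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= heart_period):
        raise ValueError("phase must lie in [0, heart_period)")
    if not E_max_eff > 0:
        raise ValueError("E_max_eff must be positive")
    tsys = Tsys0 - ksys / heart_period
    u = np.where(phase < tsys, np.sin(np.pi * phase / tsys) ** 2, 0.0)
    if u.ndim:
        return u, u * E_max_eff
    return float(u), float(u * E_max_eff)

def valve_flow(p_in, p_out, R):
    """Ideal-diode valve in series with a resistance: max(dP, 0)/R."""
    if not R > 0:
        raise ValueError("valve resistance must be positive")
    dp = np.asarray(p_in, dtype=float) - np.asarray(p_out, dtype=float)
    out = np.maximum(dp, 0.0) / R
    return out if out.ndim else float(out)

def compartment_volume(P, C, V0):
    """V = C*P + V0."""
    return C * np.asarray(P, dtype=float) + V0

def compartment_pressure(V, C, V0):
    """P = (V - V0)/C."""
    return (np.asarray(V, dtype=float) - V0) / C

def volume_derivative(q_in, q_out):
    """dV/dt = Q_in - Q_out."""
    return np.asarray(q_in, dtype=float) - np.asarray(q_out, dtype=float)

def inertial_flow_derivative(p_in, p_out, R, L, Q):
    """L dQ/dt = P_in - P_out - R*Q, returned as dQ/dt."""
    if not L > 0:
        raise ValueError("inertance must be positive")
    return (p_in - p_out - R * Q) / L


# ---------------------------------------------------------------------------
# baroreflex pieces exposed for inspection/testing
# ---------------------------------------------------------------------------

def afferent_firing(p_cs, cfg: ModelConfig):
    """Carotid firing f_cs and efferent activities (f_es, f_ev)."""
    aff = cfg.baroreflex["afferent"]
    eff = cfg.baroreflex["efferent"]
    z = np.clip((np.asarray(p_cs, dtype=float) - aff["P_n"]) / aff["k_a"], -50, 50)
    e = np.exp(z)
    f_cs = (aff["f_min"] + aff["f_max"] * e) / (1.0 + e)
    f_es = eff["f_es_inf"] + (eff["f_es_0"] - eff["f_es_inf"]) * np.exp(
        -eff["k_es"] * f_cs)
    e2 = np.exp(np.clip((f_cs - eff["f_cs_0"]) / eff["k_ev"], -50, 50))
    f_ev = (eff["f_ev_0"] + eff["f_ev_inf"] * e2) / (1.0 + e2)
    return f_cs, f_es, f_ev

def effector_target(f_es, gain, f_es_min):
    """Saturating static characteristic sigma = G*ln(f_es - f_es_min + 1)."""
    return gain * np.log1p(np.maximum(np.asarray(f_es, dtype=float) - f_es_min, 0.0))

def simulate_effector(f_es_series, times, gain, tau, delay, f_es_min, x0=0.0):
    """Integrate one effector ODE dx/dt = (sigma(f_es(t - D)) - x)/tau alone.

    ``f_es_series`` is sampled on the uniform ``times`` grid; the pure delay
    is applied by index shift.  Used to examine open-loop effector responses.
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(f_es_series, dtype=float)
    dt = times[1] - times[0]
    dshift = int(round(delay / dt))
    x = np.empty_like(times)
    x[0] = x0
    for i in range(times.size - 1):
        fd = f[max(i - dshift, 0)]
        sigma = gain * math.log1p(max(fd - f_es_min, 0.0))
        x[i + 1] = x[i] + dt * (sigma - x[i]) / tau
    return x


# ---------------------------------------------------------------------------
# parameter packing and initial state
# ---------------------------------------------------------------------------

def pack_params(cfg: ModelConfig, hf: HeartFailureParams) -> np.ndarray:
    """Assemble the flat parameter vector consumed by the jitted kernel."""
    circ = cfg.circulation
    heart = cfg.heart
    aff = cfg.baroreflex["afferent"]
    eff = cfg.baroreflex["efferent"]
    effs = cfg.baroreflex["effectors"]

    drive = cfg.basal_sympathetic_drive()
    # split the arterial R/L branch toward the two peripheral beds in
    # proportion to their basal conductances (parallel combination = R_sa, L_sa)
    r_sp_basal = effs["r_sp"]["theta0"] + effs["r_sp"]["gain"] * drive
    r_ep_basal = effs["r_ep"]["theta0"] + effs["r_ep"]["gain"] * drive
    g_sp = 1.0 / r_sp_basal
    g_ep = 1.0 / r_ep_basal
    share_sp = g_sp / (g_sp + g_ep)
    share_ep = 1.0 - share_sp
    sa = circ["systemic_arteries"]

    vals = {
        "c_sa": sa["C"], "v0_sa": sa["V0"],
        "r_sasp": sa["R"] / share_sp, "l_sasp": sa["L"] / share_sp,
        "r_saep": sa["R"] / share_ep, "l_saep": sa["L"] / share_ep,
        "c_sp": circ["splanchnic_peripheral"]["C"],
        "v0_sp": circ["splanchnic_peripheral"]["V0"],
        "c_ep": circ["extrasplanchnic_peripheral"]["C"],
        "v0_ep": circ["extrasplanchnic_peripheral"]["V0"],
        "c_sv": circ["splanchnic_venous"]["C"],
        "r_sv": circ["splanchnic_venous"]["R"],
        "c_ev": circ["extrasplanchnic_venous"]["C"],
        "r_ev": circ["extrasplanchnic_venous"]["R"],
        "c_pa": circ["pulmonary_arteries"]["C"],
        "v0_pa": circ["pulmonary_arteries"]["V0"],
        "r_pa": circ["pulmonary_arteries"]["R"],
        "l_pa": circ["pulmonary_arteries"]["L"],
        "c_pp": circ["pulmonary_peripheral"]["C"],
        "v0_pp": circ["pulmonary_peripheral"]["V0"],
        "r_pp": circ["pulmonary_peripheral"]["R"],
        "c_pv": circ["pulmonary_veins"]["C"],
        "v0_pv": circ["pulmonary_veins"]["V0"],
        "r_pv": circ["pulmonary_veins"]["R"],
        "c_la": heart["left_atrium"]["C"], "v0_la": heart["left_atrium"]["V0"],
        "r_la": heart["left_atrium"]["R"],
        "c_ra": heart["right_atrium"]["C"], "v0_ra": heart["right_atrium"]["V0"],
        "r_ra": heart["right_atrium"]["R"],
        "p0_lv": heart["left_ventricle"]["P0"], "ke_lv": hf.kE_lv,
        "v0_lv": heart["left_ventricle"]["V0"],
        "kr_lv": heart["left_ventricle"]["kR"],
        "p0_rv": heart["right_ventricle"]["P0"],
        "ke_rv": heart["right_ventricle"]["kE"],
        "v0_rv": heart["right_ventricle"]["V0"],
        "kr_rv": heart["right_ventricle"]["kR"],
        "tsys0": heart["timing"]["Tsys0"], "ksys": heart["timing"]["ksys"],
        "t0": heart["timing"]["T0"],
        "v_total": circ["total_volume"],
        "tau_p": aff["tau_p"], "tau_zp": aff["tau_zp"],
        "f_min": aff["f_min"], "f_max": aff["f_max"],
        "p_n": aff["P_n"], "k_a": aff["k_a"],
        "f_es_inf": eff["f_es_inf"], "f_es_0": eff["f_es_0"],
        "k_es": eff["k_es"], "f_es_min": eff["f_es_min"],
        "f_ev_0": eff["f_ev_0"], "f_ev_inf": eff["f_ev_inf"],
        "f_cs_0": eff["f_cs_0"], "k_ev": eff["k_ev"],
        "g_emaxlv": hf.G_Emaxlv, "tau_emaxlv": effs["emax_lv"]["tau"],
        "d_emaxlv": effs["emax_lv"]["delay"], "emax_lv0": hf.Emax_lv0,
        "g_emaxrv": effs["emax_rv"]["gain"], "tau_emaxrv": effs["emax_rv"]["tau"],
        "d_emaxrv": effs["emax_rv"]["delay"], "emax_rv0": effs["emax_rv"]["theta0"],
        "g_rsp": effs["r_sp"]["gain"], "tau_rsp": effs["r_sp"]["tau"],
        "d_rsp": effs["r_sp"]["delay"], "rsp0": effs["r_sp"]["theta0"],
        "g_rep": effs["r_ep"]["gain"], "tau_rep": effs["r_ep"]["tau"],
        "d_rep": effs["r_ep"]["delay"], "rep0": effs["r_ep"]["theta0"],
        "g_vusv": effs["vu_sv"]["gain"], "tau_vusv": effs["vu_sv"]["tau"],
        "d_vusv": effs["vu_sv"]["delay"], "vusv0": effs["vu_sv"]["theta0"],
        "g_vuev": effs["vu_ev"]["gain"], "tau_vuev": effs["vu_ev"]["tau"],
        "d_vuev": effs["vu_ev"]["delay"], "vuev0": effs["vu_ev"]["theta0"],
        "g_ts": effs["t_sym"]["gain"], "tau_ts": effs["t_sym"]["tau"],
        "d_ts": effs["t_sym"]["delay"],
        "g_tv": effs["t_vag"]["gain"], "tau_tv": effs["t_vag"]["tau"],
        "d_tv": effs["t_vag"]["delay"],
    }
    pp = np.empty(N_PARAMS)
    for i, name in enumerate(PARAM_NAMES):
        pp[i] = float(vals[name])
    return pp


def initial_state(cfg: ModelConfig, hf: HeartFailureParams,
                  pp: np.ndarray) -> np.ndarray:
    """Initial state: unstressed volumes plus compliant filling at nominal
    pressures, with the residual blood volume placed in the venous beds so
    the total matches exactly; effectors start at their basal targets, the
    LV elastance effector at the sampled operating elastance."""
    circ = cfg.circulation
    ip = cfg.init_pressures
    iv = cfg.init_volumes
    drive = cfg.basal_sympathetic_drive()
    effs = cfg.baroreflex["effectors"]
    f_ev_n = cfg.basal_f_ev()

    x_rsp = effs["r_sp"]["gain"] * drive
    x_rep = effs["r_ep"]["gain"] * drive
    x_vusv = effs["vu_sv"]["gain"] * drive
    x_vuev = effs["vu_ev"]["gain"] * drive
    x_ts = effs["t_sym"]["gain"] * drive
    x_tv = effs["t_vag"]["gain"] * f_ev_n
    x_erv = effs["emax_rv"]["gain"] * drive
    x_elv = hf.Emax_lv - hf.Emax_lv0

    def vol(comp, p):
        return circ[comp]["C"] * p + circ[comp].get("V0", 0.0)

    y = np.zeros(_core.N_STATES)
    y[0] = vol("systemic_arteries", ip["sa"])
    y[1] = vol("splanchnic_peripheral", ip["sp"])
    y[2] = vol("extrasplanchnic_peripheral", ip["ep"])
    y[5] = vol("pulmonary_arteries", ip["pa"])
    y[6] = vol("pulmonary_peripheral", ip["pp"])
    y[7] = vol("pulmonary_veins", ip["pv"])
    y[8] = cfg.heart["left_atrium"]["C"] * ip["la"] + cfg.heart["left_atrium"]["V0"]
    y[10] = cfg.heart["right_atrium"]["C"] * ip["ra"] + cfg.heart["right_atrium"]["V0"]
    y[9] = iv["lv"]
    y[11] = iv["rv"]

    vu_sv = effs["vu_sv"]["theta0"] + x_vusv
    vu_ev = effs["vu_ev"]["theta0"] + x_vuev
    assigned = y[:12].sum()
    residual = circ["total_volume"] - assigned - vu_sv - vu_ev
    c_sv = circ["splanchnic_venous"]["C"]
    c_ev = circ["extrasplanchnic_venous"]["C"]
    p_ven = residual / (c_sv + c_ev)
    y[3] = vu_sv + c_sv * p_ven
    y[4] = vu_ev + c_ev * p_ven

    # inertial flows start at rest; carotid filter at the initial SAP
    y[15] = ip["sa"]
    y[16] = x_elv
    y[17] = x_erv
    y[18] = x_rsp
    y[19] = x_rep
    y[20] = x_vusv
    y[21] = x_vuev
    y[22] = x_ts
    y[23] = x_tv
    return y


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Uniformly sampled output of one closed-loop run."""

    t: np.ndarray          # s, N+1 samples
    sap: np.ndarray        # systemic arterial pressure, mmHg
    pap: np.ndarray        # pulmonary arterial pressure, mmHg
    p_lv: np.ndarray       # LV pressure, mmHg
    v_lv: np.ndarray       # LV volume, ml
    q_av: np.ndarray       # aortic valve flow, ml/s
    q_pump: np.ndarray     # pump flow, ml/s
    p_pv: np.ndarray       # pulmonary venous pressure (PCWP surrogate), mmHg
    total_volume: np.ndarray
    heart_period: np.ndarray
    beat_onsets: np.ndarray
    hf: HeartFailureParams
    pump: PumpSetting
    T: float
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "sap": self.sap, "pap": self.pap,
            "p_lv": self.p_lv, "v_lv": self.v_lv,
            "q_av": self.q_av, "q_pump": self.q_pump,
            "p_pv": self.p_pv,
            "rpm": np.full(self.t.size, self.pump.rpm if self.pump.enabled else 0.0),
        })

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(hf: HeartFailureParams, pump: PumpSetting, T: float = 30.0,
             N: int = 2000, config: ModelConfig | None = None,
             table: PumpCurveTable | None = None,
             dt_max: float | None = None) -> SimulationResult:
    """Integrate the coupled model over (0, T) and resample onto the
    uniform grid t_m = m*T/N.  Deterministic for identical inputs."""
    if not T > 0:
        raise ValueError("T must be positive")
    if N % 2 != 0:
        raise ValueError("N must be even (the Fourier layer requires it)")
    cfg = config or default_config()
    tbl = table or default_pump_table()
    if pump.enabled:
        need_lo = pump.rpm - (2000.0 if pump.artificial_pulse else 0.0)
        need_hi = pump.rpm + (2000.0 if pump.artificial_pulse else 0.0)
        if need_lo < tbl.speeds[0] or need_hi > tbl.speeds[-1]:
            raise ValueError("pump table does not cover the modulated speed range")

    pp = pack_params(cfg, hf)
    y0 = initial_state(cfg, hf, pp)
    dt_target = dt_max if dt_max is not None else cfg.solver["dt_max"]
    n_sub = max(1, int(math.ceil((T / N) / dt_target)))

    out, onsets, n_onsets, ok = _core.integrate(
        pp, y0, tbl.speeds, tbl.dps, tbl.flows,
        pump.enabled, float(pump.rpm), pump.artificial_pulse,
        float(pump.pulse_anchor), float(T), int(N), n_sub)
    if not ok:
        raise SimulationFailure(
            f"non-physical state (hf={hf}, rpm={pump.rpm}); run discarded")

    t = np.arange(N + 1) * (T / N)
    res = SimulationResult(
        t=t, sap=out[:, 0].copy(), pap=out[:, 1].copy(),
        p_lv=out[:, 2].copy(), v_lv=out[:, 3].copy(),
        q_av=out[:, 4].copy(), q_pump=out[:, 5].copy(),
        p_pv=out[:, 6].copy(), total_volume=out[:, 7].copy(),
        heart_period=out[:, 8].copy(), beat_onsets=onsets.copy(),
        hf=hf, pump=pump, T=float(T), N=int(N))

    vtol = cfg.solver.get("volume_tol", 1e-3)
    v0 = res.total_volume[0]
    if np.max(np.abs(res.total_volume - v0)) > vtol * v0:
        raise SimulationFailure("blood volume conservation violated")
    if np.any(res.sap < 0) or np.any(res.pap < 0):
        raise SimulationFailure("negative arterial pressure")
    return res
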