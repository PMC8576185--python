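"""Estimator evaluation and hemodynamic closure.

Two reports mirror the study design: (i) label-space accuracy — per-parameter
min/max/mean/SD of exact and predicted values, absolute-error statistics
with a normal-approximation 95% CI, and the mean per-sample relative error;
(ii) closed-loop accuracy — the 0D model is re-solved with exact and with
predicted parameters for each test record and six clinical quantities
(LVEF, LVEDV, LVESV, LVEDP, LVESP, PCWP) are compared the same way.

Conventions: error = |predicted - exact| per sample; CI = mean +- 1.96 SD/sqrt(n);
relative error = mean over samples of |error|/exact (the per-sample
convention, not the ratio of means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import HeartFailureParams, ModelConfig, default_config
from .cvs0d import SimulationFailure, SimulationResult, simulate
from .pump import PumpCurveTable, PumpSetting, default_pump_table

__all__ = [
    "HemodynamicSummary",
    "error_report",
    "summarize_hemodynamics",
    "reconstruct_hemodynamics",
    "paired_hemodynamic_comparison",
    "format_report",
]

log = logging.getLogger(__name__)

HEMO_NAMES = ("LVEF", "LVEDV", "LVESV", "LVEDP", "LVESP", "PCWP")

STAT_ROWS = (
    "exact_mean", "exact_min", "exact_max", "exact_sd",
    "pred_mean", "pred_min", "pred_max", "pred_sd",
    "err_mean", "err_min", "err_max", "err_sd", "err_ci_min", "err_ci_max",
    "rel_err_mean",
)


@dataclass(frozen=True)
class HemodynamicSummary:
    """Clinical quantities extracted from a steady-state window."""

    LVEF: float    # %
    LVEDV: float   # ml
    LVESV: float   # ml
    LVEDP: float   # mmHg
    LVESP: float   # mmHg
    PCWP: float    # mmHg

    def __post_init__(self) -> None:
        if not 0 < self.LVESV < self.LVEDV:
            raise ValueError("need 0 < LVESV < LVEDV")
        ef = 100.0 * (self.LVEDV - self.LVESV) / self.LVEDV
        if abs(ef - self.LVEF) > 1e-6:
            raise ValueError("LVEF inconsistent with volumes")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in HEMO_NAMES])


def _stats_block(x: np.ndarray) -> dict:
    return {"mean": float(np.mean(x)), "min": float(np.min(x)),
            "max": float(np.max(x)), "sd": float(np.std(x, ddof=0))}


def error_report(exact, predicted, names=HeartFailureParams.NAMES
                 ) -> pd.DataFrame:
    """Per-parameter accuracy table (rows = statistics, columns = labels)."""
    exact = np.atleast_2d(np.asarray(exact, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if exact.shape != predicted.shape:
        raise ValueError("exact and predicted arrays must have equal shape")
    n = exact.shape[0]
    if n < 2:
        raise ValueError("need at least two paired samples")
    if np.any(exact == 0):
        raise ValueError("relative error undefined for exact value 0")
    err = np.abs(predicted - exact)
    cols = {}
    for j, name in enumerate(names):
        e = _stats_block(exact[:, j])
        p = _stats_block(predicted[:, j])
        d = _stats_block(err[:, j])
        half = 1.96 * d["sd"] / np.sqrt(n)
        cols[name] = {
            "exact_mean": e["mean"], "exact_min": e["min"],
            "exact_max": e["max"], "exact_sd": e["sd"],
            "pred_mean": p["mean"], "pred_min": p["min"],
            "pred_max": p["max"], "pred_sd": p["sd"],
            "err_mean": d["mean"], "err_min": d["min"],
            "err_max": d["max"], "err_sd": d["sd"],
            "err_ci_min": d["mean"] - half, "err_ci_max": d["mean"] + half,
            "rel_err_mean": float(np.mean(err[:, j] / exact[:, j])),
        }
    return pd.DataFrame(cols).reindex(list(STAT_ROWS))


def summarize_hemodynamics(sim: SimulationResult,
                           window: float = 5.0) -> HemodynamicSummary:
    """Extract the clinical summary from the final steady-state window.

    LVEDV/LVESV are the LV-volume extremes over the last ``window`` seconds
    (covering several cardiac and artificial-pulse cycles), LVEDP the LV
    pressure at the LVEDV instant, LVESP the peak LV pressure, and PCWP the
    time-averaged pulmonary venous pressure.
    """
    m = sim.t >= sim.T - window
    v = sim.v_lv[m]
    p = sim.p_lv[m]
    i_ed = int(np.argmax(v))
    edv = float(v[i_ed])
    esv = float(np.min(v))
    return HemodynamicSummary(
        LVEF=100.0 * (edv - esv) / edv,
        LVEDV=edv,
        LVESV=esv,
        LVEDP=float(p[i_ed]),
        LVESP=float(np.max(p)),
        PCWP=float(np.mean(sim.p_pv[m])),
    )


def reconstruct_hemodynamics(hf: HeartFailureParams, pump: PumpSetting,
                             config: ModelConfig | None = None,
                             table: PumpCurveTable | None = None,
                             T: float = 30.0, N: int = 2000,
                             window: float = 5.0) -> HemodynamicSummary:
    """Solve the 0D model for the given parameters and summarize it."""
    sim = simulate(hf, pump, T=T, N=N, config=config, table=table)
    return summarize_hemodynamics(sim, window=window)


def paired_hemodynamic_comparison(exact_labels, predicted_labels, speeds,
                                  config: ModelConfig | None = None,
                                  table: PumpCurveTable | None = None,
                                  T: float = 30.0, N: int = 2000,
                                  artificial_pulse: bool = True):
    """Re-solve the model with exact and with predicted parameters for each
    record and compare the six clinical quantities.

    Returns (report, n_failed); records whose either run fails are excluded
    from the statistics with a logged count.
    """
    cfg = config or default_config()
    tbl = table or default_pump_table()
    exact_labels = np.atleast_2d(exact_labels)
    predicted_labels = np.atleast_2d(predicted_labels)
    speeds = np.asarray(speeds, dtype=float)
    he, hp = [], []
    n_failed = 0
    for ye, yp, rpm in zip(exact_labels, predicted_labels, speeds):
        pump = PumpSetting(rpm=float(rpm), artificial_pulse=artificial_pulse)
        try:
            se = reconstruct_hemodynamics(
                HeartFailureParams.from_array(ye), pump, cfg, tbl, T, N)
            sp = reconstruct_hemodynamics(
                HeartFailureParams.from_array(yp), pump, cfg, tbl, T, N)
        except (SimulationFailure, ValueError) as exc:
            n_failed += 1
            log.warning("excluding record from hemodynamic comparison: %s", exc)
            continue
        he.append(se.as_array())
        hp.append(sp.as_array())
    if n_failed:
        log.warning("%d records excluded from hemodynamic comparison", n_failed)
    report = error_report(np.array(he), np.array(hp), names=HEMO_NAMES)
    return report, n_failed


def format_report(report: pd.DataFrame, title: str = "") -> str:
    """Plain-text rendering mirroring the study's table layout."""
    blocks = [("Exact", "exact"), ("Predicted", "pred"), ("Error", "err")]
    lines = []
    if title:
        lines.append(title)
    header = "{:<12s}".format("") + "".join(
        f"{c:>12s}" for c in report.columns)
    lines.append(header)
    for blk_name, prefix in blocks:
        lines.append(blk_name)
        for stat in ("mean", "min", "max", "sd", "ci_min", "ci_max"):
            row = f"{prefix}_{stat}"
            if row not in report.index:
                continue
            vals = "".join(f"{report.loc[row, c]:>12.4g}" for c in report.columns)
            lines.append(f"  {stat:<10s}" + vals)
    lines.append("Relative error")
    lines.append("  {:<10s}".format("mean") + "".join(
        f"{report.loc['rel_err_mean', c]:>12.4g}" for c in report.columns))
    return "\n".join(lines)
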