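"""Continuous-flow LVAD model: speed modulation and pressure-flow lookup.

The pump is a pressure-controlled flow generator connected LV apex ->
systemic arteries.  Its flow is read from a tabulated H-Q characteristic
(bilinear interpolation in speed x differential pressure), and the set speed
is periodically modulated by the "artificial pulse": every 2 s the speed
drops by 2,000 RPM for 0.15 s and then rises to 2,000 RPM above the set
speed for the following 0.2 s, after which it returns to the set speed.
The pulse cycle is anchored to wall-clock time and is asynchronous with the
heartbeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "PumpSetting",
    "PumpCurveTable",
    "instantaneous_speed",
    "default_pump_table",
]

log = logging.getLogger(__name__)

PULSE_PERIOD = 2.0      # s
PULSE_DROP = 2000.0     # RPM below set speed during the first phase
PULSE_RISE = 4000.0     # RPM added back (relative to the dropped level)
PULSE_T_DROP = 0.15     # s
PULSE_T_RISE = 0.20     # s

SPEED_RANGE = (4000.0, 6000.0)  # clinical operating grid of the set speed

_ML_S_PER_L_MIN = 1000.0 / 60.0


@dataclass(frozen=True)
class PumpSetting:
    """Pump configuration: set speed, artificial pulse flag, pulse anchor."""

    rpm: float
    artificial_pulse: bool = True
    pulse_anchor: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and not (SPEED_RANGE[0] <= self.rpm <= SPEED_RANGE[1]):
            raise ValueError(
                f"set speed {self.rpm} RPM outside operating range {SPEED_RANGE}"
            )
        if self.pulse_anchor < 0:
            raise ValueError("pulse anchor must be nonnegative")

    @classmethod
    def off(cls) -> "PumpSetting":
        """No mechanical assistance (pump flow identically zero)."""
        return cls(rpm=SPEED_RANGE[0], artificial_pulse=False, enabled=False)


def instantaneous_speed(t: float | np.ndarray, setting: PumpSetting):
    """Pump speed at time ``t`` (s), including the artificial pulse.

    Phase p = (t - anchor) mod 2 s: p in [0, 0.15) -> rpm - 2000;
    p in [0.15, 0.35) -> rpm + 2000; otherwise the set speed.
    """
    t = np.asarray(t, dtype=float)
    speed = np.full(t.shape, float(setting.rpm))
    if setting.artificial_pulse:
        phase = np.mod(t - setting.pulse_anchor, PULSE_PERIOD)
        speed = np.where(phase < PULSE_T_DROP, setting.rpm - PULSE_DROP, speed)
        in_rise = (phase >= PULSE_T_DROP) & (phase < PULSE_T_DROP + PULSE_T_RISE)
        speed = np.where(in_rise, setting.rpm - PULSE_DROP + PULSE_RISE, speed)
    return speed if speed.ndim else float(speed)


class PumpCurveTable:
    """Tabulated H-Q characteristic with bilinear interpolation.

    Rows are rotational speeds (RPM), columns differential pressures
    ``dP = P_outlet - P_inlet`` (mmHg), values flow in ml/s.  Queries outside
    the tabulated dP domain are clamped to the edge columns (with a logged
    warning); speeds outside the tabulated domain are an error, since the
    table must cover the set-speed grid extended by the pulse amplitude.
    """

    def __init__(self, speeds, dps, flows_ml_s):
        speeds = np.asarray(speeds, dtype=float)
        dps = np.asarray(dps, dtype=float)
        flows = np.asarray(flows_ml_s, dtype=float)
        if flows.shape != (speeds.size, dps.size):
            raise ValueError("flow table shape does not match grids")
        if np.any(np.diff(speeds) <= 0) or np.any(np.diff(dps) <= 0):
            raise ValueError("speed and dP grids must be strictly increasing")
        if np.any(np.diff(flows, axis=1) > 1e-9):
            raise ValueError("flow must be non-increasing in dP at fixed speed")
        if np.any(np.diff(flows, axis=0) < -1e-9):
            raise ValueError("flow must be non-decreasing in speed at fixed dP")
        self.speeds = speeds
        self.dps = dps
        self.flows = flows
        self._interp = RegularGridInterpolator(
            (speeds, dps), flows, method="linear", bounds_error=False, fill_value=None
        )

    def __call__(self, rpm, delta_p):
        """Flow (ml/s) at rotational speed ``rpm`` and head ``delta_p``."""
        rpm = np.asarray(rpm, dtype=float)
        delta_p = np.asarray(delta_p, dtype=float)
        if np.any(rpm < self.speeds[0] - 1e-9) or np.any(rpm > self.speeds[-1] + 1e-9):
            raise ValueError(
                f"rpm outside table domain [{self.speeds[0]}, {self.speeds[-1]}]"
            )
        clipped = np.clip(delta_p, self.dps[0], self.dps[-1])
        if np.any(clipped != delta_p):
            log.warning("pump dP query outside table domain; clamped to edge")
        pts = np.stack(
            [np.broadcast_to(rpm, clipped.shape), clipped], axis=-1
        )
        out = self._interp(pts)
        return out if out.ndim else float(out)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_csv(cls, path_or_text) -> "PumpCurveTable":
        """Read a table CSV: header row of dP values, first column speeds.

        Flows may be given in l/min (declared by a ``# units: l/min`` header
        comment) and are converted to ml/s; otherwise ml/s is assumed.
        """
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
            text = Path(path_or_text).read_text()
        else:
            text = str(path_or_text)
        unit = "ml/s"
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "units:" in line:
                    unit = line.split("units:")[1].strip()
                continue
            rows.append(line.split(","))
        dps = np.array([float(v) for v in rows[0][1:]])
        speeds = np.array([float(r[0]) for r in rows[1:]])
        flows = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        if unit == "l/min":
            flows = flows * _ML_S_PER_L_MIN
        elif unit != "ml/s":
            raise ValueError(f"unknown flow unit {unit!r}")
        return cls(speeds, dps, flows)

    def to_csv(self, path: str | Path, unit: str = "l/min") -> None:
        flows = self.flows / _ML_S_PER_L_MIN if unit == "l/min" else self.flows
        lines = [f"# units: {unit}", "rpm," + ",".join(f"{d:g}" for d in self.dps)]
        for w, row in zip(self.speeds, flows):
            lines.append(f"{w:g}," + ",".join(f"{v:.6g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def default_pump_table() -> PumpCurveTable:
    """The packaged surrogate HM3-style centrifugal characteristic."""
    text = (
        resources.files("lvadest.data").joinpath("hmiii_surrogate_curve.csv").read_text()
    )
    return PumpCurveTable.from_csv(text)
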