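"""Model configuration: circulation, heart, baroreflex and solver constants.

All constants of the closed-loop circulation live in a versioned YAML file
shipped with the package (``data/ursino1998.yaml``); the code never hard-codes
them.  Units throughout: pressures mmHg, volumes ml, flows ml/s, resistances
mmHg*s/ml, compliances ml/mmHg, inertances mmHg*s^2/ml, times s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "HeartFailureParams",
    "ModelConfig",
    "default_config",
    "load_config",
]

_DATA_PACKAGE = "lvadest.data"
_DEFAULT_CONFIG = "ursino1998.yaml"


@dataclass(frozen=True)
class HeartFailureParams:
    """The four left-heart-failure parameters the estimator recovers.

    Emax_lv
        Operating end-systolic LV elastance at run start (mmHg/ml).
    Emax_lv0
        End-systolic LV elastance in the absence of baroregulation; the
        offset of the elastance effector (mmHg/ml).
    G_Emaxlv
        Maximum baroreceptor gain on the LV elastance effector
        (mmHg/ml per unit ln-transformed sympathetic firing).
    kE_lv
        Steepness of the end-diastolic (passive) pressure-volume curve (1/ml).
    """

    Emax_lv: float
    Emax_lv0: float
    G_Emaxlv: float
    kE_lv: float

    NAMES = ("Emax_lv", "Emax_lv0", "G_Emaxlv", "kE_lv")

    def __post_init__(self) -> None:
        for name in self.NAMES:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self):
        import numpy as np

        return np.array([self.Emax_lv, self.Emax_lv0, self.G_Emaxlv, self.kE_lv])

    @classmethod
    def from_array(cls, arr) -> "HeartFailureParams":
        return cls(*(float(v) for v in arr))


@dataclass
class ModelConfig:
    """Full parameter set of the 0D model, as loaded from YAML."""

    circulation: dict
    heart: dict
    baroreflex: dict
    hf_ranges: dict
    hf_healthy: dict
    solver: dict
    init_pressures: dict
    init_volumes: dict
    source: str = "builtin"

    # -- derived basal quantities ------------------------------------------

    def basal_f_cs(self) -> float:
        aff = self.baroreflex["afferent"]
        return 0.5 * (aff["f_min"] + aff["f_max"])

    def basal_f_es(self) -> float:
        eff = self.baroreflex["efferent"]
        f_cs = self.basal_f_cs()
        return eff["f_es_inf"] + (eff["f_es_0"] - eff["f_es_inf"]) * math.exp(
            -eff["k_es"] * f_cs
        )

    def basal_f_ev(self) -> float:
        eff = self.baroreflex["efferent"]
        f_cs = self.basal_f_cs()
        e = math.exp((f_cs - eff["f_cs_0"]) / eff["k_ev"])
        return (eff["f_ev_0"] + eff["f_ev_inf"] * e) / (1.0 + e)

    def basal_sympathetic_drive(self) -> float:
        """ln(f_es,n - f_es,min + 1) at the pressure setpoint."""
        eff = self.baroreflex["efferent"]
        return math.log1p(max(self.basal_f_es() - eff["f_es_min"], 0.0))

    def healthy_hf(self) -> HeartFailureParams:
        return HeartFailureParams(**self.hf_healthy)

    def hf_range_arrays(self):
        import numpy as np

        lo = np.array([self.hf_ranges[n][0] for n in HeartFailureParams.NAMES])
        hi = np.array([self.hf_ranges[n][1] for n in HeartFailureParams.NAMES])
        return lo, hi

    def validate(self) -> None:
        circ = self.circulation
        for name, comp in circ.items():
            if name == "total_volume":
                continue
            for key, val in comp.items():
                if key in ("R", "C", "L") and not val > 0:
                    raise ValueError(f"{name}.{key} must be positive")
                if key.startswith("V0") and val < 0:
                    raise ValueError(f"{name}.{key} must be nonnegative")
        for name, lim in self.hf_ranges.items():
            if not lim[0] < lim[1]:
                raise ValueError(f"degenerate range for {name}")
        timing = self.heart["timing"]
        if not timing["Tsys0"] < timing["T0"] + 1.0:
            raise ValueError("systolic duration law inconsistent with heart period")

    def to_dict(self) -> dict:
        return asdict(self)


def _from_mapping(raw: dict, source: str) -> ModelConfig:
    cfg = ModelConfig(
        circulation=raw["circulation"],
        heart=raw["heart"],
        baroreflex=raw["baroreflex"],
        hf_ranges=raw["hf_ranges"],
        hf_healthy=raw["hf_healthy"],
        solver=raw["solver"],
        init_pressures=raw["init_pressures"],
        init_volumes=raw["init_volumes"],
        source=source,
    )
    cfg.validate()
    return cfg


def default_config() -> ModelConfig:
    """Load the packaged circulation/baroreflex constant set."""
    text = resources.files(_DATA_PACKAGE).joinpath(_DEFAULT_CONFIG).read_text()
    return _from_mapping(yaml.safe_load(text), source=_DEFAULT_CONFIG)


def load_config(path: str | Path) -> ModelConfig:
    """Load a user-supplied YAML with the same schema as the packaged file."""
    path = Path(path)
    return _from_mapping(yaml.safe_load(path.read_text()), source=str(path))
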