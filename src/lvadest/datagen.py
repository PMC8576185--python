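"""Labelled-dataset generation: pump-speed sweep x random failure severities.

For each of ``n_speeds`` equally spaced set speeds, ``n_samples`` heart
failure parameter sets are drawn i.i.d. uniformly over their configured
ranges, the closed-loop model is integrated, and the Fourier-encoded
waveform features are stored together with the labels.  Seeding is
hierarchical (master seed -> per-(speed, sample, attempt) substream) so any
record can be regenerated in isolation and results are independent of
execution order.  Simulations that end in a non-physical state are dropped
and the draw resampled (bounded retries), keeping the record count exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import HeartFailureParams, ModelConfig, default_config
from .cvs0d import SimulationFailure, simulate
from .fourier import FourierSpec, build_feature_vector, feature_length
from .pump import PumpCurveTable, PumpSetting, default_pump_table

__all__ = [
    "DatasetConfig",
    "sample_parameters",
    "generate_arrays",
    "generate_dataset",
    "load_dataset",
    "export_csv",
    "PRESETS",
]

log = logging.getLogger(__name__)

_MAX_RETRIES = 20


@dataclass(frozen=True)
class DatasetConfig:
    """Sweep layout and encoding settings for one dataset."""

    n_speeds: int = 21
    speed_range: tuple = (4000.0, 6000.0)
    n_samples: int = 10_000
    T: float = 30.0
    N: int = 2000
    K: int = 50
    seed: int = 0
    artificial_pulse: bool = True

    def __post_init__(self) -> None:
        if self.n_speeds < 1 or self.n_samples < 1:
            raise ValueError("n_speeds and n_samples must be >= 1")
        if not self.speed_range[0] < self.speed_range[1]:
            raise ValueError("degenerate speed range")

    @property
    def speeds(self) -> np.ndarray:
        lo, hi = self.speed_range
        if self.n_speeds == 1:
            return np.array([0.5 * (lo + hi)])
        return np.linspace(lo, hi, self.n_speeds)

    @property
    def n_records(self) -> int:
        return self.n_speeds * self.n_samples

    @property
    def fourier_spec(self) -> FourierSpec:
        return FourierSpec(T=self.T, N=self.N, K=self.K)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speed_range"] = list(self.speed_range)
        return d


PRESETS = {
    "full": dict(n_speeds=21, n_samples=10_000),
    "small": dict(n_speeds=5, n_samples=500),
    "tiny": dict(n_speeds=2, n_samples=20),
}


def preset_config(name: str, seed: int = 0, **overrides) -> DatasetConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return DatasetConfig(seed=seed, **kw)


def sample_parameters(n: int, ranges: dict | None = None,
                      seed=None) -> np.ndarray:
    """Draw ``n`` heart-failure parameter sets, each coordinate i.i.d.
    uniform over its range.  Returns an (n, 4) array in the canonical
    (Emax_lv, Emax_lv0, G_Emaxlv, kE_lv) order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = default_config().hf_ranges
    lo = np.array([ranges[k][0] for k in HeartFailureParams.NAMES])
    hi = np.array([ranges[k][1] for k in HeartFailureParams.NAMES])
    if np.any(lo >= hi):
        raise ValueError("degenerate sampling range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return lo + (hi - lo) * rng.random((n, 4))


def _record_rng(master_seed: int, speed_idx: int, sample_idx: int,
                attempt: int) -> np.random.Generator:
    ss = np.random.SeedSequence([master_seed, speed_idx, sample_idx, attempt])
    return np.random.default_rng(ss)


def generate_arrays(cfg: DatasetConfig, model_config: ModelConfig | None = None,
                    table: PumpCurveTable | None = None, progress: bool = False):
    """Run the sweep in memory.

    Returns (features, labels, speeds, provenance, n_failures) where
    provenance rows are (speed_idx, sample_idx, attempt_used).
    """
    mc = model_config or default_config()
    tbl = table or default_pump_table()
    spec = cfg.fourier_spec
    nf = feature_length(cfg.K)
    n = cfg.n_records
    X = np.empty((n, nf))
    Y = np.empty((n, 4))
    spd = np.empty(n)
    prov = np.empty((n, 3), dtype=np.int64)
    n_failures = 0
    t_start = time.time()
    row = 0
    for si, rpm in enumerate(cfg.speeds):
        pump = PumpSetting(rpm=float(rpm), artificial_pulse=cfg.artificial_pulse)
        for ji in range(cfg.n_samples):
            for attempt in range(_MAX_RETRIES):
                rng = _record_rng(cfg.seed, si, ji, attempt)
                hf = HeartFailureParams.from_array(
                    sample_parameters(1, mc.hf_ranges, rng)[0])
                try:
                    sim = simulate(hf, pump, T=cfg.T, N=cfg.N,
                                   config=mc, table=tbl)
                except SimulationFailure as exc:
                    n_failures += 1
                    log.warning("resampling (speed %d sample %d attempt %d): %s",
                                si, ji, attempt, exc)
                    continue
                X[row] = build_feature_vector(sim, spec)
                Y[row] = hf.as_array()
                spd[row] = rpm
                prov[row] = (si, ji, attempt)
                break
            else:
                raise RuntimeError(
                    f"persistent simulation failure at speed {si} sample {ji}")
            row += 1
        if progress:
            done = (si + 1) * cfg.n_samples
            log.info("generated %d/%d records (%.1f s)", done, n,
                     time.time() - t_start)
    return X, Y, spd, prov, n_failures


def _config_hash(cfg: DatasetConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def generate_dataset(cfg: DatasetConfig, out_path: str | Path,
                     model_config: ModelConfig | None = None,
                     table: PumpCurveTable | None = None,
                     progress: bool = False) -> dict:
    """Run the sweep and persist features/labels/provenance to HDF5 plus a
    JSON manifest sidecar.  Returns the manifest."""
    out_path = Path(out_path)
    X, Y, spd, prov, n_failures = generate_arrays(
        cfg, model_config=model_config, table=table, progress=progress)
    with h5py.File(out_path, "w") as f:
        f.create_dataset("features", data=X)
        f.create_dataset("labels", data=Y)
        f.create_dataset("speeds", data=spd)
        f.create_dataset("provenance", data=prov)
        f.attrs["config"] = json.dumps(cfg.to_dict())
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_records": int(X.shape[0]),
        "n_failures_resampled": int(n_failures),
        "feature_length": int(X.shape[1]),
        "label_names": list(HeartFailureParams.NAMES),
        "data_sha256": hashlib.sha256(
            X.tobytes() + Y.tobytes() + spd.tobytes()).hexdigest(),
        "path": str(out_path),
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def load_dataset(path: str | Path):
    """Read back (features, labels, speeds, provenance, config)."""
    with h5py.File(path, "r") as f:
        X = f["features"][:]
        Y = f["labels"][:]
        spd = f["speeds"][:]
        prov = f["provenance"][:]
        cfg = DatasetConfig(**{
            k: tuple(v) if k == "speed_range" else v
            for k, v in json.loads(f.attrs["config"]).items()})
    return X, Y, spd, prov, cfg


def export_csv(h5_path: str | Path, csv_path: str | Path) -> None:
    """Mirror the HDF5 container as a flat CSV (one record per row)."""
    X, Y, spd, prov, cfg = load_dataset(h5_path)
    cols = {}
    for j in range(X.shape[1] - 1):
        cols[f"x{j}"] = X[:, j]
    cols["rpm"] = X[:, -1]
    for j, name in enumerate(HeartFailureParams.NAMES):
        cols[name] = Y[:, j]
    cols["speed_idx"] = prov[:, 0]
    cols["sample_idx"] = prov[:, 1]
    cols["attempt"] = prov[:, 2]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
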