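"""End-to-end pipeline: generate -> split -> train -> evaluate -> close loop.

Ties the modules together into one reproducible run with a JSON manifest
recording configuration, seeds, artifact paths and content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import ModelConfig, default_config
from .datagen import DatasetConfig, generate_dataset, load_dataset, preset_config
from .evaluation import error_report, format_report, paired_hemodynamic_comparison
from .mlp import (MLPSpec, TrainConfig, LabelScaler, predict, save_model,
                  split_dataset, train_mlp)
from .pump import default_pump_table

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    preset: str
    seed: int
    dataset_config: dict
    dataset_path: str
    dataset_hash: str
    model_path: str
    model_hash: str
    report_paths: dict
    n_failures_resampled: int
    n_hemo_excluded: int
    started: float
    finished: float
    version: str = __version__

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(preset: str = "tiny", seed: int = 0,
                 out_dir: str | Path = "runs/run0",
                 hidden=(64, 64), max_hemo_records: int | None = None,
                 model_config: ModelConfig | None = None,
                 overwrite: bool = False) -> RunManifest:
    """Execute the full study pipeline at the given preset scale.

    Stages: dataset generation, speed-stratified split, MLP training,
    label-space error report, and paired hemodynamic closure on the test
    set.  ``max_hemo_records`` caps the number of test records re-simulated
    for the closure report (None = all).
    """
    t0 = time.time()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    mc = model_config or default_config()
    tbl = default_pump_table()

    stage = "generate"
    try:
        dcfg = preset_config(preset, seed=seed)
        data_path = out / "dataset.h5"
        manifest = generate_dataset(dcfg, data_path, model_config=mc,
                                    table=tbl, progress=True)
        X, Y, speeds, prov, _ = load_dataset(data_path)

        stage = "split"
        tcfg = TrainConfig(seed=seed)
        itr, iva, ite = split_dataset(X.shape[0], tcfg, speeds=speeds)

        stage = "train"
        lo, hi = mc.hf_range_arrays()
        scaler = LabelScaler(lo, hi)
        spec = MLPSpec(input_size=X.shape[1], hidden=tuple(hidden))
        model = train_mlp(X[itr], Y[itr], X[iva], Y[iva], spec, tcfg,
                          scaler=scaler)
        model_dir = out / "model"
        save_model(model, model_dir)

        stage = "evaluate"
        Y_pred = predict(model, X[ite])
        rep1 = error_report(Y[ite], Y_pred)
        rep1.to_csv(out / "label_report.csv")
        (out / "label_report.txt").write_text(
            format_report(rep1, "Estimator accuracy on the test set"))

        stage = "hemodynamics"
        sel = np.arange(ite.size)
        if max_hemo_records is not None and ite.size > max_hemo_records:
            sel = np.random.default_rng(seed).choice(
                ite.size, max_hemo_records, replace=False)
        rep2, n_excluded = paired_hemodynamic_comparison(
            Y[ite][sel], Y_pred[sel], speeds[ite][sel],
            config=mc, table=tbl, T=dcfg.T, N=dcfg.N,
            artificial_pulse=dcfg.artificial_pulse)
        rep2.to_csv(out / "hemodynamic_report.csv")
        (out / "hemodynamic_report.txt").write_text(
            format_report(rep2, "Hemodynamic closure on the test set"))
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise

    run = RunManifest(
        preset=preset, seed=seed, dataset_config=dcfg.to_dict(),
        dataset_path=str(data_path), dataset_hash=manifest["data_sha256"],
        model_path=str(model_dir),
        model_hash=_file_hash(model_dir / "weights.npz"),
        report_paths={
            "label_report_csv": str(out / "label_report.csv"),
            "label_report_txt": str(out / "label_report.txt"),
            "hemodynamic_report_csv": str(out / "hemodynamic_report.csv"),
            "hemodynamic_report_txt": str(out / "hemodynamic_report.txt"),
        },
        n_failures_resampled=manifest["n_failures_resampled"],
        n_hemo_excluded=n_excluded,
        started=t0, finished=time.time())
    run.save(out / "manifest.json")
    return run
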