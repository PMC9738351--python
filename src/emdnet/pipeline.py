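"""Stage-wise pipeline orchestration with cached intermediates.

Four stages mirror the processing workflow: simulate (synthetic cohort)
-> preprocess (filter + segment) -> decompose (EMD tensors) ->
train_eval (cross-validated classifier).  Each stage writes its output
plus a manifest recording the input hash, the configuration and the
seed, and is skipped on re-run when nothing changed (unless forced), so
the slow EMD stage is computed once per configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .cnn import TrainConfig, default_model_spec, desk_scale_train_config
from .emd import N_IMF, SiftConfig, build_imf_tensor
from .evaluation import cross_validate, make_folds, save_reports
from .records import ClassLabel, EpochSet
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_preprocess", "run_decompose",
           "run_train_eval", "run_report"]


@dataclass
class RunConfig:
    """All stage parameters; defaults are the pipeline's published constants
    (256 Hz, 0.5-32 Hz, 5 s epochs, 50% overlap, 3 IMFs, Adam
    alpha=1e-2 / beta1=0.9 / beta2=0.999, 5 folds)."""

    target_fs: float = 256.0
    band_low: float = 0.5
    band_high: float = 32.0
    epoch_s: float = 5.0
    overlap: float = 0.5
    sift: SiftConfig = field(default_factory=SiftConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    fold_mode: str = "segment_level"
    k_folds: int = 5
    normalize: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "sift" in kwargs:
            kwargs["sift"] = SiftConfig(**kwargs["sift"])
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            syn.pop("profiles", None)
            kwargs["synthetic"] = SyntheticConfig(**syn)
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)

    def yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_is_current(manifest_path: Path, fingerprint: dict) -> bool:
    if not manifest_path.exists():
        return False
    try:
        old = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    return old.get("fingerprint") == fingerprint


def _write_manifest(manifest_path: Path, fingerprint: dict, extra: dict) -> None:
    manifest_path.write_text(
        json.dumps({"fingerprint": fingerprint, **extra}, indent=2, default=str)
    )


def run_simulate(cfg: RunConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Generate the synthetic cohort; writes recordings.h5 + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "recordings.h5"
    manifest_path = out_dir / "simulate.manifest.json"
    fingerprint = {"stage": "simulate", "config": cfg.synthetic.manifest()}
    if not force and out.exists() and _stage_is_current(manifest_path, fingerprint):
        logger.info("simulate: up to date, skipping")
        return out
    ds = generate_dataset(cfg.synthetic)
    if out.exists():
        out.unlink()
    for i, rec in enumerate(ds.recordings):
        eio.write_recording_h5(rec, out, group=f"rec_{i:03d}")
    _write_manifest(manifest_path, fingerprint, {"n_recordings": len(ds.recordings),
                                                 "generator": ds.manifest})
    return out


def run_preprocess(cfg: RunConfig, recordings: str | Path, out_dir: str | Path,
                   force: bool = False) -> Path:
    """Resample, band-pass and segment every recording into the epoch store."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = Path(recordings)
    out = out_dir / "epochs.h5"
    manifest_path = out_dir / "preprocess.manifest.json"
    fingerprint = {
        "stage": "preprocess",
        "input": _file_hash(recordings),
        "config": {k: getattr(cfg, k) for k in
                   ("target_fs", "band_low", "band_high", "epoch_s", "overlap")},
    }
    if not force and out.exists() and _stage_is_current(manifest_path, fingerprint):
        logger.info("preprocess: up to date, skipping")
        return out
    epochs = EpochSet()
    for rec in eio.read_dataset_h5(recordings):
        rec = eio.resample(rec, cfg.target_fs)
        rec = eio.bandpass(rec, cfg.band_low, cfg.band_high)
        epochs.extend(eio.segment_epochs(rec, cfg.epoch_s, cfg.overlap))
    eio.write_epochs_h5(epochs, out, manifest_csv=out_dir / "epochs.manifest.csv")
    _write_manifest(manifest_path, fingerprint, {"n_epochs": len(epochs)})
    return out


def run_decompose(cfg: RunConfig, epochs_path: str | Path, out_dir: str | Path,
                  force: bool = False) -> Path:
    """Per-channel EMD of every epoch into the (n, 19, 1280, 3) tensor store."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    epochs_path = Path(epochs_path)
    out = out_dir / "imf.h5"
    manifest_path = out_dir / "decompose.manifest.json"
    fingerprint = {
        "stage": "decompose",
        "input": _file_hash(epochs_path),
        "config": asdict(cfg.sift),
    }
    if not force and out.exists() and _stage_is_current(manifest_path, fingerprint):
        logger.info("decompose: up to date, skipping")
        return out
    epochs = eio.read_epochs_h5(epochs_path)
    tensors = np.empty((len(epochs), 19, 1280, N_IMF), dtype=np.float64)
    for i, ep in enumerate(epochs):
        tensors[i] = build_imf_tensor(ep, cfg.sift)
    with h5py.File(out, "w") as f:
        f.create_dataset("imf", data=tensors)
        f.create_dataset("label", data=epochs.labels)
        f.create_dataset("subject_id",
                         data=np.array([s.encode() for s in epochs.subject_ids]))
    _write_manifest(manifest_path, fingerprint, {"n_epochs": len(epochs)})
    return out


def run_train_eval(cfg: RunConfig, imf_path: str | Path, out_dir: str | Path,
                   force: bool = False) -> Path:
    """Cross-validated training/evaluation; writes metrics + fold reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    imf_path = Path(imf_path)
    out = out_dir / "metrics.json"
    manifest_path = out_dir / "train_eval.manifest.json"
    fingerprint = {
        "stage": "train_eval",
        "input": _file_hash(imf_path),
        "config": {**asdict(cfg.train), "fold_mode": cfg.fold_mode,
                   "k": cfg.k_folds, "normalize": cfg.normalize, "seed": cfg.seed},
    }
    if not force and out.exists() and _stage_is_current(manifest_path, fingerprint):
        logger.info("train_eval: up to date, skipping")
        return out
    with h5py.File(imf_path, "r") as f:
        tensors = f["imf"][()].astype(np.float32)
        labels = f["label"][()]
        subjects = [s.decode() for s in f["subject_id"][()]]
    plan = make_folds(labels, k=cfg.k_folds, mode=cfg.fold_mode, seed=cfg.seed,
                      subject_ids=subjects)
    reports, aggregate = cross_validate(
        tensors, labels, plan, train_config=cfg.train,
        normalize=cfg.normalize, seed=cfg.seed,
    )
    save_reports(reports, aggregate, out)
    rows = []
    for i, r in enumerate(reports):
        rows.append({"fold": i, "accuracy": r.accuracy,
                     **{f"micro_{k}": v for k, v in r.micro.items()},
                     **{f"macro_{k}": v for k, v in r.macro.items()}})
        pd.DataFrame(r.confusion,
                     index=[c.name for c in ClassLabel],
                     columns=[c.name for c in ClassLabel],
                     ).to_csv(out_dir / f"confusion_fold{i}.csv")
    pd.DataFrame(rows).to_csv(out_dir / "fold_metrics.csv", index=False)
    _write_manifest(manifest_path, fingerprint, {"aggregate": aggregate})
    return out


def run_report(run_dir: str | Path) -> str:
    """Render the stored fold reports as a human-readable metrics block."""
    run_dir = Path(run_dir)
    metrics = json.loads((run_dir / "metrics.json").read_text())
    agg = metrics["aggregate"]
    lines = [
        "Cross-validated classification metrics (mean over folds)",
        "-" * 56,
        f"folds:     {agg['n_folds']}",
        f"accuracy:  {agg['mean_accuracy'] * 100:.1f}%",
    ]
    for scheme in ("micro", "macro"):
        vals = " ".join(
            f"{m}={agg[f'mean_{scheme}_{m}'] * 100:.1f}%"
            for m in ("precision", "recall", "f1")
        )
        lines.append(f"{scheme + ':':10s} {vals}")
    lines.append("pooled confusion (rows true ES/PNES/CS, cols predicted):")
    for row in agg["pooled_confusion"]:
        lines.append("  " + " ".join(f"{v:6d}" for v in row))
    return "\n".join(lines)
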