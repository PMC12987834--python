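"""Manifest, checkpoint and report I/O.

Manifests are CSV files with header ``patient_id,segment_id,view1_path,
view2_path,label``; image paths are relative to the manifest's directory and
point at single-channel PNGs.  Reports are written as a Table-style summary
(CSV + JSON twin, mean and SD as separate columns), a per-segment score CSV
and one ROC point CSV per fold x repeat evaluation.  Every CLI run also
serialises its full configuration and the package version next to its
outputs, so a saved run directory reproduces the run bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (EvalResult, MetricsReport, METRIC_LABELS,
                         METRIC_NAMES, roc_points)
from .models import ModelConfig, build_model
from .synthgen import SegmentArrays

__all__ = [
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "write_report",
    "write_run_config",
]

MANIFEST_COLUMNS = ["patient_id", "segment_id", "view1_path", "view2_path", "label"]


def read_manifest(path, check_images: bool = True) -> pd.DataFrame:
    """Read and validate a dataset manifest.

    Raises ``ValueError`` naming the offending column / segment id on schema
    violations; with ``check_images`` every referenced PNG must exist and
    decode.  Returns rows in file order with paths left relative.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "segment_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    df = df[MANIFEST_COLUMNS]
    if len(df) == 0:
        import warnings

        warnings.warn(f"manifest {path} has an empty data section")
        return df
    dup = df["segment_id"][df["segment_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate segment_id in manifest: {dup.iloc[0]!r}")
    bad = df[~df["label"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"label not in {{0,1}} for segment_id {bad['segment_id'].iloc[0]!r}")
    if check_images:
        from PIL import Image

        for _, row in df.iterrows():
            for col in ("view1_path", "view2_path"):
                img_path = path.parent / row[col]
                try:
                    with Image.open(img_path) as im:
                        im.verify()
                except Exception as exc:
                    raise ValueError(
                        f"segment_id {row['segment_id']!r}: cannot read {col} "
                        f"({img_path}): {exc}") from exc
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_dataset(manifest_path) -> SegmentArrays:
    """Load all segments referenced by a manifest into training arrays."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path, check_images=False)
    base = manifest_path.parent
    x1, x2 = [], []
    for _, row in df.iterrows():
        with Image.open(base / row["view1_path"]) as im:
            x1.append(np.asarray(im.convert("L"), dtype=np.float32) / 255.0)
        with Image.open(base / row["view2_path"]) as im:
            x2.append(np.asarray(im.convert("L"), dtype=np.float32) / 255.0)
    return SegmentArrays(
        x1=np.stack(x1)[:, None], x2=np.stack(x2)[:, None],
        labels=df["label"].to_numpy(int),
        patient_ids=df["patient_id"].to_numpy(str),
        segment_ids=df["segment_id"].to_numpy(str),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path) -> None:
    """Serialise model weights (npz) with an adjacent JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    sidecar = {"arch": model.arch, "config": model.config.to_dict(),
               "version": __version__}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_model(sidecar["arch"], ModelConfig.from_dict(sidecar["config"]))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.params()):
            p.data[...] = data[f"p{i}"]
    return model


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report: MetricsReport, results: list[EvalResult], out_dir,
                 method: str) -> dict[str, Path]:
    """Write the summary (CSV + JSON), per-segment scores and ROC CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row = {"Method": method}
    for name in METRIC_NAMES:
        if name in report.metrics:
            m, s = report.metrics[name]
            row[f"{METRIC_LABELS[name]}_mean"] = m
            row[f"{METRIC_LABELS[name]}_sd"] = s
    summary_csv = out_dir / "summary.csv"
    pd.DataFrame([row]).to_csv(summary_csv, index=False)
    summary_json = out_dir / "summary.json"
    summary_json.write_text(json.dumps({"method": method, **report.to_dict()}, indent=2))

    score_rows = []
    for res in results:
        for sid, pid, sc, lab in zip(res.segment_ids, res.patient_ids, res.scores, res.labels):
            score_rows.append((res.repeat, res.fold, pid, sid, sc, lab))
    scores_csv = out_dir / "scores.csv"
    pd.DataFrame(score_rows, columns=["repeat", "fold", "patient_id", "segment_id",
                                      "score", "label"]).to_csv(scores_csv, index=False)

    roc_paths = []
    for res in results:
        if res.labels.min() != res.labels.max():
            pts = roc_points(res.scores, res.labels)
            p = out_dir / f"roc_r{res.repeat}_f{res.fold}.csv"
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(p, index=False)
            roc_paths.append(p)
    return {"summary_csv": summary_csv, "summary_json": summary_json,
            "scores_csv": scores_csv, "roc": roc_paths}


def write_run_config(out_dir, **sections) -> Path:
    """Serialise the merged run configuration + version (provenance contract)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__}
    for name, value in sections.items():
        payload[name] = value.to_dict() if hasattr(value, "to_dict") else value
    path = out_dir / "run_config.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
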