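"""Cohort/summary CSV readers and writers, NIfTI volume I/O, configs.

CSV dialect is fixed: comma-separated, dot decimal, UTF-8, header required.
Every file written by the package is accompanied by a ``<file>.manifest.json``
sidecar recording the package version, root seed and a hash of the
generating configuration, so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, CohortTable, GroupSpec
from .phantom import ROIMask, VolumeImage
from .study import StudySummary, SUMMARY_COLUMNS

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_summary_csv",
    "read_summary_csv",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "load_cohort_spec",
    "dump_cohort_spec",
    "config_hash",
    "write_manifest",
]


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read and validate a cohort table, preserving row order.

    Raises distinct errors for missing columns, non-positive SBR values
    (naming the offending rows) and duplicate subject ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    return CohortTable(data=df, setting_name=path.stem)


def write_cohort_csv(
    cohort: CohortTable, path: str | Path, config: Any | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(path, index=False, columns=list(CohortTable.COLUMNS))
    write_manifest(path, config=config, seed=cohort.seed)
    return path


def write_summary_csv(
    summary: StudySummary, path: str | Path, config: Any | None = None
) -> Path:
    """One row per database size plus a trailing benchmark row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = summary.per_size.copy()
    bench = {c: np.nan for c in SUMMARY_COLUMNS}
    bench.update(
        size="benchmark",
        acc_mean=summary.benchmark.accuracy,
        sens_mean=summary.benchmark.sensitivity,
        spec_mean=summary.benchmark.specificity,
        mean_loss_pct=0.0,
        max_loss_pct=0.0,
    )
    df = pd.concat([df, pd.DataFrame([bench])], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")
    write_manifest(path, config=config, seed=summary.seed)
    return path


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_volume(vol: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size)), path)
    return path


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return VolumeImage(np.asarray(img.dataobj, dtype=float), voxel)


def save_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size)), path
    )
    return path


def load_mask(path: str | Path, name: str = "") -> ROIMask:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    data = np.asarray(img.dataobj)
    if not np.isin(data, (0, 1)).all():
        raise ValueError(f"mask file {path} is not binary (0/1)")
    return ROIMask(data.astype(bool), voxel, name or Path(path).stem.split(".")[0])


def dump_cohort_spec(spec: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(dataclasses.asdict(spec), sort_keys=False))
    return path


def load_cohort_spec(path: str | Path) -> CohortSpec:
    raw = yaml.safe_load(Path(path).read_text())
    return CohortSpec(
        setting_name=raw["setting_name"],
        normal=GroupSpec(**raw["normal"]),
        disease=GroupSpec(**raw["disease"]),
        seed=int(raw.get("seed", 0)),
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: Any) -> str:
    """SHA-256 over the canonical JSON form of a configuration object."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(
    artifact: str | Path, config: Any | None = None, seed: int | None = None
) -> Path:
    """Sidecar manifest for an output file: version, seed, config hash."""
    artifact = Path(artifact)
    manifest = {
        "artifact": artifact.name,
        "package": "datsbr",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    out = artifact.with_name(artifact.name + ".manifest.json")
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
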