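"""File formats and run configuration.

Events travel as tab-separated tables in the BIDS-events dialect (columns
onset / duration / trial_type / block / response_time, seconds throughout);
voxel time series as NIfTI-1 4-D volumes (TR stored in the header zooms) or
as an internal ``.npz`` matrix format that needs no imaging reader; motion
regressors as a plain six-column text file.  Scan indices are 0-based and
windows half-open everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .constants import CATEGORIES
from .synthdata import EVENT_COLUMNS, validate_events

REQUIRED_EVENT_COLUMNS = ("onset", "duration", "trial_type")


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    """Read and validate a BIDS-dialect events table.

    Errors carry 1-based data line numbers (header is line 1).  Extra
    columns are preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = set(REQUIRED_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("onset", "duration"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna())
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} at line {bad[0] + 2}"
            )
        df[col] = vals
    bad_dur = np.flatnonzero(~(df["duration"] > 0))
    if len(bad_dur):
        raise ValueError(
            f"{path}: non-positive duration at line {bad_dur[0] + 2}"
        )
    unknown = np.flatnonzero(~df["trial_type"].isin(CATEGORIES))
    if len(unknown):
        raise ValueError(
            f"{path}: unknown category {df['trial_type'].iloc[unknown[0]]!r} "
            f"at line {unknown[0] + 2}"
        )
    if "block" not in df.columns:
        df["block"] = 0
    validate_events(df)
    return df


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    nz = int(np.ceil(n_voxels / 100))
    return (10, 10, nz)


def write_series(data: np.ndarray, tr: float, path) -> None:
    """Write a scans x voxels matrix.

    ``.nii``/``.nii.gz`` produce a NIfTI-1 4-D volume on a small arbitrary
    grid (x-fastest voxel order, zero-padded), TR in the 4th header zoom;
    ``.npz`` stores the matrix and TR directly.
    """
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    n_scans, n_voxels = data.shape
    if path.suffix == ".npz" or path.name.endswith(".npz"):
        np.savez(path, data=data, tr=np.float64(tr), n_voxels=n_voxels)
        return
    shape = _grid_shape(n_voxels)
    vol = np.zeros((np.prod(shape), n_scans), dtype=np.float32)
    vol[:n_voxels] = data.T
    vol4d = vol.reshape(shape + (n_scans,), order="F")
    img = nib.Nifti1Image(vol4d, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr)))
    img.header["dim_info"] = 0
    img.header.set_xyzt_units("mm", "sec")
    img.to_filename(str(path))
    # sidecar with the true voxel count (the grid is zero-padded)
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps({"n_voxels": int(n_voxels), "tr": float(tr)})
    )


def read_series(path, mask: np.ndarray | None = None):
    """Read a series written by :func:`write_series`.

    Returns (scans x voxels matrix, tr).  ``mask`` (boolean over voxels)
    restricts the returned columns.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            data = np.asarray(z["data"], dtype=float)
            tr = float(z["tr"])
    else:
        img = nib.load(str(path))
        if img.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D series, got {img.ndim}-D")
        tr = float(img.header.get_zooms()[3])
        if tr <= 0:
            raise ValueError(f"{path}: TR missing from the header")
        vol = np.asarray(img.dataobj, dtype=float)
        n_scans = vol.shape[3]
        flat = vol.reshape(-1, n_scans, order="F")
        sidecar = path.with_suffix("").with_suffix(".json")
        if sidecar.exists():
            n_voxels = int(json.loads(sidecar.read_text())["n_voxels"])
        else:
            n_voxels = flat.shape[0]
        data = flat[:n_voxels].T
    if mask is not None:
        data = data[:, np.asarray(mask, dtype=bool)]
    return data, tr


def write_motion(motion: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(motion), fmt="%.8f")


def read_motion(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim == 1:
        m = m[:, None]
    return m


def write_sampleset(samples, prefix) -> None:
    """SampleSet as a matrix file plus a sidecar table (label, block, scans)."""
    prefix = Path(prefix)
    np.savez(prefix.with_suffix(".npz"), X=samples.X)
    pd.DataFrame(
        {
            "label": samples.labels,
            "block": samples.blocks,
            "scans": [
                " ".join(map(str, s)) for s in (samples.scan_indices or [[]] * samples.n_samples)
            ],
        }
    ).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)


def read_sampleset(prefix):
    from .signal_extraction import SampleSet

    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as z:
        X = np.asarray(z["X"], dtype=float)
    meta = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    scans = [
        [int(v) for v in str(s).split()] if isinstance(s, str) and s.strip() else []
        for s in meta["scans"].fillna("")
    ]
    return SampleSet(
        X=X,
        labels=meta["label"].to_numpy(),
        blocks=meta["block"].to_numpy(int),
        scan_indices=scans,
    )


@dataclass
class RunConfig:
    """Defaults reproduce the study's stated settings."""

    session: str = "exploration"
    tr: float = 2.04
    n_voxels: int = 1000
    hrf_delay: float = 6.0
    highpass_cutoff: float = 1.0 / 128.0
    n_repetitions: int = 5
    n_tests: int = 54
    recall_prob: tuple = (1.0, 0.65, 0.93)
    n_informative: int = 30
    effect_size: float = 1.0
    overlap_fraction: float = 0.0
    procedures: tuple = (1, 2, 3, 4, 5)
    n_perm: int = 100
    C: float = 1.0
    topk: int = 1000
    f_threshold: float = 0.5
    rfa_grid: tuple = (5, 30, 55, 80, 105, 130, 150)
    centering: str = "independent"
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("recall_prob", "procedures", "rfa_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(self).items()},
                sort_keys=False,
            )
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
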