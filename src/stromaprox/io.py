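"""NIfTI and tabular I/O with registration-consistency checks.

All internal coordinates are voxel indices; voxel spacing is taken from the
NIfTI header and applied only in the proximity module.  World affines are
used solely to refuse series whose three volumes are not on the same grid.
Units are fixed throughout: distances mm, PE %, SER dimensionless, survival
months, volumes cm³.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import DCESeries, GridMismatchError
from .proximity import BandProfile

__all__ = [
    "read_series",
    "read_volume",
    "write_volume",
    "write_mask",
    "write_band_profiles",
    "read_band_profiles",
    "write_json",
    "file_checksum",
]

AFFINE_TOL = 1e-4

BAND_CSV_COLUMNS = [
    "subject",
    "visit",
    "channel",
    "band_lo_mm",
    "band_hi_mm",
    "mean",
    "count",
]


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Load a NIfTI volume; returns (data, affine, spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, spacing


def read_series(
    s0_path: str | Path, s1_path: str | Path, s2_path: str | Path,
    t1_minutes: float = 2.5, t2_minutes: float = 7.5,
) -> DCESeries:
    """Read three co-registered volumes into a :class:`DCESeries`.

    Refuses series whose shapes differ ("grid mismatch") or whose affines
    disagree beyond ``AFFINE_TOL`` ("unregistered series").
    """
    s0, aff0, spacing = read_volume(s0_path)
    s1, aff1, _ = read_volume(s1_path)
    s2, aff2, _ = read_volume(s2_path)
    if not (s0.shape == s1.shape == s2.shape):
        raise GridMismatchError(
            f"grid mismatch: {s0.shape} / {s1.shape} / {s2.shape}"
        )
    for aff, name in ((aff1, "s1"), (aff2, "s2")):
        if np.max(np.abs(aff - aff0)) > AFFINE_TOL:
            raise GridMismatchError(f"unregistered series: affine of {name} deviates from s0")
    return DCESeries(
        s0=s0, s1=s1, s2=s2, spacing=spacing,
        t1_minutes=t1_minutes, t2_minutes=t2_minutes,
    )


def write_volume(
    data: np.ndarray, path: str | Path, spacing: tuple[float, float, float]
) -> Path:
    """Write a float volume as NIfTI-1 with a diagonal spacing affine."""
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return Path(path)


def write_mask(
    mask: np.ndarray, path: str | Path, spacing: tuple[float, float, float]
) -> Path:
    """Write a boolean mask as uint8 NIfTI-1."""
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))
    return Path(path)


def write_band_profiles(
    profiles: list[tuple[str, str, BandProfile]], path: str | Path
) -> Path:
    """Write band profiles to the tidy CSV schema (one row per band).

    ``profiles`` is a list of (subject, visit, profile) triples.
    """
    frames = [p.to_frame(subject=s, visit=v) for s, v, p in profiles]
    df = pd.concat(frames, ignore_index=True)[BAND_CSV_COLUMNS]
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_band_profiles(path: str | Path) -> pd.DataFrame:
    """Read the tidy band CSV back; column order and dtypes are fixed."""
    df = pd.read_csv(path)
    missing = set(BAND_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"band CSV missing columns: {sorted(missing)}")
    return df[BAND_CSV_COLUMNS]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(payload: dict, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return Path(path)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
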