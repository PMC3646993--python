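"""Voxel-wise contrast-enhancement kinetics for three-timepoint breast DCE-MRI.

A clinical breast DCE exam acquires one pre-contrast volume (``S0``) and two
post-contrast volumes, early (``S1``, nominally 2.5 min after injection) and
late (``S2``, nominally 7.5 min).  Two voxel-wise kinetic summaries are
derived:

* percent enhancement, ``PE = 100 * (S1 - S0) / S0`` — the early signal rise
  relative to baseline, a proxy for perfusion/permeability;
* signal enhancement ratio, ``SER = (S1 - S0) / (S2 - S0)`` — the ratio of
  early to late enhancement.  SER > 1 indicates washout (the late signal has
  already dropped back), SER ≈ 1 a plateau, 0 < SER < 1 persistent uptake.

Both maps are computed on the raw signal grid; no pharmacokinetic model is
fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DCESeries",
    "EnhancementMaps",
    "DegeneratePreContrastError",
    "GridMismatchError",
    "compute_pe",
    "compute_ser",
    "compute_enhancement_maps",
    "classify_curve",
    "CURVE_CLASSES",
]


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


class DegeneratePreContrastError(ValueError):
    """Raised when the pre-contrast volume carries no usable signal."""


@dataclass(frozen=True)
class DCESeries:
    """Three co-registered DCE volumes with spacing and timing metadata.

    Parameters
    ----------
    s0, s1, s2 : ndarray, 3-D
        Pre-contrast, early post-contrast and late post-contrast signal
        intensity volumes (arbitrary MR units) on a common voxel grid.
    spacing : tuple of float
        Voxel size in mm per axis, strictly positive.
    t1_minutes, t2_minutes : float
        Nominal post-injection sampling times of ``s1`` and ``s2``.
    """

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    t1_minutes: float = 2.5
    t2_minutes: float = 7.5

    def __post_init__(self) -> None:
        s0 = np.asarray(self.s0, dtype=float)
        s1 = np.asarray(self.s1, dtype=float)
        s2 = np.asarray(self.s2, dtype=float)
        if not (s0.shape == s1.shape == s2.shape):
            raise GridMismatchError(
                f"grid mismatch: shapes {s0.shape}, {s1.shape}, {s2.shape}"
            )
        if s0.ndim != 3:
            raise ValueError("DCESeries volumes must be 3-D")
        for vol, name in ((s0, "s0"), (s1, "s1"), (s2, "s2")):
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"{name} contains non-finite intensities")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be three positive mm values, got {spacing}")
        if not (self.t2_minutes > self.t1_minutes > 0):
            raise ValueError("timing must satisfy t2 > t1 > 0")
        object.__setattr__(self, "s0", s0)
        object.__setattr__(self, "s1", s1)
        object.__setattr__(self, "s2", s2)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape


@dataclass
class EnhancementMaps:
    """Voxel-wise PE and SER volumes with their validity masks.

    ``pe`` is in percent and may be negative (de-enhancing voxels keep their
    sign); it is NaN where the pre-contrast signal is non-positive
    (``pe_valid`` False).  ``ser`` is dimensionless and NaN outside
    ``ser_valid``; a voxel is SER-valid only where both the early enhancement
    and the washout denominator exceed ``noise_floor`` in magnitude, which
    keeps near-zero denominators in unenhancing stroma from producing
    unbounded ratios.
    """

    pe: np.ndarray
    ser: np.ndarray
    pe_valid: np.ndarray
    ser_valid: np.ndarray
    noise_floor: float = 0.0
    ser_cap: float | None = None
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 2.0))


def compute_pe(series: DCESeries) -> tuple[np.ndarray, np.ndarray]:
    """Percent-enhancement map ``100 * (S1 - S0) / S0``.

    Returns
    -------
    pe : ndarray
        PE in percent; NaN where undefined.
    valid : ndarray of bool
        True where ``S0 > 0`` (PE defined).  Voxels with non-positive
        baseline are excluded rather than clamped.

    Raises
    ------
    DegeneratePreContrastError
        If no voxel has positive pre-contrast signal.
    """
    valid = series.s0 > 0
    if not valid.any():
        raise DegeneratePreContrastError("degenerate pre-contrast series: S0 <= 0 everywhere")
    pe = np.full(series.shape, np.nan)
    np.divide(100.0 * (series.s1 - series.s0), series.s0, out=pe, where=valid)
    return pe, valid


def compute_ser(
    series: DCESeries,
    noise_floor: float = 0.0,
    cap: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal-enhancement-ratio map ``(S1 - S0) / (S2 - S0)``.

    A voxel is valid when ``S1 - S0 > noise_floor`` (it genuinely enhances)
    and ``|S2 - S0| > noise_floor`` (the denominator is resolvable); SER is
    NaN elsewhere and such voxels are excluded from all downstream band
    means.  ``cap``, if given, clips valid SER values at ``±cap`` so single
    outliers cannot dominate a band mean (off by default).
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    early = series.s1 - series.s0
    late = series.s2 - series.s0
    valid = (early > noise_floor) & (np.abs(late) > noise_floor)
    ser = np.full(series.shape, np.nan)
    np.divide(early, late, out=ser, where=valid)
    if cap is not None:
        np.clip(ser, -cap, cap, out=ser)
    return ser, valid


def compute_enhancement_maps(
    series: DCESeries,
    noise_floor: float = 0.0,
    ser_cap: float | None = None,
) -> EnhancementMaps:
    """Compute PE and SER maps for a series in one call."""
    pe, pe_valid = compute_pe(series)
    ser, ser_valid = compute_ser(series, noise_floor=noise_floor, cap=ser_cap)
    return EnhancementMaps(
        pe=pe,
        ser=ser,
        pe_valid=pe_valid,
        ser_valid=ser_valid,
        noise_floor=noise_floor,
        ser_cap=ser_cap,
        spacing=series.spacing,
    )


CURVE_CLASSES = ("washout", "plateau", "persistent", "non-enhancing")


def classify_curve(
    pe: float | np.ndarray,
    ser: float | np.ndarray,
    enhancement_floor: float = 10.0,
    plateau_lo: float = 0.9,
    plateau_hi: float = 1.1,
) -> np.ndarray:
    """Classify enhancement-curve shape from (PE, SER).

    Voxels below ``enhancement_floor`` percent early enhancement are
    non-enhancing regardless of SER.  Among enhancing voxels, SER above the
    plateau band means washout (the malignant archetype), within the band a
    plateau, and between 0 and the band persistent uptake (the benign
    archetype).  Returns an array of strings from :data:`CURVE_CLASSES`
    (a scalar array for scalar input).
    """
    pe = np.asarray(pe, dtype=float)
    ser = np.asarray(ser, dtype=float)
    pe, ser = np.broadcast_arrays(pe, ser)
    out = np.full(pe.shape, "non-enhancing", dtype=object)
    enhancing = pe >= enhancement_floor
    out[enhancing & (ser > plateau_hi)] = "washout"
    out[enhancing & (ser >= plateau_lo) & (ser <= plateau_hi)] = "plateau"
    out[enhancing & (ser > 0) & (ser < plateau_lo)] = "persistent"
    return out if out.shape else out[()]
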