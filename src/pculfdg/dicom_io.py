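"""Reading PET DICOM series, SUV computation, and hypermetabolic VOI detection.

The standardised uptake value (SUV) normalises a voxel's tracer
concentration by the injected activity per unit body weight:

    SUV = concentration (mCi/kg) / (injected activity (mCi) / body weight (kg))

A solitary pulmonary nodule enters the method only if its hottest voxel
reaches SUVmax >= 2.5 (the conventional hypermetabolic cut-off); the volume
of interest (VOI) is the bounding box of the connected supra-threshold
component containing that voxel, padded by a small margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError
from scipy import ndimage

__all__ = [
    "PETSeries",
    "VOI",
    "SeriesReadError",
    "SubthresholdError",
    "read_series",
    "suv",
    "find_voi",
    "read_voi_table",
]

#: conversion factor between becquerel and millicurie
BQ_PER_MCI = 3.7e7


class SeriesReadError(RuntimeError):
    """The directory does not hold one well-formed single PET series."""


class SubthresholdError(ValueError):
    """SUVmax is below the hypermetabolic cut-off; nodule out of method scope."""


@dataclass
class PETSeries:
    """An ordered stack of axial PET slices with calibration constants.

    ``activity`` is indexed ``(slice, row, col)`` and holds nonnegative
    tracer concentration in the same mass-based unit (mCi/kg) the SUV
    formula expects. ``injected_activity_mCi``/``body_weight_kg`` may be
    ``None`` when the source files lack the corresponding tags, in which
    case SUV is flagged unavailable but raw activity stays readable.
    """

    activity: np.ndarray
    in_plane_spacing_mm: float
    slice_thickness_mm: float
    injected_activity_mCi: float | None = None
    body_weight_kg: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 3:
            raise ValueError("activity must be a (slice, row, col) volume")
        if self.in_plane_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.activity.shape[0]

    @property
    def suv_available(self) -> bool:
        return (
            self.injected_activity_mCi is not None
            and self.body_weight_kg is not None
            and self.injected_activity_mCi > 0
            and self.body_weight_kg > 0
        )

    def suv_volume(self) -> np.ndarray:
        """Voxel-wise SUV; raises if calibration fields are missing."""
        if not self.suv_available:
            raise ValueError(
                "SUV unavailable: injected activity and/or body weight missing"
            )
        return suv(self.activity, self.injected_activity_mCi, self.body_weight_kg)

    def suvmax(self) -> float:
        return float(self.suv_volume().max())


@dataclass(frozen=True)
class VOI:
    """Inclusive voxel-index bounding box around the hypermetabolic nodule."""

    slice_min: int
    slice_max: int
    row_min: int
    row_max: int
    col_min: int
    col_max: int
    seed_voxel: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not (
            self.slice_min <= self.slice_max
            and self.row_min <= self.row_max
            and self.col_min <= self.col_max
        ):
            raise ValueError("VOI bounds out of order")
        s, r, c = self.seed_voxel
        if not (
            self.slice_min <= s <= self.slice_max
            and self.row_min <= r <= self.row_max
            and self.col_min <= c <= self.col_max
        ):
            raise ValueError("seed voxel outside VOI box")

    @property
    def slices(self) -> range:
        return range(self.slice_min, self.slice_max + 1)

    def box2d(self) -> tuple[int, int, int, int]:
        return (self.row_min, self.row_max, self.col_min, self.col_max)


def suv(concentration, injected_activity_mCi: float, body_weight_kg: float):
    """Standardised uptake value of a concentration (scalar or array).

    ``SUV = concentration * body_weight / injected_activity`` with
    concentration in mCi/kg, activity in mCi and weight in kg, making the
    result dimensionless.
    """
    if injected_activity_mCi <= 0:
        raise ValueError("injected activity must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    return np.asarray(concentration, dtype=float) * body_weight_kg / injected_activity_mCi


def _slice_sort_key(ds: pydicom.Dataset) -> float:
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        return float(ipp[2])
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    return float(getattr(ds, "InstanceNumber", 0))


def read_series(directory) -> PETSeries:
    """Read one PET DICOM series from ``directory`` into a :class:`PETSeries`.

    Slices are sorted by physical location (file names are irrelevant),
    rescale slope/intercept are applied, and SUV calibration tags are
    collected when present. Mixed series, nonuniform spacing or missing
    pixel data raise :class:`SeriesReadError`.
    """
    directory = Path(directory)
    datasets: list[pydicom.Dataset] = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            continue
        if "PixelData" not in ds:
            raise SeriesReadError(f"{path.name}: DICOM file without pixel data")
        datasets.append(ds)
    if not datasets:
        raise SeriesReadError(f"no DICOM slices found in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise SeriesReadError(f"directory mixes {len(uids)} series: {sorted(uids)}")

    datasets.sort(key=_slice_sort_key)

    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) > 1:
        raise SeriesReadError(f"nonuniform in-plane spacing across slices: {spacings}")
    (spacing_rc,) = spacings
    if abs(spacing_rc[0] - spacing_rc[1]) > 1e-6:
        raise SeriesReadError(f"non-square pixels unsupported: {spacing_rc}")

    locs = np.array([_slice_sort_key(ds) for ds in datasets])
    if len(locs) > 1:
        steps = np.diff(locs)
        if steps.min() <= 0 or np.ptp(steps) > 1e-3:
            raise SeriesReadError("slice locations not strictly and uniformly spaced")
        thickness = float(np.mean(steps))
    else:
        thickness = float(getattr(datasets[0], "SliceThickness", 1.0))

    planes = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(float) * slope + intercept)
    volume = np.clip(np.stack(planes), 0.0, None)

    first = datasets[0]
    weight = getattr(first, "PatientWeight", None)
    weight = float(weight) if weight is not None else None
    injected = None
    rpis = getattr(first, "RadiopharmaceuticalInformationSequence", None)
    if rpis:
        dose_bq = getattr(rpis[0], "RadionuclideTotalDose", None)
        if dose_bq is not None:
            injected = float(dose_bq) / BQ_PER_MCI

    return PETSeries(
        activity=volume,
        in_plane_spacing_mm=float(spacing_rc[0]),
        slice_thickness_mm=thickness,
        injected_activity_mCi=injected,
        body_weight_kg=weight,
        meta={
            "n_files": len(datasets),
            "series_uid": uids.pop(),
            "suv_calibration_missing": weight is None or injected is None,
        },
    )


def find_voi(
    series: PETSeries,
    suv_threshold: float = 2.5,
    margin_mm: float = 5.0,
    box: tuple[int, int, int, int, int, int] | None = None,
) -> VOI:
    """Locate the hypermetabolic volume of interest.

    The seed is the global SUV argmax; the VOI is the bounding box of the
    26-connected component of ``{SUV >= suv_threshold}`` containing the
    seed, padded by ``margin_mm`` (converted to voxels per axis). A
    user-supplied ``box`` ``(slice_min, slice_max, row_min, row_max,
    col_min, col_max)`` overrides the automatic derivation, mirroring the
    manual-rectangle workflow.

    Raises :class:`SubthresholdError` when SUVmax < ``suv_threshold``.
    """
    suv_vol = series.suv_volume()
    if box is not None:
        s0, s1, r0, r1, c0, c1 = (int(v) for v in box)
        sub = suv_vol[s0 : s1 + 1, r0 : r1 + 1, c0 : c1 + 1]
        if sub.size == 0:
            raise ValueError("manual VOI box is empty")
        ds, dr, dc = np.unravel_index(int(np.argmax(sub)), sub.shape)
        return VOI(s0, s1, r0, r1, c0, c1, (s0 + ds, r0 + dr, c0 + dc))

    suvmax = float(suv_vol.max())
    if suvmax < suv_threshold:
        raise SubthresholdError(
            f"SUVmax {suvmax:.2f} < {suv_threshold}: nodule is not hypermetabolic"
        )
    seed = tuple(int(i) for i in np.unravel_index(int(np.argmax(suv_vol)), suv_vol.shape))
    mask = suv_vol >= suv_threshold
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    comp = labels == labels[seed]
    ss, rr, cc = np.nonzero(comp)

    # margin pads in-plane only: axially the nodule is bounded by the
    # supra-threshold extent, and extra slices would carry no nodule signal
    pad_rc = ceil(margin_mm / series.in_plane_spacing_mm)
    n_s, n_r, n_c = series.activity.shape
    return VOI(
        int(ss.min()),
        int(ss.max()),
        max(int(rr.min()) - pad_rc, 0),
        min(int(rr.max()) + pad_rc, n_r - 1),
        max(int(cc.min()) - pad_rc, 0),
        min(int(cc.max()) + pad_rc, n_c - 1),
        seed,
    )


def read_voi_table(path) -> dict[str, tuple[int, int, int, int, int, int]]:
    """Read a manual-VOI override CSV.

    Columns: ``nodule_id, slice_min, slice_max, row_min, row_max, col_min,
    col_max`` (0-based, inclusive). Returns a mapping nodule_id -> box.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = ["nodule_id", "slice_min", "slice_max", "row_min", "row_max", "col_min", "col_max"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"VOI table missing columns: {missing}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["nodule_id"])] = tuple(int(row[c]) for c in required[1:])
    return out
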