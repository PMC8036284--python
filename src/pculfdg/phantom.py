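"""Synthetic PET phantoms of solitary hypermetabolic pulmonary nodules.

A phantom is a uniform lung background plus one nodule made of Gaussian
uptake foci. Each focus has an in-plane Gaussian profile, a Gaussian axial
envelope (so the nodule has a finite craniocaudal extent), and may drift
in position and amplitude from slice to slice — stable foci emulate
benign-like lesions, drifting multi-focus nodules malignant-like ones.
Additive Gaussian noise, clipped at zero, stands in for acquisition noise.

SUV calibration constants are chosen so the hottest voxel maps to a
configurable SUVmax, and volumes can be written as minimal single-frame
PET DICOM series that round-trip bit-exactly (up to rescale quantisation)
through :func:`pculfdg.dicom_io.read_series`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import regimes
from .dicom_io import BQ_PER_MCI, PETSeries

__all__ = [
    "FocusSpec",
    "PhantomSpec",
    "SyntheticNodule",
    "generate_phantom",
    "generate_cohort",
    "write_dicom",
]

PET_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.128"


@dataclass(frozen=True)
class FocusSpec:
    """One Gaussian uptake focus inside the nodule.

    ``center_offset_mm`` is the in-plane (row, col) offset of the focus
    from the nodule centre on the nodule's central slice;
    ``drift_mm_per_slice`` displaces it per slice and
    ``amplitude_drift_per_slice`` changes its peak activity per slice
    (amplitudes are floored at zero). ``z_offset_mm`` shifts the focus's
    axial envelope so different foci can peak on different slices.
    """

    amplitude: float
    sigma_mm: float
    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    drift_mm_per_slice: tuple[float, float] = (0.0, 0.0)
    amplitude_drift_per_slice: float = 0.0
    z_offset_mm: float = 0.0
    z_sigma_mm: float | None = None  # axial envelope width; None -> radius/2

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("focus amplitude must be positive")
        if self.sigma_mm <= 0:
            raise ValueError("focus sigma must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic nodule scan."""

    grid_shape: tuple[int, int, int] = (14, 64, 64)
    in_plane_spacing_mm: float = 3.0
    slice_thickness_mm: float = 3.3
    background_activity: float = 0.6
    noise_sd: float = 0.0
    nodule_center_mm: tuple[float, float, float] | None = None  # (z, y, x)
    nodule_radius_mm: float = 12.0
    foci: tuple[FocusSpec, ...] = ()
    seed: int = 0
    target_suvmax: float = 5.0
    body_weight_kg: float = 70.0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive extents")
        if self.in_plane_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.background_activity < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be nonnegative")
        if not 5.0 <= self.nodule_radius_mm <= 15.0:
            raise ValueError(
                "nodule radius must lie in [5, 15] mm (solitary-nodule "
                "diameter 10-30 mm)"
            )
        object.__setattr__(self, "foci", tuple(self.foci))
        if self.nodule_center_mm is None:
            ns, nr, nc = self.grid_shape
            object.__setattr__(
                self,
                "nodule_center_mm",
                (
                    (ns - 1) / 2 * self.slice_thickness_mm,
                    (nr - 1) / 2 * self.in_plane_spacing_mm,
                    (nc - 1) / 2 * self.in_plane_spacing_mm,
                ),
            )
        self._validate_foci()

    def _validate_foci(self) -> None:
        zc = self.nodule_center_mm[0]
        center_slice = zc / self.slice_thickness_mm
        for idx, f in enumerate(self.foci):
            if (
                math.hypot(*f.center_offset_mm, f.z_offset_mm)
                > self.nodule_radius_mm + 1e-9
            ):
                raise ValueError(f"focus {idx} centre outside the nodule radius")
            for s in range(self.grid_shape[0]):
                z = s * self.slice_thickness_mm
                if abs(z - zc) > self.nodule_radius_mm:
                    continue
                dy = f.center_offset_mm[0] + f.drift_mm_per_slice[0] * (s - center_slice)
                dx = f.center_offset_mm[1] + f.drift_mm_per_slice[1] * (s - center_slice)
                if math.hypot(dy, dx) > self.nodule_radius_mm + 1e-9:
                    raise ValueError(
                        f"focus {idx} drifts outside the nodule on slice {s}"
                    )

    def focus_center_mm(self, focus: FocusSpec, slice_index: int) -> tuple[float, float]:
        """In-plane (y, x) position of a focus centre on a given slice."""
        center_slice = self.nodule_center_mm[0] / self.slice_thickness_mm
        return (
            self.nodule_center_mm[1]
            + focus.center_offset_mm[0]
            + focus.drift_mm_per_slice[0] * (slice_index - center_slice),
            self.nodule_center_mm[2]
            + focus.center_offset_mm[1]
            + focus.drift_mm_per_slice[1] * (slice_index - center_slice),
        )


def noise_free_field(spec: PhantomSpec) -> np.ndarray:
    """Deterministic activity field: background plus the foci Gaussians."""
    ns, nr, nc = spec.grid_shape
    y = np.arange(nr) * spec.in_plane_spacing_mm
    x = np.arange(nc) * spec.in_plane_spacing_mm
    Y, X = np.meshgrid(y, x, indexing="ij")
    field = np.full(spec.grid_shape, spec.background_activity, dtype=float)

    zc = spec.nodule_center_mm[0]
    center_slice = zc / spec.slice_thickness_mm
    sigma_z = spec.nodule_radius_mm / 2.0
    for s in range(ns):
        z = s * spec.slice_thickness_mm
        for f in spec.foci:
            # per-focus axial envelope: foci may peak on different slices
            # and have different axial extents
            sz = f.z_sigma_mm if f.z_sigma_mm is not None else sigma_z
            envelope = math.exp(-((z - zc - f.z_offset_mm) ** 2) / (2 * sz**2))
            amp = max(0.0, f.amplitude + f.amplitude_drift_per_slice * (s - center_slice))
            if amp == 0.0:
                continue
            cy, cx = spec.focus_center_mm(f, s)
            field[s] += (
                amp
                * envelope
                * np.exp(-((Y - cy) ** 2 + (X - cx) ** 2) / (2 * f.sigma_mm**2))
            )
    return field


def generate_phantom(spec: PhantomSpec) -> PETSeries:
    """Generate a phantom scan; deterministic for a given spec (seed included).

    The voxel value is background + sum of foci Gaussians + Gaussian noise,
    clipped at zero. Injected activity is set so the hottest voxel maps to
    ``spec.target_suvmax``.
    """
    field = noise_free_field(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        field = field + rng.normal(0.0, spec.noise_sd, size=field.shape)
    field = np.clip(field, 0.0, None)

    peak = float(field.max())
    injected = (
        peak * spec.body_weight_kg / spec.target_suvmax if peak > 0 else 1.0
    )
    return PETSeries(
        activity=field,
        in_plane_spacing_mm=spec.in_plane_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        injected_activity_mCi=injected,
        body_weight_kg=spec.body_weight_kg,
        meta={"phantom_spec": spec},
    )


@dataclass(frozen=True)
class SyntheticNodule:
    """One generated cohort member with its ground-truth label."""

    nodule_id: str
    label: str  # "malignant" | "benign"
    spec: PhantomSpec
    series: PETSeries = field(repr=False)


def _uniform(rng: np.random.Generator, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _sample_spec(rng: np.random.Generator, regime: dict, seed: int) -> PhantomSpec:
    radius = _uniform(rng, regime["radius_mm"])
    n_foci = int(rng.integers(regime["n_foci"][0], regime["n_foci"][1] + 1))
    amplitude = _uniform(rng, regime["amplitude"])

    grid = regimes.GRID
    n_slices = grid["grid_shape"][0]
    # keep drifted foci inside the nodule over its axial extent
    slices_half = radius / grid["slice_thickness_mm"]

    foci = []
    amp = amplitude
    for i in range(n_foci):
        sigma = _uniform(rng, regime["sigma_mm"])
        offset_r = radius * _uniform(rng, regime["offset_frac"]) if i else 0.0
        theta = rng.uniform(0, 2 * math.pi)
        offset = (offset_r * math.sin(theta), offset_r * math.cos(theta))
        z_off = radius * _uniform(rng, regime.get("z_offset_frac", (0.0, 0.0)))
        z_off *= 1 if rng.uniform() < 0.5 else -1
        # cap the in-plane radius so the (y, x, z) centre stays in the nodule
        max_r = math.sqrt(max(radius**2 - z_off**2, 0.0))
        if offset_r > max_r:
            offset = (offset[0] * max_r / offset_r, offset[1] * max_r / offset_r)
            offset_r = max_r
        drift_mag = _uniform(rng, regime["drift_mm"])
        max_drift = max(0.0, (radius - offset_r) / max(slices_half, 1.0) * 0.9)
        drift_mag = min(drift_mag, max_drift)
        phi = rng.uniform(0, 2 * math.pi)
        drift = (drift_mag * math.sin(phi), drift_mag * math.cos(phi))
        adrift = amp * _uniform(rng, regime["amplitude_drift_frac"])
        adrift *= 1 if rng.uniform() < 0.5 else -1
        foci.append(
            FocusSpec(
                amplitude=amp,
                sigma_mm=sigma,
                center_offset_mm=offset,
                drift_mm_per_slice=drift,
                amplitude_drift_per_slice=adrift,
                z_offset_mm=z_off,
                z_sigma_mm=radius * _uniform(rng, regime.get("z_sigma_frac", (0.5, 0.5))),
            )
        )
        amp *= _uniform(rng, regime["amplitude_decay"])

    return PhantomSpec(
        grid_shape=grid["grid_shape"],
        in_plane_spacing_mm=grid["in_plane_spacing_mm"],
        slice_thickness_mm=grid["slice_thickness_mm"],
        background_activity=grid["background_activity"],
        noise_sd=grid["noise_sd"],
        nodule_radius_mm=radius,
        foci=tuple(foci),
        seed=seed,
        target_suvmax=_uniform(rng, regime["target_suvmax"]),
    )


def generate_cohort(
    n_malignant_like: int,
    n_benign_like: int,
    seed: int,
) -> list[SyntheticNodule]:
    """A reproducible cohort of labelled phantoms.

    Malignant-like members are drawn from the high-heterogeneity regime
    (several drifting foci with stacked amplitude levels), benign-like ones
    from the low-heterogeneity regime (one stable focus); both regimes are
    frozen in :mod:`pculfdg.regimes`. Identical arguments give
    byte-identical voxel data.
    """
    if n_malignant_like < 0 or n_benign_like < 0:
        raise ValueError("cohort counts must be nonnegative")
    rng = np.random.default_rng(seed)
    cohort: list[SyntheticNodule] = []
    plan = [(regimes.MALIGNANT_LIKE, i) for i in range(n_malignant_like)]
    plan += [(regimes.BENIGN_LIKE, i) for i in range(n_benign_like)]
    for regime, i in plan:
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = _sample_spec(rng, regime, child_seed)
        label = regime["label"]
        cohort.append(
            SyntheticNodule(
                nodule_id=f"{label[:3]}_{i:03d}",
                label=label,
                spec=spec,
                series=generate_phantom(spec),
            )
        )
    return cohort


def write_manifest(cohort: list[SyntheticNodule], path) -> None:
    """CSV manifest of generated labels (nodule_id, label)."""
    import pandas as pd

    pd.DataFrame(
        {"nodule_id": [n.nodule_id for n in cohort], "label": [n.label for n in cohort]}
    ).to_csv(path, index=False)


def write_dicom(series: PETSeries, directory, series_number: int = 1) -> list[Path]:
    """Write a series as minimal single-frame PET DICOM files, one per slice.

    Rescale slope is chosen so the 16-bit range covers the maximum
    activity; SUV calibration (patient weight, injected dose) is stored in
    the standard tags. Files round-trip through
    :func:`pculfdg.dicom_io.read_series` within one rescale step.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    vol = series.activity
    slope = max(float(vol.max()), 1e-12) / 65535.0
    pixels = np.round(vol / slope).astype(np.uint16)

    entropy = [f"{series_number}", f"{vol.shape}", f"{float(vol.sum()):.6e}"]
    series_uid = generate_uid(entropy_srcs=entropy)
    study_uid = generate_uid(entropy_srcs=entropy + ["study"])

    paths = []
    for s in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = PET_SOP_CLASS_UID
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=entropy + [str(s)])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "PT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesNumber = series_number
        ds.InstanceNumber = s + 1
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"

        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.PixelSpacing = [series.in_plane_spacing_mm, series.in_plane_spacing_mm]
        ds.SliceThickness = series.slice_thickness_mm
        z = s * series.slice_thickness_mm
        ds.ImagePositionPatient = [0.0, 0.0, z]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = z

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = 0.0
        ds.PixelData = pixels[s].tobytes()

        if series.body_weight_kg is not None:
            ds.PatientWeight = series.body_weight_kg
        if series.injected_activity_mCi is not None:
            rpi = pydicom.Dataset()
            rpi.RadionuclideTotalDose = series.injected_activity_mCi * BQ_PER_MCI
            ds.RadiopharmaceuticalInformationSequence = [rpi]

        path = directory / f"slice_{s:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
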