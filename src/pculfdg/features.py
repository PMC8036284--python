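"""The four ordinal visual features of a transformed nodule sequence.

I   nesting degree — deepest chain of contours nested one within another
    anywhere in the sequence (metabolic heterogeneity);
II  shape change — how much the outer uptake contour changes between
    consecutive slices, after centroid alignment (1 - Jaccard overlap);
III maximum-uptake shift — largest in-plane jump of the hottest pixel
    between consecutive slices, normalised by the nodule equivalent radius;
IV  size of the contour directly enclosing the maximum uptake (mm^2).

The features were originally scored visually; here they are measured
quantitatively from per-slice contour trees and binned onto the weighted
ordinal scales used by the ranking stage, so that manually scored tables
and automated extraction are interchangeable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import ContourTree

__all__ = [
    "RawFeatures",
    "FeatureRecord",
    "BinningConfig",
    "nesting_degree",
    "shape_change",
    "max_shift",
    "max_contour_size",
    "bin_to_scales",
    "bin_cohort",
    "tercile_thresholds",
    "read_feature_table",
]

#: ordinal scale maxima for variables 1-4
SCALE_MAX = (4, 3, 3, 3)


@dataclass(frozen=True)
class RawFeatures:
    """Continuous measurements the ordinal scores are binned from.

    ``shape_change`` and ``max_shift`` are ``None`` when fewer than two
    usable slices exist (the degradation contract maps them to score 1).
    """

    nesting_depth: int
    shape_change: float | None
    max_shift: float | None
    max_contour_area_mm2: float

    def __post_init__(self) -> None:
        if self.nesting_depth < 0 or self.max_contour_area_mm2 < 0:
            raise ValueError("raw features must be nonnegative")
        if self.shape_change is not None and not 0.0 <= self.shape_change <= 1.0:
            raise ValueError("shape_change must lie in [0, 1]")
        if self.max_shift is not None and self.max_shift < 0:
            raise ValueError("max_shift must be nonnegative")


@dataclass(frozen=True)
class FeatureRecord:
    """Ordinal scores of one nodule: v1 in 1..4, v2-v4 in 1..3."""

    nodule_id: str
    v1: int
    v2: int
    v3: int
    v4: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        for j, v in enumerate(self.values):
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= SCALE_MAX[j]):
                raise ValueError(
                    f"v{j + 1}={v!r} outside ordinal scale 1..{SCALE_MAX[j]}"
                )
        if self.label not in ("malignant", "benign", "unknown", "pattern"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def values(self) -> tuple[int, int, int, int]:
        return (self.v1, self.v2, self.v3, self.v4)


@dataclass(frozen=True)
class BinningConfig:
    """Thresholds mapping raw measurements onto the ordinal scales.

    ``v2_thresholds``/``v3_thresholds`` are the strictly increasing upper
    bounds of scores 1 and 2. ``v4_mode`` is ``"tercile"`` (relative
    small/medium/large within the analysed cohort) or ``"fixed"`` using
    ``v4_thresholds_mm2`` (needed for single-nodule runs).
    """

    v2_thresholds: tuple[float, float] = (0.15, 0.35)
    v3_thresholds: tuple[float, float] = (0.2, 0.5)
    v4_mode: str = "tercile"
    v4_thresholds_mm2: tuple[float, float] = (20.0, 60.0)

    def __post_init__(self) -> None:
        for name in ("v2_thresholds", "v3_thresholds", "v4_thresholds_mm2"):
            t = getattr(self, name)
            if not t[0] < t[1]:
                raise ValueError(f"{name} must be strictly increasing")
        if self.v4_mode not in ("tercile", "fixed"):
            raise ValueError("v4_mode must be 'tercile' or 'fixed'")


def nesting_degree(trees: list[ContourTree]) -> int:
    """Highest degree of contour nesting anywhere in the sequence."""
    if not trees:
        return 0
    return max(tree.depth() for tree in trees)


def _outer_mask(tree: ContourTree) -> tuple[np.ndarray, tuple[int, int]] | None:
    node = tree.outer_component_of_max()
    if node is None:
        return None
    return node.mask, tree.crop_offset


def _aligned_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two masks after integer centroid alignment."""
    ar, ac = np.nonzero(a)
    br, bc = np.nonzero(b)
    dr = int(round(ar.mean() - br.mean()))
    dc = int(round(ac.mean() - bc.mean()))
    pix_a = set(zip(ar.tolist(), ac.tolist()))
    pix_b = set(zip((br + dr).tolist(), (bc + dc).tolist()))
    inter = len(pix_a & pix_b)
    union = len(pix_a | pix_b)
    return inter / union


def shape_change(trees: list[ContourTree]) -> float | None:
    """Mean (1 - overlap) of outer contours across consecutive slice pairs.

    Masks are centroid-aligned before comparison, so a rigid in-plane
    shift of the whole structure (e.g. respiratory motion) does not count
    as shape change. Returns ``None`` when fewer than two slices carry a
    usable outer contour.
    """
    masks = [_outer_mask(t) for t in trees]
    vals = []
    for prev, cur in zip(masks, masks[1:]):
        if prev is None or cur is None:
            continue
        vals.append(1.0 - _aligned_jaccard(prev[0], cur[0]))
    if not vals:
        return None
    return float(np.mean(vals))


def _equivalent_radius_mm(trees: list[ContourTree]) -> float | None:
    areas = []
    for t in trees:
        node = t.outer_component_of_max()
        if node is not None:
            areas.append(node.area_mm2)
    if not areas:
        return None
    return math.sqrt(max(areas) / math.pi)


def _max_emission_point(tree: ContourTree) -> tuple[float, float] | None:
    """Location of the maximum emission on one slice.

    The centroid of the most nested contour containing the hottest pixel
    (the "white dot" region); falls back to the pixel itself when the tree
    has no node there. Using the region centroid rather than the raw argmax
    keeps the location stable under acquisition noise.
    """
    if tree.global_max is None:
        return None
    node = tree.node_containing(tree.global_max, deepest=True)
    if node is None:
        return (float(tree.global_max[0]), float(tree.global_max[1]))
    return node.centroid


def max_shift(trees: list[ContourTree]) -> float | None:
    """Largest consecutive-slice jump of the maximum emission, in units of
    the nodule equivalent radius (radius of the circle matching the
    largest outer-contour area)."""
    points = [_max_emission_point(t) for t in trees]
    disp = []
    for p, q in zip(points, points[1:]):
        if p is None or q is None:
            continue
        disp.append(math.hypot(p[0] - q[0], p[1] - q[1]))
    if not disp:
        return None
    radius = _equivalent_radius_mm(trees)
    if radius is None or radius <= 0:
        return None
    return max(disp) / radius


def max_contour_size(trees: list[ContourTree]) -> float:
    """Largest area (mm^2) of the contour directly surrounding the maximum
    emission, over the whole sequence; 0 when no slice qualifies."""
    best = 0.0
    for t in trees:
        if t.global_max is None:
            continue
        node = t.node_containing(t.global_max, deepest=True)
        if node is not None:
            best = max(best, node.area_mm2)
    return best


def raw_features(trees: list[ContourTree]) -> RawFeatures:
    """All four raw measurements from a nodule's per-slice contour trees."""
    if not trees:
        raise ValueError("no contour trees supplied")
    return RawFeatures(
        nesting_depth=nesting_degree(trees),
        shape_change=shape_change(trees),
        max_shift=max_shift(trees),
        max_contour_area_mm2=max_contour_size(trees),
    )


def _bin(value: float, thresholds: tuple[float, float]) -> int:
    if value < thresholds[0]:
        return 1
    if value < thresholds[1]:
        return 2
    return 3


def tercile_thresholds(areas) -> tuple[float, float]:
    """Cohort terciles of the max-contour areas (for the relative
    small/medium/large scale of variable 4)."""
    arr = np.asarray(list(areas), dtype=float)
    if arr.size == 0:
        raise ValueError("no areas to compute terciles from")
    t1, t2 = np.quantile(arr, [1 / 3, 2 / 3])
    if not t1 < t2:
        t2 = t1 + 1e-9
    return float(t1), float(t2)


def bin_to_scales(
    raw: RawFeatures,
    config: BinningConfig = BinningConfig(),
    nodule_id: str = "nodule",
    label: str = "unknown",
    v4_thresholds: tuple[float, float] | None = None,
) -> FeatureRecord:
    """Map raw measurements onto the weighted ordinal scales.

    v1: depth 0-1 -> 1, 2 -> 2, 3 -> 3, >=4 -> 4 (clamped).
    v2/v3: three bins below/between/above the configured thresholds;
    an undefined measurement (too few slices) maps to 1 with a warning.
    v4: bins against ``v4_thresholds`` (e.g. cohort terciles) or the fixed
    config thresholds.
    """
    v1 = int(min(max(raw.nesting_depth, 1), 4))

    if raw.shape_change is None:
        warnings.warn(f"{nodule_id}: shape change undefined (<2 usable slices); scored 1")
        v2 = 1
    else:
        v2 = _bin(raw.shape_change, config.v2_thresholds)

    if raw.max_shift is None:
        warnings.warn(f"{nodule_id}: max shift undefined (<2 usable slices); scored 1")
        v3 = 1
    else:
        v3 = _bin(raw.max_shift, config.v3_thresholds)

    if v4_thresholds is None:
        if config.v4_mode == "tercile":
            raise ValueError(
                "v4_mode='tercile' needs cohort thresholds; use bin_cohort() "
                "or pass v4_thresholds"
            )
        v4_thresholds = config.v4_thresholds_mm2
    v4 = _bin(raw.max_contour_area_mm2, v4_thresholds)
    return FeatureRecord(nodule_id, v1, v2, v3, v4, label)


def bin_cohort(
    raws: dict[str, RawFeatures],
    config: BinningConfig = BinningConfig(),
    labels: dict[str, str] | None = None,
) -> list[FeatureRecord]:
    """Bin a whole cohort, deriving the variable-4 terciles from it."""
    labels = labels or {}
    if config.v4_mode == "tercile":
        thresholds = tercile_thresholds(r.max_contour_area_mm2 for r in raws.values())
    else:
        thresholds = config.v4_thresholds_mm2
    return [
        bin_to_scales(raw, config, nodule_id=nid, label=labels.get(nid, "unknown"),
                      v4_thresholds=thresholds)
        for nid, raw in raws.items()
    ]


def read_feature_table(path) -> list[FeatureRecord]:
    """Read a manually scored feature table CSV.

    Columns ``nodule_id, v1, v2, v3, v4`` and optional ``label``.
    Out-of-scale rows raise with their (1-based, header-inclusive) line
    number so manual tables can be fixed in place.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    required = ["nodule_id", "v1", "v2", "v3", "v4"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            records.append(
                FeatureRecord(
                    nodule_id=str(row["nodule_id"]),
                    v1=int(row["v1"]),
                    v2=int(row["v2"]),
                    v3=int(row["v3"]),
                    v4=int(row["v4"]),
                    label=str(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else "unknown",
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {line}: {exc}") from exc
    return records
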