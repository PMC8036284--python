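"""The iso-contour transform: resample, normalise, render, and build the
nested-contour hierarchy.

Each axial PET slice is resampled to an isotropic 1 mm grid, min-max
normalised to [0, 1], and rendered as a grayscale contour plot. Feature
extraction works on the *contour tree*: connected components of the
superlevel sets ``{v >= k/levels}`` for ``k = 1..levels-1``, with edges
given by strict spatial containment. The hottest pixel ("maximum
emission") usually sits inside the most nested contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure
from skimage.transform import resize

__all__ = [
    "SliceImage",
    "ContourNode",
    "ContourTree",
    "resample_slice",
    "normalize",
    "render_contour_png",
    "build_contour_tree",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SliceImage:
    """A 2-D slice on an isotropic grid (1 mm after resampling)."""

    values: np.ndarray
    spacing_mm: float = 1.0
    source_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("SliceImage values must be 2-D")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def resample_slice(raw: np.ndarray, spacing_mm, source_index: int | None = None) -> SliceImage:
    """Resample a slice from ``spacing_mm`` per pixel to a 1x1 mm grid.

    The output side length is the physical extent rounded to the nearest
    millimetre (half away from zero): a 192x192 matrix at 3.6458 mm/pixel
    becomes 700x700. Bilinear interpolation; values are not normalised here.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D slice")
    if np.ndim(spacing_mm) > 0:
        sp = tuple(float(v) for v in np.ravel(spacing_mm))
        if len(set(sp)) > 1:
            raise ValueError(f"non-square pixel spacing unsupported: {sp}")
        spacing_mm = sp[0]
    spacing_mm = float(spacing_mm)
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")

    out_shape = (
        _round_half_away(raw.shape[0] * spacing_mm),
        _round_half_away(raw.shape[1] * spacing_mm),
    )
    if out_shape == raw.shape:
        values = raw.copy()
    else:
        values = resize(
            raw, out_shape, order=1, preserve_range=True,
            anti_aliasing=spacing_mm < 1.0, mode="edge",
        )
    return SliceImage(values=values, spacing_mm=1.0, source_index=source_index)


def normalize(image: SliceImage | np.ndarray) -> SliceImage:
    """Min-max normalise to [0, 1]; a constant slice maps to all zeros."""
    if isinstance(image, SliceImage):
        values, spacing, src = image.values, image.spacing_mm, image.source_index
    else:
        values, spacing, src = np.asarray(image, dtype=float), 1.0, None
    if not np.all(np.isfinite(values)):
        raise ValueError("normalize requires finite values")
    lo, hi = float(values.min()), float(values.max())
    if hi > lo:
        out = (values - lo) / (hi - lo)
    else:
        out = np.zeros_like(values)
    return SliceImage(values=out, spacing_mm=spacing, source_index=src)


def render_contour_png(
    image: SliceImage,
    levels: int = 256,
    literal_mode: bool = True,
    path=None,
) -> np.ndarray:
    """Render a normalised slice as an 8-bit grayscale contour plot.

    In *literal* mode the quantised intensity is OR-ed with a matrix of
    ones and used as the transparency of black ink composited over a white
    background: ``gray = 255 - (round(255*v) | 1)``. Setting the least
    significant bit merges adjacent intensity pairs, which is what creates
    the banded, topographic look.

    In *explicit* mode (``literal_mode=False``) the boundaries of the
    superlevel sets at thresholds ``k/levels`` are additionally drawn dark
    over the literal rendering, making the nested contours unambiguous.
    """
    v = image.values
    if v.min() < -1e-9 or v.max() > 1 + 1e-9:
        raise ValueError("render_contour_png expects a normalised image")
    q = np.round(255.0 * np.clip(v, 0.0, 1.0)).astype(np.uint8) | np.uint8(1)
    gray = (255 - q.astype(np.int32)).astype(np.uint8)

    if not literal_mode:
        for k in range(1, levels):
            mask = v >= k / levels
            if not mask.any():
                break
            interior = ndimage.binary_erosion(mask, structure=_EIGHT, border_value=1)
            gray[mask & ~interior] = 0

    if path is not None:
        Image.fromarray(gray, mode="L").save(path)
    return gray


@dataclass
class ContourNode:
    """One connected superlevel-set component (an uptake contour region)."""

    node_id: int
    level: int
    mask: np.ndarray  # bool, in crop coordinates
    area_mm2: float
    centroid: tuple[float, float]  # (row, col), absolute resampled coords
    parent: int | None
    children: list[int] = field(default_factory=list)

    def boundary_polygons(self) -> list[np.ndarray]:
        """Closed boundary curves of the region (crop coordinates)."""
        return measure.find_contours(self.mask.astype(float), 0.5)


@dataclass
class ContourTree:
    """Per-slice hierarchy of nested uptake contours inside the VOI crop."""

    nodes: dict[int, ContourNode]
    levels: int
    crop_offset: tuple[int, int]
    crop_shape: tuple[int, int]
    maxima: list[tuple[int, int]]
    global_max: tuple[int, int] | None
    global_max_value: float
    slice_index: int | None = None

    @property
    def roots(self) -> list[int]:
        return [nid for nid, n in self.nodes.items() if n.parent is None]

    def is_empty(self) -> bool:
        return not self.nodes

    def depth(self) -> int:
        """Longest root-to-leaf chain of strictly nested contours."""
        if not self.nodes:
            return 0
        memo: dict[int, int] = {}

        def down(nid: int) -> int:
            if nid not in memo:
                kids = self.nodes[nid].children
                memo[nid] = 1 + (max(down(c) for c in kids) if kids else 0)
            return memo[nid]

        return max(down(r) for r in self.roots)

    def _to_crop(self, point_abs: tuple[int, int]) -> tuple[int, int] | None:
        r = point_abs[0] - self.crop_offset[0]
        c = point_abs[1] - self.crop_offset[1]
        if 0 <= r < self.crop_shape[0] and 0 <= c < self.crop_shape[1]:
            return (r, c)
        return None

    def node_containing(self, point_abs: tuple[int, int], deepest: bool = True) -> ContourNode | None:
        """Deepest (or shallowest) contour region containing an absolute pixel."""
        pt = self._to_crop(point_abs)
        if pt is None:
            return None
        hits = [n for n in self.nodes.values() if n.mask[pt]]
        if not hits:
            return None
        key = (lambda n: n.level) if deepest else (lambda n: -n.level)
        return max(hits, key=key)

    def ancestors(self, node: ContourNode) -> list[ContourNode]:
        chain = []
        cur = node
        while cur.parent is not None:
            cur = self.nodes[cur.parent]
            chain.append(cur)
        return chain

    def outer_component_of_max(self) -> ContourNode | None:
        """Root contour enclosing this slice's maximum emission."""
        if self.global_max is None:
            return None
        node = self.node_containing(self.global_max, deepest=False)
        return node

    def to_dict(self) -> dict:
        """JSON-serialisable dump (node geometry summarised, masks omitted)."""
        deepest = (
            self.node_containing(self.global_max) if self.global_max is not None else None
        )
        return {
            "levels": self.levels,
            "slice_index": self.slice_index,
            "crop_offset": list(self.crop_offset),
            "global_max": list(self.global_max) if self.global_max else None,
            "global_max_value": self.global_max_value,
            "nodes": [
                {
                    "id": n.node_id,
                    "level": n.level,
                    "area_mm2": n.area_mm2,
                    "centroid": list(n.centroid),
                    "parent": n.parent,
                    "is_global_max_leaf": deepest is not None and n.node_id == deepest.node_id,
                }
                for n in self.nodes.values()
            ],
        }


def build_contour_tree(
    image: SliceImage,
    voi_box: tuple[int, int, int, int] | None = None,
    levels: int = 8,
) -> ContourTree:
    """Build the nested-contour hierarchy of a normalised slice.

    Components of ``{v >= k/levels}`` for ``k = 1..levels-1`` are computed
    inside the (inclusive) ``voi_box = (row_min, row_max, col_min,
    col_max)`` crop with 8-connectivity. A component whose pixel set equals
    its parent's is merged into it, so edges always mean *strict*
    containment — the tree counts visible contours, not raw thresholds.
    Areas are in mm^2 (1 mm^2 per pixel after resampling); local maxima are
    located and the hottest ("maximum emission") is flagged.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    v = image.values
    if voi_box is None:
        voi_box = (0, v.shape[0] - 1, 0, v.shape[1] - 1)
    r0, r1, c0, c1 = (int(b) for b in voi_box)
    crop = v[r0 : r1 + 1, c0 : c1 + 1]
    if crop.size == 0:
        raise ValueError("empty VOI")

    px_area = image.spacing_mm**2
    nodes: dict[int, ContourNode] = {}
    next_id = 0
    prev_labels: np.ndarray | None = None
    prev_map: dict[int, int] = {}

    for k in range(1, levels):
        mask = crop >= k / levels
        labels, ncomp = ndimage.label(mask, structure=_EIGHT)
        if ncomp == 0:
            break
        cur_map: dict[int, int] = {}
        for lab in range(1, ncomp + 1):
            comp = labels == lab
            size = int(comp.sum())
            parent_id: int | None = None
            if k > 1:
                rs, cs = np.nonzero(comp)
                parent_id = prev_map[int(prev_labels[rs[0], cs[0]])]
                if nodes[parent_id].mask.sum() == size:
                    # identical region one level down: same visible contour
                    cur_map[lab] = parent_id
                    continue
            rs, cs = np.nonzero(comp)
            node = ContourNode(
                node_id=next_id,
                level=k,
                mask=comp,
                area_mm2=size * px_area,
                centroid=(float(rs.mean()) + r0, float(cs.mean()) + c0),
                parent=parent_id,
            )
            nodes[next_id] = node
            if parent_id is not None:
                nodes[parent_id].children.append(next_id)
            cur_map[lab] = next_id
            next_id += 1
        prev_labels, prev_map = labels, cur_map

    # local maxima above the first threshold
    maxima: list[tuple[int, int]] = []
    global_max = None
    gmax_val = float(crop.max()) if crop.size else 0.0
    if gmax_val >= 1.0 / levels:
        peaks = (ndimage.maximum_filter(crop, size=3, mode="constant") == crop) & (
            crop >= 1.0 / levels
        )
        for r, c in zip(*np.nonzero(peaks)):
            maxima.append((int(r) + r0, int(c) + c0))
        gr, gc = np.unravel_index(int(np.argmax(crop)), crop.shape)
        global_max = (int(gr) + r0, int(gc) + c0)

    return ContourTree(
        nodes=nodes,
        levels=levels,
        crop_offset=(r0, c0),
        crop_shape=crop.shape,
        maxima=maxima,
        global_max=global_max,
        global_max_value=gmax_val,
        slice_index=image.source_index,
    )
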