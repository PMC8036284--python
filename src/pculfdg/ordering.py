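"""Linear ordering of nodules by GDM2 distance from a pattern object.

The four ordinal scores of each nodule are compared against an ideal
"pattern" profile using GDM2, the generalised distance measure for
non-metric (ordinal) data. GDM2 replaces differences by sign comparisons
against *every* object in the analysed set, so a distance is only defined
relative to a context:

    d_ik = 1/2 - [ sum_j w_j a_ikj b_kij
                   + sum_j sum_{l != i,k} w_j a_ilj b_klj ]
                 / ( 2 * sqrt( sum_j sum_{l != i} w_j a_ilj^2
                               * sum_j sum_{l != k} w_j b_klj^2 ) )

with a_ipj = sign(x_ij - x_pj) and b_krj = sign(x_kj - x_rj). The measure
is symmetric, bounded in [0, 1], and zero for identical profiles.

The synthetic variable of a nodule is its GDM2 distance from the pattern
object (best value on each stimulant variable); sorting ascending orders
nodules from most to least malignant-like. The sorted sequence is split at
its three largest consecutive gaps (maximum gradient method) into groups
I-IV, and a fixed distance threshold (0.4) gives a binary expectation of
malignancy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import FeatureRecord

__all__ = [
    "ScaleSpec",
    "OrderingResult",
    "DegenerateContextError",
    "GroupingError",
    "DEFAULT_SCALES",
    "pattern_object",
    "gdm2_pairwise",
    "gdm2_distance",
    "synthetic_variable",
    "max_gradient_groups",
    "classify",
    "summarize",
    "round_half_away",
]

GROUP_NAMES = ("I", "II", "III", "IV")


class DegenerateContextError(ValueError):
    """The GDM2 denominator vanished for non-identical profiles."""


class GroupingError(ValueError):
    """Too few distinct synthetic-variable values to place 3 boundaries."""


@dataclass(frozen=True)
class ScaleSpec:
    """Ordinal scale, a-priori weight and direction of one diagnostic variable.

    A *stimulant* variable's larger values indicate malignancy; a *neutral*
    variable has no preferred direction but still enters the distance with
    its weight.
    """

    variable: int
    scale_max: int
    weight: float
    kind: str  # "stimulant" | "neutral"

    def __post_init__(self) -> None:
        if self.kind not in ("stimulant", "neutral"):
            raise ValueError("kind must be 'stimulant' or 'neutral'")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")
        if self.scale_max < 2:
            raise ValueError("ordinal scale needs at least 2 levels")


#: nesting 0.6, shape change 0.3, max-uptake shift 0.05 (stimulants),
#: max-contour size 0.05 (neutral) — weights fixed a priori.
DEFAULT_SCALES: tuple[ScaleSpec, ...] = (
    ScaleSpec(1, 4, 0.60, "stimulant"),
    ScaleSpec(2, 3, 0.30, "stimulant"),
    ScaleSpec(3, 3, 0.05, "stimulant"),
    ScaleSpec(4, 3, 0.05, "neutral"),
)


def _validate_scales(scales) -> tuple[ScaleSpec, ...]:
    scales = tuple(scales)
    if abs(sum(s.weight for s in scales) - 1.0) > 1e-9:
        raise ValueError("variable weights must sum to 1")
    return scales


def pattern_object(
    scales=DEFAULT_SCALES,
    neutral_reference: int | None = None,
) -> FeatureRecord:
    """The ideal reference profile distances are measured from.

    Stimulant variables take their scale maximum (upper-pole pattern);
    the neutral variable takes ``neutral_reference`` (default: the scale
    midpoint), since it has no preferred direction yet its weight is kept.
    """
    scales = _validate_scales(scales)
    if len(scales) != 4:
        raise ValueError("expected the four diagnostic variables")
    vals = []
    for s in scales:
        if s.kind == "stimulant":
            vals.append(s.scale_max)
        else:
            vals.append(neutral_reference if neutral_reference is not None
                        else (s.scale_max + 1) // 2)
    return FeatureRecord("pattern", *vals, label="pattern")


def gdm2_pairwise(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Full GDM2 distance matrix of the rows of ``X`` (n objects x m
    ordinal variables), given per-variable ``weights``.

    Vectorised evaluation of the sign-comparison formula; the literal
    triple-loop definition is kept as an independent oracle in the test
    suite.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a context of at least 2 objects")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    S = np.sign(X[:, None, :] - X[None, :, :])  # S[i, l, j] = sign(x_ij - x_lj)
    # cross term over all l (l = i and l = k contribute exactly 0)
    T = np.einsum("ilj,klj,j->ik", S, S, w)
    pair = np.einsum("ikj,kij,j->ik", S, S, w)  # = -sum_j w_j S[i,k,j]^2
    D = np.einsum("ilj,j->i", S**2, w)

    num = pair + T
    den = 2.0 * np.sqrt(np.outer(D, D))

    d = np.full_like(num, np.nan)
    ok = den > 0
    d[ok] = 0.5 - num[ok] / den[ok]
    if not ok.all():
        ii, kk = np.nonzero(~ok)
        for i, k in zip(ii, kk):
            if np.array_equal(X[i], X[k]):
                d[i, k] = 0.0
            else:
                raise DegenerateContextError(
                    "all objects tied on every variable but profiles differ"
                )
    # identical profiles are exactly distance 0 (no float residue)
    same = (X[:, None, :] == X[None, :, :]).all(axis=-1)
    d[same] = 0.0
    return np.clip(d, 0.0, 1.0)


def _context_matrix(context: list[FeatureRecord]) -> np.ndarray:
    return np.array([r.values for r in context], dtype=float)


def _index_of(record: FeatureRecord, context: list[FeatureRecord]) -> int:
    for idx, r in enumerate(context):
        if r is record:
            return idx
    for idx, r in enumerate(context):
        if r.values == record.values:
            return idx
    raise ValueError(f"record {record.nodule_id!r} is not part of the context")


def gdm2_distance(
    record_i: FeatureRecord,
    record_k: FeatureRecord,
    context: list[FeatureRecord],
    scales=DEFAULT_SCALES,
) -> float:
    """GDM2 distance between two records *within* a context set.

    Both records must belong to ``context`` (which should include the
    pattern object when distances to it are wanted). The value depends on
    the whole context, not only on the pair: adding or removing objects
    changes every distance. Symmetric, in [0, 1], zero for identical
    profiles.
    """
    scales = _validate_scales(scales)
    if not context:
        raise ValueError("empty context")
    X = _context_matrix(list(context))
    w = np.array([s.weight for s in scales])
    i = _index_of(record_i, list(context))
    k = _index_of(record_k, list(context))
    return float(gdm2_pairwise(X, w)[i, k])


@dataclass(frozen=True)
class OrderingResult:
    """Synthetic variable, sort order and (optionally) grouping of a cohort."""

    nodule_ids: tuple[str, ...]
    distances: np.ndarray  # GDM2 distance to the pattern, cohort order
    order: np.ndarray  # ascending sort permutation (most malignant-like first)
    pattern: FeatureRecord
    boundaries: tuple[float, float, float] | None = None
    groups: tuple[str, ...] | None = None  # "I".."IV" per nodule, cohort order

    def sorted_ids(self) -> list[str]:
        return [self.nodule_ids[i] for i in self.order]


def synthetic_variable(
    cohort: list[FeatureRecord],
    scales=DEFAULT_SCALES,
    pattern: FeatureRecord | None = None,
    pattern_in_context: bool = True,
) -> OrderingResult:
    """GDM2 distance of every cohort record from the pattern object.

    The context set is the cohort plus the pattern object (the pattern can
    be excluded from the reference sums with ``pattern_in_context=False``).
    Distance 0 means "identical to the pattern", so ascending order ranks
    nodules from most to least malignant-like.
    """
    scales = _validate_scales(scales)
    if not cohort:
        raise ValueError("empty cohort")
    if pattern is None:
        pattern = pattern_object(scales)
    X = _context_matrix(list(cohort) + [pattern])
    w = np.array([s.weight for s in scales])
    n = len(cohort)

    if pattern_in_context:
        dmat = gdm2_pairwise(X, w)
        dist = dmat[:n, n]
    else:
        # pattern is the compared object but excluded from the l-sums
        dist = _distances_excluding_pattern(X, w, n)

    order = np.argsort(dist, kind="stable")
    return OrderingResult(
        nodule_ids=tuple(r.nodule_id for r in cohort),
        distances=np.asarray(dist, dtype=float),
        order=order,
        pattern=pattern,
    )


def _distances_excluding_pattern(X: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Distances of rows 0..n-1 from row n, with row n dropped from the
    reference sums (leave-pattern-out context)."""
    S = np.sign(X[:, None, :] - X[None, :, :])
    p = n
    dist = np.empty(n)
    for i in range(n):
        if np.array_equal(X[i], X[p]):
            dist[i] = 0.0
            continue
        pair = float(np.dot(w, S[i, p] * S[p, i]))
        mask = np.ones(n + 1, dtype=bool)
        mask[[i, p]] = False
        cross = float(np.einsum("lj,lj,j->", S[i, mask], S[p, mask], w))
        mask_i = np.ones(n + 1, dtype=bool)
        mask_i[p] = False  # l ranges over the cohort only
        Di = float(np.einsum("lj,j->", S[i, mask_i] ** 2, w))
        Dp = float(np.einsum("lj,j->", S[p, mask_i] ** 2, w))
        den = 2.0 * np.sqrt(Di * Dp)
        if den == 0:
            if np.array_equal(X[i], X[p]):
                dist[i] = 0.0
                continue
            raise DegenerateContextError(
                "all objects tied on every variable but profiles differ"
            )
        dist[i] = 0.5 - (pair + cross) / den
    return np.clip(dist, 0.0, 1.0)


def max_gradient_groups(result: OrderingResult, n_groups: int = 4) -> OrderingResult:
    """Split the sorted synthetic variable at its largest consecutive gaps.

    The ``n_groups - 1`` largest differences between subsequent sorted
    values define the group borders (boundary value = gap midpoint; equal
    gaps are resolved toward the smaller index). Groups are labelled I..IV
    from the smallest distance, i.e. from most malignant-like.
    """
    d_sorted = result.distances[result.order]
    n_bounds = n_groups - 1
    if len(d_sorted) < n_groups or len(np.unique(d_sorted)) < n_groups:
        raise GroupingError(
            f"need at least {n_groups} distinct synthetic-variable values"
        )
    gaps = np.diff(d_sorted)
    chosen = sorted(range(len(gaps)), key=lambda i: (-gaps[i], i))[:n_bounds]
    boundaries = tuple(sorted(float((d_sorted[i] + d_sorted[i + 1]) / 2) for i in chosen))
    labels = tuple(
        GROUP_NAMES[int(np.searchsorted(boundaries, d, side="right"))]
        for d in result.distances
    )
    return replace(result, boundaries=boundaries, groups=labels)


def classify(result: OrderingResult, threshold: float = 0.4) -> list[str]:
    """Expected nature of each nodule at the distance threshold.

    A distance from the pattern at or below the threshold indicates
    distinct features of malignancy (``"malignant"``); above it the lesion
    can be expected to be benign (``"benign"``). The boundary itself counts
    as malignant.
    """
    return ["malignant" if d <= threshold else "benign" for d in result.distances]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the reported percentages)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def summarize(group_counts) -> dict:
    """Cohort-level statistics from per-group (malignant, benign) counts.

    ``group_counts`` holds four pairs, groups I..IV in order. Reports the
    confidently classified share (groups I and IV), the indeterminate share
    (II and III), the accuracy of the distance-threshold rule (malignant
    nodules falling into groups I or II, i.e. at or below the threshold,
    out of all malignant nodules), and each group's share of either label.
    Percentages are rounded to one decimal, half away from zero.
    """
    counts = [(int(m), int(b)) for m, b in group_counts]
    if len(counts) != 4 or any(m < 0 or b < 0 for m, b in counts):
        raise ValueError("expected nonnegative (malignant, benign) counts for 4 groups")
    total = sum(m + b for m, b in counts)
    total_mal = sum(m for m, _ in counts)
    total_ben = sum(b for _, b in counts)
    if total == 0:
        raise ValueError("empty cohort")

    sizes = [m + b for m, b in counts]
    confident = sizes[0] + sizes[3]
    indeterminate = sizes[1] + sizes[2]

    def pct(num: int, den: int) -> float | None:
        return round_half_away(100.0 * num / den, 1) if den else None

    return {
        "n_total": total,
        "n_malignant": total_mal,
        "n_benign": total_ben,
        "group_sizes": dict(zip(GROUP_NAMES, sizes)),
        "confident_pct": pct(confident, total),
        "indeterminate_pct": pct(indeterminate, total),
        "accuracy_at_threshold_pct": pct(counts[0][0] + counts[1][0], total_mal),
        "group_label_shares_pct": {
            name: {
                "malignant": pct(m, total_mal),
                "benign": pct(b, total_ben),
            }
            for name, (m, b) in zip(GROUP_NAMES, counts)
        },
    }
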