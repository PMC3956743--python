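"""Numerosity-pair table and perceptually controlled wagon-array geometry.

The comparison task presents two arrays of rectangular "wagons" whose
numerosities stand in one of seven ratios (1:2 ... 7:8), two pairs per ratio.
To force number-based (rather than area- or size-based) responding, the two
arrays of a pair share the same virtual bounding rectangle (hence the same
external perimeter), have the same total surface area (achieved by shortening
the items of the more numerous array at constant item height), and share their
minimum and maximum item lengths so that the larger set is not simply the set
of smaller elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .errors import InfeasibleGeometryError

__all__ = [
    "RATIO_ORDER",
    "DISPLAY_MS",
    "StimulusPair",
    "GeometryConfig",
    "WagonArray",
    "build_pair_table",
    "generate_wagon_arrays",
    "ratio_fraction",
    "array_to_svg",
]

#: Canonical block order, easiest (most discriminable) ratio first.
RATIO_ORDER: tuple[str, ...] = ("1:2", "2:3", "3:4", "4:5", "5:6", "6:7", "7:8")

#: Per-ratio display duration of each array, in milliseconds.  Durations grow
#: with ratio because the numerosities themselves grow; they are long enough to
#: inspect every element but too short for serial counting.
DISPLAY_MS: dict[str, int] = {
    "1:2": 900,
    "2:3": 1000,
    "3:4": 1400,
    "4:5": 1800,
    "5:6": 2200,
    "6:7": 2600,
    "7:8": 3000,
}

#: The 14 numerosity pairs: for each ratio, a small-numerosity and a
#: large-numerosity realization.  All numerosities exceed 3 (outside the
#: subitizing range) except in the first 1:2 pair.
_PAIR_NUMEROSITIES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "1:2": ((3, 6), (4, 8)),
    "2:3": ((4, 6), (6, 9)),
    "3:4": ((6, 8), (9, 12)),
    "4:5": ((4, 5), (12, 15)),
    "5:6": ((5, 6), (15, 18)),
    "6:7": ((6, 7), (18, 21)),
    "7:8": ((7, 8), (21, 24)),
}


def ratio_fraction(ratio_label: str) -> float:
    """Numerical value (small/large, in (0, 1)) of a ratio label like ``"2:3"``."""
    a, b = ratio_label.split(":")
    return int(a) / int(b)


@dataclass(frozen=True)
class StimulusPair:
    """One ratio-labelled numerosity pair of the comparison task."""

    n_small: int
    n_large: int
    ratio_label: str
    set_size_index: int  # 1 = small-numerosity, 2 = large-numerosity variant
    display_ms: int

    def __post_init__(self) -> None:
        if not self.n_small < self.n_large:
            raise ValueError("n_small must be strictly smaller than n_large")
        a, b = (int(s) for s in self.ratio_label.split(":"))
        if Fraction(self.n_small, self.n_large) != Fraction(a, b):
            raise ValueError(
                f"{self.n_small} vs {self.n_large} does not reduce to {self.ratio_label}"
            )
        if self.set_size_index not in (1, 2):
            raise ValueError("set_size_index must be 1 or 2")
        if self.display_ms != DISPLAY_MS[self.ratio_label]:
            raise ValueError("display_ms does not match the per-ratio schedule")
        if self.n_small < 3:
            raise ValueError("numerosities below 3 are not presented")


def build_pair_table() -> list[StimulusPair]:
    """Return the 14 stimulus pairs, grouped by ratio in canonical block order."""
    pairs: list[StimulusPair] = []
    for ratio in RATIO_ORDER:
        for idx, (ns, nl) in enumerate(_PAIR_NUMEROSITIES[ratio], start=1):
            pairs.append(
                StimulusPair(
                    n_small=ns,
                    n_large=nl,
                    ratio_label=ratio,
                    set_size_index=idx,
                    display_ms=DISPLAY_MS[ratio],
                )
            )
    return pairs


@dataclass(frozen=True)
class GeometryConfig:
    """Geometric parameters of wagon-array construction (abstract units).

    ``length_range`` must be wide enough that the two set sizes of every pair
    admit a common total length: for numerosities (n1, n2), feasibility needs
    (n2 - 2) * min <= (n1 - 2) * max.  The default (0.5, 2.5) covers every
    pair of the published table.
    """

    item_height: float = 1.0
    length_range: tuple[float, float] = (0.5, 2.5)
    bounding_box: tuple[float, float] = (20.0, 20.0)
    area_tolerance: float = 1e-6  # relative to total area
    max_placement_attempts: int = 2000
    max_array_restarts: int = 50


@dataclass
class WagonArray:
    """A placed array of axis-aligned wagon rectangles.

    ``rectangles`` holds (length, height, x, y) with (x, y) the lower-left
    corner; all heights are equal within an array and every rectangle lies
    inside ``bounding_box`` without overlapping another.
    """

    rectangles: list[tuple[float, float, float, float]] = field(default_factory=list)
    bounding_box: tuple[float, float] = (0.0, 0.0)
    numerosity: int = 0

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r[0] for r in self.rectangles])

    @property
    def total_area(self) -> float:
        return float(sum(l * h for l, h, _, _ in self.rectangles))

    def to_json(self) -> str:
        return json.dumps(
            {
                "bounding_box": list(self.bounding_box),
                "numerosity": self.numerosity,
                "rectangles": [list(r) for r in self.rectangles],
            }
        )


def _shared_total_length(n1: int, n2: int, lmin: float, lmax: float) -> float:
    """Common total item length feasible for both numerosities.

    With the shared min and max lengths pinned in each array, an array of n
    items can realize any total length in
    [lmin + lmax + (n-2)*lmin, lmin + lmax + (n-2)*lmax].  The midpoint of the
    intersection of the two arrays' intervals is returned.
    """
    lo = lmin + lmax + max(n1 - 2, n2 - 2) * lmin
    hi = lmin + lmax + min(n1 - 2, n2 - 2) * lmax
    if lo > hi + 1e-12:
        raise InfeasibleGeometryError(
            f"no common total length for numerosities {n1} and {n2} "
            f"with length range ({lmin}, {lmax})"
        )
    return 0.5 * (lo + hi)


def _draw_lengths(
    n: int, total: float, lmin: float, lmax: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n item lengths in [lmin, lmax] with pinned min/max summing to ``total``.

    The extreme items take the shared min and max exactly; the n-2 interior
    lengths are drawn uniformly and then contracted affinely toward lmin (when
    the draw overshoots the target) or toward lmax (when it undershoots), which
    keeps every length inside the bounds and hits the target sum exactly.
    """
    interior_target = total - lmin - lmax
    m = n - 2
    if m == 0:
        if abs(interior_target) > 1e-9:
            raise InfeasibleGeometryError("two items cannot absorb an interior total")
        return np.array([lmin, lmax])
    if not (m * lmin - 1e-9 <= interior_target <= m * lmax + 1e-9):
        raise InfeasibleGeometryError("interior total outside attainable range")
    draw = rng.uniform(lmin, lmax, size=m)
    s = draw.sum()
    if s >= interior_target:
        denom = s - m * lmin
        r = 0.0 if denom <= 0 else (interior_target - m * lmin) / denom
        interior = lmin + (draw - lmin) * r
    else:
        denom = m * lmax - s
        r = 0.0 if denom <= 0 else (m * lmax - interior_target) / denom
        interior = lmax - (lmax - draw) * r
    return np.concatenate(([lmin, lmax], interior))


def _overlaps(
    a: tuple[float, float, float, float], b: tuple[float, float, float, float]
) -> bool:
    la, ha, xa, ya = a
    lb, hb, xb, yb = b
    return (xa < xb + lb) and (xb < xa + la) and (ya < yb + hb) and (yb < ya + ha)


def _place(
    lengths: np.ndarray, cfg: GeometryConfig, rng: np.random.Generator
) -> list[tuple[float, float, float, float]]:
    """Rejection-sample non-overlapping positions inside the bounding box."""
    W, H = cfg.bounding_box
    h = cfg.item_height
    for _ in range(cfg.max_array_restarts):
        placed: list[tuple[float, float, float, float]] = []
        ok = True
        for length in lengths:
            if length > W or h > H:
                raise InfeasibleGeometryError("item larger than bounding box")
            for _ in range(cfg.max_placement_attempts):
                x = rng.uniform(0.0, W - length)
                y = rng.uniform(0.0, H - h)
                rect = (float(length), float(h), float(x), float(y))
                if not any(_overlaps(rect, other) for other in placed):
                    placed.append(rect)
                    break
            else:
                ok = False
                break
        if ok:
            return placed
    raise InfeasibleGeometryError("could not place items without overlap")


def generate_wagon_arrays(
    pair: StimulusPair,
    geometry_cfg: GeometryConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[WagonArray, WagonArray]:
    """Build the two perceptually controlled arrays realizing ``pair``.

    Both arrays share the bounding box (hence external perimeter), the total
    item area (equal item height, shared total length), and the minimum and
    maximum item lengths.  Placement is randomized under ``rng``.

    Raises
    ------
    InfeasibleGeometryError
        When no length assignment can equate areas while pinning the shared
        min/max lengths at the two numerosities (e.g. a degenerate
        ``length_range`` collapsed to a point).
    """
    cfg = geometry_cfg if geometry_cfg is not None else GeometryConfig()
    rng = np.random.default_rng() if rng is None else rng
    lmin, lmax = cfg.length_range
    total = _shared_total_length(pair.n_small, pair.n_large, lmin, lmax)
    arrays = []
    for n in (pair.n_small, pair.n_large):
        lengths = _draw_lengths(n, total, lmin, lmax, rng)
        rects = _place(lengths, cfg, rng)
        arrays.append(
            WagonArray(rectangles=rects, bounding_box=cfg.bounding_box, numerosity=n)
        )
    a1, a2 = arrays
    if abs(a1.total_area - a2.total_area) > cfg.area_tolerance * a1.total_area:
        raise InfeasibleGeometryError("area equating failed beyond tolerance")
    return a1, a2


def array_to_svg(array: WagonArray, scale: float = 20.0) -> str:
    """Render an array as a minimal SVG string (for documentation)."""
    W, H = array.bounding_box
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W * scale:.0f}" '
        f'height="{H * scale:.0f}" viewBox="0 0 {W * scale:.0f} {H * scale:.0f}">',
        f'<rect width="{W * scale:.0f}" height="{H * scale:.0f}" fill="#ddd"/>',
    ]
    for length, h, x, y in array.rectangles:
        # SVG's y axis points down; flip so (x, y) stays the lower-left corner.
        parts.append(
            f'<rect x="{x * scale:.1f}" y="{(H - y - h) * scale:.1f}" '
            f'width="{length * scale:.1f}" height="{h * scale:.1f}" fill="#000"/>'
        )
    parts.append("</svg>")
    return "".join(parts)
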