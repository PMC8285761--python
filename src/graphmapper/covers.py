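"""Open covers of the lens codomain and pull back membership.

Three cover families:

* :class:`IntervalCover` — ``n`` equally sized overlapping closed
  intervals on the line; consecutive elements share a fraction
  ``overlap_g`` of their length.
* :class:`GridCover` — the product of two interval covers: a grid of
  overlapping rectangles in the plane (row-major element order).
* :class:`RBFCover` — ``n`` Gaussian kernels ``phi(x, x_i) =
  exp(-(x - x_i)^2 / delta)`` at fixed centers on ``[0, 1]``; used by the
  differentiable pooling operator, where kernel overlap is controlled by
  the scale ``delta`` instead of an overlap fraction.

Cover elements are treated as closed sets, so a lens value sitting
exactly on a shared boundary belongs to both neighbors.  This is a
measure-zero deviation from open covers that avoids dropping nodes on
finite data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lenses import LensValues

__all__ = [
    "IntervalCover",
    "GridCover",
    "RBFCover",
    "make_interval_cover",
    "make_grid_cover",
    "make_rbf_cover",
    "hard_membership",
    "rbf_kernel",
]


@dataclass
class IntervalCover:
    """Ordered cover of ``[lo, hi]`` by closed intervals (endpoints may be
    infinite for covers such as the two half-lines of a spectral split)."""

    elements: list[tuple[float, float]]
    overlap_g: float = 0.0

    def __post_init__(self) -> None:
        for a, b in self.elements:
            if not a <= b:
                raise ValueError(f"degenerate interval ({a}, {b})")

    @property
    def n(self) -> int:
        return len(self.elements)

    @property
    def dim(self) -> int:
        return 1

    @property
    def range(self) -> tuple[float, float]:
        return (
            min(a for a, _ in self.elements),
            max(b for _, b in self.elements),
        )

    def is_bounded(self) -> bool:
        lo, hi = self.range
        return math.isfinite(lo) and math.isfinite(hi)

    def membership(self, x: np.ndarray) -> list[np.ndarray]:
        """Indices of nodes whose value lies in each (closed) element."""
        x = np.asarray(x, dtype=float).ravel()
        return [
            np.flatnonzero((x >= a - 1e-12) & (x <= b + 1e-12))
            for a, b in self.elements
        ]


@dataclass
class GridCover:
    """Row-major grid of overlapping rectangles covering a 2D bounding box."""

    x_cover: IntervalCover
    y_cover: IntervalCover

    @property
    def nx(self) -> int:
        return self.x_cover.n

    @property
    def ny(self) -> int:
        return self.y_cover.n

    @property
    def n(self) -> int:
        return self.nx * self.ny

    @property
    def dim(self) -> int:
        return 2

    @property
    def elements(self) -> list[tuple[float, float, float, float]]:
        # row-major: iterate y (rows) outer, x (columns) inner
        return [
            (xa, xb, ya, yb)
            for ya, yb in self.y_cover.elements
            for xa, xb in self.x_cover.elements
        ]

    @property
    def range(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.x_cover.range, self.y_cover.range)

    def is_bounded(self) -> bool:
        return self.x_cover.is_bounded() and self.y_cover.is_bounded()

    def membership(self, xy: np.ndarray) -> list[np.ndarray]:
        xy = np.asarray(xy, dtype=float)
        mx = self.x_cover.membership(xy[:, 0])
        my = self.y_cover.membership(xy[:, 1])
        mx_sets = [set(m.tolist()) for m in mx]
        return [
            np.asarray(sorted(set(my_row.tolist()) & mx_col), dtype=int)
            for my_row in my
            for mx_col in mx_sets
        ]


@dataclass
class RBFCover:
    """Gaussian-kernel cover of the unit interval.

    ``scale`` (delta) controls overlap: at large scales every kernel sees
    every point roughly equally; at small scales each point effectively
    belongs to the nearest center only.  The default scale is
    ``1 / n^2``, which shrinks kernels as the cover gets finer.
    """

    centers: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        if self.centers.size < 1:
            raise ValueError("need at least one kernel center")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.scale <= 0:
            raise ValueError("kernel scale delta must be positive")

    @property
    def n(self) -> int:
        return self.centers.size

    @property
    def dim(self) -> int:
        return 1

    def kernel_values(self, x: np.ndarray) -> np.ndarray:
        """``phi(x_i, c_j)`` matrix of shape ``(len(x), n)``."""
        return rbf_kernel(np.asarray(x, dtype=float).ravel()[:, None],
                          self.centers[None, :], self.scale)


def rbf_kernel(x, center, scale: float) -> np.ndarray:
    """Radial basis function ``exp(-(x - center)^2 / scale)``: equals 1 at
    the center and decreases strictly with distance."""
    return np.exp(-((np.asarray(x) - np.asarray(center)) ** 2) / scale)


def make_interval_cover(
    n: int, overlap_g: float, lo: float, hi: float
) -> IntervalCover:
    """``n`` equal-length intervals over ``[lo, hi]`` with fractional overlap.

    Element length is ``L = (hi - lo) / (1 + (n - 1) (1 - g))`` and left
    endpoints step by ``L (1 - g)``, so consecutive elements intersect in
    a segment of length ``g * L``; the first element starts at ``lo`` and
    the last ends at ``hi``.
    """
    if n < 1:
        raise ValueError("need n >= 1 intervals")
    if not 0.0 <= overlap_g < 1.0:
        raise ValueError("overlap fraction must lie in [0, 1)")
    if not lo < hi:
        raise ValueError("need lo < hi")
    span = hi - lo
    length = span / (1.0 + (n - 1) * (1.0 - overlap_g))
    step = length * (1.0 - overlap_g)
    elements = [(lo + i * step, lo + i * step + length) for i in range(n)]
    # pin the final endpoint against accumulated rounding
    a_last, _ = elements[-1]
    elements[-1] = (a_last, hi)
    return IntervalCover(elements, overlap_g=overlap_g)


def make_grid_cover(
    nx: int, ny: int, overlap_g: float, bbox: tuple[tuple[float, float], tuple[float, float]]
) -> GridCover:
    """Grid cover of a bounding box ``((xlo, xhi), (ylo, yhi))``.

    A degenerate axis (zero extent) collapses to a single cell spanning a
    unit-width band around the constant value.
    """
    import warnings

    (xlo, xhi), (ylo, yhi) = bbox
    covers = []
    for axis_n, lo, hi, label in ((nx, xlo, xhi, "x"), (ny, ylo, yhi, "y")):
        if hi <= lo:
            warnings.warn(f"degenerate bbox on {label}-axis; using one cell")
            covers.append(IntervalCover([(lo - 0.5, lo + 0.5)], overlap_g=overlap_g))
        else:
            covers.append(make_interval_cover(axis_n, overlap_g, lo, hi))
    return GridCover(covers[0], covers[1])


def make_rbf_cover(n: int, scale_delta: float | None = None) -> RBFCover:
    """``n`` kernels with centers equally spaced on ``[0, 1]``.

    For ``n > 1`` the centers are ``i / (n - 1)``; a single kernel sits at
    0.5.  The scale defaults to ``1 / n^2`` when not given.
    """
    if n < 1:
        raise ValueError("need n >= 1 kernels")
    centers = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    scale = 1.0 / n**2 if scale_delta is None else float(scale_delta)
    return RBFCover(centers, scale)


def rescale_lens(lens: LensValues, cover) -> np.ndarray:
    """Affinely map lens values onto the cover's range, per dimension.

    Guarantees total coverage: after rescaling, every node falls inside
    the union of the cover elements.  A constant lens dimension maps to
    the midpoint of the cover range.  Covers with unbounded elements are
    taken at face value (no rescaling).
    """
    vals = lens.values.copy()
    if not cover.is_bounded():
        return vals
    if cover.dim == 1:
        ranges = [cover.range]
    else:
        ranges = list(cover.range)
    for j, (clo, chi) in enumerate(ranges):
        lo, hi = vals[:, j].min(), vals[:, j].max()
        if hi - lo < 1e-15:
            vals[:, j] = 0.5 * (clo + chi)
        else:
            vals[:, j] = clo + (vals[:, j] - lo) * (chi - clo) / (hi - lo)
    return vals


def hard_membership(
    lens: LensValues, cover, rescale: bool = True
) -> list[np.ndarray]:
    """Pull back sets ``f^{-1}(U_i)`` for an interval or grid cover.

    Returns one sorted node-index array per cover element (in element
    order).  Lens values are first rescaled onto the cover range (see
    :func:`rescale_lens`), so every node lands in at least one element;
    values on an overlap belong to all covering elements.
    """
    if lens.dim != cover.dim:
        raise ValueError(
            f"lens dimension {lens.dim} does not match cover dimension {cover.dim}"
        )
    vals = rescale_lens(lens, cover) if rescale else lens.values
    if cover.dim == 1:
        return cover.membership(vals[:, 0])
    return cover.membership(vals)
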