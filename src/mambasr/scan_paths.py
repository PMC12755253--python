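"""Scan orderings used to serialize 2D token grids for selective scanning.

A selective state-space layer consumes a 1D token sequence, so a 2D feature
grid must first be flattened along some traversal.  Raster (horizontal or
vertical) traversals place diagonally adjacent pixels far apart in the
sequence ("pixel forgetting"); diagonal traversals keep a pixel and its
diagonal neighbours at sequence distance 1.  The hybrid scan set used by the
super-resolution network combines horizontal, vertical and diagonal
(or zigzag) traversals, each forward and reversed.

Cells are indexed row-major, 0-based: cell ``r * width + c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

SCAN_KINDS = ("horizontal", "vertical", "antidiagonal", "maindiagonal", "zigzag")
SCAN_DIRECTIONS = ("forward", "reverse")

__all__ = [
    "ScanOrder",
    "ScanSet",
    "build_scan_order",
    "build_scan_set",
    "invert_order",
    "serialize",
    "deserialize",
    "SCAN_KINDS",
    "SCAN_DIRECTIONS",
]


@dataclass(frozen=True)
class ScanOrder:
    """A bijective traversal of an ``height x width`` grid.

    ``order[t]`` is the row-major cell index visited at sequence position
    ``t``; ``inverse[cell]`` is the sequence position of ``cell``.
    """

    height: int
    width: int
    kind: str
    direction: str
    order: np.ndarray
    inverse: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=np.intp)
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "inverse", invert_order(order))

    @property
    def n_cells(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class ScanSet:
    """The collection of scan orders driving the parallel SSM heads."""

    orders: List[ScanOrder]
    scan_type: str
    scan_count: int

    def __post_init__(self) -> None:
        if not self.orders:
            raise ValueError("ScanSet needs at least one order")
        h, w = self.orders[0].height, self.orders[0].width
        if any(o.height != h or o.width != w for o in self.orders):
            raise ValueError("all scan orders must share the same grid size")
        if self.scan_count != len(self.orders):
            raise ValueError("scan_count must equal len(orders)")

    @property
    def height(self) -> int:
        return self.orders[0].height

    @property
    def width(self) -> int:
        return self.orders[0].width


def invert_order(order: Sequence[int]) -> np.ndarray:
    """Invert a permutation: result ``o`` satisfies ``o[order[t]] == t``."""
    order = np.asarray(order, dtype=np.intp)
    n = order.size
    if n == 0:
        raise ValueError("empty permutation")
    seen = np.zeros(n, dtype=bool)
    if order.min() < 0 or order.max() >= n:
        raise ValueError("permutation entries must lie in 0..n-1")
    seen[order] = True
    if not seen.all():
        raise ValueError("input is not a permutation (duplicate entries)")
    inv = np.empty(n, dtype=np.intp)
    inv[order] = np.arange(n, dtype=np.intp)
    return inv


def _antidiagonal_order(height: int, width: int) -> np.ndarray:
    """Anti-diagonals d = r + c in increasing d, increasing row within each."""
    cells = []
    for d in range(height + width - 1):
        r_lo = max(0, d - width + 1)
        r_hi = min(d, height - 1)
        for r in range(r_lo, r_hi + 1):
            cells.append(r * width + (d - r))
    return np.asarray(cells, dtype=np.intp)


def _zigzag_order(height: int, width: int) -> np.ndarray:
    """JPEG-style zigzag: anti-diagonals with alternating traversal sense."""
    cells = []
    for d in range(height + width - 1):
        r_lo = max(0, d - width + 1)
        r_hi = min(d, height - 1)
        rows = range(r_lo, r_hi + 1)
        if d % 2 == 0:
            rows = reversed(list(rows))  # even diagonals run bottom-left -> top-right
        for r in rows:
            cells.append(r * width + (d - r))
    return np.asarray(cells, dtype=np.intp)


def _mirror_columns(order: np.ndarray, height: int, width: int) -> np.ndarray:
    """Apply a traversal to the horizontally mirrored grid, mapped back."""
    r, c = np.divmod(order, width)
    return r * width + (width - 1 - c)


def build_scan_order(height: int, width: int, kind: str, direction: str = "forward") -> ScanOrder:
    """Construct one scan order over an ``height x width`` grid.

    Parameters
    ----------
    kind
        ``horizontal`` (row-major raster), ``vertical`` (column-major),
        ``antidiagonal`` (anti-diagonals ``d = r + c``, increasing row within
        each), ``maindiagonal`` (the anti-diagonal traversal of the
        horizontally mirrored grid, mirrored back, i.e. diagonals
        ``r - c``), or ``zigzag`` (JPEG-style alternating anti-diagonals).
    direction
        ``forward``, or ``reverse`` for the exactly reversed visitation.
    """
    if height < 1 or width < 1:
        raise ValueError(f"grid dimensions must be positive, got {height}x{width}")
    if kind not in SCAN_KINDS:
        raise ValueError(f"unknown scan kind {kind!r}; expected one of {SCAN_KINDS}")
    if direction not in SCAN_DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")

    if kind == "horizontal":
        order = np.arange(height * width, dtype=np.intp)
    elif kind == "vertical":
        order = np.arange(height * width, dtype=np.intp).reshape(height, width).T.ravel()
    elif kind == "antidiagonal":
        order = _antidiagonal_order(height, width)
    elif kind == "maindiagonal":
        order = _mirror_columns(_antidiagonal_order(height, width), height, width)
    else:  # zigzag
        order = _zigzag_order(height, width)

    if direction == "reverse":
        order = order[::-1].copy()
    return ScanOrder(height=height, width=width, kind=kind, direction=direction, order=order)


def build_scan_set(height: int, width: int, scan_type: str = "diagonal", scan_count: int = 8) -> ScanSet:
    """Build the hybrid multi-path scan set.

    With ``scan_count=8`` and ``scan_type='diagonal'`` the set is the four
    kinds {horizontal, vertical, antidiagonal, maindiagonal} x {forward,
    reverse}; ``scan_type='zigzag'`` substitutes the zigzag traversal and its
    column-mirrored variant for the two diagonal kinds.  ``scan_count=4``
    keeps only the forward direction of each kind, so every scan family stays
    represented.
    """
    if scan_type not in ("diagonal", "zigzag"):
        raise ValueError(f"unknown scan_type {scan_type!r}")
    if scan_count not in (4, 8):
        raise ValueError(f"scan_count must be 4 or 8, got {scan_count}")

    if scan_type == "diagonal":
        kinds = ["horizontal", "vertical", "antidiagonal", "maindiagonal"]
        orders = [build_scan_order(height, width, k, "forward") for k in kinds]
    else:
        orders = [
            build_scan_order(height, width, "horizontal", "forward"),
            build_scan_order(height, width, "vertical", "forward"),
            build_scan_order(height, width, "zigzag", "forward"),
        ]
        # mirrored zigzag plays the role of the second diagonal family
        zz = build_scan_order(height, width, "zigzag", "forward")
        mirrored = _mirror_columns(zz.order, height, width)
        orders.append(ScanOrder(height=height, width=width, kind="zigzag",
                                direction="forward", order=mirrored))

    if scan_count == 8:
        reversed_orders = [
            ScanOrder(height=height, width=width, kind=o.kind, direction="reverse",
                      order=o.order[::-1].copy())
            for o in orders
        ]
        orders = orders + reversed_orders
    return ScanSet(orders=orders, scan_type=scan_type, scan_count=scan_count)


def serialize(features: np.ndarray, order: ScanOrder) -> np.ndarray:
    """Flatten a ``[C, H, W]`` grid to a ``[C, H*W]`` sequence along ``order``."""
    features = np.asarray(features)
    if features.ndim != 3 or features.shape[1:] != (order.height, order.width):
        raise ValueError(
            f"feature grid shape {features.shape} does not match order grid "
            f"{order.height}x{order.width}"
        )
    return features.reshape(features.shape[0], -1)[:, order.order]


def deserialize(seq: np.ndarray, order: ScanOrder) -> np.ndarray:
    """Inverse of :func:`serialize`: ``[C, H*W]`` sequence back to the grid."""
    seq = np.asarray(seq)
    if seq.ndim != 2 or seq.shape[1] != order.n_cells:
        raise ValueError(f"sequence shape {seq.shape} does not match order length {order.n_cells}")
    return seq[:, order.inverse].reshape(seq.shape[0], order.height, order.width)
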