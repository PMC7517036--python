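"""Areas of interest (AOIs): regular grid partitions of a stimulus.

An AOI partition tiles the stimulus exactly with axis-aligned rectangles,
indexed 1..s in row-major order (AOI 1 is top-left). Cell boundaries sit
at ``floor(k * width / cols)`` so every pixel of the stimulus belongs to
exactly one cell; cells are half-open on their right/bottom edges, with
the last row/column absorbing the remainder.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass


@dataclass(frozen=True)
class AOIPartition:
    """A grid partition of a ``width x height`` stimulus into rows*cols AOIs."""

    rows: int
    cols: int
    stimulus_width: int
    stimulus_height: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("invalid grid: rows and cols must be >= 1")
        if self.stimulus_width < self.cols or self.stimulus_height < self.rows:
            raise ValueError("invalid grid: stimulus smaller than the grid")

    @property
    def s(self) -> int:
        """Number of AOIs."""
        return self.rows * self.cols

    @property
    def x_bounds(self) -> list[int]:
        return [(k * self.stimulus_width) // self.cols for k in range(self.cols + 1)]

    @property
    def y_bounds(self) -> list[int]:
        return [(k * self.stimulus_height) // self.rows for k in range(self.rows + 1)]

    @property
    def regions(self) -> list[tuple[int, int, int, int]]:
        """Rectangles ``(x0, y0, x1, y1)``, half-open, in row-major AOI order."""
        xb, yb = self.x_bounds, self.y_bounds
        return [
            (xb[c], yb[r], xb[c + 1], yb[r + 1])
            for r in range(self.rows)
            for c in range(self.cols)
        ]

    def assign(self, x: float, y: float, clamp: bool = False) -> int:
        """Return the 1-based AOI index containing pixel position ``(x, y)``.

        Out-of-bounds positions raise unless ``clamp`` is set, in which case
        they are clamped to the nearest edge (eye-tracker noise can land a
        fixation just outside the screen).
        """
        w, h = self.stimulus_width, self.stimulus_height
        if clamp:
            x = min(max(x, 0.0), w - 1)
            y = min(max(y, 0.0), h - 1)
        elif not (0 <= x < w and 0 <= y < h):
            raise ValueError(
                f"fixation outside stimulus: ({x}, {y}) not in [0,{w}) x [0,{h})"
            )
        col = bisect_right(self.x_bounds, x) - 1
        row = bisect_right(self.y_bounds, y) - 1
        # interior boundary points fall in the cell to their right/below by
        # the half-open convention; the last bound equals width/height and is
        # unreachable for in-bounds x, y
        col = min(col, self.cols - 1)
        row = min(row, self.rows - 1)
        return row * self.cols + col + 1


def make_grid_partition(rows: int, cols: int, width: int, height: int) -> AOIPartition:
    """Build a ``rows x cols`` grid partition of a ``width x height`` stimulus.

    ``make_grid_partition(3, 1, w, h)`` gives three horizontal bands and
    ``(1, 3, w, h)`` three vertical strips — the two 3-AOI divisions used to
    contrast horizontal with vertical gaze behaviour.
    """
    return AOIPartition(rows=rows, cols=cols, stimulus_width=width, stimulus_height=height)


def assign_aoi(x: float, y: float, partition: AOIPartition, clamp: bool = False) -> int:
    """Functional alias for :meth:`AOIPartition.assign`."""
    return partition.assign(x, y, clamp=clamp)
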