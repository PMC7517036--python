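"""Transition-count matrices over AOIs.

The matrix ``C`` records immediate gaze transitions: entry ``c_ij`` is the
number of times AOI ``j`` was visited directly after AOI ``i``. The
fictional entry/exit state (gaze arriving at / leaving the stimulus) is
ignored: for non-trivial trajectories the number of entries and exits per
AOI are equal up to one, so row and column totals nearly coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aoi import AOIPartition
from .types import ScanPath


@dataclass(frozen=True)
class TransitionCounts:
    """An s×s matrix of non-negative integer transition counts."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=np.int64)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("transition count matrix must be square")
        if (C < 0).any():
            raise ValueError("transition counts must be non-negative")
        object.__setattr__(self, "C", C)

    @property
    def s(self) -> int:
        return self.C.shape[0]

    @property
    def N(self) -> int:
        """Total number of transitions."""
        return int(self.C.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """N_i: number of transitions leaving each AOI."""
        return self.C.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """N_j: number of transitions arriving at each AOI."""
        return self.C.sum(axis=0)

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        if self.C.shape != other.C.shape:
            raise ValueError("cannot add transition counts of different AOI counts")
        return TransitionCounts(self.C + other.C)


def aoi_sequence(path: ScanPath, partition: AOIPartition, clamp: bool = False) -> list[int]:
    """Map a scanpath to its sequence of visited AOI indices (1-based)."""
    return [partition.assign(f.x, f.y, clamp=clamp) for f in path.fixations]


def collapse_repeats(seq: list[int]) -> list[int]:
    """Merge runs of consecutive identical AOIs into single visits."""
    out: list[int] = []
    for a in seq:
        if not out or out[-1] != a:
            out.append(a)
    return out


def counts_from_sequence(seq: list[int], s: int, include_self: bool = True) -> TransitionCounts:
    """Count immediate transitions in a 1-based AOI index sequence.

    With ``include_self=False`` consecutive same-AOI fixations are first
    collapsed into single visits, so the diagonal of the result is zero.
    """
    if not include_self:
        seq = collapse_repeats(seq)
    C = np.zeros((s, s), dtype=np.int64)
    for i, j in zip(seq, seq[1:]):
        C[i - 1, j - 1] += 1
    return TransitionCounts(C)


def build_transition_counts(
    path: ScanPath,
    partition: AOIPartition,
    include_self: bool = True,
    clamp: bool = False,
) -> TransitionCounts:
    """Build the AOI transition-count matrix of one scanpath.

    An empty or single-fixation path yields an all-zero matrix with N = 0;
    downstream channel construction rejects that case explicitly.
    """
    seq = aoi_sequence(path, partition, clamp=clamp)
    return counts_from_sequence(seq, partition.s, include_self=include_self)


def cluster_counts(counts_list: list[TransitionCounts]) -> TransitionCounts:
    """Sum transition-count matrices element-wise.

    This is how gaze data is pooled before computing channel measures: the
    fixation transitions of several observers on one stimulus (or of one
    observer over several stimuli) are added together, and the measures are
    computed on the pooled channel. Summing counts is not the same as
    averaging measures — two deterministic observers moving in opposite
    cycles pool into a genuinely uncertain channel.
    """
    if not counts_list:
        raise ValueError("cluster_counts requires a non-empty list")
    total = counts_list[0]
    for c in counts_list[1:]:
        total = total + c
    return total
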