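"""Time-resolved channel measures: how gaze statistics evolve with viewing time.

Truncating every scanpath to its first ``t`` seconds and re-fitting the
pooled channel traces the build-up of the measures: stationary, joint
entropy and mutual information typically rise and then stabilise as the
observer moves from global scanning to focused re-inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .aoi import AOIPartition
from .channel import MEASURE_COLUMNS, ChannelMeasures, GazeChannel
from .counts import build_transition_counts, cluster_counts
from .types import ScanPath

#: Default observation-time grid in seconds (5 s steps over a 45 s viewing).
DEFAULT_TIMES: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45)


def truncate_by_time(path: ScanPath, t: float) -> ScanPath:
    """Keep the fixations with onset strictly before ``t`` seconds.

    A fixation straddling ``t`` is kept iff it *started* before ``t``;
    ``t = 0`` yields an empty path.
    """
    if t < 0:
        raise ValueError("truncation time must be >= 0")
    return ScanPath(
        fixations=[f for f in path.fixations if f.onset < t],
        stimulus_width=path.stimulus_width,
        stimulus_height=path.stimulus_height,
    )


@dataclass
class EvolutionCurve:
    """Channel measures at a grid of observation times.

    Entries where the truncated paths hold no transitions are ``None``
    (flagged empty rather than erroring: very short viewing windows may
    contain at most one fixation).
    """

    times: list[float]
    measures: list[ChannelMeasures | None]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_s, measure, value); empty entries NaN."""
        rows = []
        for t, m in zip(self.times, self.measures):
            d = m.to_dict() if m is not None else {c: float("nan") for c in MEASURE_COLUMNS}
            for name, value in d.items():
                rows.append({"time_s": t, "measure": name, "value": value})
        return pd.DataFrame(rows)

    def plot(self, ax=None, measures: Sequence[str] = ("H(X)", "H(X,Y)", "I(X;Y)")):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wide = self.to_frame().pivot(index="time_s", columns="measure", values="value")
        for name in measures:
            ax.plot(wide.index, wide[name], marker="o", label=name)
        ax.set_xlabel("observation time (s)")
        ax.set_ylabel("bits")
        ax.legend()
        return ax


def evolution_curve(
    paths: Sequence[ScanPath],
    partition: AOIPartition,
    times: Sequence[float] = DEFAULT_TIMES,
    include_self: bool = True,
    clamp: bool = False,
    log_base: float = 2.0,
) -> EvolutionCurve:
    """Measure evolution over observation time for pooled scanpaths.

    For each time ``t`` the paths are truncated to onset < t, their
    transition counts pooled, and the channel measures computed.
    """
    times = list(times)
    if not times:
        raise ValueError("times must be non-empty")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    out: list[ChannelMeasures | None] = []
    for t in times:
        counts = cluster_counts(
            [build_transition_counts(truncate_by_time(p, t), partition,
                                     include_self=include_self, clamp=clamp)
             for p in paths]
        )
        if counts.N == 0:
            out.append(None)
        else:
            out.append(GazeChannel.from_counts(counts).measures(log_base=log_base))
    return EvolutionCurve(times=times, measures=out)
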