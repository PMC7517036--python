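"""Core record types: fixations and scanpaths.

A *fixation* is a period during which gaze rests at one location; a
*scanpath* is the time-ordered sequence of one observer's fixations on
one stimulus. Coordinates are 0-based pixels, origin at the top-left of
the stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Fixation:
    """One fixation event.

    Parameters
    ----------
    onset : float
        Seconds from stimulus onset; must be >= 0.
    duration : float
        Fixation duration in milliseconds; must be > 0.
    x, y : float
        Gaze position in pixels (x from left, y from top).
    observer_id, stimulus_id : str
        Labels identifying the observer and the stimulus.
    """

    onset: float
    duration: float
    x: float
    y: float
    observer_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.onset}")
        if not self.duration > 0:
            raise ValueError(f"fixation duration must be > 0, got {self.duration}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fixation position must be finite")


@dataclass
class ScanPath:
    """An ordered fixation sequence of one observer on one stimulus.

    Invariants checked at construction: onsets are non-decreasing and all
    fixations carry the same ``observer_id`` and ``stimulus_id``.
    """

    fixations: list[Fixation] = field(default_factory=list)
    stimulus_width: int = 0
    stimulus_height: int = 0

    def __post_init__(self) -> None:
        for a, b in zip(self.fixations, self.fixations[1:]):
            if b.onset < a.onset:
                raise ValueError("scanpath onsets must be non-decreasing")
        ids = {(f.observer_id, f.stimulus_id) for f in self.fixations}
        if len(ids) > 1:
            raise ValueError("all fixations in a scanpath must share observer and stimulus")

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    @property
    def observer_id(self) -> str:
        return self.fixations[0].observer_id if self.fixations else ""

    @property
    def stimulus_id(self) -> str:
        return self.fixations[0].stimulus_id if self.fixations else ""
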