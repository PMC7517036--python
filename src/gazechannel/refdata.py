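"""Reference measure tables from a published eye-tracking study.

Clustered gaze-channel measures (9 regular-grid AOIs, pooled transition
counts, base-2 logs) for twelve paintings viewed by ten observers during
45 s of free viewing, together with the paintings' informational
aesthetics scores. The tables serve as worked-example inputs for
arithmetic-identity checks — joint-entropy additivity, normalized MI,
and the mean / population-SD summary rows — not as data this package can
recompute (the underlying fixation recordings and painting images are
not distributed).

Stimulus rows are labelled a1..a6 and b1..b6: two paintings from each of
six chronological periods of the painter's career.
"""

from __future__ import annotations

import pandas as pd

# Per-painting clustered measures: H(X), H(X|Y), H(X,Y), I(X;Y), I/H(X),
# plus the aesthetics scores Mk, Mb and the region count Ms^-1(0.25).
_PAINTINGS = [
    # id,   H(X),   H(X|Y), H(X,Y), I(X;Y), normMI,  Mk,    Mb,    Ms_inv
    ("a1", 2.8246, 1.6747, 4.4993, 1.1499, 0.4071, 0.759, 0.418, 1264),
    ("b1", 3.1072, 1.9764, 5.0835, 1.1417, 0.3674, 0.650, 0.310, 2020),
    ("a2", 2.9821, 1.7874, 4.7695, 1.1930, 0.4000, 0.739, 0.463, 875),
    ("b2", 2.9958, 1.4709, 4.4667, 1.5244, 0.5088, 0.850, 0.575, 1417),
    ("a3", 2.8518, 1.5188, 4.3706, 1.3336, 0.4676, 0.718, 0.385, 1396),
    ("b3", 2.9251, 1.6460, 4.5711, 1.2799, 0.4375, 0.726, 0.295, 1272),
    ("a4", 3.0384, 1.6874, 4.7259, 1.3591, 0.4473, 0.697, 0.345, 1648),
    ("b4", 3.0211, 1.7187, 4.7399, 1.3039, 0.4316, 0.581, 0.349, 2736),
    ("a5", 2.9510, 1.4157, 4.3667, 1.5296, 0.5183, 0.593, 0.339, 2456),
    ("b5", 3.1591, 1.6422, 4.8013, 1.5174, 0.4803, 0.594, 0.322, 1758),
    ("a6", 3.1250, 1.4451, 4.5702, 1.6797, 0.5375, 0.714, 0.315, 2375),
    ("b6", 3.1379, 1.7465, 4.8844, 1.3906, 0.4432, 0.592, 0.312, 2095),
]

# Per-observer clustered measures over the twelve paintings.
_OBSERVERS = [
    ("observer1", 3.0243, 1.7807, 4.8049, 1.2444, 0.4115),
    ("observer2", 3.0720, 1.8207, 4.8926, 1.2531, 0.4079),
    ("observer3", 3.1014, 1.7515, 4.8529, 1.3514, 0.4357),
    ("observer4", 3.0953, 1.8891, 4.9844, 1.2048, 0.3892),
    ("observer5", 3.0950, 1.7306, 4.8257, 1.3639, 0.4407),
    ("observer6", 3.1359, 1.8256, 4.9615, 1.3090, 0.4174),
    ("observer7", 3.1335, 1.9187, 5.0522, 1.2155, 0.3879),
    ("observer8", 3.1296, 1.7296, 4.8592, 1.3986, 0.4469),
    ("observer9", 3.1534, 1.7098, 4.8631, 1.4440, 0.4579),
    ("observer10", 3.1200, 1.6647, 4.7847, 1.4557, 0.4666),
]

# Ordinal-pattern measures of the same paintings: normalized permutation
# entropy PE and statistical complexity C (with normalized MI and Mk for
# cross-measure comparison).
_ORDINAL = [
    ("a1", 0.4071, 0.759, 0.9777, 0.0279),
    ("b1", 0.3674, 0.650, 0.9924, 0.0097),
    ("a2", 0.4000, 0.739, 0.9621, 0.0493),
    ("b2", 0.5088, 0.850, 0.9154, 0.1044),
    ("a3", 0.4676, 0.718, 0.9518, 0.0601),
    ("b3", 0.4375, 0.726, 0.9231, 0.0981),
    ("a4", 0.4473, 0.697, 0.9140, 0.1051),
    ("b4", 0.4316, 0.581, 0.9973, 0.0036),
    ("a5", 0.5183, 0.593, 0.9940, 0.0078),
    ("b5", 0.4803, 0.594, 0.9760, 0.0316),
    ("a6", 0.5375, 0.714, 0.9260, 0.0919),
    ("b6", 0.4432, 0.592, 0.9867, 0.0172),
]


def painting_measures() -> pd.DataFrame:
    """Clustered channel measures and aesthetics scores for 12 paintings."""
    return pd.DataFrame(
        _PAINTINGS,
        columns=["id", "H(X)", "H(X|Y)", "H(X,Y)", "I(X;Y)", "normalized MI",
                 "Mk", "Mb", "Ms_inv_0.25"],
    )


def observer_measures() -> pd.DataFrame:
    """Clustered channel measures for 10 observers."""
    return pd.DataFrame(
        _OBSERVERS,
        columns=["id", "H(X)", "H(X|Y)", "H(X,Y)", "I(X;Y)", "normalized MI"],
    )


def painting_ordinal_measures() -> pd.DataFrame:
    """Permutation entropy and statistical complexity for 12 paintings."""
    return pd.DataFrame(
        _ORDINAL, columns=["id", "normalized MI", "Mk", "PE", "C"]
    )
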