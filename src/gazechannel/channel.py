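"""The gaze information channel and its Shannon measure set.

The normalized transition-count matrix defines a discrete channel X -> Y
between the AOIs: with ``N`` total transitions, row totals ``N_i`` and
column totals ``N_j``,

    joint        p(i, j) = c_ij / N
    conditional  p(j | i) = c_ij / N_i          (rows with N_i > 0)
    input        pi_i     = N_i / N             (where the gaze is)
    output       q_j      = N_j / N             (where it goes next)

By construction ``pX @ P = pY``. The channel stands on its own: it does
not require the fixation sequence to be a first-order Markov chain — if
the process has higher-order structure, ``P`` is simply the matrix of
average one-step transition probabilities.

Measures (log base 2 by default, i.e. bits):

    Hs   = H(X)      stationary entropy: uncertainty of gaze location
    H(Y|i)           per-AOI row entropy: uncertainty of the next AOI
    Ht   = H(Y|X)    transition entropy: pi-weighted mean of H(Y|i)
    Hxy  = H(X,Y)    joint entropy = Hs + Ht
    HY   = H(Y)      entropy of the output marginal
    I    = I(X;Y)    mutual information = Hs + HY - Hxy = HY - Ht
    normMI = I / Hs  fraction of location uncertainty explained by the
                     previous location

For long trajectories row and column marginals nearly coincide and
``I ≈ Hs - Ht``; the implementation computes I exactly from the joint,
so the information identity ``I = Hs + HY - Hxy`` holds to machine
precision for every channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aoi import AOIPartition
from .counts import TransitionCounts, build_transition_counts, cluster_counts
from .types import ScanPath

#: Column labels used for tabular output, in canonical order.
MEASURE_COLUMNS = ["H(X)", "H(X|Y)", "H(X,Y)", "I(X;Y)", "normalized MI"]


def _entropy(p: np.ndarray, log_base: float) -> float:
    """Shannon entropy with the 0·log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(log_base))).sum())


@dataclass(frozen=True)
class GazeChannel:
    """Joint, conditional, and marginal distributions of a gaze channel.

    ``conditional`` rows whose AOI was never left (``N_i = 0``) are NaN and
    flagged unsupported; they carry zero weight in every measure.
    """

    joint: np.ndarray
    conditional: np.ndarray
    pX: np.ndarray
    pY: np.ndarray
    supported: np.ndarray  # boolean row mask: N_i > 0

    @property
    def s(self) -> int:
        return self.joint.shape[0]

    @classmethod
    def from_counts(cls, counts: TransitionCounts) -> "GazeChannel":
        """Normalize a transition-count matrix into a channel.

        Raises
        ------
        ValueError
            If the matrix holds no transitions ("empty channel").
        """
        N = counts.N
        if N == 0:
            raise ValueError("empty channel: no transitions to normalize")
        C = counts.C.astype(float)
        Ni = counts.row_totals.astype(float)
        joint = C / N
        supported = Ni > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            conditional = C / Ni[:, None]
        conditional[~supported] = np.nan
        return cls(
            joint=joint,
            conditional=conditional,
            pX=Ni / N,
            pY=counts.col_totals.astype(float) / N,
            supported=supported,
        )

    @classmethod
    def from_joint(cls, joint: np.ndarray) -> "GazeChannel":
        """Build a channel from a joint probability matrix (sums to 1)."""
        joint = np.asarray(joint, dtype=float)
        if joint.ndim != 2 or joint.shape[0] != joint.shape[1]:
            raise ValueError("joint matrix must be square")
        if (joint < 0).any() or not np.isclose(joint.sum(), 1.0, atol=1e-9):
            raise ValueError("joint matrix must be a probability distribution")
        pX = joint.sum(axis=1)
        pY = joint.sum(axis=0)
        supported = pX > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            conditional = joint / pX[:, None]
        conditional[~supported] = np.nan
        return cls(joint=joint, conditional=conditional, pX=pX, pY=pY, supported=supported)

    def measures(self, log_base: float = 2.0) -> "ChannelMeasures":
        return channel_measures(self, log_base=log_base)


@dataclass(frozen=True)
class ChannelMeasures:
    """The Shannon measure bundle of a gaze channel (entropies in the
    units of ``log_base``; bits for the default base 2)."""

    Hs: float
    Ht: float
    Hxy: float
    HY: float
    I: float
    normMI: float
    row_entropies: np.ndarray
    log_base: float = 2.0

    def to_dict(self) -> dict[str, float]:
        """Measures keyed by their canonical table column names."""
        return {
            "H(X)": self.Hs,
            "H(X|Y)": self.Ht,
            "H(X,Y)": self.Hxy,
            "I(X;Y)": self.I,
            "normalized MI": self.normMI,
        }


def channel_measures(channel: GazeChannel, log_base: float = 2.0) -> ChannelMeasures:
    """Compute the full Shannon measure set of a gaze channel.

    ``Hxy = Hs + Ht`` and ``I = Hs + HY - Hxy`` hold exactly. ``normMI``
    is NaN (with a warning) for the degenerate single-support channel
    where ``Hs = 0``.
    """
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    Hs = _entropy(channel.pX, log_base)
    HY = _entropy(channel.pY, log_base)
    row_H = np.full(channel.s, np.nan)
    for i in np.flatnonzero(channel.supported):
        row_H[i] = _entropy(channel.conditional[i], log_base)
    # unsupported rows have pX == 0 and drop out of the weighted average
    Ht = float(np.nansum(np.where(channel.supported, channel.pX * row_H, 0.0)))
    Hxy = Hs + Ht
    I = Hs + HY - Hxy  # == HY - Ht
    if Hs == 0.0:
        warnings.warn("normalized MI undefined: stationary entropy is zero")
        normMI = float("nan")
    else:
        normMI = I / Hs
    return ChannelMeasures(
        Hs=Hs, Ht=Ht, Hxy=Hxy, HY=HY, I=I, normMI=normMI,
        row_entropies=row_H, log_base=log_base,
    )


class GazeChannelModel:
    """Gaze information channel estimated from fixation scanpaths.

    The model pools the AOI transition counts of one or more scanpaths on
    a common partition; :meth:`fit` normalizes them into the channel and
    computes its measure bundle.

    Parameters
    ----------
    counts : TransitionCounts
        Pooled transition counts over the partition's AOIs.
    partition : AOIPartition, optional
        The AOI partition the counts were built on (kept for reporting).

    Examples
    --------
    >>> from gazechannel import make_grid_partition, GazeChannelModel
    >>> part = make_grid_partition(3, 3, 1920, 1080)
    >>> res = GazeChannelModel.from_scanpaths(paths, part).fit()  # doctest: +SKIP
    >>> res.I, res.normMI  # doctest: +SKIP
    """

    def __init__(self, counts: TransitionCounts, partition: AOIPartition | None = None):
        self.counts = counts
        self.partition = partition

    @classmethod
    def from_scanpaths(
        cls,
        paths: Sequence[ScanPath],
        partition: AOIPartition,
        include_self: bool = True,
        clamp: bool = False,
    ) -> "GazeChannelModel":
        """Pool the transition counts of several scanpaths into one model."""
        counts = cluster_counts(
            [build_transition_counts(p, partition, include_self=include_self, clamp=clamp)
             for p in paths]
        )
        return cls(counts, partition)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        partition: AOIPartition,
        include_self: bool = True,
        clamp: bool = False,
    ) -> "GazeChannelModel":
        """Build from a fixation table with columns
        observer_id, stimulus_id, onset_s, duration_ms, x_px, y_px."""
        from .io import scanpaths_from_frame

        paths = scanpaths_from_frame(df, partition.stimulus_width, partition.stimulus_height)
        return cls.from_scanpaths(paths, partition, include_self=include_self, clamp=clamp)

    def fit(self, log_base: float = 2.0) -> "GazeChannelResults":
        channel = GazeChannel.from_counts(self.counts)
        return GazeChannelResults(self, channel, channel.measures(log_base=log_base))


@dataclass
class GazeChannelResults:
    """Fitted gaze channel: distributions, measures, and reporting."""

    model: GazeChannelModel
    channel: GazeChannel
    measures: ChannelMeasures

    # measure accessors mirror the bundle for convenience
    @property
    def Hs(self) -> float:
        return self.measures.Hs

    @property
    def Ht(self) -> float:
        return self.measures.Ht

    @property
    def Hxy(self) -> float:
        return self.measures.Hxy

    @property
    def HY(self) -> float:
        return self.measures.HY

    @property
    def I(self) -> float:
        return self.measures.I

    @property
    def normMI(self) -> float:
        return self.measures.normMI

    def to_row(self) -> dict[str, float]:
        return self.measures.to_dict()

    def summary(self) -> str:
        """Plain-text summary table of the fitted channel."""
        m = self.measures
        s = self.channel.s
        lines = [
            "Gaze information channel",
            "=" * 40,
            f"AOIs:                 {s}",
            f"Transitions (N):      {self.model.counts.N}",
            f"Log base:             {m.log_base:g}",
            "-" * 40,
            f"H(X)  stationary      {m.Hs:10.4f}",
            f"H(Y|X) transition     {m.Ht:10.4f}",
            f"H(X,Y) joint          {m.Hxy:10.4f}",
            f"I(X;Y) mutual info    {m.I:10.4f}",
            f"I/H(X) normalized MI  {m.normMI:10.4f}",
            "-" * 40,
            "Per-AOI next-gaze uncertainty H(Y|i):",
        ]
        for i in range(s):
            h = self.measures.row_entropies[i]
            txt = f"{h:.4f}" if np.isfinite(h) else "(never left)"
            lines.append(f"  AOI {i + 1:>3}: pi={self.channel.pX[i]:.4f}  H(Y|i)={txt}")
        return "\n".join(lines)

    def plot_transition_matrix(self, ax=None):
        """Heat map of the conditional transition matrix p(j|i)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.channel.conditional, cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("next AOI j")
        ax.set_ylabel("current AOI i")
        ax.set_xticks(range(self.channel.s), [str(k + 1) for k in range(self.channel.s)])
        ax.set_yticks(range(self.channel.s), [str(k + 1) for k in range(self.channel.s)])
        ax.figure.colorbar(im, ax=ax, label="p(j|i)")
        return ax
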