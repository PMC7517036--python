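"""Synthetic scanpaths from known Markov chains, and synthetic test images.

The simulator draws AOI visit sequences from a first-order Markov chain
with known initial distribution and transition matrix, places each
fixation uniformly inside its AOI rectangle (downstream computation only
uses the AOI index), and spaces onsets on a fixed clock. Because the
generating chain is known, every channel measure has a closed form to
recover: the stationary distribution pi solves pi P = pi, and the true
channel has joint diag(pi) @ P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aoi import AOIPartition
from .channel import ChannelMeasures, GazeChannel
from .types import Fixation, ScanPath


@dataclass
class ChainSpec:
    """A first-order Markov chain over ``s`` AOIs plus fixation timing.

    ``onset_step`` (seconds) and ``duration_ms`` model a steady fixation
    rhythm: four fixations per second with 200 ms dwell by default, a
    typical free-viewing cadence.
    """

    P: np.ndarray
    pi0: np.ndarray
    n_fix: int = 100
    seed: int = 0
    onset_step: float = 0.25
    duration_ms: float = 200.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.pi0 = np.asarray(self.pi0, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if (self.P < 0).any() or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("P must be row-stochastic")
        if (self.pi0 < 0).any() or not np.isclose(self.pi0.sum(), 1.0, atol=1e-9):
            raise ValueError("pi0 must be a probability distribution")
        if self.pi0.shape != (self.P.shape[0],):
            raise ValueError("pi0 length must match P")
        if self.n_fix < 1:
            raise ValueError("n_fix must be >= 1")

    @property
    def s(self) -> int:
        return self.P.shape[0]


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1 (least squares; unique for ergodic P)."""
    P = np.asarray(P, dtype=float)
    s = P.shape[0]
    A = np.vstack([P.T - np.eye(s), np.ones(s)])
    b = np.zeros(s + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def chain_measures(P: np.ndarray, log_base: float = 2.0) -> ChannelMeasures:
    """Closed-form channel measures of a stationary chain.

    The channel of an infinitely long trajectory has joint distribution
    ``p(i, j) = pi_i P_ij`` with both marginals equal to pi; this is the
    convergence target of the empirical measures.
    """
    P = np.asarray(P, dtype=float)
    pi = stationary_distribution(P)
    joint = pi[:, None] * P
    return GazeChannel.from_joint(joint).measures(log_base=log_base)


def sample_states(spec: ChainSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one AOI state sequence (0-based) of length n_fix from the chain."""
    cum_pi0 = np.cumsum(spec.pi0)
    cum_P = np.cumsum(spec.P, axis=1)
    u = rng.random(spec.n_fix)
    states = np.empty(spec.n_fix, dtype=np.int64)
    states[0] = np.searchsorted(cum_pi0, u[0], side="right")
    for k in range(1, spec.n_fix):
        states[k] = np.searchsorted(cum_P[states[k - 1]], u[k], side="right")
    return np.minimum(states, spec.s - 1)  # guard cumulative round-off


def simulate_scanpaths(
    spec: ChainSpec,
    partition: AOIPartition,
    n_paths: int = 1,
    observer_prefix: str = "sim",
    stimulus_id: str = "synthetic",
) -> list[ScanPath]:
    """Simulate ``n_paths`` scanpaths from the chain over a partition.

    Each path gets an independent random stream derived from the global
    seed and its index, so the output is reproducible path-by-path and
    identical across runs with the same spec.
    """
    if partition.s != spec.s:
        raise ValueError(f"partition has {partition.s} AOIs but chain has {spec.s}")
    regions = partition.regions
    paths = []
    for p in range(n_paths):
        rng = np.random.default_rng([spec.seed, p])
        states = sample_states(spec, rng)
        fixations = []
        for k, a in enumerate(states):
            x0, y0, x1, y1 = regions[a]
            fixations.append(
                Fixation(
                    onset=k * spec.onset_step,
                    duration=spec.duration_ms,
                    x=rng.uniform(x0, x1),
                    y=rng.uniform(y0, y1),
                    observer_id=f"{observer_prefix}{p + 1}",
                    stimulus_id=stimulus_id,
                )
            )
        paths.append(
            ScanPath(
                fixations=fixations,
                stimulus_width=partition.stimulus_width,
                stimulus_height=partition.stimulus_height,
            )
        )
    return paths


@dataclass
class SyntheticImageSpec:
    """Recipe for a deterministic test image.

    Kinds: ``constant`` (one grey level everywhere), ``two_tone_blocks``
    (black left half, white right half), ``gradient`` (horizontal ramp
    0..255), ``iid_noise`` (independent uniform bytes, seeded).
    """

    kind: str = "constant"
    width: int = 64
    height: int = 64
    seed: int = 0
    value: int = 128

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.kind not in {"constant", "two_tone_blocks", "gradient", "iid_noise"}:
            raise ValueError(f"unknown image kind {self.kind!r}")


def make_synthetic_image(spec: SyntheticImageSpec) -> np.ndarray:
    """Deterministically build the luminance image described by ``spec``."""
    w, h = spec.width, spec.height
    if spec.kind == "constant":
        return np.full((h, w), spec.value, dtype=np.uint8)
    if spec.kind == "two_tone_blocks":
        img = np.zeros((h, w), dtype=np.uint8)
        img[:, w // 2:] = 255
        return img
    if spec.kind == "gradient":
        ramp = np.linspace(0, 255, w).round().astype(np.uint8)
        return np.tile(ramp, (h, 1))
    rng = np.random.default_rng(spec.seed)
    return rng.integers(0, 256, size=(h, w), dtype=np.uint8)
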