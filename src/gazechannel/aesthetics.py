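"""Informational aesthetics measures for raster images.

Five observer-free measures of image order and complexity:

* ``Mb`` — palette redundancy: one minus the colour histogram entropy
  relative to its maximum (24 bits for RGB, 8 for luminance). Bense-style
  informational reading of Birkhoff's aesthetic measure.
* ``Mk`` — Kolmogorov redundancy: one minus compressed size over raw
  size, with a lossless compressor standing in for the (uncomputable)
  Kolmogorov complexity ``K(I)``.
* ``I(C,R)`` / ``Ms(n)`` — the colour–region information channel: mutual
  information between the palette and an ``n``-region spatial partition,
  normalized by the palette entropy. ``Ms`` grows from 0 (single region)
  to 1 (one region per pixel); the inverse map ``Ms⁻¹(ratio) = n`` — the
  number of regions a greedy splitter needs to capture a given fraction
  of the palette correlation — measures compositional complexity.
* ``PE`` — two-dimensional permutation entropy: Shannon entropy of the
  distribution of ordinal patterns of overlapping ``dx × dy`` pixel
  windows, normalized by ``log (dx·dy)!``.
* ``C`` — statistical complexity: ``PE`` times the normalized
  Jensen–Shannon distance between the ordinal-pattern distribution and
  the uniform one. Zero both for fully ordered (PE = 0) and fully random
  (P uniform) images; both ``PE`` and ``C`` are invariant to the log base.

Images are numpy arrays: ``(Ny, Nx)`` uint8 for luminance, ``(Ny, Nx, 3)``
uint8 for RGB.
"""

from __future__ import annotations

import bz2
import lzma
import zlib
from dataclasses import dataclass
from math import factorial, log
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Rect = tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open

#: ITU-R BT.601 luma weights for RGB -> luminance conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_COMPRESSORS: dict[str, Callable[[bytes], bytes]] = {
    "deflate": lambda b: zlib.compress(b, 9),
    "zlib": lambda b: zlib.compress(b, 9),
    "bz2": lambda b: bz2.compress(b, 9),
    "lzma": lambda b: lzma.compress(b, preset=9),
}


def load_image(path: str, mode: str = "rgb") -> np.ndarray:
    """Read a PNG/JPEG file into an RGB or luminance uint8 array."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return arr if mode == "rgb" else to_luminance(arr)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit luminance via BT.601 weights, rounded to nearest."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    return np.rint(image[..., :3].astype(float) @ _LUMA).clip(0, 255).astype(np.uint8)


def _color_codes(image: np.ndarray, mode: str) -> tuple[np.ndarray, int]:
    """Flattened integer colour codes and the palette size ``2**Hmax``."""
    image = np.asarray(image)
    if mode == "luminance":
        return to_luminance(image).ravel().astype(np.int64), 256
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("rgb mode requires an (Ny, Nx, 3) array")
    r, g, b = (image[..., k].astype(np.int64) for k in range(3))
    return ((r << 16) | (g << 8) | b).ravel(), 1 << 24


@dataclass(frozen=True)
class PaletteDistribution:
    """Colour/luminance histogram of an image and its entropy (bits)."""

    mode: str
    values: np.ndarray   # distinct colour codes present
    counts: np.ndarray   # pixel counts per distinct code
    H: float             # palette entropy in bits
    Hmax: float          # 24 (rgb) or 8 (luminance)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def palette_distribution(image: np.ndarray, mode: str = "rgb") -> PaletteDistribution:
    codes, palette_size = _color_codes(image, mode)
    if codes.size == 0:
        raise ValueError("empty image")
    values, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    H = float(-(p * np.log2(p)).sum())
    return PaletteDistribution(mode=mode, values=values, counts=counts,
                               H=H, Hmax=float(np.log2(palette_size)))


def palette_redundancy(image: np.ndarray, mode: str = "rgb") -> tuple[PaletteDistribution, float]:
    """Relative palette redundancy ``Mb = (Hmax - H(C)) / Hmax`` in [0, 1]."""
    dist = palette_distribution(image, mode)
    return dist, (dist.Hmax - dist.H) / dist.Hmax


@dataclass(frozen=True)
class AestheticScores:
    """Compression-based order scores of one image."""

    K_bits: float  # approximated Kolmogorov complexity: compressed size in bits
    Mk: float      # Kolmogorov redundancy, clamped to [0, 1]
    compressor: str
    mode: str


def kolmogorov_redundancy(
    image: np.ndarray, compressor: str = "deflate", mode: str = "rgb"
) -> AestheticScores:
    """Kolmogorov redundancy ``Mk = (N·Hmax - K(I)) / (N·Hmax)``.

    ``K(I)`` is approximated by the size, in bits, of the raw row-major
    pixel buffer compressed with a lossless codec (deflate at maximum
    level by default). Header overhead can push ``K`` past ``N·Hmax`` on
    tiny noise images, so the score is clamped to [0, 1].
    """
    try:
        fn = _COMPRESSORS[compressor]
    except KeyError:
        raise ValueError(f"unknown compressor {compressor!r}; "
                         f"choose from {sorted(_COMPRESSORS)}") from None
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if mode == "luminance":
        buf, Hmax = to_luminance(image).tobytes(), 8.0
    else:
        if image.ndim != 3:
            raise ValueError("rgb mode requires an (Ny, Nx, 3) array")
        buf, Hmax = np.ascontiguousarray(image[..., :3], dtype=np.uint8).tobytes(), 24.0
    N = image.shape[0] * image.shape[1]
    K = 8.0 * len(fn(buf))
    Mk = min(1.0, max(0.0, (N * Hmax - K) / (N * Hmax)))
    return AestheticScores(K_bits=K, Mk=Mk, compressor=compressor, mode=mode)


# --------------------------------------------------------------------------
# Colour–region information channel
# --------------------------------------------------------------------------


def _check_tiling(regions: list[Rect], Nx: int, Ny: int) -> None:
    area = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in regions)
    if area != Nx * Ny:
        raise ValueError("regions must tile the image exactly")
    for x0, y0, x1, y1 in regions:
        if not (0 <= x0 < x1 <= Nx and 0 <= y0 < y1 <= Ny):
            raise ValueError(f"region {(x0, y0, x1, y1)} outside image bounds")


def _region_mi_term(region_counts: np.ndarray, global_counts: np.ndarray, N: int) -> float:
    """Contribution of one region to I(C, R) in bits.

    ``(1/N) Σ_c n_cr log2(n_cr N / (n_c n_r))`` over colours with n_cr > 0.
    """
    n_r = region_counts.sum()
    if n_r == 0:
        return 0.0
    nz = region_counts > 0
    ncr = region_counts[nz].astype(float)
    nc = global_counts[nz].astype(float)
    return float((ncr * np.log2(ncr * N / (nc * n_r))).sum() / N)


def color_region_mi(image: np.ndarray, regions: list[Rect], mode: str = "luminance") -> float:
    """Mutual information I(C, R) between colours and a region partition, in bits.

    The joint distribution is ``p(c, r)`` = (pixels of colour c inside
    region r) / N. A single region gives I = 0; one region per pixel
    recovers the full palette entropy H(C).
    """
    codes, _ = _color_codes(image, mode)
    Ny, Nx = np.asarray(image).shape[:2]
    _check_tiling(regions, Nx, Ny)
    # dense relabel of the palette so per-region histograms stay small
    values, dense = np.unique(codes, return_inverse=True)
    dense = dense.reshape(Ny, Nx)
    K = len(values)
    global_counts = np.bincount(dense.ravel(), minlength=K)
    N = Nx * Ny
    return sum(
        _region_mi_term(
            np.bincount(dense[y0:y1, x0:x1].ravel(), minlength=K), global_counts, N
        )
        for x0, y0, x1, y1 in regions
    )


@dataclass
class MsResult:
    """Outcome of the greedy region-growing inversion of Ms."""

    n: int                 # region count reached
    ratio: float           # Ms(n) actually achieved
    target: float          # requested ratio
    reached: bool          # ratio >= target within max_regions
    curve: list[float]     # Ms(1), Ms(2), ..., Ms(n)
    regions: list[Rect]


def _best_split(dense: np.ndarray, rect: Rect, global_counts: np.ndarray,
                N: int, K: int, stride: int) -> tuple[float, Rect, Rect] | None:
    """Best axis-aligned cut of ``rect`` by colour–region MI gain.

    Returns (gain_bits, child_a, child_b), or None when the region cannot
    contribute further information: it is a single pixel in both
    directions, or already colour-pure (every descendant split has zero
    gain forever).
    """
    x0, y0, x1, y1 = rect
    sub = dense[y0:y1, x0:x1]
    h, w = sub.shape
    counts = np.bincount(sub.ravel(), minlength=K)
    if (counts > 0).sum() < 2:
        return None
    parent = _region_mi_term(counts, global_counts, N)
    best: tuple[float, Rect, Rect] | None = None
    for axis in (0, 1):  # 0: horizontal cut (split rows), 1: vertical cut
        extent = h if axis == 0 else w
        if extent < 2:
            continue
        # per-line colour histograms, cumulated to give the first part of
        # every candidate cut in one pass
        lines = sub if axis == 0 else sub.T
        hist = np.zeros((extent, K), dtype=np.int64)
        idx = np.repeat(np.arange(extent), lines.shape[1])
        np.add.at(hist, (idx, lines.ravel()), 1)
        cum = hist.cumsum(axis=0)
        total = cum[-1]
        for k in range(stride, extent, stride):
            left, right = cum[k - 1], total - cum[k - 1]
            gain = (_region_mi_term(left, global_counts, N)
                    + _region_mi_term(right, global_counts, N) - parent)
            if axis == 0:
                a, b = (x0, y0, x1, y0 + k), (x0, y0 + k, x1, y1)
            else:
                a, b = (x0, y0, x0 + k, y1), (x0 + k, y0, x1, y1)
            if best is None or gain > best[0]:
                best = (gain, a, b)
    return best


def ms_inverse(
    image: np.ndarray,
    ratio: float,
    mode: str = "luminance",
    max_regions: int = 4096,
    stride: int = 1,
) -> MsResult:
    """Number of regions needed to reach ``Ms(n) >= ratio``.

    Grows a binary space partition greedily: each step splits the region
    whose best axis-aligned cut maximizes the increase in I(C, R), until
    the mutual-information ratio reaches ``ratio`` or ``max_regions`` is
    hit (then the result is flagged unreached). Refinement never
    decreases I(C, R), so the Ms curve is non-decreasing.

    ``stride`` > 1 restricts candidate cuts to every ``stride``-th pixel
    boundary, trading resolution for speed on large images.
    """
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must lie in [0, 1]")
    codes, _ = _color_codes(image, mode)
    Ny, Nx = np.asarray(image).shape[:2]
    values, dense = np.unique(codes, return_inverse=True)
    dense = dense.reshape(Ny, Nx)
    K = len(values)
    N = Nx * Ny
    p = np.bincount(dense.ravel(), minlength=K) / N
    HC = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    if HC == 0.0:
        raise ValueError("ratio undefined for zero palette entropy (constant image)")
    global_counts = np.bincount(dense.ravel(), minlength=K)

    regions: list[Rect] = [(0, 0, Nx, Ny)]
    splits: list[tuple[float, Rect, Rect] | None] = [
        _best_split(dense, regions[0], global_counts, N, K, stride)
    ]
    I = 0.0
    curve = [0.0]
    while I / HC < ratio and len(regions) < max_regions:
        gains = [s[0] if s is not None else -np.inf for s in splits]
        k = int(np.argmax(gains))
        if not np.isfinite(gains[k]):
            break  # every region colour-pure or single-pixel: I is maximal
        # zero-gain splits of mixed regions are taken too: they refine
        # toward cuts that do separate colours (e.g. checkerboards)
        gain, a, b = splits[k]
        regions[k] = a
        splits[k] = _best_split(dense, a, global_counts, N, K, stride)
        regions.append(b)
        splits.append(_best_split(dense, b, global_counts, N, K, stride))
        I += gain
        curve.append(min(I / HC, 1.0))
    achieved = min(I / HC, 1.0)
    return MsResult(n=len(regions), ratio=achieved, target=ratio,
                    reached=achieved >= ratio - 1e-9, curve=curve, regions=regions)


# --------------------------------------------------------------------------
# Ordinal patterns: permutation entropy and statistical complexity
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinalDistribution:
    """Distribution over the ``(dx·dy)!`` ordinal patterns of an image.

    Only observed patterns are stored (``pattern_index`` holds their
    lexicographic permutation ranks); unobserved patterns have zero
    probability and are handled in closed form by the entropy routines.
    """

    dx: int
    dy: int
    n: int                      # (dx*dy)! possible patterns
    pattern_index: np.ndarray   # ranks of observed patterns, sorted
    probs: np.ndarray           # their probabilities, sum to 1
    windows: int                # number of windows counted


def _lehmer_rank(perms: np.ndarray) -> np.ndarray:
    """Lexicographic rank of each permutation row of ``perms`` (shape M×d)."""
    M, d = perms.shape
    ranks = np.zeros(M, dtype=np.int64)
    for k in range(d - 1):
        smaller_later = (perms[:, k + 1:] < perms[:, [k]]).sum(axis=1)
        ranks += smaller_later * factorial(d - 1 - k)
    return ranks


def ordinal_pattern_distribution(
    image: np.ndarray, dx: int = 2, dy: int = 2, max_patterns: int = 362880
) -> OrdinalDistribution:
    """Ordinal-pattern distribution of all overlapping ``dx × dy`` windows.

    Each window is flattened row-major and its values ranked; ties break
    by position (the earlier pixel takes the lower rank, via a stable
    argsort), so a constant window maps to the identity pattern. The
    pattern is the argsort permutation, identified by its lexicographic
    rank among the ``(dx·dy)!`` permutations.
    """
    arr = to_luminance(np.asarray(image)) if np.asarray(image).ndim == 3 else np.asarray(image)
    Ny, Nx = arr.shape
    if dx < 1 or dy < 1 or dx * dy < 2:
        raise ValueError("degenerate embedding: dx*dy must be >= 2")
    if Nx < dx or Ny < dy:
        raise ValueError("image smaller than the embedding window")
    d = dx * dy
    n = factorial(d)
    if n > max_patterns:
        raise ValueError(f"(dx*dy)! = {n} exceeds the pattern cap {max_patterns}")
    windows = sliding_window_view(arr, (dy, dx)).reshape(-1, d)
    perms = np.argsort(windows, axis=1, kind="stable")
    ranks = _lehmer_rank(perms)
    values, counts = np.unique(ranks, return_counts=True)
    return OrdinalDistribution(
        dx=dx, dy=dy, n=n,
        pattern_index=values, probs=counts / counts.sum(),
        windows=windows.shape[0],
    )


def _shannon(p: np.ndarray, base: float) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / log(base))


def permutation_entropy(dist: OrdinalDistribution, base: float = np.e) -> float:
    """Normalized permutation entropy ``PE = S(P) / log n`` in [0, 1].

    Base-invariant: the same value results for any log base.
    """
    if dist.n < 2:
        raise ValueError("degenerate embedding: need at least 2 patterns")
    return _shannon(dist.probs, base) / (log(dist.n) / log(base))


def jensen_shannon_q(dist: OrdinalDistribution, base: float = np.e) -> float:
    """Jensen–Shannon divergence Q(P, U) to the uniform pattern distribution."""
    n = dist.n
    k = len(dist.probs)
    mix = (dist.probs + 1.0 / n) / 2.0
    S_mix = _shannon(mix, base)
    if n > k:  # unobserved patterns contribute (1/2n) log(2n) each
        S_mix += (n - k) * (1.0 / (2 * n)) * (log(2 * n) / log(base))
    return S_mix - _shannon(dist.probs, base) / 2.0 - (log(n) / log(base)) / 2.0


def q_max(n: int, base: float = np.e) -> float:
    """Maximum Jensen–Shannon divergence to uniform over n patterns."""
    ln = lambda v: log(v) / log(base)
    return -0.5 * ((n + 1) / n * ln(n + 1) + ln(n) - 2 * ln(2 * n))


def statistical_complexity(dist: OrdinalDistribution, base: float = np.e) -> float:
    """Statistical complexity ``C = Q(P,U) · PE / Qmax``.

    Vanishes for a point-mass P (perfect order) and for P uniform
    (pure randomness); positive in between. Base-invariant.
    """
    pe = permutation_entropy(dist, base=base)
    return jensen_shannon_q(dist, base=base) * pe / q_max(dist.n, base=base)
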