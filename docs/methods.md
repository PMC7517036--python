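# Methods

## The gaze channel

A scanpath is reduced to its sequence of visited AOIs by point-in-rectangle
lookup on a regular grid. Grid cell boundaries sit at `floor(k·width/cols)`
and `floor(k·height/rows)`; cells are half-open on their right/bottom edges,
with the last row/column closed, so every in-bounds pixel belongs to exactly
one AOI. Coordinates are 0-based with the origin at the top-left — a
convention this package fixes explicitly since tracker exports vary.
Out-of-bounds fixations raise by default; an optional clamp mode snaps them
to the nearest edge, since tracker noise can land samples just off-screen.

Immediate transitions are counted into the matrix `C`. Two conventions are
supported:

* `include_self=True` (default): consecutive fixations inside one AOI count
  as a self-transition `i→i`. This is the convention consistent with the
  diagonal-heavy transition matrices of free-viewing data, where normalized
  MI in the 0.4–0.5 range is typical.
* `include_self=False`: runs of same-AOI fixations are collapsed to single
  visits before pairing, zeroing the diagonal.

The fictional entry/exit state (gaze arriving at and leaving the stimulus)
is ignored: its single unmatched entry and exit make row and column totals
differ by at most one, negligible for any non-trivial trajectory.

Normalization gives joint `p(i,j)`, conditional `p(j|i)`, input marginal
`π` (row totals) and output marginal `q` (column totals); `π P = q` holds
exactly by construction. Rows that are never left (`N_i = 0`) have undefined
conditional distributions: they are flagged unsupported, carry NaN rows, and
enter the transition entropy with weight zero (their `π_i` is zero).

Measures use the `0·log 0 = 0` convention and base-2 logarithms by default
(entropies in bits; any base can be requested — normalized MI is
dimensionless either way). Joint entropy is computed as `Hs + Ht`, which
equals the direct joint-distribution entropy identically; mutual information
is computed from the exact identity `I = H(X) + H(Y) − H(X,Y) = H(Y) − H(Y|X)`
against the *output* marginal. For finite trajectories the two marginals
differ slightly, so `I` can differ in the third decimal from `H(X) − H(Y|X)`;
reporting both marginals and computing `I` exactly keeps every information
identity true to machine precision, which the property suite asserts.

Degenerate channels: an empty count matrix raises (`"empty channel"`); a
channel whose stationary entropy is zero reports NaN normalized MI with a
warning while `I = 0` is still returned.

## Pooling and time evolution

Group-level channels are obtained by *summing transition counts* — over
observers for one stimulus, or over stimuli for one observer — and fitting
the pooled matrix. Summing counts is deliberate: the measures of a sum are
not the mean of the measures (two deterministic, opposite-cycling observers
pool into a maximally uncertain channel), and pooling is what keeps sparse
9-AOI matrices well populated. Pooling is associative and commutative, and
scaling all counts by a constant leaves every measure unchanged.

Evolution curves truncate each path to fixations with onset strictly below
`t` (a fixation straddling `t` is kept iff it started before `t`), pool, and
refit per time point. The default grid is 5 s steps over a 45 s viewing —
a typical free-viewing trial length; the grid is configurable. Windows
holding no transitions yield flagged empty entries rather than errors.

## Informational aesthetics measures

**Palette redundancy.** `Mb = (Hmax − H(C))/Hmax` with `Hmax = 24` bits for
the RGB palette (2²⁴ colours) and 8 bits for luminance (256 levels).
Luminance uses ITU-R BT.601 weights (0.299, 0.587, 0.114), rounded to the
nearest integer.

**Kolmogorov redundancy.** `Mk = (N·Hmax − K(I))/(N·Hmax)`, with `K(I)`
approximated by the bit-length of the raw row-major pixel buffer under a
lossless compressor — deflate at maximum level by default; bz2 and lzma are
selectable. Compressing the raw buffer rather than an image container makes
`K` independent of file-format headers, but absolute `Mk` values still
depend on the codec, so only codec-stable comparisons are meaningful. Header
overhead can exceed `N·Hmax` for tiny incompressible images, hence the
clamp to [0, 1].

**Colour–region channel.** `I(C,R)` uses the joint distribution of (colour,
region) over an exact rectangular tiling. `Ms(n) = I(C,R)/H(C)` runs from 0
(one region) to 1 (one region per pixel). The inverse `Ms⁻¹(ratio)` grows a
binary space partition greedily: each step takes, over all current regions,
the axis-aligned cut maximizing the gain in `I(C,R)` (candidate cuts at
every pixel boundary; a stride option thins them for speed). Zero-gain cuts
of colour-mixed regions are accepted — a checkerboard region has no
informative single cut, yet its grandchildren cuts are informative — while
colour-pure regions are never split, so the greedy `Ms` curve is
non-decreasing and reaches 1 when allowed enough regions. Refinement can
only increase mutual information, which the tests verify independently on
random images. The greedy region count is algorithm-dependent; it is a
complexity *index*, not a canonical segmentation.

**Ordinal patterns.** All overlapping `dx × dy` windows (defaults 2 × 2)
are flattened row-major and ranked with a stable argsort, so ties break in
favour of the earlier position — constant regions map to the identity
pattern rather than being discarded, which matters for images with flat
areas. Patterns are identified by the lexicographic rank of the argsort
permutation among all `(dx·dy)!` permutations (24 for the default window;
a cap on `(dx·dy)!` guards against infeasible embeddings). Permutation
entropy `PE = S(P)/log n!` and statistical complexity
`C = Q(P,U)·PE/Qmax`, with `Q` the Jensen–Shannon divergence to the uniform
pattern distribution and `Qmax` its maximum, are computed with natural logs
internally; both are log-base invariant, asserted by test. Unobserved
patterns enter `Q` in closed form, so the full `n`-vector is never
materialized. On pattern families interpolating between a point mass and
uniform, `Q/Qmax ≈ 1 − PE`, so `C ≈ (1 − PE)·PE` — the functional shape
that makes complexity vanish at both the ordered and the random extreme.

## Synthetic data

The scanpath simulator draws AOI sequences from a user-specified first-order
Markov chain and places each fixation uniformly inside its AOI rectangle —
sufficient because all downstream computation depends only on the AOI index,
not on within-AOI position. Onsets advance on a fixed 0.25 s clock with
200 ms durations, a realistic free-viewing fixation cadence; both are
configurable. One global seed plus the path index feeds
`numpy.random.default_rng`, so output is reproducible path-by-path. The
generator emulates the statistical structure the channel measures respond
to (stationary occupancy and one-step transition probabilities); it does
not model saccade amplitude/velocity profiles, saliency-driven attention,
center bias, or non-stationary viewing phases, so passing recovery tests
demonstrates estimator correctness, not realism of simulated gaze.

Synthetic images (constant, two-tone blocks, horizontal gradient, i.i.d.
uniform noise) pin the aesthetics measures to their closed-form extremes:
`Mb = 1` and `PE = 0` for constant images, `I(C,R) = H(C)` for the matched
two-tone split, `PE → 1` for large noise images.

## Verification strategy and problem sizes

* Channel measures are checked against a term-by-term brute-force evaluator
  (scalar sums over the joint distribution) to 1e−12, exhaustively for all
  3×3 count matrices with up to 4 transitions and on a seeded batch with up
  to 12.
* Stochastic recovery uses 10⁵ simulated transitions of a known 3-state
  chain: measures within 0.02 bits of the chain's closed forms, conditional
  rows within total-variation distance 0.02. The size is chosen so sampling
  error sits well inside those bands.
* Permutation entropy of 256×256 i.i.d. noise is within 0.01 of 1 — the
  sampling-error bound for ~65k windows over 24 patterns.
* Shipped reference tables of published clustered gaze measures are used
  only for arithmetic identities (joint-entropy additivity, normalized MI,
  mean and population-SD summary rows), since the underlying fixation
  recordings and stimulus images are not redistributable. Per-painting
  aesthetics values are likewise not reproduction targets: they depend on
  the original images and on unspecified compressor/segmentation choices.
  Their structural signatures — base invariance of `C`, the monotone `Ms`
  curve, the `C ≈ (1 − PE)·PE` shape — are tested instead.

## Known limitations

* Only regular-grid (and 3-band/3-strip) AOI partitions are built in;
  content-dependent AOIs would need custom rectangles.
* The channel is first-order by construction: higher-order sequence
  structure is averaged into one-step probabilities.
* `Ms⁻¹` from the greedy splitter is not comparable across different
  segmentation algorithms, and `Mk` is not comparable across codecs.
* Fixation detection from raw gaze samples is out of scope; inputs are
  already-detected fixations.
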