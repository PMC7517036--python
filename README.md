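# gazechannel

Information-theoretic analysis of eye-tracking scanpaths and of images, for
researchers in visual cognition, computational aesthetics, and human–computer
interaction.

When an observer free-views a stimulus, their fixation sequence can be mapped
onto a grid of **areas of interest (AOIs)**. The matrix `C` of immediate
AOI-to-AOI transitions — `c_ij` counts how often AOI `j` was fixated directly
after AOI `i` — defines, once normalized, a discrete **information channel**
`X → Y` between the AOIs:

```
p(i,j) = c_ij / N      joint            N  = Σ c_ij
p(j|i) = c_ij / N_i    transition       N_i = Σ_j c_ij
π_i    = N_i / N       stationary       q_j = N_j / N  (output marginal)
```

On this channel the package computes, in bits:

| measure | meaning |
|---|---|
| `H(X)` (Hs) | stationary entropy: uncertainty of *where* gaze is |
| `H(Y\|i)` | uncertainty of the next AOI from AOI `i` |
| `H(Y\|X)` (Ht) | transition entropy: π-weighted mean of `H(Y\|i)` |
| `H(X,Y)` | joint entropy, `= Hs + Ht` exactly |
| `I(X;Y)` | mutual information `= H(X) + H(Y) − H(X,Y)` |
| `I/H(X)` | normalized MI: the share of location uncertainty explained by the previous location |

The channel coincides with a first-order Markov chain interpretation when one
holds, but does not depend on it: for higher-order gaze dynamics `p(j|i)` is
simply the average one-step transition probability.

The package also implements observer-free **informational aesthetics
measures** for raster images: palette redundancy `Mb = (Hmax − H(C))/Hmax`,
compression-based Kolmogorov redundancy `Mk = (N·Hmax − K(I))/(N·Hmax)`, the
colour–region information channel `I(C,R)` with its ratio `Ms(n) = I(C,R)/H(C)`
and inverse `Ms⁻¹(ratio) = n` (compositional complexity via a greedy
MI-maximizing binary space partition), two-dimensional **permutation entropy**
`PE = S(P)/log (dx·dy)!` over ordinal patterns of pixel windows, and the
Jensen–Shannon **statistical complexity** `C(P) = Q(P,U)·PE/Qmax`.

A seeded Markov-chain scanpath simulator and synthetic image generators make
every measure testable against closed forms without any external data.

## Worked example

Simulate ten observers from a known 3-state chain over three vertical strips,
pool their transitions, and fit the channel:

```python
import numpy as np
import gazechannel as gc

P = np.array([[0.70, 0.20, 0.10],
              [0.30, 0.50, 0.20],
              [0.10, 0.30, 0.60]])
spec = gc.ChainSpec(P=P, pi0=np.full(3, 1/3), n_fix=200, seed=7)
part = gc.make_grid_partition(1, 3, 1920, 1080)   # vertical 3-AOI division
paths = gc.simulate_scanpaths(spec, part, n_paths=10)
res = gc.GazeChannelModel.from_scanpaths(paths, part).fit()
print(res.summary())
```

```
Gaze information channel
========================================
AOIs:                 3
Transitions (N):      1990
Log base:             2
----------------------------------------
H(X)  stationary          1.5582
H(Y|X) transition         1.2543
H(X,Y) joint              2.8125
I(X;Y) mutual info        0.3043
I/H(X) normalized MI      0.1953
----------------------------------------
Per-AOI next-gaze uncertainty H(Y|i):
  AOI   1: pi=0.4236  H(Y|i)=1.1126
  AOI   2: pi=0.3040  H(Y|i)=1.4819
  AOI   3: pi=0.2724  H(Y|i)=1.2207
```

With 1990 pooled transitions the estimates sit close to the generating
chain's closed forms (`Hs=1.5614`, `Ht=1.2998`, `I=0.2616` bits, from
`gc.chain_measures(P)`): gaze spends most time in AOI 1 (`π₁=0.42`), and
about 20% of the uncertainty about the next fixation location is explained
by the current one.

## Command line

```sh
gazechan simulate --spec chain.json --paths 10 --out fix.csv --manifest-out man.json
gazechan channel fix.csv --manifest man.json --grid 3x3 --out per_path.csv
gazechan cluster fix.csv --manifest man.json --by stimulus --summary --out pooled.csv
gazechan evolve fix.csv --manifest man.json --times 5,15,45 --out evolution.csv
gazechan aesthetics painting.png --mode luminance --ms-ratios 0.25 --out aes.csv
```

Fixation CSVs use the columns
`observer_id, stimulus_id, onset_s, duration_ms, x_px, y_px`; stimulus pixel
dimensions come from a JSON manifest `{"stimulus": [width, height]}`.

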