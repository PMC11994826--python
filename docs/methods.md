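# Methods

## Problem

Multilevel thresholding partitions an 8-bit image's gray levels
`0 … 255` into `m` classes with `m − 1` threshold values
`t_1 < … < t_{m−1}`, each in `[1, 255]`. A level `p` belongs to class `i`
iff `t_i ≤ p < t_{i+1}` (half-open intervals, with `t_0 = 0` and
`t_m = 256`). Color images are treated as three independent channels,
each thresholded on its own histogram; no joint 3-D color histogram is
built. The package fixes `L = 256` levels; 16-bit inputs are rescaled to
8 bits on load with `round(v·255/65535)`, because every constant in the
pipeline (the PSNR peak of 255, the SSIM stabilizers) presumes an 8-bit
dynamic range.

## Objectives

Both criteria operate on the normalized channel histogram
`p_i = f_i / N` and are **maximized**:

* **Otsu between-class variance**
  `σ_B = Σ_i ω_i (μ_i − μ_T)²`, with class mass `ω_i = Σ_{j∈C_i} p_j`,
  class mean `μ_i = Σ j·p_j / ω_i` and global mean `μ_T`.
* **Kapur entropy** `Σ_i H_i`,
  `H_i = −Σ_{j∈C_i} (p_j/ω_i)·ln(p_j/ω_i)` (natural log; the base only
  rescales the arg-max).

Empty classes (`ω_i = 0`) and zero-probability levels contribute 0 to
either objective rather than raising: candidate solutions that strand a
class are merely unrewarded, which keeps the search landscape smooth.

The fast evaluation path (`ObjectiveEvaluator`) precomputes prefix sums
of `p`, `j·p` and `p·ln p`, scoring a tuple in `O(m)`. For empty classes
this is exact, not approximate: the prefix sums are unchanged across
runs of zero bins, so the mass difference is exactly `0.0` and the
empty-class branch triggers reliably.

### Exhaustive oracle

`exhaustive_search` enumerates every strictly increasing tuple in
`[1, 255]` in lexicographic order and keeps the first maximizer, so ties
resolve to the lexicographically smallest tuple deterministically. The
enumeration is vectorized in chunks over the prefix sums. A budget of
`C(255, k) ≤ 5·10⁶` combinations (overridable) bounds the cost; `k ≤ 3`
at 256 levels fits, which is all the verification pipeline needs. The
oracle is the ground truth against which the stochastic search is
validated.

## The optimizer

The Reptile Search Algorithm moves `N` candidate vectors through the box
`[1, 255]^n` over `T` iterations split into four equal quarters
(1-based `t`, boundaries at `⌊T/4⌋`, `⌊T/2⌋`, `⌊3T/4⌋`):

| quarter | strategy | update for coordinate j |
|---|---|---|
| 1 | high walk (exploration) | `best_j·η_ij·β − R_ij·rand` |
| 2 | belly walk (exploration) | `best_j·x_{r1,j}·ES(t)·rand` |
| 3 | hunting coordination (exploitation) | `best_j·P_ij·rand` |
| 4 | hunting cooperation (exploitation) | `best_j − η_ij·ε − R_ij·rand` |

with

* `P_ij = α + (x_ij − mean(x_i)) / (best_j·(UB−LB) + ε)` — percentage
  difference from the incumbent best, `α = 0.1`;
* `η_ij = best_j · P_ij` — hunting operator, scaled by `β = 0.1` in the
  high walk;
* `R_ij = (best_j − x_{r2,j}) / (best_j + ε)` — reduction function,
  `r2` a uniformly random candidate index redrawn per coordinate;
* `ES(t) = 2·r3·(1 − t/T)`, `r3 ~ U[−1, 1]` drawn once per iteration — a
  stochastic schedule decaying from magnitude 2 to 0;
* every `rand` a fresh `U[0, 1]` draw per coordinate from one seeded
  generator; `r1` a uniform candidate index drawn per candidate.

`ε = 1e−10` guards the divisions; positions are clamped to the box after
every update.

### Gbest operator

After each candidate's phase move, a PSO-style velocity step pulls it
toward the population's global best:

    v' = w·v + c1·rand1·(Pbest − x) + c2·rand2·(Gbest − x)
    x' = x + v'

with `c1 = c2 = 2` and inertia `w` decayed linearly from 0.9 to 0.2 over
the run (`w(t) = w_max − (w_max − w_min)(t−1)/(T−1)`). The wiring is a
design choice the underlying method description leaves open: the Gbest
step *augments* every phase rather than replacing one, and selection is
greedy — the best of {old position, phase move, Gbest move} is kept.
Greedy selection plus Gbest retention makes the best-so-far trace
monotone non-decreasing (elitism), which the convergence analysis of
this family of optimizers presumes. The per-candidate velocity persists
across iterations regardless of which move wins.

### Decoding

The search is continuous; fitness is always evaluated on decoded
thresholds: clamp to `[1, 255]`, round half-up, sort, and move
duplicates to the next free level above (wrapping downward when the top
is exhausted). Rounding at evaluation rather than rounding the state
keeps the velocity dynamics smooth while guaranteeing that every
reported solution is a valid strictly increasing integer vector.

### Defaults

Population 25, 100 iterations, 30 repetitions, `β = α = 0.1` — the study
protocol this implementation follows. All randomness flows from a single
`numpy` `Generator` per run; identical (inputs, config, seed) give
bit-identical results.

## Segmentation quality

The "segmented image" scored by the metrics is the class-mean
reconstruction: each pixel carries the mean intensity of its class in
that image, rounded to the nearest integer (empty classes get their
interval midpoint). Class means minimize RMSE among per-class constant
reconstructions and make the decomposition
`RMSE² = total variance − σ_B` exact (up to integer rounding of the
means), so PSNR at the exhaustive Otsu optimum is non-decreasing in the
threshold count.

* `RMSE = sqrt(mean((I − Seg)²))`
* `PSNR = 20·log10(255 / RMSE)` dB, `+inf` for a perfect match
  (serialized as `inf`)
* `SSIM` in its global single-window form with `C1 = 6.5025`,
  `C2 = 58.52252` and population (1/N) variances — not the 11×11
  sliding-window variant of the original SSIM formulation, which would
  produce different (typically lower) values.

For color images, metrics are computed per channel and averaged.

## Benchmark statistics

Repeated runs aggregate to the mean and *sample* (n−1) standard
deviation per (image, channel, objective, K, algorithm) cell. The
Friedman analysis ranks algorithms within each case (case = image ×
channel × K; rank 1 best, ties averaged — the standard Friedman
treatment), sums ranks over cases, and reports

    χ² = 12n/(A(A+1)) · Σ_j (R̄_j − (A+1)/2)²

with its χ²(A−1) p-value, plus ordinal final ranks where tied mean ranks
share the better ordinal. No multiple-testing correction is applied.
Only the RSA-Gbest optimizer and a same-budget uniform random-search
baseline are built in; other optimizers plug in through the
`benchmark.BUILTIN_OPTIMIZERS`-style registry (a callable
`(hist, k, objective, cfg, seed) → (thresholds, fitness)`).

## Synthetic fixtures

The generators emulate the *statistical* structure the method assumes —
multimodal intensity histograms — not the pixel content of any public
benchmark or clinical image set:

* `gaussian_mixture_image` — pixels i.i.d. from a Gaussian intensity
  mixture, rounded and clipped to `[0, 255]`; mode means/stds/weights
  chosen per test (typically modes at 64/192 with σ ≈ 5–10, i.e.
  well-separated peaks like a foreground/background X-ray histogram).
* `delta_histogram` — exact point masses for closed-form checks.
* `ramp_image` — exactly uniform histogram; the Kapur k=1 optimum is
  analytically 128.

Because the pixels are i.i.d., these fixtures have no spatial texture,
boundaries or noise correlation; passing tests demonstrate correctness
of the histogram-domain optimization and of the metric computations, not
segmentation quality on natural or clinical images.

## Problem sizes and numerical choices

Test and verification runs use 64×64–128×128 fixtures, K ≤ 6, and
reduced optimizer budgets where the property being checked (elitism,
determinism, bounds) is size-independent; the oracle-recovery check uses
the full protocol (population 25, 100 iterations) on 10 two-mode
histograms × 10 seeds. Tolerances: histogram normalization 1e−12,
objective identities 1e−9, total-variance decomposition 1e−6.
Comparisons between stochastic scores and the oracle use the fraction of
the optimum attained (≥ 99.9% counts as recovery).

## Known limitations

* Fitness is evaluated on rounded thresholds; two continuous positions
  decoding to the same integers are equivalent to the selection rule.
* The exhaustive oracle is bounded by the enumeration budget; it is a
  verification device, not a production path for K > 3 at 256 levels.
* Global SSIM saturates near 1 for any reconstruction that preserves the
  image mean and variance structure; it discriminates less than the
  windowed variant.
* The Gbest wiring (augmentation of all four phases with greedy
  acceptance) is one defensible reading of an under-specified design;
  alternative wirings would change the trajectory but not the contract
  (bounds, elitism, determinism) the tests pin down.
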