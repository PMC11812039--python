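# Methods

## Model

A self-similar tree conserves a power of branch radius across every
ramification. Writing flow through a limb of radius r as f = c·r^α, mass
conservation at a split of limb c into limbs a and b gives

    r_a^α + r_b^α = r_c^α,

and summing over any *transect* — a cut separating all leaves from the
root exactly once — gives the trunk's flow back. Counting the branches on
a transect at radius ≈ r yields n = (r0/r)^α. Both relations are
homogeneous, so the coefficient c, the unit of length, and the factor two
between radius and diameter all cancel; the package accepts radii and
diameters interchangeably and only α survives into any estimate.

The count relation implies that the diameter of a randomly selected
branch is power-law distributed with tail P(d ≥ x) = (x_m/x)^α above a
cutoff x_m. Throughout, α denotes the exponent of the *cumulative*
distribution (the negative slope of the log–log exceedance curve); the
probability-density exponent is larger by one.

## Estimator

Diameters at or above x_m are binned logarithmically: bin k covers
[x_m·λ^k, x_m·λ^(k+1)), half-open with boundary values assigned upward,
and bin indices are computed as floor of the log-ratio with a relative
1e-12 guard so values intended to sit on a boundary land deterministically
in the upper bin regardless of how they were computed. Binning by powers
of λ (default 2) suppresses within-scale noise; estimates should not
depend materially on λ, and the suite checks agreement within 0.15 across
λ ∈ {1.5, 2, 3} on self-similar samples of n ≥ 10³.

Integrating the tail over a bin gives a geometric mass function on the
bin index, Pr(k) = (1 − λ^(−α))·λ^(−αk), with the same exponent as the
tail. Its likelihood has the closed-form maximizer

    α̂ = ln(1 + N/S) / ln λ,   N = Σ n_k,   S = Σ k·n_k,

which the tests verify against a brute-force grid search of the binned
log-likelihood (step 1e-4). S = 0 — all mass in the first bin — is a
degenerate sample in which α is unbounded above and is reported as an
error, not a number. At the study's sample sizes (n = 500) the estimator's
bias is ≲ 0.013 across α ∈ [1.5, 3].

Confidence intervals are nonparametric bootstrap percentile intervals
(default 10,000 resamples, seeded). Because α̂ depends on the data only
through the bin counts, resampling is implemented as a multinomial draw
over bin indices, which is exactly equivalent to iid resampling of the
retained diameters and orders of magnitude faster. Degenerate resamples
are redrawn with a capped round count and logged. Measured coverage of
the 95 % interval at n = 500 is 92–96 % across α ∈ [1.5, 3].

### The cutoff x_m

x_m is a per-dataset judgement, not a fitted quantity: it should exclude
the small-diameter region where measurement error or censorship (a brush
too thick, a branch judged too small to carve) bends the tail curve. The
implemented check is the one practitioners apply visually: the local
log–log slope of the exceedance curve within the first bin above x_m
should match −α̂; a relative mismatch beyond 25 % flags the cutoff.
With fewer than three distinct diameters in that bin the diagnostic is
"unavailable" rather than an error. `choose_xm` automates the search for
the smallest passing cutoff but is explicitly non-canonical — it selects
the smallest *defensible* cutoff, not necessarily the best one, and on
smoothly censored data can stop inside the transition region.

Replicates (independent annotations of the same work) are fitted
separately by default; pooling is an explicit flag, since replicate
spread is itself informative about annotation subjectivity.

## Synthetic data

`generate_tree` grows a binary tree from one trunk. Per ramification a
smaller:larger ratio u ~ Uniform[0.6, 1.0] is drawn; child radii follow
from the closed-form solution of the ramification relation at exponent α,
child lengths from the same construction at exponent β with the *same* u,
so slimmer children are also shorter — the sum relation constrains only
the pair, and coupling to u is the simplest consistent completion. Child
directions open ±(0.35 ± Uniform[−0.15, 0.15]) radians about the parent.
A limb whose radius falls below stop_ratio·r0 (default 0.1, i.e. roughly
a tenth of the trunk) is kept but not subdivided. One seeded PCG64 stream
drives everything, consumed depth-first child-a-first (u, then the two
angle jitters, then the a-subtree), so equal parameters and seed give a
bit-identical branch list. A branch budget (default 10⁶) turns runaway
recursion at tiny stop ratios into a clean error.

The defaults make visually tree-like figures, but the angular geometry is
irrelevant to the diameter statistics under test. What the generator
deliberately does *not* emulate: non-binary whorls, tapering along a
limb, breakage/pruning (coppicing breaks self-similarity by design),
bark-width measurement artifacts, and reticulation. Passing recovery
tests on these trees therefore demonstrates correctness of the estimator
under the self-similar model, not robustness to every violation real
trees exhibit.

Two finite-size effects of generated trees matter when fitting their own
diameters: the stopping rule piles terminal branches just below
stop_ratio·r0, and the trunk end of the distribution holds only a handful
of branches. Fitting with x_m at the very smallest diameter therefore
biases α̂ low — visibly so for asymmetric trees, whose stopping radii are
smeared over a range. Placing x_m a factor of ~2–3 above the stopping
diameter restores recovery (the README example shows both the bias-free
fit and the diagnostic that would catch the bad cutoff). This mirrors the
small-scale curvature seen in real annotation data and is why the
round-trip tests specify the cutoff above the stopping scale.

`sample_diameters` bypasses tree geometry and draws iid from the tail law
by inverse transform, d = x_m·U^(−1/α) with U ~ Uniform(0, 1]; it is the
null model the estimator assumes, used for calibration (KS distance to
the analytic tail < 0.01 at n = 10⁵).

`tree_to_diameters` emulates hand annotation: one diameter per branch,
each multiplied by an independent lognormal factor with median 1 and
coefficient of variation noise_cv (default tests use 2 %, a plausible
scale for careful annotation of a clean rendering).

## Annotation files

The SVG reader treats every straight segment — `line` elements and
two-point `path` elements in absolute, relative, and H/V dialects — as
one diameter mark, composes the full affine transform stack (translate,
scale, rotate, matrix, skew), and reports Euclidean lengths. Curves and
multi-segment paths are skipped with a logged count; zero-length
segments are excluded with a warning naming the element. Lengths are
invariant to rotation and translation and scale exactly with scale
transforms. If the document declares a physical width plus a viewBox, a
user-units-per-cm factor is derived; an explicit scale argument always
wins; otherwise lengths stay in user units, which is harmless because
the estimate is scale-free. Layer filtering by group id or Inkscape
label lets one file carry several observer replicates.

## Box-counting dimension

Trees are rasterized deterministically at 256×256 (any power of two):
each limb becomes a round-capped stroke of width equal to its diameter
after uniform scaling into the canvas with a 5 % margin, with
anti-aliasing off — occupancy is strictly binary. Dimension is the OLS
slope of log2 (occupied boxes) on log2 (boxes across the width) over
dyadic grids 2¹..2⁸ aligned to the image origin; the single-box 2⁰ grid
is excluded as identically 1. Offset averaging over four half-box grid
shifts exists as an optional flag but is off by default, keeping the
plain construction. The degenerate anchors are exact to machine
precision: a filled plane gives D = 2, a one-pixel line D = 1, a single
pixel D = 0, and D increases with α across {1, 2, 3} for fixed seed and
geometry since higher α packs in more branches.

## Numerical and design choices

- Ramifications are solved in closed form, child_b = parent·(1 +
  u^α)^(−1/α); a bracketing root-finder appears only as an independent
  oracle in the tests.
- Transects for the conservation check are enumerated by depth, with
  terminal limbs shallower than the current depth carried through; this
  matches the bisection construction and is unambiguous on asymmetric
  trees. The check is exact (≤ 1e-9 relative) at the generating α and
  strictly positive at any other exponent once a ramification is
  asymmetric.
- The CSV writer emits shortest round-trip reprs and the reader parses
  with round-trip precision, so write-then-read is bit exact.
- CLI reports are JSON plus CSV tables (tail curves, box counts) rather
  than rendered plots, keeping plotting backends swappable; every command
  takes one seed and echoes it in its report.

## Problem sizes

The test suite's simulation scales are chosen to pin each property with
comfortable statistical margin on a single CPU: 200 replicates at n = 500
for recovery/coverage, n = 10⁵ draws for distributional calibration,
trees up to a few thousand branches, 100 random tables for the
likelihood-optimality check. The full suite runs in a few seconds.

## Known limitations

- The estimator assumes a pure power-law tail above x_m; smoothly
  censored or curved tails can pass the 25 % slope check at a cutoff that
  still carries mild bias.
- Asymmetric trees narrower than ~16-fold radius contrast give only 3–4
  usable bins at λ = 2; intervals are honest but wide, and finite-size
  bias near the stopping scale is material (see above).
- The SVG reader covers the hand-annotation dialect (straight marks,
  affine transforms); it does not interpret CSS-styled transforms,
  `use`/`symbol` indirection, or units declared per element.
- Box-counting dimension is measured on the 2-D rendering; it depends on
  branch lengths, angles, and overlap, not on α alone.
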