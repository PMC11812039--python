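# arborscale

Tools for measuring and simulating **branch-thickness scaling** in trees —
real, simulated, or depicted in artwork.

Self-similar trees preserve a power of branch radius across every
ramification: where a limb of radius `r_c` splits into limbs `r_a` and
`r_b`,

    r_a^α + r_b^α = r_c^α

The exponent α interpolates between classical rules — α = 2 is da Vinci's
area-preserving rule, α = 3 is Murray's law of optimal fluid transport —
and the same exponent governs how many branches of a given radius the tree
contains, `n = (r0/r)^α`. Consequently the diameter of a randomly chosen
branch follows a power law with tail `P(d ≥ x) = (x_m/x)^α`, so α can be
estimated from a flat list of branch diameters with no topology recorded
at all. That makes it measurable from hand-annotated images: overlay one
line segment per branch diameter in an SVG editor, extract the lengths,
and fit.

The package provides:

- **`arborscale.scaling`** — closed-form branching proportions, branch
  counts, and transect-based conservation checks.
- **`arborscale.simulate`** — seeded random self-similar trees obeying the
  ramification relation exactly (radii with exponent α, lengths with an
  analogous exponent β), plus direct sampling from the power-law diameter
  model.
- **`arborscale.annotation`** — SVG line-annotation and CSV diameter-list
  readers/writers.
- **`arborscale.fit`** — the estimator: logarithmic binning by powers of
  λ (default 2), closed-form maximum-likelihood α̂ = ln(1 + N/S)/ln λ,
  bootstrap confidence intervals, tail-distribution curves, and a
  slope-match diagnostic for the cutoff x_m. α follows the
  cumulative-distribution convention (the negative log–log tail slope).
- **`arborscale.boxcount`** — rasterization of trees to 256×256 binary
  images and box-counting fractal dimension D, the regression slope of
  log2 (occupied boxes) against log2 (boxes across the width).
- **`arborscale` CLI** — `analyze`, `simulate`, and `boxcount` commands
  tying the stages together with JSON/CSV reports.

## Worked example

Generate a random α = 2 tree, annotate it with 2 % measurement noise,
and recover the exponent:

```python
import arborscale as arb

tree = arb.generate_tree(alpha=2.0, stop_ratio=0.02, seed=42)
print("branches:", len(tree))

sample = arb.tree_to_diameters(tree, noise_cv=0.02, seed=1)
xm = 3 * 2 * tree.trunk_radius * tree.stop_ratio   # above the stopping pile-up
fit = arb.fit_power_law(sample, xm=xm, n_boot=2000, seed=2)
print(f"alpha_hat = {fit.alpha_hat:.3f}  95% CI [{fit.ci_low:.3f}, {fit.ci_high:.3f}]")

diag = arb.threshold_diagnostic(sample, fit)
print("cutoff flagged:", diag.flagged)

res = arb.box_count_dimension(arb.rasterize_tree(tree))
print(f"box-counting D = {res.dimension:.3f} (r^2 = {res.r_squared:.4f})")
```

prints

```
branches: 7599
alpha_hat = 2.069  95% CI [1.870, 2.306]
cutoff flagged: False
box-counting D = 1.706 (r^2 = 0.9991)
```

The fitted exponent brackets the generating α = 2; the threshold
diagnostic confirms the tail slope at the cutoff matches the inference
(placing `x_m` at the very smallest diameters would instead pick up the
pile-up created by the stopping rule and bias α̂ low — the same
small-scale curvature that motivates a cutoff on real data). The fractal
dimension lands between 1 and 2, as tree silhouettes do, and increases
with α for fixed geometry.

The same analysis runs from the shell on annotation files:

```sh
arborscale simulate --alpha 2 --seed 42 --out-dir sim
arborscale analyze --input sim/diameters.csv --xm 0.12 --seed 2 --out-dir report
arborscale boxcount --input sim/tree.pgm --grids 1..8
```

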