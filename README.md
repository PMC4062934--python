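# petalpol

Imaging polarimetry of bull's-eye "artificial flower" targets and
mixed-effects analysis of bee learning curves.

Flowers can carry polarization patterns — produced by their petal surface
structure — that insect pollinators with polarization-sensitive vision may
learn as foraging cues. Testing that idea requires two computational
pieces, both provided here for anyone running or reanalyzing such an
experiment:

1. **Rotating-analyzer Stokes polarimetry.** From a stack of linear-count
   frames taken through a polarizer at known angles θ_k (plus a dark
   frame), estimate per-pixel linear Stokes parameters by least squares on
   I(θ) = ½(S0 + S1 cos 2θ + S2 sin 2θ), and derive the angle of
   polarization φ = ½·atan2(S2, S1) ∈ [0°, 180°) and degree of linear
   polarization d = √(S1²+S2²)/S0 ∈ [0, 1], with false-color rendering
   (hue = AoP, brightness = DoLP) and per-ring circular summaries.
2. **Learning-curve analysis.** For per-bee binary choice sequences, fit a
   logistic mixed model logit P(correct) = (β0+b_i) + (β1+s_i)x_t with
   per-bee random intercept b_i and random slope s_i (Laplace-approximate
   marginal likelihood), compare nested models by Δdeviance (χ² LRT) and
   AIC, test intensity-contrast × experience interactions, and plot binned
   learning curves with Wilson 95% CIs. The constrained Latin-square
   rearrangement of a 4×4 target grid between foraging bouts is included.

A synthetic layer renders analyzer stacks of bull's-eye targets (two
concentric polarizer rings, perpendicular "contrast" vs parallel "plain")
with exact ground truth, and simulates choice sequences with between-bee
heterogeneity — so the full pipeline is testable end to end without a
camera or a bee. See `docs/methods.md` for the models, defaults and their
rationale.

## Worked example

```python
from petalpol import synthetic_scene as ss, image_ingest as ing, \
    polarimetry as pol, behavior as bh

# --- polarimetry: render a "contrast" target with mild read noise
pattern = ss.make_target_pattern("contrast")
stack = ss.render_stack(pattern, ss.AcquisitionConfig(read_noise_sd=300.0, seed=0))
stack = ing.dark_subtract(stack)
maps = pol.compute_maps(pol.estimate_stokes(stack))
summary = pol.ring_summary(maps, pattern)
print(summary.rings.round(3))
print(f"inter-ring AoP difference: {summary.inter_ring_aop_difference_deg:.3f} deg")
```

```
       aop_deg   dolp  n_pixels
inner   90.049  0.994   45244.0
outer    0.002  0.995   67416.0
inter-ring AoP difference: 89.953 deg
```

The two polarizer rings are recovered ~90° apart (exactly 90° without
noise) at DoLP ≈ 1: the perpendicular bull's-eye configuration.

```python
# --- behavior: simulate 9 bees x 100 trials and test for learning
table = ss.simulate_choices(seed=1)
print(bh.fit_report(table, treatment="synthetic-DF"))
```

```
{'treatment': 'synthetic-DF', 'deviance_null': 1162.4982,
 'deviance_full': 1154.5038, 'delta_deviance': 7.9944, 'df': 1,
 'p': 0.0047, 'aic_null': 1168.4982, 'aic_full': 1162.5038}
```

Adding the experience term drops the deviance by 8.0 (χ²(1) p ≈ 0.005) and
the AIC by 6.0: the simulated foragers learned, as their generating slope
(β1 = log 3, chance → ~75% correct over the session) says they should.
`bh.learning_curve(table, bin_size=20)` gives the matching binned curve
(57.8% → 76.7% correct with Wilson CIs).

The same operations are exposed on the command line:

```sh
petalpol render --kind contrast --seed 1 --out stack/
petalpol maps --dir stack/ --mode aop_weighted --out target.png
petalpol simulate --bees 9 --trials 100 --seed 1 --out choices.csv
petalpol fit --choices choices.csv --spec experience
petalpol shuffle --previous layout.csv --seed 2
```

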