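# gapscale

Quantitative analysis of how gap-gene expression boundaries in *Drosophila*
embryos move over developmental time and scale with embryo length.

## The problem

During nuclear cycles 13–14 the six gap genes (*gt*, *hb*, *Kr*, *kni*,
*otd*, *tll*) form broad expression domains along the anterior–posterior
(AP) axis, read out in part from the maternal Bicoid (Bcd) gradient
C(ξ) ≈ A·exp(−ξL/λ), where ξ = x/L is fractional embryo length. In
inbred-line pairs selected for embryo-size extremes, the Bcd gradient
scales with length either through its amplitude *A* or through its length
constant *λ* — two different positional-information inputs. This package
implements, as a tested reusable pipeline, the statistics used to ask how
the resulting gap-gene patterns scale:

- **Boundary positions.** Each domain flank where expression crosses 50%
  of the domain peak is a named boundary; 20 boundaries form a fixed AP
  registry (kni1 < otd1 < tll1 < hb1/gt3 < … < tll3 < hb4).
- **Moving spans.** Δξ of a boundary between two time classes or stages
  (initial = nc13–T2, intermediate = T4–T5, final = T8–T9) within one
  line; regressions of large-line spans on small-line spans.
- **Scaling coefficient.** S = dξ/(dL/L), estimated per boundary as the
  OLS slope of ξ on L/⟨L⟩ with both lines of a pair pooled; S > 0 is
  over-scaling, S < 0 under-scaling, S = 0 perfect scaling. Stage-wise and
  between-pair correlations of S, and its "tilt" along AP.
- **Bcd threshold model.** Monte-Carlo ensembles of noisy gradients per
  line; the Bcd-encoded positional difference ΔξB(T) = ⟨ξ_L⟩ − ⟨ξ_S⟩ per
  threshold, with sd(ΔξB) = √(σ₁²/n₁ + σ₂²/n₂).

Because no public imaging data accompany the study design, the package
ships a first-class synthetic generator (`gapscale.synthetic`) that
emulates the cohorts with known ground truth — embryo lengths, boundary
trajectories, true S values, and optionally rendered two-channel
pseudo-microscopy images — so every estimator can be validated by
parameter recovery. Real 50-bin profile tables enter through the same CSV
dialect (`gapscale.io`).

## Worked example

`examples/03_scaling_analysis.py` generates a default cohort (two pairs,
15 embryos per line per time class) and estimates final-stage S per
boundary:

```
final-stage S per boundary (P_A):
    gt1 xi=0.064 S = +0.206  [+0.185, +0.227]
   kni1 xi=0.100 S = +0.195  [+0.175, +0.215]
   ...
   tll3 xi=0.843 S = -0.232  [-0.251, -0.212]
    hb4 xi=0.925 S = -0.255  [-0.278, -0.232]

P_A: tilt correlation r(S, xi) = -0.969 (p = 2.4e-12)
P_lambda: tilt correlation r(S, xi) = -0.974 (p = 5.3e-13)

between-pair final S: r = 0.995, slope = 1.003 (95% CI 0.95..1.05)
```

The strongly negative r(S, ξ) is the global scaling tilt — anterior
boundaries over-scale, posterior boundaries under-scale — and the
between-pair slope near 1 is the convergence of final-stage scaling
characteristics between the amplitude- and λ-scaled pairs.
`examples/04_bcd_threshold_model.py` prints the corresponding input-side
signature: anterior ΔξB = +0.079 ± 0.014 for the amplitude-scaled pair and
−0.024 ± 0.005 for the λ-scaled pair, both vanishing near mid-embryo.

The other examples cover cohort generation (`01`), boundary detection and
registry naming (`02`), and the image-rendering → extraction round trip
(`05`).

## Layout

| module | contents |
|---|---|
| `gapscale.registry` | boundary registry, time classes, stage definitions |
| `gapscale.config` | line/pair/trajectory/staging configuration, defaults |
| `gapscale.synthetic` | cohort generator, Bcd profiles, ground truth |
| `gapscale.render` | schematic embryo image renderer |
| `gapscale.imaging` | orientation, profile extraction, time-class staging |
| `gapscale.boundaries` | half-maximum detection, registry naming, positional errors |
| `gapscale.dynamics` | stage means, moving spans, ΔξP, span regressions |
| `gapscale.scaling` | scaling coefficient S, correlations, tilt |
| `gapscale.bcdmodel` | Monte-Carlo threshold model, ΔξB |
| `gapscale.io` | CSV dialects, TIFF stacks, ground-truth JSON |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
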