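# saplingcrown

Outermost crown profile modelling for naturally regenerated conifer
saplings, and crown-morphology comparison between silvicultural
treatments (shelterwood-cut strips vs uncut strips).

## The problem

A sapling's crown profile — outer crown radius as a function of depth below
the tree tip — summarises how the tree allocates growth between lateral
light capture and height. Ordinary regression curves pass through the
middle of the branch-radius cloud; the biologically interesting envelope is
the **outermost** profile, the boundary the longest branches trace. This
package implements a complete pipeline for estimating that envelope from
destructive branch measurements and comparing the resulting crown
morphology between treatments:

1. **Geometry** — from per-branch field measurements (tip-to-base distance
   `L`, chord length `BC`, insertion angle `VA`), derive the outer crown
   radius `OCR = BC·sin(VA)`, the depth of the branch tip
   `DINC = L − BC·cos(VA)`, and the relative depth `RDINC = DINC/CL`
   (0 at the tip, 1 at the crown base).
2. **Profile models** — the power-exponential form

   `OCR = a1·DBH^a2 · RDINC^(a3 + a4·CR) · exp(a5·RDINC)`

   (plus a modified variable-exponent Kozak form and both basic shapes),
   where `DBH` is stem diameter (cm) and `CR = CL/HT` the crown ratio.
   For `a5 < 0` the depth of the largest radius has the closed form
   `t* = (a3 + a4·CR)/(−a5)`, capped at 1.
3. **Nonlinear quantile regression** — fit the profile at quantile levels
   τ = 0.50 … 0.99 (step 0.01) by minimising the pinball loss
   `ρ_τ(u) = u·(τ − 1[u<0])`, smoothed-continuation optimiser with an
   exact-loss polish.
4. **Boundary (frontier) regression** — per sapling, the minimal-area
   polynomial envelope of its branch tips: a linear program minimising
   `∫φ_θ` subject to `φ_θ(x_i) ≥ y_i` (degree chosen by AIC/BIC on the
   envelope slack).
5. **Quantile selection** — the quantile whose curve is closest (mean
   absolute distance on a 10,001-point depth grid) to each sapling's
   boundary; strip-level summaries by averaging and by aggregate distance.
6. **Morphology comparison** — inflection depth, largest crown radius,
   upper-crown volume `V = π·CL·∫ r(t)² dt` (rotational integral, tip to
   inflection), and per-year Welch tests on annual branch-length growth.

A synthetic-stand generator with a known envelope truth (one-sided
multiplicative Beta noise below the envelope) makes every stage testable
without field data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
stand that mirrors the field sample (49 + 30 saplings):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_fit_profiles.py --seed 1
python analysis/03_select_quantile.py
python analysis/04_compare_morphology.py
```

which prints (abridged):

```
  shelterwood_cut: 49 saplings, 1201 branches | DBH 2.48±0.80 cm ...
  shelterwood_cut: mean outermost quantile 0.88, aggregate argmin 0.90
  uncut:           mean outermost quantile 0.86, aggregate argmin 0.89
  inflection depth: cut 0.797, uncut 0.645
  DBH 2 cm: largest radius cut 0.222 m / uncut 0.307 m; volume diff 0.0483 m^3
  2016: growth cut 17.2 cm / uncut 14.2 cm  (p=1.2e-05)
```

Read: the boundary-guided selection recovers 0.88 as the outermost
quantile for the cut strip (the level at which the generator placed the
envelope), the cut-strip crown peaks deeper (relative depth 0.80 vs 0.64),
the shade-grown (uncut) saplings hold the larger maximal radius and crown
volume at equal stem size, and their early growth advantage reverses two
years after the strip cut. Tables land under `results/`. The same stages
are exposed as a console script (`saplingcrown simulate|fit|select|compare`)
and as library functions (`saplingcrown.pipeline`).

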