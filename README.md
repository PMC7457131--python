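# alpgraze

Analysis toolkit for breed-structured cattle grazing studies on alpine
pastures. It is written for grassland and livestock scientists who compare
how cattle breeds along a productivity gradient differ in **anatomy**
(body weight, claw-base area, static pressure), **movement** (GPS and
pedometer records, evenness of space use, response to terrain), and
**foraging** (diet composition, forage quality, selectivity) — and who want
those trait relationships analysed as **allometries** with standardized
major axis (SMA) line fitting.

## What it computes

**Anatomy.** Claw-base area from traced outline polygons (shoelace area of
the four left claws, doubled: `A = 2 Σ area`), static pressure `P = W / A`
(kg/cm²), daily weight change `(W_end − W_start)/days`, and metabolic
livestock units `LU = (W / 600 kg)^0.75` with the stocking arithmetic
`Σ LU / ha`.

**Movement.** Mean travel speed from 15 s GPS fixes with a jump filter for
position errors; steps/h and lying ratio from pedometer intervals;
occupancy counts on a 5 × 5 m grid clipped to the paddock; Camargo's
evenness of space use

```
E = 1 − Σ_{i<j} |p_i − p_j| / S
```

over **all** S cells inside the paddock (zeros included); percent slope by
Horn's eight-neighbour gradient of the DEM and Euclidean distance to water
per cell; and a standardized habitat coefficient per cow and paddock from a
quasi-Poisson log-linear regression of cell counts on each z-scored
covariate, fitted by IRLS.

**Foraging.** Diet proportions `p_s` from bite sequences; forage quality
`Q = Σ p_s q_s` on the Briemle 1–9 indicator scale, with species-group
values resolved per pasture from relevée member abundances; Pielou's
selection evenness `J = (−Σ p ln p)/ln S`; diet shares per plant group; and
a profile-likelihood estimator of the quality-selectivity temperature τ in
the choice model `P(s) ∝ availability_s · e^{τ q_s}`.

**Allometry.** SMA fits `b = sign(r)·s_y/s_x`, `a = ȳ − b x̄` with F-based
slope CIs; a likelihood-ratio test of a common slope across groups
(χ²_{g−1}); Wald tests for **shift** along the common axis (scores
`y + b_c x`) and for **elevation** offsets (scores `y − b_c x`), with the
common-slope variance propagated; Tukey–Kramer range tests; and a
sequential breed × paddock-size ANOVA.

**Synthetic herd.** A fully seeded generator produces an entire study —
cows, claw outlines on a power law `A = k_a W^{k_b} e^ε`, GPS tracks from a
biased correlated random walk whose stationary occupancy is proportional to
`exp(−β_s z_slope − β_w z_water + τ z_quality)`, pedometer intervals with
distance-proportional Poisson step counts, and quality-weighted bite
sequences — so the whole pipeline can be exercised and checked for
parameter recovery without any field data.

## Worked example

```
$ alpgraze simulate --seed 1 --out study/
seed=1 config=study/study.yaml
$ alpgraze report --config study/study.yaml --out results/ --seed 1
report written to results/ (seed=1, config_hash=e62a233e4d93)
```

`results/per_cow.csv` then holds one row per cow; averaging it by breed
(seed 1, default configuration: 9 cows per breed, three pastures) gives

| breed | weight (kg) | claw base (cm²) | pressure (kg/cm²) | steps/h | Camargo E | Pielou J | diet Q |
|-------|------------:|----------------:|------------------:|--------:|----------:|---------:|-------:|
| HC    |         412 |             288 |              1.43 |    76.9 |     0.603 |    0.837 |   5.44 |
| OB    |         555 |             295 |              1.89 |    87.7 |     0.461 |    0.633 |   7.20 |
| AH    |         690 |             336 |              2.06 |    90.8 |     0.370 |    0.619 |   7.41 |

reading: the low-productivity breed (HC) is the lightest but carries the
least weight per claw area, takes the fewest steps, spreads most evenly
over its paddock, selects plants least strictly (highest J), and therefore
ingests the lowest-quality diet. `results/allometry.csv` reports, for nine
standard trait pairs, the overall SMA fit and the breed comparison; for
weight vs claw base at this seed the common slope is not rejected
(p = 0.75) while the breeds are shifted along the common line
(shift p ≈ 8 × 10⁻⁵) and offset in elevation (p ≈ 4 × 10⁻⁴) — heavy breeds
sit further up the line, and HC has more claw area at a given weight.

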