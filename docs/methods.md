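# Methods

This note documents the models and procedures implemented in `alpgraze`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Study design assumed by the pipeline

The package analyses grazing studies with the following shape: several
cattle breeds spanning a productivity gradient graze a rotation of
pastures, one paddock per breed and pasture, with paddock sizes adjusted so
stocking density (in metabolic livestock units, LU = (W/600 kg)^0.75) is
comparable across breeds. Per cow the data are: start and end body
weights; traced claw-base outlines of the left fore- and hindfoot (medial
and lateral claw); GPS fixes at a nominal 15 s interval in a projected
metric CRS; pedometer intervals (step counts, lying seconds); and bite
sequences with one plant taxon per recorded bite. Per pasture: a boundary
polygon, a DEM, water-point coordinates, and plant availability, with
Briemle forage-quality indicator values (1–9) per taxon and relevée
abundances for species groups.

## Anatomy

Claw areas are shoelace polygon areas (orientation-independent, via
shapely). The left side proxies the right, so the total claw base is twice
the sum of the four left-claw areas; a missing or duplicated foot × claw
combination is an error, not a guess. Static pressure is body weight over
total claw base in kg/cm² — deliberately a pressure of *mass* (no gravity
factor); multiply by 98.0665 for kPa. The weight entering the pressure
quotient is the end-of-season weight by default (claws are measured at the
end of the season); this is configurable. Whether calves contribute LU to
stocking densities is left to the caller — the arithmetic accepts any list
of LU values.

## Movement

**Speed.** Sum of Euclidean inter-fix distances divided by the elapsed
first-to-last time. Segments longer than `max_step_m` are discarded as
position errors; the default corresponds to an implied speed of 10 km/h
over one 15 s interval (≈ 41.7 m), far above sustained cow travel but
permissive of short trots. Elapsed time is not reduced when segments are
dropped, so the filter can only lower the estimate.

**Occupancy grid.** 5 × 5 m half-open cells anchored at the lower-left
corner of the paddock bounding box; a fix exactly on an edge belongs to the
higher-index cell. A cell is "inside" when its center falls in the paddock
polygon. Fixes landing on outside cells (GPS noise near fences) are
counted and reported, never silently dropped.

**Camargo evenness** is computed over *all* inside cells, zero-count cells
included; excluding zeros would make the index trivially high for
clustered use. The O(S log S) sorted prefix-sum form is used,
`Σ_{i<j}(p_(j) − p_(i)) = Σ_k p_(k)(2k − S + 1)`, and is tested to 1e-12
against literal pairwise enumeration.

**Covariates.** Percent slope (100·tan θ) by Horn's eight-neighbour
kernel, edges padded by replication; water distance as the minimum
Euclidean distance from cell centers to any water point. Both are z-scored
within the paddock mask before regression so the coefficients are
comparable across paddocks and individuals.

**Occupancy regression.** Counts over masked cells are regressed on one
z-scored covariate at a time with a Poisson log-linear model fitted by
IRLS (tested to 1e-8 against a GLM oracle). Standard errors are inflated
by the Pearson-χ² dispersion — a quasi-likelihood acknowledgement of
extra-Poisson, spatially structured variation. This deliberately replaces
a latent-Gaussian spatial error model: at the desk scale targeted here the
standardized coefficient, not the spatial field, is the quantity of
interest, and the independence approximation biases the coefficient little
while understating its certainty — which the dispersion inflation partly
repairs. The known cost is that residual spatial autocorrelation is not
modelled.

## Foraging

Diet proportions are bite counts over total bites per cow × pasture,
without duration weighting of observation bouts. Forage quality is
Q = Σ p_s q_s. Species groups are first-class taxa whose q is the
relevée-abundance-weighted mean of their members, resolved per pasture.
Pielou's J uses only taxa actually consumed (p > 0): it measures the
evenness of *selection*, not of the species pool; a single-taxon diet
leaves J undefined and is flagged rather than coerced. The selectivity
temperature τ (in P(s) ∝ a_s e^{τ q_s}) is estimated by bounded
maximisation of the multinomial log-likelihood on [−10, 10].

## Allometry statistics

SMA slope b = sign(r)·s_y/s_x, intercept a = ȳ − b x̄; the slope CI is the
standard F-based interval b(√(B+1) ± √B) with
B = F_{1−α}(1, n−2)(1−r²)/(n−2). The fit equals the first principal axis
of the z-scored variables back-transformed to the data scale (tested to
1e-10).

**Common slope.** At trial slope b the residual axis u = y − bx and fitted
axis v = y + bx are uncorrelated exactly when b is a group's own SMA
slope. The statistic LR(b) = −Σ_i w_i log(1 − r²_{uv,i}(b)) is minimised
over b (log-scale bounded search); the minimum is referred to χ²_{g−1}.
The weights are w_i = n_i − 3, the Fisher-z effective sample size for a
correlation test: with the naive n_i weights the empirical size at
g = 3, n = 30 is ≈ 0.06 rather than 0.05. The sampling variance of the
common slope is taken from the numerical curvature of the profile at its
minimum.

**Shift and elevation.** Both are Wald tests on group means of axis
scores — v = y + b_c x for shift (displacement *along* the common line),
u = y − b_c x for elevation (parallel offset). Group score variances use
n_i − 2 denominators; the shared common-slope uncertainty enters the
contrast covariance through the score-mean derivatives ±x̄_i, correlating
the group means. Because the covariance is estimated, the statistic is
referred to a Hotelling-T² F reference with pooled residual df
m = Σ(n_i − 2): W(m − p + 1)/(pm) ~ F(p, m − p + 1), p = g − 1. The plain
χ² reference is measurably liberal (≈ 0.058 at the reference design); the
Hotelling form holds 0.05 within simulation error. When the common-slope
test rejects at α (default 0.05, configurable), shift and elevation are
still computed from the forced common slope and flagged
(`common_slope_rejected`) — reporting lines under a forced common slope is
standard practice when slopes are heterogeneous.

Variables enter SMA on their original scales by default; a log-transform
flag is not applied implicitly because the downstream trait pairs include
signed quantities (weight change) and bounded indices.

**Tukey range tests** use the Tukey–Kramer studentized-range statistic
with the exact distribution from scipy; for g = 2 this reduces to the
pooled two-sample t-test. The breed × paddock-size ANOVA is sequential
(type I) on response ~ breed + size + breed:size with size continuous.
Across the nine standard allometric pairs no multiplicity adjustment is
applied by default (per-pair p-values are reported); a Holm option exists
at the call level via the returned table.

## Synthetic herd generator

The generator is first-class, tested code that emulates the study design
above; its defaults define the reference conditions for the end-to-end
tests.

* **Cows.** Weights lognormal per breed (medians 358 / 582 / 679 kg for
  the low/medium/high-productivity breeds, σ_log 0.08–0.10 — an
  order-of-magnitude choice, as within-breed variances are rarely
  published). Claw area A = k_a W^0.61 e^ε with breed-specific k_a so the
  low-productivity breed has relatively larger claws; outlines are
  rendered as elliptical 24-gons whose shoelace areas reproduce A/2
  exactly, so the anatomy stage round-trips by construction.
* **Terrain.** DEMs are smoothed Gaussian random fields rescaled so the
  Horn mean slope matches the target (19.2 / 48.1 / 25.1 % for the three
  pasture types); forage quality is a second smoothed field around the
  availability-weighted mean Briemle value of the pasture.
* **Movement.** A discrete-time walk on the 5 m analysis grid at 15 s
  steps. A two-state Markov chain produces lying bouts (stationary
  fraction = rest_prob, mean bout 20 min). When active, the cow attempts
  a move with probability move_prob, proposing one of its eight neighbours
  with turning-angle persistence weights e^{κ cos Δθ}, and accepts with
  the Metropolis probability min(1, e^{s_dest − s_here}) for
  s = −β_s z(slope) − β_w z(water) + τ z(quality). With κ = 0 the chain is
  reversible and its stationary occupancy is exactly ∝ e^s, which makes
  the regression coefficient an identifiable target: the recovery
  experiment therefore runs with κ = 0 and GPS noise off, isolating
  estimator bias from kernel non-reversibility and measurement blur. The
  default κ = 0.8 produces realistically tortuous tracks for the
  end-to-end studies.
* **GPS error** is AR(1) per axis (ρ = 0.98) with stationary per-axis SD
  2.63 m, i.e. a 3.1 m median radial error — the accuracy class of
  consumer GPS collars. Independent per-fix errors would be unrealistic
  here: at 15 s fixes they would add an apparent ~800 m/h to every speed.
  Autocorrelated error is gentler but still inflates speeds by roughly
  100 m/h, which is why simulated speeds sit above the distance actually
  walked; step counts, drawn from the *true* per-interval distance
  (Poisson, mean ∝ distance), stay strongly correlated with GPS speeds
  (r² ≈ 0.86 across cow × paddock in the default study).
* **Diet.** Bites are multinomial with P(s) ∝ a_s e^{τ q_s}; τ = 0
  reproduces availability. Daily weight change is
  intake_efficiency · (Q − maintenance_quality) + noise; maintenance
  quality rises with breed productivity (2.8 / 7.9 / 8.4 on the Briemle
  scale), so the undemanding breed gains weight on forage that makes the
  demanding breeds lose. These, like the movement coefficients (β_s, β_w,
  τ increasing with productivity), are calibrated to reproduce the
  qualitative breed *orderings* — fewest steps, most even space use, most
  even and lowest-quality diet for the low-productivity breed — not any
  particular field means.

Everything is driven by one seed through named SeedSequence streams; the
same (seed, config) gives byte-identical output.

**What the synthetic tests show — and what they do not.** Passing the
end-to-end tests shows the pipeline's stages compose correctly, preserve
cross-references, and detect the statistical signal the generator encodes
at realistic sample sizes (9 cows per breed). It does not validate the
generator as a model of real cattle: real herds have social behaviour,
diurnal rhythm, weather response, and spatially correlated diet choice
that the generator omits, and real GPS error is burstier than AR(1).
Conclusions about real data rest on the per-stage oracle tests (exact
arithmetic, evenness and SMA oracles, test calibration), not on the
realism of the walk.

## Numerical choices and degenerate inputs

* Problem sizes: the default synthetic study tracks 3 days per pasture at
  15 s fixes (17 280 fixes per cow and pasture) and records 400 bites per
  cow and pasture; the calibration experiments use 1000 null simulations
  and the recovery experiment 50 replicate walks of 20 000 steps on a
  ~2000-cell paddock. These sizes make the reported rates stable to a few
  per mille while keeping the whole suite in the minutes range.
* Duplicate timestamps for one cow are an error, never averaged.
* An all-zero occupancy vector, a constant covariate, a single-taxon diet,
  a group with n < 3, or zero variance in an SMA variable raise
  `DegenerateDataError` (CLI exit code 3); referential violations raise
  `ValidationError` (exit code 2) naming the offending record.
* The common-slope search runs on log |b| within [min|b_i|/10,
  max|b_i|·10]; a numerically flat profile (slope barely identified)
  yields a huge finite slope variance so downstream Wald tests degrade to
  p ≈ 1 instead of NaN.
* Spatial inputs must arrive in a projected metric CRS; the package never
  reprojects. DEMs are exchanged as Esri ASCII grids (written with full
  float precision so write → read round-trips exactly), boundaries as WKT,
  everything tabular as UTF-8 CSV with a header.

## Known limitations

* The occupancy regression's independence approximation (see above) makes
  its standard errors optimistic in strongly autocorrelated landscapes,
  even with dispersion inflation.
* The walk moves on grid-cell centers; speeds are quantised to multiples
  of 5 m per step before GPS noise, and sub-cell habitat structure is
  invisible.
* Pielou's J treats each recorded taxon (species or field group) as one
  unit; regrouping changes S and therefore J.
* Tukey tests assume homoscedastic groups; with strongly breed-dependent
  variances the range test is approximate (Tukey–Kramer handles unequal n,
  not unequal variance).
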