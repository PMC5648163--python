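# Methods

This note records the model, the numerical choices, and what the test
suite does and does not demonstrate.

## The forward model the generator implements

Enamel at tooth coordinate (x, d) — x the arc distance along the
enamel–dentin junction (EDJ) from the dentin horn in mm, d the relative
depth from the EDJ (0) to the outer surface (1) — follows a two-wave
history:

- **Secretion.** The secretory front reaches x at
  t_sec(x) = e_l⁻¹(x), the inverse of the extension curve
  e_l(t) = e_lmax − a + a·erf(s·t − o·s).  Apposition then thickens the
  enamel at `apposition_rate`, so the material point at depth d first
  exists at t_exist = t_sec(x) + d·T(x)/rate, where T(x) is the full local
  thickness.  On deposition, density jumps from 0 to
  `secretion_density_frac × max_density` (default 0.25 × 2.62 g/cm³;
  secreted enamel carries roughly a fifth to a third of mature mineral
  weight).
- **Maturation.** After a lag that shrinks linearly toward the surface,
  lag(d) = max(0, lag_cuspal − gradient·d), density rises along a logistic
  ramp of fixed duration to `max_density`.  The ramp is logistic for
  differentiability and two-parameter control; the linear, floored lag is
  the simplest form that makes near-surface maturation briefer.

Every event time and density has a closed form (`density_at`,
`crossing_time`, `landmark_position`), so rendered images can be checked
against analytic truth rather than against a second simulation.

### Generator defaults (the study conditions)

| parameter | default | why |
| --- | --- | --- |
| extension (a, s, e_lmax) | 22 mm, 0.009 d⁻¹, 38 mm | first molar ~29 mm at 100 d, nearly complete by 200 d |
| extension offset o | 37.17 d | chosen so e_l(−49 d) = 0 exactly: the crown initiates, with zero length, 49 days before birth |
| secretion_density_frac | 0.25 | secreted enamel at ~25% of mature density |
| maturation lag (cuspal, gradient) | 40 d, 25 d per unit depth | time averaging ≈ 78 d at the EDJ, ≈ 55 d at the surface |
| maturation_duration | 60 d | a prolonged, diffuse second wave |
| apposition_rate | 0.1 mm/d | secretion at a location is brief (~10 d to full thickness), giving the secretory front its steep angle to the EDJ |
| max_density | 2.62 g/cm³ | reference maximum mid-depth density |
| noise_frac | 0.05 | 5% multiplicative measurement noise |
| series | 45 specimens, 0–540 d | cross-sectional ontogenetic series |

The synthetic calibration lines have zero intercept (slopes 4.0×10⁻⁵ and
1.6×10⁻⁴ g/cm³ per grey unit for the two pretend batches).  The real batch
lines (intercepts 1.54 and 1.49 g/cm³) remain the package defaults for real
data, but they cannot represent densities below their intercepts — in
particular secretory enamel (~0.66 g/cm³) and the 40% onset threshold
(1.048 g/cm³).  Rendering through them clips, with a logged count; the
zero-intercept lines keep the synthetic pipeline self-consistent end to
end.

### What the generator does not emulate

2D sections are generated directly (no tomography, no reconstruction
artifacts); the EDJ is a straight line of configurable slope, not a curved
anatomical junction; there are no incremental features (cross-striations,
Retzius lines), no wear beyond explicit cropping, no mineral-phase
distinction, and maturation is deterministic given position — real
maturation geometry is visibly stochastic between individuals.  Passing
tests therefore demonstrate that the pipeline recovers a known two-wave
history from images with realistic noise and sampling, not that real
enamel follows this parameterization.

## Pipeline numerical choices

- **Background convention:** grey 0 is background; formed enamel is ≥ 1.
  Real images with a nonzero floor can raise `--background-threshold`.
- **EDJ tracing:** the dentin-facing (bottom) mask boundary per column,
  connectivity-checked; speck components under ~0.5% of the main blob are
  dropped, and a ragged sub-pixel wedge at the secretory tip (≤ 5% of
  columns) is truncated.  The staircase path is smoothed with a linear
  Savitzky–Golay kernel (window 9), which reproduces straight boundaries
  exactly, endpoints included, before arc length is integrated.
- **Flattening:** one pixel of arc per distance bin; 20 depth bins by
  default.  Normals are marched in half-pixel steps to the current outer
  surface, with the final face refined by interpolating the 0.5-level mask
  crossing.  Depth is measured from the 0.5-level mask contour (half a
  pixel dentin-ward of the boundary pixel centers).  Background is filled
  with nearest-enamel values before bilinear sampling so faces do not
  bleed zeros.  Depth is relative to the *current*, not final, surface —
  still-thickening columns put their momentary surface at depth 1.
- **Landmarks:** mid-depth is relative depth 0.5, interpolated between
  depth bins; the profile is 3-bin median filtered; positions are reported
  at bin centers (zero-mean quantization).  Sub-pixel anchoring limits
  landmark agreement with analytic truth to about ±2 bins at 46 µm — under
  a day of developmental time at the local front speeds.
- **Growth fitting:** residuals are in position (mm), where the
  measurement lives, never requiring the singular inverse.  The global
  stage is a seeded 200-point Latin-hypercube sweep of the (a, s, o) box;
  the best six starts get constrained SLSQP refinement.  Extension curves
  are *pinned* through (initiation day, 0): crown initiation means zero
  length, and without the pin the three parameters ride a flat likelihood
  ridge (the offset's relative uncertainty exceeds 40%; with the pin it
  drops below 9%).  Maturation onset/completion curves, whose fronts start
  moving only after the lag, instead get a ceiling constraint
  (≤ 0.25 mm at the initiation day).  e_lmax defaults to the longest
  specimen's extension length.
- **Age re-assignment:** t_m = extension_age(e_l); specimens at e_lmax
  keep their chronological age (size carries no information once growth
  stops).  Ties in t_m are broken by 10⁻⁶ day × rank so every pixel series
  has a strictly increasing time grid.
- **Sampler:** single-site Gaussian proposals; infeasible candidates
  (monotonicity, 10⁻⁵ g/cm³ minimum increment, bounds [0, 1.05 × 2.62])
  are rejected outright; step size adapts by Robbins–Monro toward 25%
  acceptance during the burn-in half only, then freezes, preserving
  detailed balance.  Walkers start from the isotonic regression of the
  pixel's data, jittered per walker and projected back into the feasible
  set.  σ_t defaults to 0.05 × 2.62 g/cm³, constant across t: "5% of
  measurable densities" read as 5% of the density scale, because a
  proportional error would make near-zero early densities implausibly
  precise (a proportional mode is available).  Retention pools the four
  walkers evenly by uniform thinning of post-burn-in states.  All
  randomness flows from spawned `SeedSequence` children, so runs are
  bit-reproducible pixel by pixel.
- **Assembly:** densities are stored as percent of 2.62 g/cm³ in
  `pct_min_samples` (ages × pixels × samples); absent pixel-ages hold the
  sentinel −1 with `age_mask` 0.  Daily interpolation is linear (which
  preserves monotonicity), zero before a pixel's first presence, constant
  after its last; the default window opens at the fitted initiation day.
  Threshold crossings are interpolated within the day.  Rate fields are
  first differences of the posterior-mean daily trajectory (%/day);
  display smoothing uses a Gaussian of σ = 1 px spatially and 8 days
  temporally.

## Scaled problem sizes

The test suite and the acceptance script run the pipeline at sizes chosen
to exercise every stage while staying light: the end-to-end study uses 12
specimens sampled evenly over the M1 active formation window (10–300 days;
the crown is essentially complete by ~250–300 days), ~320 pixel locations,
and 20,000 MCMC samples per pixel.  Spreading so few specimens over the
full 540-day ontogeny would make completion-time error a property of the
age layout rather than of the method: with ~36-day gaps, chord-vs-sigmoid
interpolation alone contributes ~8 days RMS.  Over the formation window
the pipeline recovers per-pixel 85%-completion times to ~8 days RMS,
bias-dominated (linear interpolation crosses a concave ramp late, and the
monotone posterior's plateau behavior — below — drags the ramp top down).

## Known limitations

- **Plateau marginals are order statistics.**  With near-constant data and
  exchangeable Gaussian noise, the flat-prior monotone posterior is
  exactly the law of the order statistics of iid normals (for three equal
  observations the outer marginal means sit 0.85σ from the data — the
  sampler reproduces this against closed form).  Pointwise credible bands
  on long mature plateaus therefore spread across ±2σ while the truth is
  constant, and their pointwise coverage of a constant truth is far below
  nominal.  This is a property of the model, not of the sampler — the
  sampler matches exhaustive enumeration to TV < 0.02 on small instances.
  Posterior-mean trajectories remain accurate (~0.1 g/cm³ RMS during
  formation), and derived quantities that integrate over the trajectory
  (completion times, rate fields, time averaging) are well behaved.
- **Parameter-level identifiability.**  Even with the initiation pin, 5%
  multiplicative positional noise on 45 landmarks bounds any estimator's
  precision (constrained Cramér–Rao: ~2.5% on a, ~6% on s, ~8.5% on o), so
  all three parameters land within 10% in roughly 60–80% of replicates,
  not nearly always.  The fitted *curve*, as opposed to its parameters, is
  recovered far more tightly.
- Oblique sectioning, loph torsion, enamel wear beyond a cuspal crop, and
  model transfer between molar types are out of scope.
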