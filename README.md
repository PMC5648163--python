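# mineralwave

Dynamic probabilistic modeling of tooth enamel mineralization from an
ontogenetic series of static density images.

## The problem

Tooth enamel forms in two phases.  Ameloblasts first *secrete* a
partially mineralized protein scaffold, with the secretory front extending
along the enamel–dentin junction (EDJ) from the cusp toward the cervix and
the enamel thickening by apposition toward the outer surface.  Most mineral
is then added during *maturation*, a slower, more diffuse wave that raises
hydroxyapatite (HAp) density to its mature maximum.  Because each location
in the crown accumulates mineral over an extended window, the chemistry
recorded in enamel (stable isotopes, trace elements, toxins) is
*time-averaged* — and reading seasonal or physiological histories out of
teeth requires knowing, per location, when mineral actually arrived.

Maturation cannot be watched directly.  What can be measured is a
cross-sectional series: molars from many animals that died at different
ages, each scanned once, with grey values calibrated to HAp density
(g/cm³).  `mineralwave` reconstructs the shared dynamic history from such a
series, for researchers in dental biology, archaeology and paleoclimate
who need per-location mineralization timing.

## The method

1. **Density calibration** — batch-specific lines `ρ = slope·Px + intercept`
   convert pixel grey values to densities (defaults: `ρ = 6.9×10⁻⁵·Px + 1.54`
   and `ρ = 2.8×10⁻⁴·Px + 1.49` for scan batches 1 and 2).
2. **Shape standardization** — each section is flattened along its traced
   EDJ into (arc distance from the dentin horn, relative depth) coordinates;
   per-specimen landmarks are the extension length `e_l` and the farthest
   positions where mid-depth density reaches 40% (maturation onset) and 85%
   (completion) of the 2.62 g/cm³ reference maximum.
3. **Growth curves** — landmark progress versus age is fit with integrated
   Gaussians, `e_l(t) = e_lmax − a + a·erf(s·t − o·s)`, constrained at the
   histologically known crown initiation day (−49 d for M1, +84 d for M2).
   The closed-form inverse
   `t_m = [erf⁻¹((a + e_l − e_lmax)/a) + o·s]/s`
   re-assigns each specimen a *size-modeled age* from its extension length,
   sharpening the developmental time axis.
4. **Monotone-trajectory MCMC** — each standardized pixel yields a short
   noisy density series across specimens.  Its mineralization history ρ_m(t)
   is sampled under the Gaussian likelihood
   `log L = Σ_t −(ρ_m(t) − ρ_d(t))²/(2σ_t²)`
   with a flat prior over non-decreasing trajectories (min increment
   10⁻⁵ g/cm³ per interval), using Metropolis–Hastings with four walkers and
   150,000 samples per pixel, of which 100 are retained.
5. **Model assembly** — posteriors are stored in an HDF5 file with datasets
   `age_mask`, `ages`, `locations`, `pct_min_samples`, then interpolated to
   a daily grid to derive deposition-rate fields and per-location
   time-averaging maps.

A forward simulator (`synthetic_tooth`) renders ontogenetic series of
grayscale sections from a two-wave model with fully analytic ground truth,
so every stage is testable without any scan data.

## Worked example

```python
import numpy as np
import mineralwave as mw
from mineralwave.density_calibration import calibrate_section
from mineralwave.shape_standardization import trace_edj, flatten, measure_landmarks
from mineralwave.growth_curves import fit_growth_curve, SpecimenRecord, reassign_ages
from mineralwave.mineralization_mcmc import MCMCConfig, build_pixel_series, run_all_pixels
from mineralwave import model_assembly as ma

params = mw.WaveModelParams()                      # two-wave forward model
ages = list(np.linspace(10, 300, 12))              # ages-at-death (days)
sections, truth = mw.simulate_series(params, ages, seed=0, pixel_size_mm=0.1)

flats, records = [], []
for sec in sections:
    dmap = calibrate_section(sec, mw.SYNTHETIC_CALIBRATIONS[sec.batch])
    flat = flatten(dmap, trace_edj(dmap), n_depth_bins=10)
    lm = measure_landmarks(flat)
    flats.append(flat)
    records.append(SpecimenRecord(sec.specimen_id, sec.age_days, lm.e_l))

fit = fit_growth_curve([(r.chronological_age, r.e_l) for r in records],
                       el_max=max(r.e_l for r in records), seed=0)
print(f"extension fit: a={fit.params.a:.2f} mm, s={fit.params.s:.5f} /day, "
      f"o={fit.params.o:.1f} d (RSS {fit.rss:.2f} mm^2)")

records = reassign_ages(records, fit.params)
cfg = MCMCConfig(n_samples=20_000, seed=0)
series = build_pixel_series(flats, records, cfg, distance_stride=12)
posteriors, usable = run_all_pixels(series, cfg)
model = ma.assemble_model(posteriors, usable, output_path="scratch/model.h5",
                          edj_bin_mm=flats[0].edj_bin_mm, n_depth_bins=10)
print(f"model: {model.n_pixels} pixels x {model.ages.size} ages x "
      f"{model.n_samples} retained samples")

daily = ma.interpolate_daily(model, n_days=420, t_start=-49.0)
bands = ma.time_averaging_map(daily).band_means()
print("time averaging (days): inner %.1f, mid %.1f, outer %.1f"
      % (bands['inner'], bands['mid'], bands['outer']))
```

Output:

```
extension fit: a=21.85 mm, s=0.00906 /day, o=38.3 d (RSS 0.02 mm^2)
model: 320 pixels x 12 ages x 100 retained samples
time averaging (days): inner 66.5, mid 61.0, outer 55.8
```

The fitted amplitude/slope/offset sit close to the generator's true curve
(a = 22 mm, s = 0.009/day, o = 37.2 d); the assembled model reproduces the
key geometry: inner enamel averages chemistry over more days than outer
enamel, because the maturation lag after secretion shrinks toward the
surface.

The same pipeline is scriptable from the shell:

```bash
mineralwave simulate --out-dir raw --n-specimens 45 --seed 0
mineralwave calibrate --manifest raw/manifest.csv --out density.h5 --synthetic-calibration
mineralwave standardize --density-maps density.h5 --out-flattened flat.h5 --out-landmarks landmarks.csv
mineralwave fit-growth --landmarks landmarks.csv --out fits.json
mineralwave sample --flattened flat.h5 --ages fits.ages.csv --out model.h5
mineralwave derive --model model.h5 --out-dir derived --frames
```

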