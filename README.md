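# optoquant

Optical quantal analysis of neuromodulator release.

Genetically encoded indicators (GEIs) for transmitters such as serotonin
(5-HT) and oxytocin (OXT) make vesicular release visible as localized
ΔF/F0 hotspots in wide-field fluorescence movies.  `optoquant` turns such
movies into presynaptic release properties at single-synapse resolution:

- **spatial spread length constant λ** — decay constant of the
  single-exponential fit ΔF/F0(r) = A·exp(−r/λ) to a release site's radial
  profile, after Landweber deconvolution of the optical PSF;
- **quantal size q and release probability Pr** — from low-frequency
  (0.1 Hz) trial trains via an equal-spacing Gaussian-mixture fit of the
  trial-amplitude distribution (peaks at 0, q, 2q, …) and failure counting;
- **readily releasable pool (RRP) and vesicular refilling rate** — from
  long 16 Hz trains: the slow sensor response (τ_off up to ~9 s) is
  inverted by nonnegative regression onto shifted impulse-response
  templates, and the late phase of the cumulative-release curve is
  back-extrapolated (intercept → RRP, slope → refill), converted to
  vesicles by dividing by q.

Because raw imaging data for the published group values are not publicly
deposited, the package includes a first-class synthetic-movie generator
(`optoquant.simulate`) with known ground truth — release dynamics, sensor
kinetics, optics, bleaching, noise — so every stage is validated by
parameter recovery.  See `docs/methods.md` for the models and numerical
choices.

Intended users: slice/culture imaging labs doing GEI-based transmission
analysis, and methods developers who need a testable reference
implementation of the optical quantal-analysis chain.

## Worked example

Simulate a single release site with λ = 0.74 μm, run the pipeline, and fit
the spread constant:

```python
import numpy as np
from optoquant import preprocess, hotspots
from optoquant.simulate import HotspotSpec, SimulationConfig, simulate_movie

px = 0.1625                      # μm per pixel (40x objective)
stim = tuple(1.0 + np.arange(20) / 16.0)   # 20 pulses at 16 Hz
site = HotspotSpec(center_um=(3.9, 3.9), lambda_um=0.74, quantal_size=0.008)
config = SimulationConfig(image_shape=(48, 48), pixel_size_um=px,
                          n_frames=32, stim_times=stim, hotspots=[site],
                          f0_mean=4444.0, psf_sigma_um=0.25, seed=7)
movie, truth, events = simulate_movie(config)

psf = preprocess.gaussian_psf(0.25 / px)
reg = preprocess.register_translation(movie)
dec = preprocess.landweber_deconvolve(reg.aligned, psf, n_iter=50)
dff = preprocess.compute_dff(dec.stack, f0_window=(0, 10))

peak_frame = int(np.nanargmax(np.nansum(dff.dff, axis=(1, 2))))
mp = hotspots.max_dff_map(dff.dff, (peak_frame, peak_frame + 1))
mp.pixel_size_um = px
center = hotspots.find_center(mp.values)
profile = hotspots.radial_profile(mp, center, max_radius_um=2.0)
fit = hotspots.fit_spread(profile, r_min_um=2 * px)
print(f"lambda = {fit.lambda_um:.3f} um  (R2 = {fit.r2:.3f})")
```

Output:

```
lambda = 0.786 um  (R2 = 0.980)
```

The recovered 0.786 μm estimates the spatial spread constant of the
simulated site (truth 0.74 μm; single noisy movies scatter by several
percent, and averages over 20 fixtures land within a few percent of
truth): the PSF blur that widened the raw profile has been removed by the
50 Landweber iterations, and the single-exponential fit reads the decay
length off the radial profile.

A command-line interface wraps the same stages
(`optoquant simulate | preprocess | analyze-spread | analyze-quantal |
analyze-pool | report | recover`); stimulus timing is a JSON file with
explicit onset times, configs are YAML, tables are CSV with a config hash
on every row.

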