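# splitkit

Spectral demixing and post-processing for multi-color single-molecule
localization microscopy (SMLM) acquired through a dichroic image splitter.

## The problem

In splitter-based multi-color SMLM, the emission of every fluorophore is
divided by a dichroic mirror into a short-wavelength (λ_S) and a
long-wavelength (λ_L) channel imaged side by side on one camera.  Each
molecule is therefore localized twice, with photon counts I_S and I_L whose
ratio r = I_L / I_S is a fingerprint of the fluorophore species — spectrally
close dyes (e.g. AF647 / CF660C / CF680) that cannot be separated by filters
become separable by ratiometry.  The difficulty is what to do with the two
position estimates **X**_S and **X**_L: classical demixers keep only one
channel's coordinates, wasting the other channel's photons (the localization
precision of a fit with I photons is σ = σ₀/√I, so discarding photons
costs precision), while mixing channels naively re-introduces the chromatic
shift between them.

`splitkit` implements the photon-budget-preserving resolution of this
trade-off, plus everything around it:

- **Pairing & filtering** — per-frame mutual-nearest-neighbor matching of
  the two channel tables within a tolerance (default 100 nm) after automatic
  registration (translation by image cross-correlation, optionally a full
  affine fit absorbing unequal channel magnification).  Detections seen in
  only one channel are rejected: background noise fires independently in
  each channel and rarely coincides, so the coincidence condition is a
  strong spurious-localization filter.
- **Species assignment** — sector regions on the bivariate histogram of
  (I_S, I_L): a half-open ratio interval plus total-intensity bounds, with
  cross-talk estimation from single-labeled samples.
- **Output coordinates** — six methods: `lambdaS`, `lambdaL`, `brightest`,
  `mean`, `wmean`, `wmean_chroma`.  The photon-weighted mean
  **X** = w_S·**X**_S + w_L·**X**_L with w_c = I_c/(I_S+I_L) has variance
  σ₀²/(I_S+I_L): the full photon budget, as if no splitter were present.
  The simple mean cancels the chromatic shift exactly but loses precision
  whenever r > 3 compared with the brighter channel (break-even at exactly
  r = 3).  `wmean_chroma` keeps the weighted mean's precision and removes
  its residual ratio-dependent chromatic offset by registering it against
  the simple-mean positions and fitting a low-order polynomial field per
  species, which is then subtracted.
- **Refinement of re-localizations** — molecules detected on consecutive
  frames are chained (50 nm search radius) and their coordinates redrawn
  around the photon-weighted centroid with σ = σ_psf/√N_ph, keeping the
  localization density that plain merging destroys.
- **Drift correction** — time-binned image cross-correlation on the sum of
  all demixed channels (the drift is common to simultaneously imaged
  channels).
- **Metrics** — 2D histogram rendering, Fourier ring correlation resolution
  (FRC, 1/7 criterion, random-half splits), annulus-normalized radial
  particle profiles, two-Gaussian axial profile alignment, and the
  intensity-weighted average emission wavelength of a fluorophore seen
  through a filter chain.
- **Simulator** — ground-truthed two-channel tables with exact binomial
  photon splitting (I_S + I_L = I per event), shot-noise-limited per-channel
  localization error, chromatic offset fields, geometric blinking runs,
  detection thresholds and background, for testing every stage end to end.

The processing stages are sklearn-style estimators (`ChannelAligner`,
`ChromaticCorrector`, `ConsecutiveRefiner`, `DriftCorrector` with
`fit`/`transform` and fitted `*_` attributes); plain functions wrap them for
one-shot use, and a `splitkit` CLI wires them into the full workflow.

## Worked example

Two co-located fluorophore species (ratios r = 0.6 and 3.5, every blink
2000 photons, PSF FWHM 300 nm, constant chromatic shift (24, 8) nm on the
λ_L channel), 5000 detections per species:

```python
import numpy as np
from splitkit import (SectorRegion, assign_species, demix_coordinates,
                      colocated_species_scenario)

cfg, pairs = colocated_species_scenario(n_detections=5000, seed=42)
boundary = float(np.sqrt(0.6 * 3.5))          # geometric-mean sector boundary
sectors = [SectorRegion("red", 0.0, boundary),
           SectorRegion("blue", boundary, 1e9)]
labels, rejection = assign_species(pairs, sectors)

for method in ("lambdaL", "brightest", "mean", "wmean", "wmean_chroma"):
    res = demix_coordinates(pairs, labels, method, chroma_degree=0)
    off = res.tables["blue"].xy.mean(0) - res.tables["red"].xy.mean(0)
    sd = np.concatenate([t.xy - t.xy.mean(0) for t in res.tables.values()]).std()
    print(f"{method:>12}: inter-species offset ({off[0]:+5.1f}, {off[1]:+5.1f}) nm,"
          f" cloud sd {sd:4.2f} nm")
```

prints

```
     lambdaL: inter-species offset ( -0.1,  -0.2) nm, cloud sd 4.02 nm
   brightest: inter-species offset (+23.8,  +8.0) nm, cloud sd 3.43 nm
        mean: inter-species offset ( -0.2,  -0.1) nm, cloud sd 3.18 nm
       wmean: inter-species offset ( +9.5,  +3.1) nm, cloud sd 2.85 nm
wmean_chroma: inter-species offset ( -0.2,  -0.1) nm, cloud sd 2.85 nm
```

Reading the numbers: localizing both species from λ_L avoids any chromatic
offset but has the worst precision (4.0 nm — the dim channel of the red
species wastes most of its photons).  `brightest` shows the full (24, 8) nm
chromatic shift because the two species come from opposite channels.  The
simple `mean` cancels the shift but its spread (3.18 nm) exceeds the
shot-noise optimum.  `wmean` reaches the optimum σ₀/√2000 = 2.85 nm yet
keeps a residual ratio-dependent offset of (9.5, 3.1) nm; `wmean_chroma`
removes that too — optimal precision and no chromatic error.  Both species
are assigned with zero measured cross-talk at this photon budget.

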