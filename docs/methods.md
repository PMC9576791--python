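# Methods

## Statistical model

A single-molecule localization is modeled as **X** ~ N(**μ**, σ²) per axis,
with σ = σ₀/√I for I detected photons and PSF standard deviation σ₀ (we use
σ₀ = FWHM/2√(2 ln 2); the default setup values are camera pixel 100 nm,
σ_psf = 140 nm, and a simulation PSF FWHM of 300 nm ⇒ σ₀ ≈ 127.4 nm).  An
ideal dichroic splitter divides the I photons between the channels without
loss, I = I_S + I_L, so the two channel localizations are
**X**_c ~ N(**μ**_c, σ₀²/I_c) with **μ**_S ≠ **μ**_L in general because of
chromatic errors.  Only shot noise is modeled; background and fitting bias
are treated as removable by the coincidence and intensity filters.

For the photon-weighted mean with w_c = I_c/(I_S + I_L), the output variance
is w_L²σ₀²/I_L + w_S²σ₀²/I_S = σ₀²/(I_S + I_L): the splitter costs no
precision.  The simple mean has variance (σ₀²/I_L + σ₀²/I_S)/4, which beats
localizing from the brighter channel alone iff the channel ratio is below 3
(√(1+r) < 2); both closed forms live in `splitkit.precision` and the
break-even point is exposed as `break_even_ratio()` (root-finding, though the
root is analytic).  The weighted mean's centroid sits at
w_L**μ**_L + w_S**μ**_S, i.e. it retains a fraction (w_L − ½) of the
inter-channel chromatic shift; the simple mean's centroid (μ_L + μ_S)/2 is
chromatic-free, which is why it serves as the registration reference for the
correction below.

## Chromatic correction (`wmean_chroma`)

For every assigned pair we form Δ**x** = **x**_wm − **x**_m.  Its
expectation, (w_L − ½)(**μ**_L − **μ**_S), varies smoothly with position
(lateral chromatic aberration plus unequal channel magnification), while its
random part (localization noise, photon fluctuations; tens of nm per pair,
zero mean) averages out.  We fit Δx and Δy against the simple-mean positions
with a 2D polynomial (total degree ≤ `degree`, default 1; coordinates are
centered and scaled before building the Vandermonde matrix) and subtract the
fitted field from the weighted-mean positions.

The fit is done **per species** by default.  The retained chromatic fraction
(w_L − ½) depends on the species' ratio r, so a single pooled fit against
position cannot distinguish two species occupying the same region and would
leave their relative offset untouched; fitting each demixed channel
separately sends every species' centroid to its simple-mean (chromatic-free)
position.  A pooled fit (`per_species_chroma=False`) is available for
single-species data or diagnostics.

Degenerate geometry (all pairs collinear) makes the design matrix
rank-deficient and raises an error suggesting a lower degree.  A minimum of
10·(degree+1)² pairs is required per fit.

## Pairing rules

Pairing is strictly per frame and mutual-nearest-neighbor within the
tolerance (default 100 nm, the upper end of the 50–100 nm window that
accommodates chromatic offsets plus two localization errors).  Ambiguity is
resolved by rejection, not by choice: a detection whose two nearest
in-tolerance partners are equidistant (within 1 fm) is discarded together
with both partners, and a non-reciprocated nearest neighbor stays unpaired.
Rationale: a wrong match corrupts both the ratio and the fused coordinate,
while a discarded localization only costs density; multi-emitter coincidence
events are meant to be filtered anyway.  The channel registration
(`ChannelAligner`) is estimated once per dataset — splitter geometry is
static; drift is handled downstream on the demixed data.  Translation comes
from the sub-pixel (centroid-refined) peak of the cross-correlation of the
two rendered channel histograms; the affine model then iterates
nearest-neighbor pairing and least squares three times so that
magnification-displaced points at the field edges re-enter the fit.

## Grouping and refinement

Re-localizations are chained greedily in frame order: a detection on frame f
may join a group last extended on frame f−1 whose photon-weighted centroid
lies within the search radius (default 50 nm); a group accepts at most one
member per frame, so same-frame detections never merge; equidistant
candidates resolve to the lower group index.  In `refine` mode every member
keeps its photon count but its coordinates are redrawn i.i.d. from an
isotropic 2D normal centered on the group centroid with per-axis
σ = σ_psf/√N_ph (N_ph the group's photon sum) — encoding the combined
precision without collapsing density or creating single-pixel artifacts.
`merge` mode produces one localization per group (photons = N_ph, frame =
first member's).  Singletons are redrawn too by default
(`redraw_singletons=False` exempts them).  All draws derive from an explicit
seed.

## Drift

The demixed channels are concatenated (drift is common to simultaneously
acquired channels), frames are cut into equal time bins (default 10), each
bin is rendered at 25 nm (configurable) and shifted onto the first bin by
the sub-pixel cross-correlation peak.  Bins with fewer than 10 localizations
are interpolated over.  Per-frame drift is linear interpolation between bin
centers, constant beyond the ends, and is subtracted from all channels.

## FRC

Each repeat (default 10) splits the localizations Bernoulli(½), renders both
halves on a common square grid (default 5 nm pixels), ring-averages
Re⟨F₁F₂*⟩/√(⟨|F₁|²⟩⟨|F₂|²⟩) over 90 uniform frequency bins up to Nyquist,
smooths with a 3-bin moving average, and reports 1/f at the first
interpolated crossing below 1/7 (flagged "not reached" if the curve never
crosses — in particular when the localization precision outruns the Nyquist
limit of the chosen pixel; render finer in that case).  Known limitation:
re-localizations of one molecule falling into both halves correlate the
halves, biasing FRC optimistic; upstream grouping/refinement is the
mitigation, no further correction is applied.

## Spectral average

The average emission wavelength of a fluorophore in a channel is
λ₀ = ∫λI(λ)dλ / ∫I(λ)dλ over 630–800 nm, where I(λ) is the emission
spectrum multiplied by all filter/dichroic transmissions and the camera
quantum efficiency, all linearly interpolated to a 0.5 nm grid (trapezoidal
integration).  The statistic is invariant under rescaling any input
spectrum.

## Simulator

`simulate_acquisition` draws, per blink event: a total photon count (fixed,
Poisson, or median-parameterized lognormal), an exact binomial split
I_L ~ Bin(I, r/(1+r)) — so I_S + I_L = I holds per event and the ratio r in
expectation — then per-channel positions with noise σ₀/√I_c around
**μ** (S) and **μ** + chromatic_field(**μ**) (L).  Blinking is a per-frame
on-probability with geometric run lengths (defaults 1e-4 and mean 2; these
are exercise parameters for the grouping stage, not a photophysical model).
Per-channel detection thresholds and uniform background with lognormal
photons generate realistic unpaired detections.  What the simulator does
*not* emulate: camera pixelation and EMCCD noise, fitting artifacts,
non-Gaussian PSFs, axial structure, bleaching kinetics, emission-spectrum
heterogeneity between molecules.  Passing tests therefore validate the
statistical machinery of demixing, not robustness to fitting pathologies in
real data.

Benchmark presets: `colocated_species_scenario` (two co-located species, r = 0.6 and
3.5, fixed 2000-photon events, FWHM 300 nm, constant (24, 8) nm chromatic
shift, 50 detections per species by default — enlarged runs only shrink the
Monte-Carlo error) and `grouping_scenario` (300 scattered emitters in a
2 µm field, ~1000-photon events in runs of mean 2.5 frames over 4000
frames), used as the standard scenario for refinement, FRC and drift
checks.  Problem sizes in the test suite (10⁴–10⁵ events, 8–10 drift bins,
≤ 10⁶-pixel renders) are chosen so each statistical check resolves its
tolerance with ≥ 3σ margin while the whole suite stays interactive.

## Numerical choices

- Coordinates are float64 nm throughout; frames are 1-based int64.
- All interval conventions are half-open ([min, max) rectangles, ratio
  sectors, histogram pixels), so adjacent regions partition exactly.
- `brightest` resolves I_S = I_L ties to λ_S.
- CSV output formats floats with shortest round-trip repr and input parses
  with round-trip precision, so write→read→write is byte-stable.
- Every stochastic operation (refinement, FRC splits, simulation) takes an
  explicit seed; identical seeds give identical outputs.

## Known limitations

- Sectors are ratio/total-intensity wedges, not free polygons.
- Two splitter channels only; no 3D (z) columns; no raw-frame fitting — the
  package consumes localization tables.
- Chromatic model is a global polynomial; no local/nonparametric warp.
- Drift is lateral and piecewise-linear in time; no fiducial tracking.
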