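# Methods

## Measurement model

### Line profiles

A calibrated image is a set of named 2D channels with a physical pixel size
(µm/px) and a bit depth (12 bits by default, saturation at 4095). Continuous
coordinates are in µm with pixel centres at `(i + 0.5)·pixel_size`; all
sub-pixel sampling is bilinear, with no smoothing beyond the band average
described next. A profile is extracted along a closed contour resampled to
uniform arc-length spacing `ds` (default: one pixel). At each sample the
intensity is the mean of `band_px = 3` bilinear samples spaced one pixel
apart along the local contour normal — emulating the finite width of a
manually traced polyline while staying well below the minimum hole width.
Profiles live on the half-open circular domain `[0, L)`; the first and last
samples are adjacent, and every downstream operation treats them that way.

### Hole detection

The detection threshold is anchored to the *unsaturated* peak of the WFA
channel — the maximum sample strictly below the saturation level — so
clipped pixels cannot inflate it. The threshold fraction is swept over
[0.40, 0.66] in 0.01 steps; for each fraction, maximal circular runs of
samples strictly below the threshold whose interpolated width is ≥ 0.5 µm
are counted, and the fraction maximising the count is kept, ties broken
toward the smallest fraction (most conservative boundaries). Hole
boundaries are linear interpolations of the threshold crossing between the
neighbouring samples, which removes the dependence of the 0.5-µm width
cutoff on `ds`. Runs wrapping the profile origin are merged into one hole;
any single supra-threshold sample splits a run (we do not bridge
single-sample blips — the choice is documented here because it is not
forced by the measurement definition). A profile entirely below threshold
degenerates to a single full-circle hole.

The threshold is selected per cell; a cohort-level override is available in
the run configuration for batch-calibrated acquisitions.

### Occupancy classification

A channel occupies a hole when it shows a local maximum strictly inside the
hole interval whose prominence — its height above the higher of the two
channel values at the hole boundaries — reaches `k_sigma` times the
channel's robust noise sd (1.4826·MAD of first differences / √2, insensitive
to bumps and slow structure).

`k_sigma` defaults to **5.0**. The rationale: the criterion compares the
maximum over the ~15–50 samples of a hole against just two boundary samples,
so the prominence of a *pure-noise* hole concentrates around 2–2.5 σ with an
upper tail reaching ≈ 4.5–5 σ, while a genuine marker bump (contracted to at
least 5 pixel-noise sd by the generator, and in practice ≈ 20 σ at the
profile level after band averaging) sits far above. Measured on synthetic
cohorts at SNR 10, k = 5 is the equal-error point (false-positive and
false-negative call rates both ≈ 0.8 %); k = 3 would admit ≈ 18 % false
positives because it sits inside the noise-prominence distribution. The
parameter is exposed and logged with every run.

### Pericellular morphometry

Soma masks are Otsu-thresholded from the soma/PV channel, reduced to the
largest connected component and hole-filled. The pericellular band is the
set of outside pixels whose Euclidean distance to the soma is at most the
band width (0.8 µm default); half a pixel is subtracted from the
centre-to-centre distance so a rasterised disk reproduces the annulus
closed form `π((r+w)² − r²)` to well within 2 % at 0.031 µm/px. Bands
narrower than one pixel degrade to the one-pixel shell, and bands touching
the image edge are flagged as clipped. Coverage is the marker∩band area in
µm², normalised by the cell perimeter; "combined" coverage takes the union
of the listed marker masks before intersection.

Puncta detection implements the flood-from-maximum ("noise tolerance")
prominence definition so the printed 12-bit settings (500 for vGlut1, 2000
for vGAT) are directly meaningful: a descending union-find sweep with
8-connectivity gives each regional maximum a birth (its summit value) and a
death (the level at which it merges into a higher-born component);
prominence = birth − death, plateaus are reported once at their centroid,
and survivors are referenced to the image minimum (so a constant image
yields no puncta). The implementation is cross-checked in the tests against
an exhaustive saddle-search oracle. Prominence values are
acquisition-specific configuration and are never rescaled across bit depths.
Contact between a punctum and an astrocytic mask is Boolean overlap within a
configurable radius (default 0: same pixel).

Disruption profiles lay adjacent 0.4 × 0.4 mm² ROIs along the image x-axis
from the injection site (direction supplied as a flag, since section
orientation is an acquisition property) and report mean ± sd intensity per
ROI.

### Trace metrics and seizure detection

Sweeps are excluded when their baseline sd exceeds 3× the group median
(formalising the exclusion of sweeps with baseline fluctuation or noise);
at least two survivors are averaged. After baseline subtraction: peak is the
extremum magnitude in the response window; charge is `|∫ i dt|` by the
trapezoid rule (pA·s ≡ pC); decay time is the interpolated time from the
peak to its first fall to 37 % of peak (a direct reading of the
100 %→37 % definition, not an exponential fit — for a true exponential it
equals 0.9943 τ); decay slope is 0.63·peak / decay time. A trace that never
reaches 37 % within the window is censored, not extrapolated. Because the
charge window is not fixed by the measurement definition, it is a required
parameter. Inward currents are stored signed and reported as magnitudes
with a polarity field. iGluSnFR net change normalises the pre-blockade
(ACSF) peak to 100 %: `100·(peak_blocked − peak_acsf)/peak_acsf`.

Seizure detection scores spikes as rectified excursions above
`amp_factor × A_base` (default 2×), where `A_base` is the **mean of per-0.5-s
block maxima of |x|** over the baseline window. This deflection-amplitude
reading of "average baseline amplitude" matches how a visual scorer judges
baseline: for Gaussian background the rectified mean is ≈ 0.8 σ, and any 2×
threshold on it would be crossed ~11 % of the time, making a
zero-false-positive detector impossible; the block-maximum measure puts the
2× threshold at ≈ 6 σ, which background essentially never crosses while
qualifying discharges (≥ 2× typical deflections) always do. Spikes merge
within a 1-ms refractory window; candidate events are maximal spike spans
with inter-spike intervals ≤ 1/min_rate (0.5 s), padded by half an interval
at each end, and are kept when ≥ 5 s long with mean spike rate ≥ 2 Hz. On
noisy records a single broad sharp-wave can contribute more than one
rectified peak, so the reported spike rate upper-bounds the discharge rate;
the qualification logic is unaffected.

## Synthetic data

The generator emulates the acquisition the analyses assume: 12-bit
intensities, 0.031 µm pixels, a WFA coat of ~0.6 µm radial thickness on a
9-µm-radius soma contour. Hole troughs drop to 10 % of the WFA level with a
flat floor across the nominal interval and raised-cosine edges one PSF width
(0.1 µm) wide placed *outside* it; after Gaussian PSF blurring the entire
nominal interval therefore stays strictly below 40 % of peak — the floor of
the detection-threshold range — which is asserted as an invariant. Hole
widths are uniform on 0.5–1.5 µm with ~25 holes per net and inter-hole peaks
of at least 0.9 µm (0.5 µm of net plus taper margins); these counts and
widths are plausible defaults for a perforated coat, not literature claims.
Marker bumps (Gaussian, σ = 0.2 µm) are placed uniformly within the central
60 % of their hole to avoid boundary ambiguity, with per-hole channel
combinations drawn from a configurable exclusive partition; amplitudes are
required to stay ≥ 5 pixel-noise sd after PSF attenuation. Noise is
additive Gaussian (optional Poisson shot noise) applied after the PSF, as in
a photodetector; SNR is defined as WFA peak / noise sd. All randomness
flows from one explicit seed; identical (configuration, seed) reproduces
bit-identical arrays.

Pericellular images realise a requested band-coverage fraction as randomly
chosen angular sectors (72 sectors, so coverage resolves to ~1.4 %) and
place puncta with a 0.6-µm minimum separation — close enough to be dense,
far enough that overlapping tails cannot pull a genuine punctum's prominence
below the vGlut1 setting. EEG background is Gaussian; discharge epochs add
cos²-shaped sharp waves at the requested rate with amplitude expressed as a
multiple of the same block-maximum baseline measure the detector uses.

The bundled occupancy presets encode the reported cohort percentages for
each marker panel (e.g. astrocytic reporter 63 %, Kir4.1 71 %, both 62 %;
vGlut1 71 %, astro 53 %, both 44 %, any ≈ 80 %; three-channel panel with
vGlut1∧vGAT 37 %, any 95 %). For the three-channel panel only the synaptic
combination marginals, the astrocytic marginal and the overall occupancy are
pinned by the published numbers; the remaining cells of the Boolean lattice
are filled by allocating astrocytic presence proportionally across the
synaptic categories — the maximally uninformative completion consistent
with the constraints.

What the generator does **not** emulate: irregular (non-circular) soma
contours, spatially varying WFA brightness, bleed-through between channels,
z-dimension effects, photobleaching, and correlated (structured) noise.
Passing the recovery benchmarks therefore demonstrates correctness of the
measurement chain under the stated noise model, not robustness to every
property of real micrographs; the contour is taken as given in both worlds
(no automatic soma segmentation, matching the manual tracing workflow).

## Benchmark problem sizes

The recovery benchmarks use 40 nets per cohort (~25 holes each, ≈ 1000
holes, SNR 10), matching the per-figure cohort size of the source data; at
this size the binomial sampling sd of a cohort percentage is ≈ 1.6 points,
well inside the ±5-point acceptance band. Detection-oracle checks run 1000
random profiles up to 4096 samples; maxima-oracle checks use 24–32 px
images where the exhaustive saddle search is exact.

## Known limitations

- Hole widths are reported as arc widths at the selected threshold, which
  for the synthetic trough shape exceed the nominal (design) widths by
  roughly one PSF width per side; counts and occupancy are unaffected.
- The prominence-based occupancy call assumes a single dominant bump per
  channel per hole; two same-channel bumps in one hole are counted once.
- `find_maxima` is a Python union-find; it is exact but not optimised for
  very large images (fine up to ~10⁶ pixels).
- ABF files are not read; sweeps are exchanged as CSV or plain-text ATF.
- Group summaries stop at mean ± sd with per-cell values retained;
  hypothesis testing is deliberately delegated to external statistics tools.
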