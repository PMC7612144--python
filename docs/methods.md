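# Methods

This note documents the models and procedures implemented in `cmquant`,
the parameters that matter, the design decisions taken where the procedure
left room, and what the synthetic-data generators do and do not emulate.

## Two-channel segmentation and colocalization

The question the imaging pipeline answers is how much of a punctate enzyme
signal (VASH2, the tubulin carboxypeptidase subunit) sits on the polymerized
microtubule network (TUBULIN channel) of a cardiomyocyte, from two-channel
STED images at ~20 nm pixel size.

**Dynamic thresholding.** Each channel is treated as an HSV rendering. With
a grayscale display LUT the hue and saturation planes are constant, so the
hue window [0, 180] and saturation window [0, 43] pass every pixel and
classification reduces to the Value plane, which is the channel intensity
rescaled from its bit-depth range to [0, 255]. The background-adjusted mean
`k` is the mean Value over non-background pixels; "non-background" is taken
as Value > 0, the only reading that does not depend circularly on the
thresholds themselves. A pixel is signal iff its Value lies in
[k + 30, 220] (inclusive at both ends). The upper bound deliberately
excludes saturated pixels. All-zero images degrade to k = 0 with a warning.

**Adaptive denoising.** The binary mask is smoothed with a normalized,
truncated 2-D Gaussian kernel and re-binarized at 0.5. The filamentous
channel uses a 5x5 kernel when k >= 35 and 3x3 otherwise; punctate channels
(VASH2, MAP4) always use 3x3. Only kernel sizes are specified by the
procedure, so the width follows the standard size-to-sigma convention
`sigma = 0.3*((size-1)/2 - 1) + 0.8` (0.8 px for 3x3, 1.1 px for 5x5).
Borders are handled by edge-inclusive reflection. The operation order
(threshold, then denoise the mask) follows the procedure's stated sequence;
a config switch `denoise_before_threshold` offers the alternative reading
(smooth the Value plane, then threshold).

**Metrics.** Within the cell ROI: `v` and `t` are the VASH2 and TUBULIN
signal-pixel counts, `o = |VASH2 ∩ TUBULIN|` the overlap count, the
on-microtubule fraction is `o/v` and the off fraction `(v - o)/v` (the
complement; the two always sum to 1 when v > 0, and are NaN when v = 0).
The PCC is the Pearson correlation of the two *denoised intensity* images
over all ROI pixels (signal-only pixels via config); it shares its
numerical kernel with the statistics module. Because the two channels are
denoised with their channel-specific kernels, identical inputs yield a PCC
of exactly 1 only when both channels select the same kernel (k < 35). MFI
is the mean raw VASH2 intensity over the ROI.

## Puncta quantification

MAP4 oligomer puncta are connected components (8-connectivity) of the
punctate channel's signal mask. A component's diameter is the
equivalent-circle diameter `2*sqrt(area/pi) * pixel_size` (maximum Feret
diameter via config); components are counted only when strictly larger
than 400 nm, and the count is normalized against the ROI area in um².
Thresholding dilates a disc's apparent radius by roughly the PSF tail
(~60-80 nm in diameter at the default contrast), so objects within that
margin of 400 nm can cross the filter; the synthetic recovery study keeps
a margin on both sides of the cut, as any real size-filtered count should.

## Trace kinetics

Cells are field-paced at 2 Hz; stimuli are assumed at multiples of the
period starting at t = 0 (the acquisition system exports no trigger
channel), so beats are fixed one-period windows and trailing partial
windows are discarded. Per-beat metrics are computed on each beat and on
the pointwise average beat.

*Sarcomere.* Resting length is the median over the diastolic baseline
window — by default the **final** 5 % of the beat, i.e. the pre-stimulus
interval of the next stimulus, because contraction begins at the window
start and a leading window would sit on the upstroke. Peak shortening is
`(resting - min SL)/resting * 100`. Velocities are magnitudes of the
central-difference dSL/dt, the departure maximum taken before the peak and
the return maximum after it; time to peak is the time of the minimum
(earliest sample on ties). Optional moving-average smoothing is off by
default.

*Calcium.* The Fura-2 ratio is the pointwise 360/380 nm channel ratio
(zero denominators are an error naming the sample). Basal defaults to the
stimulus-onset sample: the modelled transient decays only asymptotically,
so every trailing window carries a small positive bias while the onset
instant is unbiased (`baseline_at='pre_stimulus'` selects the trailing
window for noisy recordings; beat-averaging is the intended noise control).
Amplitude is peak minus basal; release/reuptake speeds are the extreme
forward differences before/after the peak; elevation time is stimulus to
peak; reuptake time is the linearly interpolated first crossing of
basal + amplitude/2 after the peak (90 %-decay via `decay_frac=0.9`). A
trace with no decay phase reports NaN with a warning.

## Densitometry

Band normalization is two-step and per gel: Norm1 divides the target band
by the loading molecular-weight marker band of the same lane; Norm2 divides
Norm1 by the control-group mean of Norm1 on that gel, so the control group
averages exactly 1 and fold changes compare across gels. The control mean
is per-gel rather than pooled, since the marker band is what carries
comparability across gels. Co-sedimentation dose-response series report
bound intensity normalized to the lowest dose and a Spearman rank
correlation of bound amount vs dose (constant series report 0 — fully tied
ranks carry no trend).

## Statistics

Two procedures are provided: the two-tailed Pearson correlation test via
the t transform `t = r*sqrt(n-2)/sqrt(1-r^2)` with n-2 degrees of freedom,
and the two-tailed unpaired t-test (pooled-variance Student by default,
Welch via flag). P-values are floored at 1e-15 rather than reported as 0.
`correlated_dataset` constructs n-point datasets with an exactly prescribed
r² (residual orthogonal to the regressor and intercept, scaled to the
target variance ratio); with n = 12 the resulting two-tailed P values for
r² = 0.6165 and 0.4529 round to 0.0025 and 0.0165 — the internal
consistency that supports the inferred pooled sample size of 12 (6 per
genotype) for those correlations, which is flagged here because it is an
inference, not a stated value.

## Synthetic-data generators

The generators exist so every pipeline is testable against known truth;
their defaults are fixed study conditions, not tuning knobs.

**STED pair.** Filaments are straight segments with uniform random
orientation/position (length 2-8 um), rendered at a 60 nm structure width:
a 25 nm microtubule plus primary/secondary antibody shell images at
~85 nm apparent FWHM once convolved with the 60 nm-FWHM Gaussian PSF,
matching what immunolabeled microtubules look like under STED. Enzyme
puncta are Gaussian spots of 20 nm physical sigma (PSF-limited, as expected
for a single VASH2/SVBP complex) at 1.5x filament peak intensity. On/off
assignment is deterministic — exactly `round(n_puncta * true_frac_on)`
puncta are placed on filament centerlines (length-weighted), the rest
uniformly at least 200 nm from any centerline — so the attached truth
fraction is noise-free. Acquisition applies the PSF, Poisson photon noise
(`photon_scale` = 200 mean photons at unit intensity), Gaussian read noise
(sd 2 photons) and a fixed digital gain mapping unit intensity to about
two-thirds of the 16-bit range. Curvature, depletion-beam physics, drift
and multi-frame effects are deliberately absent: passing recovery tests
shows the estimator is unbiased under this geometry and noise model, not
that it survives scanner artifacts or dense crossing networks.

The default field (512 px at 20 nm; 12 filaments; 80 puncta) was chosen so
filament occupancy is sparse enough that chance overlap of off-filament
puncta is negligible; under these conditions the pixel-overlap estimator
`o/v` recovers the true on-fraction with mean absolute error well below
0.05 at fractions 0.2-0.8. The estimator's residual negative bias grows
with the true fraction because each on-punctum loses the part of its
thresholded disc that overhangs the microtubule band.

**Puncta fields.** Discs of known diameter — detectable sizes uniform in
480-800 nm, sub-threshold distractors in 200-300 nm (kept below ~360 nm so
PSF dilation cannot push them over the 400 nm cut) — placed without
overlap, then acquired like the STED channels.

**Traces.** One beat of sarcomere shortening is
`SL(t) = baseline - amplitude*sin²(pi*t/T_c)` on [0, T_c], baseline
elsewhere (defaults 1.80 um, 0.18 um, 0.30 s at 1 kHz sampling; additive
Gaussian noise). Ground truth is closed-form: shortening
`amplitude/baseline*100 %`, time to peak `T_c/2`, peak speeds
`amplitude*pi/T_c`. The calcium ratio per beat is
`R(t) = basal + amplitude*(1-exp(-t/tau_rise))*exp(-t/tau_decay)`
(defaults 1.0, 0.5, 30 ms, 150 ms); the 380 nm channel is constant and the
360 nm channel is `R(t)*F380`, so the recomputed ratio reproduces the model
exactly. Calcium ground truth (actual peak amplitude, peak time, 50 %-decay
time, extreme slopes) is computed numerically on a 100x-oversampled
noiseless grid, because the parameter `amplitude` multiplies a product
whose maximum is below 1. No beat-to-beat alternans, baseline drift or
pacing artifacts are simulated.

**Gels.** Control bands around `control_mean`, treated bands around
`control_mean * effect_multiplier` (default 2x), a shared positive marker
column, all with multiplicative noise of the stated CV (default 15 %);
with zero CV the treated Norm2 equals the effect multiplier exactly.

**Competition.** A 1-D lattice (2000 sites) random-sequential-adsorption
model: competitor molecules (footprint 4 sites, echoing the four
microtubule-binding repeats of 4R-MAP4) adsorb first at each dose, then a
fixed amount of enzyme (footprint 2) binds the remaining free stretches.
Doses map to binding attempts via `molecules_per_unit`
(default `n_sites/(4*map4_footprint)`), scaled so the 0-4 dose range spans
no competition to substantial occlusion. One uniform placement attempt per
molecule; collisions leave the molecule unbound. Expected bound enzyme is
non-increasing in competitor dose by a coupling argument; the simulation is
a caricature of binding-site occlusion, not a thermodynamic binding model
(no off-rates, no cooperativity, no taxol effects).

## Numerical choices and degenerate inputs

Inclusive threshold bounds (ties at k+30 and 220 are signal); 0-based
row-major coordinates with the origin top-left; earliest-index tie-breaks
for peak times; NaN-with-warning for undefined ratios (no VASH2 pixels, no
decay phase) but hard errors for malformed inputs (empty ROI, zero marker
density, non-binary masks, mismatched grids, traces shorter than one
period). Runs are deterministic given inputs, config and seed; reports
carry a config hash so each metric row is traceable to exact parameter
values.

## Problem sizes

The test suite and the acceptance script use 512-px fields (50 per
condition for colocalization recovery, 30 for puncta recovery), 10 s traces
at 1 kHz, 100 competition replicates and 10,000 null replicates for type-I
calibration — sizes at which the Monte-Carlo standard errors are an order
of magnitude below the tolerances being checked.

## Known limitations

Straight-filament geometry understates occlusion and crossing density of a
real cardiomyocyte microtubule network; the HSV pathway assumes grayscale
or near-grayscale channel renderings (strongly saturated composite
renderings would interact with the s <= 43 window); puncta detection
operates on the same signal mask as colocalization, an interpretation of an
ImageJ workflow whose thresholding was not specified; the off-microtubule
fraction implements the complement `(v-o)/v` for the printed but
dimensionally inconsistent `(1-o)/v`; beat segmentation assumes strict
pacing capture (no arrhythmic-beat rejection).
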