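# Methods

This note documents the models implemented in cestkit, the numerical
choices behind them, what the synthetic phantoms do and do not emulate,
and the package's known limitations.

## Signal model and conventions

Offsets are stored in ppm relative to the nominal water frequency, with
positive ppm downfield (amide at +3.5 ppm). Frames with |offset| ≥ 20 ppm
(configurable `m0_threshold_ppm`) are treated as unsaturated M0
references; multiple M0 frames are averaged pixelwise before division.
Images are row-major with the row index increasing downward, matching
radiological display of cardiac short-axis slices after the orientation
stage. The gyromagnetic constant used throughout is
γ/2π = 42.577 MHz/T, so ω₁ [rad/s] = 2π · 42.577 · B₁ [µT]; B1 inputs
are in microtesla everywhere.

## Bloch-McConnell propagator

Pools exchange with free water by two-site first-order kinetics
(solute→water rate k_b, water→solute k_b·f_b, equilibrium sizes 1 and
f_b); solute–solute exchange is not modeled, and at most four pools are
supported. Under continuous-wave irradiation the coupled system is
linear time-invariant, so each saturation or recovery block is
propagated exactly by `expm` of the augmented homogeneous
(3N+1)×(3N+1) matrix — no time discretization error. Only CW blocks are
supported; shaped or pulsed saturation is out of scope.

Trajectory simulation carries magnetization across schedule entries
(no full-relaxation assumption). The readout is modeled as an
instantaneous sample sin(θ)·Mz_water followed by Mz → Mz·cos(θ) on every
pool with transverse spoiling — a single-shot EPI approximation. The
true readout history of a specific sequence is not reproduced; this is a
deliberate simplification, and the readout model is configurable
(`spoil`, flip angle per entry) and recorded in the schedule.

## Two-step Lorentzian fitting

Step 0 fits water + semisolid MT (model Z = 1 − L_w − L_mt) over all
offsets by trust-region bounded least squares (tolerances 1e-8, max 400
evaluations); the fitted water center is the B0 shift and is subtracted
from the axis. Step 0 deliberately uses all points — the exclusion band
applies only to the refit. Step 1 refits water + MT on the corrected
axis excluding offsets with 1.4 ≤ |Δω| ≤ 4 ppm. Step 2 computes the
Lorentzian difference (reference fit minus data, CEST peaks positive)
over all offsets and fits the requested solute pools to it.

Default pool table (center / FWHM-init / amplitude bounds): water
(0 ppm, 1.4, A ∈ [0.02, 1]); MT (−2.5 ppm, 25, A ∈ [0, 0.4], center
constrained to ±0.5 ppm and FWHM to [15, 100] — the broad MT line is
otherwise degenerate with solute tails on a ±6 ppm axis and tightening
its center to literature values removes most of the amide bias); amide
(+3.5, 1.0); creatine/amine (+2.0, 1.0); hydroxyl (+1.0, 1.0); rNOE
(−3.5, 3.0). All entries are editable through `FitConfig` because
bounded Lorentzian fitting is sensitive to these choices.

Known bias: even noiseless, the recovered amide amplitude sits ~5–10%
below truth because the reference fit absorbs part of the solute tails
lying outside the exclusion band. This is intrinsic to the two-step
scheme; relative contrasts between tissues are preserved.

## Field mapping

WASSR spectra are cubic-spline interpolated onto exactly 1000 uniform
points before a single-Lorentzian fit with a free baseline in
[0.8, 1.2] (whether the baseline should be fixed at 1 was an open
choice; free is implemented and logged). The double-angle map marks
pixels invalid when |M₂θ/2Mθ| > 1 or Mθ is below a noise floor
(default 5× background sd when supplied). B1 maps acquired at lower
resolution are matched to the reference image with bicubic spline
interpolation; no coregistration is attempted — maps are assumed
aligned. T1 fitting uses saturation recovery with bounds T1 ∈
[1 ms, 10·max(TR)] and requires ≥ 4 TRs spanning a real recovery range.

## QUESP

The closed-form CW MTRasym expression is used for fitting at any
saturation time; the MTR_Rex and omega-plot routes additionally assume
t_p ≫ T1a and full inter-readout relaxation, and
`steady_state_warning` flags acquisitions violating either (threshold
5 × T1a). The omega plot regresses 1/MTR_Rex on 1/ω₁²; pixels with
non-positive slope or intercept are invalid. R1a comes from a pixelwise
T1 map when available, else a scalar T1; the initial magnetization Zi
defaults to 1 (overridable). Fit bounds default to f_b ∈ [1e-6, 0.05],
k_b ∈ [10, 2e4] s⁻¹, init (1e-3, 1000).

The closed form agrees with the full simulator to within 10% only in
the dilute, low-spillover regime — in practice ω₁ small against the
solute shift (e.g. B₁ ≤ 2 µT at 3.5 ppm, ≤ 4 µT at 5 ppm, at 7T). At
higher ratios the analytic expression overestimates MTRasym by tens of
percent, which is a property of the approximation, not of the fit.

## Fingerprinting

Dictionaries enumerate (f_b, k_b, R1a, R2a) lexicographically in that
order; rows are L2-normalized and matching uses cosine similarity, so
the reported dot product is bounded in [0, 1] for non-negative signals
and matching is invariant to positive scaling of the measurement. Ties
break to the lowest row index. The grid cap defaults to 2e6 entries.
Only one solute pool's (f_b, k_b) varies per dictionary by default,
mirroring single-metabolite phantom studies. Concentration conversion
uses a 111 M water-proton pool (55.5 M × 2 protons):
c [mM] = f_b · 111000 / n_protons.

A caveat measured on synthetic data: f_b and k_b are partially
degenerate when the schedule varies saturation power weakly; a ~30-image
schedule with B₁ spread over 0–6 µT resolves them to within one grid
step in ≥ 95% of SNR-50 trials, while short schedules do not.

## Preprocessing

Motion binning sums each acquisition segment's projections, takes a
centered moving average (default window 5 segments) and flags segments
whose sum falls below (moving average − n_sigma·sd), with the standard
deviation taken globally over the moving-average series (a windowed sd
was the alternative; global is implemented and flagged here). To keep
quantified contrasts comparable across offsets, the same number of
segments is discarded everywhere: the largest flagged count at any
offset is removed per offset, dropping the lowest-sum segments.
Retained projections are never altered — membership only. Binned
projections can be exported for external gridding reconstruction; no
NUFFT is included.

PCA denoising is global (all pixels, not tissue-wise): the pixels ×
offsets matrix is centered by the mean spectrum, the truncation rank
minimizes the empirical indicator function IND(n) = RE(n)/(c−n)² with
RE(n) = √(Σ_{j>n} λ_j / (r(c−n))), and spectra are rebuilt from the
leading components. Exactly low-rank data short-circuit to the true
rank when the residual reaches the numerical floor; constant data
return unchanged with rank 0.

Thermal drift is modeled as one global multiplicative factor linear in
acquisition time, least-squares fitted to the reference-frame means and
divided out per frame; richer drift models were considered out of
scope and the minimal model is recorded in the manifest.

## LV segmentation

The LV mask is the epicardial polygon minus the endocardial polygon
(even-odd fill, pixel centers strictly inside). All coordinates are
recentered on the mask centroid; per-pixel angles come from atan2 in a
y-up display frame; the frame is rotated so the inferior insertion
point sits at 0° with angles increasing toward the anterior point
along the arc of span < 180° (the anatomically septal side; an
override exists for atypical geometries). The septum splits into two
equal-angle halves and the free wall into four equal-angle quarters;
equal angle rather than equal mid-wall arc length was an open choice.
Sectors are half-open [start, end) so boundary pixels are deterministic.
The six masks always partition the LV mask exactly.

## Pixel filtering and display

The filter chain is ordered κ → B0 → MT: discard |κ − mean| >
kappa_sigma · sample-sd (statistics over the dataset's valid pixels —
one animal per bundle; multi-animal pooling is done by concatenating
per-dataset surviving-pixel tables), then |B0| > 0.25 ppm, then MT
amplitude < 0.02 (all thresholds configurable). Per-step survivor
counts go into the manifest. Display clipping uses linear-interpolation
percentiles and clips (never discards) values outside the range.

## Synthetic phantoms

The generator emulates the study conditions end to end: a 300.33 MHz
(7T) proton frequency, 64×64 single-slice matrices, a cardiac
short-axis annulus (outer radius 20 px, inner 12 px, insertion points
at 180°/270°, homogeneous amide amplitude 0.05 or six distinct-sector
amplitudes), creatine-like vial layouts for QUESP/fingerprinting,
WASSR dips of width 0.35 ppm, double-angle pairs from
S(θ) = sin(κθ)·M0, variable-TR recovery series, and analytic annulus
chord-profile projections with attenuation + shift corruption standing
in for respiratory motion. Z-spectra come from Lorentzian sums (fast
path) or the Bloch-McConnell propagator (physics path). Noise is
Gaussian on the normalized signal (sd 0.002–0.005 in the shipped
conditions); Rician noise, coil shading, realistic anatomy, k-space
physics, and motion beyond sinogram-level corruption are *not*
emulated — so passing tests demonstrate correctness of the estimators
under the stated models, not robustness to every artifact of real
scanner data.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path: 61-offset spectra, 64×64 matrices (~900-pixel myocardium),
~100-row dictionaries with 31-entry schedules, and 50–100 Monte-Carlo
repetitions per property.

## Limitations

Single-slice 2D only; CW saturation only; no NUFFT reconstruction; no
DICOM; the ParaVision key map targets one dialect and fails loudly on
others; QUEST (varied saturation time) fitting and pulsed-saturation
corrections are not implemented; MT is a Lorentzian line, not a
super-Lorentzian.
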