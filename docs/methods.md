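# Methods

## Forward optical model

Light transport is modelled with the steady-state diffusion approximation
for a homogeneous semi-infinite medium with an extrapolated boundary. For a
pencil source and a detector at separation ρ on the surface,

    R(ρ) = (1/4π) [ z₀ (µ_eff + 1/r₁) e^(−µ_eff r₁) / r₁²
                  + (z₀ + 2 z_b)(µ_eff + 1/r₂) e^(−µ_eff r₂) / r₂² ]

with z₀ = 1/(µa + µs′), D = 1/(3(µa + µs′)), µ_eff = √(3 µa (µa + µs′)),
z_b = 2AD, r₁ = √(ρ² + z₀²), r₂ = √(ρ² + (z₀ + 2 z_b)²). A is the internal
reflection parameter (default 2.95, tissue–air with n ≈ 1.4; A = 1 for a
matched boundary). The absolute scale of R is irrelevant downstream: all
difference-based quantities are invariant to constant channel gains.
Assumptions: homogeneous bulk tissue (no layering, no vessel-resolved
geometry), scattering-dominated transport (a warning is raised if
µa/µs′ > 0.1), continuous-wave operation only. The test suite verifies the
closed form against an independent transcription (10⁻¹⁰ relative) and a
10⁵-photon Monte-Carlo random walk (agreement within sampling error,
observed ≈ 2 % at 25–32 mm).

Chromophore absorption uses decadic molar extinction coefficients of HbO₂
and Hb at 670/780/808/850 nm, shipped as a CSV resource (values from the
standard compiled hemoglobin spectra, in cm⁻¹/M, converted to mm⁻¹/mM on
load), with the ln(10) factor applied explicitly and a small non-hemoglobin
background µa per wavelength. The reduced-scattering prior is a Mie power
law µs′(λ) = 1.0·(λ/800 nm)^(−1.2) mm⁻¹.

The differential pathlength factor DPF(λ, ρ) = (1/ρ)·∂(−ln R)/∂µa is
evaluated by complex-step differentiation of the closed form (step 10⁻³⁰),
i.e. the analytic derivative to machine precision with no subtractive
cancellation; tests cross-check it against central finite differences.

## Synthetic cohort

The generator emulates the study design: 20 subjects, four patch locations
(left/right radial, left/right carotid), three trials each, 2.24 Hz
sampling, and the 150-s protocol of five contiguous 30-s segments (normal
breathing, ~5 s inhalation + ~25 s breath hold, normal, deep breathing,
normal), on a half-open [start, end) time axis.

Per location the latent truth is built from interpretable parameters:

| parameter | meaning | default / population source |
|---|---|---|
| baseline HbT₀ | absolute total hemoglobin | 60 µM (N(60, 5) across subjects) |
| baseline StO₂₀ | absolute saturation | 70 % (N(70, 3)) |
| BH rise (HbT, StO₂) | peak % change during breath hold | published per-location means ± SD, signed normal |
| DB pk-pk (HbT µM, StO₂ %) | oscillation amplitude | published per-location means ± SD, moment-matched lognormal |
| DB oscillation time (StO₂, HbT) | adjacent-extremum interval (half-period) | published per-location means ± SD, lognormal, floored at 1 s |
| HbT response delay | chemoreflex lag of HbT behind StO₂ | lognormal(1.5 s, 0.5 s), capped at 5 s |

Waveform shapes: the breath-hold response is a smoothstep ramp starting
after the inhalation lead and peaking at hold end, with exponential recovery
(τ = 8 s); deep-breathing responses are sinusoids (StO₂ starting at segment
onset, HbT delayed and at twice the oscillation time, i.e. half the
frequency) with 10 % CV per-cycle amplitude jitter and an exponential
ring-down when the exercise stops; normal segments carry low-pass Gaussian
physiological fluctuation (σ = 0.15 µM HbT, 0.05 % StO₂, 2 s correlation
time). HbT and StO₂ are generated directly and HbO₂/Hb derived, so
HbT = HbO₂ + Hb holds exactly. `true_features` stores the generating
parameters themselves, not re-measured values.

Distribution choices: strictly positive amplitudes and times use lognormals
moment-matched to the published mean/SD, so positivity and exact first/second
moments hold simultaneously (sample means converge to the published means —
tested at n = 200 within 3 SE). Breath-hold % changes are left signed
(plain normals): their published SDs exceed their means (e.g. 1.2 ± 3.2 %),
and the underlying physiology does not force a rise in StO₂, so truncation
or lognormal shapes would distort both the mean and the phenomenology. The
right-side breath-hold and HbT parameters, which the source study reports
only in an appendix not available here, mirror the corresponding left-side
values. Between-location correlation of each parameter family is 0.5 by
default (a Gaussian copula), reflecting shared systemic physiology;
demographics (65 % assigned female at birth, 70 % nonwhite, 40/40/20 skin
tones, vitals 115 ± 11 / 71 ± 7 mmHg, 72 ± 11 bpm) and carotid anatomy
(typical adult bulb depth/diameter and ICA/ECA diameters) are carried as
metadata with no effect on hemodynamics by default, matching the null
demographic effects the pipeline is expected to report.

Noise model (fractions of clean intensity): multiplicative photon noise
σ = 10⁻³ per sample, slow per-channel drift (linear + one slow sinusoid,
σ = 2·10⁻³ per trial), and Poisson-count motion artifacts (0.3 events per
trial, ~2 % amplitude, 1.5 s raised-cosine bumps, common to all channels of
a patch with random coupling). These levels put the deep-breathing HbT SNR
of typical trials well above the 1 dB selection threshold while making
motion-corrupted trials measurably noisier, which is what the trial
selection stage exploits.

What the generator does **not** emulate: cardiac pulsation, respiratory
mechanics, skin-tone-dependent optical coupling, layered tissue above the
carotid bulb, and inter-channel crosstalk. Passing round-trip tests
therefore demonstrates internal consistency of the forward/inverse pair and
correctness of the statistical machinery under the published summary
statistics — not device-level parity with any particular hardware, whose
proprietary reconstruction may differ.

## Reconstruction

ΔOD(λ, ρ, t) = ln(I_ref / I(t)) with I_ref the mean over the reference
window (first 20 s, the protocol baseline). Non-positive intensities are
flagged and excluded; a trial with > 20 % flagged samples is marked
low-quality (still emitted). Concentration changes are solved per sample by
weighted least squares pooling both detector distances,
ΔOD/(DPF·ρ) = ln10·(ε_HbO₂ ΔC_HbO₂ + ε_Hb ΔC_Hb), with DPF evaluated at the
baseline optical properties and held fixed per trial (linearized modified
Beer–Lambert, appropriate for the ≤ few-% µa excursions generated) and
channel weights ∝ 1/Var(ΔOD) estimated from the reference window (uniform
when the window is noiseless).

Absolute baseline: CW intensities are relative, but StO₂ is reported in
absolute percent, so baseline optical properties are estimated from the
spatial decay of the gain-corrected reference intensities across the two
distances. Rather than the asymptotic ln(ρ²I)-slope formula — which with
only two distances at 25/32 mm biases µa by ~7 %, too coarse for the 3 %
round-trip requirement — the measured ratio R(ρ₁)/R(ρ₂) is inverted against
the exact closed form by Brent root-finding in µa per wavelength (scattering
prior fixed), and the absolute µa spectrum (minus background) is unmixed
into HbO₂₀/Hb₀. Degenerate geometry, negative chromophore absorption, or an
unphysical saturation trigger a fallback to the configured default baseline
(60 µM, 70 %) with a warning flag. This step assumes calibrated channel
gains (the recording's `gain` field); an unrecorded gain error biases the
absolute baseline, though all Δ-quantities remain gain-invariant. A
mis-specified scattering prior rescales DPF and hence Δ-amplitudes (≈ −16 %
for +20 % µs′) while leaving waveform shape and all timing features intact —
a known limitation of any single-prior CW method.

StO₂(t) = 100·(HbO₂₀ + ΔHbO₂)/(HbT₀ + ΔHbT), clamped to [0, 100] with the
clamp count retained as a quality signal. Optional linear detrending
(fitted over the first and last normal segments) is off by default.

## Feature extraction

Baseline = mean over the first 20 s. Breath-hold maximum % change =
100·(max over the BH segment − baseline)/baseline, computed on absolute HbT
(baseline offset + Δ) and on StO₂.

Extrema for the deep-breathing features are located on a 3-sample moving
average with a prominence floor of 0.2 × the segment IQR and enforced
alternation (keeping the more extreme of same-kind neighbors); extremum
*values* are read from the raw samples (refined within ±1 sample) so the
smoothing does not attenuate peak-to-peak amplitudes. Because
`scipy.signal.find_peaks` cannot assign full prominence near segment edges,
a leading/trailing extremum is recovered when the head/tail contains an
interior turning point that is prominent (full floor toward the interior,
half the floor toward the truncated boundary side); a segment cut mid-rise
never fakes one because the boundary sample itself is not eligible.
Oscillation time = mean interval between adjacent alternating extrema (a
half-period for a sinusoid) — the generator parameterizes exactly this
quantity and both modules share the convention constant, so agreement is
structural. Peak-to-peak amplitude = mean |peak − adjacent trough|.

Trial selection: the deep-breathing HbT segment is mean-removed, Hann
windowed, and its periodogram's largest non-DC-lobe bin taken as the
fundamental (±2 bins as the main lobe); the first five harmonics are
excluded and the remaining band power, rescaled for excluded bins, is
noise — SNR = 10·log₁₀(P_signal/P_noise), capped at 100 dB for a clean
tone. A Hann window is used instead of linear detrending because removing a
fitted line from a finite sinusoid leaks signal power across the whole
band. The estimate is flagged unreliable when fewer than two fundamental
periods fit the segment or the spectrum is dominated by an unresolvable
near-DC component. The least-noisy trial is analyzed; if all trials at a
location fall below the threshold — interpreted as 1 dB, the unit of the
SNR estimator — the location is excluded for that subject. Ties go to the
earliest trial. The 2-SD outlier screen (sample SD, single pass, per
parameter × location across subjects) is applied exactly once.

## Equivalence statistics

For each of the six parameters and four artery pairs, subjects with both
locations present enter a paired Wilcoxon TOST: with d = x − y and margin
Δ > 0, the lower test applies a one-sided signed-rank test to d + Δ
(alternative greater) and the upper to d − Δ (alternative less);
p_TOST = max of the two, Bonferroni-adjusted by m = 4 (the artery pairs per
parameter), equivalence declared at p_adj ≤ 0.05. Signed-rank p-values use
the exact null distribution for tie-free samples with n ≤ 25 (cached via
the standard generating-polynomial recursion) and otherwise the normal
approximation with tie-corrected variance and ±0.5 continuity correction —
the same policy as the R implementation this battery mirrors. The exact
path matters: exhaustive analysis of the approximation shows worst-case
error 0.024 vs the exact null at n = 4, while the exact path is, by
construction, identical to sign-enumeration. Zeros are dropped (Wilcoxon
convention); an all-identical difference vector takes a degenerate path
decided by its position relative to the margins.

The location estimate is the Hodges–Lehmann pseudo-median (median of the
n(n+1)/2 Walsh averages of d) with a 95 % CI from signed-rank inversion of
the ordered Walsh averages (exact null quantiles for n ≤ 50, normal
approximation above). The shipped margins are the published thresholds
(HbT pk-pk 1.2 µM; StO₂ pk-pk 0.5 %; HbT %change 3.7 %; StO₂ %change
3.2 %; HbT osc time 2.1 s; StO₂ osc time 1.4 s) and are deliberately
immutable defaults; `suggest_threshold` exposes an SD-based rule (max of
the arm SDs, or the SD of differences) for new data, clearly documented as
not reproducing every published value.

Ancillary screens: Kendall τ-b (scipy, cross-checked against brute-force
pair counting) of each parameter × location against vitals and ipsilateral
carotid anatomy, |τ| > 0.2 marginal and > 0.4 moderate, reported at
Bonferroni-adjusted p ≤ 0.05; Kruskal–Wallis with η² = (H − k + 1)/(n − k),
floored at 0, for sex/race/skin-tone effects. The TOST sample-size
calculator iterates the parametric paired-TOST power (noncentral-t, the
convention of the standard power packages) to the smallest n meeting the
target; tests verify it against a 100 000-replicate Monte-Carlo power curve.

## Numerical and design choices

* Single seeded `numpy.random.Generator` per cohort; fixed seed ⇒
  byte-identical outputs (hash-verified in tests).
* Time in seconds from trial start; half-open segment intervals; units in
  column-name suffixes (`_uM`, `_pct`, `_s`, `_mm`, `_nm`, `_db`).
* Problem sizes used by the verification suites: 500 statistics-stage
  replicates and 20 full end-to-end replicates for the equivalence
  reproduction; 10 000 replicates for the TOST boundary-size calibration;
  10⁵ photons for the Monte-Carlo forward check — sizes chosen so each
  estimate's sampling error is several times smaller than the effect it
  checks.
* Oscillation-time convention: "time from one peak/trough to the next" is
  read as the adjacent-alternating-extremum interval (half-period). The
  published values (HbT ≈ 7 s vs StO₂ ≈ 3.3–3.7 s at twice the frequency)
  are consistent with either the half- or full-period reading; the package
  uses one convention end-to-end, so equivalence conclusions are unaffected.

## Known limitations

* Self-consistency, not device parity: the hardware's proprietary
  reconstruction is not published; this package targets a canonical CW
  diffusion forward/inverse pair that is exact in round trip.
* Absolute HbT₀/StO₂₀ depend on the scattering prior and calibrated gains;
  only Δ-based and timing features are robust to both.
* The homogeneous semi-infinite geometry ignores the layered neck anatomy;
  absolute baselines over the carotid should be read as effective bulk
  values.
* Equivalence power statements inherit the bivariate-normal /
  0.5-correlation assumptions of the cohort generator wherever the source
  study does not constrain them.
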