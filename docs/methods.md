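# Methods

## Signal-processing chain

Every recording passes the same centralised chain before any endpoint is
computed:

1. **DC removal** — subtraction of the whole-recording mean.  A high-pass
   filter would also work, but all exported spectra start above 1 Hz, so
   mean subtraction is sufficient and exactly idempotent.
2. **Resampling to 100 Hz** — linear interpolation onto the common
   100 Hz grid (dialect switch `preprocess.interp`: `linear` | `polyphase`,
   the latter a band-limited `resample_poly` alternative for sensitivity
   analyses).  Native rates below 100 Hz are rejected.  Note that linear
   interpolation from rates that are not integer multiples of 100 Hz
   attenuates the upper bands; this is a genuine property of the
   harmonised chain, and one reason gamma-band endpoints can still carry
   a laboratory signature after centralised processing.
3. **Low-pass at 49 Hz** — a 201-tap Hamming-windowed sinc FIR applied
   forward-backward (zero phase).  The single-pass design has half
   amplitude (−6 dB) at the cutoff and is flat within ±0.5 dB through
   47 Hz; 49 Hz rejects both 50 Hz and 60 Hz mains after resampling.
4. **Artifact rejection** — the RMS of consecutive 1 s windows is
   summarised by its median and MAD (scaled by the usual 1.4826
   normal-consistency factor, so the multiplier is in robust-sigma
   units); windows with RMS above `median + k·MAD` (default `k = 6`) are
   flagged, padded by 0.5 s and merged.  The threshold is data-relative:
   scaling the whole recording by any gain leaves the mask unchanged.
   If the MAD is zero (perfectly homogeneous RMS, e.g. a pure tone) only
   windows above 10× the median are flagged, so clean stationary signals
   yield an empty mask.  The rule is fully deterministic; there is no
   manual-confirmation step, which is exactly the kind of per-site
   freedom the pipeline is meant to remove.
5. **Analysis windows** — symbolic windows resolve against the dose
   event: "pre" is 30–60 min before the injection, "post" 30–60 min
   after.  Clean spans are the complement of the artifact mask within
   the window; spans shorter than one Welch segment (10.24 s) are
   dropped.  Recordings with more than `max_masked_fraction` (default
   50%) of a needed window masked are excluded and listed with reasons.

## Spectra and endpoints

Spectra are Welch periodograms with Hamming windows of 1024 samples
(512 frequency values at 100 Hz, bin width 100/1024 ≈ 0.0977 Hz) and 50%
overlap.  Segments never bridge artifact gaps: each clean span is tiled
independently and trailing partial segments are dropped.  The averaged
periodogram is rescaled so that the **sum** of all spectrum values equals
the mean squared value of the analysed samples; on this convention band
power is literally a sum of bins, so a hardware gain g multiplies every
raw power by g² and cancels exactly in relative power and in raw-power
percent change.  The export grid is the 481 bins whose centres lie
strictly between 1 and 48 Hz (1.074…47.95 Hz).

Band membership is half-open on bin centres, [low, high), with the last
band closed at 48 Hz — this reconciles "18–32 Hz" with "18–31.9 Hz"
style edge conventions.  Total power sums the bins strictly inside the
total range, default (1, 48) Hz; the alternative (0.5, 48) Hz denominator
used by some sites for relative gamma is supported because the full FFT
grid is retained below 1 Hz (the synthetic signals carry genuine
0.5–1 Hz content, so the dialect is not cosmetic).  The per-epoch dialect
(`epoch_powers`: 10 s epochs, single-segment periodograms, epochs
overlapping the mask skipped; `aggregate_bins`: mean ± SEM per time bin)
mirrors how sites process data locally.

Percent change from baseline is computed within recording on raw band
power by default (`use="relative"` is available for the comparison of
the two conventions); raw-power percent change is invariant to any
constant gain and to most dialect differences, which is why it shows the
smallest laboratory share of all endpoints.

## Statistical models

Per laboratory, a one-way fixed-effects linear model with the test group
as the only factor: group means, pooled residual variance
σ̂ε² = RSS/(n − g), contrast SE = σ̂ε·√(1/n₁ + 1/n₂), t-based two-sided
p-values and 95% confidence limits.  With two groups the contrast equals
the difference of group means.  p-values are reported unadjusted, and the
output says so.

Across laboratories, the linear mixed model with a fixed group effect
and random laboratory and laboratory-by-group intercepts.  REML
estimation profiles the restricted likelihood over the two variance
ratios γb = σb²/σε², γd = σd²/σε² with non-negativity box constraints;
the covariance inverse and determinant use the Woodbury/matrix-
determinant identities on the (labs + cells)-dimensional random-effect
space, so each criterion evaluation is cheap even for hundreds of
observations.  Optimisation is L-BFGS-B with deterministic multi-start
(method-of-moments ratios, the origin, equal ratios) and tolerance 1e-10
on the criterion; ratios below 1e-10 are snapped to the boundary, so
interaction components estimated as exactly zero — a routine outcome in
heterogeneous studies — are reported as 0 and flagged.  On balanced data
with interior optima the estimates coincide with the closed-form
expected-mean-squares (ANOVA) estimator; the test suite asserts this to
1e-6 and also cross-checks variance components and the restricted
log-likelihood against lme4's `lmer` via Rscript.

Mixed-model group contrasts use the GLS estimate at the REML optimum
with Wald normal intervals and p-values.  This is a deliberate,
documented simplification relative to Kenward–Roger or Satterthwaite
degrees of freedom: with the lab counts typical here the normal
approximation is anticonservative for small-lab designs, and the
package's focus is the variance decomposition, not the contrast df.

Variance tables print one column per condition with cells
"estimate (share%)", estimates to 4 decimals and shares to 2; the Total
row is the exact component sum.  Boxplot summaries use linear-interpolation
(type-7) quartiles and 1.5·IQR whiskers clamped to data values.

Endpoints bounded below by zero (total power, relative theta, relative
gamma) are log10-transformed before modelling.  Percent change can be
negative and is analysed untransformed.

## Synthetic studies

The generator exists to make every pipeline claim testable against known
truth; it emulates the *structure* of a multi-site mouse qEEG study, not
mouse physiology in full.

**Waveforms.**  Each recording is a sum of three independent Gaussian
components built by spectral shaping on the FFT grid: a 1/f^α background
(α = 2, flat below 1 Hz, band-limited to 0.5–48 Hz), a theta bump
(Gaussian profile, centre 7 Hz, width 1.2 Hz) and a gamma bump (centre
40 Hz, width 4 Hz).  The three squared scalings solve a 3×3 linear
system so the realised total power (1–48 Hz) and theta/gamma band powers
hit their targets exactly on the grid before any processing; infeasible
targets (background band content exceeding a requested fraction) raise a
configuration error.  Defaults: pre-gain RMS 50 µV, relative theta 0.30,
relative gamma 0.06.  Components carry 0.5–1 Hz content so the
(0.5, 48) Hz total-range dialect differs measurably from (1, 48).

**Laboratory profiles.**  Gain (multiplicative amplitude), native rate,
sensor noise floor (default 1 µV RMS white noise, added after gain),
artifact rate (default 20/h) and amplitude (8× running RMS, biphasic
0.2–1 s transients at Poisson times, positions logged as ground truth),
surgeon quality (scales the structured signal against the noise floor),
and an analysis dialect (total-power range, gamma/theta band edges,
artifact multiplier, epoch length, and the reporting scale — fraction
vs percent — that makes locally analysed relative power differ by
orders of magnitude across sites).

**Biology.**  Subject-level lognormal variation: total power
(log10 SD 0.3), theta fraction (0.05), gamma fraction (0.1); a
session-level power wobble (0.05) and a session-level dose-response
wobble on post-dose gamma (0.05).  In the cross-over phase the subject
traits persist across that animal's dose sessions; washout is modelled
as independence between sessions (no carry-over).  Group effects are
multiplicative on band-power targets; defaults follow the directions
reported for these models — transgenic total power ×0.7 and relative
theta ×1.15; post-dose gamma ×1.05 at the low dose and ×1.4 at
0.2 mg/kg, applied only after the dose event at 3600 s.  The magnitudes
are the package's choices.

**Phase templates** (`localisation.yaml`, `harmonisation.yaml`,
`ringtest.yaml`): localisation draws lab gains with log10 SD 2 (orders
of magnitude, as unharmonised hardware produces) and heterogeneous rates
and dialects; harmonisation uses a common convention and gain log10
SD 0.15; ring-testing is a 6-lab vehicle/0.05/0.2 mg/kg cross-over with
dose annotations and per-lab dialects.  With these defaults the
laboratory share of log10 total power is ≈99% under localisation and
≈50% under harmonisation (biological and residual lab variability
comparable), and on the ring-test the laboratory share of log10 relative
gamma is ≈40–50% centrally versus ≈98% under local dialects, while
percent change shows ≈0% laboratory share under both — the qualitative
pattern multi-site studies report.

**Scale.**  Real studies record 48 h per animal; the templates use
desk-scale durations (600 s for the genotype phases; 7200 s for the
ring-test so the 30–60 min pre/post windows are exact, dose at 3600 s).
The acceptance script runs the templates at full size (5 labs × 2 × 12
and 6 labs × 12 × 3 doses); the test suite uses a 4-lab × 8-animal
ring-test to stay fast.  Everything is deterministic given the design
seed, file-for-file.

**What passing does not show.**  The synthetic signals are stationary
Gaussian mixtures without sleep architecture, circadian theta
modulation, epileptiform events or non-stationary drug kinetics; real
EEG adds those on top.  Tests passing here validate the pipeline's
arithmetic, invariances and estimator behaviour — not that any
particular animal study will replicate.

## Numerical notes and limitations

* EDF files are 16-bit with a symmetric physical range spanning the
  data, so round-trip error is ≤ range/2¹⁵ per sample; the writer
  requires whole-second recordings (1 s data records).  Dose events ride
  as EDF+ annotations ("dose <label>"); a metadata `dose_events` column
  overrides file annotations when pre/post segments arrive as separate
  files.
* Welch mean-square normalisation uses the segmented samples (with
  overlap multiplicity), so the sum-equals-mean-square identity is exact
  by construction on the analysed data.
* Variance-component estimates at 5–20 laboratory levels carry large
  sampling variability (CV ≈ √(2/(L−1)) at best); single-study shares
  should be read with that in mind.  The interaction component is often
  estimated exactly 0 — a boundary phenomenon, flagged in the fit
  object, not a numerical failure.
* Multiple-testing correction is deliberately absent (per-lab p-values
  are reported unadjusted, as stated in the outputs).
* Exclusion thresholds (masked fraction, minimum clean span) live in the
  pipeline configuration, never in stage code.
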