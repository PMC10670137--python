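# Methods

`fdnirs` analyzes frequency-domain multi-distance (FDMD) near-infrared
spectroscopy recordings of the motor cortex around single-pulse TMS probes
delivered before and after theta-burst stimulation (TBS), and ships a
synthetic-session generator so every stage of the analysis can be verified
end to end without human recordings. This note documents the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic data can and cannot establish.

## Stimulation protocol model

A session consists of 3 pre-TBS blocks, one TBS train, and 5 post-TBS
blocks. Each block interleaves 25 real and 25 sham single pulses in seeded
random order with inter-stimulus intervals drawn uniformly from 6–8 s;
blocks are separated by 6–10 s. The TBS train is either continuous (cTBS:
3-pulse 50 Hz bursts every 200 ms for 40 s) or intermittent (iTBS: 2 s
trains of the same bursts every 10 s over 190 s); both deliver exactly 600
pulses. Some protocol descriptions in the source literature disagree on the
inter-block interval (4–10 s vs 6–10 s appear in the same figure caption);
we use 6–10 s, matching the methods text, and expose it as a constant.

The source protocol does not state the gap between the last pre-TBS pulse
and the TBS train, nor between the train and the first post block; both
default to 60 s (configurable), long enough for band-pass transients from
the train epoch to die out before post-TBS probes are analyzed. The first
stimulus falls 30 s into the recording so every segment has a quiet
lead-in.

## Synthetic tissue dynamics

Ground truth is generated directly in concentration space. Baseline
concentrations default to HbO₂ = 42 µM, HHb = 18 µM (total hemoglobin
60 µM at 70 % saturation — ordinary adult-head values). Each stimulus may
add an evoked total-hemoglobin response

    ΔtHb(t) = tHb₀ · (a/100) · g(t − onset),

where `g` is a gamma-density kernel scaled to unit peak, with mode
(peak latency) 3.5 s and standard deviation (dispersion) 1.5 s, so an
amplitude `a` means "the evoked peak is a % of baseline tHb". The kernel is
zero for t < 0 (causal). The evoked change is split 80 % / 20 % between
HbO₂ and HHb, reproducing the measured pattern of blood-volume and HbO₂
increases with near-flat HHb. Default amplitudes are zero everywhere except
real pulses after cTBS, which get a = 14 % — the scale of the group effect
the pipeline is designed to resolve; sham pulses never evoke anything.

Physiological noise rides on tHb as sinusoids with seeded random phase:
cardiac 1.1 Hz at 1 % of baseline, respiratory 0.25 Hz at 0.5 %, Mayer
waves 0.1 Hz at 0.5 %, plus a random-walk drift of 0.01 %/sample. All noise
fields set to zero give a bit-reproducible noise-free session. One session
seed feeds three fixed child streams (schedule, tissue, optics), so adding
draws to one stage never perturbs another.

What the generator does **not** emulate: scalp/skull partial-volume
effects and layered tissue, systemic blood-pressure coupling between the
oscillations and the evoked response, habituation or drift of the evoked
amplitude, subject-to-subject response heterogeneity, and non-Gaussian
instrument noise. Passing tests therefore establish the correctness of the
computation chain under its own model assumptions, not the physiological
validity of any particular recording.

## Forward optical model

At each sample and wavelength the absorption coefficient is
μa = ln 10 · (ε_HbO₂·C_HbO₂ + ε_HHb·C_HHb) with ε in 1/(mM·cm). The default
extinction values (690 nm: 0.276 / 2.052; 830 nm: 0.974 / 0.693) are the
compiled in-vitro hemoglobin spectra widely used in tissue optics, and the
table is fully overridable. Reduced scattering μs′ is constant in time
(8 and 7 cm⁻¹ at 690/830 nm).

The photon-density wave of an intensity-modulated source (110 MHz) decays
with complex attenuation κ = k_r + i·k_i defined by

    k_r² − k_i² = 3 μa (μa + μs′),
    2 k_r k_i   = 3 (μa + μs′) ω / v,

with ω the angular modulation frequency and v = c/1.4 the speed of light in
tissue. Signals are emitted as IAC(r) = A e^(−k_r r)/r², phase(r) = k_i r +
φ₀, and IDC(r) = A_DC e^(−κ₀ r)/r² with κ₀ = √(3 μa (μa+μs′)). Two
deliberate simplifications: the 1/r² geometric factor makes ln(r²·IAC),
ln(r²·IDC) and phase *exactly* linear in distance, so the slope-based
inversion below is exactly testable (real semi-infinite
extrapolated-boundary solutions are only asymptotically linear and are out
of scope); and κ uses 3 μa (μa + μs′), not the μs′ ≫ μa approximation
3 μa μs′, because the closed-form inversion is exact under this form.

Instrument noise is multiplicative Gaussian on the intensities (relative SD
0.5 %) and additive on phase (1 mrad). Motion artifacts arrive as a Poisson
process (0.2/min, 2 s long) and scale each channel by an independent
log-normal factor around ×2 — the per-channel independence is what breaks
the distance linearity and lets the R² gate see them. Every artifact window
is recorded as a ground-truth label; downstream analysis uses the labels by
default and offers MAD-threshold jump detection for unlabeled recordings.

## Inversion

Per sample and wavelength, ordinary least squares of ln(r²·IAC), ln(r²·IDC)
and unwrapped phase against the four separations (2, 2.5, 3, 3.5 cm) gives
slopes S_AC, S_DC, S_phase, intercepts, and R². With a = |S_AC| the closed
forms

    μa  = (ω / 2v) · (a/S_phase − S_phase/a),
    μs′ = (a² − S_phase²) / (3 μa) − μa,

recover the optical properties from the AC/phase slope pair (the DC slope
is computed and reported but not used: amplitude and phase are less
sensitive to ambient light). Two-wavelength μa is then solved for the two
chromophore concentrations through the extinction matrix, and tHb — the
blood-volume proxy — is their exact sum, an identity maintained through
every later stage.

Quality control: a sample is kept only if R² ≥ 0.97 for *both* the
amplitude and the phase fit at *both* wavelengths (the chromophore solve
needs both wavelengths, so a one-wavelength failure invalidates the
sample; the cross-wavelength rule is our choice, the per-fit rule is the
published one). Slopes outside the physical region (S_AC ≥ 0, S_phase ≤ 0,
or |S_AC| ≤ S_phase, which would imply μa ≤ 0) invalidate the sample
rather than raising. The R² of a zero-variance response is defined as 0
(the textbook formula is 0/0); this makes the gate reject flat-line
channels. Regression is strictly per sample with no temporal smoothing.
OLS slope p-values are available in the diagnostics output but are not
used as a gate.

## Signal conditioning

Chromophore series are band-passed 0.02–0.7 Hz with a Hanning windowed-sinc
FIR (1001 taps at 10.4 Hz), applied as a single symmetric convolution with
reflection padding — zero phase by symmetry, so event latencies are
preserved. The kernel is mean-subtracted, making the DC gain exactly zero
while leaving the passband within 0.1 % of unity; measured gains are ≈ 1.00
at 0.1 Hz and < 10⁻⁴ at the 1.1 Hz cardiac line. Invalid samples are
linearly interpolated before convolution and the validity mask is dilated
by half the kernel width around invalid runs, so every output sample a bad
input could have touched is itself marked invalid. tHb is re-derived as the
sum of the filtered chromophores, preserving additivity exactly. Filtering
operates on the chromophore series (inversion first, filter second); the R²
gate acts on the raw optical fits.

Segmentation takes the (0, 6] s window after each stimulus — within the
minimum 6 s inter-stimulus interval, so windows never overlap the next
probe. The value at the sample nearest the onset is subtracted (the
stimulus time is the baseline); a `pre-window` mode averaging the 0.5 s
before onset is provided because single-sample baselines are noise
sensitive. The difference is expressed as percent of the signal's absolute
concentration level, taken as the median of the unfiltered valid samples:
after a 0.02 Hz high-pass the filtered trace is zero-mean, so the
onset-sample value itself carries no absolute scale and cannot be the
denominator. (With ~0.5 % fluctuations the onset sample of the *unfiltered*
series and its median differ by < 1 %, so this choice only stabilizes the
denominator; it does not change what is measured.)

An event is discarded when more than 1/3 of its window samples failed the
raw-data gate, when a labeled (or detected) motion-artifact window overlaps
[onset, onset + 6 s], or when the baseline is unusable (invalid onset
sample, or absolute level below 10⁻³ µM). Summaries are the mean normalized
change over the valid window samples; discard reasons are kept per event so
per-condition accounting can be reported.

## Statistics

Kept event summaries are the unit of analysis, pooled across subjects for
Welch two-sample t-tests (Satterthwaite df; two-sided). Pre-TBS events from
the two paradigm sessions are pooled only if neither the real-vs-real nor
the sham-vs-sham pre-TBS comparison is significant at α = 0.05. The
contrast matrix covers real-vs-sham within each epoch/paradigm, post-cTBS
vs post-iTBS for each modality, and post-vs-pre for each paradigm and
modality, for each of BV, HbO₂ and HHb.

For subjects measured under both paradigms, a linear mixed model
`change ~ condition` (levels pre / cTBS / iTBS, reference pre) with a
Gaussian random intercept per subject is fitted by REML (statsmodels
MixedLM). The cTBS-vs-iTBS contrast is obtained by refitting with the
reference releveled rather than by post-hoc contrast algebra. p-values are
Wald-type with the normal approximation by default; a `conditional-t`
option uses the within-group denominator df (n − groups − contrasts)
familiar from nlme-style software, which matters only at very small sample
sizes. A fit with numerically zero between-subject variance is flagged
singular — it reduces to pooled OLS — and its estimates are still reported.
No multiplicity adjustment is applied anywhere; every table labels its
p-values as unadjusted.

## Verification strategy and problem sizes

The acceptance checks run the *whole* chain (generator → inversion →
conditioning → statistics) at the default study conditions:

- **Exactness**: 1000 random (μa, μs′) forward/inverse round trips must
  agree to ≤ 10⁻⁸ relative; tHb = HbO₂ + HHb must hold exactly on every
  valid sample; a noise-free null session must give every segment mean as
  exactly zero (≤ 10⁻⁹).
- **Calibration**: with all noise sources on and zero evoked amplitude, the
  real-vs-sham post-cTBS Welch test at α = 0.05 must reject in 3–7 % of
  400 independent sessions.
- **Recovery**: 200 replicates of a five-subject crossover cohort with the
  14 % cTBS response; the mixed model's cTBS-vs-pre estimate must fall
  within ±3 SE of the replicate's noise-free estimand in ≥ 95 % of
  replicates, and the iTBS contrast must center on zero. The estimand is
  defined by the pipeline itself (≈ amplitude × window mean of the filtered
  response kernel, ≈ 6.5 % for a 14 % peak, not the 14 % peak): comparing
  each noisy replicate against its own noise-free twin (same seeds, hence
  same schedules) isolates noise-induced error from the deterministic
  window/filter functional.
- **Gates**: constructed fixtures verify that the R² gate discards exactly
  the corrupted samples and the >1/3 rule exactly the constructed events,
  by count.

Problem sizes (400 null sessions, 200 recovery replicates, 1000 round
trips) were chosen so Monte-Carlo standard errors are well inside the
asserted bands while a full run stays in the minutes range.

## Known limitations

- The forward model is deliberately self-consistent with the inversion;
  agreement does not validate either against multi-layer photon transport.
- Subject heterogeneity of the evoked response is not modeled, so the
  random-intercept variance in synthetic cohorts is near zero and the LMM
  is exercised mostly in its singular regime (the non-degenerate regime is
  covered by summary-level simulations in the test suite).
- Artifact detection by MAD thresholding is basic; labeled artifacts are
  the primary mechanism for synthetic data.
- With the default dense stimulus train, the high-pass's undershoot around
  each real response bleeds a small negative offset (≈ −1 %) into the
  interleaved post-cTBS sham segments, so synthetic sham-vs-sham contrasts
  across paradigms can reach significance at large event counts. This is a
  property of event-related band-pass analysis under dense interleaving,
  not a bug in the bookkeeping; it is invisible in the pre epoch and does
  not affect the null-calibration or recovery checks, which compare like
  with like.
- DC-slope-based inversions, absolute phantom calibration, and SNIRF
  ingestion are out of scope.
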