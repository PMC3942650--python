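# Methods

This note documents the models, defaults and numerical choices behind
`ratabr`, in the spirit of a methods appendix: what is simulated, what is
measured, which knobs matter, and what the synthetic validation does and
does not demonstrate about real data.

## 1. ABR waveform model

An averaged ABR trace is modelled as

    v(t) = Σ_k  A_k · b(t; τ_k, w_k)  +  ε(t),      ε(t) ~ N(0, σ²) i.i.d.

where the sum runs over waves k = I…V and `b` is a derivative-of-Gaussian
biphasic bump normalised so that its positive peak sits at latency τ_k, its
negative trough at τ_k + w_k, and its peak-to-peak excursion is exactly
A_k. The closed form is

    b(t) = z·exp(−z²/2) / (2e^{−1/2}),   z = (τ_k + w_k/2 − t) / (w_k/2).

Nothing in the downstream analysis depends on this particular morphology
beyond "positive peak followed by a negative trough"; the derivative of a
Gaussian is simply the smoothest such shape with closed-form extrema, which
lets tests compare recovered peaks/troughs/amplitudes against analytic
values.

**Amplitude.** A_k = base_amplitude_k · a(f) · g(L), with

* base peak-to-peak amplitudes at 80 dB SPL (μV): II 3.5 > I 2.6 > IV 1.9 >
  V 1.3 > III 0.9 — the canonical rat ordering with wave II largest and
  wave III smallest, at magnitudes typical of young-adult rat recordings;
* a(f) ∈ (0, 1] the age-group amplitude factor at stimulus frequency f;
* g(L) the growth function of effective level
  L = intensity − baseline_threshold(f) − threshold_shift(f): zero for
  L ≤ 0, linear in L up to saturation at L = 40 dB. This is the simplest
  monotone input–output function consistent with a descending-series
  protocol; real ABR growth functions are sigmoidal, but only monotonicity
  and the zero below threshold matter to the threshold logic.

**Latency.** τ_k = base_latency_k + slope · (80 − intensity)/10 + delay(f),
with base latencies 1.3, 2.1, 2.9, 3.7, 4.8 ms (waves I–V), slope 0.1 ms
per 10 dB of attenuation, and an age delay per frequency. Width w_k =
0.25 ms for all waves.

**Baseline thresholds** (young group, dB SPL): 45, 45, 40, 40, 35, 35, 30
at 0.5, 1, 2, 4, 8, 16, 32 kHz — the young-group mean audiogram rounded to
the 5 dB acquisition grid (declining from ≈44 dB at 0.5 kHz to ≈31 dB at
32 kHz, low frequencies worse than high, as in young Wistar rats).

**Age-effect defaults.** The study design this emulates reports only the
range endpoints of the group threshold shifts, so the per-frequency
defaults interpolate linearly in log₂(frequency) between them:

| group  | threshold shift (dB) | amplitude factor | latency delay (ms) |
|--------|----------------------|------------------|--------------------|
| young  | 0                    | 1.0              | 0                  |
| middle | 24.38 → 33.75        | 0.75 → 0.55      | 0 → 0.14           |
| old    | 30.63 → 46.25        | 0.50 → 0.15      | 0 → 0.20           |

(low → high frequency). The 0.5 kHz anchors make the arithmetic identities
young + shift = group mean hold exactly (43.75 + 24.38 = 68.13;
43.75 + 30.63 = 74.38). Amplitude factors are a single per-frequency scalar
applied to all waves; per-wave factors are supported but not defaulted.
Latency delays are capped at 0.2 ms so that every delayed trough still
falls inside its assignment region (§3). Note that at study-scale shifts
the *measured* amplitude decline in old animals is much larger than
1 − a(f): the threshold elevation also pushes the 80 dB stimulus down the
growth function (e.g. at 32 kHz the old group sits ≈4 dB above threshold,
so wave II drops by ≈98%, not 85%) — the same compounding that makes real
aged high-frequency responses nearly flat.

**Noise** is added as a single post-averaging Gaussian residual
(default σ = 0.35 μV, 10% of the wave-II base amplitude), not as 500
averaged sweeps; the averaged-trace statistics are identical and the cost
is desk-scale. The pre-stimulus segment carries noise only.

**Sampling.** 25 kHz, window −5 … +10 ms around stimulus onset. Rat ABR
waves complete within ~6 ms, and the 5 ms pre-stimulus segment supplies the
background-SD estimate.

**Seeding.** Every trace's generator is
`SeedSequence([master_seed, subject_index, freq_mHz, intensity])`, so any
single trace is reproducible in isolation and distinct subjects get
independent noise. Micrograph fields use an analogous
`SeedSequence([seed, group, subject, section, position])` chain.

## 2. Threshold detection and its statistical limits

The detector follows the acquisition-protocol definition literally: per
recording, response = whole-trace peak-to-peak over 0–8 ms post-onset
(config switch: largest single-wave amplitude instead); criterion =
response **strictly** greater than 2 × the sample SD (n−1 denominator) of
that recording's own pre-stimulus segment; threshold = lowest tested
intensity passing the criterion with all higher intensities also passing.

On noiseless averages this is exact: below threshold the trace is
identically zero, so 0 > 0 fails; at and above it the response is positive.
The detected threshold therefore equals the generator's ground truth (the
lowest grid intensity with positive effective level) in every cell.

With any σ > 0, however, the rule is not a valid detector: the max−min of
n ≈ 200 Gaussian samples concentrates near 5.3σ, so pure noise exceeds the
2σ criterion with probability ≈ 1 at every intensity and the sequential
rule returns the lowest tested intensity. The effect is scale-free — no
signal-to-noise ratio fixes it — and explains why this criterion works in
practice only when a human examiner first identifies repeatable waveforms
before applying it. The package implements the published rule rather than a
re-invented one; the acceptance script reports the measured noisy recovery
rate as-is. Users analysing real (noisy) averages should treat the
automatic threshold as a lower bound and review the per-intensity
peak-to-peak audit trail included in every `ThresholdResult`.

## 3. Wave identification

Peaks are local maxima (SciPy `find_peaks`) inside per-wave search windows;
the tallest wins, earliest on ties (latency is the quantity of interest, so
the earliest equal-height peak is the conservative choice). A peak must
exceed the 2×background-SD criterion or the wave is omitted. The trough is
the deepest local minimum after the peak and before the next wave's window
starts (wave V: before its own window's end), falling back to the lowest
sample of that span if the segment is monotone.

Default windows (ms post-onset): I 0.5–1.7, II 1.8–2.5, III 2.6–3.3,
IV 3.4–4.4, V 4.5–6.2. They are deliberately **disjoint** — the trough of
wave k must have an unambiguous home between wave k's peak and wave k+1's
window — and bracket the template latencies at 80 dB including the age
delays. They are config-overridable (`search_windows`) and were chosen for
measurements at 80 dB SPL, where amplitudes and latencies are reported; at
low intensities the latency shift moves peaks rightward, which matters only
to the threshold detector, and that uses peak-to-peak, not wave windows.

Latencies are taken at sample resolution (no sub-sample interpolation) and
reported to 0.01 ms; the 0.5 ms acoustic transit time is added to reported
latencies and cancels exactly in interpeak differences
(PI-PIV ≡ PI-PII + PII-PIV holds to machine precision by construction).

## 4. Micrograph model and densitometry

Fields are 256×256 px (0.25 μm/px) with background N(40, 8²) gray units,
clipped to [0, 255]. Signal consists of perisomatic rings (annuli, outer
radius 9 px, thickness 3 px; default 12 per field) and neuropil puncta
(radius 1 px → 3×3 blocks; default 150), placed by rejection sampling with
no overlap so the ground-truth mask and the placement log agree exactly.
Signal pixels are elevated by gain × condition_factor (default gain 120);
the condition factor (young 1.0, middle 0.75, old 0.5 in the default
three-group setting) scales both the number of profiles and the gain,
emulating fewer and paler terminals with age.

The analysis chain is: inverted 8-bit gray from the red channel
(255 − red; DAB is dark, so staining maps to high values); a 1–99
percentile linear stretch to [0, 255] (robust to outliers, rank-preserving,
and exactly invariant to affine gray-level changes — the original
normalisation macro is not recoverable, so a documented robust stand-in is
used); labeling at field mean + 2 SD (population SD; with ~10⁵ pixels the
n vs n−1 distinction is immaterial), strict inequality; indices per field:
mean gray over labeled pixels (config switch for whole-field) and summed
labeled area (px², μm² when calibrated). No minimum connected-component
size is imposed (an option exists, default 0).

Aggregation treats the **field** as the ANOVA observation — matching the
field-level degrees of freedom such analyses report (e.g. F(2, 58) from
three groups of ~20 fields, exceeding animal counts) — and also emits
per-subject means (and both SD and SEM at group level) for sensitivity
checks.

## 5. Statistics

Standard fixed-effects one-way ANOVA sums of squares in double precision;
p-values from SciPy's F survival function. The summary-statistic form uses
SS_w = Σ(nᵢ−1)sᵢ² and is algebraically identical to the raw form —
property-tested to machine precision. Zero within-group variance with
unequal means yields the F = +∞ sentinel with p = 0 (this occurs naturally
on noiseless synthetic cohorts, where all subjects in a group are
identical). Scheffé contrasts use the protected inequality above; by
construction no pair can be significant when the omnibus test is not.

Each frequency (and wave × frequency, and densitometric index) is tested
independently with no multiple-testing correction, mirroring the reporting
convention of the field; a Bonferroni switch exists, off by default.
No-response thresholds are excluded from ANOVA with the dropped count
recorded in the table's metadata. Stars: * p<0.05, ** p<0.01, *** p<0.001.

The Monte-Carlo type-I error check draws group observations directly from
the null Gaussian model (3 groups × n = 8, 10 000 replicates, vectorised)
rather than synthesising 10 000 full ABR cohorts: the ANOVA inputs have
identical distribution, at a small fraction of the cost.

## 6. Problem sizes used in validation

The test and acceptance runs use: the full three-group cohort (3 × 8
subjects × 7 frequencies × 11 intensities = 1848 traces) for threshold
recovery and directional checks; 10 000 replicates for the type-I error;
1000 random fixtures for the summary/raw ANOVA identity and 200 for the
Scheffé oracle; and a histology cohort of 3 groups × 4 subjects × 2
sections × 3 fields (72 fields of 256×256 px) for densitometric recovery —
large enough that the condition-factor ratios are estimated within a few
percent, small enough to run in seconds.

## 7. What the synthetic validation does and does not show

The generators share the analysis code's *assumptions* (biphasic waves
inside known latency ranges, Gaussian background, additive signal in
micrographs), so passing tests demonstrate correctness of the
implementation and internal consistency of the definitions — not robustness
to real-data pathologies. Not emulated: electrical/movement artifacts,
sweep-to-sweep variability and artifact rejection, filter ringing,
waveform-morphology changes with age beyond uniform scaling/delay, sloped
illumination or uneven DAB background, out-of-focus fields, section-to-
section staining variability beyond the per-group factor. The threshold
criterion's noise sensitivity (§2) is the clearest example of a definition
that is exact under the model yet fragile on real traces.

## 8. Known limitations

* Automatic thresholds on noisy averages are biased low (§2); use the
  audit trail or the any-wave criterion mode with caution.
* Wave windows assume 80 dB SPL measurement conditions; strongly delayed
  or immature waveforms need custom windows.
* Densitometric indices depend on the normalisation stand-in where the
  original macro was unspecified; the mean-gray index is additionally
  sensitive to the labeled-only vs whole-field switch.
* The amplitude growth function saturates at 40 dB above threshold; supra-
  saturation effects (rollover) are not modelled.
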