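# Methods

## Problem and model

The detector assigns one of three phases — exhalation, inhalation,
nonbreathing — to each 0.195 s window (3120 samples at 16 kHz) of a
breathing-training audio stream. Exhalation covers two acoustic
subtypes: *acoustic* exhalations (airborne breath sound) and *airflow*
exhalations (wind-like turbulence of breath hitting the microphone
membrane, low-frequency and high-energy); both collapse to one class at
decision time. The pipeline is transfer learning: a frozen 1024-d audio
embedding, then a trainable head `softmax(W2ᵀ·swish(W1ᵀe + b1) + b2)`
with 32 hidden units, `swish(x) = x·σ(x)`. Heads are trained with
mini-batch Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999, batch 32) on categorical
cross-entropy, early stopping with patience 10 on validation loss and
best-epoch weight restoration. No class balancing is applied: the
nonbreathing class is left dominant so that the detector errs against
false breathing positives in noisy rooms. From `n` seeded candidates the
3 with the lowest validation loss form an equal-weight soft-voting
ensemble (probabilities averaged before thresholding).

### Decision policy

Ordered thresholds rather than argmax: exhalation is checked first
(`p_ex ≥ τ_ex`), then inhalation, else nonbreathing; both thresholds
default to 0.3 and comparisons are inclusive, so `τ = 1` remains
attainable by certainty-1 predictions. Youden-J search evaluates
`J = sensitivity + specificity − 1` at every distinct observed score
plus {0, 1} (J is piecewise constant between observed scores) and breaks
ties toward the smallest threshold.

### Exhalation hold

Streamed calls are smoothed by forcing the output to exhalation for
300 ms after each raw exhalation call; every raw exhalation resets the
timer. The comparison at expiry is strict (`t < hold_until`), so a call
exactly at the boundary uses the raw phase. The hold is applied to
decision outputs, not probabilities, and by construction can only
increase exhalation output — exhalation recall with the heuristic is
never below recall without it, while specificity may drop.

## Front-end choices

The published front end fixes the window/hop (25/10 ms), the 64 mel
bands over 125–7500 Hz, and the `log(S + 0.001)` compression, but not
the window function, FFT length, or magnitude-vs-power choice. We use a
periodic Hann window, FFT length 512, a magnitude spectrogram, and
unnormalized HTK-mel triangular filters — the conventions of the
pretrained audio-event network this front end feeds — and valid (no-pad)
framing so a 15,600-sample input always yields exactly 96 time steps
and silence maps exactly to the `log(0.001)` floor. All are recorded in
module constants; the pretrained-backend adapter may override them.

## Embedding backends

The real embedding network is an optional adapter (tensorflow + model
download); it raises an explicit error when unavailable rather than
falling back silently. The default backend is a deterministic surrogate:
per-mel-band mean, standard deviation, maximum, and mean absolute first
difference of the log-mel patch (256 features) pushed through a fixed
seeded Gaussian projection to 1024 dims with a tanh squashing. The
surrogate preserves exactly the band-energy contrasts that distinguish
the synthetic archetypes, which is what the training, decision,
heuristic, session and metric layers need in order to be exercised
end to end; it is not a perceptual model and makes no claim about
performance on real breathing audio.

## Guidance pattern and session dynamics

The canonical pattern at 6 BPM is 4-1-5-0 s. For other rates the pauses
are held at (1, 0) s and the active time `60/bpm − 1` is split 4:5
between inhalation and exhalation — the unique linear rule consistent
with both published patterns (6 BPM → 4-1-5-0; 7 BPM → 3.37-1-4.21-0).
Rates with `60/bpm ≤ 1` are rejected.

The boat dynamics are only qualitatively constrained by the app they
model, so the constants here are package definitions: base speed 1,
acceleration 2, max speed 4 (units/s), decay rate 1 s⁻¹, integrated by
explicit Euler at the tick rate (default 30 Hz). "Exhalation accuracy"
is likewise operationalized here as guided-exhalation coverage: the
fraction of ticks inside guided exhalation intervals on which the
smoothed detector output was exhalation. Distance and speed are
monotone/bounded by construction and excluded from any quantitative
comparison with the original app.

## Annotation model

Label tracks are half-open, non-overlapping intervals over
{exhalation_acoustic, exhalation_airflow, inhalation, nonbreathing,
unclear}; gaps are implicitly nonbreathing. Two raters are merged by
pairing intervals with maximal temporal overlap: boundary pairs within
200 ms are averaged, larger differences are flagged for manual
resolution (never auto-chosen), class conflicts — including intervals
only one rater drew — become `unclear`, which never invents agreement.
Cohen's κ is computed on the 0.195 s frame grid over the three detector
classes, with frames touching `unclear` removed pairwise; the original
κ was computed on time series of unstated granularity, so values are
comparable only in spirit. Frame projection assigns each frame the
phase with the largest temporal overlap (ties: exhalation > inhalation >
nonbreathing) and masks any frame touching `unclear`.

## Synthetic data

The generator emulates the *structure* of breathing-training audio, not
its realism. Archetypes (fixed, deliberately exaggerated):

| class | synthesis | target RMS |
|---|---|---|
| inhalation | white noise band-passed 300–2000 Hz, cosine on/off ramps | 0.05 |
| exhalation (acoustic) | white noise low-passed at 4 kHz | 0.15 |
| exhalation (airflow) | white noise low-passed at 220 Hz (≥80 % energy < 500 Hz) | 0.30 |
| nonbreathing events | tones 0.5–4 kHz, chirps, click bursts | 0.10 |
| ambient | white noise throughout | 0.003 |

Sessions follow the BPM-scaled pattern with Gaussian boundary jitter
(SD 0.05 s default); exhalation subtype is drawn per cycle (airflow
probability 0.2, echoing the minority share of airflow samples in the
original training material); pauses host a nonbreathing event with
probability 0.3. All randomness derives from a single config seed via
`numpy.random.SeedSequence` spawning, so identical configs are
bit-identical. A preset mirrors the original training-set composition
(4574 / 418 / 2470 / 11,752 frames).

Passing the end-to-end tests therefore shows the pipeline is wired
correctly — embeddings separate the classes, training converges,
thresholds and the hold behave as specified, metrics are computed
right — and does **not** show that the detector would reach any
particular accuracy on real breathing audio, with its speaker
variability, microphone differences, and noise-suppression artifacts.

## Benchmark sizes and numerical choices

The package's standard verification benchmark trains 8 candidate heads
(ensemble of 3, max 40 epochs) on 300 frames per class (airflow
exhalations at 60, one fifth, matching their minority status) and
evaluates on a fresh 60 s synthetic session; this recovers multi-class
balanced accuracy (Urbanowicz) ≳ 0.93, where the shortfall from 1.0 is
dominated by frames straddling jittered phase boundaries. The candidate
count is configurable up to the original's 1000-candidate sweep.

Other numeric conventions: probabilities renormalized to sum exactly to
1 after ensemble averaging; zero-denominator metrics surfaced as NaN
with a warning, never silently 0; metric values kept at full precision
internally and rounded to 2 decimals only for presentation; ensemble
selection ties broken by candidate order; remainder audio shorter than
one frame dropped, never padded; stereo collapsed by channel averaging;
resampling by band-limited polyphase filtering.

## Known limitations

- The surrogate embedding is a verification device; real-audio accuracy
  claims require the pretrained backend and real recordings.
- The streaming model (most-recent-window at 30 Hz) is one concrete
  reading of "runs every frame, ~30×/s"; gapless framing is also
  provided and used by the offline CLI path.
- The in-app accuracy formula and wind-strength scaling of the original
  biofeedback are not published; the definitions here are package
  conventions.
- Annotation merging resolves only what the stated rules determine;
  >200 ms disagreements always require a human decision.
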