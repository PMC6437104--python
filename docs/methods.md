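# Methods

`laughdx` implements a complete screening chain for depression based on
the acoustic structure of laughter: laughter audio → plosive segmentation
→ six sound variables per plosive → laugh-level network exemplars → tanh
MLP / hybrid RBFN classifiers → diagnostic evaluation. The clinical
recordings this methodology was developed on are private, so the package
also ships a seeded simulator that reproduces their documented structure
and serves as ground truth for every test.

## The laughter model

Laughter decomposes hierarchically into episodes, bouts, and *plosives* —
short percussive calls repeated every 200–220 ms, appearing in the
waveform as isolated energy peaks separated by silence. The plosive is
the analysis unit throughout.

### Synthesis (laughsim)

Each plosive is source–filter synthesized:

- **Voiced source**: an impulse train at the plosive's F0 with a
  first-difference applied, the standard minimal approximation of the
  glottal pulse train plus lip-radiation tilt.
- **Noise source**: white Gaussian noise.
- **Vocal tract**: three cascaded second-order resonators (unit gain at
  resonance) around 700 / 1400 / 2600 Hz — an open, /a/-like laughter
  vowel — with per-plosive jitter.
- **Mixing**: the two sources are filtered separately, equalized to unit
  RMS *after* the resonator cascade, and combined as
  `(1 − noise_mix)·voiced + noise_mix·noise`. Mixing after the filter is
  deliberate: a resonator cascade passes broadband noise roughly 30×
  more power than a sparse pulse train, so pre-filter mixing would make
  `noise_mix` a misleading label. Post-filter equalization makes
  `noise_mix` literally the aperiodic fraction of emitted energy, which
  is what the annotation claims.
- **Envelope**: 5 ms linear attack, cosine release over the last 40% —
  plosives are percussive.
- The assembled laugh is band-limited to 50–10,000 Hz (the recording
  band of the original protocol) with a zero-phase Butterworth filter.

Plosive onsets are spaced uniformly in the configured 200–220 ms band;
plosive count per laugh is 4 with probability 0.2, else uniform on
{5, 6, 7}, so most laughs support the five-plosive network schemas.
Laughs per subject are Poisson with means 17 (patients) and 21
(controls), matching the study sizes (30 patients, 20 controls, ≈950
laughs).

### Class effects

Depressed laughter is emulated with three configurable effect sizes,
each in the clinically reported direction (weaker, less frequency-
colored, flatter):

| effect | default | mechanism |
|---|---|---|
| spectral entropy | −1 bit | lower `noise_mix` + narrower formant bandwidths |
| energy | −6 dB | linear amplitude scale on every plosive |
| F0 arch | gain × 0.5 | shrunk rise–fall template across plosives |

F0 of plosive *k* is `base_f0 · (1 + gain · a_k)` with a fixed rise–fall
template `a_k`; patients get the shrunk gain. With all three effects at
zero the two classes are drawn from identical distributions (verified by
rank tests and by the null-effect control below).

Spectral entropy is not an analytic function of the synthesis controls,
so the entropy offset is realised through a calibration table: reference
plosives are synthesized across a noise-mix grid once per sample rate,
their measured entropies monotonized, and the subject's target entropy
(baseline + offset) inverted through the table. One "breathiness" level
drives both the noise mix and a bandwidth scale (0.6 + 0.8·mix), which
widens the reachable entropy span to comfortably above ±1 bit around the
control baseline (mix 0.32). The mix is floored at 0.05; below that the
spectrum is so line-like that LPC formant estimates snap to harmonics.

The clinically reported effect *directions* are fixed; the *sizes* above are
the package's choice of a clearly detectable but not caricatured effect
(−6 dB ≈ halved amplitude; −1 bit ≈ the separation visible between the
entropy distributions of patient and control laughs in prior entropy-only
work). They are config fields, not constants.

### What the simulator does not emulate

Real laughter voicing types (song-like vs grunt-like), inter-plosive
aspiration, room acoustics and recorder coloration, overlapped speech,
and between-laugh within-subject drift. Consequently, passing tests
show the *pipeline* recovers what the generator planted under realistic
SNR and timing variation; they do not certify clinical performance on
real recordings — the published accuracy figures come from a private
clinical dataset and are not reproducible here.

## Plosive detection (plosive_segmenter)

The recording is band-passed (zero-phase, order-8 Butterworth, 50–10,000
Hz), and sliding-RMS envelopes are computed. Detection uses two window
lengths:

- a **detection envelope** (60 ms) on which plosives are unimodal bumps:
  local maxima above `onset_threshold_rel` (default 0.1) of the global
  peak, at least 150 ms apart (just under the shortest plosive repetition
  period), are plosive candidates; the smaller of two conflicting peaks
  is dropped, which makes the detection count monotone non-increasing in
  the threshold;
- a **boundary envelope** (15 ms) on which the segment limits are the
  threshold crossings around each peak, extended to the nearest envelope
  local minimum but never below half the threshold (beyond that the walk
  would trace silence-floor noise and jitter the onset).

RMS was chosen over a Hilbert envelope because plosives are defined by
energy, and the threshold is relative to the per-recording peak because
recording gain is unknown. The clarity filter then rejects non-plosive
events with logged reason codes: segments outside 30–350 ms, near-peak
plateaus longer than 350 ms, and — because a detector can carve a long
hum into plosive-sized pieces — any segment belonging to a *coalesced
event* (consecutive segments with no true silence between them) longer
than 350 ms. On simulator output this detector reaches ≥ 0.95 recall and
precision with onset error about −5 ± 1 ms (a constant detection lead
that cancels in inter-onset gaps).

## The six sound variables (acoustic_features)

Per detected plosive:

1. **Duration** (ms) from the segment bounds.
2. **F0 mean** (Hz): normalized autocorrelation per 10 ms frame (30 ms
   window, 75–600 Hz search band). A frame is voiced iff the best
   in-band autocorrelation peak ≥ 0.65; among peaks within 85% of the
   best, the smallest lag wins (the period is the *smallest* repetition
   interval — this rejects period-doubling errors), refined by parabolic
   interpolation; residual octave errors are snapped to the track median.
   The mean is over voiced frames only, NaN-flagged when none.
   The 0.65 voicing threshold is set where formant-filtered noise stops
   producing spurious voiced frames while genuinely voiced plosives at
   the control noise mix are unaffected.
3. **F1–F3** (Hz): LPC (order 2 + fs/1000, autocorrelation method,
   Hamming window, pre-emphasis 0.6) root-solved; poles inside the unit
   circle with 90–5,000 Hz frequency and bandwidth < 400 Hz qualify.
   Up to three 30 ms frames per plosive are analyzed and the per-formant
   median taken. Pre-emphasis is moderate (0.6, not the speech-standard
   0.97) because the synthesized source already carries the radiation
   tilt; full pre-emphasis over-tilts the spectrum and biases F1 toward
   the nearest strong harmonic.
4. **Average power**: mean squared amplitude (dimensionless on
   normalized audio).
5. **Spectral Shannon entropy** (bits): −Σ p·log₂p over the power
   spectrum restricted to 50–10,000 Hz, rectangular window, FFT length =
   segment length unless overridden. Gain-invariant by construction.
6. **Voiced fraction**: voiced frames × 10 ms over the onset-to-next-
   onset interval (to the plosive's own end for the last one), clamped
   to [0, 1].

Unmeasurable values are NaN with explicit flags, never silent defaults.

## Network schemas

The stored data matrix is one row per plosive (all six variables with
the three formants as separate numbers, placement, onset, and the
dichotomous health status coded 1 = depression, 2 = control, exactly as
in files). Network exemplars are laughs; their first five plosives feed
three schemas:

- **ANN40** (p = 40): eight channels × five plosives. The published
  "6 + 2 per plosive" layout counts the patient/control label itself as
  an input channel — feeding the target to the classifier, which makes
  any reported validity meaningless. The default layout therefore uses
  six acoustic numbers (duration, F0 mean, F1, F2, power, entropy) plus
  placement and onset time; the formant set is reduced to F1/F2 so the
  eight-channel budget closes (F3 and voiced fraction stay in the data
  matrix, and F3 is the least reliably estimated formant anyway). A
  `label_channel` mode swaps onset for the health label to reproduce the
  literal layout — it exists to *demonstrate* the leakage (it reaches
  ≥99% accuracy on null data) and is never a default.
- **EANN5** (p = 5): average power of plosives 1–5.
- **P5ANN6** (p = 6): the six acoustic numbers of the fifth plosive.

Laughs with fewer than five plosives are excluded (padding would
dominate training at these sample sizes); laughs with unmeasured
channels are excluded from the schemas that need them (EANN5 needs
energy only). All inputs are z-scored with parameters fit on the
training split only; constant channels (e.g. placement in a fixed
layout) map to zero.

## Classifiers (neural_models)

All units are hyperbolic tangent; targets are +1 (depression) / −1
(control), converted from the {1, 2} file coding only at this boundary.
Training is batch ("static") backpropagation with momentum:

    Δw(t) = −η_layer · ∂MSE/∂w + μ · Δw(t−1)

- **MLPs** (ANN, EANN, 5PANN): layers p–16–9–1, per-layer steps
  1.0 / 0.1 / 0.01, momentum 0.7, at most 10,000 epochs with an MSE stop
  (default floor 1e-4 — the original protocol names MSE as the stop
  criterion without a value). Weights initialize uniform in [−0.5, 0.5]
  (seeded), the classic scale for tanh nets on standardized inputs.
- **RBFN** (ANN40 only, as in the study): 8 k-means centers under
  Euclidean distance (own Lloyd implementation: assignment-convergence
  stop, ≤100 unsupervised epochs, empty clusters reseeded from the
  farthest point; cross-checked against scikit-learn on separable
  blobs), widths σ_j = mean distance to the two nearest centers (a
  standard scale-free overlap heuristic), Gaussian layer
  φ_j = exp(−‖x−c_j‖²/2σ_j²), then a 4-unit tanh layer and tanh output
  trained by the same momentum rule (steps 1.0 / 0.1) with centers
  frozen, ≤10,000 supervised epochs.

Divergence (non-finite epoch MSE) aborts with a diagnostic suggesting
smaller steps; with bounded tanh outputs the classic blow-up manifests
as overflowing weights rather than exploding MSE. Gradient correctness
is property-tested against central finite differences.

The decision rule is `label = +1 iff score > threshold` (default 0; a
score exactly at the threshold is classed control — documented strict
inequality).

## Splitting and evaluation

The holdout is 80/20, stratified, at subject granularity by default — no
subject's laughs straddle the split, because under laugh-level splitting
a network can memorize subject identity and "predict" the held-out
laughs of training subjects, inflating accuracy even for null data.
`kfold_split` deals subjects of each class round-robin into k folds
(each fold an 80/20 split at k = 5); the fold mean is the package's
preferred held-out estimate since every subject is held out exactly
once. Repeated seeded holdouts with mean ± sd reporting are also
supported.

The evaluation battery per trained model:

- **Confusion matrix** with the row-percent view (rows close to 100%);
  depression is the positive class.
- **Validity**: accuracy, sensitivity, *effectiveness*, precision.
  "Effectiveness" is implemented as specificity (tn/(tn+fp)) — the
  published confusion-matrix and validity tables are numerically
  consistent only under that reading (a 91.15% depression row pairs
  with sensitivity 0.91, an 84.61% controls row with effectiveness
  0.84). Undefined ratios are flagged `None`, never NaN.
- **Performance**: MSE, NMSE (MSE over target variance), Pearson r,
  % error, and the model-selection scores
  AIC = n·ln(MSE) + 2k and MDL = n·ln(MSE) + (k/2)·ln(n),
  with k the total trainable weight-and-bias count (RBFN centers and
  widths included: the stored model needs them). These follow the
  classic neural-network simulator conventions; both penalties are
  strictly increasing in k at fixed MSE.
- **ROC**: threshold sweep over the unique scores (scikit-learn's sweep,
  trapezoid AUC), property-tested against exhaustive concordant-pair
  counting with half credit for ties.
- **Input sensitivity**: each channel swept over its training mean ± 1 sd
  in 50 steps with all others held at their means; the channel's score is
  the standard deviation of the network output, ranked descending.
  Constant channels score 0, flagged. The ±1 sd range is a config.
- Reports are emitted at two levels: per laugh and per subject (majority
  vote over a subject's laughs, ties toward depression — in screening a
  missed patient costs more than a false alarm). Which level the
  original tables report is ambiguous, so both are always produced.

## Problem sizes and numerical choices

The shipped experiments run at the study's own scale: 50 subjects,
≈900 laughs, ≈700 five-plosive exemplars, 40-input networks — small
enough that the full chain (synthesis through training) takes well under
a minute per cohort on one CPU. The null-effect control regenerates ten
independent null cohorts and takes the 5-fold mean per cohort; that is
the dominant cost of the test suite (a few minutes). Tie-breaks and
degenerate inputs are all explicit: zero-energy segments flag `silent`
with entropy 0, empty F0 tracks flag `short_for_f0`, score ties go to
control at the laugh level and to depression at the subject vote, and
k-means warns when distinct exemplars are fewer than centers.

## Known limitations

- The simulator's class effects are directional stand-ins, not estimates
  from clinical audio; absolute classifier accuracy on this synthetic
  cohort (near-perfect at the default effect sizes) says nothing about
  accuracy on real patients.
- The F0 tracker assumes a single voice and 75–600 Hz pitch; formant
  estimates degrade for near-line spectra (mitigated, not eliminated, by
  the 0.6 pre-emphasis, multi-frame median, and noise-mix floor).
- The clarity filter approximates the original study's partially manual
  audit with duration/plateau rules only; laugh-vs-speech discrimination
  is out of scope.
- Subject-level reports on a 20% holdout rest on ~10 subjects; their
  variance is large, which is why the cross-validated fold mean is the
  preferred estimate.
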