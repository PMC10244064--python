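# Methods

This document specifies the signal-processing model, the parameter defaults
and why they were chosen, the scope of the synthetic generator, and the
numerical choices that affect results.

## Montages and derivations

All analyses run on microvolt-scaled scalp EEG with 10-20 electrode names
(`eeg_io.normalize_label` strips "EEG"/reference suffixes and fixes case).
Two derivations are used:

- a **symmetric bipolar montage** of 24 anode–cathode pairs, 12 per
  hemisphere, mirror-matched so that every left pair has the homologous
  right pair (enforced by `BipolarMontage`); asymmetry measures are only
  meaningful if both hemispheres are measured identically;
- a **common average reference** over all channels, used as an independent
  cross-check for slow-wave detection (see below).

Sleep stages come from a CSV hypnogram of scored epochs;
`extract_segments` merges contiguous epochs of the requested stage(s),
removes artifact spans and flags recordings with less than a minimum of
scored data (default 20 min — shorter samples give unstable densities).
Repeat nights are averaged per feature with `pool_nights`; single-night
patients are passed through and flagged.

## Delta power

Welch periodograms (Hann window, 4-s segments, 50% overlap) are averaged
over all scored NREM intervals per channel and integrated over 0.5–4 Hz.
Per-hemisphere power is the mean over that side's bipolar channels. 4-s
windows give 0.25 Hz resolution, enough to resolve the 0.5 Hz band edge
while tolerating intervals as short as a single 30-s epoch.

## Slow waves

Slow waves are detected on four lateralized bipolar channels (F3-C3, F7-T7
on the left; F4-C4, F8-T8 on the right). The trace is band-passed 0.5–4 Hz
(4th-order Butterworth applied forward and backward, i.e. zero-phase).
Candidate events are **negative half-waves**: stretches between a
positive-to-negative and the next negative-to-positive zero crossing,
lasting 0.25–1 s (the period range of 0.5–2 Hz waves). A candidate is kept
only when its trough falls inside a qualifying negative half-wave of the
average-referenced *anode* electrode — this referential cross-check rejects
events generated by the cathode of the bipolar pair.

The **duration criterion is the defining one**; an amplitude floor
(`min_amplitude_uv`) is off by default because absolute amplitudes depend
strongly on montage and filtering. The run configuration used in validation
sets a 30 µV floor to suppress background-noise half-waves when densities
are compared against a known ground truth. Per side we report density
(events/min), and the median trough amplitude, duration and descending
slope (amplitude / time-to-trough).

## Spindles

Spindles are detected during NREM 2 on one centro-inferior-temporal bipolar
channel per side (C3-FT9, C4-FT10). The trace is band-passed 11–16 Hz; the
RMS envelope (0.2 s moving window) must exceed the N2-segment mean + 1.5 SD
for 0.5–3 s. The duration filter is applied to supra-threshold runs
*before* events closer than 0.5 s are merged, so that sub-criterion noise
blips cannot chain into spurious events. The adaptive (mean + k·SD)
threshold is self-calibrating across recordings but mildly compresses
density asymmetries at unphysiologically high spindle rates, because the
denser side raises its own threshold; at physiological rates (1.5–3/min)
the bias is negligible. Amplitude is the peak-to-peak range of the
filtered ±3 s epoch around each spindle's maximal trough; epochs truncated
by a recording edge are flagged but still counted for density.

## Spindle/slow-oscillation coupling

Coupling is the **inter-trial coherence** (ITC) of the delta-band Hilbert
phase sampled at each spindle's maximal trough:

    ITC = | (1/N) Σ exp(i φ_k) |

ITC is 1 for perfectly locked phases and tends to 0 for uniform phases;
for N uniform phases its expectation is √π / (2√N), not 0, which matters
when comparing small samples. ITC is chosen over phase-amplitude coupling
because it is *exactly invariant* to spindle amplitude — amplitude is a
separate analysed feature, and the coupling measure must not re-express it.

## Asymmetry statistics

Every feature is summarized per patient as the lateralization index
LI = (L − R)/(L + R), which is dimensionless, bounded in [−1, 1] (for
non-negative inputs), antisymmetric under hemisphere exchange and invariant
to units. Group contrasts use the Mann-Whitney U test — exact permutation
enumeration when both groups have ≤ 7 patients or when ties are present and
the total is small, the normal approximation with tie correction otherwise —
reported with the probability-of-superiority effect size ES = U/(n₁n₂) and
Dunn (Bonferroni-style) correction over the feature family. Night-to-night
stability and paired hemisphere contrasts use Wilcoxon signed-rank logic on
per-patient LIs.

## Classification

The per-patient LI matrix feeds a CART decision tree (Gini impurity, no
depth cap) evaluated by stratified 5-fold cross-validation, repeated with
fresh fold assignments (default 5000 iterations; 500 in the examples for
speed). Chance level is estimated by an identical procedure with labels
permuted anew at every iteration (class counts preserved). The shuffle
null is the correct chance oracle: naive repeated CV on a fixed
uninformative matrix sits slightly *below* 50% ("anti-learning" — the
held-out fold is depleted of the class the tree just fit), whereas the
shuffle null is properly centred on 50%. Runs are compared by unpaired
t-tests on per-iteration accuracies with Šidák adjustment, and the pooled
2×2 contingency table by Fisher's exact test.

## Synthetic generator: scope

`sleepasym.synthetic` generates multichannel sleep EEG with exact
ground truth for validation. Per hemisphere it superimposes:

- 1/f (pink) background noise, 12 µV SD, with a per-side delta gain;
- a coherent 0.75 Hz slow oscillation on the frontal-central-parietal trio;
- half-sine negative slow waves at a programmed rate/amplitude/duration —
  each wave is written to the anode electrode, so it appears on **both**
  bipolar channels of its side (detected count ≈ 2× injected count);
- Hann-windowed 13 Hz spindle bursts whose troughs are placed at von
  Mises-distributed slow-oscillation phases (concentration κ chosen by
  `kappa_for_itc` to hit a target ITC);
- brief derivative-of-Gaussian IED transients (verified not to trigger the
  spindle detector).

Cohorts draw per-patient LIs from per-feature (median, SD) profiles, with
the right-focus group mirrored. The generator is a *validation instrument*,
not a biophysical model: it contains no spindle frequency variability, no
stage transitions within blocks, no artifacts, and its slow waves are
stereotyped half-sines.

## Numerical choices and their consequences

- **Zero-phase filtering** (`sosfiltfilt`) avoids phase distortion but rings:
  around large events it creates tiny (< 5 µV) qualifying half-waves, which
  is why validation counts apply an amplitude floor, and why exact
  duration-criterion checks are done on composites written directly in the
  filtered domain.
- **Band-pass attenuation**: a 0.5 s, 80 µV half-sine emerges from the
  0.5–4 Hz filter at ≈ 56 µV and ≈ 0.4 s. Absolute amplitudes are
  filter-dependent; lateralization indices are not, because both sides pass
  through the same filter.
- The RMS envelope clips the moving mean of squares at zero before the
  square root; floating-point error can otherwise produce NaN envelopes on
  near-zero traces and silently disable detection.
- ITC of an empty phase set is NaN (undefined), not 0, because 0 is the
  meaningful asymptotic value for uniform phases.
- All stochastic procedures take explicit seeds (`numpy.random.default_rng`)
  and are bit-reproducible given (inputs, seed).

## Parameter defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| delta band | 0.5–4 Hz | standard slow-activity band |
| SW duration | 0.25–1 s | period range of 0.5–2 Hz half-waves |
| SW amplitude floor | off (`None`) | duration is the defining criterion; amplitudes are montage-dependent |
| spindle band | 11–16 Hz | sigma band, both slow and fast spindles |
| spindle threshold | mean + 1.5 SD of N2 RMS envelope | self-calibrating across recordings |
| spindle duration | 0.5–3 s | standard spindle duration bounds |
| merge gap | 0.5 s | fuses fragmented detections of one spindle |
| coupling epoch | ±3 s around trough, ≥1 s kept | enough delta cycles for a stable Hilbert phase |
| min scored stage | 20 min | density estimates below this are unstable |
| CV | 5-fold stratified, 5000 iterations | fold-assignment variance is the dominant noise source |

## Limitations

- Detection parameters are tuned for adult NREM sleep at ≥ 100 Hz sampling;
  they are not validated for neonatal or intracranial data.
- The LI is undefined when L + R = 0 and unstable when L + R is near zero;
  features with near-zero bilateral values should be excluded upstream.
- The adaptive spindle threshold compresses density LIs at extreme rates
  (see above).
- The synthetic generator validates the *pipeline*, not clinical claims; no
  statement about real patients follows from recovering programmed
  asymmetries in simulation.
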