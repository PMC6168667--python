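# Methods

`ppigate` implements a dual-modality prepulse-inhibition (PPI) analysis:
the same auditory session yields a **muscular** gating index (acoustic
startle reflex, ASR, from orbicularis oculi EMG) and a **neural** one
(P2−N1 event-related-potential amplitude from EEG), measured over the same
trials. The central obstacle is that startle-evoked blinks contaminate the
EEG precisely time-locked to the stimuli; the package removes them with
Infomax ICA plus a fully automated component classifier, so no manual
component selection or per-epoch statistical thresholding is needed.

## Experimental model

A session consists of two blocks of 80 pseudorandomly ordered trials —
20 pulse-alone (P) and 20 prepulse+pulse trials per lead interval (P30,
P60, P120, the prepulse preceding the pulse by 30/60/120 ms) — flanked by
five leading and five trailing P trials (170 trials). Events mark the
**pulse onset** in every trial type; the condition label carries the
prepulse interval. Recordings are 512 Hz: 11 scalp channels (10–20
system), one EOG, a periocular EMG pair (EMG1/EMG2), and left/right
earlobe references.

For both modalities the gating index per interval is

%PPI = 100·(P − PP)/P = 100·(1 − PP/P),

the per-subject percent reduction of the prepulse-condition amplitude
relative to pulse alone. It is undefined (missing, never zero) when the
pulse-alone amplitude is not positive, can be negative (facilitation), and
group values are always computed subject-first, then averaged.

## Signal chain

Shared conditioning on the continuous recording: re-reference to the
earlobe average; zero-phase 4th-order Butterworth high-pass at 0.25 Hz;
zero-phase band-stop notches (±2 Hz, 4th order) at 60 Hz and every
harmonic below Nyquist (60/120/180/240 Hz at 512 Hz). "4th order" is the
design order of one pass; forward–backward application squares the
magnitude response. Edges use odd-reflection padding of up to three
nominal impulse lengths so the slow high-pass transient stays clear of the
analysis windows.

**EMG branch.** Bipolar derivation EMG1 − EMG2 (a config switch averages
the pair instead); band-pass 24–200 Hz; rectification; 15.9 Hz low-pass;
the envelope is clamped at zero where filter ringing undershoots. Segments
span −300…+300 ms around pulse onset (307 samples at 512 Hz) with a
baseline mean over −50…0 ms. ASR = envelope maximum in 20–120 ms
(endpoints inclusive after rounding) minus the baseline, floored at zero;
a config flag scores the raw maximum instead. Trials are rejected in one
deterministic pass when the in-window maximum exceeds its condition's
mean + 3·SD (sample SD) or the baseline exceeds the subject's baseline
mean + 3·SD — strict inequality with a small numerical guard (10⁻⁶
relative, far below physiological variability), so trials identical up to
filtering round-off are never rejected; the two criteria combine
disjunctively by default (config switch for conjunctive). Note that a
mean+3·SD rule is inert for small trial counts (the maximum attainable
z-score of n values is √(n−1)); it is meaningful at this design's 40–50
trials per condition. Subjects whose mean ASR to pulse alone falls below
20 digital units (20 × 0.0488 ≈ 0.976 μV at the default ADC resolution;
boundary inclusive as responder) are non-responders: the pipeline still
processes them fully but group statistics exclude them.

**EEG branch.** Scalp epochs −1…+1 s around pulse onset, baselined to the
mean of −650…−150 ms — a window upstream of every prepulse so all
conditions share the same reference interval; 40 Hz zero-phase low-pass per
epoch. ICA and artifact removal follow (see below), then epochs are
averaged per condition. N1 is the most negative sample in 60–165 ms, P2
the most positive in 165–275 ms (window edges rounded to the nearest
sample, both ends inclusive, ties to the earliest sample). The neural
amplitude is P2 − N1; analysis channels default to Fz, Cz, Pz. There is
deliberately **no** statistical epoch rejection in the EEG branch: trials
with big blinks are exactly the high-startle trials, and discarding them
would decouple the two modalities. EMG-rejected trials therefore stay in
the EEG average by default (a `synchronized_rejection` switch exists for
methodological comparison).

## ICA and automated component classification

Infomax (natural-gradient, annealing learning rate, non-extended,
`mne.preprocessing.infomax`) runs on the 11 scalp channels only, after
centering and EEGLAB-style sphering (2·C^(−1/2)). Stopping: weight change
< 1e-7 or 512 iterations. The unmixing matrix is *trained* on a temporally
decimated copy of the concatenated epochs (default every 4th sample,
~43 000 samples — far above the ≈20·ch² ≈ 2 400 guideline for 11
channels); activations and reconstruction always use the full-resolution
data. Decimation cuts the fit cost ~4× with no measurable effect on
separation in our benchmarks. Everything is seeded and bit-reproducible.
Components are ordered by descending projected variance with signs fixed
so each mixing column's largest weight is positive.

EOG, EMG1 and EMG2 are *not* decomposed; they serve as classification
references, processed with the same filters and epoching as the ICA input
(band-matched). Five criteria score each component:

| criterion | statistic | flag when | default |
|---|---|---|---|
| autocornelation | lag-20 ms Pearson r, per epoch, averaged | below threshold | "auto" = mean − 2·SD across components |
| focal topography | max z of \|mixing weights\| across channels | above | z > 3.5 |
| focal trial activity | max z across epochs of per-epoch max \|activation\| | above | z > 10 |
| stimulus-locked SNR | SD of component ERP in 0…+1 s ÷ SD in −1…0 s | below | ratio < 1 |
| reference correlation | max \|r\| with EOG/EMG1/EMG2 | above | r > 0.2 |

Degenerate-case conventions: a constant activation has autocorrelation 1
(never muscle-flagged); a zero pre-stimulus SD gives SNR +∞ (never
flagged); zero-variance references are skipped with a warning. The final
decision is the **union** of the flags (config-switchable to majority
vote); removal reconstructs the epochs from the kept components, and
flagging *every* component is an error rather than an empty
reconstruction. The blink-detection role of the ADJUST/FASTER plug-ins is
covered by the reference-correlation and focal-topography criteria; those
algorithms are not reimplemented (known limitation). "Lag 20" is read as
20 ms (not samples), and the SNR flag direction is "below 1 ⇒ not
stimulus-locked"; both are exposed in the config.

## Statistics

Per modality, condition effects are tested within subjects: Shapiro–Wilk
per condition at α = 0.05 gates between repeated-measures ANOVA (all
conditions Gaussian; statsmodels `AnovaRM`) and the Friedman test. A table
in which every subject is constant across conditions short-circuits to
(χ² = 0, p = 1) — such data carry no condition information but would
otherwise produce a 0/0 F-statistic. Post hocs run only after a
significant omnibus: Tukey HSD (parametric) or paired two-sided Wilcoxon
signed-rank with Bonferroni multiplication by the number of contrasts
(nonparametric); amplitude contrasts are P vs each prepulse condition,
%PPI contrasts are the three interval pairs. Muscular–neural association
uses Kendall's tau-b between the ASR %PPI and each electrode's %PPI per
interval (nine correlations). Missing %PPI values are excluded listwise
per test with counts logged. All of Friedman, Wilcoxon (exact enumeration
at small n), Kendall tau-b, the z-score rules and the rejection rule are
validated against independent brute-force oracles in the test suite, and
the omnibus holds its nominal 5% type-I rate (4–6.5% over 1000 null
tables) by simulation.

## Synthetic sessions and ground truth

The simulator emits the full trial structure above with every planted
quantity recorded. Defaults (chosen once as a realistic desk-scale study;
amplitudes in μV):

* **Startle EMG**: a per-subject band-limited (24–200 Hz) noise carrier
  under a gamma envelope peaking ~55 ms post pulse, unit-normalised;
  per-trial amplitude = 50 · (1 − %PPI/100) · lognormal jitter (σ = 0.3,
  unit mean). Planted muscular %PPI: 35/55/35 for 30/60/120 ms. Using one
  fixed carrier makes the zero-jitter, zero-noise session *exactly*
  scale-equivariant, so the pipeline must recover the planted %PPI to
  machine precision — the strongest available end-to-end identity.
* **Neural ERP**: Gaussian N1 (−12 μV, 100 ms, σ 15 ms) and P2 (+18 μV,
  200 ms, σ 24 ms) with fronto-central topographies (distinct gain vectors,
  so the neural subspace is rank 2), scaled per condition by the planted
  neural %PPI 40/55/40. The EOG receives a 0.15-gain copy (real EOG sees
  some brain signal).
* **Blink**: one rank-1 source (Gaussian pulse, peak 100 ms, σ 60 ms),
  EOG gain 120, scalp gains 0.45 (frontopolar) → 0.07 (parietal), amplitude
  coupled to the same condition factor and jitter as the startle — the
  confound of interest: stronger startles blink harder, biasing any method
  that discards blink epochs.
* **Noise**: per-channel 1/f EEG noise (SD 8), white sensor noise (SD 2),
  EOG/EMG/reference white noise (3/2/0.5), and coherent mains (60 Hz plus
  0.4×/0.2× harmonics, amplitude 5, random per-channel gain and common
  phase). Inter-trial interval uniform 2.5–3.5 s (unstated in the source
  protocol; enough for the ±1 s epochs plus slack).

What the simulator does **not** model: prepulse-evoked potentials, startle
habituation across blocks, saccades and non-blink muscle artifact,
electrode drift/impedance changes, or a biophysical forward model. Passing
the recovery tests therefore demonstrates correctness of the *pipeline
arithmetic and the blink-removal mechanism* under a controlled confound,
not performance on arbitrary real recordings.

## Problem sizes and reproducibility

The validation batch used by the test suite is 20 seeded replicates of an
8-subject study (160 full per-subject pipelines, 170 trials each); the
acceptance script reruns 5 replicates plus the noiseless identity and a
1000-replicate null calibration. With these sizes the grand-mean recovered
%PPI stays within ±5 points (muscular) and ±10 points (neural) of the
planted values, ICA cleaning reduces the Fz ERP's RMS error against the
artifact-free truth by >50% (typically ~80%), blink-component detection is
at or near 100% with ~0% neural false flags. All randomness flows from
explicit seeds (per-subject seeds spawned from a master `SeedSequence`);
identical seeds give byte-identical recordings, unmixing matrices and
reports — manifests deliberately contain no timestamps.

## Known limitations

* BrainVision/EDF writers are minimal (float32 multiplexed; 16-bit EDF
  with 1 s records and zero-padded tails) — fixture-grade, not
  archival-grade.
* The "auto" autocorrelation threshold (mean − 2·SD across components) is
  this package's definition; the original advisory tool's auto mode is not
  publicly specified. A fixed r can be configured instead.
* Tukey HSD treats the condition groups as independent samples (the
  classical test, as in common practice after a repeated-measures
  omnibus); a within-subject contrast procedure is not provided.
* Component classification quality degrades when the blink topography is
  not rank-1 or when fewer than ~100 epochs are available (the focal-trial
  z-threshold of 10 is unreachable below 101 epochs).
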