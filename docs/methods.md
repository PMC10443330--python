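# Methods

## Binary point matching

A recogniser is a binary spectrogram template plus a calibrated score
cut-off. The template is built from one manually chosen reference call:
its spectrogram, restricted to user-chosen frequency limits, is
binarised at an **amplitude cut-off** — cells at or above the cut-off
are "on" (call), the rest "off" (non-call). Cells exactly at the
cut-off count as on; the on and off sets partition the in-band grid
exactly. On and off both matter: the matcher rewards energy where the
call has energy *and* silence where the call has silence, which is what
separates a structured call from broadband noise.

The match score at alignment offset *t* against a survey spectrogram is

    score(t) = mean(dB over on cells at t) − mean(dB over off cells at t).

No published closed form exists for the matching statistic of the
technique this follows; the mean-contrast form above is our
interpretation of "matching on and off points", chosen because it makes
the conventional starting score cut-off of 3 directly readable as "the
on region averages at least 3 dB hotter than the off region". Two
consequences the implementation preserves exactly:

- **Gain invariance.** Adding a constant to every survey cell cancels
  in the difference of means, so matching is insensitive to overall
  recording level (and to our dB-reference choice, below).
- **Degenerate off set.** A template with no off cells (amplitude
  cut-off at the floor) scores mean-on minus the spectrogram floor.

Detections are local maxima of the score trace at or above the score
cut-off. A plateau counts once, at its first frame. Nearby peaks are
suppressed greedily: peaks are visited in descending score (earlier
frame wins ties) and a peak closer than `min_separation_frames` to an
accepted one is dropped. The default separation is one template
duration. Detection counts are raw peak counts — repeated detections of
one long vocalisation are counted separately, matching how published
call-level counts (tens of thousands of detections across a few hundred
files) are tallied.

## Spectrogram conventions

- Magnitude STFT, Hamming window (periodic), window sizes 256/512/1024
  preferred (512 default; 256 trades frequency for time resolution,
  suiting highly pulsatile calls). Other sizes work with a warning.
- Frame layout: hop = window_size × (1 − overlap); default overlap 0.
  Frame count = floor((n − window)/hop) + 1; frame 0 starts at sample
  0; indices 0-based, intervals half-open; bins 0..Nyquist.
- **dB reference**: 20·log10(|X| / max|X|) per spectrogram, so the
  global maximum is exactly 0 dB. Amplitude cut-offs like −31 dB are
  defined relative to this maximum. Zero-magnitude cells floor at
  −120 dB (configurable). An all-zero clip has no reference; it
  returns an all-floor spectrogram with a warning rather than an error,
  since survey files can be near-silent.
- Surveys recorded at a different rate than the template's build rate
  are resampled (polyphase) to the template rate before matching — bin
  geometry must agree — and the action is logged.
- Integer PCM normalises by the dtype's full scale (a full-scale 16-bit
  sample reads as ±32767/32768); multichannel files use channel 1 with
  a warning.
- An optional `gain_db` pre-gain in template construction emulates
  "amplification settings": adding k dB before thresholding is
  equivalent to lowering the amplitude cut-off by k.

## Score cut-off calibration

For each template, score traces are matched once per evaluation file
and re-thresholded at each cut-off of a grid (start 3.0, step 0.2 by
default; the stop defaults to the ceiling of the maximum observed score
so the grid always brackets the optimum). Re-thresholding stored traces
is provably equivalent to re-running the matcher at every cut-off; a
`mode="rematch"` path exists and the tests assert the equivalence.

At each cut-off the file-level confusion counts feed the **ROC value**
(PA TP + PA TN)/n_files — a scalar file-level accuracy, *not* area
under an ROC curve; the ROC *curve* here is ROC value plotted against
cut-off. The optimum is the cut-off maximising ROC value, ties broken
toward the higher cut-off (fewer false positives at equal accuracy).
The objective is ROC value only; where missing calls is costlier than
false alarms, recall at the chosen cut-off is reported alongside and
should inform the final choice. Per species, calibrated templates are
ranked by ROC value at optimum and the top `keep` (default 3, typical
final recognisers use 2–4) are flagged as the final recogniser.

## Evaluation rules

Annotations are per-file presence/absence — there is no call-level
ground truth — so **every** detection in a present file is a call-level
TP and every detection in an absent file a call-level FP. This is
deliberately lenient: a detection triggered by noise in a file where
the species happens to call elsewhere still counts as TP. We adopt the
rule as the field convention it is, and flag it here: call precision is
an upper bound on "the detector found actual calls".

File level: ≥1 detection in a present file → PA TP; in an absent file →
PA FP; no detections → PA FN / PA TN. PA counts always sum to the
evaluation-file count. Metrics with zero denominators are reported as
missing, never 0. Report tables round to 3 decimal places, halves away
from zero; false-positive source summaries to 1 decimal place (their
pre-rounding sum is exactly 100; post-rounding sums may drift by a few
tenths). Keeping evaluation sets balanced is the user's job; the
tallier warns when prevalence leaves [0.30, 0.70].

The bundled reference tables (`chorusmatch.datasets`) come from a
published eight-species frog-recogniser study whose audio is
proprietary; they pin the metric arithmetic (every printed metric
re-derives from its printed counts at 3 dp), not the matcher.

## Synthetic soundscape generator

The generator emulates the *structure* of wetland survey audio, not its
sound: white-noise floor (default −60 dB RMS re full scale), continuous
narrowband insect-like bands and episodic bird-like chirps (the two
interferer archetypes: continuous sources can fire a recogniser all
file long, episodic ones only occasionally), and planted calls —
pulsatile (AM pulse trains), tonal, or harmonic stacks — in the frog
band (0.3–4 kHz).

**SNR contract**: a call planted at s dB has band-limited RMS (4th-order
Butterworth bandpass over the call's nominal band, over the call's
interval) exactly s dB above the background's band-limited RMS there.
Defaults mirror field protocols: 60-s files at 44.1 kHz, prevalence 0.5
(balanced presence/absence), 2–4 calls per present file. All randomness
flows from one integer seed; same seed, same bytes. A fixed scalar SNR
consumes no random draws, so corpora regenerated at different SNRs from
the same seed share the identical background and call schedule — SNR
sweeps are paired comparisons, which is why per-seed performance
degrades (weakly) monotonically as SNR drops rather than merely in
expectation.

What passing tests on synthetic data do **not** show: robustness to
real chorus overlap, reverberation, species with similar calls in the
target band, recorder self-noise, or geographic call variation. The
synthetic corpus is a correctness harness for the pipeline, not a
benchmark of field performance.

## Problem sizes in the test and acceptance runs

The stochastic end-to-end checks use 22.05 kHz audio and shortened
files — 30 × 15 s for score-cut-off recovery, 10 × 10 s × 5 seeds ×
4 SNRs for the degradation sweep, with the degradation measured at a
fixed operating cut-off of 6.0 (midway between background scores ≈3 and
matched-call scores ≈25) — sizes chosen to keep the suite quick while
leaving tens of independent files per estimate. The generator defaults
(60 s at 44.1 kHz) remain the field conditions.

## Known limitations

- One template = one reference call; no averaging or multi-call
  template induction (candidate-call selection is manual by design).
- No spectrogram cross-correlation matching; binary point matching
  only.
- File-level evaluation only; no onset/offset overlap scoring.
- False-positive source attribution is human-in-the-loop; no acoustic
  auto-classification of interferers, and no convergence statistic for
  the "review until consistent" stopping rule (the verification sheet
  supports incremental labelling instead).
- WAV (PCM/float) input only; no FLAC/MP3, no denoising preprocessing.
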