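# chorusmatch

Binary spectrogram template matching for multi-species acoustic call
recognisers, with calibrated score cut-offs and file-level performance
accounting.

## The problem

Passive acoustic monitoring programs — for example, tracking frog
responses to wetland restoration — accumulate thousands of short survey
recordings per season. A *call recogniser* automates scanning them for a
target species. This package implements the classic, transparent
template-matching approach end to end:

1. **Spectrograms** (`chorusmatch.audio`): magnitude STFT in dB relative
   to the spectrogram's global maximum, so the loudest cell is exactly
   0 dB and amplitude thresholds transfer between recordings.
2. **Binary templates** (`chorusmatch.templates`): a reference call's
   spectrogram region is split at an *amplitude cut-off* into "on"
   (call) and "off" (non-call) cells. Lowering the cut-off (e.g. −31 →
   −37 dB) grows the on region.
3. **Binary point matching** (`chorusmatch.matching`): sliding the
   template across a survey spectrogram, the score at each alignment is

   ```
   score(t) = mean dB over on cells − mean dB over off cells
   ```

   a gain-invariant dB contrast. Local maxima of the score trace at or
   above a *score cut-off* are detections.
4. **Calibration** (`chorusmatch.calibration`): the score cut-off is
   swept from a permissive 3.0 upward in 0.2 steps; at each cut-off the
   file-level confusion counts are tallied and the **ROC value**

   ```
   ROC = (PA TP + PA TN) / number of evaluation files
   ```

   is computed (a file-level accuracy — *not* area under a curve). The
   optimal cut-off maximises ROC value; the best few templates per
   species form the final recogniser.
5. **Evaluation** (`chorusmatch.evaluation`): call-level precision and
   file-level (survey) precision/recall against per-file
   presence/absence annotations, reported like the standard
   per-template performance table.
6. **False-positive audit** (`chorusmatch.fp_sources`): export detected
   false positives for manual source attribution (insects, other frogs,
   birds, weather, ...) and summarise them as percentages.
7. **Synthetic soundscapes** (`chorusmatch.soundscapes`): ground-truthed
   WAV corpora — frog-like pulsatile/tonal/harmonic calls in the
   0.3–4 kHz band at controlled band-limited SNR, over a noise floor
   with continuous (insect band) and episodic (bird chirp) interferers —
   so the whole pipeline is testable without proprietary field audio.

A reference performance table from a published eight-species frog
recogniser study (Murray–Darling Basin) ships in
`chorusmatch.datasets`; the test suite re-derives every printed metric
from its printed confusion counts.

## Worked example

Simulate a corpus, build a template from one planted call, and calibrate
its score cut-off:

```python
import pandas as pd
from chorusmatch import (CallModel, SpectrogramParams, compute_metrics,
                         generate_evaluation_set, make_binary_template)
from chorusmatch.pipeline import calibrate_template, extract_reference_call

# 1. simulate a ground-truthed survey corpus
model = CallModel("tonal", carrier_freq=620.0, bandwidth=150.0, duration=0.25)
corpus = generate_evaluation_set(
    "corpus", n_files=12, prevalence=0.5, species={"banjo_like": model},
    snr_db=20.0, seed=7, duration=10.0, sample_rate=22050,
)

# 2. cut a reference call out of the corpus and binarise it at -18 dB
truth = pd.read_csv(corpus.ground_truth_path)
call = truth.iloc[0]
reference = extract_reference_call(
    corpus.audio_dir / call.survey_id, call.onset_s, call.offset_s,
    species="banjo_like", site="synthetic",
)
template = make_binary_template(
    reference, amplitude_cutoff=-18.0, freq_limits=(370.0, 870.0),
    params=SpectrogramParams(window_size=512),
)
print(f"template {template.name}: {len(template.on_points)} on / "
      f"{len(template.off_points)} off points")

# 3. calibrate the score cut-off against the annotations
result = calibrate_template(
    template, corpus.wav_paths, pd.read_csv(corpus.annotation_path),
    start=3.0, step=0.2,
)
metrics = compute_metrics(result.counts)
print(f"optimal score cut-off: {result.optimal_cutoff:.1f}")
print(f"ROC value {result.roc_value:.3f}, survey recall {metrics.survey_recall:.3f}, "
      f"call precision {metrics.call_precision:.3f}")
```

Output:

```
template -18_survey_000.wav:4.000-4.250_synthetic: 20 on / 256 off points
optimal score cut-off: 23.8
ROC value 1.000, survey recall 1.000, call precision 1.000
```

The template's on region (20 cells) is the tonal call's energy above
−18 dB; at +20 dB SNR the matched call scores ≈25 dB of on/off contrast
while background alignments stay near 0, so the calibrator finds a
cut-off that classifies all 12 files correctly (6 present, 6 absent).
Ties in ROC value break toward the higher cut-off, which is why the
chosen cut-off sits near the top of the sweep grid rather than just
above 3.

The same workflow is scriptable from the shell:

```bash
chorusmatch simulate --out-dir corpus --n-files 12 --seed 7 --species banjo_like
chorusmatch build-template --audio corpus/survey_000.wav --species banjo_like \
    --onset 4.0 --offset 4.25 --cutoff -18 --freq-low 370 --freq-high 870 \
    --out template.json
chorusmatch calibrate --template template.json --audio-dir corpus \
    --annotations corpus/annotations.csv --out-dir calib
chorusmatch detect --template calib/template.json --audio-dir corpus --out detections.csv
chorusmatch evaluate --detections detections.csv \
    --annotations corpus/annotations.csv --out report.csv
```

## Documentation

`docs/methods.md` describes the model, its numerical conventions, the
synthetic-data generator's scope and the design decisions in detail.
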