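"""Binary point matching: slide a template over a survey spectrogram.

The match score at alignment offset ``t`` is the mean dB level over the
template's on cells minus the mean over its off cells, both read from
the survey spectrogram at that offset.  A well-aligned call makes the on
region "hot" relative to the off region, so scores are dB differences:
a score of 3 means the on region averages 3 dB louder than the off
region.  Because the score is a difference of means, adding a constant
gain to every survey cell leaves the trace unchanged — matching is
insensitive to overall recording level.

Detections are local maxima of the score trace at or above a score
cut-off, with greedy suppression of nearby lower peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .audio import AudioClip, Spectrogram, compute_spectrogram, read_wav, resample_clip
from .templates import BinaryTemplate

__all__ = [
    "ScoreTrace",
    "Detection",
    "score_template",
    "find_detections",
    "run_recogniser",
    "detections_to_frame",
    "DETECTION_COLUMNS",
]

log = logging.getLogger(__name__)

#: Column order of every detection table written by this module.
DETECTION_COLUMNS = ("survey_id", "template_name", "species", "time_s", "score")


@dataclass
class ScoreTrace:
    """Per-offset match scores for one template against one survey file.

    ``time_axis[t]`` is the survey time (seconds) at which the template
    start is aligned for offset ``t``.  The trace has
    ``survey_frames − duration_frames + 1`` entries (empty when the
    survey is shorter than the template).
    """

    scores: np.ndarray
    time_axis: np.ndarray
    template_name: str
    survey_id: str
    species: str = ""


@dataclass(frozen=True)
class Detection:
    """One thresholded peak of a score trace."""

    survey_id: str
    template_name: str
    species: str
    time: float
    score: float


def score_template(template: BinaryTemplate, survey: Spectrogram) -> ScoreTrace:
    """Score every alignment of ``template`` against ``survey``.

    The survey spectrogram must have been computed with the template's
    window size, overlap and sample rate (bin geometry must agree).  If
    the template has no off points the off mean is replaced by the
    survey's floor level.
    """
    if survey.params.window_size != template.window_size:
        raise ValueError(
            f"window_size mismatch: template {template.window_size}, "
            f"survey {survey.params.window_size}"
        )
    if abs(survey.params.overlap_fraction - template.overlap_fraction) > 1e-12:
        raise ValueError("overlap_fraction mismatch between template and survey")
    if survey.sample_rate != template.sample_rate:
        raise ValueError(
            f"sample_rate mismatch: template {template.sample_rate}, "
            f"survey {survey.sample_rate}"
        )

    dur = template.duration_frames
    hop_s = template.params.hop / template.sample_rate
    n_offsets = survey.n_frames - dur + 1
    if n_offsets <= 0:
        warnings.warn(
            f"survey {survey.n_frames} frames shorter than template {dur}; "
            "empty score trace",
            stacklevel=2,
        )
        return ScoreTrace(
            scores=np.empty(0),
            time_axis=np.empty(0),
            template_name=template.name,
            survey_id="",
            species=template.species,
        )

    rows = np.asarray(template.band_bins)
    row_index = {b: i for i, b in enumerate(rows)}
    band = survey.amplitude[rows, :]

    on_mask = np.zeros((rows.size, dur))
    for p in template.on_points:
        on_mask[row_index[p.freq_bin], p.frame_offset] = 1.0
    off_mask = np.zeros((rows.size, dur))
    for p in template.off_points:
        off_mask[row_index[p.freq_bin], p.frame_offset] = 1.0

    # Sliding sums over on/off cells, accumulated frame column by frame
    # column: exact float arithmetic, no FFT round-off.
    on_sum = np.zeros(n_offsets)
    off_sum = np.zeros(n_offsets)
    for fo in range(dur):
        cols = band[:, fo:fo + n_offsets]
        w_on = on_mask[:, fo]
        if w_on.any():
            on_sum += w_on @ cols
        w_off = off_mask[:, fo]
        if w_off.any():
            off_sum += w_off @ cols

    n_on = len(template.on_points)
    n_off = len(template.off_points)
    if n_off:
        scores = on_sum / n_on - off_sum / n_off
    else:
        scores = on_sum / n_on - survey.floor_db

    times = np.arange(n_offsets) * hop_s
    return ScoreTrace(
        scores=scores,
        time_axis=times,
        template_name=template.name,
        survey_id="",
        species=template.species,
    )


def _plateau_peaks(scores: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau counts once, at its first frame."""
    peaks: list[int] = []
    n = scores.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[j + 1] == scores[i]:
            j += 1
        left_ok = i == 0 or scores[i - 1] < scores[i]
        right_ok = j == n - 1 or scores[j + 1] < scores[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def find_detections(
    trace: ScoreTrace,
    score_cutoff: float,
    min_separation_frames: int,
) -> list[Detection]:
    """Threshold and peak-pick a score trace.

    Returns the local maxima with score ≥ ``score_cutoff``, greedily
    suppressing any peak closer than ``min_separation_frames`` frames to
    an already-accepted higher peak.  Ties break toward the earlier
    frame (a plateau is reported at its first frame).  Output is sorted
    by time.
    """
    if min_separation_frames < 1:
        raise ValueError("min_separation_frames must be >= 1")
    scores = np.asarray(trace.scores)
    if scores.size == 0:
        return []

    candidates = [i for i in _plateau_peaks(scores) if scores[i] >= score_cutoff]
    candidates.sort(key=lambda i: (-scores[i], i))
    accepted: list[int] = []
    for i in candidates:
        if all(abs(i - a) >= min_separation_frames for a in accepted):
            accepted.append(i)
    accepted.sort()

    return [
        Detection(
            survey_id=trace.survey_id,
            template_name=trace.template_name,
            species=trace.species,
            time=float(trace.time_axis[i]),
            score=float(scores[i]),
        )
        for i in accepted
    ]


def detections_to_frame(detections: Iterable[Detection]) -> pd.DataFrame:
    """Detection records as a DataFrame with the documented column order."""
    rows = [
        (d.survey_id, d.template_name, d.species, d.time, d.score)
        for d in detections
    ]
    return pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))


def run_recogniser(
    templates: Sequence[BinaryTemplate],
    survey_paths: Sequence[str | Path],
    cutoffs: Mapping[str, float] | None = None,
    *,
    min_separation_frames: int | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Batch-run recognisers over survey files; return the detection table.

    Each template needs a score cut-off, either from ``cutoffs`` (keyed
    by template name) or from its own calibrated ``score_cutoff`` field.
    Survey audio at a different sample rate is resampled to the
    template's rate (logged).  Unreadable files are skipped with a
    logged error so one bad file does not abort a batch.
    """
    cutoffs = dict(cutoffs or {})
    for t in templates:
        if t.name not in cutoffs:
            if t.score_cutoff is None:
                raise ValueError(f"template {t.name!r} has no score cut-off")
            cutoffs[t.name] = t.score_cutoff

    all_detections: list[Detection] = []
    for path in survey_paths:
        try:
            clip = read_wav(path)
        except (OSError, ValueError) as exc:
            log.error("skipping unreadable survey file %s: %s", path, exc)
            continue
        spec_cache: dict[tuple, Spectrogram] = {}
        for template in templates:
            key = (template.window_size, template.overlap_fraction, template.sample_rate)
            if key not in spec_cache:
                use = clip
                if clip.sample_rate != template.sample_rate:
                    log.info(
                        "resampling %s from %d to %d Hz to match template geometry",
                        path, clip.sample_rate, template.sample_rate,
                    )
                    use = resample_clip(clip, template.sample_rate)
                spec_cache[key] = compute_spectrogram(use, template.params)
            trace = score_template(template, spec_cache[key])
            trace.survey_id = clip.source_id
            sep = min_separation_frames or template.duration_frames
            found = find_detections(trace, cutoffs[template.name], sep)
            log.debug("%s × %s: %d detections", clip.source_id, template.name, len(found))
            all_detections.extend(found)

    table = detections_to_frame(all_detections)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
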