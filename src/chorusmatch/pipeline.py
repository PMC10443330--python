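"""End-to-end glue: reference-call extraction, batch spectrograms, and
the build → calibrate → evaluate workflow over a directory of surveys.

These helpers wire the single-purpose modules together the way a survey
campaign uses them: cut a reference call out of a recording (with a
time buffer), binarise it into a template, sweep score cut-offs against
an annotated file set, and report file-level performance at the chosen
cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .audio import Spectrogram, SpectrogramParams, compute_spectrogram, read_wav, resample_clip
from .calibration import CalibrationResult, select_optimal_cutoff, sweep_cutoffs
from .evaluation import (
    AnnotatedFile,
    ConfusionCounts,
    PerformanceMetrics,
    annotations_from_table,
    compute_metrics,
    tally,
)
from .matching import detections_to_frame, find_detections, score_template
from .templates import BinaryTemplate, ReferenceCall, make_binary_template

__all__ = [
    "extract_reference_call",
    "load_survey_spectrograms",
    "calibrate_template",
    "evaluate_template",
]


def extract_reference_call(
    wav_path: str | Path,
    onset_s: float,
    offset_s: float,
    species: str,
    *,
    site: str = "",
    buffer_s: float = 0.15,
) -> ReferenceCall:
    """Cut a call segment (with a time buffer on both sides) out of a file."""
    clip = read_wav(wav_path)
    segment = clip.segment(max(onset_s - buffer_s, 0.0),
                           min(offset_s + buffer_s, clip.duration))
    return ReferenceCall(
        clip=segment, species=species, site=site, time_buffer_s=buffer_s,
        provenance=f"{Path(wav_path).name}:{onset_s:.3f}-{offset_s:.3f}",
    )


def load_survey_spectrograms(
    wav_paths: Sequence[str | Path],
    params: SpectrogramParams,
    target_rate: int | None = None,
) -> dict[str, Spectrogram]:
    """Spectrograms keyed by file name, resampling to ``target_rate`` if set."""
    out: dict[str, Spectrogram] = {}
    for path in wav_paths:
        clip = read_wav(path)
        if target_rate is not None and clip.sample_rate != target_rate:
            clip = resample_clip(clip, target_rate)
        out[clip.source_id] = compute_spectrogram(clip, params)
    return out


def calibrate_template(
    template: BinaryTemplate,
    wav_paths: Sequence[str | Path],
    annotation_table: pd.DataFrame,
    *,
    start: float = 3.0,
    step: float = 0.2,
    stop: float | None = None,
) -> CalibrationResult:
    """Sweep score cut-offs for one template over annotated survey files."""
    surveys = load_survey_spectrograms(wav_paths, template.params,
                                       target_rate=template.sample_rate)
    annotations = annotations_from_table(annotation_table)
    curve = sweep_cutoffs(template, surveys, annotations,
                          start=start, step=step, stop=stop)
    return select_optimal_cutoff(curve)


def evaluate_template(
    template: BinaryTemplate,
    wav_paths: Sequence[str | Path],
    annotation_table: pd.DataFrame,
    score_cutoff: float | None = None,
) -> tuple[ConfusionCounts, PerformanceMetrics, pd.DataFrame]:
    """Run one recogniser at a fixed score cut-off and tally performance.

    Returns the confusion counts, the derived metrics and the detection
    table.  ``score_cutoff`` defaults to the template's calibrated one.
    """
    cutoff = score_cutoff if score_cutoff is not None else template.score_cutoff
    if cutoff is None:
        raise ValueError(f"template {template.name!r} has no score cut-off")
    surveys = load_survey_spectrograms(wav_paths, template.params,
                                       target_rate=template.sample_rate)
    annotations = annotations_from_table(annotation_table)
    detections = []
    for survey_id, spec in surveys.items():
        trace = score_template(template, spec)
        trace.survey_id = survey_id
        detections.extend(find_detections(trace, cutoff, template.duration_frames))
    table = detections_to_frame(detections)
    counts = tally(table, annotations, template.species)
    return counts, compute_metrics(counts), table
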