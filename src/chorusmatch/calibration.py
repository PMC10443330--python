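"""Score cut-off calibration by sweeping an ROC-value curve.

The score cut-off is the principal tuning knob of a recogniser: it sets
how similar a stretch of survey audio must be to the template before a
detection is returned.  Calibration sweeps cut-offs from a permissive
starting value (default 3, i.e. the on region at least 3 dB hotter than
the off region) upward in small increments (default 0.2), tallies
file-level confusion counts at each cut-off against the annotations,
and picks the cut-off with the highest ROC value — the proportion of
evaluation files classified correctly.  Ties break toward the higher
cut-off, which yields fewer false positives at equal accuracy.

Score traces are matched once per file and re-thresholded per cut-off;
``mode="rematch"`` instead re-runs the full matcher at every cut-off
(the two are equivalent; re-thresholding is just faster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .audio import Spectrogram
from .evaluation import AnnotatedFile, ConfusionCounts, compute_metrics, tally
from .matching import ScoreTrace, detections_to_frame, find_detections, score_template
from .templates import BinaryTemplate

__all__ = [
    "RocCurve",
    "RocPoint",
    "CalibrationResult",
    "sweep_cutoffs",
    "select_optimal_cutoff",
    "rank_templates",
    "plot_roc_curves",
]


@dataclass(frozen=True)
class RocPoint:
    score_cutoff: float
    counts: ConfusionCounts
    roc_value: float


@dataclass(frozen=True)
class RocCurve:
    """ROC value as a function of score cut-off for one template."""

    points: tuple[RocPoint, ...]
    template_name: str
    species: str

    @property
    def cutoffs(self) -> np.ndarray:
        return np.array([p.score_cutoff for p in self.points])

    @property
    def roc_values(self) -> np.ndarray:
        return np.array([p.roc_value for p in self.points])


@dataclass(frozen=True)
class CalibrationResult:
    template_name: str
    species: str
    optimal_cutoff: float
    counts: ConfusionCounts
    roc_value: float
    curve: RocCurve


def _cutoff_grid(start: float, step: float, stop: float) -> list[float]:
    if step <= 0:
        raise ValueError("step must be positive")
    if not start < stop:
        raise ValueError("start must be below stop")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def sweep_cutoffs(
    template: BinaryTemplate,
    surveys: Mapping[str, Spectrogram],
    annotations: Sequence[AnnotatedFile],
    *,
    start: float = 3.0,
    step: float = 0.2,
    stop: float | None = None,
    min_separation_frames: int | None = None,
    mode: str = "rethreshold",
) -> RocCurve:
    """Build the ROC-value curve for one template over a cut-off grid.

    ``stop`` defaults to the ceiling of the maximum observed trace score,
    so the grid always brackets the optimum.  ``surveys`` maps survey_id
    to the file's spectrogram (same STFT geometry as the template).
    """
    if not annotations:
        raise ValueError("no annotated files to calibrate against")
    if mode not in ("rethreshold", "rematch"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    sep = min_separation_frames or template.duration_frames

    def match_all() -> dict[str, ScoreTrace]:
        traces = {}
        for survey_id, spec in surveys.items():
            trace = score_template(template, spec)
            trace.survey_id = survey_id
            traces[survey_id] = trace
        return traces

    traces = match_all()
    max_score = max(
        (float(t.scores.max()) for t in traces.values() if t.scores.size),
        default=start,
    )
    if stop is None:
        stop = max(math.ceil(max_score), start + step)

    points = []
    for cutoff in _cutoff_grid(start, step, stop):
        if mode == "rematch":
            traces = match_all()  # full matching repeated at every cut-off
        detections = []
        for trace in traces.values():
            detections.extend(find_detections(trace, cutoff, sep))
        counts = tally(detections_to_frame(detections), annotations, template.species)
        points.append(RocPoint(cutoff, counts, compute_metrics(counts).roc_value))

    return RocCurve(points=tuple(points), template_name=template.name,
                    species=template.species)


def select_optimal_cutoff(curve: RocCurve) -> CalibrationResult:
    """Pick the cut-off maximising ROC value; ties go to the higher cut-off."""
    if not curve.points:
        raise ValueError("empty ROC curve")
    best = curve.points[0]
    for point in curve.points[1:]:
        if point.roc_value >= best.roc_value:
            best = point
    return CalibrationResult(
        template_name=curve.template_name,
        species=curve.species,
        optimal_cutoff=best.score_cutoff,
        counts=best.counts,
        roc_value=best.roc_value,
        curve=curve,
    )


def rank_templates(
    results: Sequence[CalibrationResult],
    keep: int = 3,
) -> pd.DataFrame:
    """Rank calibrated templates per species by ROC value at optimum.

    The top ``keep`` templates per species are flagged as the species'
    final recogniser; the rest carry an exclusion flag.  Ordering is
    deterministic (ties broken by template name) and invariant to the
    input order.
    """
    if not results:
        raise ValueError("no calibration results to rank")
    rows = [
        {
            "species": r.species,
            "template_name": r.template_name,
            "optimal_cutoff": r.optimal_cutoff,
            "roc_value": r.roc_value,
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values(
        ["species", "roc_value", "template_name"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = table.groupby("species").cumcount() + 1
    table["selected"] = table["rank"] <= keep
    table["excluded"] = ~table["selected"]
    return table


def plot_roc_curves(curves: Sequence[RocCurve], path=None):
    """ROC value vs score cut-off, one line per template; returns the figure."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for curve in curves:
        ax.plot(curve.cutoffs, curve.roc_values, marker=".", label=curve.template_name)
    ax.set_xlabel("Score cut-off")
    ax.set_ylabel("ROC value")
    ax.set_ylim(0.0, 1.05)
    if curves:
        ax.legend()
        ax.set_title(f"Score cut-off calibration — {curves[0].species}")
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
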