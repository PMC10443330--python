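"""Confusion accounting and performance metrics for recognisers.

Evaluation is at two levels.  Call level: every detection in a file
where the species is present counts as a true positive, every other
detection as a false positive (the annotations are per-file
presence/absence, so a detection cannot be checked against an individual
call).  File (survey) level: a file with at least one detection is
classified "detected"; cross-tabulating against presence gives the PA
(presence/absence) TP/FP/FN/TN counts.

Derived metrics::

    call_precision   = count_tp / (count_tp + count_fp)
    survey_precision = pa_tp / (pa_tp + pa_fp)
    survey_recall    = pa_tp / (pa_tp + pa_fn)
    roc_value        = (pa_tp + pa_tn) / n_files

``roc_value`` is a file-level accuracy — the proportion of evaluation
files classified correctly — NOT the area under an ROC curve.  Ratios
with a zero denominator are reported as missing (None), never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AnnotatedFile",
    "ConfusionCounts",
    "PerformanceMetrics",
    "tally",
    "compute_metrics",
    "evaluation_report",
    "load_annotations",
    "annotations_from_table",
    "round_half_away",
]

#: Column order of the evaluation report, mirroring the standard
#: per-template performance table.
REPORT_COLUMNS = (
    "species", "template_name", "count_fp", "count_tp", "call_precision",
    "pa_fp", "pa_tp", "pa_fn", "pa_tn",
    "survey_precision", "survey_recall", "roc",
)


def round_half_away(x: float, ndigits: int) -> float:
    """Round with halves away from zero (matches how the report tables
    are conventionally printed, unlike Python's banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class AnnotatedFile:
    """Per-file ground truth: which species are present in a survey file."""

    survey_id: str
    species_present: frozenset[str]
    duration: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_present", frozenset(self.species_present))


@dataclass(frozen=True)
class ConfusionCounts:
    """Call-level detection counts and file-level PA confusion counts."""

    count_tp: int
    count_fp: int
    pa_tp: int
    pa_fp: int
    pa_fn: int
    pa_tn: int
    n_files: int

    def __post_init__(self) -> None:
        fields = (self.count_tp, self.count_fp, self.pa_tp, self.pa_fp,
                  self.pa_fn, self.pa_tn, self.n_files)
        if any(v < 0 for v in fields):
            raise ValueError("confusion counts must be non-negative")
        if self.pa_tp + self.pa_fp + self.pa_fn + self.pa_tn != self.n_files:
            raise ValueError(
                "PA counts must sum to the number of evaluation files "
                f"({self.pa_tp}+{self.pa_fp}+{self.pa_fn}+{self.pa_tn} != {self.n_files})"
            )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Derived metrics; a field is None when its denominator is zero."""

    call_precision: float | None
    survey_precision: float | None
    survey_recall: float | None
    roc_value: float


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV with columns survey_id, species, present (0/1)."""
    table = pd.read_csv(path, dtype={"survey_id": str, "species": str})
    missing = {"survey_id", "species", "present"} - set(table.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    return table


def annotations_from_table(table: pd.DataFrame) -> list[AnnotatedFile]:
    """Collapse a long-format annotation table into AnnotatedFile records."""
    files = []
    for survey_id, group in table.groupby("survey_id", sort=True):
        present = frozenset(group.loc[group["present"].astype(int) == 1, "species"])
        files.append(AnnotatedFile(survey_id=str(survey_id), species_present=present))
    return files


def tally(
    detections: pd.DataFrame,
    annotations: Sequence[AnnotatedFile],
    species: str,
) -> ConfusionCounts:
    """Tally call- and file-level confusion counts for one species.

    Every detection of ``species`` in a file where it is present is a
    call-level TP; every other detection a call-level FP (even if it is
    temporally far from any true call — file-level annotation cannot
    distinguish).  File level: ≥1 detection in a present file → PA TP;
    ≥1 in an absent file → PA FP; none in a present file → PA FN; none
    in an absent file → PA TN.

    The counts are invariant to detection ordering.  Merging detection
    tables from several templates without double-counting is the
    caller's responsibility.
    """
    ids = {a.survey_id for a in annotations}
    if len(ids) != len(annotations):
        raise ValueError("duplicate survey_id in annotations")
    present_ids = {a.survey_id for a in annotations if species in a.species_present}

    det = detections
    if "species" in det.columns and len(det):
        det = det[det["species"] == species]
    unknown = sorted(set(det["survey_id"].astype(str)) - ids) if len(det) else []
    if unknown:
        raise ValueError(f"detections reference unknown survey_id(s): {unknown}")

    prevalence = len(present_ids) / len(ids) if ids else 0.0
    if ids and not (0.3 <= prevalence <= 0.7):
        warnings.warn(
            f"evaluation set unbalanced for {species!r}: prevalence "
            f"{prevalence:.2f} is outside [0.30, 0.70]",
            stacklevel=2,
        )

    per_file = det.groupby("survey_id").size().to_dict() if len(det) else {}
    count_tp = sum(n for sid, n in per_file.items() if sid in present_ids)
    count_fp = sum(n for sid, n in per_file.items() if sid not in present_ids)

    detected = set(per_file)
    pa_tp = len(detected & present_ids)
    pa_fp = len(detected - present_ids)
    pa_fn = len(present_ids - detected)
    pa_tn = len(ids - present_ids - detected)

    return ConfusionCounts(
        count_tp=int(count_tp), count_fp=int(count_fp),
        pa_tp=pa_tp, pa_fp=pa_fp, pa_fn=pa_fn, pa_tn=pa_tn,
        n_files=len(ids),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    """Precision, recall and ROC value from confusion counts.

    ``roc_value`` is (PA TP + PA TN)/n_files, a scalar file-level
    accuracy.  It is not an area under a curve; the ROC *curve* of the
    calibrator plots this value against the score cut-off.
    """
    if counts.n_files <= 0:
        raise ValueError("n_files must be positive")
    return PerformanceMetrics(
        call_precision=_ratio(counts.count_tp, counts.count_tp + counts.count_fp),
        survey_precision=_ratio(counts.pa_tp, counts.pa_tp + counts.pa_fp),
        survey_recall=_ratio(counts.pa_tp, counts.pa_tp + counts.pa_fn),
        roc_value=(counts.pa_tp + counts.pa_tn) / counts.n_files,
    )


def evaluation_report(
    rows: Iterable[tuple[str, str, ConfusionCounts]],
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """One report row per (species, template) with counts and 3-dp metrics.

    Column order is fixed (see ``REPORT_COLUMNS``); metrics are rounded
    to 3 decimal places with halves away from zero; undefined metrics
    are left empty.
    """
    records = []
    for species, template_name, counts in rows:
        m = compute_metrics(counts)
        records.append({
            "species": species,
            "template_name": template_name,
            "count_fp": counts.count_fp,
            "count_tp": counts.count_tp,
            "call_precision": None if m.call_precision is None else round_half_away(m.call_precision, 3),
            "pa_fp": counts.pa_fp,
            "pa_tp": counts.pa_tp,
            "pa_fn": counts.pa_fn,
            "pa_tn": counts.pa_tn,
            "survey_precision": None if m.survey_precision is None else round_half_away(m.survey_precision, 3),
            "survey_recall": None if m.survey_recall is None else round_half_away(m.survey_recall, 3),
            "roc": round_half_away(m.roc_value, 3),
        })
    table = pd.DataFrame(records, columns=list(REPORT_COLUMNS))
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
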