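"""Bookkeeping of manually verified false-positive sound sources.

When a recogniser fires in a file where the species is absent, the
detection is a false positive, and knowing *what* triggered it — a
cricket band, another frog, rain on the microphone — tells you how to
improve the template.  Attribution is inherently a human-in-the-loop
step: this module exports a verification sheet for a person to label,
re-imports the labelled sheet, and summarises labels as percentages per
category, per species.

Continuous interferers (insect bands, chorusing congeners, steady rain)
tend to dominate these summaries because they can trigger detections
throughout an entire recording, whereas episodic sounds (a passing car,
a single bird phrase) contribute only a handful each.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .evaluation import AnnotatedFile, round_half_away
from .matching import DETECTION_COLUMNS, Detection

__all__ = [
    "FpCategory",
    "LabeledFp",
    "summarize_fp",
    "export_verification_sheet",
    "load_verification_sheet",
    "summary_table",
]


class FpCategory(str, Enum):
    """Closed set of interfering sound-source categories."""

    ANTHROPOGENIC = "anthropogenic"
    WATER_SOUNDS = "water_sounds"
    BIRDS = "birds"
    INSECTS = "insects"
    OTHER_GEOPHONY = "other_geophony"
    OTHER_ANIMALS = "other_animals"
    OTHER_FROGS = "other_frogs"
    WEATHER = "weather"


#: Canonical row order for pretty-printed summaries.
CATEGORY_ORDER = tuple(FpCategory)

SHEET_COLUMNS = list(DETECTION_COLUMNS) + ["category", "verifier"]


@dataclass(frozen=True)
class LabeledFp:
    """One verified false-positive detection with its attributed source."""

    detection: Detection
    category: FpCategory
    verifier: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", FpCategory(self.category))


def summarize_fp(labels: Sequence[LabeledFp], species: str) -> dict[FpCategory, float]:
    """Percentage of labelled false positives per category for one species.

    Percentages are of the species' total labelled false positives,
    rounded to 1 decimal place (half away from zero); categories with no
    labels report 0.  Before rounding the percentages sum to exactly
    100; after rounding the sum can drift by a few tenths.  The result
    is invariant to label order and to who verified each detection.
    """
    mine = [l for l in labels if l.detection.species == species]
    if not mine:
        raise ValueError(f"no labelled false positives for species {species!r}")
    total = len(mine)
    out: dict[FpCategory, float] = {}
    for cat in CATEGORY_ORDER:
        n = sum(1 for l in mine if l.category is cat)
        out[cat] = round_half_away(100.0 * n / total, 1)
    return out


def summary_table(
    summaries: dict[str, dict[FpCategory, float]],
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Combine per-species summaries into one table (categories × species)."""
    table = pd.DataFrame(
        {sp: {cat.value: pct.get(cat, 0.0) for cat in CATEGORY_ORDER}
         for sp, pct in summaries.items()}
    )
    table.index.name = "category"
    table = table.reindex([c.value for c in CATEGORY_ORDER])
    if out_csv is not None:
        table.to_csv(out_csv)
    return table


def export_verification_sheet(
    detections: pd.DataFrame,
    annotations: Sequence[AnnotatedFile],
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Sheet of unverified false positives for a human to label.

    Rows are the detections that fall in files where the detected
    species is absent per the annotations — i.e. certain false
    positives.  The ``category`` and ``verifier`` columns are left empty
    for the reviewer; the filled sheet re-imports via
    :func:`load_verification_sheet`.
    """
    present: dict[str, frozenset[str]] = {
        a.survey_id: a.species_present for a in annotations
    }
    unknown = sorted(set(detections["survey_id"].astype(str)) - set(present)) if len(detections) else []
    if unknown:
        raise ValueError(f"detections reference unknown survey_id(s): {unknown}")

    if len(detections):
        is_fp = [
            row.species not in present[str(row.survey_id)]
            for row in detections.itertuples()
        ]
        sheet = detections.loc[is_fp, list(DETECTION_COLUMNS)].copy()
    else:
        sheet = pd.DataFrame(columns=list(DETECTION_COLUMNS))
    sheet["category"] = ""
    sheet["verifier"] = ""
    sheet = sheet.reset_index(drop=True)
    if out_csv is not None:
        sheet.to_csv(out_csv, index=False)
    return sheet


def load_verification_sheet(path: str | Path) -> list[LabeledFp]:
    """Re-import a labelled verification sheet; unlabelled rows are skipped
    (the sheet supports incremental labelling across review sessions)."""
    table = pd.read_csv(path, dtype={"survey_id": str, "category": str, "verifier": str})
    missing = set(SHEET_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"verification sheet {path} lacks columns {sorted(missing)}")
    labels = []
    for row in table.itertuples():
        cat = "" if pd.isna(row.category) else str(row.category).strip()
        if not cat:
            continue
        labels.append(
            LabeledFp(
                detection=Detection(
                    survey_id=str(row.survey_id),
                    template_name=str(row.template_name),
                    species=str(row.species),
                    time=float(row.time_s),
                    score=float(row.score),
                ),
                category=FpCategory(cat),
                verifier="" if pd.isna(row.verifier) else str(row.verifier),
            )
        )
    return labels
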