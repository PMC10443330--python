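"""Binary on/off templates built from reference call clips.

A binary template partitions a rectangular spectrogram region — the
template's frequency band times its duration — into "on" cells (call)
and "off" cells (non-call) at a user-chosen amplitude cut-off: cells at
or above the cut-off are on, all others off.  Lowering the cut-off
(making it more negative) grows the on region.  One template together
with a calibrated score cut-off constitutes one recogniser.

Templates serialise losslessly to a small JSON document so that a
calibrated recogniser can be archived and re-run later.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .audio import AudioClip, Spectrogram, SpectrogramParams, compute_spectrogram

__all__ = [
    "TemplatePoint",
    "BinaryTemplate",
    "ReferenceCall",
    "make_binary_template",
    "render_template",
    "save_template",
    "load_template",
]

TEMPLATE_FORMAT_VERSION = 1


class TemplatePoint(NamedTuple):
    """One spectrogram cell of a template: absolute frequency bin and
    frame offset relative to the template start."""

    freq_bin: int
    frame_offset: int


@dataclass(frozen=True)
class ReferenceCall:
    """A manually selected call segment used to build a template.

    ``time_buffer_s`` / ``freq_buffer_hz`` record the margins kept
    around the call in the time and frequency domains so that the
    template learns some of the surrounding soundscape (the off region
    is matched too, so a little context improves discrimination).
    """

    clip: AudioClip
    species: str
    site: str = ""
    time_buffer_s: float = 0.0
    freq_buffer_hz: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.time_buffer_s < 0 or self.freq_buffer_hz < 0:
            raise ValueError("buffer margins must be non-negative")


@dataclass(frozen=True)
class BinaryTemplate:
    """On/off point sets over a (frequency band × duration) grid.

    Invariants enforced on construction: the on and off sets are
    disjoint, the on set is non-empty, and together they tile the full
    grid of in-band bins × template frames exactly.
    """

    name: str
    species: str
    on_points: frozenset[TemplatePoint]
    off_points: frozenset[TemplatePoint]
    amplitude_cutoff: float
    freq_limits: tuple[float, float]
    window_size: int
    duration_frames: int
    sample_rate: int
    overlap_fraction: float = 0.0
    score_cutoff: float | None = None
    site: str = ""

    def __post_init__(self) -> None:
        low, high = self.freq_limits
        if not low < high:
            raise ValueError(f"inverted freq_limits {self.freq_limits}")
        if not self.on_points:
            raise ValueError("empty template: no on points")
        if self.on_points & self.off_points:
            raise ValueError("on/off point sets overlap")
        band = set(self.band_bins)
        grid = {
            TemplatePoint(b, f)
            for b in band
            for f in range(self.duration_frames)
        }
        if set(self.on_points) | set(self.off_points) != grid:
            raise ValueError(
                "on/off points do not exactly tile the in-band grid"
            )

    @property
    def band_bins(self) -> tuple[int, ...]:
        """Absolute bin indices whose center frequency lies within freq_limits."""
        low, high = self.freq_limits
        df = self.sample_rate / self.window_size
        bins = [
            b for b in range(self.window_size // 2 + 1)
            if low <= b * df <= high
        ]
        return tuple(bins)

    @property
    def params(self) -> SpectrogramParams:
        return SpectrogramParams(
            window_size=self.window_size,
            overlap_fraction=self.overlap_fraction,
        )

    @property
    def duration_seconds(self) -> float:
        return self.duration_frames * self.params.hop / self.sample_rate

    def mask(self) -> np.ndarray:
        """Boolean array (in-band bins × frames); True where the cell is on."""
        rows = {b: i for i, b in enumerate(self.band_bins)}
        out = np.zeros((len(rows), self.duration_frames), dtype=bool)
        for p in self.on_points:
            out[rows[p.freq_bin], p.frame_offset] = True
        return out

    def with_score_cutoff(self, score_cutoff: float) -> "BinaryTemplate":
        return replace(self, score_cutoff=float(score_cutoff))


def make_binary_template(
    call: ReferenceCall,
    amplitude_cutoff: float,
    freq_limits: tuple[float, float],
    params: SpectrogramParams | None = None,
    *,
    name: str | None = None,
    gain_db: float = 0.0,
) -> BinaryTemplate:
    """Binarise a reference call's spectrogram into a template.

    Within ``freq_limits`` (inclusive on bin centers), cells whose level
    is at or above ``amplitude_cutoff`` dB become on points; all other
    in-band cells become off points; out-of-band cells are excluded
    entirely.  ``gain_db`` is an optional pre-gain added to every cell
    before thresholding — equivalent to lowering the cut-off — exposed
    for recordings whose amplification differs from the template's.
    """
    params = params or SpectrogramParams()
    low, high = freq_limits
    nyquist = call.clip.sample_rate / 2
    if not (0 < low < high):
        raise ValueError(f"inverted or non-positive freq_limits {freq_limits}")
    if high >= nyquist:
        raise ValueError(f"freq_limits {freq_limits} exceed Nyquist {nyquist}")

    spec = compute_spectrogram(call.clip, params)
    rows = spec.band_indices(low, high)
    if rows.size == 0:
        raise ValueError(f"freq_limits {freq_limits} contain no frequency bins")
    band = spec.amplitude[rows, :] + gain_db

    on_mask = band >= amplitude_cutoff
    if not on_mask.any():
        raise ValueError(
            f"empty template: amplitude cut-off {amplitude_cutoff} dB is above "
            "every in-band cell"
        )

    on_points, off_points = set(), set()
    for i, b in enumerate(rows):
        for f in range(band.shape[1]):
            point = TemplatePoint(int(b), int(f))
            (on_points if on_mask[i, f] else off_points).add(point)

    if name is None:
        ident = call.provenance or call.species
        name = f"{int(round(amplitude_cutoff))}_{ident}_{call.site or 'NA'}"

    return BinaryTemplate(
        name=name,
        species=call.species,
        on_points=frozenset(on_points),
        off_points=frozenset(off_points),
        amplitude_cutoff=float(amplitude_cutoff),
        freq_limits=(float(low), float(high)),
        window_size=params.window_size,
        duration_frames=band.shape[1],
        sample_rate=call.clip.sample_rate,
        overlap_fraction=params.overlap_fraction,
        site=call.site,
    )


def render_template(template: BinaryTemplate, path: str | Path | None = None):
    """Render the template as a two-colour raster (orange = on, blue = off).

    Axes are labelled in Hz and seconds.  Returns the matplotlib figure;
    if ``path`` is given the figure is also written there as PNG.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    mask = template.mask()
    df = template.sample_rate / template.window_size
    bins = template.band_bins
    hop_s = template.params.hop / template.sample_rate
    extent = (
        0.0,
        template.duration_frames * hop_s,
        bins[0] * df,
        (bins[-1] + 1) * df,
    )
    fig, ax = plt.subplots()
    ax.imshow(
        mask,
        origin="lower",
        aspect="auto",
        interpolation="nearest",
        cmap=ListedColormap(["#3366cc", "#ff8800"]),  # off, on
        vmin=0,
        vmax=1,
        extent=extent,
    )
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Frequency (Hz)")
    ax.set_title(f"{template.name} ({template.amplitude_cutoff:g} dB cut-off)")
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def _points_to_list(points: frozenset[TemplatePoint]) -> list[list[int]]:
    return sorted([p.freq_bin, p.frame_offset] for p in points)


def save_template(template: BinaryTemplate, path: str | Path) -> None:
    """Serialise a template to JSON (lossless, deterministic byte-for-byte)."""
    doc = {
        "format_version": TEMPLATE_FORMAT_VERSION,
        "name": template.name,
        "species": template.species,
        "site": template.site,
        "amplitude_cutoff": template.amplitude_cutoff,
        "freq_limits": list(template.freq_limits),
        "window_size": template.window_size,
        "duration_frames": template.duration_frames,
        "sample_rate": template.sample_rate,
        "overlap_fraction": template.overlap_fraction,
        "score_cutoff": template.score_cutoff,
        "on_points": _points_to_list(template.on_points),
        "off_points": _points_to_list(template.off_points),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


_REQUIRED_FIELDS = (
    "name", "species", "amplitude_cutoff", "freq_limits", "window_size",
    "duration_frames", "sample_rate", "on_points", "off_points",
)


def load_template(path: str | Path) -> BinaryTemplate:
    """Load a template saved by :func:`save_template`.

    Raises a schema error naming the missing field; the type invariants
    (disjoint point sets, exact tiling) are re-validated on load.
    """
    doc = json.loads(Path(path).read_text())
    for key in _REQUIRED_FIELDS:
        if key not in doc:
            raise ValueError(f"template file {path}: missing field '{key}'")
    return BinaryTemplate(
        name=doc["name"],
        species=doc["species"],
        site=doc.get("site", ""),
        on_points=frozenset(TemplatePoint(int(b), int(f)) for b, f in doc["on_points"]),
        off_points=frozenset(TemplatePoint(int(b), int(f)) for b, f in doc["off_points"]),
        amplitude_cutoff=float(doc["amplitude_cutoff"]),
        freq_limits=tuple(float(x) for x in doc["freq_limits"]),
        window_size=int(doc["window_size"]),
        duration_frames=int(doc["duration_frames"]),
        sample_rate=int(doc["sample_rate"]),
        overlap_fraction=float(doc.get("overlap_fraction", 0.0)),
        score_cutoff=doc.get("score_cutoff"),
    )
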