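"""WAV input and decibel spectrograms.

Every downstream stage — template construction, binary point matching,
score-cut-off calibration — operates on magnitude spectrograms expressed
in decibels relative to the spectrogram's own global maximum.  Under this
convention the loudest cell of any clip sits at exactly 0 dB, which makes
template amplitude cut-offs such as −31 dB portable across recordings
made at different gains or distances from the sensor.

Frames are laid out with 0-based indices and half-open intervals: frame
``t`` covers samples ``[t*hop, t*hop + window_size)``, frequency bin 0 is
DC, and only bins in ``[0, Nyquist]`` are kept.  The frame count is
``floor((n_samples − window_size)/hop) + 1`` with
``hop = window_size*(1 − overlap_fraction)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

__all__ = [
    "AudioClip",
    "SpectrogramParams",
    "Spectrogram",
    "read_wav",
    "compute_spectrogram",
    "resample_clip",
    "DB_FLOOR_DEFAULT",
]

#: dB value assigned to zero-magnitude cells and to fully silent clips.
DB_FLOOR_DEFAULT = -120.0

#: Window sizes used by typical field protocols; others work but warn.
_PREFERRED_WINDOW_SIZES = (256, 512, 1024)

#: Reference-convention tag attached to every spectrogram.
DB_REFERENCE_TAG = "dB re spectrogram global maximum"


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform in [−1, 1] with its sample rate.

    Parameters
    ----------
    samples
        1-D float array; values are expected (not enforced) in [−1, 1].
    sample_rate
        Sampling frequency in Hz; must be a positive integer.
    source_id
        Opaque identifier of the originating file, used to label
        detections.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip.samples must be one-dimensional")
        if samples.size < 1:
            raise ValueError("AudioClip must contain at least one sample")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.sample_rate

    def segment(self, start_s: float, end_s: float, source_id: str | None = None) -> "AudioClip":
        """Return the sub-clip covering ``[start_s, end_s)`` seconds, clamped to the clip."""
        i0 = max(0, int(round(start_s * self.sample_rate)))
        i1 = min(self.samples.size, int(round(end_s * self.sample_rate)))
        if i1 <= i0:
            raise ValueError(f"empty segment [{start_s}, {end_s}) requested")
        return AudioClip(self.samples[i0:i1], self.sample_rate,
                         source_id=source_id if source_id is not None else self.source_id)


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT parameters shared by template construction and matching.

    ``window_size`` of 512 samples suits most pulsed and tonal frog
    calls at 44.1 kHz; 256 trades frequency resolution for time
    resolution (useful for highly pulsatile calls).
    """

    window_size: int = 512
    overlap_fraction: float = 0.0
    window_function: str = "hamming"

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.window_size not in _PREFERRED_WINDOW_SIZES:
            warnings.warn(
                f"window_size {self.window_size} is outside the usual "
                f"{_PREFERRED_WINDOW_SIZES}; proceeding anyway",
                stacklevel=2,
            )
        if self.hop < 1:
            raise ValueError("overlap_fraction too large: hop would be zero")

    @property
    def hop(self) -> int:
        """Samples between consecutive frame starts."""
        return int(round(self.window_size * (1.0 - self.overlap_fraction)))


@dataclass
class Spectrogram:
    """A dB magnitude spectrogram (rows = frequency bins, columns = frames).

    ``amplitude[i, j]`` is the level of bin ``i`` in frame ``j`` in dB
    relative to the global maximum cell, so ``amplitude.max() == 0`` for
    any non-silent clip.  Zero-magnitude cells (and all cells of a silent
    clip) are floored at ``floor_db``.
    """

    amplitude: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    params: SpectrogramParams
    sample_rate: int
    floor_db: float = DB_FLOOR_DEFAULT
    reference: str = DB_REFERENCE_TAG

    @property
    def n_bins(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.amplitude.shape[1]

    def band_indices(self, low_hz: float, high_hz: float) -> np.ndarray:
        """Indices of bins whose center frequency lies in [low_hz, high_hz]."""
        if not low_hz < high_hz:
            raise ValueError(f"inverted frequency limits ({low_hz}, {high_hz})")
        return np.nonzero((self.freq_axis >= low_hz) & (self.freq_axis <= high_hz))[0]


def _normalise_pcm(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to float in [−1, 1] by the dtype's full scale."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise ValueError(f"unsupported WAV sample format {data.dtype}")


def read_wav(path: str | Path) -> AudioClip:
    """Read a RIFF WAV file as a mono :class:`AudioClip`.

    Multichannel files are reduced to their first channel (with a
    warning).  Integer PCM is normalised to [−1, 1] by the dtype's full
    scale, so a full-scale 16-bit sample maps to ±32767/32768.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # corrupt header, truncated file, ...
        raise OSError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path}")
    if data.ndim == 2:
        warnings.warn(f"{path.name}: multichannel file, using channel 1 only", stacklevel=2)
        data = data[:, 0]
    samples = _normalise_pcm(np.asarray(data))
    return AudioClip(samples, int(rate), source_id=path.name)


def compute_spectrogram(
    clip: AudioClip,
    params: SpectrogramParams | None = None,
    floor_db: float = DB_FLOOR_DEFAULT,
) -> Spectrogram:
    """Compute the dB spectrogram of ``clip``.

    The magnitude STFT is converted to dB as ``20*log10(|X|/max|X|)`` so
    the global maximum is exactly 0 dB.  An all-zero clip has no valid
    reference; it yields an all-floor spectrogram with a warning rather
    than an error, since survey files can contain near-silence.
    """
    params = params or SpectrogramParams()
    w = params.window_size
    n = clip.samples.size
    if n < w:
        raise ValueError(
            f"clip of {n} samples is shorter than one window ({w} samples)"
        )
    hop = params.hop
    n_frames = (n - w) // hop + 1
    frames = sliding_window_view(clip.samples, w)[::hop][:n_frames]
    window = get_window(params.window_function, w, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * window, axis=1)).T  # (bins, frames)

    peak = mag.max()
    if peak == 0.0:
        warnings.warn(
            "silent clip: no valid dB reference, returning all-floor spectrogram",
            stacklevel=2,
        )
        db = np.full(mag.shape, floor_db)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag / peak)
        db = np.maximum(db, floor_db)

    starts = np.arange(n_frames) * hop
    return Spectrogram(
        amplitude=db,
        freq_axis=np.fft.rfftfreq(w, 1.0 / clip.sample_rate),
        time_axis=(starts + w / 2.0) / clip.sample_rate,
        params=params,
        sample_rate=clip.sample_rate,
        floor_db=floor_db,
    )


def resample_clip(clip: AudioClip, target_rate: int) -> AudioClip:
    """Resample ``clip`` to ``target_rate`` Hz (polyphase filtering).

    Needed before matching when a survey file's rate differs from the
    rate the template was built at: bin geometry must agree.
    """
    if target_rate == clip.sample_rate:
        return clip
    ratio = Fraction(int(target_rate), int(clip.sample_rate))
    resampled = resample_poly(clip.samples, ratio.numerator, ratio.denominator)
    return AudioClip(np.asarray(resampled, dtype=np.float64), int(target_rate),
                     source_id=clip.source_id)
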