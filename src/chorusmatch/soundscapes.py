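"""Ground-truthed synthetic soundscapes for recogniser development.

Field evaluation data for frog recognisers are rarely shareable, so this
module fabricates survey files with known content: a broadband noise
floor, continuous and episodic interferers (insect bands, rain,
bird-like chirps, competing calls), and planted frog-like calls at
controlled signal-to-noise ratios.  The calls are not playback-quality
imitations — they only need the spectro-temporal structure (pulse
trains, tones, harmonic stacks in the 0.3–4 kHz frog band) that the
template matcher keys on.

SNR contract: a call planted at ``snr_db`` has its band-limited RMS —
measured within the call's frequency band over the call's duration —
exactly ``snr_db`` decibels above the band-limited RMS of the background
it is mixed into.  All randomness flows from a single integer seed;
regenerating with the same seed is bit-identical.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, chirp, sosfiltfilt
from scipy.signal.windows import tukey

from .audio import AudioClip

__all__ = [
    "CallModel",
    "Interferer",
    "PlantedCall",
    "SoundscapeSpec",
    "GroundTruth",
    "EvaluationSet",
    "synthesize_call",
    "synthesize_soundscape",
    "generate_evaluation_set",
    "write_wav",
    "default_interferers",
    "DEFAULT_SPECIES",
]

DEFAULT_SAMPLE_RATE = 44_100
DEFAULT_DURATION_S = 60.0
DEFAULT_NOISE_FLOOR_DB = -60.0

CALL_TYPES = ("pulsatile", "tonal", "harmonic_stack")
INTERFERER_KINDS = ("insect_band", "rain_broadband", "bird_chirp", "competing_call")


@dataclass(frozen=True)
class CallModel:
    """Parametric description of a synthetic call.

    ``pulsatile`` — a carrier tone amplitude-modulated by a smooth pulse
    train at ``pulse_rate`` (crackly Crinia-style calls).  ``tonal`` — a
    single windowed sinusoid (short "bonk"-style notes).
    ``harmonic_stack`` — a fundamental plus decaying harmonics (honks
    and whirring calls).  ``bandwidth`` describes the nominal spectral
    extent used for band-limited SNR measurement and for choosing
    template frequency limits.
    """

    call_type: str
    carrier_freq: float
    bandwidth: float
    duration: float
    pulse_rate: float | None = None
    amplitude: float = 1.0
    n_harmonics: int = 3

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call_type {self.call_type!r}")
        if self.duration <= 0:
            raise ValueError("call duration must be positive")
        if self.call_type == "pulsatile" and not self.pulse_rate:
            raise ValueError("pulsatile calls need a pulse_rate")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def band(self, min_half_width: float = 50.0) -> tuple[float, float]:
        """Frequency band (Hz) used for SNR measurement and templates."""
        half = max(self.bandwidth / 2.0, min_half_width)
        return (max(self.carrier_freq - half, 10.0), self.carrier_freq + half)


#: Default species models emulating a mixed frog chorus in the
#: 0.3–4 kHz band: a pulsatile 2.8 kHz call, a short low tonal "bonk",
#: and a mid-band harmonic call.
DEFAULT_SPECIES: dict[str, CallModel] = {
    "crinia_like": CallModel("pulsatile", carrier_freq=2800.0, bandwidth=600.0,
                             duration=0.8, pulse_rate=20.0),
    "banjo_like": CallModel("tonal", carrier_freq=620.0, bandwidth=150.0,
                            duration=0.25),
    "peron_like": CallModel("harmonic_stack", carrier_freq=1100.0,
                            bandwidth=400.0, duration=0.9),
}


@dataclass(frozen=True)
class Interferer:
    """A background sound source.

    ``level_db`` is the RMS level relative to digital full scale over
    the interferer's active span.  ``duration=None`` means the whole
    file (continuous interferers such as insect bands); episodic kinds
    place events at ``rate_per_min`` within the span.
    """

    kind: str
    level_db: float
    start: float = 0.0
    duration: float | None = None
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in INTERFERER_KINDS:
            raise ValueError(f"unknown interferer kind {self.kind!r}")


@dataclass(frozen=True)
class PlantedCall:
    model: CallModel
    onset: float
    snr_db: float
    species: str


@dataclass(frozen=True)
class SoundscapeSpec:
    """Recipe for one synthetic survey file; ``seed`` is mandatory."""

    seed: int
    duration: float = DEFAULT_DURATION_S
    sample_rate: int = DEFAULT_SAMPLE_RATE
    noise_floor_db: float = DEFAULT_NOISE_FLOOR_DB
    interferers: tuple[Interferer, ...] = ()
    planted_calls: tuple[PlantedCall, ...] = ()
    survey_id: str = "soundscape"

    def __post_init__(self) -> None:
        object.__setattr__(self, "interferers", tuple(self.interferers))
        object.__setattr__(self, "planted_calls", tuple(self.planted_calls))
        for call in self.planted_calls:
            if call.onset < 0 or call.onset + call.model.duration > self.duration:
                raise ValueError(
                    f"over-full schedule: call at {call.onset:.2f}s "
                    f"(+{call.model.duration:.2f}s) exceeds file duration "
                    f"{self.duration}s"
                )


@dataclass
class GroundTruth:
    """Exact content of one generated file, consistent with its WAV."""

    survey_id: str
    species_present: tuple[str, ...]
    calls: list[dict]
    interferers: list[dict]


@dataclass
class EvaluationSet:
    """Paths of a generated evaluation corpus."""

    audio_dir: Path
    annotation_path: Path
    ground_truth_path: Path
    interferer_log_path: Path
    survey_ids: list[str]

    @property
    def wav_paths(self) -> list[Path]:
        return [self.audio_dir / sid for sid in self.survey_ids]


def synthesize_call(model: CallModel, sample_rate: int) -> AudioClip:
    """Render one call; peak-normalised then scaled by ``model.amplitude``."""
    nyquist = sample_rate / 2.0
    if model.carrier_freq + model.bandwidth / 2.0 >= nyquist:
        raise ValueError(
            f"carrier {model.carrier_freq} Hz + bandwidth/2 reaches Nyquist "
            f"({nyquist} Hz)"
        )
    n = max(int(round(model.duration * sample_rate)), 1)
    t = np.arange(n) / sample_rate
    envelope = tukey(n, alpha=0.2)

    if model.call_type == "tonal":
        x = np.sin(2 * np.pi * model.carrier_freq * t) * envelope
    elif model.call_type == "harmonic_stack":
        x = np.zeros(n)
        for k in range(1, model.n_harmonics + 1):
            f = k * model.carrier_freq
            if f >= nyquist:
                break
            x += np.sin(2 * np.pi * f * t) / k
        x *= envelope
    else:  # pulsatile: raised-cosine pulse train, cubed to sharpen pulses
        pulses = (0.5 * (1.0 - np.cos(2 * np.pi * model.pulse_rate * t))) ** 3
        x = np.sin(2 * np.pi * model.carrier_freq * t) * pulses * envelope

    peak = np.abs(x).max()
    if peak > 0 and model.amplitude > 0:
        x = x / peak * model.amplitude
    else:
        x = np.zeros(n)
    return AudioClip(x, sample_rate, source_id=f"call_{model.call_type}")


def _band_sos(band: tuple[float, float], sample_rate: int):
    low, high = band
    nyquist = sample_rate / 2.0
    low = max(low, 1.0)
    high = min(high, nyquist * 0.999)
    return butter(4, [low, high], btype="bandpass", fs=sample_rate, output="sos")


def _band_rms(x: np.ndarray, band: tuple[float, float], sample_rate: int) -> float:
    y = sosfiltfilt(_band_sos(band, sample_rate), x)
    return float(np.sqrt(np.mean(y ** 2)))


def _render_interferer(
    intf: Interferer, n_total: int, fs: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    """Waveform of one interferer plus its log entries."""
    out = np.zeros(n_total)
    level = 10.0 ** (intf.level_db / 20.0)
    start = int(round(intf.start * fs))
    span_s = intf.duration if intf.duration is not None else n_total / fs - intf.start
    stop = min(n_total, start + int(round(span_s * fs)))
    seg_len = stop - start
    if seg_len <= 0:
        return out, []
    log_entries = [{
        "kind": intf.kind, "start_s": start / fs, "duration_s": seg_len / fs,
        "level_db": intf.level_db,
    }]
    p = dict(intf.params)

    if intf.kind == "insect_band":
        center = float(p.get("center_freq", 3800.0))
        bw = float(p.get("bandwidth", 400.0))
        noise = rng.standard_normal(seg_len)
        band = (center - bw / 2.0, center + bw / 2.0)
        shaped = sosfiltfilt(_band_sos(band, fs), noise)
        rms = np.sqrt(np.mean(shaped ** 2))
        if rms > 0:
            out[start:stop] = shaped / rms * level
    elif intf.kind == "rain_broadband":
        out[start:stop] = rng.standard_normal(seg_len) * level
    elif intf.kind == "bird_chirp":
        f0 = float(p.get("f0", 2000.0))
        f1 = float(p.get("f1", 2800.0))
        chirp_dur = float(p.get("chirp_duration", 0.2))
        rate = float(p.get("rate_per_min", 4.0))
        n_events = int(round(rate * (seg_len / fs) / 60.0))
        n_chirp = int(round(chirp_dur * fs))
        tt = np.arange(n_chirp) / fs
        proto = chirp(tt, f0=f0, f1=f1, t1=chirp_dur) * np.hanning(n_chirp)
        rms = np.sqrt(np.mean(proto ** 2))
        proto = proto / rms * level if rms > 0 else proto
        for _ in range(n_events):
            at = start + int(rng.integers(0, max(seg_len - n_chirp, 1)))
            end = min(at + n_chirp, n_total)
            out[at:end] += proto[: end - at]
            log_entries.append({
                "kind": "bird_chirp_event", "start_s": at / fs,
                "duration_s": (end - at) / fs, "level_db": intf.level_db,
            })
    elif intf.kind == "competing_call":
        model: CallModel = p["model"]  # type: ignore[assignment]
        rate = float(p.get("rate_per_min", 4.0))
        n_events = int(round(rate * (seg_len / fs) / 60.0))
        proto = synthesize_call(model, fs).samples
        rms = np.sqrt(np.mean(proto ** 2))
        proto = proto / rms * level if rms > 0 else proto
        for _ in range(n_events):
            at = start + int(rng.integers(0, max(seg_len - proto.size, 1)))
            end = min(at + proto.size, n_total)
            out[at:end] += proto[: end - at]
            log_entries.append({
                "kind": "competing_call_event", "start_s": at / fs,
                "duration_s": (end - at) / fs, "level_db": intf.level_db,
            })
    return out, log_entries


def synthesize_soundscape(spec: SoundscapeSpec) -> tuple[AudioClip, GroundTruth]:
    """Mix noise floor, interferers and planted calls per the spec.

    The background (floor + interferers) is rendered first; each call is
    then scaled so its band-limited RMS sits exactly ``snr_db`` above
    the background's band-limited RMS over the call interval, and added.
    Deterministic for a given spec (including the seed).
    """
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)

    floor_rms = 10.0 ** (spec.noise_floor_db / 20.0)
    background = rng.standard_normal(n) * floor_rms
    interferer_log: list[dict] = []
    for intf in spec.interferers:
        wave, entries = _render_interferer(intf, n, fs, rng)
        background += wave
        interferer_log.extend(entries)

    mix = background.copy()
    call_log: list[dict] = []
    for call in spec.planted_calls:
        wave = synthesize_call(call.model, fs).samples
        i0 = int(round(call.onset * fs))
        i1 = i0 + wave.size
        band = call.model.band()
        bg_rms = _band_rms(background[i0:i1], band, fs)
        if bg_rms <= 0:
            bg_rms = 1e-8
        call_rms = _band_rms(wave, band, fs)
        gain = bg_rms * 10.0 ** (call.snr_db / 20.0) / call_rms if call_rms > 0 else 0.0
        mix[i0:i1] += wave * gain
        call_log.append({
            "species": call.species, "onset_s": call.onset,
            "offset_s": call.onset + call.model.duration, "snr_db": call.snr_db,
        })

    peak = np.abs(mix).max()
    if peak > 1.0:  # rescale the whole mix: SNR ratios are preserved
        warnings.warn(
            f"{spec.survey_id}: mix peak {peak:.2f} exceeds full scale; "
            "rescaling", stacklevel=2,
        )
        mix /= peak

    truth = GroundTruth(
        survey_id=spec.survey_id,
        species_present=tuple(sorted({c.species for c in spec.planted_calls})),
        calls=call_log,
        interferers=interferer_log,
    )
    return AudioClip(mix, fs, source_id=spec.survey_id), truth


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    data = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate, np.round(data * 32767).astype(np.int16))


def default_interferers() -> tuple[Interferer, ...]:
    """A continuous insect band plus episodic bird-like chirps — the two
    archetypal interferer classes (continuous vs episodic)."""
    return (
        Interferer("insect_band", level_db=-45.0,
                   params={"center_freq": 3800.0, "bandwidth": 400.0}),
        Interferer("bird_chirp", level_db=-35.0,
                   params={"f0": 2000.0, "f1": 2800.0, "rate_per_min": 4.0}),
    )


def _schedule_onsets(
    n_calls: int, duration: float, call_dur: float, rng: np.random.Generator
) -> list[float]:
    """Non-overlapping onsets: one call per equal slot, jittered."""
    margin = 0.25
    usable = duration - 2 * margin
    slot = usable / n_calls
    onsets = []
    for k in range(n_calls):
        jitter_room = max(slot - call_dur - 0.1, 0.0)
        onsets.append(margin + k * slot + rng.uniform(0.0, jitter_room))
    return onsets


def generate_evaluation_set(
    out_dir: str | Path,
    *,
    n_files: int = 30,
    prevalence: float = 0.5,
    species: Mapping[str, CallModel] | None = None,
    snr_db: float | tuple[float, float] = (3.0, 20.0),
    seed: int = 0,
    duration: float = DEFAULT_DURATION_S,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    calls_per_file: tuple[int, int] = (2, 4),
    interferers: Sequence[Interferer] | None = None,
) -> EvaluationSet:
    """Generate a balanced presence/absence evaluation corpus.

    For each species, exactly ``round(n_files * prevalence)`` files
    contain its calls (assignment is a deterministic function of the
    seed).  Files where several species are present contain mixed
    choruses, exercising multi-species recognition.  Emits one WAV per
    file plus an annotation CSV (``survey_id, species, present``), a
    ground-truth CSV of exact call onsets/offsets/SNRs, and an
    interferer log CSV.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    species = dict(species or DEFAULT_SPECIES)
    interferers = tuple(default_interferers() if interferers is None else interferers)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(seed)
    n_present = int(round(n_files * prevalence))
    present_in: dict[str, set[int]] = {}
    for name in sorted(species):
        present_in[name] = set(master.permutation(n_files)[:n_present].tolist())
    file_seeds = [int(master.integers(0, 2**31 - 1)) for _ in range(n_files)]

    survey_ids, ann_rows, truth_rows, intf_rows = [], [], [], []
    for i in range(n_files):
        survey_id = f"survey_{i:03d}.wav"
        rng = np.random.default_rng(file_seeds[i])
        calls = []
        for name in sorted(species):
            if i not in present_in[name]:
                continue
            model = species[name]
            n_calls = int(rng.integers(calls_per_file[0], calls_per_file[1] + 1))
            for onset in _schedule_onsets(n_calls, duration, model.duration, rng):
                if isinstance(snr_db, tuple):
                    snr = float(rng.uniform(*snr_db))
                else:
                    snr = float(snr_db)
                calls.append(PlantedCall(model=model, onset=onset,
                                         snr_db=snr, species=name))
        spec = SoundscapeSpec(
            seed=file_seeds[i], duration=duration, sample_rate=sample_rate,
            interferers=interferers, planted_calls=tuple(calls),
            survey_id=survey_id,
        )
        clip, truth = synthesize_soundscape(spec)
        write_wav(out_dir / survey_id, clip)

        survey_ids.append(survey_id)
        for name in sorted(species):
            ann_rows.append((survey_id, name, int(i in present_in[name])))
        for entry in truth.calls:
            truth_rows.append((survey_id, entry["species"], entry["onset_s"],
                               entry["offset_s"], entry["snr_db"]))
        for entry in truth.interferers:
            intf_rows.append((survey_id, entry["kind"], entry["start_s"],
                              entry["duration_s"], entry["level_db"]))

    annotation_path = out_dir / "annotations.csv"
    with open(annotation_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["survey_id", "species", "present"])
        writer.writerows(ann_rows)
    ground_truth_path = out_dir / "ground_truth.csv"
    with open(ground_truth_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["survey_id", "species", "onset_s", "offset_s", "snr_db"])
        writer.writerows(truth_rows)
    interferer_log_path = out_dir / "interferers.csv"
    with open(interferer_log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["survey_id", "kind", "start_s", "duration_s", "level_db"])
        writer.writerows(intf_rows)

    return EvaluationSet(
        audio_dir=out_dir,
        annotation_path=annotation_path,
        ground_truth_path=ground_truth_path,
        interferer_log_path=interferer_log_path,
        survey_ids=survey_ids,
    )
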