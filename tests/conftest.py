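import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chorusmatch.audio import Spectrogram, SpectrogramParams

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_template(mask, first_bin=0, sample_rate=22050, window_size=512,
                  name="toy", species="toy_frog"):
    """Build a BinaryTemplate from a boolean on-mask over a bin×frame grid.

    Row i of ``mask`` is absolute frequency bin ``first_bin + i``; the
    frequency limits are chosen to map exactly onto those bins.
    """
    from chorusmatch.templates import BinaryTemplate, TemplatePoint

    mask = np.asarray(mask, dtype=bool)
    n_bins, dur = mask.shape
    df = sample_rate / window_size
    on, off = set(), set()
    for i in range(n_bins):
        for f in range(dur):
            p = TemplatePoint(first_bin + i, f)
            (on if mask[i, f] else off).add(p)
    return BinaryTemplate(
        name=name, species=species,
        on_points=frozenset(on), off_points=frozenset(off),
        amplitude_cutoff=-20.0,
        freq_limits=(first_bin * df - 0.4 * df,
                     (first_bin + n_bins - 1) * df + 0.4 * df),
        window_size=window_size, duration_frames=dur,
        sample_rate=sample_rate,
    )


def make_spectrogram(amplitude, sample_rate=22050, window_size=512,
                     overlap_fraction=0.0, floor_db=-120.0):
    """Build a Spectrogram directly from a dB matrix (test helper)."""
    amplitude = np.asarray(amplitude, dtype=float)
    params = SpectrogramParams(window_size=window_size,
                               overlap_fraction=overlap_fraction)
    n_bins, n_frames = amplitude.shape
    hop = params.hop
    return Spectrogram(
        amplitude=amplitude,
        freq_axis=np.arange(n_bins) * sample_rate / window_size,
        time_axis=(np.arange(n_frames) * hop + window_size / 2) / sample_rate,
        params=params,
        sample_rate=sample_rate,
        floor_db=floor_db,
    )
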