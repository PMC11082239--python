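"""Enclosure attenuation measurement from sine-sweep recordings.

To characterize how much sound an anechoic recording box keeps out, a
sweep is played from a loudspeaker outside the box and recorded by the
microphones inside under several door configurations (open, inner door
closed, fully closed).  For each scenario the one-sided FFT magnitudes of
all sweep segments and channels are averaged in the linear domain,
converted to dB and smoothed with a 51-point moving average; the
attenuation of a scenario is then simply the dB difference against the
open-door reference, frequency by frequency.  Because the loudspeaker and
room response cancel in the difference, only relative absorption is
measured.

Where the box blocks the sweep entirely, the measured spectrum bottoms out
at the noise floor of the measurement chain; :func:`noise_floor_db`
estimates that floor (median level of the flattest decile of the spectrum)
so it can be reported alongside the attenuation, not corrected for.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .audio_io import Recording
from .dsp import SPECTRUM_EPS, moving_average

__all__ = [
    "SweepScenario",
    "extract_sweep_segments",
    "scenario_spectrum",
    "attenuation_spectrum",
    "band_mean_db",
    "noise_floor_db",
]


@dataclasses.dataclass
class SweepScenario:
    """Named set of equal-length multichannel sweep excerpts.

    ``segments`` is a list of ``(n_channels, n_samples)`` arrays, all of
    the same shape and sample rate (nominally nine 21 s clips of four
    channels: three sweeps from each of three recordings per scenario).
    """

    name: str
    segments: list[np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a scenario needs at least one segment")
        self.segments = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in self.segments]
        shape = self.segments[0].shape
        for s in self.segments[1:]:
            if s.shape != shape:
                raise ValueError(
                    f"all segments must share a shape; got {shape} and {s.shape}"
                )
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def extract_sweep_segments(
    rec: Recording, timestamps_s: list[float], seg_s: float = 21.0
) -> list[np.ndarray]:
    """Cut ``seg_s``-long multichannel excerpts starting at each timestamp.

    Every excerpt is exactly ``round(seg_s * rate)`` samples and must lie
    fully inside the recording.
    """
    n_seg = int(round(seg_s * rec.rate))
    out = []
    for t in timestamps_s:
        start = int(round(t * rec.rate))
        if start < 0 or start + n_seg > rec.n_samples:
            raise ValueError(
                f"segment [{t}, {t + seg_s}) s lies outside the "
                f"{rec.duration_s:.2f} s recording"
            )
        out.append(rec.samples[:, start : start + n_seg].copy())
    return out


def scenario_spectrum(
    scenario: SweepScenario, smooth_window: int = 51
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged, smoothed magnitude spectrum of a scenario in dB.

    Per segment and channel the one-sided FFT magnitude is computed; the
    magnitudes are averaged in the linear domain over all segments x
    channels, converted to dB, then smoothed with a centered moving
    average.
    """
    n = scenario.segments[0].shape[1]
    acc = np.zeros(n // 2 + 1)
    count = 0
    for seg in scenario.segments:
        mags = np.abs(np.fft.rfft(seg, axis=1))
        acc += mags.sum(axis=0)
        count += seg.shape[0]
    mean_mag = acc / count
    db = 20.0 * np.log10(mean_mag + SPECTRUM_EPS)
    freqs = np.fft.rfftfreq(n, d=1.0 / scenario.rate)
    return freqs, moving_average(db, smooth_window)


def attenuation_spectrum(
    reference: tuple[np.ndarray, np.ndarray], test: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """dB attenuation (reference minus test) on a shared frequency grid."""
    f_ref, db_ref = reference
    f_test, db_test = test
    if f_ref.shape != f_test.shape or not np.allclose(f_ref, f_test):
        raise ValueError("spectra are on different frequency grids")
    return f_ref, db_ref - db_test


def band_mean_db(
    freqs: np.ndarray, values_db: np.ndarray, f_lo_hz: float, f_hi_hz: float
) -> float:
    """Mean of a dB curve over [f_lo_hz, f_hi_hz]."""
    mask = (freqs >= f_lo_hz) & (freqs <= f_hi_hz)
    if not mask.any():
        raise ValueError(f"no frequency bins in [{f_lo_hz}, {f_hi_hz}] Hz")
    return float(np.mean(values_db[mask]))


def noise_floor_db(values_db: np.ndarray, flatness_window: int = 51) -> float:
    """Estimate the measurement noise floor of a spectrum in dB.

    The floor reveals itself as the flattest stretches of the curve: the
    local variability (rolling std over ``flatness_window`` bins) is
    computed, and the median level of the flattest decile of bins is
    returned.
    """
    values_db = np.asarray(values_db, dtype=np.float64)
    if len(values_db) < flatness_window:
        raise ValueError("spectrum shorter than the flatness window")
    mean = moving_average(values_db, flatness_window)
    sq_mean = moving_average(values_db**2, flatness_window)
    local_var = np.maximum(sq_mean - mean**2, 0.0)
    cutoff = np.quantile(local_var, 0.10)
    flattest = values_db[local_var <= cutoff]
    return float(np.median(flattest))
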