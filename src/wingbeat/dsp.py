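"""Core signal primitives shared by the extraction and validation pipelines.

Butterworth filters are designed and applied as cascaded second-order
sections: the 30th-order high-pass used for detection prefiltering is
numerically unusable in any direct form, while an SOS cascade keeps every
pole comfortably inside the unit circle.  Filtering is causal forward-only —
no zero-phase double pass — so that the energy-threshold semantics of the
detector are identical to what a streaming implementation would see.

Resampling is polyphase with a Kaiser-window FIR designed for a narrow
(~125 Hz) transition band so that content just below the output Nyquist
survives while anything above it is strongly suppressed.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

__all__ = [
    "FilterSpec",
    "EnergyProfile",
    "design_butterworth",
    "apply_filter",
    "resample_to_16k",
    "resample",
    "windowed_energy",
    "moving_average",
    "magnitude_spectrum_db",
    "SPECTRUM_EPS",
]

#: magnitude floor added before dB conversion; well below any physical noise
#: floor but keeps log10 finite on exact zeros.
SPECTRUM_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """A designed IIR filter: parameters plus its SOS realization."""

    kind: str  # "low_pass" | "high_pass"
    order: int
    cutoff_hz: float
    rate_hz: float
    sos: np.ndarray

    def pole_moduli(self) -> np.ndarray:
        """Modulus of every pole of the cascade (stability ⇔ all < 1)."""
        moduli = []
        for section in self.sos:
            poles = np.roots(section[3:])
            moduli.extend(np.abs(poles))
        return np.asarray(moduli)


@dataclasses.dataclass(frozen=True)
class EnergyProfile:
    """Per-window signal energies with the bookkeeping to map windows back
    to sample indices: window ``k`` covers samples
    ``[k*hop, k*hop + window_len)`` of the source signal."""

    energies: np.ndarray
    window_len: int
    hop: int
    n_samples: int

    def __post_init__(self) -> None:
        expected = (self.n_samples - self.window_len) // self.hop + 1
        if len(self.energies) != expected:
            raise ValueError(
                f"profile has {len(self.energies)} energies, expected {expected}"
            )

    @property
    def n_windows(self) -> int:
        return len(self.energies)

    def window_bounds(self, k: int) -> tuple[int, int]:
        return k * self.hop, k * self.hop + self.window_len


def design_butterworth(kind: str, order: int, cutoff_hz: float, rate_hz: float) -> FilterSpec:
    """Design a Butterworth low- or high-pass as second-order sections.

    The digital design is bilinear with pre-warping, so the -3.01 dB point
    lands on ``cutoff_hz`` exactly.
    """
    if kind not in ("low_pass", "high_pass"):
        raise ValueError(f"kind must be 'low_pass' or 'high_pass', got {kind!r}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rate_hz / 2} Hz)"
        )
    btype = "lowpass" if kind == "low_pass" else "highpass"
    sos = _sig.butter(order, cutoff_hz, btype=btype, fs=rate_hz, output="sos")
    return FilterSpec(kind=kind, order=order, cutoff_hz=float(cutoff_hz),
                      rate_hz=float(rate_hz), sos=sos)


def apply_filter(spec: FilterSpec, x: np.ndarray, rate_hz: float | None = None) -> np.ndarray:
    """Causal forward filtering along the last axis; output length == input."""
    if rate_hz is not None and rate_hz != spec.rate_hz:
        raise ValueError(
            f"filter designed for {spec.rate_hz} Hz applied to {rate_hz} Hz signal"
        )
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return _sig.sosfilt(spec.sos, x, axis=-1)


def _antialias_fir(up: int, down: int, transition_hz: float, atten_db: float,
                   rate_in_hz: float) -> np.ndarray:
    """Kaiser-window low-pass for polyphase resampling at rate up*rate_in."""
    max_rate = max(up, down)
    fs_up = rate_in_hz * up
    width_norm = 2.0 * transition_hz / fs_up  # fraction of Nyquist at fs_up
    numtaps, beta = _sig.kaiserord(atten_db, width_norm)
    numtaps = int(numtaps) | 1  # odd length, linear phase type I
    # -6 dB point half a transition band below the target Nyquist so the
    # stopband starts at the new Nyquist itself.
    cutoff_norm = 1.0 / max_rate - width_norm / 2.0
    if cutoff_norm <= 0:
        raise ValueError("transition band too wide for this resampling ratio")
    return _sig.firwin(numtaps, cutoff_norm, window=("kaiser", beta))


def resample(x: np.ndarray, rate_in_hz: float, rate_out_hz: float,
             transition_hz: float = 125.0, atten_db: float = 85.0) -> np.ndarray:
    """Anti-aliased polyphase resampling along the last axis.

    The in/out rates must be rationally related.  Output length is
    ``round(n_in * rate_out / rate_in)``.
    """
    if rate_in_hz <= 0 or rate_out_hz <= 0:
        raise ValueError("rates must be positive")
    frac = Fraction(rate_out_hz / rate_in_hz).limit_denominator(1000)
    if abs(float(frac) - rate_out_hz / rate_in_hz) > 1e-9:
        raise ValueError(
            f"rate ratio {rate_out_hz}/{rate_in_hz} is not rational within tolerance"
        )
    x = np.asarray(x, dtype=np.float64)
    up, down = frac.numerator, frac.denominator
    if up == down == 1:
        return x.copy()
    h = _antialias_fir(up, down, transition_hz, atten_db, rate_in_hz)
    # resample_poly scales an array window by `up` itself; pass h unscaled
    y = _sig.resample_poly(x, up, down, axis=-1, window=h)
    n_expected = int(round(x.shape[-1] * up / down))
    return y[..., :n_expected]


def resample_to_16k(x: np.ndarray, rate_in_hz: float) -> np.ndarray:
    """Resample a signal (or channel stack) to the 16 kHz clip rate."""
    return resample(x, rate_in_hz, 16000.0)


def windowed_energy(x: np.ndarray, window_len: int = 3279, hop: int = 1024) -> EnergyProfile:
    """Sum-of-squares energy over a sliding window.

    ``energies[k] = sum(x[k*hop : k*hop + window_len] ** 2)``; a trailing
    partial window is dropped rather than zero-padded (a padded window's
    deflated energy would bias the mean threshold downward).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("windowed_energy expects a single channel")
    if window_len < 1 or hop < 1:
        raise ValueError("window_len and hop must be positive")
    if len(x) < window_len:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one window ({window_len})"
        )
    sq = np.square(x)
    windows = np.lib.stride_tricks.sliding_window_view(sq, window_len)[::hop]
    energies = windows.sum(axis=1)
    return EnergyProfile(energies=energies, window_len=window_len, hop=hop,
                         n_samples=len(x))


def moving_average(values: np.ndarray, window: int = 51) -> np.ndarray:
    """Centered moving average; at the edges the window shrinks
    symmetrically to the available points, so output length == input length
    and a constant sequence is a fixed point."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n == 0:
        return values.copy()
    half = (window - 1) // 2
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, n - 1 - idx), half)
    cs = np.concatenate(([0.0], np.cumsum(values)))
    return (cs[idx + k + 1] - cs[idx - k]) / (2 * k + 1)


def magnitude_spectrum_db(x: np.ndarray, rate_hz: float,
                          eps: float = SPECTRUM_EPS) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude spectrum in dB.

    Returns ``(frequencies_hz, 20*log10(|X(f)| + eps))`` with frequency
    resolution ``rate_hz / len(x)``.  No window or normalization is applied;
    spectra meant for comparison must share a length.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot take the spectrum of an empty signal")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate_hz)
    return freqs, 20.0 * np.log10(mags + eps)
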