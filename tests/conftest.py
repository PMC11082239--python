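"""Shared fixtures: small synthetic scenes and clip builders.

All audio fixtures are generated programmatically and seeded; nothing is
read from disk except what a test itself writes to tmp_path.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import wingbeat as wb


@pytest.fixture(scope="session")
def short_fixture():
    """A 60 s, 3-event, 20 dB in-band SNR scene with ground truth."""
    return wb.make_extraction_fixture(n_events=3, snr_db=20.0, seed=1,
                                      duration_s=60.0)


@pytest.fixture(scope="session")
def short_fixture_clips(short_fixture):
    rec, truth = short_fixture
    clips, report = wb.extract(rec)
    return clips, report, truth


def make_clip(samples: np.ndarray, rate: int = 16000, species: str = "Bombus terrestris",
              date: dt.date = dt.date(2022, 6, 14), index: int = 0) -> wb.Clip:
    return wb.Clip(samples=np.atleast_2d(samples), rate=rate, start_offset=0,
                   date=date, species=species, index=index)


def sine_clip(freq_hz: float = 1000.0, amp: float = 1.0, n_channels: int = 4,
              rate: int = 16000, duration_s: float = 2.5) -> wb.Clip:
    t = np.arange(int(duration_s * rate)) / rate
    wave = amp * np.sin(2 * np.pi * freq_hz * t)
    return make_clip(np.tile(wave, (n_channels, 1)), rate=rate)


def truth_midpoints_at(truth, rate_in: int, rate_out: int) -> list[int]:
    """Ground-truth event midpoints converted to the clip-rate timeline."""
    return [int(round((iv.start + iv.end) / 2 / rate_in * rate_out)) for iv in truth]
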