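"""Fixed-length clip extraction from long quiet multichannel recordings.

The pipeline turns a long, mostly silent multichannel recording into
non-overlapping 2500 ms clips containing acoustic activity:

1. resample every channel to the 16 kHz clip rate;
2. select the loudest channel (maximum sum of squared samples) — detection
   runs on that single channel to keep the cost of the remaining steps low;
3. prefilter that channel with a 4th-order Butterworth low-pass at 1500 Hz
   and a 30th-order Butterworth high-pass at 180 Hz, suppressing the
   low-frequency environmental noise that penetrates the recording
   enclosure;
4. compute windowed signal energy (window 3279 samples, hop 1024);
5. mark windows whose energy exceeds 1.6x the file-wide mean energy as
   active, and merge overlapping/abutting active windows into intervals;
6. discard isolated short activity (< 1 s with no neighbour within
   2500 ms) as noise;
7. greedily cover the remaining activity with non-overlapping fixed-length
   clip windows;
8. cut the clips from the *unfiltered* resampled multichannel signal.

Because the threshold is relative to the file's own mean energy, a
recording with constant amplitude yields no clips by construction.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np

from .audio_io import Clip, Recording
from .dsp import (
    EnergyProfile,
    apply_filter,
    design_butterworth,
    resample,
    windowed_energy,
)

__all__ = [
    "PipelineParams",
    "ActivityInterval",
    "ExtractionReport",
    "select_loudest_channel",
    "detect_activity",
    "prune_isolated",
    "segment_clips",
    "extract",
]


class ActivityInterval(NamedTuple):
    """Half-open sample-index range [start, end) marked as active."""

    start: int
    end: int


@dataclasses.dataclass(frozen=True)
class PipelineParams:
    """All tunables of the extraction pipeline, defaulting to the reference
    configuration the detector was characterized with."""

    target_rate_hz: int = 16000
    lp_cutoff_hz: float = 1500.0
    lp_order: int = 4
    hp_cutoff_hz: float = 180.0
    hp_order: int = 30
    window_len: int = 3279
    hop: int = 1024
    threshold_factor: float = 1.6
    clip_ms: float = 2500.0
    min_isolated_ms: float = 1000.0
    neighbor_range_ms: float = 2500.0

    def __post_init__(self) -> None:
        numeric = dataclasses.asdict(self)
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.clip_ms < self.min_isolated_ms:
            raise ValueError("clip_ms must be >= min_isolated_ms")

    @property
    def clip_len_samples(self) -> int:
        return int(round(self.clip_ms / 1000.0 * self.target_rate_hz))


@dataclasses.dataclass
class ExtractionReport:
    """Per-recording account of what the pipeline did."""

    source_id: str
    n_windows: int
    energy_threshold: float
    n_raw_intervals: int
    n_pruned_intervals: int
    clip_offsets: list[int]
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_clips(self) -> int:
        return len(self.clip_offsets)

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "n_windows": self.n_windows,
            "energy_threshold": self.energy_threshold,
            "n_raw_intervals": self.n_raw_intervals,
            "n_pruned_intervals": self.n_pruned_intervals,
            "n_clips": self.n_clips,
            "clip_offsets": [int(o) for o in self.clip_offsets],
            "warnings": list(self.warnings),
        }


def select_loudest_channel(rec: Recording) -> int:
    """Index of the channel with the largest sum of squared samples;
    ties break to the lowest index."""
    if rec.n_samples == 0:
        raise ValueError("cannot select a channel from an empty recording")
    sums = np.einsum("ij,ij->i", rec.samples, rec.samples)
    return int(np.argmax(sums))


def detect_activity(
    profile: EnergyProfile, threshold_factor: float = 1.6
) -> tuple[float, list[ActivityInterval]]:
    """Threshold window energies at ``threshold_factor`` times their mean.

    Windows with energy strictly above the threshold are active ("strictly"
    makes the constant-signal case unambiguous: nothing exceeds 1.6x its own
    mean).  Active windows map to sample ranges ``[k*hop, k*hop+window_len)``
    and overlapping or abutting ranges are merged.
    """
    if profile.n_windows == 0:
        raise ValueError("empty energy profile")
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    threshold = float(threshold_factor * np.mean(profile.energies))
    intervals: list[ActivityInterval] = []
    for k in np.flatnonzero(profile.energies > threshold):
        start, end = profile.window_bounds(int(k))
        if intervals and start <= intervals[-1].end:
            intervals[-1] = ActivityInterval(intervals[-1].start, max(intervals[-1].end, end))
        else:
            intervals.append(ActivityInterval(start, end))
    return threshold, intervals


def _check_sorted(intervals: list[ActivityInterval]) -> None:
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start < prev.end:
            raise ValueError(f"intervals unsorted or overlapping: {prev} then {cur}")
    for iv in intervals:
        if not 0 <= iv.start < iv.end:
            raise ValueError(f"degenerate interval {iv}")


def prune_isolated(
    intervals: list[ActivityInterval],
    rate_hz: float,
    min_isolated_ms: float = 1000.0,
    neighbor_range_ms: float = 2500.0,
) -> list[ActivityInterval]:
    """Drop short, isolated activity as noise.

    An interval is removed iff it is shorter than ``min_isolated_ms`` AND
    the gap to both its predecessor and successor (in the original list)
    exceeds ``neighbor_range_ms``; a missing neighbour counts as an
    infinite gap.
    """
    intervals = list(intervals)
    _check_sorted(intervals)
    min_len = min_isolated_ms / 1000.0 * rate_hz
    max_gap = neighbor_range_ms / 1000.0 * rate_hz
    kept = []
    for i, iv in enumerate(intervals):
        duration = iv.end - iv.start
        gap_prev = iv.start - intervals[i - 1].end if i > 0 else np.inf
        gap_next = intervals[i + 1].start - iv.end if i < len(intervals) - 1 else np.inf
        isolated = gap_prev > max_gap and gap_next > max_gap
        if duration < min_len and isolated:
            continue
        kept.append(iv)
    return kept


def segment_clips(
    intervals: list[ActivityInterval], clip_len_samples: int, n_total_samples: int
) -> list[int]:
    """Greedy left-to-right placement of non-overlapping clip windows.

    Walk the intervals in order; open a clip window at the start of the
    first uncovered activity (shifted left if it would overrun the file
    end).  Intervals fully covered by that window are consumed.  An
    interval running past the window's end makes the next clip start
    exactly at that end (back-to-back coverage of long activity); otherwise
    the next clip opens at the next uncovered interval's start.  Every
    returned window overlaps at least one interval and every interval is
    overlapped by at least one window, unless the file is shorter than one
    clip (then no clips are returned).
    """
    _check_sorted(intervals)
    if intervals and intervals[-1].end > n_total_samples:
        raise ValueError("activity extends past the end of the recording")
    if clip_len_samples < 1:
        raise ValueError("clip length must be positive")
    if n_total_samples < clip_len_samples:
        return []
    offsets: list[int] = []
    i = 0
    while i < len(intervals):
        start, end = intervals[i]
        if offsets:
            covered_until = offsets[-1] + clip_len_samples
            if end <= covered_until:
                i += 1
                continue
            start = max(start, covered_until)
        if start + clip_len_samples > n_total_samples:
            start = n_total_samples - clip_len_samples
            if offsets and start < offsets[-1] + clip_len_samples:
                break  # no room left without overlap
        offsets.append(start)
        while i < len(intervals) and intervals[i].end <= start + clip_len_samples:
            i += 1
    return offsets


def extract(rec: Recording, params: PipelineParams | None = None) -> tuple[list[Clip], ExtractionReport]:
    """Run the full extraction pipeline on one recording.

    Clips are cut from the resampled but otherwise untouched multichannel
    signal; the prefilter exists only to drive detection.
    """
    params = params or PipelineParams()
    report_warnings: list[str] = []
    if rec.rate != params.target_rate_hz:
        resampled = resample(rec.samples, rec.rate, params.target_rate_hz)
    else:
        resampled = np.asarray(rec.samples, dtype=np.float64)
    n_total = resampled.shape[1]
    clip_len = params.clip_len_samples

    def _empty_report(n_windows: int = 0, threshold: float = float("nan"),
                      n_raw: int = 0, n_pruned: int = 0) -> ExtractionReport:
        return ExtractionReport(
            source_id=rec.source_id, n_windows=n_windows,
            energy_threshold=threshold, n_raw_intervals=n_raw,
            n_pruned_intervals=n_pruned, clip_offsets=[],
            warnings=report_warnings,
        )

    if n_total < clip_len or n_total < params.window_len:
        msg = (f"recording {rec.source_id!r} is shorter than one clip "
               f"({n_total} < {clip_len} samples); no clips extracted")
        report_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
        return [], _empty_report()

    channel = select_loudest_channel(
        Recording(samples=resampled, rate=params.target_rate_hz, date=rec.date,
                  species=rec.species, source_id=rec.source_id)
    )
    lp = design_butterworth("low_pass", params.lp_order, params.lp_cutoff_hz,
                            params.target_rate_hz)
    hp = design_butterworth("high_pass", params.hp_order, params.hp_cutoff_hz,
                            params.target_rate_hz)
    filtered = apply_filter(hp, apply_filter(lp, resampled[channel]))
    profile = windowed_energy(filtered, params.window_len, params.hop)
    threshold, raw_intervals = detect_activity(profile, params.threshold_factor)
    pruned = prune_isolated(raw_intervals, params.target_rate_hz,
                            params.min_isolated_ms, params.neighbor_range_ms)
    offsets = segment_clips(pruned, clip_len, n_total)
    clips = [
        Clip(
            samples=resampled[:, o : o + clip_len].copy(),
            rate=params.target_rate_hz,
            start_offset=int(o),
            date=rec.date,
            species=rec.species,
            index=i,
        )
        for i, o in enumerate(offsets)
    ]
    report = ExtractionReport(
        source_id=rec.source_id,
        n_windows=profile.n_windows,
        energy_threshold=threshold,
        n_raw_intervals=len(raw_intervals),
        n_pruned_intervals=len(pruned),
        clip_offsets=[int(o) for o in offsets],
        warnings=report_warnings,
    )
    return clips, report
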