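"""Per-clip sound-level statistic and per-species summaries.

Each clip gets a single level value: per channel the DC offset is removed
and a 50 Hz 4th-order Butterworth high-pass applied, the per-channel mean
squares are pooled (averaged) across channels, and the pooled mean square is
expressed in dB.  Pooling mean squares rather than averaging per-channel dB
keeps the statistic exactly 20*log10(a)-homogeneous under amplitude scaling.

By default the reference is digital full scale (dBFS).  Absolute SPL re
20 µPa is available when the recording chain's calibration (pascal per
full-scale unit) is known; without it, levels from different hardware are
not comparable on an absolute scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .audio_io import Clip
from .dsp import apply_filter, design_butterworth

__all__ = ["LevelConfig", "clip_spl", "summarize_levels", "level_histograms"]

_P_REF_PA = 20e-6  # standard reference pressure


@dataclasses.dataclass(frozen=True)
class LevelConfig:
    hp_cutoff_hz: float = 50.0
    hp_order: int = 4
    reference: str = "full_scale"  # or "pascal_calibrated"
    calibration_pa_per_unit: float | None = None

    def __post_init__(self) -> None:
        if self.reference not in ("full_scale", "pascal_calibrated"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.reference == "pascal_calibrated" and not self.calibration_pa_per_unit:
            raise ValueError("pascal_calibrated reference requires calibration_pa_per_unit")


def clip_spl(clip: Clip, cfg: LevelConfig | None = None) -> float:
    """Mean level of one clip in dB (dBFS, or dB re 20 µPa if calibrated)."""
    cfg = cfg or LevelConfig()
    if clip.n_samples == 0:
        raise ValueError("cannot compute the level of an empty clip")
    x = np.asarray(clip.samples, dtype=np.float64)
    x = x - x.mean(axis=1, keepdims=True)  # offset correction
    hp = design_butterworth("high_pass", cfg.hp_order, cfg.hp_cutoff_hz, clip.rate)
    x = apply_filter(hp, x)
    pooled_ms = float(np.mean(x**2))
    if cfg.reference == "pascal_calibrated":
        pooled_ms *= cfg.calibration_pa_per_unit**2
        ref_sq = _P_REF_PA**2
    else:
        ref_sq = 1.0
    if pooled_ms == 0.0:
        return -np.inf
    return 10.0 * np.log10(pooled_ms / ref_sq)


def summarize_levels(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean level and clip count from a manifest with spl_db."""
    if manifest.empty:
        raise ValueError("empty manifest")
    rows = manifest.dropna(subset=["spl_db"])
    if rows.empty:
        raise ValueError("manifest has no spl_db values to summarize")
    out = (
        rows.groupby("species")["spl_db"]
        .agg(mean_spl_db="mean", n_clips="count")
        .reset_index()
    )
    return out


def level_histograms(
    manifest: pd.DataFrame,
    bin_width_db: float = 1.0,
    range_db: tuple[float, float] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-species histograms of clip levels.

    Returns ``{species: (bin_edges, counts)}``.  A shared range (default:
    data range padded to whole bins) makes the histograms comparable across
    species.
    """
    if bin_width_db <= 0:
        raise ValueError("bin_width_db must be positive")
    rows = manifest.dropna(subset=["spl_db"])
    if rows.empty:
        raise ValueError("manifest has no spl_db values")
    values = rows["spl_db"].to_numpy(dtype=float)
    if range_db is None:
        lo = np.floor(values.min() / bin_width_db) * bin_width_db
        hi = np.ceil(values.max() / bin_width_db) * bin_width_db
        hi = hi if hi > lo else lo + bin_width_db
        range_db = (float(lo), float(hi))
    n_bins = max(1, int(round((range_db[1] - range_db[0]) / bin_width_db)))
    out = {}
    for species, group in rows.groupby("species"):
        counts, edges = np.histogram(
            group["spl_db"].to_numpy(dtype=float), bins=n_bins, range=range_db
        )
        out[str(species)] = (edges, counts)
    return out
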