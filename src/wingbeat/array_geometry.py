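"""Star microphone-array geometry and the spatial-aliasing design range.

The array is one centre microphone plus three outer microphones equally
spaced (120 deg) on a circle of radius ``r`` around it, so any two outer
microphones are ``r*sqrt(3)`` apart.  A basic delay-and-sum beamformer
works well while the element spacing ``d`` satisfies ``0.25 < d/lambda <
0.5``: below that the phase differences vanish into noise, above it
spatial aliasing sets in.  For this mixed-spacing star the usable band is
bounded below by the large outer-pair spacing and above by the small
centre-to-outer radius, so

    f_low  = 0.25 * c / (r*sqrt(3)),    f_high = 0.5 * c / r.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["StarArray", "outer_pair_spacing", "beamforming_range"]


@dataclasses.dataclass(frozen=True)
class StarArray:
    """Four-microphone star array in the z=0 plane, centre at the origin."""

    radius_m: float = 0.055
    speed_of_sound_mps: float = 343.0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError(f"radius must be positive, got {self.radius_m}")
        if self.speed_of_sound_mps <= 0:
            raise ValueError("speed of sound must be positive")

    @property
    def positions(self) -> np.ndarray:
        """(4, 3) coordinates in metres: centre first, then the three outer
        microphones at 90, 210 and 330 degrees."""
        angles = np.deg2rad([90.0, 210.0, 330.0])
        outer = np.stack(
            [self.radius_m * np.cos(angles), self.radius_m * np.sin(angles),
             np.zeros(3)], axis=1
        )
        return np.vstack([np.zeros(3), outer])


def outer_pair_spacing(array: StarArray) -> float:
    """Distance in metres between any two outer microphones (= r*sqrt(3))."""
    return array.radius_m * math.sqrt(3.0)


def beamforming_range(array: StarArray) -> tuple[int, int]:
    """Usable delay-and-sum band (f_low, f_high) in Hz, rounded to 1 Hz.

    The lower bound applies the d/lambda > 0.25 rule to the outer-pair
    spacing (the largest spacing in the array), the upper bound applies
    d/lambda < 0.5 to the centre-to-outer radius (the smallest).
    """
    c = array.speed_of_sound_mps
    f_low = 0.25 * c / outer_pair_spacing(array)
    f_high = 0.5 * c / array.radius_m
    return int(round(f_low)), int(round(f_high))
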