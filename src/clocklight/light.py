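"""Diel light-intensity profiles.

Four light regimes are used throughout the package, mirroring a growth
setup in which LED intensity is reprogrammed every three minutes over a
12-hour light period:

* ``LowLight`` — constant 50 umol photons m-2 s-1.
* ``ClearDay`` — a smooth unimodal curve peaking at 600 umol photons
  m-2 s-1 at hour 6 (half-sine parameterization ``600*sin(pi*t/12)``),
  emulating the parabolic course of sunlight on a cloudless day.
* ``HighLightPulse`` — Low Light baseline, stepped up to the Clear Day
  intensities for one hour starting 8 h after dawn (a cloud clearing).
* ``ShadePulse`` — Clear Day divided by 10 on the same 8-9 h window
  (a cloud passing over).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CONDITIONS",
    "LightProfile",
    "clear_day_intensity",
    "make_light_profile",
]

#: The four light regimes, in canonical order.
CONDITIONS = ("LowLight", "ClearDay", "HighLightPulse", "ShadePulse")

#: Hours of the light period.
DAY_LENGTH_H = 12.0

#: Interval at which the LED intensity is updated (3 minutes).
TIME_STEP_H = 0.05

#: Peak Clear Day intensity, umol photons m-2 s-1.
PEAK_INTENSITY = 600.0

#: Constant Low Light intensity, umol photons m-2 s-1.
LOW_LIGHT_INTENSITY = 50.0

#: One-hour pulse window (hours after dawn), half-open.
PULSE_WINDOW = (8.0, 9.0)


def clear_day_intensity(t: np.ndarray | float) -> np.ndarray | float:
    """Clear Day irradiance at time ``t`` (hours after dawn): 600*sin(pi*t/12)."""
    return PEAK_INTENSITY * np.sin(np.pi * np.asarray(t, dtype=float) / DAY_LENGTH_H)


@dataclass(frozen=True)
class LightProfile:
    """A light regime sampled on the 3-minute LED update grid.

    ``times`` are hours after dawn spanning [0, 12]; ``intensity`` is in
    umol photons m-2 s-1 and is nonnegative.
    """

    condition: str
    times: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have the same shape")
        if np.any(self.intensity < 0):
            raise ValueError("light intensity must be nonnegative")

    def at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linearly interpolated intensity at time(s) ``t``."""
        return np.interp(t, self.times, self.intensity)


def make_light_profile(condition_name: str) -> LightProfile:
    """Build the light profile for one of the four named conditions.

    Raises ``ValueError`` for an unknown condition, naming the valid ones.
    """
    if condition_name not in CONDITIONS:
        raise ValueError(
            f"unknown light condition {condition_name!r}; "
            f"valid conditions are {', '.join(CONDITIONS)}"
        )
    n_steps = int(round(DAY_LENGTH_H / TIME_STEP_H))
    times = np.linspace(0.0, DAY_LENGTH_H, n_steps + 1)
    in_pulse = (times >= PULSE_WINDOW[0]) & (times < PULSE_WINDOW[1])
    clear = clear_day_intensity(times)

    if condition_name == "LowLight":
        intensity = np.full_like(times, LOW_LIGHT_INTENSITY)
    elif condition_name == "ClearDay":
        intensity = clear
    elif condition_name == "ShadePulse":
        intensity = np.where(in_pulse, clear / 10.0, clear)
    else:  # HighLightPulse
        intensity = np.where(in_pulse, clear, LOW_LIGHT_INTENSITY)
    return LightProfile(condition_name, times, intensity)
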