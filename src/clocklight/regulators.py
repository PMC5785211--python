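"""Phospho-regulator time series (RpaA~P and RpaB~P).

RpaA~P is the clock-output master regulator: its phosphorylation ramps
monotonically from dawn to dusk and is insensitive to abrupt light
changes, so the same ramp is used for all four light conditions.

RpaB~P responds to light *inversely* and rapidly:

* divided by ~3.1 within 15 min of the High Light pulse onset,
* multiplied by ~1.9 within 15 min of the Shade pulse onset,
* multiplied by ~1.7 between hour 10 and hour 12 of the Clear Day
  (the sunset ramp-down of light).

Both series are produced on an arbitrary raw scale; all downstream use
is after joint 0-1 scaling across the four conditions
(:func:`clocklight.expression.scale_unit_interval`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .light import PULSE_WINDOW, LightProfile

__all__ = ["RegulatorTrajectory", "make_regulator_trajectories"]

#: Time (h) for the pulse response to reach its full fold change.
PULSE_RESPONSE_H = 0.25
#: Exponential relaxation time constant (h) after a pulse ends.
RELAXATION_TAU_H = 0.5
#: Fold changes of RpaB~P: High Light pulse, Shade pulse, Clear Day sunset.
HIGH_LIGHT_FOLD = 1.0 / 3.1
SHADE_FOLD = 1.9
SUNSET_FOLD = 1.7


@dataclass(frozen=True)
class RegulatorTrajectory:
    """A driver time series (regulator phosphorylation or a cluster mean).

    ``values`` may be on a raw scale (generator output) or 0-1
    normalized (model input); times are hours after dawn, strictly
    increasing. The interpolation rule between samples is
    piecewise-linear.
    """

    name: str
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.times, self.values)

    def sampled(self, times: np.ndarray) -> "RegulatorTrajectory":
        """The same trajectory restricted to ``times``."""
        times = np.asarray(times, dtype=float)
        return RegulatorTrajectory(self.name, times, np.asarray(self.at(times)))


def _rpaa_ramp(t: np.ndarray) -> np.ndarray:
    # Logistic dawn->dusk ramp from 0.2 to 1.0 raw units, centered at hour 6.
    return 0.2 + 0.8 / (1.0 + np.exp(-(t - 6.0) / 1.5))


def _pulse_factor(t: np.ndarray, fold: float) -> np.ndarray:
    """Multiplicative RpaB~P response to a 1-h pulse starting at hour 8.

    Log-linear approach to the full fold over the first 15 min, hold for
    the rest of the pulse, then exponential return to baseline with a
    30-min time constant.
    """
    t0, t1 = PULSE_WINDOW
    factor = np.ones_like(t)
    rising = (t >= t0) & (t < t0 + PULSE_RESPONSE_H)
    factor[rising] = fold ** ((t[rising] - t0) / PULSE_RESPONSE_H)
    held = (t >= t0 + PULSE_RESPONSE_H) & (t < t1)
    factor[held] = fold
    after = t >= t1
    factor[after] = 1.0 + (fold - 1.0) * np.exp(-(t[after] - t1) / RELAXATION_TAU_H)
    return factor


def _sunset_rise(t: np.ndarray) -> np.ndarray:
    # Geometric rise by SUNSET_FOLD between hour 10 and hour 12.
    rise = np.ones_like(t)
    late = t >= 10.0
    rise[late] = SUNSET_FOLD ** ((np.minimum(t[late], 12.0) - 10.0) / 2.0)
    return rise


def make_regulator_trajectories(
    light: LightProfile,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> tuple[RegulatorTrajectory, RegulatorTrajectory]:
    """RpaA~P and RpaB~P raw time series for one light condition.

    Deterministic by default; ``noise_sd > 0`` adds seeded multiplicative
    log-normal noise (sd on the log scale).
    """
    t = light.times
    rpaa = _rpaa_ramp(t)

    if light.condition == "LowLight":
        rpab = np.ones_like(t)
    elif light.condition == "ClearDay":
        rpab = _sunset_rise(t)
    elif light.condition == "HighLightPulse":
        rpab = _pulse_factor(t, HIGH_LIGHT_FOLD)
    elif light.condition == "ShadePulse":
        rpab = _sunset_rise(t) * _pulse_factor(t, SHADE_FOLD)
    else:
        raise ValueError(f"unknown light condition {light.condition!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rpaa = rpaa * np.exp(rng.normal(0.0, noise_sd, t.shape))
        rpab = rpab * np.exp(rng.normal(0.0, noise_sd, t.shape))

    return (
        RegulatorTrajectory("RpaA~P", t, rpaa),
        RegulatorTrajectory("RpaB~P", t, rpab),
    )
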