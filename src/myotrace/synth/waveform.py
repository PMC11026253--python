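"""Parametric action-potential waveform with analytically known shape features.

The waveform is a piecewise curve — baseline, half-cosine upstroke, plateau,
then a linear or half-cosine ("sigmoidal") repolarisation — rather than a
biophysical ionic model.  The point of the parametrisation is that every shape
property a feature extractor should recover (RMP, APA, dV/dt_max, APD20/50/90,
AUC90) has a closed form, so the generator can serve as ground truth.

Conventions: voltages in mV, durations in ms, upstroke velocity in V/s
(numerically equal to mV/ms).  The *activation time* of the waveform is the
instant of maximum upstroke velocity, i.e. the midpoint of the half-cosine
upstroke; all APDs are measured from there, matching the extractor's fiducial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "APWaveformParams",
    "analytic_features",
    "generate_ap_waveform",
    "waveform_voltage",
]

REPOL_SHAPES = ("linear", "sigmoidal")

#: fraction of the repolarisation still to go at the APD90 / APD50 / APD20 levels
_REMAINING = {0.2: 0.8, 0.5: 0.5, 0.9: 0.1}


@dataclass(frozen=True)
class APWaveformParams:
    """Ground-truth parameters of one action potential.

    Parameters
    ----------
    rmp_mV:
        Resting (baseline) membrane potential, typically −85..−65 mV.
    apa_mV:
        Action potential amplitude (peak minus RMP), must be positive.
    upstroke_duration_ms:
        Full rise time of the half-cosine upstroke.
    apd90_ms:
        Target duration at 90 % repolarisation, measured from the activation
        time (midpoint of the upstroke).
    plateau_fraction:
        Unitless 0..1; scales the flat plateau held at the peak and thereby
        the APD20/APD90 ratio (0 → purely triangular repolarisation).
    repolarisation_shape:
        ``"linear"`` or ``"sigmoidal"`` (half-cosine) descent after the plateau.
    """

    rmp_mV: float = -80.0
    apa_mV: float = 100.0
    upstroke_duration_ms: float = 1.0
    apd90_ms: float = 250.0
    plateau_fraction: float = 0.25
    repolarisation_shape: str = "sigmoidal"

    def __post_init__(self) -> None:
        if not self.apa_mV > 0:
            raise ValueError(f"apa_mV must be positive, got {self.apa_mV}")
        if not self.upstroke_duration_ms > 0:
            raise ValueError("upstroke_duration_ms must be positive")
        if not self.apd90_ms > self.upstroke_duration_ms:
            raise ValueError(
                f"apd90_ms ({self.apd90_ms}) must exceed the upstroke duration "
                f"({self.upstroke_duration_ms})"
            )
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1]")
        if self.repolarisation_shape not in REPOL_SHAPES:
            raise ValueError(
                f"repolarisation_shape must be one of {REPOL_SHAPES}, "
                f"got {self.repolarisation_shape!r}"
            )

    def with_apd90(self, apd90_ms: float) -> "APWaveformParams":
        """Copy of the parameters with a different APD90 target."""
        return replace(self, apd90_ms=apd90_ms)


# x such that the half-cosine descent has completed fraction (1 - c) when the
# remaining fraction is c:  (1 + cos(pi x)) / 2 == c
def _cosine_x(c: float) -> float:
    return math.acos(2.0 * c - 1.0) / math.pi


def _geometry(params: APWaveformParams) -> dict:
    """Internal piecewise-segment bookkeeping (all times in ms from upstroke onset)."""
    tu = params.upstroke_duration_ms
    act = tu / 2.0  # activation time = max slope of the half-cosine upstroke
    plateau = params.plateau_fraction * 0.8 * params.apd90_ms
    t_plateau_end = tu + plateau
    t90 = act + params.apd90_ms
    span = t90 - t_plateau_end  # plateau end -> 90 % crossing
    if span <= 0:
        raise ValueError(
            "plateau_fraction too large for the requested apd90_ms: the plateau "
            "would end after the 90 % repolarisation time"
        )
    if params.repolarisation_shape == "linear":
        # linear descent reaching rmp at t_end; crosses the 10 %-remaining
        # level after 90 % of its total duration
        t_end = t_plateau_end + span / 0.9
        repol_dur = t_end - t_plateau_end
    else:
        repol_dur = span / _cosine_x(0.1)
        t_end = t_plateau_end + repol_dur
    return {
        "tu": tu,
        "act": act,
        "t_plateau_end": t_plateau_end,
        "repol_dur": repol_dur,
        "t_end": t_end,
        "t90": t90,
    }


def waveform_voltage(params: APWaveformParams, t_ms: np.ndarray) -> np.ndarray:
    """Evaluate the waveform at times ``t_ms`` (ms from upstroke onset)."""
    g = _geometry(params)
    t = np.asarray(t_ms, dtype=float)
    v = np.full(t.shape, params.rmp_mV, dtype=float)

    up = (t >= 0) & (t < g["tu"])
    v[up] = params.rmp_mV + params.apa_mV * (1 - np.cos(np.pi * t[up] / g["tu"])) / 2

    plat = (t >= g["tu"]) & (t < g["t_plateau_end"])
    v[plat] = params.rmp_mV + params.apa_mV

    rep = (t >= g["t_plateau_end"]) & (t < g["t_end"])
    u = t[rep] - g["t_plateau_end"]
    if params.repolarisation_shape == "linear":
        frac = 1.0 - u / g["repol_dur"]
    else:
        frac = (1 + np.cos(np.pi * u / g["repol_dur"])) / 2
    v[rep] = params.rmp_mV + params.apa_mV * frac
    return v


def ap_duration_ms(params: APWaveformParams, level: float) -> float:
    """Analytic APD at repolarisation ``level`` in {0.2, 0.5, 0.9} (or any 0<level<1)."""
    g = _geometry(params)
    c = 1.0 - level  # fraction of the amplitude still above baseline at crossing
    if params.repolarisation_shape == "linear":
        t_cross = g["t_plateau_end"] + g["repol_dur"] * (1.0 - c)
    else:
        t_cross = g["t_plateau_end"] + g["repol_dur"] * _cosine_x(c)
    return t_cross - g["act"]


def total_duration_ms(params: APWaveformParams) -> float:
    """Time from upstroke onset until the waveform is back at baseline."""
    return _geometry(params)["t_end"]


def analytic_features(params: APWaveformParams) -> dict:
    """Closed-form values of all seven shape properties of the waveform.

    Returns a dict with keys ``RMP`` (mV), ``APA`` (mV), ``dVdt_max`` (V/s),
    ``APD20``/``APD50``/``APD90`` (ms), ``AUC90`` (mV*s) and
    ``activation_ms`` (ms from upstroke onset).
    """
    g = _geometry(params)
    apa, tu = params.apa_mV, g["tu"]
    # area above baseline from activation to the 90 % crossing, piecewise:
    # second half of the half-cosine upstroke ...
    auc = apa / 2.0 * (tu / 2.0 + tu / math.pi)
    # ... the plateau ...
    auc += apa * (g["t_plateau_end"] - tu)
    # ... and the descent down to the 10 %-remaining level
    if params.repolarisation_shape == "linear":
        desc = g["t90"] - g["t_plateau_end"]
        auc += 0.5 * (1.0 + 0.1) * apa * desc
    else:
        x90 = _cosine_x(0.1)
        r = g["repol_dur"]
        auc += apa / 2.0 * (x90 * r + r / math.pi * math.sin(math.pi * x90))
    return {
        "RMP": params.rmp_mV,
        "APA": apa,
        "dVdt_max": apa * math.pi / (2.0 * tu),
        "APD20": ap_duration_ms(params, 0.2),
        "APD50": ap_duration_ms(params, 0.5),
        "APD90": params.apd90_ms,
        "AUC90": auc / 1000.0,
        "activation_ms": g["act"],
    }


def generate_ap_waveform(params: APWaveformParams, sampling_rate: float) -> np.ndarray:
    """Sample one isolated action potential at ``sampling_rate`` Hz.

    The returned series starts and ends at ``params.rmp_mV`` and contains the
    full waveform from upstroke onset to return to baseline (plus one sample
    of trailing baseline).

    Raises
    ------
    ValueError
        If ``sampling_rate`` is below 1 kHz — insufficient to resolve a
        millisecond-scale upstroke.
    """
    if sampling_rate < 1000.0:
        raise ValueError(
            f"sampling_rate must be at least 1000 Hz to resolve the upstroke, "
            f"got {sampling_rate}"
        )
    dt_ms = 1000.0 / sampling_rate
    t_end = total_duration_ms(params)
    n = int(math.ceil(t_end / dt_ms)) + 2
    t = np.arange(n) * dt_ms
    return waveform_voltage(params, t)
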