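"""Synthetic paced AP trains with stimulation artifacts, noise and injected
pro-arrhythmic abnormalities, plus a ground-truth log of every injected event.

The generator emulates the ex vivo protocol: trains of ≥20 paced beats at
0.5/1/2/3/4 Hz, a biphasic stimulation artifact preceding each upstroke, and
APD rate adaptation (APD shortens linearly with pacing frequency).  When
impaired shortening is configured, APD becomes frequency-invariant and the
tissue follows fast pacing 2:1 (every other stimulus fails to capture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..trace import TraceRecording
from .waveform import APWaveformParams, analytic_features, total_duration_ms, waveform_voltage

__all__ = [
    "AbnormalityConfig",
    "BeatTruth",
    "EventTruth",
    "RecordingTruth",
    "generate_recording",
    "PACING_FREQS_HZ",
]

#: pacing frequencies of the recording protocol
PACING_FREQS_HZ = (0.5, 1.0, 2.0, 3.0, 4.0)

#: default linear APD90 rate-adaptation slope (ms of shortening per Hz)
DEFAULT_RATE_ADAPTATION_MS_PER_HZ = 41.46


@dataclass(frozen=True)
class AbnormalityConfig:
    """Per-recording abnormality injection settings.

    ``ead_prob`` is per captured beat; ``extrasystole_prob`` and
    ``couplet_prob`` are per diastolic interval (an interval hosts at most one
    spontaneous event, couplet taking precedence); ``alternans_depth_ms`` is
    the peak-to-peak beat-to-beat APD90 alternation; pacing at a frequency in
    ``capture_failure_freqs_Hz`` produces 2:1 capture with frequency-invariant
    APD (the impaired-shortening phenotype).
    """

    ead_prob: float = 0.0
    extrasystole_prob: float = 0.0
    couplet_prob: float = 0.0
    alternans_depth_ms: float = 0.0
    capture_failure_freqs_Hz: frozenset = frozenset()
    ead_amp_mV: float = 15.0
    ead_width_ms: float = 30.0
    couplet_interval_ms: float = 250.0

    def __post_init__(self) -> None:
        for name in ("ead_prob", "extrasystole_prob", "couplet_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.alternans_depth_ms < 0:
            raise ValueError("alternans_depth_ms must be non-negative")
        object.__setattr__(
            self, "capture_failure_freqs_Hz", frozenset(self.capture_failure_freqs_Hz)
        )

    @property
    def impaired_shortening(self) -> bool:
        return len(self.capture_failure_freqs_Hz) > 0


@dataclass
class BeatTruth:
    """Ground truth for one paced beat (or stimulus)."""

    stim_time_s: float
    captured: bool
    activation_time_s: float | None = None
    features: dict = field(default_factory=dict)


@dataclass
class EventTruth:
    """One injected abnormality event."""

    type: str          # 'ead' | 'extrasystole' | 'couplet'
    time_s: float
    beat_index: int | None = None


@dataclass
class RecordingTruth:
    """Ground-truth log accompanying a generated recording."""

    beats: list
    events: list
    pacing_freq: float
    waveform: APWaveformParams

    @property
    def n_captured(self) -> int:
        return sum(1 for b in self.beats if b.captured)

    def events_of(self, kind: str) -> list:
        return [e for e in self.events if e.type == kind]


def _biphasic_artifact(t_ms: np.ndarray, amp_mV: float, width_ms: float = 2.0) -> np.ndarray:
    """One full sine cycle over ``width_ms`` — positive then negative lobe."""
    out = np.zeros_like(t_ms)
    inside = (t_ms >= 0) & (t_ms < width_ms)
    out[inside] = amp_mV * np.sin(2 * np.pi * t_ms[inside] / width_ms)
    return out


def _ead_bump(t_ms: np.ndarray, center_ms: float, amp_mV: float, width_ms: float) -> np.ndarray:
    """Raised-cosine depolarising hump of full width ``width_ms``."""
    out = np.zeros_like(t_ms)
    u = t_ms - center_ms
    inside = np.abs(u) < width_ms / 2
    out[inside] = amp_mV * (1 + np.cos(2 * np.pi * u[inside] / width_ms)) / 2
    return out


def adapted_apd90(
    waveform: APWaveformParams,
    pacing_freq: float,
    impaired: bool,
    slope_ms_per_hz: float = DEFAULT_RATE_ADAPTATION_MS_PER_HZ,
    min_apd90_ms: float = 60.0,
) -> float:
    """APD90 at ``pacing_freq``, treating ``waveform.apd90_ms`` as the 1 Hz value.

    Healthy tissue shortens its APD linearly with rate; impaired tissue does not.
    """
    if impaired:
        return waveform.apd90_ms
    return max(waveform.apd90_ms - slope_ms_per_hz * (pacing_freq - 1.0), min_apd90_ms)


def generate_recording(
    waveform: APWaveformParams,
    pacing_freq: float,
    n_beats: int,
    abnormalities: AbnormalityConfig | None = None,
    noise_sd: float = 0.0,
    artifact_amp: float = 25.0,
    seed: int = 0,
    sampling_rate: float = 10_000.0,
    upstroke_latency_ms: float = 6.0,
    rate_adaptation_ms_per_hz: float = DEFAULT_RATE_ADAPTATION_MS_PER_HZ,
    start_offset_s: float = 0.1,
    patient_id: str = "",
    location_id: str = "",
) -> tuple[TraceRecording, RecordingTruth]:
    """Generate a paced AP train and the log of everything injected into it.

    ``n_beats`` is the number of stimuli delivered; with 2:1 capture failure
    only every other stimulus elicits an AP.  ``waveform.apd90_ms`` is the
    1 Hz reference APD90; rate adaptation is applied per
    :func:`adapted_apd90`.  Same seed ⇒ bit-identical output.

    Raises
    ------
    ValueError
        If the adapted AP (plus latency and baseline margin) does not fit in
        the pacing cycle and capture failure is not configured at this
        frequency — a physically inconsistent request.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if pacing_freq <= 0:
        raise ValueError("pacing_freq must be positive")
    abn = abnormalities or AbnormalityConfig()
    rng = np.random.default_rng(seed)

    cycle_ms = 1000.0 / pacing_freq
    fails_here = any(math.isclose(pacing_freq, f) for f in abn.capture_failure_freqs_Hz)
    apd90_f = adapted_apd90(
        waveform, pacing_freq, abn.impaired_shortening, rate_adaptation_ms_per_hz
    )
    longest_apd90 = apd90_f + abn.alternans_depth_ms / 2.0
    footprint_ms = (
        upstroke_latency_ms
        + total_duration_ms(waveform.with_apd90(longest_apd90))
        + 25.0  # diastolic baseline needed by the feature extractor
    )
    effective_cycle = cycle_ms * (2.0 if fails_here else 1.0)
    if footprint_ms > effective_cycle:
        raise ValueError(
            f"action potential footprint ({footprint_ms:.0f} ms) exceeds the "
            f"pacing cycle ({effective_cycle:.0f} ms) at {pacing_freq} Hz and "
            "capture failure is not configured: physically inconsistent request"
        )

    dt_ms = 1000.0 / sampling_rate
    total_ms = start_offset_s * 1000.0 + n_beats * cycle_ms + 300.0
    n_samples = int(round(total_ms / dt_ms))
    t_ms = np.arange(n_samples) * dt_ms
    v = np.full(n_samples, waveform.rmp_mV)

    stim_times_ms = start_offset_s * 1000.0 + np.arange(n_beats) * cycle_ms
    beats: list[BeatTruth] = []
    events: list[EventTruth] = []

    def add_segment(onset_ms: float, curve_params: APWaveformParams) -> None:
        dur = total_duration_ms(curve_params)
        i0 = int(round(onset_ms / dt_ms))
        i1 = min(int(round((onset_ms + dur) / dt_ms)) + 2, n_samples)
        local = t_ms[i0:i1] - onset_ms
        v[i0:i1] += waveform_voltage(curve_params, local) - curve_params.rmp_mV

    # ---- paced beats -------------------------------------------------------
    repol_end_ms: list[float] = []  # end of each captured AP, for diastole bookkeeping
    for k, stim_ms in enumerate(stim_times_ms):
        # stimulation artifact always present
        i0 = int(round(stim_ms / dt_ms))
        i1 = min(i0 + int(round(2.0 / dt_ms)) + 1, n_samples)
        v[i0:i1] += _biphasic_artifact(t_ms[i0:i1] - stim_ms, artifact_amp)

        captured = not (fails_here and k % 2 == 1)
        if not captured:
            beats.append(BeatTruth(stim_time_s=stim_ms / 1000.0, captured=False))
            continue

        beat_apd90 = apd90_f
        if abn.alternans_depth_ms > 0:
            beat_apd90 += (abn.alternans_depth_ms / 2.0) * (1 if k % 2 == 0 else -1)
        bp = waveform.with_apd90(beat_apd90)
        onset_ms = stim_ms + upstroke_latency_ms
        add_segment(onset_ms, bp)
        feats = analytic_features(bp)
        act_ms = onset_ms + feats.pop("activation_ms")
        beats.append(
            BeatTruth(
                stim_time_s=stim_ms / 1000.0,
                captured=True,
                activation_time_s=act_ms / 1000.0,
                features=feats,
            )
        )

        # EAD: depolarising hump between the APD20 and APD90 times
        if abn.ead_prob > 0 and rng.random() < abn.ead_prob:
            lo = feats["APD20"] + abn.ead_width_ms / 2 + 5.0
            hi = feats["APD90"] - abn.ead_width_ms / 2 - 5.0
            if hi > lo:
                center = act_ms + rng.uniform(lo, hi)
                j0 = int(round((center - abn.ead_width_ms) / dt_ms))
                j1 = min(int(round((center + abn.ead_width_ms) / dt_ms)), n_samples)
                v[j0:j1] += _ead_bump(
                    t_ms[j0:j1], center, abn.ead_amp_mV, abn.ead_width_ms
                )
                events.append(EventTruth("ead", center / 1000.0, beat_index=k))
        repol_end_ms.append(act_ms + feats["APD90"])

    # ---- spontaneous activity in diastolic intervals -----------------------
    spont_dur = total_duration_ms(waveform.with_apd90(apd90_f))
    for k in range(n_beats):
        if not beats[k].captured:
            continue
        t90 = (beats[k].activation_time_s or 0.0) * 1000.0 + beats[k].features["APD90"]
        next_stim = stim_times_ms[k + 1] if k + 1 < n_beats else total_ms - 100.0
        lo = t90 + 100.0  # diastolic phase ≥ 100 ms after the previous APD90
        p = rng.random()
        if abn.couplet_prob > 0 and p < abn.couplet_prob:
            hi = next_stim - (abn.couplet_interval_ms + spont_dur) - 10.0
            if hi > lo:
                onset = rng.uniform(lo, hi)
                sp = waveform.with_apd90(apd90_f)
                for j in range(2):
                    add_segment(onset + j * abn.couplet_interval_ms, sp)
                events.append(EventTruth("couplet", onset / 1000.0, beat_index=k))
        elif abn.extrasystole_prob > 0 and p < abn.couplet_prob + abn.extrasystole_prob:
            hi = next_stim - spont_dur - 10.0
            if hi > lo:
                onset = rng.uniform(lo, hi)
                add_segment(onset, waveform.with_apd90(apd90_f))
                events.append(EventTruth("extrasystole", onset / 1000.0, beat_index=k))

    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, size=n_samples)

    rec = TraceRecording(
        samples=v,
        sampling_rate=sampling_rate,
        stim_times=stim_times_ms / 1000.0,
        pacing_freq=pacing_freq,
        patient_id=patient_id,
        location_id=location_id,
        seed=seed,
    )
    truth = RecordingTruth(beats=beats, events=events, pacing_freq=pacing_freq, waveform=waveform)
    return rec, truth
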