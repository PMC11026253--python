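"""Detection of pro-arrhythmic tissue abnormalities in segmented recordings.

Three tissue-arrhythmia event types are recognised — early
afterdepolarisations (EADs, depolarising deflections during repolarisation),
extrasystoles (non-stimulated full AP between paced beats), and spontaneous
couplets (two stimulation-independent AP in quick succession) — plus two
non-event abnormalities: APD alternans (sustained beat-to-beat long–short
alternation) and impaired APD shortening (failure of rate adaptation with
loss of 1:1 capture at fast pacing).

All thresholds were chosen as config-exposed defaults; the original
identification of these phenomena was visual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .apfeatures import APMeasurement, APWindow, segment_aps, measure_ap, qc_ap
from .trace import TraceRecording

__all__ = [
    "AbnormalityReport",
    "detect_eads",
    "detect_extrasystoles",
    "detect_spontaneous_couplets",
    "detect_apd_alternans",
    "detect_impaired_shortening",
    "analyse_recording",
    "combine_reports",
]

EAD_MIN_PROMINENCE_MV = 5.0
EAD_MIN_DVDT_VS = 0.5
COUPLET_MAX_INTERVAL_MS = 500.0
ALTERNANS_MIN_BEATS = 6
ALTERNANS_ABS_MS = 5.0
ALTERNANS_REL = 0.05
CAPTURE_FAILURE_FREQS = (2.0, 3.0, 4.0)


@dataclass
class AbnormalityReport:
    """Per-location abnormality findings."""

    events: list = field(default_factory=list)  # (type, time_s) tuples
    apd_alternans: dict = field(default_factory=dict)       # freq -> True/False/None
    impaired_shortening: bool | None = None                 # None = indeterminate
    failing_frequencies: list = field(default_factory=list)
    patient_id: str = ""
    location_id: str = ""

    @property
    def tissue_arrhythmia(self) -> bool:
        return len(self.events) > 0

    @property
    def any_alternans(self) -> bool:
        return any(v is True for v in self.apd_alternans.values())

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "location_id": self.location_id,
            "events": [{"type": t, "time_s": s} for t, s in self.events],
            "tissue_arrhythmia": self.tissue_arrhythmia,
            "apd_alternans": {str(k): v for k, v in self.apd_alternans.items()},
            "impaired_shortening": self.impaired_shortening,
            "failing_frequencies": list(self.failing_frequencies),
        }


def _smooth(v: np.ndarray, fs: float, width_ms: float = 1.0) -> np.ndarray:
    n = max(int(round(width_ms * fs / 1000.0)), 1)
    if n <= 1:
        return v
    kernel = np.ones(n) / n
    return np.convolve(v, kernel, mode="same")


def detect_eads(
    window: APWindow,
    rmp: float,
    apa: float,
    min_prominence_mV: float = EAD_MIN_PROMINENCE_MV,
    min_dvdt_Vs: float = EAD_MIN_DVDT_VS,
) -> list[float]:
    """Times (s) of early afterdepolarisations within one AP.

    An EAD is a local depolarising deflection during repolarisation — between
    the APD20 time and the 90 %-repolarisation level — with prominence of at
    least ``min_prominence_mV`` on the (lightly smoothed) trace and a
    preceding positive dV/dt of at least ``min_dvdt_Vs``.
    """
    fs = window.fs
    v = window.rec.samples
    # search segment: from the first crossing below the 20 % level to the
    # first crossing below the 90 % level (or window end)
    thr20 = rmp + 0.8 * apa
    thr90 = rmp + 0.1 * apa
    i_act = int(round(window.activation_time_s * fs))
    seg = v[i_act:window.end]
    peak = int(np.argmax(seg))
    below20 = np.flatnonzero(seg[peak:] < thr20)
    if below20.size == 0:
        return []
    s0 = peak + int(below20[0])
    below90 = np.flatnonzero(seg[s0:] < thr90)
    s1 = s0 + int(below90[0]) if below90.size else seg.size
    if s1 - s0 < int(round(5e-3 * fs)):
        return []
    sm = _smooth(seg[s0:s1], fs)
    peaks, props = find_peaks(sm, prominence=min_prominence_mV)
    dv = np.gradient(sm) * fs / 1000.0  # V/s
    out = []
    for p in peaks:
        pre = dv[max(p - int(round(10e-3 * fs)), 0):p + 1]
        if pre.size and np.max(pre) >= min_dvdt_Vs:
            out.append((i_act + s0 + p) / fs)
    return out


def _spontaneous_groups(
    windows: list[APWindow],
    couplet_max_interval_ms: float,
) -> list[list[APWindow]]:
    """Group consecutive spontaneous AP closer than the couplet interval."""
    groups: list[list[APWindow]] = []
    current: list[APWindow] = []
    for w in windows:
        if w.tag != "spontaneous":
            if current:
                groups.append(current)
                current = []
            continue
        if (
            current
            and (w.activation_time_s - current[-1].activation_time_s) * 1000.0
            <= couplet_max_interval_ms
        ):
            current.append(w)
        else:
            if current:
                groups.append(current)
            current = [w]
    if current:
        groups.append(current)
    return groups


def detect_extrasystoles(
    rec: TraceRecording,
    windows: list[APWindow],
    couplet_max_interval_ms: float = COUPLET_MAX_INTERVAL_MS,
) -> list[float]:
    """Times (s) of isolated spontaneous AP (not part of a couplet)."""
    return [
        g[0].activation_time_s
        for g in _spontaneous_groups(windows, couplet_max_interval_ms)
        if len(g) == 1
    ]


def detect_spontaneous_couplets(
    rec: TraceRecording,
    windows: list[APWindow],
    couplet_max_interval_ms: float = COUPLET_MAX_INTERVAL_MS,
) -> list[float]:
    """Times (s) of spontaneous couplets: ≥2 consecutive spontaneous AP with
    inter-AP interval at most ``couplet_max_interval_ms``; each run is one event."""
    return [
        g[0].activation_time_s
        for g in _spontaneous_groups(windows, couplet_max_interval_ms)
        if len(g) >= 2
    ]


def detect_apd_alternans(
    apd_sequence_ms,
    min_beats: int = ALTERNANS_MIN_BEATS,
    abs_threshold_ms: float = ALTERNANS_ABS_MS,
    rel_threshold: float = ALTERNANS_REL,
) -> bool | None:
    """APD alternans over a sequence of consecutive accepted APD values (ms).

    True iff successive APD differences alternate in sign over at least
    ``min_beats`` consecutive beats and the mean |ΔAPD| within that run is at
    least ``max(abs_threshold_ms, rel_threshold × mean APD)``.  Returns
    ``None`` (indeterminate) for sequences shorter than ``min_beats``.
    """
    apd = np.asarray(list(apd_sequence_ms), dtype=float)
    apd = apd[np.isfinite(apd)]
    if apd.size < min_beats:
        return None
    diffs = np.diff(apd)
    signs = np.sign(diffs)
    threshold = max(abs_threshold_ms, rel_threshold * float(np.mean(apd)))
    # scan maximal runs of strictly alternating, non-zero difference signs
    i = 0
    while i < diffs.size:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < diffs.size and signs[j + 1] == -signs[j]:
            j += 1
        run = diffs[i:j + 1]  # spans len(run) + 1 beats
        if run.size + 1 >= min_beats and np.mean(np.abs(run)) >= threshold:
            return True
        i = j + 1
    return False


def detect_impaired_shortening(
    per_frequency_summaries,
    capture_ratios: dict,
    check_freqs=CAPTURE_FAILURE_FREQS,
) -> tuple[bool | None, list[float]]:
    """Impaired APD shortening / failure to follow fast pacing.

    ``per_frequency_summaries`` maps pacing frequency (Hz) to mean APD90 (ms)
    at that frequency; ``capture_ratios`` maps frequency to (captured AP /
    delivered stimuli).  Flagged iff the capture ratio is below 1 at any of
    the fast frequencies, or the mean APD90 at a fast frequency exceeds the
    cycle length there.  Indeterminate (``None``) unless summaries exist at
    ≥2 frequencies including at least one fast one.
    """
    freqs = sorted(set(per_frequency_summaries) | set(capture_ratios))
    fast = [f for f in freqs if any(np.isclose(f, c) for c in check_freqs)]
    if len(freqs) < 2 or not fast:
        return None, []
    failing = []
    for f in fast:
        ratio = capture_ratios.get(f, 1.0)
        if ratio < 0.99:
            failing.append(f)
            continue
        apd90 = per_frequency_summaries.get(f)
        if apd90 is not None and np.isfinite(apd90) and apd90 > 1000.0 / f:
            failing.append(f)
    return (len(failing) > 0), failing


def analyse_recording(
    rec: TraceRecording,
    ead_min_prominence_mV: float = EAD_MIN_PROMINENCE_MV,
    couplet_max_interval_ms: float = COUPLET_MAX_INTERVAL_MS,
    alternans_min_beats: int = ALTERNANS_MIN_BEATS,
) -> tuple[AbnormalityReport, list[APMeasurement], float]:
    """Run all per-recording detectors on one paced recording.

    Returns the (single-frequency) report, the QC'd measurements, and the
    capture ratio at the recording's pacing frequency.
    """
    windows = segment_aps(rec)
    measurements = []
    for w in windows:
        m = measure_ap(w)
        qc_ap(m)
        measurements.append(m)

    report = AbnormalityReport(patient_id=rec.patient_id, location_id=rec.location_id)
    for w, m in zip(windows, measurements):
        if m.accepted and np.isfinite(m.apd20) and np.isfinite(m.apd90):
            for t in detect_eads(w, m.rmp, m.apa, ead_min_prominence_mV):
                report.events.append(("ead", t))
    for t in detect_extrasystoles(rec, windows, couplet_max_interval_ms):
        report.events.append(("extrasystole", t))
    for t in detect_spontaneous_couplets(rec, windows, couplet_max_interval_ms):
        report.events.append(("couplet", t))
    report.events.sort(key=lambda e: e[1])

    apd_seq = [
        m.apd90
        for w, m in zip(windows, measurements)
        if w.tag == "stimulated" and m.accepted
    ]
    report.apd_alternans[rec.pacing_freq] = detect_apd_alternans(
        apd_seq, min_beats=alternans_min_beats
    )

    n_stim = int(rec.stim_times.size)
    n_capt = sum(1 for w in windows if w.tag == "stimulated")
    ratio = n_capt / n_stim if n_stim else np.nan
    return report, measurements, ratio


def combine_reports(
    reports: list[AbnormalityReport],
    apd90_by_freq: dict,
    capture_ratios: dict,
) -> AbnormalityReport:
    """Merge per-frequency reports from one location and evaluate impaired
    shortening across frequencies."""
    merged = AbnormalityReport(
        patient_id=reports[0].patient_id if reports else "",
        location_id=reports[0].location_id if reports else "",
    )
    for r in reports:
        merged.events.extend(r.events)
        merged.apd_alternans.update(r.apd_alternans)
    merged.events.sort(key=lambda e: e[1])
    flag, failing = detect_impaired_shortening(apd90_by_freq, capture_ratios)
    merged.impaired_shortening = flag
    merged.failing_frequencies = failing
    return merged
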