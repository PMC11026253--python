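"""Segmentation of paced recordings into single action potentials, QC, and
computation of the seven AP shape properties.

Fiducials and estimators follow standard cardiac-EP conventions:

* activation time = time of maximum upstroke velocity (dV/dt_max);
* RMP = median of the last 20 ms of diastolic baseline before the stimulus
  blanking window (or before the upstroke for spontaneous AP);
* APA = peak potential − RMP;
* APD_x = time from activation to the first downward crossing of
  RMP + (1 − x) · APA, with linear interpolation between samples;
* AUC90 = trapezoidal integral of (V − RMP) from activation to the APD90
  crossing, in mV·s.

QC rejects AP with recording artifacts, APA strictly below 75 mV, or
insufficient separation of the upstroke from the stimulation artifact
(dV/dt_max inside the post-stimulus blanking window), plus AP lacking a
usable baseline or failing to repolarise before the window ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import TraceRecording

__all__ = [
    "APWindow",
    "APMeasurement",
    "segment_aps",
    "compute_rmp",
    "compute_apa",
    "compute_dvdt_max",
    "compute_apd",
    "compute_auc90",
    "measure_ap",
    "qc_ap",
    "extract_features",
    "summarise_location",
    "PROPERTIES",
]

PROPERTIES = ("RMP", "APA", "dVdt_max", "APD20", "APD50", "APD90", "AUC90")

APA_REJECT_THRESHOLD_MV = 75.0      # reject strictly below this amplitude
DEFAULT_BLANKING_MS = 5.0           # post-stimulus artifact blanking
DEFAULT_CAPTURE_WINDOW_MS = 50.0    # upstroke within this after a stimulus => paced
ARTIFACT_DVDT_VS = 1000.0           # |dV/dt| beyond this outside the upstroke
ARTIFACT_VOLTAGE_MV = 60.0          # excursions above this are non-physiological


class QCStatus:
    ACCEPTED = "accepted"
    ARTIFACT = "artifact"
    LOW_AMPLITUDE = "low_amplitude"
    UPSTROKE_IN_ARTIFACT = "upstroke_in_artifact"
    NO_BASELINE = "no_baseline"
    INCOMPLETE_REPOLARISATION = "incomplete_repolarisation"


@dataclass
class APWindow:
    """One segmented AP: a slice of the recording containing a single upstroke."""

    rec: TraceRecording
    start: int                  # inclusive sample index
    end: int                    # exclusive sample index
    activation_time_s: float    # time of dV/dt_max
    tag: str                    # 'stimulated' | 'spontaneous'
    stim_time_s: float | None = None

    @property
    def samples(self) -> np.ndarray:
        return self.rec.samples[self.start:self.end]

    @property
    def fs(self) -> float:
        return self.rec.sampling_rate


@dataclass
class APMeasurement:
    """One QC'd action potential and its seven shape properties."""

    rmp: float = np.nan          # mV
    apa: float = np.nan          # mV
    dvdt_max: float = np.nan     # V/s
    apd20: float = np.nan        # ms
    apd50: float = np.nan        # ms
    apd90: float = np.nan        # ms
    auc90: float = np.nan        # mV*s
    activation_time: float = np.nan  # s from recording start
    tag: str = "stimulated"
    pacing_freq: float = np.nan
    patient_id: str = ""
    location_id: str = ""
    qc_status: str = QCStatus.ACCEPTED
    flags: dict = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.qc_status == QCStatus.ACCEPTED

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "location_id": self.location_id,
            "pacing_freq": self.pacing_freq,
            "activation_time_s": self.activation_time,
            "tag": self.tag,
            "RMP": self.rmp,
            "APA": self.apa,
            "dVdt_max": self.dvdt_max,
            "APD20": self.apd20,
            "APD50": self.apd50,
            "APD90": self.apd90,
            "AUC90": self.auc90,
            "qc_status": self.qc_status,
        }


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, end) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = ([0] if mask[0] else []) + list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1) + ([mask.size] if mask[-1] else [])
    return list(zip(starts, ends))


def segment_aps(
    rec: TraceRecording,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    capture_window_ms: float = DEFAULT_CAPTURE_WINDOW_MS,
    min_region_ms: float = 4.0,
    detect_frac: float = 0.4,
    full_ap_frac: float = 0.6,
    min_amplitude_mV: float = 30.0,
) -> list[APWindow]:
    """Segment a recording into non-overlapping single-AP windows.

    Candidate AP are contiguous regions staying above a threshold at
    ``detect_frac`` of the trace amplitude for at least ``min_region_ms``
    (which rejects the 2 ms biphasic stimulation artifact) and reaching
    ``full_ap_frac`` of the amplitude (which rejects partial deflections such
    as late EADs re-crossing the threshold).  A window is tagged
    ``stimulated`` iff its dV/dt_max falls within ``capture_window_ms`` after
    a stimulus.

    Returns an empty list when no upstroke is detectable; raises on an empty
    trace.
    """
    if rec.n_samples == 0:
        raise ValueError("empty trace")
    v = rec.samples
    fs = rec.sampling_rate
    baseline = float(np.median(v))
    amp = float(np.max(v) - baseline)
    if amp < min_amplitude_mV:
        return []
    thr = baseline + detect_frac * amp
    min_len = int(round(min_region_ms * fs / 1000.0))

    regions = [
        (s, e)
        for s, e in _runs_above(v > thr)
        if (e - s) >= min_len and np.max(v[s:e]) >= baseline + full_ap_frac * amp
    ]
    if not regions:
        return []

    dv = np.diff(v)  # mV per sample; time of dv[i] is (i + 0.5) / fs
    back = int(round(10.0 * fs / 1000.0))
    fwd = int(round(2.0 * fs / 1000.0))
    act_times = []
    for s, e in regions:
        lo = max(s - back, 0)
        hi = min(s + fwd, dv.size)
        i = lo + int(np.argmax(dv[lo:hi]))
        act_times.append((i + 0.5) / fs)

    windows: list[APWindow] = []
    margin = int(round(35.0 * fs / 1000.0))
    gap = int(round(30.0 * fs / 1000.0))
    for j, ((s, e), act) in enumerate(zip(regions, act_times)):
        w_start = max(int(round(act * fs)) - margin, 0)
        if j > 0:
            w_start = max(w_start, regions[j - 1][1])
        w_end = (
            max(int(round(act_times[j + 1] * fs)) - gap, e)
            if j + 1 < len(regions)
            else rec.n_samples
        )
        # match to a stimulus: upstroke within the capture window after it
        stim_time = None
        if rec.stim_times.size:
            deltas = act - rec.stim_times
            ok = (deltas >= 0) & (deltas <= capture_window_ms / 1000.0)
            if ok.any():
                stim_time = float(rec.stim_times[np.flatnonzero(ok)[-1]])
        windows.append(
            APWindow(
                rec=rec,
                start=w_start,
                end=w_end,
                activation_time_s=act,
                tag="stimulated" if stim_time is not None else "spontaneous",
                stim_time_s=stim_time,
            )
        )
    return windows


def _baseline_bounds(window: APWindow, baseline_ms: float = 20.0) -> tuple[int, int] | None:
    """Sample range of the pre-upstroke baseline, or None if unavailable."""
    fs = window.fs
    if window.tag == "stimulated" and window.stim_time_s is not None:
        hi = int(round(window.stim_time_s * fs))
        lo = hi - int(round(baseline_ms * fs / 1000.0))
    else:
        hi = int(round((window.activation_time_s - 0.005) * fs))
        lo = hi - int(round(baseline_ms * fs / 1000.0))
    if lo < window.start or lo < 0:
        return None
    return lo, hi


def compute_rmp(window: APWindow, blanking_ms: float = DEFAULT_BLANKING_MS) -> float:
    """Median of the last 20 ms of diastolic baseline; NaN if unavailable."""
    bounds = _baseline_bounds(window)
    if bounds is None:
        return np.nan
    lo, hi = bounds
    return float(np.median(window.rec.samples[lo:hi]))


def compute_apa(window: APWindow, rmp: float) -> float:
    """Action potential amplitude: peak potential after activation minus RMP."""
    fs = window.fs
    i_act = int(round(window.activation_time_s * fs))
    seg = window.rec.samples[i_act:window.end]
    if seg.size == 0:
        return np.nan
    return float(np.max(seg) - rmp)


def compute_dvdt_max(window: APWindow) -> float:
    """Maximum upstroke velocity (V/s) around the activation time."""
    fs = window.fs
    i = int(round(window.activation_time_s * fs))
    lo = max(i - int(round(2e-3 * fs)), max(window.start, 0))
    hi = min(i + int(round(2e-3 * fs)), window.rec.n_samples - 1)
    dv = np.diff(window.rec.samples[lo:hi + 1])
    if dv.size == 0:
        return np.nan
    return float(np.max(dv) * fs / 1000.0)  # mV/sample -> mV/ms == V/s


def _peak_index(window: APWindow) -> int:
    fs = window.fs
    i_act = int(round(window.activation_time_s * fs))
    seg = window.rec.samples[i_act:window.end]
    return i_act + int(np.argmax(seg))


def compute_apd(window: APWindow, rmp: float, apa: float, level: float) -> float:
    """APD at repolarisation ``level`` (0.2/0.5/0.9), ms; NaN when the
    repolarisation never crosses the threshold inside the window."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    thr = rmp + (1.0 - level) * apa
    v = window.rec.samples
    fs = window.fs
    start = _peak_index(window)
    below = np.flatnonzero(v[start:window.end] < thr)
    if below.size == 0:
        return np.nan
    j = start + int(below[0])
    if j == 0:
        return np.nan
    v0, v1 = v[j - 1], v[j]
    frac = (v0 - thr) / (v0 - v1) if v1 != v0 else 0.0
    t_cross = (j - 1 + frac) / fs
    return (t_cross - window.activation_time_s) * 1000.0


def compute_auc90(window: APWindow, rmp: float, apd90: float) -> float:
    """Trapezoidal area of (V − RMP) from activation to the APD90 crossing, mV·s."""
    if not np.isfinite(apd90):
        return np.nan
    fs = window.fs
    v = window.rec.samples
    t0 = window.activation_time_s
    t1 = t0 + apd90 / 1000.0
    i0 = int(np.ceil(t0 * fs))
    i1 = int(np.floor(t1 * fs))
    i1 = min(i1, window.end - 1)
    if i1 <= i0:
        return 0.0
    core = float(np.trapezoid(v[i0:i1 + 1] - rmp, dx=1.0 / fs))
    # fractional leading segment t0 .. i0/fs (linear interpolation at t0)
    if i0 >= 1:
        f = i0 - t0 * fs
        va = v[i0] + (v[i0 - 1] - v[i0]) * f
        core += 0.5 * (va + v[i0] - 2 * rmp) * (f / fs)
    # fractional trailing segment i1/fs .. t1
    if i1 + 1 < window.rec.n_samples:
        f = t1 * fs - i1
        vb = v[i1] + (v[i1 + 1] - v[i1]) * f
        core += 0.5 * (v[i1] + vb - 2 * rmp) * (f / fs)
    return core  # (mV) x (s)


def measure_ap(
    window: APWindow,
    blanking_ms: float = DEFAULT_BLANKING_MS,
) -> APMeasurement:
    """Compute all shape properties and diagnostic flags for one AP window.

    QC is *not* applied here; pass the result through :func:`qc_ap`.
    """
    rec = window.rec
    fs = window.fs
    m = APMeasurement(
        activation_time=window.activation_time_s,
        tag=window.tag,
        pacing_freq=rec.pacing_freq,
        patient_id=rec.patient_id,
        location_id=rec.location_id,
    )
    m.flags["has_baseline"] = _baseline_bounds(window) is not None
    m.rmp = compute_rmp(window, blanking_ms)
    if np.isfinite(m.rmp):
        m.apa = compute_apa(window, m.rmp)
    m.dvdt_max = compute_dvdt_max(window)

    sep_ok = True
    if window.tag == "stimulated" and window.stim_time_s is not None:
        sep_ok = window.activation_time_s >= window.stim_time_s + blanking_ms / 1000.0
    m.flags["upstroke_separated"] = sep_ok

    if np.isfinite(m.rmp) and np.isfinite(m.apa) and m.apa > 0:
        m.apd20 = compute_apd(window, m.rmp, m.apa, 0.2)
        m.apd50 = compute_apd(window, m.rmp, m.apa, 0.5)
        m.apd90 = compute_apd(window, m.rmp, m.apa, 0.9)
        m.auc90 = compute_auc90(window, m.rmp, m.apd90)
    m.flags["repolarised"] = bool(np.isfinite(m.apd90))

    # artifact scan: derivative spikes or non-physiological voltages outside
    # the upstroke (and outside stimulus blanking intervals)
    v = window.samples
    dv = np.diff(v) * fs / 1000.0
    mask = np.ones(dv.size, dtype=bool)
    i_act = int(round(window.activation_time_s * fs)) - window.start
    u = int(round(3e-3 * fs))
    mask[max(i_act - u, 0):i_act + u] = False
    for st in rec.stim_times:
        i = int(round(st * fs)) - window.start
        if -dv.size < i < dv.size:
            mask[max(i - 2, 0):i + int(round(blanking_ms * fs / 1000.0))] = False
    artifact = bool(np.any(np.abs(dv[mask]) > ARTIFACT_DVDT_VS)) or bool(
        np.any(v > ARTIFACT_VOLTAGE_MV)
    )
    m.flags["artifact_free"] = not artifact
    return m


def qc_ap(
    m: APMeasurement,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    apa_threshold_mV: float = APA_REJECT_THRESHOLD_MV,
) -> str:
    """Assign the QC status for one measured AP.

    The amplitude rule is strict: APA exactly at the threshold is accepted,
    anything below it is rejected.
    """
    if not m.flags.get("has_baseline", False) or not np.isfinite(m.rmp):
        status = QCStatus.NO_BASELINE
    elif not m.flags.get("upstroke_separated", True):
        status = QCStatus.UPSTROKE_IN_ARTIFACT
    elif not m.flags.get("artifact_free", True):
        status = QCStatus.ARTIFACT
    elif np.isfinite(m.apa) and m.apa < apa_threshold_mV:
        status = QCStatus.LOW_AMPLITUDE
    elif not m.flags.get("repolarised", False):
        status = QCStatus.INCOMPLETE_REPOLARISATION
    else:
        status = QCStatus.ACCEPTED
    m.qc_status = status
    return status


def extract_features(
    rec: TraceRecording,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    capture_window_ms: float = DEFAULT_CAPTURE_WINDOW_MS,
    apa_threshold_mV: float = APA_REJECT_THRESHOLD_MV,
) -> list[APMeasurement]:
    """Segment, measure, and QC every AP in a recording."""
    out = []
    for w in segment_aps(rec, blanking_ms, capture_window_ms):
        m = measure_ap(w, blanking_ms)
        qc_ap(m, blanking_ms, apa_threshold_mV)
        out.append(m)
    return out


def measurements_frame(measurements: list[APMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in measurements])


def summarise_location(
    measurements: list[APMeasurement],
    min_ap_per_freq: int = 20,
) -> pd.DataFrame:
    """Per-frequency arithmetic mean of each property over accepted AP.

    One summary row per pacing frequency, mirroring "one data point per
    recording location" reporting.  Emits a warning when a frequency has
    fewer than ``min_ap_per_freq`` accepted AP, and returns an empty frame
    (with a warning) when nothing was accepted.
    """
    accepted = [m for m in measurements if m.accepted]
    if not accepted:
        warnings.warn("no accepted AP in this location; empty summary", stacklevel=2)
        return pd.DataFrame(columns=["pacing_freq", "n_ap", *PROPERTIES])
    df = measurements_frame(accepted)
    rows = []
    for freq, g in df.groupby("pacing_freq", sort=True):
        if len(g) < min_ap_per_freq:
            warnings.warn(
                f"only {len(g)} accepted AP at {freq} Hz "
                f"(protocol minimum is {min_ap_per_freq})",
                stacklevel=2,
            )
        rows.append(
            {
                "pacing_freq": freq,
                "n_ap": len(g),
                **{p: float(g[p].mean()) for p in PROPERTIES},
            }
        )
    return pd.DataFrame(rows)
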