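"""Feature computations against geometric oracles, QC rules, summaries."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotrace.apfeatures import (
    APMeasurement,
    APWindow,
    QCStatus,
    compute_apa,
    compute_apd,
    compute_auc90,
    compute_dvdt_max,
    compute_rmp,
    extract_features,
    qc_ap,
    segment_aps,
    summarise_location,
)
from myotrace.synth import APWaveformParams, AbnormalityConfig, analytic_features, generate_recording
from myotrace.trace import TraceRecording

from conftest import FS, make_step_recording


def _whole_window(rec, up_t, tag="spontaneous"):
    return APWindow(rec=rec, start=0, end=rec.n_samples,
                    activation_time_s=up_t, tag=tag)


def test_rmp_is_baseline_median():
    rec, up_t = make_step_recording()
    w = _whole_window(rec, up_t)
    assert compute_rmp(w) == pytest.approx(-80.0)


def test_rmp_of_noisy_baseline():
    rng = np.random.default_rng(0)
    v = np.full(4000, -73.4) + rng.normal(0, 0.5, 4000)
    rec = TraceRecording(v, FS, np.array([]), 1.0)
    w = APWindow(rec, 0, 4000, activation_time_s=0.35, tag="spontaneous")
    assert compute_rmp(w) == pytest.approx(-73.4, abs=0.1)


def test_apa_peak_minus_rmp():
    rec, up_t = make_step_recording(peak=35.0)
    w = _whole_window(rec, up_t)
    assert compute_apa(w, -80.0) == pytest.approx(115.0)


def test_dvdt_of_linear_ramp():
    # -80 -> +30 mV in 1 ms: 110 V/s
    fs = FS
    ramp = np.linspace(-80.0, 30.0, int(fs / 1000) + 1)
    v = np.concatenate([np.full(300, -80.0), ramp, np.full(300, 30.0)])
    rec = TraceRecording(v, fs, np.array([]), 1.0)
    w = APWindow(rec, 0, v.size, activation_time_s=(300 + 5) / fs, tag="spontaneous")
    assert compute_dvdt_max(w) == pytest.approx(110.0, abs=1.0)


def test_apd_of_triangular_descent():
    # instantaneous rise to +20, linear fall to -80 over 300 ms:
    # APD20/50/90 at 60/150/270 ms
    rec, up_t = make_step_recording(fall_ms=300.0)
    w = _whole_window(rec, up_t)
    rmp, apa = -80.0, 100.0
    assert compute_apd(w, rmp, apa, 0.2) == pytest.approx(60.0, abs=0.2)
    assert compute_apd(w, rmp, apa, 0.5) == pytest.approx(150.0, abs=0.2)
    assert compute_apd(w, rmp, apa, 0.9) == pytest.approx(270.0, abs=0.2)


def test_auc90_rectangle_and_triangle():
    # rectangle: 100 mV above baseline for 200 ms -> 20 mV*s
    rec, up_t = make_step_recording(fall_ms=200.0, shape="rectangle")
    w = _whole_window(rec, up_t)
    apd90 = compute_apd(w, -80.0, 100.0, 0.9)
    assert compute_auc90(w, -80.0, apd90) == pytest.approx(20.0, abs=0.05)
    # triangle integrated to the 90 % crossing: 0.5*(100+10)*0.27 = 14.85 mV*s
    rec, up_t = make_step_recording(fall_ms=300.0)
    w = _whole_window(rec, up_t)
    assert compute_auc90(w, -80.0, 270.0) == pytest.approx(14.85, abs=0.05)


def test_incomplete_repolarisation_is_nan():
    rec, up_t = make_step_recording(fall_ms=300.0)
    w = APWindow(rec, 0, rec.index_of(up_t + 0.100), up_t, "spontaneous")
    assert np.isnan(compute_apd(w, -80.0, 100.0, 0.9))


def test_segmentation_counts(default_waveform):
    rec, _ = generate_recording(default_waveform, 1.0, 20, seed=0)
    ws = segment_aps(rec)
    assert len(ws) == 20
    assert all(w.tag == "stimulated" for w in ws)
    flat = TraceRecording(np.full(5000, -80.0), FS, np.array([]), 1.0)
    assert segment_aps(flat) == []
    with pytest.raises(ValueError, match="empty"):
        segment_aps(TraceRecording(np.array([]), FS, np.array([]), 1.0))


def test_spontaneous_ap_is_tagged(default_waveform):
    p = default_waveform.with_apd90(180.0)
    rec, truth = generate_recording(
        p, 0.5, 6, AbnormalityConfig(extrasystole_prob=0.5), seed=5
    )
    ws = segment_aps(rec)
    spont = [w for w in ws if w.tag == "spontaneous"]
    assert len(spont) == len(truth.events_of("extrasystole"))


def test_qc_amplitude_threshold_is_strict():
    ok = APMeasurement(apa=75.0, rmp=-80.0, apd90=200.0,
                       flags={"has_baseline": True, "upstroke_separated": True,
                              "artifact_free": True, "repolarised": True})
    assert qc_ap(ok) == QCStatus.ACCEPTED
    low = APMeasurement(apa=74.9, rmp=-80.0, apd90=200.0,
                        flags=dict(ok.flags))
    assert qc_ap(low) == QCStatus.LOW_AMPLITUDE


def test_upstroke_too_close_to_stimulus_rejected(default_waveform):
    # 1 ms latency puts dV/dt_max inside the 5 ms blanking window
    rec, _ = generate_recording(
        default_waveform, 1.0, 5, upstroke_latency_ms=1.0, seed=0
    )
    ms = extract_features(rec)
    assert ms and all(m.qc_status == QCStatus.UPSTROKE_IN_ARTIFACT for m in ms)


def test_no_baseline_rejection():
    # stimulated AP whose window starts after the baseline segment
    rec, up_t = make_step_recording(baseline_ms=10.0)
    w = APWindow(rec, 0, rec.n_samples, up_t, "stimulated", stim_time_s=up_t - 0.002)
    m = APMeasurement(flags={"has_baseline": False})
    assert qc_ap(m) == QCStatus.NO_BASELINE
    assert np.isnan(compute_rmp(w))


@settings(max_examples=20, deadline=None)
@given(st.lists(st.floats(60.0, 130.0), min_size=3, max_size=12))
def test_qc_monotone_in_amplitude_threshold(apas):
    """Lowering the APA threshold never decreases the accepted count."""
    def n_accepted(threshold):
        count = 0
        for apa in apas:
            m = APMeasurement(apa=apa, rmp=-80.0, apd90=200.0,
                              flags={"has_baseline": True, "upstroke_separated": True,
                                     "artifact_free": True, "repolarised": True})
            count += qc_ap(m, apa_threshold_mV=threshold) == QCStatus.ACCEPTED
        return count
    assert n_accepted(60.0) >= n_accepted(75.0) >= n_accepted(90.0)


def test_sampling_rate_robustness(default_waveform):
    feats = {}
    for fs in (5000.0, 20000.0):
        rec, _ = generate_recording(default_waveform, 1.0, 3, seed=0, sampling_rate=fs)
        ms = [m for m in extract_features(rec) if m.accepted]
        assert ms
        feats[fs] = ms[0]
    a, b = feats[5000.0], feats[20000.0]
    for attr in ("apd20", "apd50", "apd90"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=0.2)
    for attr in ("rmp", "apa"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=0.5)


def test_summarise_location_means(default_waveform):
    rec, _ = generate_recording(default_waveform, 1.0, 20, seed=0)
    ms = extract_features(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = summarise_location(ms)
    assert len(summary) == 1
    assert summary["n_ap"].iloc[0] == 20
    truth = analytic_features(default_waveform)
    assert summary["APD90"].iloc[0] == pytest.approx(truth["APD90"], abs=0.2)

    # alternating APDs average to the midpoint
    alt = []
    for apd in [200.0, 160.0] * 10:
        alt.append(APMeasurement(apa=100, rmp=-80, apd90=apd, pacing_freq=1.0,
                                 flags={"has_baseline": True, "upstroke_separated": True,
                                        "artifact_free": True, "repolarised": True}))
        qc_ap(alt[-1])
    s = summarise_location(alt)
    assert s["APD90"].iloc[0] == pytest.approx(180.0)


def test_summarise_empty_warns():
    with pytest.warns(UserWarning, match="no accepted"):
        s = summarise_location([])
    assert s.empty
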