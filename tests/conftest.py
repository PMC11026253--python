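import numpy as np
import pytest

from myotrace.synth import APWaveformParams, generate_recording
from myotrace.trace import TraceRecording

FS = 10_000.0


@pytest.fixture(scope="session")
def default_waveform() -> APWaveformParams:
    return APWaveformParams()


@pytest.fixture(scope="session")
def clean_recording(default_waveform):
    """Noise-free 1 Hz train of 8 identical AP (plus artifacts)."""
    rec, truth = generate_recording(
        default_waveform, pacing_freq=1.0, n_beats=8, seed=0
    )
    return rec, truth


def make_step_recording(
    rmp: float = -80.0,
    peak: float = 20.0,
    fall_ms: float = 300.0,
    baseline_ms: float = 50.0,
    fs: float = FS,
    shape: str = "triangle",
) -> tuple[TraceRecording, float]:
    """Idealised AP with an instantaneous upstroke: a rectangle or triangle.

    Returns the recording and the upstroke time in seconds.  Used as an
    independent geometric oracle for the feature computations.
    """
    dt = 1.0 / fs
    n_base = int(round(baseline_ms / 1000.0 * fs))
    n_fall = int(round(fall_ms / 1000.0 * fs))
    up_t = n_base * dt
    if shape == "triangle":
        seg = np.linspace(peak, rmp, n_fall + 1)
    else:  # rectangle: hold at peak then drop
        seg = np.concatenate([np.full(n_fall, peak), [rmp]])
    v = np.concatenate([
        np.full(n_base, rmp), seg, np.full(n_base, rmp),
    ])
    rec = TraceRecording(
        samples=v, sampling_rate=fs, stim_times=np.array([]), pacing_freq=1.0
    )
    return rec, up_t
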