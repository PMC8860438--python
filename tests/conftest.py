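import numpy as np
import pytest

from sospindle import Hypnogram, Recording, SimConfig, generate_recording
from sospindle.synthio import fractal_noise


@pytest.fixture(scope="session")
def n3_recording():
    """One-channel N3 recording with planted spindles and SOs at the
    detectors' operating densities (events fill the top quartile of the
    threshold reference distributions)."""
    cfg = SimConfig(
        channel_labels=("Cz",),
        stage_plan=(("W", 30.0), ("N3", 480.0), ("N2", 60.0)),
        spindle_rate=15.0, so_rate=3.0, coupled_fraction=0.0,
        so_exclusion=2.0, seed=11,
    )
    rec, hyp, truth = generate_recording(cfg)
    return cfg, rec, hyp, truth


@pytest.fixture(scope="session")
def coupled_recording():
    """Multichannel recording with phase-coupled spindles (kappa = 6)."""
    cfg = SimConfig(
        stage_plan=(("W", 30.0), ("N3", 600.0), ("N2", 60.0)),
        spindle_rate=12.0, so_rate=3.0, coupled_fraction=0.25,
        coupling_mu=0.3, coupling_kappa=6.0, seed=21,
    )
    rec, hyp, truth = generate_recording(cfg)
    return cfg, rec, hyp, truth


@pytest.fixture()
def noise_recording():
    """Event-free 1/f noise, one channel, all N3."""
    rng = np.random.default_rng(5)
    fs = 128.0
    n = int(600 * fs)
    sig = fractal_noise(n, fs, 1.5, 10.0, rng)
    rec = Recording(sig[None, :], fs, ("Cz",))
    hyp = Hypnogram.from_plan((("N3", 600.0),))
    return rec, hyp


def match_events(detected_times, truth_times, tol=0.25):
    """Greedy one-to-one matching; returns (tp, fp, fn, f1)."""
    detected_times = np.sort(np.asarray(detected_times))
    truth_times = np.asarray(truth_times)
    used = np.zeros(len(detected_times), dtype=bool)
    tp = 0
    for t in truth_times:
        if len(detected_times) == 0:
            break
        d = np.abs(detected_times - t)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol:
            used[i] = True
            tp += 1
    fp = int(len(detected_times) - tp)
    fn = int(len(truth_times) - tp)
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    return tp, fp, fn, f1
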