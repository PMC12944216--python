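import numpy as np
import pytest

import mosswave as mw

DEFAULT_SEED = 5


@pytest.fixture(scope="session")
def default_protocol():
    """300 s buffer then continuous stimulus to the end of a 900 s recording."""
    return mw.StimulusProtocol(pulses=[(300.0, 900.0)], recording_duration_s=900.0)


@pytest.fixture(scope="session")
def default_colony(default_protocol):
    """The benchmark colony: ~40 ground-truth regions, default noise."""
    stack, gt, geom = mw.simulate_colony(seed=DEFAULT_SEED, protocol=default_protocol)
    return stack, gt, geom


@pytest.fixture(scope="session")
def fitted_pipeline(default_colony, default_protocol):
    """Full default-parameter pipeline fitted on the benchmark colony."""
    stack, _gt, _geom = default_colony
    return mw.MossWavePipeline().fit(stack, protocol=default_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def gaussian_wave(times, peak_time, amplitude, sigma):
    """Programmed wave shape: Gaussian in time on a zero baseline."""
    t = np.asarray(times, dtype=float)
    return amplitude * np.exp(-((t - peak_time) ** 2) / (2.0 * sigma**2))


def match_events(detected_times, true_times, window_s=15.0):
    """Greedy one-to-one matching of detected to true peak times."""
    used = set()
    tp = 0
    for tt in sorted(true_times):
        cand = [
            j
            for j, dt in enumerate(detected_times)
            if abs(dt - tt) <= window_s and j not in used
        ]
        if cand:
            used.add(cand[0])
            tp += 1
    fn = len(true_times) - tp
    fp = len(detected_times) - tp
    return tp, fp, fn
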