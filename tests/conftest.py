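import numpy as np
import pytest

from gaitrp import DEFAULT_PROFILES, generate_subject


@pytest.fixture(scope="session")
def hc_record():
    """One HC subject: 60 s at 50 Hz."""
    return generate_subject(DEFAULT_PROFILES["HC"], 60.0, 50.0, seed=11)


@pytest.fixture(scope="session")
def als_record():
    return generate_subject(DEFAULT_PROFILES["ALS"], 60.0, 50.0, seed=12)


@pytest.fixture(scope="session")
def hd_record():
    return generate_subject(DEFAULT_PROFILES["HD"], 60.0, 50.0, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def detect_bursts(x: np.ndarray, fs: float, thresh_frac: float = 0.1):
    """Independent burst-segmentation oracle: threshold the trace at a
    fraction of its peak and return (onset_times, burst_durations) of the
    contiguous supra-threshold segments."""
    x = np.asarray(x, dtype=float)
    mask = x > thresh_frac * x.max()
    edges = np.diff(mask.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        onsets = np.insert(onsets, 0, 0)
    if mask[-1]:
        offsets = np.append(offsets, len(x))
    durations = (offsets - onsets) / fs
    return onsets / fs, durations


def stride_cv_oracle(x: np.ndarray, fs: float) -> float:
    """Empirical stride-interval CV from burst onsets."""
    onsets, _ = detect_bursts(x, fs)
    strides = np.diff(onsets)
    return float(strides.std() / strides.mean())
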