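import numpy as np
import pytest

from epifed.synth import SyntheticSpec, generate_eeg_dataset
from epifed.types import Annotation, EEGRecording, RunConfig


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """One seeded multi-hospital dataset shared by read-only tests."""
    return generate_eeg_dataset(default_spec)


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_recording(
    n_seconds: float = 10.0,
    fs: float = 32.0,
    n_channels: int = 3,
    seed: int = 0,
    annotations=None,
) -> EEGRecording:
    g = np.random.default_rng(seed)
    n = int(round(n_seconds * fs))
    return EEGRecording(
        subject_id=f"sub{seed}",
        signal=g.standard_normal((n, n_channels)),
        fs=fs,
        channel_names=[f"c{i}" for i in range(n_channels)],
        annotations=annotations or [],
    )


def make_burst_pair_data(seed: int, n: int = 60, m: int = 4, fs: float = 32.0):
    """Separable paired windows for classifier tests: class 1 windows carry
    brief high-amplitude bursts on half the channels, class 0 is plain
    noise. Returns (windows_a, windows_b, labels, fs, graph)."""
    from epifed.graph import ChannelGraph, renormalize_adjacency

    rng = np.random.default_rng(seed)
    ta, tb = int(fs), int(2 * fs)
    y = np.repeat([0, 1], n // 2)

    def background(t_len):
        # smoothed noise -> threshold crossings come in multi-sample runs,
        # so the single-sample impulses below stand out as many SHORT spikes
        white = rng.standard_normal((t_len + 8, m))
        kernel = np.ones(6) / 6.0
        smooth = np.stack(
            [np.convolve(white[:, q], kernel, mode="same") for q in range(m)], axis=1
        )[:t_len]
        return smooth / smooth.std(axis=0)

    wa = np.stack([background(ta) for _ in range(n)])
    wb = np.stack([background(tb) for _ in range(n)])

    # class 1: single-sample impulses on half the channels -> many short
    # spike runs there (the structure the seizure indicator keys on)
    def add_impulses(w, i):
        t_len = w.shape[1]
        for start in range(2, t_len - 1, max(t_len // 8, 2)):
            w[i, start, : m // 2] += 6.0

    for i in np.flatnonzero(y):
        add_impulses(wa, i)
        add_impulses(wb, i)
    a = np.ones((m, m)) - np.eye(m)
    graph = ChannelGraph(adjacency=a, a_hat=renormalize_adjacency(a))
    return wa, wb, y, fs, graph


@pytest.fixture()
def two_state_recording() -> EEGRecording:
    """660 s recording: 600 s interictal then 60 s preictal."""
    return make_recording(
        n_seconds=660.0,
        fs=32.0,
        n_channels=2,
        seed=3,
        annotations=[
            Annotation("interictal", 0.0, 600.0),
            Annotation("preictal", 600.0, 660.0),
        ],
    )
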