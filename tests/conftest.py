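import numpy as np
import pytest

from dynspdcm.data import RegionalTimeSeries


@pytest.fixture(scope="session")
def face_validity_reports():
    """Ten seeded face-validity experiments (shared across tests).

    Each runs the full analysis on one stationary and one dynamic
    4-node benchmark dataset (15 windows of 200 scans at TR 0.72 s).
    """
    from dynspdcm.simulation import run_face_validity

    return [run_face_validity(seed) for seed in range(1, 11)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_ts():
    """A short 3-region series of smooth noise for plumbing tests."""
    gen = np.random.default_rng(7)
    data = gen.standard_normal((300, 3)).cumsum(axis=0) * 0.01 + gen.standard_normal((300, 3))
    return RegionalTimeSeries(data, tr=0.72, region_names=["a", "b", "c"])


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return path
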