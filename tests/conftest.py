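import numpy as np
import pandas as pd
import pytest

from tmabquant.benchmark import roundtrip_scenario
from tmabquant.detect import IsotopeCluster, PeakGroup
from tmabquant.scheme import LabelingScheme


@pytest.fixture(scope="session")
def roundtrip():
    """Noise-free simulated study pushed through the full pipeline once."""
    return roundtrip_scenario(seed=1234)


@pytest.fixture
def five_plex_scheme():
    return LabelingScheme(
        runs={
            "run1": {
                "D0": ("control", "control_r1"),
                "D3": ("control", "control_r2"),
                "D6": ("treated", "treated_r1"),
                "D9": ("treated", "treated_r2"),
                "D12": ("treated", "treated_r3"),
            }
        },
        reference="control",
    )


def make_cluster(cluster_id, mono_mz, intensities, z=2, rt=20.0):
    """Hand-built isotope cluster for quantification unit tests."""
    k = np.arange(len(intensities))
    return IsotopeCluster(
        cluster_id=cluster_id,
        z=z,
        mono_mz=mono_mz,
        rt=rt,
        member_mz=mono_mz + k * 1.0033548378 / z,
        member_intensity=np.asarray(intensities, dtype=float),
        member_index=np.arange(len(intensities)) + cluster_id * 10,
    )


def make_group(channel_intensities, scheme, run_id="run1", z=2, n_labels=1):
    """PeakGroup with given representative intensity per tag (None = missing)."""
    channels = {}
    cid = 0
    for tag, inten in channel_intensities.items():
        if inten is None:
            channels[tag] = None
        else:
            channels[tag] = make_cluster(cid, 500.0 + cid * 3.0, [inten, inten * 0.5], z=z)
            cid += 1
    return PeakGroup(
        run_id=run_id,
        z=z,
        n_labels=n_labels,
        channels=channels,
        neutral_mass=1000.0,
        rt=20.0,
    )


@pytest.fixture
def group_factory(five_plex_scheme):
    def _make(channel_intensities, **kw):
        return make_group(channel_intensities, five_plex_scheme, **kw)

    return _make
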