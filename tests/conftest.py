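import numpy as np
import pandas as pd
import pytest

from roamrange import SampledTrack, SimConfig, simulate_track, utm_inverse

#: excursion destinations used by most simulated-dog fixtures
SITES = (((350.0, 120.0), 1.0), ((-280.0, 300.0), 1.0), ((150.0, -400.0), 1.0))


def make_track(xy, dt_s=60.0, dog_id="toy", household=None, t0="2019-06-10 06:00:00"):
    """Planar toy track: fixes at the given (x, y) metres, dt_s apart."""
    xy = np.asarray(xy, dtype=float)
    ts = pd.Timestamp(t0, tz="Etc/GMT-3") + pd.to_timedelta(
        np.arange(len(xy)) * dt_s, unit="s"
    )
    lon, lat = utm_inverse(xy[:, 0], xy[:, 1])
    frame = pd.DataFrame(
        {"timestamp": ts, "lon": lon, "lat": lat, "x": xy[:, 0], "y": xy[:, 1]}
    )
    return SampledTrack(dog_id=dog_id, fixes=frame, household_xy=household)


@pytest.fixture(scope="session")
def roaming_cfg():
    return SimConfig(attraction_sites=SITES, seed=11)


@pytest.fixture(scope="session")
def roaming_dog(roaming_cfg):
    """One full-length simulated deployment (track, truth)."""
    track, truth = simulate_track(roaming_cfg)
    assert track is not None
    return track, truth


@pytest.fixture(scope="session")
def short_roaming_dog():
    """A 24 h deployment for tests that don't need five days of data."""
    cfg = SimConfig(attraction_sites=SITES, deployment_hours=24.0, seed=7)
    track, truth = simulate_track(cfg)
    assert track is not None
    return track, truth, cfg
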