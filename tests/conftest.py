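import numpy as np
import pandas as pd
import pytest

from memprobe.geometry import FrameGeometry
from memprobe.synthetic import (
    TiltComponent,
    TrajectoryParams,
    generate_trajectory,
)

BOX = np.array([6.4, 6.4, 7.0])


def make_probe_frame(c_pos, n_pos, box=BOX, extra_phosphates=True):
    """Minimal frame with a two-atom probe and a phosphate plane per leaflet."""
    positions = [c_pos, n_pos]
    names = ["C1", "N1"]
    masses = [12.011, 14.007]
    resids = [1, 1]
    resnames = ["PRB", "PRB"]
    if extra_phosphates:
        for z, rid in ((5.5, 2), (5.5, 3), (1.5, 4), (1.5, 5)):
            positions.append([1.0 + rid, 1.0, z])
            names.append("P")
            masses.append(30.974)
            resids.append(rid)
            resnames.append("LIP")
    return FrameGeometry(
        positions=np.array(positions, dtype=float),
        names=np.array(names, dtype=object),
        masses=np.array(masses),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        box=box,
    )


@pytest.fixture(scope="session")
def bimodal_trajectory():
    """Fluid-like synthetic trajectory: tilt modes at 28 and 120 deg."""
    params = TrajectoryParams(
        n_frames=4000,
        tilt_model=[TiltComponent(28.0, 25.0, 0.5), TiltComponent(120.0, 25.0, 0.5)],
        depth_model=(0.8, 0.15),
        seed=42,
    )
    return generate_trajectory(params)


@pytest.fixture(scope="session")
def small_trajectory():
    params = TrajectoryParams(n_frames=20, n_lipids_per_leaflet=16, seed=5)
    return generate_trajectory(params)


@pytest.fixture
def annotated_emission():
    """220-record emission ensemble with a known -0.3 eV deep/low-tilt shift."""
    rng = np.random.default_rng(123)
    n = 220
    depth = rng.normal(0.8, 0.15, n)
    tilt = rng.uniform(0, 180, n)
    energy = 3.0 + rng.normal(0, 0.05, n)
    deep_low = (depth > 0.8) & (tilt < 40.0)
    energy[deep_low] -= 0.3
    return pd.DataFrame(
        {
            "snapshot_id": np.arange(n),
            "state": 1,
            "energy_eV": energy,
            "osc_strength": np.abs(rng.normal(0.3, 0.05, n)),
            "kind": "emission",
            "depth_nm": depth,
            "tilt_deg": tilt,
        }
    )
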