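"""Shared study conditions for the analysis drivers.

Two synthetic membrane models at 305 K-like conditions:
* gel-like (DPPC-analog): unimodal probe tilt near 28 deg, deeper and
  narrower penetration-depth distribution;
* fluid-like (DOPC-analog): bimodal tilt (28 deg plus a reversed-orientation
  mode at 120 deg), shallower and wider depth distribution.

Emission energies are coupled to geometry (lower energy for deeper and less
tilted probes) with 0.05 eV Gaussian noise, emulating the structure-spectrum
association under study.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"

GEL_TILT = [{"mode_deg": 28.0, "concentration": 25.0, "weight": 1.0}]
FLUID_TILT = [
    {"mode_deg": 28.0, "concentration": 25.0, "weight": 0.55},
    {"mode_deg": 120.0, "concentration": 12.0, "weight": 0.45},
]
GEL_DEPTH = {"mean_nm": 0.95, "sd_nm": 0.10}
FLUID_DEPTH = {"mean_nm": 0.80, "sd_nm": 0.15}
COUPLING = {
    "depth_slope_ev_per_nm": -0.4,
    "tilt_slope_ev": -0.3,
    "noise_sd_ev": 0.05,
}
SEED = 1


def membrane_config(kind: str, **extra):
    from memprobe.pipeline import make_config

    tilt = GEL_TILT if kind == "gel" else FLUID_TILT
    depth = GEL_DEPTH if kind == "gel" else FLUID_DEPTH
    cfg = make_config(
        seed=SEED,
        trajectory={"n_frames": 1500, "tilt_model": tilt, "depth_model": depth},
        coupling=COUPLING,
        **extra,
    )
    return cfg
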