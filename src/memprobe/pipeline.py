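"""End-to-end orchestration of the synthetic analysis stages.

A single declarative config (YAML-compatible nested dict) drives every
stage; all stochastic stages take explicit seeds, so identical config ->
bit-identical outputs.  Each run writes a ``runlog.json`` with the config
hash and per-stage counts (frames read, snapshots selected, records
emitted): the protocol's arithmetic is its main silent-failure risk, so the
counts are logged at every boundary.

Stage layout of an emission run (the absorption run is the same minus the
secondary protocol and correlation):

  simulate  -> synthetic trajectory + ground-truth sidecar
  geometry  -> per-frame tilt/depth series + histograms
  sample    -> hierarchical manifest (n_secondary x n_sub sub-snapshots)
  excite    -> synthetic vertical transitions coupled to depth/tilt
  spectra   -> Lorentzian ensemble spectrum + detected bands
  correlate -> scatter tables + permutation association test
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from memprobe import geometry as mg
from memprobe import sampling as ms
from memprobe import spectra as sp
from memprobe.correlation import join_annotations, scatter_table, test_association
from memprobe.qm import read_excitation_table, write_excitation_table
from memprobe.synthetic import (
    CouplingParams,
    FLUOROPHORE_NAMES,
    SyntheticTrajectory,
    TiltComponent,
    TrajectoryParams,
    generate_excitations,
    generate_trajectory,
)

__all__ = [
    "DEFAULT_CONFIG",
    "config_hash",
    "make_config",
    "run_absorption_pipeline",
    "run_emission_pipeline",
]


class StageError(RuntimeError):
    """A stage is missing its input; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "trajectory": {
        "n_frames": 1500,
        "frame_interval_ns": 0.1,
        "n_lipids_per_leaflet": 64,
        "tilt_model": [{"mode_deg": 28.0, "concentration": 20.0, "weight": 1.0}],
        "depth_model": {"mean_nm": 0.8, "sd_nm": 0.15},
    },
    "histograms": {"tilt_bin_deg": 5.0, "depth_bin_nm": 0.05},
    "sampling": {
        # absorption: primary equidistant seeds, then a random ensemble
        "n_primary": 30,
        "n_random": 300,
        # emission: hierarchical protocol
        "n_secondary": 22,
        "secondary_length_ns": 2.0,
        "sub_window_ns": [1.0, 2.0],
        "n_sub": 10,
        "window_ns": None,  # default: last third (absorption) / last 50 ns (emission)
        "secondary_jitter": {"tilt_sd_deg": 5.0, "depth_sd_nm": 0.05},
    },
    "coupling": {
        "base_energy_ev": 3.0,
        "depth_slope_ev_per_nm": 0.0,
        "tilt_slope_ev": 0.0,
        "noise_sd_ev": 0.05,
        "f_mean": 0.3,
        "f_sd": 0.05,
    },
    "spectra": {"delta_ev": 0.1, "band_prominence": 0.05},
    "correlation": {"enabled": True, "tilt_thresh_deg": 40.0, "n_perm": 2000},
    "excitation_table": None,  # path to a real TD-DFT table; bypasses 'excite'
}


def make_config(**overrides) -> dict:
    """Deep-merged copy of the default config."""

    def merge(base: dict, over: dict) -> dict:
        out = copy.deepcopy(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    return merge(DEFAULT_CONFIG, overrides)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _tilt_model(cfg: list[dict]) -> list[TiltComponent]:
    return [TiltComponent(c["mode_deg"], c["concentration"], c["weight"]) for c in cfg]


def _simulate(config: dict) -> SyntheticTrajectory:
    t = config["trajectory"]
    params = TrajectoryParams(
        n_frames=t["n_frames"],
        frame_interval_ns=t["frame_interval_ns"],
        n_lipids_per_leaflet=t["n_lipids_per_leaflet"],
        tilt_model=_tilt_model(t["tilt_model"]),
        depth_model=(t["depth_model"]["mean_nm"], t["depth_model"]["sd_nm"]),
        seed=config["seed"],
    )
    return generate_trajectory(params)


def _geometry_series(traj: SyntheticTrajectory) -> pd.DataFrame:
    """Recompute tilt/depth per frame from coordinates (not the ground truth)."""
    rows = []
    for i, frame in enumerate(traj.frames):
        probe_idx = frame.select(names=FLUOROPHORE_NAMES, resnames="PRB")
        leaflet = mg.assign_leaflet(frame, probe_idx)
        phos_plane = frame.positions[frame.select(names="P"), 2]
        mid = phos_plane.mean()
        phos_idx = frame.select(names="P")
        host = phos_idx[
            frame.positions[phos_idx, 2] > mid
            if leaflet == "upper"
            else frame.positions[phos_idx, 2] < mid
        ]
        rows.append(
            {
                "frame": i,
                "time_ns": frame.time,
                "tilt_deg": mg.probe_tilt_angle(frame, leaflet=leaflet),
                "depth_nm": mg.penetration_depth(frame, probe_idx, host, leaflet=leaflet),
            }
        )
    return pd.DataFrame(rows)


def _histograms(series: pd.DataFrame, config: dict) -> dict[str, mg.OrientationHistogram]:
    h = config["histograms"]
    return {
        "tilt": mg.build_histogram(series["tilt_deg"].to_numpy(), h["tilt_bin_deg"], (0.0, 180.0)),
        "depth": mg.build_histogram(
            series["depth_nm"].to_numpy(), h["depth_bin_nm"], (-1.0, 2.0)
        ),
    }


def _write_histograms(hists: dict, outdir: Path) -> None:
    for name, hist in hists.items():
        pd.DataFrame({"center": hist.centers, "density": hist.density}).to_csv(
            outdir / f"hist_{name}.csv", index=False
        )


def _coupling(config: dict) -> CouplingParams:
    c = config["coupling"]
    return CouplingParams(
        base_energy_ev=c["base_energy_ev"],
        depth_slope_ev_per_nm=c["depth_slope_ev_per_nm"],
        tilt_slope_ev=c["tilt_slope_ev"],
        noise_sd_ev=c["noise_sd_ev"],
        f_mean=c["f_mean"],
        f_sd=c["f_sd"],
        seed=config["seed"] + 1,
    )


def _runlog(outdir: Path, config: dict, counts: dict) -> None:
    log = {"config_hash": config_hash(config), "config": config, "counts": counts}
    (outdir / "runlog.json").write_text(json.dumps(log, indent=2, default=str))


def run_absorption_pipeline(config: dict, outdir: str | Path) -> dict:
    """Synthetic absorption run: simulate -> geometry -> sample -> spectrum."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    traj = _simulate(config)
    traj.write_ground_truth(outdir / "ground_truth.csv")
    counts["frames"] = len(traj.frames)

    series = _geometry_series(traj)
    series.to_csv(outdir / "geometry.csv", index=False)
    hists = _histograms(series, config)
    _write_histograms(hists, outdir)

    s = config["sampling"]
    index = ms.TrajectoryIndex("s0", traj.times)
    t0, t1 = traj.times[0], traj.times[-1]
    window = s["window_ns"] or (t0 + 2.0 * (t1 - t0) / 3.0, t1)
    primary = ms.equidistant_snapshots(
        index, ms.SamplingPlan(window[0], window[1], s["n_primary"], "equidistant")
    )
    rand = ms.random_snapshots(
        index,
        ms.SamplingPlan(window[0], window[1], s["n_random"], "random", seed=config["seed"] + 2),
    )
    manifest = pd.concat([primary.entries, rand.entries], ignore_index=True)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    counts["snapshots_primary"] = len(primary)
    counts["snapshots_random"] = len(rand)

    if config.get("excitation_table"):
        try:
            exc = read_excitation_table(config["excitation_table"])
        except FileNotFoundError as exc_err:
            raise StageError(f"spectra stage: excitation table not found: {exc_err}") from exc_err
    else:
        desc = series.iloc[rand.entries["frame_index"].to_numpy()].copy()
        desc["snapshot_id"] = np.arange(len(desc))
        exc = generate_excitations(desc, _coupling(config), kind="absorption")
    write_excitation_table(exc, outdir / "excitations.csv")
    counts["excitation_records"] = len(exc)

    spectrum = sp.ensemble_spectrum(exc, delta=config["spectra"]["delta_ev"])
    spectrum.write(outdir / "spectrum_absorption.tsv")
    bands = sp.find_bands(sp.normalize(spectrum), config["spectra"]["band_prominence"])
    (outdir / "bands.json").write_text(json.dumps({"bands": bands}, indent=2))
    counts["bands"] = len(bands)

    _runlog(outdir, config, counts)
    return {
        "trajectory": traj,
        "geometry": series,
        "histograms": hists,
        "manifest": manifest,
        "excitations": exc,
        "spectrum": spectrum,
        "bands": bands,
        "counts": counts,
    }


def run_emission_pipeline(config: dict, outdir: str | Path) -> dict:
    """Synthetic emission run with the hierarchical protocol and correlation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    rng = np.random.default_rng(config["seed"] + 3)

    traj = _simulate(config)
    traj.write_ground_truth(outdir / "ground_truth.csv")
    counts["frames"] = len(traj.frames)

    series = _geometry_series(traj)
    series.to_csv(outdir / "geometry.csv", index=False)
    hists = _histograms(series, config)
    _write_histograms(hists, outdir)

    s = config["sampling"]
    index = ms.TrajectoryIndex("s1", traj.times)
    t0, t1 = traj.times[0], traj.times[-1]
    window = s["window_ns"] or (max(t0, t1 - 50.0), t1)
    manifest = ms.emission_protocol(
        index,
        primary_window=tuple(window),
        n_secondary=s["n_secondary"],
        secondary_length_ns=s["secondary_length_ns"],
        sub_window=tuple(s["sub_window_ns"]),
        n_sub=s["n_sub"],
    )
    manifest.write_csv(outdir / "manifest.csv")
    counts["sub_snapshots"] = len(manifest)

    # secondary trajectories are emulated: each sub-snapshot inherits its
    # seed frame's geometry plus a small jitter standing in for the short
    # secondary dynamics
    if config.get("excitation_table"):
        try:
            exc = read_excitation_table(config["excitation_table"])
        except FileNotFoundError as exc_err:
            raise StageError(f"spectra stage: excitation table not found: {exc_err}") from exc_err
        annotated = exc
    else:
        seed_rows = series.iloc[manifest.entries["seed_frame_index"].to_numpy()]
        jit = s["secondary_jitter"]
        desc = pd.DataFrame(
            {
                "snapshot_id": np.arange(len(manifest)),
                "tilt_deg": np.clip(
                    seed_rows["tilt_deg"].to_numpy()
                    + rng.normal(0, jit["tilt_sd_deg"], len(manifest)),
                    0.0,
                    180.0,
                ),
                "depth_nm": seed_rows["depth_nm"].to_numpy()
                + rng.normal(0, jit["depth_sd_nm"], len(manifest)),
            }
        )
        exc = generate_excitations(desc, _coupling(config), kind="emission")
        annotated = exc
    write_excitation_table(exc, outdir / "excitations.csv")
    counts["excitation_records"] = len(exc)

    spectrum = sp.ensemble_spectrum(exc, delta=config["spectra"]["delta_ev"])
    spectrum.write(outdir / "spectrum_emission.tsv")
    bands = sp.find_bands(sp.normalize(spectrum), config["spectra"]["band_prominence"])
    (outdir / "bands.json").write_text(json.dumps({"bands": bands}, indent=2))
    counts["bands"] = len(bands)

    result: dict = {
        "trajectory": traj,
        "geometry": series,
        "histograms": hists,
        "manifest": manifest,
        "excitations": exc,
        "spectrum": spectrum,
        "bands": bands,
        "counts": counts,
    }

    if config["correlation"]["enabled"]:
        for axis in ("depth", "tilt"):
            scatter_table(annotated, axis=axis).to_csv(
                outdir / f"scatter_{axis}.csv", index=False
            )
        assoc = test_association(
            annotated,
            tilt_thresh_deg=config["correlation"]["tilt_thresh_deg"],
            n_perm=config["correlation"]["n_perm"],
            seed=config["seed"] + 4,
        )
        (outdir / "association.json").write_text(json.dumps(assoc.to_dict(), indent=2))
        counts["association_group"] = assoc.n_group
        result["association"] = assoc

    _runlog(outdir, config, counts)
    return result
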