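"""Generate the two synthetic probe-in-bilayer trajectories.

Writes per-membrane ground truth (frame, tilt, depth), the topology, and a
short multi-model PDB excerpt for inspection, under results/simulate/.
"""

from common import RESULTS, membrane_config

from memprobe.io import write_multimodel_pdb
from memprobe.pipeline import _simulate


def main() -> None:
    out = RESULTS / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    for kind in ("gel", "fluid"):
        traj = _simulate(membrane_config(kind))
        traj.write_ground_truth(out / f"{kind}_ground_truth.csv")
        traj.topology.write_csv(out / f"{kind}_topology.csv")
        write_multimodel_pdb(traj.topology, traj.frames[:5], out / f"{kind}_excerpt.pdb")
        gt = traj.ground_truth
        print(
            f"{kind}: {len(traj.frames)} frames | tilt mean {gt.tilt_deg.mean():.1f} deg"
            f" | depth {gt.depth_nm.mean():.3f} +/- {gt.depth_nm.std():.3f} nm"
        )


if __name__ == "__main__":
    main()
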