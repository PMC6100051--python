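"""Build the QM fragment and point-charge environment for sampled frames.

The probe is truncated at the first acyl bond (methyl-capped fluorophore),
every other molecule becomes whole-molecule point charges at its minimum
image.  Writes the XYZ fragment and the x-y-z-q file for the first few
frames of the fluid-like trajectory under results/embedding/.
"""

import numpy as np
from common import RESULTS, membrane_config

from memprobe.embedding import (
    build_environment,
    truncate_to_fluorophore,
    write_point_charges,
    write_xyz,
)
from memprobe.pipeline import _simulate
from memprobe.synthetic import DEFAULT_CUT_BOND


def main() -> None:
    out = RESULTS / "embedding"
    out.mkdir(parents=True, exist_ok=True)
    traj = _simulate(membrane_config("fluid"))
    for i, frame in enumerate(traj.frames[:3]):
        frag = truncate_to_fluorophore(traj.topology, frame.positions, DEFAULT_CUT_BOND)
        write_xyz(frag, out / f"frame{i}_fragment.xyz", comment=f"frame {i}")
        env = build_environment(frame, frame.select(resids=1))
        write_point_charges(env, out / f"frame{i}_pointcharges.txt")
        print(
            f"frame {i}: QM fragment {frag.n_atoms} atoms "
            f"(+{len(frag.link_atoms)} link H), environment {env.n_points} charges, "
            f"total {env.total_charge:+.9f} e"
        )
        assert abs(env.total_charge) < 1e-9


if __name__ == "__main__":
    main()
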