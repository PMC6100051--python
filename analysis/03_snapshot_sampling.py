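"""Build the absorption and emission sampling manifests.

Absorption: 30 equidistant seeds over the equilibrated window plus a
300-frame random ensemble.  Emission: the hierarchical protocol — 22
equidistant seeds from the last 50 ns, 10 equidistant sub-snapshots between
1 and 2 ns of each secondary run — 220 geometries per membrane.
Writes results/sampling/{kind}_{stage}_manifest.csv.
"""

import numpy as np
from common import RESULTS

from memprobe.sampling import (
    SamplingPlan,
    TrajectoryIndex,
    emission_protocol,
    equidistant_snapshots,
    random_snapshots,
)


def main() -> None:
    out = RESULTS / "sampling"
    out.mkdir(parents=True, exist_ok=True)
    # a 150 ns excited-state store at 0.1 ns intervals per membrane
    times = np.round(np.arange(0.0, 150.0001, 0.1), 6)
    for kind in ("gel", "fluid"):
        traj = TrajectoryIndex(f"{kind}-s1", times)
        absorption = equidistant_snapshots(
            traj, SamplingPlan(50.0, 150.0, 30, "equidistant")
        )
        absorption.write_csv(out / f"{kind}_absorption_manifest.csv")
        rand = random_snapshots(
            traj, SamplingPlan(50.0, 150.0, 300, "random", seed=11)
        )
        rand.write_csv(out / f"{kind}_absorption_random_manifest.csv")
        emission = emission_protocol(traj, (100.0, 150.0))
        emission.write_csv(out / f"{kind}_emission_manifest.csv")
        print(
            f"{kind}: absorption {len(absorption)} seeds + {len(rand)} random; "
            f"emission {emission.entries.trajectory_id.nunique()} secondaries x "
            f"{len(emission) // emission.entries.trajectory_id.nunique()} = {len(emission)}"
        )


if __name__ == "__main__":
    main()
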