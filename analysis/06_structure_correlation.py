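"""Relate emission energy to probe depth and tilt; test the association.

Scatter tables (energy vs. depth / tilt, oscillator strength carried along)
and the permutation test of the deep/low-tilt vs. rest energy difference,
for both membrane models.  Writes results/correlation/.
"""

import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from common import RESULTS, membrane_config

from memprobe.correlation import scatter_table, test_association
from memprobe.pipeline import run_emission_pipeline


def main() -> None:
    out = RESULTS / "correlation"
    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey="row")
    for col, kind in enumerate(("gel", "fluid")):
        res = run_emission_pipeline(membrane_config(kind), RESULTS / f"emission_{kind}")
        exc = res["excitations"]
        for row, axis in enumerate(("depth", "tilt")):
            t = scatter_table(exc, axis=axis)
            t.to_csv(out / f"{kind}_scatter_{axis}.csv", index=False)
            sc = axes[row][col].scatter(t["x"], t["energy_eV"], c=t["f"], s=8, cmap="viridis")
            axes[row][col].set_xlabel(f"{axis} ({'nm' if axis == 'depth' else 'deg'})")
            axes[row][col].set_title(kind)
        assoc = test_association(exc, n_perm=5000, seed=2)
        (out / f"{kind}_association.json").write_text(json.dumps(assoc.to_dict(), indent=2))
        print(
            f"{kind}: deep/low-tilt group n={assoc.n_group}, "
            f"mean energy shift {assoc.mean_diff_ev:+.3f} eV, p={assoc.p_value:.4f}"
        )
    for row in axes:
        row[0].set_ylabel("emission energy (eV)")
    fig.colorbar(sc, ax=axes, label="oscillator strength", shrink=0.8)
    fig.savefig(out / "scatter.png", dpi=150)


if __name__ == "__main__":
    main()
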