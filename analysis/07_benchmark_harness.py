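"""Exercise the TD-DFT benchmark harness against the packaged references.

A mock engine adapter replays the stored vertical-excitation tables for the
methyl-truncated fluorophore (gas phase and implicit water/cyclohexane) so
the full contract — adapter invocation, entry validation, per-state deltas
at 0.02 eV / 0.02 f tolerance with energy-ordered pairing — runs offline.
A real engine (e.g. a TURBOMOLE or PySCF wrapper producing the excitation
CSV schema) plugs into the same `CommandTemplateAdapter` contract.
Writes results/benchmark/report_{environment}.csv.
"""

from common import RESULTS

from memprobe.qm import (
    EngineRun,
    MockAdapter,
    compare_to_benchmark,
    engine_contract,
    load_benchmark_table,
    register_adapter,
)


def main() -> None:
    out = RESULTS / "benchmark"
    out.mkdir(parents=True, exist_ok=True)
    for env in ("gas", "water-cosmo", "cyclohexane-cosmo"):
        ref = load_benchmark_table(env)
        register_adapter(f"stored-{env}", MockAdapter(ref))
        entries = []
        for functional in ("PBE0", "B3LYP"):
            for basis in ("cc-pVDZ", "cc-pVTZ", "aug-cc-pVDZ", "aug-cc-pVTZ"):
                entries += engine_contract(
                    f"stored-{env}",
                    EngineRun("fluorophore.xyz", functional, basis, 5, environment=env),
                )
        report = compare_to_benchmark(entries, ref, 0.02, 0.02, order_by_energy=True)
        report.to_csv(out / f"report_{env}.csv", index=False)
        n_pass = (report["status"] == "pass").sum()
        s1 = ref[(ref.functional == "PBE0") & (ref.basis == "cc-pVDZ") & (ref.state == 1)]
        print(
            f"{env}: {n_pass}/{len(report)} states pass; "
            f"PBE0/cc-pVDZ S1 = {float(s1.energy_eV.iloc[0]):.2f} eV "
            f"(f = {float(s1.osc_strength.iloc[0]):.2f})"
        )


if __name__ == "__main__":
    main()
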