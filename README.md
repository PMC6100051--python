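# memprobe

Analysis pipeline for the orientation and membrane-penetration depth of a
solvatochromic fluorescent probe (Laurdan-type) in phospholipid bilayers, and
for how those geometric degrees of freedom shape its simulated absorption and
emission spectra.

Laurdan's emission is the workhorse readout for membrane fluidity (gel vs.
liquid-crystalline lipid phases, e.g. DPPC vs. DOPC at ~305 K), yet the
microscopic link between where/how the fluorophore sits in the bilayer and
what it emits is subtle.  This package implements, as tested and reusable
code, the chain of analyses needed to probe that link:

1. **Geometric observables.**  The fluorophore *tilt angle* is the angle
   between the bilayer normal **n** (laboratory z) and the carbonyl-carbon →
   amino-nitrogen vector: 0° means the fluorophore lies along the normal with
   its nitrogen toward the water phase, 90° in the membrane plane, 180° bent
   back toward the membrane interior.  The *penetration depth* is the signed
   projection onto **n** of (phosphate-plane COM − probe COM) for the host
   leaflet, positive toward the bilayer midplane.  Histograms, modes, and
   leaflet assignment are included; all conventions are leaflet-independent.
2. **Hierarchical snapshot sampling.**  Equidistant and uniform-random
   selection over trajectory windows, and the two-level emission protocol:
   22 equidistant seeds from the last 50 ns of an excited-state run, each
   spawning a short secondary trajectory sub-sampled 10 times between 1 and
   2 ns — 22 × 10 = 220 geometries per bilayer.
3. **Electrostatic embedding.**  The probe's inert alkyl tail is cut and
   methyl-capped (link H at 0.109 nm along the cut bond) to form the QM
   fragment; every surrounding molecule becomes force-field point charges,
   kept whole and placed at its minimum image, written as `x y z q` text.
4. **Nuclear-ensemble spectra.**  I(E) = (1/N_snap) Σᵢ fᵢ·L(E − ΔEᵢ; δ) with
   a unit-area Lorentzian L of FWHM δ = 0.1 eV; energy↔wavelength conversion
   and band detection.
5. **Structure–spectrum correlation.**  A permutation test of the mean
   emission-energy difference between "deep and less tilted" configurations
   and the rest, quantifying whether low-energy (high-wavelength) emission
   tracks probe geometry.
6. **TD-DFT interface.**  Excitation-table I/O, a pluggable engine-adapter
   contract, and an offline benchmark harness against packaged reference
   vertical-excitation tables (PBE0/B3LYP × four basis sets, gas phase and
   implicit water/cyclohexane).

A synthetic-data generator produces probe-in-bilayer trajectories with known
tilt mixtures and Gaussian depth distributions, plus excitation ensembles
whose energies are linearly coupled to depth and cos(tilt) — so every stage
is testable end-to-end with exact ground truth, no MD or QM engine required.
Real trajectories (multi-model PDB, GRO, or anything MDAnalysis reads) and
real TD-DFT tables drop into the same interfaces.

## Worked example

```python
from memprobe.pipeline import make_config, run_emission_pipeline

fluid = make_config(seed=1)
fluid["trajectory"]["tilt_model"] = [          # fluid-like: bimodal tilt
    {"mode_deg": 28.0, "concentration": 25.0, "weight": 0.55},
    {"mode_deg": 120.0, "concentration": 12.0, "weight": 0.45},
]
fluid["coupling"].update(depth_slope_ev_per_nm=-0.4, tilt_slope_ev=-0.3,
                         noise_sd_ev=0.05)
res = run_emission_pipeline(fluid, "out_fluid")
print(res["counts"])
print(res["bands"])
print(res["association"].to_dict())
```

prints (seed 1):

```
{'frames': 1500, 'sub_snapshots': 220, 'excitation_records': 220, 'bands': 2,
 'association_group': 47}
[(2.43999999999998, 1.0, 0.9914699688631373),
 (2.809999999999972, 0.8616142785819334, 0.40254671627061145)]
{'depth_thresh_nm': 0.7757632393261267, 'tilt_thresh_deg': 40.0,
 'mean_diff_ev': -0.32617243253885997, 'p_value': 0.0004997501249375312,
 'n_group': 47, 'n_rest': 173}
```

The 220 sub-snapshots are the hierarchical protocol's 22 × 10 manifest; the
two detected bands (≈0.37 eV apart) arise from the two tilt populations,
and the permutation test attributes a −0.33 eV shift to the deep/low-tilt
group at p ≈ 5·10⁻⁴.  A gel-like config (single 28° tilt mode) yields one
band.  The numbered drivers under `analysis/` run this story step by step
(`python analysis/01_simulate_bilayer_probe.py`, … `07_benchmark_harness.py`)
and write tables under `results/`.

There is also a thin CLI: `mps simulate-data | sample | embed | spectra |
correlate | run-all` (see `mps --help`).

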