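# Methods

## Geometric observables

The bilayer is treated as planar with its normal fixed to the laboratory z
axis.  This is the standard convention for planar bilayer simulations and is
what fixed-axis tilt histograms imply; it is *not* appropriate for strongly
undulating or curved membranes, where an instantaneous fitted normal would be
needed (a documented limitation, not an option here).

All semantics are made leaflet-independent by orienting the normal from the
bilayer midplane toward the water phase of the leaflet hosting the probe
(+z for the upper leaflet, −z for the lower).  Consequences:

* **Tilt angle** — angle between the carbonyl-carbon → nitrogen vector of the
  fluorophore and the leaflet-oriented normal.  0° always means "nitrogen
  toward water", 90° "in the membrane plane", 180° "nitrogen toward the
  membrane interior", in either leaflet.  The C→N vector is taken at its
  minimum image, so a probe straddling a periodic boundary is handled.
* **Penetration depth** — signed projection of (phosphate COM − probe COM)
  onto the leaflet-oriented normal.  Positive = deeper than the phosphate
  plane (toward the midplane); "penetrates deeper" maps to larger positive
  values.  The sign convention is a package choice: the source histograms do
  not state one.
* **Probe COM** — by default the *fluorophore moiety* atoms (naphthalenoid
  core, carbonyl C/O, amino N); the calling code can pass any selection
  (e.g. the whole molecule including the acyl tail).  Mass-weighted,
  hydrogens included when present; selections are made whole across periodic
  boundaries before the COM is taken.
* **Chain tilt** — first→last chain-atom vector against the leaflet normal,
  folded to [0°, 90°] since a chain has no head/tail polarity for this
  observable.  The endpoints are a package choice (first to last carbon);
  other conventions (per-segment averages) exist and would differ for bent
  chains.
* **Leaflet assignment** — probe COM z against the mean z of all phosphate
  atoms.  A COM numerically on the midplane (within 1 pm) is refused rather
  than silently assigned.

Histogram defaults: 5° bins on [0°, 180°] for tilt (resolving the ≈13°
separation between the probe and lipid-chain orientational modes), 0.05 nm
bins for depth.  Histograms are density-normalised; the mode is the centre of
the maximum-density bin with ties resolved to the lower bin.

## Synthetic data generator

The generator emulates a single probe in a 128-lipid bilayer (64 per
leaflet) and exists so that every downstream stage has exact ground truth:

* **Tilt** is drawn from a mixture of von-Mises-like kernels
  exp(κ·cos(θ−μ)) restricted to [0°, 180°] and renormalised — bounded
  support matching the tilt definition.  Sampling is by inverse CDF on a
  20001-point grid (error far below the 5° analysis bins); κ = ∞ is a point
  mass, so degenerate checks are exact.  Defaults: a gel-like membrane is
  unimodal at 28° (κ = 25); a fluid-like one adds a second, broader mode at
  120° (κ = 12, weight 0.45), reproducing the reversed-fluorophore
  population seen in fluid bilayers.
* **Depth** is Gaussian; defaults N(0.95, 0.10) nm (gel-like, deeper and
  narrower) and N(0.80, 0.15) nm (fluid-like, shallower and wider).
* The **probe is rigid** (ground- and excited-state geometries of this
  fluorophore are nearly identical, so orientation/position are the relevant
  degrees of freedom); phosphate pseudo-atoms sit exactly on their leaflet
  planes (jittered only laterally), so recomputed tilt/depth equal the
  sampled ground truth to floating point.  Ground truth is emitted as a CSV
  sidecar (frame, time_ns, tilt_deg, depth_nm).
* **Excitation ensembles**: energy = E₀ + a·depth + b·cos(tilt) + N(0, σ),
  with defaults E₀ = 3.0 eV, a = −0.4 eV/nm, b = −0.3 eV, σ = 0.05 eV for
  the coupled (emission) configurations — chosen so the deep/low-tilt
  population emits ≈0.3–0.5 eV lower, the magnitude needed to give a
  resolved second band at δ = 0.1 eV broadening.  Oscillator strengths are
  normal, truncated at zero, N(0.3, 0.05) — matching the bright S1
  oscillator strength scale of the fluorophore.

What the generator does **not** emulate: force-field energetics, dynamical
correlation between frames (frames are i.i.d., so sampling-protocol
autocorrelation effects are invisible), lipid conformational detail, probe
internal flexibility, and any physics connecting the linear energy–geometry
coupling to actual electrostatics.  Passing tests therefore demonstrate the
*machinery* (definitions, protocol arithmetic, statistics, spectra) on known
distributions, not the photophysics of real membranes.

## Snapshot sampling

Equidistant selection is endpoint-inclusive with (n−1) equal intervals; the
source protocols never state the endpoint convention, and the inclusive rule
is the simplest reproducible one.  n = 1 selects the window midpoint.
Requested times snap to the nearest stored frame (ties → earlier frame).
The hierarchical emission protocol (defaults 22 seeds from the last 50 ns,
2 ns secondaries, 10 sub-snapshots in [1, 2] ns → 220 geometries) only
bookkeeps the sub-sampling; running the secondary (polarizable) dynamics is
an input, not something the package does.  In the synthetic pipeline each
sub-snapshot inherits its seed frame's geometry plus a small jitter
(5° tilt, 0.05 nm depth) standing in for the short secondary run.

## Electrostatic embedding

* **Whole-molecule inclusion** with no distance cutoff by default: cutting
  molecules at a radius would create artificial net charges at the boundary.
  An optional molecule-COM cutoff exists for very large systems.
* Each environment molecule is made whole, then rigidly shifted by box
  vectors so its COM is the minimum image with respect to the QM COM — this
  preserves all intramolecular distances exactly.
* **Tail truncation**: the QM fragment is the methyl-capped fluorophore (the
  alkyl tail carries no frontier orbitals); the link hydrogen is placed
  along the cut-bond direction at the standard C–H length 0.109 nm.  Cutting
  inside a ring is refused.  Whether the full chain should remain in the QM
  region is genuinely open; `truncate_to_fluorophore` is optional and the QM
  selection is free.
* Boundary charges (Z1 scheme): if the severed tail is retained as point
  charges, the tail atom of the cut bond is zeroed and its charge spread
  uniformly over the remaining tail atoms, conserving the molecular total.
* Environment points closer than 0.05 nm to a QM atom trigger a *warning*,
  not exclusion — close contacts indicate a broken wrap, which should be
  surfaced, not silently "fixed".
* Point-charge files are `x y z q` with fixed 10-decimal formatting (nm or
  bohr), so read-back is bit-exact at the written precision.

## Nuclear-ensemble spectra

I(E) = (1/N_snap) Σ fᵢ · L(E − ΔEᵢ; δ), with L a unit-area Lorentzian whose
**FWHM is δ** (default 0.1 eV) — the common convention in nuclear-ensemble
codes; peak height of one line is f·2/(πδ).  N_snap counts *distinct
snapshots*, so several states of one snapshot add without diluting each
other, while duplicating a whole snapshot changes nothing.  Intensities are
relative: no absolute cross-section prefactor, and no E³ emission prefactor
by default (an optional flag provides it), since spectra are compared by
shape after max-normalisation.  Default grids: 2.0–6.0 eV (absorption) and
1.5–4.5 eV (emission) at 0.005 eV — 20 points per FWHM.  Wavelength
conversion uses λ = 1239.841984/E nm·eV as a plain intensity remap by
default; a Jacobian flag multiplies by |dE/dλ| when an area-preserving
density is wanted.  Band finding is prominence-based (default 0.05 of the
normalised maximum) on local maxima, sorted by position.

## Structure–spectrum association

Statistic: mean emission energy of {depth > d₀ AND tilt < t₀} minus the
complement's mean.  Defaults d₀ = ensemble median depth (never yields an
empty group) and t₀ = 40°, bracketing the ground-state orientational mode
(≈28°); both are explicit parameters because no canonical cutoffs exist.
Two-sided permutation p-value from label shuffles (default 2000) with the
add-one estimator (1 + #{|T*| ≥ |T|})/(n_perm + 1), reproducible by seed and
never exactly zero.  Degenerate groupings raise instead of returning NaN.

## TD-DFT interface

The package computes no electronic structure.  Vertical transitions enter as
delimited tables (snapshot_id, state, energy_eV, osc_strength[, kind,
depth_nm, tilt_deg]); validation reports offending line numbers.  An engine
is any adapter returning benchmark entries — a command-template adapter runs
an external program that writes the same schema, and a mock adapter replays
stored tables for offline work.  Reference vertical-excitation tables for
the methyl-truncated fluorophore (PBE0/B3LYP × cc-pVDZ/cc-pVTZ/aug-cc-pVDZ/
aug-cc-pVTZ; gas phase, implicit water, implicit cyclohexane) ship as
package data.  Comparison tolerance 0.02 eV / 0.02 f — the cross-code
spread expected from differing quadrature grids and convergence settings.
Because PBE0/cc-pVDZ in cyclohexane has a near-degenerate S2/S3 pair
(3.89/3.90 eV) whose ordering differs across columns, the comparison can
pair states by ascending energy instead of by index; missing states are
reported "untested" rather than failed.

## Pipeline, determinism, problem sizes

A single nested config drives all stages; every stochastic stage derives its
seed from the config seed, so identical configs give bit-identical outputs.
Each run writes a `runlog.json` with the config hash and per-stage counts —
the protocol's arithmetic (30 seeds, 22 × 10 = 220 geometries) is the main
silent-failure risk, so counts are logged at every boundary.

Problem sizes used by the analysis drivers and checks — the package's own
choices balancing statistical resolution against desk-scale runtimes:
1500-frame trajectories for pipeline runs, 20 000 frames for distribution
recovery (SE of the depth mean ≈ 0.001 nm), 220-record ensembles matching
the emission protocol, 500 replicate ensembles at 199 permutations for the
null calibration of the association test, and 2000–5000 permutations for
single reported p-values.

## Known limitations

* Fixed laboratory-z normal: wrong for undulating/curved membranes.
* Orthorhombic boxes only.
* Synthetic frames are statistically independent; protocol properties that
  depend on trajectory autocorrelation are untested.
* The engine contract is exercised against stored tables unless a real
  TD-DFT adapter is registered; geometry optimization and solvation models
  live entirely in the engine.
* The association statistic is a two-group mean difference by design — it
  quantifies the stated qualitative claim and is not a regression model of
  energy on geometry.
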