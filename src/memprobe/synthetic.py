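"""Synthetic bilayer+probe trajectories and coupled excitation ensembles.

The generator emulates the study conditions of a single Laurdan-like probe in
a 128-lipid bilayer (64 per leaflet): a rigid probe whose orientation is drawn
from a tilt-angle mixture (unimodal near 28 deg for a gel-like membrane,
bimodal with a second mode above 90 deg for a fluid-like one) and whose
penetration depth is Gaussian.  Emission/absorption ensembles are generated
with transition energies linearly coupled to depth and cos(tilt) plus
Gaussian noise, so every downstream stage has a known ground truth.

It deliberately omits force-field energetics, lipid conformational detail and
thermal probe flexibility: the probe is a rigid body, lipids are phosphate
pseudo-atoms (plus an optional two-atom acyl chain), and frames are
statistically independent rather than dynamically correlated.

Tilt kernel: a von-Mises-like density ``exp(kappa * cos(theta - mu))``
restricted to [0, 180] deg and renormalised, sampled by inverse CDF on a fine
grid.  ``kappa = inf`` degenerates to a point mass at the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from memprobe.geometry import FrameGeometry

__all__ = [
    "TiltComponent",
    "TrajectoryParams",
    "CouplingParams",
    "Topology",
    "SyntheticTrajectory",
    "generate_trajectory",
    "generate_excitations",
    "sample_tilt_mixture",
    "FLUOROPHORE_NAMES",
    "TAIL_NAMES",
    "DEFAULT_CUT_BOND",
]

# Rigid probe template in its local frame (nm).  The fluorophore axis
# (carbonyl carbon C1 -> amino nitrogen N1) lies along local +z; ring carbons
# C2..C4 and the carbonyl oxygen O1 flesh out the moiety so its centre of
# mass is off the axis endpoints, as for a real naphthalene core.  A
# ten-carbon acyl tail CT1..CT10 hangs below C1 along local -z.
_TEMPLATE = [
    # name, element, mass, x, y, z, charge
    ("C1", "C", 12.011, 0.000, 0.000, 0.000, 0.35),
    ("O1", "O", 15.999, 0.115, 0.000, -0.045, -0.42),
    ("C2", "C", 12.011, -0.120, 0.000, 0.130, -0.05),
    ("C3", "C", 12.011, 0.120, 0.000, 0.250, -0.05),
    ("C4", "C", 12.011, -0.120, 0.000, 0.370, -0.05),
    ("N1", "N", 14.007, 0.000, 0.000, 0.500, -0.30),
] + [
    (f"CT{i}", "C", 12.011, 0.0, 0.0, -0.126 * i, 0.052 if i > 1 else 0.05)
    for i in range(1, 11)
]
# bonds by name: ring chain + carbonyl + tail
_TEMPLATE_BONDS = (
    [("C1", "O1"), ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "N1"), ("C1", "CT1")]
    + [(f"CT{i}", f"CT{i+1}") for i in range(1, 10)]
)

FLUOROPHORE_NAMES = ["C1", "O1", "C2", "C3", "C4", "N1"]
TAIL_NAMES = [f"CT{i}" for i in range(1, 11)]
#: default truncation bond: keep CT1 as the methyl cap, drop CT2..CT10
DEFAULT_CUT_BOND = ("CT1", "CT2")

PROBE_RESNAME = "PRB"
LIPID_RESNAME = "LIP"


@dataclass
class TiltComponent:
    """One component of the angular mixture: mode (deg), concentration, weight."""

    mode_deg: float
    concentration: float
    weight: float


@dataclass
class TrajectoryParams:
    n_frames: int
    frame_interval_ns: float = 0.1
    n_lipids_per_leaflet: int = 64
    box_nm: tuple[float, float, float] = (6.4, 6.4, 7.0)
    tilt_model: list[TiltComponent] = field(
        default_factory=lambda: [TiltComponent(28.0, 20.0, 1.0)]
    )
    depth_model: tuple[float, float] = (0.8, 0.15)  # mean, sd (nm)
    phosphate_plane_z: tuple[float, float] = (5.5, 1.5)  # upper, lower (nm)
    chain_model: TiltComponent | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("n_lipids_per_leaflet must be >= 1")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        w = sum(c.weight for c in self.tilt_model)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"tilt mixture weights must sum to 1 (got {w})")
        if any(c.concentration <= 0 for c in self.tilt_model):
            raise ValueError("tilt concentrations must be positive")
        if self.depth_model[1] < 0:
            raise ValueError("depth sd must be non-negative")
        if self.phosphate_plane_z[0] <= self.phosphate_plane_z[1]:
            raise ValueError("upper phosphate plane must lie above the lower one")


@dataclass
class CouplingParams:
    """Linear structure->energy coupling for synthetic excitation ensembles.

    energy = base_energy + depth_slope*depth + tilt_slope*cos(tilt) + N(0, noise_sd)
    """

    base_energy_ev: float = 3.0
    depth_slope_ev_per_nm: float = 0.0
    tilt_slope_ev: float = 0.0  # per unit of cos(tilt)
    noise_sd_ev: float = 0.0
    f_mean: float = 0.3
    f_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_ev < 0:
            raise ValueError("noise_sd_ev must be >= 0")
        if self.f_mean <= 0:
            raise ValueError("f_mean must be positive")
        if self.f_sd < 0:
            raise ValueError("f_sd must be >= 0")


@dataclass
class Topology:
    """Static per-atom attributes plus molecular bonds (by atom index)."""

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    bonds: list[tuple[int, int]]

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "element": self.elements,
                "mass": self.masses,
                "charge": self.charges,
                "resid": self.resids,
                "resname": self.resnames,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        """Topology as delimited text; bonds appended as an index-pair table."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        bonds = pd.DataFrame(self.bonds, columns=["i", "j"])
        bonds.to_csv(path.with_suffix(".bonds.csv"), index=False)


@dataclass
class SyntheticTrajectory:
    frames: list[FrameGeometry]
    topology: Topology
    ground_truth: pd.DataFrame  # frame, time_ns, tilt_deg, depth_nm
    chain_tilts: np.ndarray | None = None  # (n_frames, n_chains) deg

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def write_ground_truth(self, path: str | Path) -> None:
        self.ground_truth.to_csv(path, index=False)


def _mixture_density(theta: np.ndarray, model: list[TiltComponent]) -> np.ndarray:
    dens = np.zeros_like(theta)
    for comp in model:
        mu = np.radians(comp.mode_deg)
        kappa = comp.concentration
        # subtract the max exponent per component for numerical stability
        expo = kappa * np.cos(theta - mu)
        kern = np.exp(expo - expo.max())
        norm = np.trapezoid(kern, theta)
        dens += comp.weight * kern / norm
    return dens


def sample_tilt_mixture(
    model: list[TiltComponent], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw tilt angles (deg) from the angular mixture on [0, 180].

    Components with ``concentration = inf`` (or beyond float overflow, in
    practice > 1e12) are point masses at their mode.  Finite components are
    sampled by inverse CDF on a 20001-point grid, accurate to well under the
    5-deg histogram bins used downstream.
    """
    weights = np.array([c.weight for c in model])
    which = rng.choice(len(model), size=n, p=weights)
    out = np.empty(n)
    theta_grid = np.linspace(0.0, np.pi, 20001)
    for k, comp in enumerate(model):
        mask = which == k
        m = int(mask.sum())
        if m == 0:
            continue
        if not np.isfinite(comp.concentration) or comp.concentration > 1e12:
            out[mask] = comp.mode_deg
            continue
        dens = _mixture_density(theta_grid, [TiltComponent(comp.mode_deg, comp.concentration, 1.0)])
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(theta_grid))])
        cdf /= cdf[-1]
        u = rng.uniform(size=m)
        out[mask] = np.degrees(np.interp(u, cdf, theta_grid))
    return out


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking local +z to ``axis`` (unit vector), Rodrigues form."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _build_topology(params: TrajectoryParams) -> Topology:
    names, elements, masses, charges, resids, resnames = [], [], [], [], [], []
    bonds: list[tuple[int, int]] = []
    name_to_idx: dict[str, int] = {}
    for name, el, mass, *_xyz, q in _TEMPLATE:
        name_to_idx[name] = len(names)
        names.append(name)
        elements.append(el)
        masses.append(mass)
        charges.append(q)
        resids.append(1)
        resnames.append(PROBE_RESNAME)
    # neutralise the probe exactly (template charges nearly cancel already)
    probe_q = np.array(charges, dtype=float)
    probe_q -= probe_q.sum() / len(probe_q)
    charges = list(probe_q)
    bonds.extend((name_to_idx[a], name_to_idx[b]) for a, b in _TEMPLATE_BONDS)

    with_chain = params.chain_model is not None
    resid = 2
    for _leaflet in ("upper", "lower"):
        for _ in range(params.n_lipids_per_leaflet):
            i_p = len(names)
            names.append("P")
            elements.append("P")
            masses.append(30.974)
            charges.append(0.0)
            resids.append(resid)
            resnames.append(LIPID_RESNAME)
            if with_chain:
                for cname in ("CA1", "CA2"):
                    names.append(cname)
                    elements.append("C")
                    masses.append(12.011)
                    charges.append(0.0)
                    resids.append(resid)
                    resnames.append(LIPID_RESNAME)
                bonds.append((i_p, i_p + 1))
                bonds.append((i_p + 1, i_p + 2))
            resid += 1
    return Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        masses=np.array(masses, dtype=float),
        charges=np.array(charges, dtype=float),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        bonds=bonds,
    )


def generate_trajectory(params: TrajectoryParams) -> SyntheticTrajectory:
    """Generate ``n_frames`` statistically independent frames plus ground truth.

    Per frame the rigid probe is placed in the upper leaflet with a tilt drawn
    from ``tilt_model`` (angle of the C1->N1 axis against +z), a uniform
    azimuth, and its fluorophore centre of mass at
    ``phosphate_plane_z[0] - depth`` with depth drawn from ``depth_model``.
    Phosphate pseudo-atoms sit exactly on their leaflet planes (jittered only
    in x/y), so the recomputed observables reproduce the ground truth exactly
    up to floating-point error.
    """
    rng = np.random.default_rng(params.seed)
    topo = _build_topology(params)
    box = np.asarray(params.box_nm, dtype=float)
    n = params.n_frames

    tilts = sample_tilt_mixture(params.tilt_model, n, rng)
    mean_d, sd_d = params.depth_model
    depths = np.full(n, mean_d) if sd_d == 0 else rng.normal(mean_d, sd_d, size=n)
    azimuths = rng.uniform(0, 2 * np.pi, size=n)
    xy = rng.uniform(0.25, 0.75, size=(n, 2)) * box[:2]

    template_xyz = np.array([[x, y, z] for _, _, _, x, y, z, _ in _TEMPLATE])
    fl_idx = np.arange(len(FLUOROPHORE_NAMES))  # template order: fluorophore first
    fl_masses = np.array([m for _, _, m, *_ in _TEMPLATE[: len(FLUOROPHORE_NAMES)]])
    fl_com_local = (fl_masses[:, None] * template_xyz[fl_idx]).sum(axis=0) / fl_masses.sum()

    with_chain = params.chain_model is not None
    n_per = params.n_lipids_per_leaflet
    n_lip = 2 * n_per
    grid = int(np.ceil(np.sqrt(n_per)))
    chain_tilts_all = np.empty((n, n_lip)) if with_chain else None
    gk = np.arange(n_per)
    base_xy = np.column_stack(
        [(gk // grid + 0.5) * box[0] / grid, (gk % grid + 0.5) * box[1] / grid]
    )
    atoms_per_lipid = 3 if with_chain else 1
    n_probe = len(template_xyz)

    frames: list[FrameGeometry] = []
    for t in range(n):
        pos = np.zeros((topo.n_atoms, 3))
        theta = np.radians(tilts[t])
        axis = np.array(
            [
                np.sin(theta) * np.cos(azimuths[t]),
                np.sin(theta) * np.sin(azimuths[t]),
                np.cos(theta),
            ]
        )
        rot = _rotation_to(axis)
        probe_xyz = template_xyz @ rot.T
        fl_com = fl_masses[:, None] * probe_xyz[fl_idx]
        fl_com = fl_com.sum(axis=0) / fl_masses.sum()
        target = np.array([xy[t, 0], xy[t, 1], params.phosphate_plane_z[0] - depths[t]])
        probe_xyz += target - fl_com
        pos[:n_probe] = probe_xyz

        if with_chain:
            cm = params.chain_model
            ch = sample_tilt_mixture([TiltComponent(cm.mode_deg, cm.concentration, 1.0)], n_lip, rng)
            ch_az = rng.uniform(0, 2 * np.pi, size=n_lip)
            chain_tilts_all[t] = ch
        for half, (plane_z, down) in enumerate(
            [(params.phosphate_plane_z[0], -1.0), (params.phosphate_plane_z[1], +1.0)]
        ):
            jit = rng.uniform(-0.05, 0.05, size=(n_per, 2))
            p_xyz = np.column_stack([base_xy + jit, np.full(n_per, plane_z)])
            start = n_probe + half * n_per * atoms_per_lipid
            block = slice(start, start + n_per * atoms_per_lipid)
            if not with_chain:
                pos[block] = p_xyz
            else:
                sl = slice(half * n_per, (half + 1) * n_per)
                psi = np.radians(ch[sl])
                # chains point toward the midplane, tilted psi off the normal
                v = np.column_stack(
                    [
                        np.sin(psi) * np.cos(ch_az[sl]),
                        np.sin(psi) * np.sin(ch_az[sl]),
                        down * np.cos(psi),
                    ]
                )
                stacked = np.empty((n_per, 3, 3))
                stacked[:, 0] = p_xyz
                stacked[:, 1] = p_xyz + 0.5 * v
                stacked[:, 2] = p_xyz + 1.0 * v
                pos[block] = stacked.reshape(-1, 3)
        frames.append(
            FrameGeometry(
                positions=pos,
                names=topo.names,
                masses=topo.masses,
                resids=topo.resids,
                resnames=topo.resnames,
                box=box,
                time=t * params.frame_interval_ns,
                charges=topo.charges,
            )
        )

    gt = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_ns": np.arange(n) * params.frame_interval_ns,
            "tilt_deg": tilts,
            "depth_nm": depths,
        }
    )
    return SyntheticTrajectory(
        frames=frames, topology=topo, ground_truth=gt, chain_tilts=chain_tilts_all
    )


def generate_excitations(
    descriptors: pd.DataFrame,
    params: CouplingParams,
    kind: str = "emission",
    state: int = 1,
) -> pd.DataFrame:
    """One vertical transition per descriptor row (columns tilt_deg, depth_nm).

    Energies follow the linear coupling of :class:`CouplingParams`; oscillator
    strengths are drawn from a normal truncated at zero.  The returned table
    uses the excitation schema (snapshot_id, state, energy_eV, osc_strength)
    with the generating descriptors carried along.
    """
    if len(descriptors) == 0:
        raise ValueError("descriptor list is empty")
    for col in ("tilt_deg", "depth_nm"):
        if col not in descriptors.columns:
            raise ValueError(f"descriptors missing column {col!r}")
    rng = np.random.default_rng(params.seed)
    depth = descriptors["depth_nm"].to_numpy(dtype=float)
    tilt = np.radians(descriptors["tilt_deg"].to_numpy(dtype=float))
    n = len(descriptors)
    energy = (
        params.base_energy_ev
        + params.depth_slope_ev_per_nm * depth
        + params.tilt_slope_ev * np.cos(tilt)
    )
    if params.noise_sd_ev > 0:
        energy = energy + rng.normal(0.0, params.noise_sd_ev, size=n)
    if params.f_sd == 0:
        f = np.full(n, params.f_mean)
    else:
        a = (0.0 - params.f_mean) / params.f_sd  # truncate at zero
        f = truncnorm.rvs(a, np.inf, loc=params.f_mean, scale=params.f_sd, size=n, random_state=rng)
    snapshot_id = (
        descriptors["snapshot_id"].to_numpy()
        if "snapshot_id" in descriptors.columns
        else np.arange(n)
    )
    return pd.DataFrame(
        {
            "snapshot_id": snapshot_id,
            "state": state,
            "energy_eV": energy,
            "osc_strength": f,
            "kind": kind,
            "depth_nm": depth,
            "tilt_deg": descriptors["tilt_deg"].to_numpy(dtype=float),
        }
    )
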