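"""Geometric observables of a membrane-embedded probe.

All lengths are in nanometres, all angles in degrees, boxes are orthorhombic.
The bilayer is assumed planar with its normal along the laboratory z axis
(the standard convention for planar bilayer simulations; not appropriate for
strongly undulating membranes).

Sign conventions
----------------
* The *leaflet-oriented* normal points from the bilayer midplane toward the
  water phase of the leaflet hosting the probe: +z for the upper leaflet,
  -z for the lower one.  Tilt and depth are therefore leaflet-independent:
  tilt 0 deg always means "nitrogen toward water", and a positive depth
  always means "probe centre of mass deeper than the phosphate plane".
* Penetration depth is the signed projection of (phosphate COM - probe COM)
  onto the leaflet-oriented normal.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameGeometry",
    "OrientationHistogram",
    "SelectionError",
    "TopologyError",
    "AmbiguousLeafletError",
    "bilayer_normal",
    "leaflet_normal",
    "assign_leaflet",
    "probe_tilt_angle",
    "penetration_depth",
    "chain_tilt_angle",
    "build_histogram",
    "group_com",
]


class SelectionError(ValueError):
    """An atom selection is empty, missing, or ambiguous."""


class TopologyError(ValueError):
    """Masses/charges/bonds required for an operation are absent or invalid."""


class AmbiguousLeafletError(ValueError):
    """The probe centre of mass lies exactly on the bilayer midplane."""


@dataclass
class FrameGeometry:
    """One coordinate frame with the topology attributes the observables need.

    Parameters
    ----------
    positions : (n, 3) float array, nm
    names : (n,) str array — atom names (e.g. ``"C1"``, ``"N1"``, ``"P"``)
    masses : (n,) float array, amu
    resids : (n,) int array — molecule/residue id; a molecule is one resid
    resnames : (n,) str array
    box : (3,) float array, nm — orthorhombic box edges
    time : float, ns
    charges : optional (n,) float array, e — needed for embedding only
    """

    positions: np.ndarray
    names: np.ndarray
    masses: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    box: np.ndarray
    time: float = 0.0
    charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        for attr in ("names", "masses", "resids", "resnames"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length does not match positions")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def select(
        self,
        names: str | list[str] | None = None,
        resnames: str | list[str] | None = None,
        resids: int | list[int] | None = None,
    ) -> np.ndarray:
        """Return the indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            names = [names] if isinstance(names, str) else list(names)
            mask &= np.isin(self.names.astype(str), names)
        if resnames is not None:
            resnames = [resnames] if isinstance(resnames, str) else list(resnames)
            mask &= np.isin(self.resnames.astype(str), resnames)
        if resids is not None:
            resids = [resids] if isinstance(resids, (int, np.integer)) else list(resids)
            mask &= np.isin(self.resids, resids)
        return np.flatnonzero(mask)

    def single_atom(self, name: str, resname: str | None = None) -> int:
        idx = self.select(names=name, resnames=resname)
        if len(idx) == 0:
            raise SelectionError(f"atom {name!r} not found")
        if len(idx) > 1:
            raise SelectionError(f"atom {name!r} matched {len(idx)} atoms; expected one")
        return int(idx[0])


def _make_whole(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a group across periodic boundaries relative to its first atom."""
    ref = positions[0]
    delta = positions - ref
    delta -= box * np.round(delta / box)
    return ref + delta


def group_com(frame: FrameGeometry, idx: np.ndarray, unwrap: bool = True) -> np.ndarray:
    """Mass-weighted centre of mass of the atoms ``idx`` (group made whole first)."""
    idx = np.asarray(idx, dtype=int)
    if len(idx) == 0:
        raise SelectionError("empty selection has no centre of mass")
    m = frame.masses[idx]
    total = m.sum()
    if total <= 0:
        raise TopologyError("selection has zero total mass")
    pos = frame.positions[idx]
    if unwrap:
        pos = _make_whole(pos, frame.box)
    return (m[:, None] * pos).sum(axis=0) / total


def bilayer_normal(frame: FrameGeometry) -> np.ndarray:
    """Unit bilayer normal: the laboratory z axis by convention."""
    return np.array([0.0, 0.0, 1.0])


def leaflet_normal(frame: FrameGeometry, leaflet: str) -> np.ndarray:
    """Normal oriented from the midplane toward the water phase of ``leaflet``."""
    n = bilayer_normal(frame)
    if leaflet == "upper":
        return n
    if leaflet == "lower":
        return -n
    raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")


def assign_leaflet(
    frame: FrameGeometry,
    probe_idx: np.ndarray,
    phosphate_name: str = "P",
) -> str:
    """Assign the probe to a leaflet by comparing its COM z to the midplane.

    The midplane is the mean z of all phosphate atoms (both leaflets).
    """
    p_idx = frame.select(names=phosphate_name)
    if len(p_idx) == 0:
        raise SelectionError(f"no phosphate atoms named {phosphate_name!r}")
    midplane = float(frame.positions[p_idx, 2].mean())
    com_z = float(group_com(frame, probe_idx)[2])
    if abs(com_z - midplane) < 1e-9:  # numerically on the midplane
        raise AmbiguousLeafletError("probe centre of mass lies exactly on the midplane")
    return "upper" if com_z > midplane else "lower"


def probe_tilt_angle(
    frame: FrameGeometry,
    carbonyl_name: str = "C1",
    nitrogen_name: str = "N1",
    leaflet: str = "upper",
) -> float:
    """Tilt of the fluorophore: angle (deg) between C->N and the leaflet normal.

    0 deg: fluorophore parallel to the normal, nitrogen toward the water phase.
    90 deg: fluorophore in the membrane plane.  180 deg: nitrogen pointing
    toward the membrane interior.
    """
    c = frame.positions[frame.single_atom(carbonyl_name)]
    n_at = frame.positions[frame.single_atom(nitrogen_name)]
    v = n_at - c
    v -= frame.box * np.round(v / frame.box)  # minimum image C->N
    norm = np.linalg.norm(v)
    if norm == 0:
        raise SelectionError("carbonyl and nitrogen atoms coincide")
    cos_t = float(np.dot(v / norm, leaflet_normal(frame, leaflet)))
    return float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))


def penetration_depth(
    frame: FrameGeometry,
    probe_idx: np.ndarray,
    phosphate_idx: np.ndarray,
    leaflet: str = "upper",
) -> float:
    """Signed penetration depth (nm) of the probe below the phosphate plane.

    Projection of (phosphate COM - probe COM) onto the leaflet-oriented
    normal; positive when the probe sits deeper (closer to the midplane)
    than the phosphate plane of its host leaflet.
    """
    probe_com = group_com(frame, probe_idx)
    phos_com = group_com(frame, phosphate_idx)
    n = leaflet_normal(frame, leaflet)
    return float(np.dot(phos_com - probe_com, n))


def chain_tilt_angle(
    frame: FrameGeometry,
    chain_idx: np.ndarray,
    leaflet: str = "upper",
) -> float:
    """Acyl-chain tilt: angle between the first->last chain atom vector and the
    leaflet normal, folded to [0, 90] deg (a chain has no head/tail polarity
    for this observable)."""
    chain_idx = np.asarray(chain_idx, dtype=int)
    if len(chain_idx) < 2:
        raise SelectionError("chain tilt needs at least two atoms")
    pos = _make_whole(frame.positions[chain_idx], frame.box)
    v = pos[-1] - pos[0]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise SelectionError("degenerate chain: first and last atoms coincide")
    cos_t = abs(float(np.dot(v / norm, leaflet_normal(frame, leaflet))))
    return float(np.degrees(np.arccos(np.clip(cos_t, 0.0, 1.0))))


@dataclass
class OrientationHistogram:
    """Density-normalised histogram of tilt angles or penetration depths."""

    edges: np.ndarray
    density: np.ndarray
    n_samples: int
    bin_width: float = field(init=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.edges) != len(self.density) + 1:
            raise ValueError("edges must have one more entry than density")
        widths = np.diff(self.edges)
        if np.any(self.density < 0):
            raise ValueError("negative density")
        total = float(np.sum(self.density * widths))
        if self.density.any() and abs(total - 1.0) > 1e-9:
            raise ValueError(f"histogram not density-normalised (integral {total})")
        self.bin_width = float(widths[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mode(self) -> float:
        """Centre of the maximum-density bin; ties resolve to the lower bin."""
        return float(self.centers[int(np.argmax(self.density))])

    def local_maxima(self, min_rel_height: float = 0.1) -> np.ndarray:
        """Centres of interior local maxima above ``min_rel_height``·max density."""
        d = self.density
        peak = d.max()
        if peak == 0:
            return np.array([])
        idx = [
            i
            for i in range(len(d))
            if d[i] >= min_rel_height * peak
            and (i == 0 or d[i] > d[i - 1])
            and (i == len(d) - 1 or d[i] >= d[i + 1])
        ]
        return self.centers[idx]


def build_histogram(
    samples: np.ndarray,
    bin_width: float,
    value_range: tuple[float, float],
) -> OrientationHistogram:
    """Bin ``samples`` on ``value_range`` with fixed ``bin_width`` (density norm).

    Samples outside the range are dropped with a warning rather than silently
    clipped; the density then normalises over the retained samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = value_range
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-12))
    edges = lo + bin_width * np.arange(n_bins + 1)
    inside = (samples >= lo) & (samples <= edges[-1])
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} samples outside [{lo}, {edges[-1]}] dropped",
            stacklevel=2,
        )
        samples = samples[inside]
        if samples.size == 0:
            raise ValueError("all samples outside the histogram range")
    density, _ = np.histogram(samples, bins=edges, density=True)
    return OrientationHistogram(edges=edges, density=density, n_samples=int(samples.size))
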