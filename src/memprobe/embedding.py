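"""QM fragment construction and point-charge environments.

For vertical-transition single points the probe fluorophore is treated
quantum mechanically while every surrounding molecule (waters, lipids)
becomes a set of fixed point charges taken from the force field.  Two rules
keep the embedding physical:

* whole-molecule inclusion — a molecule contributes either all of its atoms
  or none, so no artificial net charges appear at a cutoff boundary (there
  is no distance cutoff by default; an optional molecule-COM cutoff exists);
* minimum-image placement — each environment molecule is rigidly shifted by
  box vectors so its centre of mass is the periodic image nearest the QM
  centre of mass, which preserves all intramolecular distances.

The probe's inert alkyl tail carries no frontier orbitals and can be cut
away: the fragment is capped to a methyl by a hydrogen placed along the cut
bond at the standard C-H distance (0.109 nm).  Charges of the removed tail
are handled Z1-style: the tail-side atom of the cut bond is zeroed and its
charge spread uniformly over the remaining tail atoms, conserving the
molecular total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from memprobe.geometry import FrameGeometry, SelectionError, TopologyError, group_com
from memprobe.synthetic import Topology

__all__ = [
    "QMFragment",
    "ChargeEnvironment",
    "truncate_to_fluorophore",
    "redistribute_tail_charges",
    "build_environment",
    "write_point_charges",
    "read_point_charges",
    "write_xyz",
]

C_H_BOND_NM = 0.109
BOHR_PER_NM = 1.0 / 0.052917721092


@dataclass
class QMFragment:
    """Atoms entering the quantum region, with link-atom bookkeeping."""

    names: list[str]
    elements: list[str]
    positions: np.ndarray  # (n, 3) nm
    net_charge: int = 0
    link_atoms: list[dict] = field(default_factory=list)  # replaced atom, H position

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class ChargeEnvironment:
    positions: np.ndarray  # (m, 3) nm
    charges: np.ndarray  # (m,) e
    molecule_ids: np.ndarray  # resid of origin

    @property
    def n_points(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def _molecule_graph(topology: Topology) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_atoms))
    g.add_edges_from(topology.bonds)
    return g


def truncate_to_fluorophore(
    topology: Topology,
    positions: np.ndarray,
    cut_bond: tuple[str, str],
    probe_resid: int = 1,
) -> QMFragment:
    """Cut the probe at ``cut_bond = (kept_atom, removed_atom)`` and cap with H.

    Everything connected to ``removed_atom`` once the bond is severed is
    dropped; a hydrogen is placed along the cut-bond direction at 0.109 nm
    from the kept atom.  Cutting a bond inside a ring (severing it does not
    disconnect the molecule) is a topology error.
    """
    positions = np.asarray(positions, dtype=float)
    probe_idx = np.flatnonzero(topology.resids == probe_resid)
    if len(probe_idx) == 0:
        raise SelectionError(f"no atoms with resid {probe_resid}")
    name_of = {int(i): str(topology.names[i]) for i in probe_idx}
    keep_name, drop_name = cut_bond
    try:
        i_keep = next(i for i, nm in name_of.items() if nm == keep_name)
        i_drop = next(i for i, nm in name_of.items() if nm == drop_name)
    except StopIteration as exc:
        raise SelectionError(f"cut bond {cut_bond} not resolvable in probe") from exc

    g = _molecule_graph(topology).subgraph(probe_idx).copy()
    if not g.has_edge(i_keep, i_drop):
        raise TopologyError(f"no bond between {keep_name} and {drop_name}")
    g.remove_edge(i_keep, i_drop)
    if nx.has_path(g, i_keep, i_drop):
        raise TopologyError(f"cut bond {cut_bond} lies inside a ring")
    drop_side = nx.node_connected_component(g, i_drop)
    kept = [i for i in probe_idx if i not in drop_side]

    direction = positions[i_drop] - positions[i_keep]
    direction /= np.linalg.norm(direction)
    h_pos = positions[i_keep] + C_H_BOND_NM * direction

    names = [name_of[i] for i in kept] + ["HL1"]
    elements = [str(topology.elements[i]) for i in kept] + ["H"]
    pos = np.vstack([positions[kept], h_pos[None, :]])
    return QMFragment(
        names=names,
        elements=elements,
        positions=pos,
        net_charge=0,
        link_atoms=[{"replaced": drop_name, "bonded_to": keep_name, "h_position": h_pos}],
    )


def redistribute_tail_charges(
    topology: Topology, cut_bond: tuple[str, str], probe_resid: int = 1
) -> np.ndarray:
    """Z1 boundary-charge scheme for the truncated tail, returned as a full
    charge array: the tail-side atom of the cut bond is zeroed and its charge
    spread uniformly over the other removed-tail atoms (molecular total
    conserved).  Useful when the severed tail is to be retained as point
    charges rather than discarded."""
    charges = topology.charges.copy()
    probe_idx = np.flatnonzero(topology.resids == probe_resid)
    name_of = {int(i): str(topology.names[i]) for i in probe_idx}
    keep_name, drop_name = cut_bond
    i_keep = next(i for i, nm in name_of.items() if nm == keep_name)
    i_drop = next(i for i, nm in name_of.items() if nm == drop_name)
    g = _molecule_graph(topology).subgraph(probe_idx).copy()
    g.remove_edge(i_keep, i_drop)
    tail = sorted(nx.node_connected_component(g, i_drop))
    rest = [i for i in tail if i != i_drop]
    if rest:
        charges[rest] += charges[i_drop] / len(rest)
    charges[i_drop] = 0.0
    return charges


def build_environment(
    frame: FrameGeometry,
    qm_idx: np.ndarray,
    r_min_nm: float = 0.05,
    com_cutoff_nm: float | None = None,
) -> ChargeEnvironment:
    """Point charges for every molecule not intersecting the QM selection.

    Molecules (= residues) are kept whole and shifted to their minimum image
    relative to the QM centre of mass.  ``com_cutoff_nm`` optionally drops
    whole molecules whose COM lies beyond the cutoff.  Environment points
    closer than ``r_min_nm`` to any QM atom trigger a warning (a broken wrap
    usually, not physics to fix silently).
    """
    if frame.charges is None or np.any(~np.isfinite(frame.charges)):
        raise TopologyError("per-atom charges are required for the environment")
    qm_idx = np.asarray(qm_idx, dtype=int)
    if len(qm_idx) == 0:
        raise SelectionError("empty QM selection")
    qm_resids = set(frame.resids[qm_idx].tolist())
    qm_com = group_com(frame, qm_idx)
    box = frame.box

    pos_out, q_out, mol_out = [], [], []
    for rid in np.unique(frame.resids):
        if rid in qm_resids:
            continue
        idx = np.flatnonzero(frame.resids == rid)
        pos = frame.positions[idx].copy()
        # make molecule whole, then shift to the COM minimum image wrt QM
        ref = pos[0]
        pos -= box * np.round((pos - ref) / box)
        m = frame.masses[idx]
        com = (m[:, None] * pos).sum(axis=0) / m.sum()
        shift = box * np.round((com - qm_com) / box)
        pos -= shift
        com -= shift
        if com_cutoff_nm is not None and np.linalg.norm(com - qm_com) > com_cutoff_nm:
            continue
        pos_out.append(pos)
        q_out.append(frame.charges[idx])
        mol_out.append(np.full(len(idx), rid))

    if not pos_out:
        return ChargeEnvironment(
            positions=np.empty((0, 3)), charges=np.empty(0), molecule_ids=np.empty(0, dtype=int)
        )
    env = ChargeEnvironment(
        positions=np.vstack(pos_out),
        charges=np.concatenate(q_out),
        molecule_ids=np.concatenate(mol_out).astype(int),
    )
    qm_pos = frame.positions[qm_idx]
    d = np.linalg.norm(env.positions[:, None, :] - qm_pos[None, :, :], axis=2)
    n_close = int((d.min(axis=1) < r_min_nm).sum())
    if n_close:
        warnings.warn(
            f"{n_close} environment points closer than {r_min_nm} nm to a QM atom "
            "(check periodic wrapping)",
            stacklevel=2,
        )
    return env


def write_point_charges(
    env: ChargeEnvironment, path: str | Path, units: str = "nm"
) -> Path:
    """Write ``x y z q`` per line with fixed 10-decimal formatting.

    ``units`` selects nm (default) or bohr for the coordinates; charges are
    always in elementary charge units.  Reading the file back reproduces the
    values bit-exactly at the written precision.
    """
    if units not in ("nm", "bohr"):
        raise ValueError(f"units must be 'nm' or 'bohr', got {units!r}")
    path = Path(path)
    scale = 1.0 if units == "nm" else BOHR_PER_NM
    if env.n_points == 0:
        warnings.warn("writing an empty point-charge environment", stacklevel=2)
    with open(path, "w") as fh:
        for (x, y, z), q in zip(env.positions * scale, env.charges):
            fh.write(f"{x:.10f} {y:.10f} {z:.10f} {q:.10f}\n")
    return path


def read_point_charges(path: str | Path, units: str = "nm") -> ChargeEnvironment:
    data = np.loadtxt(path, ndmin=2) if Path(path).stat().st_size else np.empty((0, 4))
    scale = 1.0 if units == "nm" else 1.0 / BOHR_PER_NM
    return ChargeEnvironment(
        positions=data[:, :3] * scale,
        charges=data[:, 3],
        molecule_ids=np.full(len(data), -1, dtype=int),
    )


def write_xyz(fragment: QMFragment, path: str | Path, comment: str = "") -> Path:
    """QM fragment as a standard XYZ file (coordinates in Angstrom)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{fragment.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(fragment.elements, fragment.positions * 10.0):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    return path
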