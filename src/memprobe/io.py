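"""Reading and writing coordinate frames via MDAnalysis.

memprobe works in nanometres internally; MDAnalysis uses Angstrom, so every
conversion happens here and nowhere else.  Multi-model PDB and GRO frame
sequences are the interchange formats (XTC/TRR also load if MDAnalysis has
the reader for them).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from memprobe.geometry import FrameGeometry
from memprobe.synthetic import Topology

__all__ = ["write_multimodel_pdb", "write_gro_sequence", "load_frames"]

_NM_PER_ANGSTROM = 0.1


def _universe_from(topology: Topology, frames: list[FrameGeometry]):
    import MDAnalysis as mda

    n_res = int(topology.resids.max())
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=n_res,
        atom_resindex=topology.resids - 1,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.names.astype(str))
    u.add_TopologyAttr("masses", topology.masses)
    u.add_TopologyAttr("charges", topology.charges)
    resnames = [""] * n_res
    for rid, rname in zip(topology.resids, topology.resnames):
        resnames[rid - 1] = str(rname)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("elements", topology.elements.astype(str))

    coords = np.stack([f.positions for f in frames]) / _NM_PER_ANGSTROM
    boxes = np.stack(
        [np.concatenate([f.box / _NM_PER_ANGSTROM, [90.0, 90.0, 90.0]]) for f in frames]
    )
    u.load_new(coords, dimensions=boxes, format="memory")
    return u


def write_multimodel_pdb(topology: Topology, frames: list[FrameGeometry], path: str | Path) -> None:
    """All frames as MODEL/ENDMDL records of one PDB file."""
    import MDAnalysis as mda

    u = _universe_from(topology, frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDA warns about absent altLocs etc.
        with mda.Writer(str(path), multiframe=True, n_atoms=u.atoms.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_gro_sequence(
    topology: Topology, frames: list[FrameGeometry], directory: str | Path, stem: str = "frame"
) -> list[Path]:
    """One GRO file per frame: ``<stem>_00000.gro`` ... in ``directory``."""
    import MDAnalysis as mda

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    u = _universe_from(topology, frames)
    paths = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, _ in enumerate(u.trajectory):
            p = directory / f"{stem}_{i:05d}.gro"
            with mda.Writer(str(p), n_atoms=u.atoms.n_atoms) as w:
                w.write(u.atoms)
            paths.append(p)
    return paths


def _cryst1_box_nm(path: str | Path) -> np.ndarray | None:
    """Orthorhombic box from a PDB CRYST1 record (some readers drop it)."""
    path = Path(path)
    if path.suffix.lower() not in (".pdb", ".ent"):
        return None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                edges = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                return edges * _NM_PER_ANGSTROM
    return None


def load_frames(
    path: str | Path,
    topology: Topology | None = None,
    frame_interval_ns: float | None = None,
) -> list[FrameGeometry]:
    """Load a multi-model PDB (or any MDAnalysis-readable trajectory) as frames.

    Masses/charges come from ``topology`` when given (PDB does not store
    them); otherwise MDAnalysis' guesses are used and charges are absent.
    Frame times default to the trajectory's own times (ps -> ns) unless
    ``frame_interval_ns`` overrides them.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    fallback_box = _cryst1_box_nm(path)
    frames = []
    for i, ts in enumerate(u.trajectory):
        if topology is not None:
            names, masses = topology.names, topology.masses
            resids, resnames = topology.resids, topology.resnames
            charges = topology.charges
        else:
            names = u.atoms.names.astype(object)
            masses = u.atoms.masses
            resids = u.atoms.resids
            resnames = u.atoms.resnames.astype(object)
            charges = None
        if frame_interval_ns is not None:
            time_ns = i * frame_interval_ns
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # readers without dt warn
                time_ns = float(ts.time) * 1e-3  # MDAnalysis time is ps
        if ts.dimensions is not None:
            box = ts.dimensions[:3] * _NM_PER_ANGSTROM
        elif fallback_box is not None:
            box = fallback_box
        else:
            raise ValueError(f"{path}: no box information in trajectory")
        frames.append(
            FrameGeometry(
                positions=ts.positions * _NM_PER_ANGSTROM,
                names=names,
                masses=masses,
                resids=resids,
                resnames=resnames,
                box=box,
                time=time_ns,
                charges=charges,
            )
        )
    return frames
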