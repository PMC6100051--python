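"""QM fragment truncation and point-charge environment construction."""

import numpy as np
import pytest

from memprobe.embedding import (
    build_environment,
    read_point_charges,
    redistribute_tail_charges,
    truncate_to_fluorophore,
    write_point_charges,
    write_xyz,
)
from memprobe.geometry import FrameGeometry, TopologyError
from memprobe.synthetic import (
    DEFAULT_CUT_BOND,
    FLUOROPHORE_NAMES,
    TAIL_NAMES,
    Topology,
    TrajectoryParams,
    generate_trajectory,
)

TIP3P = (-0.834, 0.417, 0.417)


def water_frame(n_waters=3, box=(3.0, 3.0, 3.0), offset=(0.0, 0.0, 0.0)):
    """QM probe dimer at the box centre + rigid 3-site waters around it."""
    positions = [[1.5, 1.5, 1.5], [1.5, 1.5, 1.9]]
    names = ["C1", "N1"]
    masses = [12.011, 14.007]
    charges = [0.1, -0.1]
    resids = [1, 1]
    resnames = ["PRB", "PRB"]
    rng = np.random.default_rng(0)
    for w in range(n_waters):
        o = rng.uniform(0.3, 2.7, 3) + np.asarray(offset)
        h1 = o + [0.095, 0.0, 0.0]
        h2 = o + [-0.024, 0.092, 0.0]
        positions += [o, h1, h2]
        names += ["OW", "HW1", "HW2"]
        masses += [15.999, 1.008, 1.008]
        charges += list(TIP3P)
        resids += [2 + w] * 3
        resnames += ["SOL"] * 3
    return FrameGeometry(
        positions=np.array(positions),
        names=np.array(names, dtype=object),
        masses=np.array(masses),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        box=np.array(box),
        charges=np.array(charges),
    )


@pytest.fixture
def probe_trajectory():
    return generate_trajectory(TrajectoryParams(n_frames=1, n_lipids_per_leaflet=9, seed=0))


class TestTruncation:
    def test_tail_removed_and_methyl_cap_added(self, probe_trajectory):
        topo, frame = probe_trajectory.topology, probe_trajectory.frames[0]
        frag = truncate_to_fluorophore(topo, frame.positions, DEFAULT_CUT_BOND)
        assert set(FLUOROPHORE_NAMES) <= set(frag.names)
        assert "CT1" in frag.names  # the retained methyl carbon
        assert not (set(TAIL_NAMES[1:]) & set(frag.names))
        # atom bookkeeping: probe - removed tail + one link hydrogen
        n_probe = int((topo.resids == 1).sum())
        assert frag.n_atoms == n_probe - len(TAIL_NAMES[1:]) + 1

    def test_link_hydrogen_collinear_at_standard_ch_length(self, probe_trajectory):
        topo, frame = probe_trajectory.topology, probe_trajectory.frames[0]
        frag = truncate_to_fluorophore(topo, frame.positions, DEFAULT_CUT_BOND)
        names = list(topo.names)
        ct1 = frame.positions[names.index("CT1")]
        ct2 = frame.positions[names.index("CT2")]
        h = frag.link_atoms[0]["h_position"]
        assert np.linalg.norm(h - ct1) == pytest.approx(0.109, abs=1e-9)
        cosang = np.dot(h - ct1, ct2 - ct1) / (
            np.linalg.norm(h - ct1) * np.linalg.norm(ct2 - ct1)
        )
        assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_cut_bond_inside_ring_raises(self, probe_trajectory):
        topo, frame = probe_trajectory.topology, probe_trajectory.frames[0]
        ring_topo = Topology(
            names=topo.names,
            elements=topo.elements,
            masses=topo.masses,
            charges=topo.charges,
            resids=topo.resids,
            resnames=topo.resnames,
            bonds=topo.bonds + [(list(topo.names).index("CT2"), list(topo.names).index("CT4"))],
        )
        with pytest.raises(TopologyError):
            truncate_to_fluorophore(ring_topo, frame.positions, ("CT2", "CT3"))

    def test_xyz_roundtrip_atom_count(self, probe_trajectory, tmp_path):
        topo, frame = probe_trajectory.topology, probe_trajectory.frames[0]
        frag = truncate_to_fluorophore(topo, frame.positions, DEFAULT_CUT_BOND)
        p = write_xyz(frag, tmp_path / "frag.xyz")
        lines = p.read_text().splitlines()
        assert int(lines[0]) == frag.n_atoms == len(lines) - 2

    def test_tail_charge_redistribution_conserves_molecular_charge(self, probe_trajectory):
        topo = probe_trajectory.topology
        q = redistribute_tail_charges(topo, DEFAULT_CUT_BOND)
        probe = topo.resids == 1
        assert q[probe].sum() == pytest.approx(topo.charges[probe].sum(), abs=1e-12)
        assert q[list(topo.names).index("CT2")] == 0.0


class TestEnvironment:
    def test_three_waters_give_nine_neutral_points(self):
        frame = water_frame(3)
        env = build_environment(frame, frame.select(resids=1))
        assert env.n_points == 9
        assert env.total_charge == pytest.approx(0.0, abs=1e-9)

    def test_zwitterionic_molecule_stays_neutral(self):
        # +/- site pair on one molecule, like a PC headgroup
        frame = water_frame(2)
        frame.charges[frame.resids == 2] = [0.8, -0.4, -0.4]
        env = build_environment(frame, frame.select(resids=1))
        assert env.total_charge == pytest.approx(0.0, abs=1e-9)

    def test_whole_molecule_inclusion(self):
        frame = water_frame(4)
        env = build_environment(frame, frame.select(resids=1))
        ids, counts = np.unique(env.molecule_ids, return_counts=True)
        assert all(c == 3 for c in counts)  # no partial waters

    def test_minimum_image_wrapping_near_box_edge(self):
        # waters displaced a full box away must wrap back within half a box
        frame = water_frame(5, offset=(3.0, 0.0, 0.0))
        qm_idx = frame.select(resids=1)
        env = build_environment(frame, qm_idx)
        from memprobe.geometry import group_com

        qm_com = group_com(frame, qm_idx)
        delta = np.abs(env.positions - qm_com)
        assert np.all(delta <= frame.box / 2 + 0.11)  # molecule extent slack

    def test_wrapping_preserves_intramolecular_distances(self):
        frame = water_frame(5, offset=(2.5, 2.5, 0.0))
        env = build_environment(frame, frame.select(resids=1))
        for rid in np.unique(env.molecule_ids):
            pos = env.positions[env.molecule_ids == rid]
            oh1 = np.linalg.norm(pos[1] - pos[0])
            oh2 = np.linalg.norm(pos[2] - pos[0])
            assert oh1 == pytest.approx(0.095, abs=1e-9)
            assert oh2 == pytest.approx(np.hypot(0.024, 0.092), abs=1e-9)

    def test_missing_charges_raise(self):
        frame = water_frame(1)
        frame.charges = None
        with pytest.raises(TopologyError):
            build_environment(frame, frame.select(resids=1))

    def test_close_contact_warns_but_keeps_point(self):
        frame = water_frame(1)
        frame.positions[2] = frame.positions[0] + [0.01, 0, 0]  # water O on QM atom
        with pytest.warns(UserWarning, match="closer than"):
            env = build_environment(frame, frame.select(resids=1))
        assert env.n_points == 3

    def test_synthetic_bilayer_environment_is_neutral(self, probe_trajectory):
        frame = probe_trajectory.frames[0]
        env = build_environment(frame, frame.select(resids=1))
        assert env.n_points == 18  # 9 lipids per leaflet, one pseudo-atom each
        assert env.total_charge == pytest.approx(0.0, abs=1e-9)


class TestPointChargeFile:
    def test_roundtrip_is_exact_at_written_precision(self, tmp_path):
        frame = water_frame(3)
        env = build_environment(frame, frame.select(resids=1))
        p = write_point_charges(env, tmp_path / "pc.txt")
        back = read_point_charges(p)
        assert np.array_equal(back.charges, np.round(env.charges, 10))
        assert np.allclose(back.positions, env.positions, atol=5e-11)

    def test_nine_lines_and_zero_column_sum(self, tmp_path):
        frame = water_frame(3)
        env = build_environment(frame, frame.select(resids=1))
        p = write_point_charges(env, tmp_path / "pc.txt")
        lines = p.read_text().splitlines()
        assert len(lines) == 9
        assert sum(float(l.split()[3]) for l in lines) == pytest.approx(0.0, abs=1e-9)

    def test_bohr_units_roundtrip(self, tmp_path):
        frame = water_frame(2)
        env = build_environment(frame, frame.select(resids=1))
        p = write_point_charges(env, tmp_path / "pc.txt", units="bohr")
        back = read_point_charges(p, units="bohr")
        assert np.allclose(back.positions, env.positions, atol=1e-10)

    def test_empty_environment_warns_and_writes_empty_file(self, tmp_path):
        frame = water_frame(0)
        env = build_environment(frame, frame.select(resids=1))
        with pytest.warns(UserWarning, match="empty"):
            p = write_point_charges(env, tmp_path / "pc.txt")
        assert p.read_text() == ""
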