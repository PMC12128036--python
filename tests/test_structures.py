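"""GRO I/O, periodic geometry and atomistic-to-CG mapping."""

import numpy as np
import pytest

from micellekit.errors import (
    GroParseError,
    MappingError,
    UnsupportedFormatError,
)
from micellekit.structures import (
    BeadSpec,
    Box,
    Frame,
    MoleculeTopology,
    Trajectory,
    map_atomistic_to_cg,
    minimum_image_displacement,
    read_gro,
    read_trajectory_json,
    write_gro,
    write_trajectory_json,
)


def two_bead_frame():
    return Frame(
        time=0.0,
        box=Box(30.0, 30.0, 30.0),
        coordinates=np.array([[10.0, 10.0, 10.0], [12.5, 10.0, 10.0]]),
        mol_index=np.array([0, 0]),
        species=np.array(["AOT"], dtype=object),
        bead_names=np.array(["H1", "T1"], dtype=object),
    )


class TestGro:
    def test_nm_to_angstrom_conversion(self, tmp_path):
        p = tmp_path / "two.gro"
        p.write_text(
            "two beads\n    2\n"
            "    1AOT     H1    1   1.000   1.000   1.000\n"
            "    1AOT     T1    2   1.250   1.000   1.000\n"
            "   3.00000   3.00000   3.00000\n"
        )
        frame = read_gro(p)
        np.testing.assert_allclose(frame.coordinates[0], [10.0, 10.0, 10.0])
        np.testing.assert_allclose(frame.box.lengths, [30.0, 30.0, 30.0])

    def test_round_trip_within_format_precision(self, tmp_path):
        frame = two_bead_frame()
        frame.coordinates += 0.123456  # force non-representable digits
        p = tmp_path / "rt.gro"
        write_gro(frame, p)
        back = read_gro(p)
        # GRO stores nm with 3 decimals -> 0.01 A precision
        assert np.abs(back.coordinates - frame.coordinates).max() <= 0.005 + 1e-9
        np.testing.assert_allclose(back.box.lengths, frame.box.lengths)

    def test_box_line_formatting(self, tmp_path):
        frame = two_bead_frame()
        frame.box = Box(380.0, 380.0, 380.0)
        p = tmp_path / "box.gro"
        write_gro(frame, p)
        assert "38.00000  38.00000  38.00000" in p.read_text().splitlines()[-1]

    def test_truncated_atom_block_is_an_error(self, tmp_path):
        p = tmp_path / "trunc.gro"
        p.write_text(
            "truncated\n    3\n"
            "    1AOT     H1    1   1.000   1.000   1.000\n"
            "   3.00000   3.00000   3.00000\n"
        )
        with pytest.raises(GroParseError, match="truncated"):
            read_gro(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text(
            "bad\n    1\n"
            "    1AOT     H1    1   x.000   1.000   1.000\n"
            "   3.00000   3.00000   3.00000\n"
        )
        with pytest.raises(GroParseError, match="line 3"):
            read_gro(p)

    def test_triclinic_box_rejected(self, tmp_path):
        p = tmp_path / "tri.gro"
        p.write_text(
            "triclinic\n    1\n"
            "    1AOT     H1    1   1.000   1.000   1.000\n"
            "   3.0 3.0 3.0 0.0 0.0 1.5 0.0 0.0 0.0\n"
        )
        with pytest.raises(UnsupportedFormatError):
            read_gro(p)

    def test_long_bead_names_truncated_with_warning(self, tmp_path):
        frame = two_bead_frame()
        frame.bead_names = np.array(["HEADBEAD1", "T1"], dtype=object)
        with pytest.warns(UserWarning, match="truncated"):
            write_gro(frame, tmp_path / "long.gro")

    def test_against_mdanalysis_reader(self, tmp_path):
        """Independent oracle: MDAnalysis parses our output identically."""
        mda = pytest.importorskip("MDAnalysis")
        frame = two_bead_frame()
        p = tmp_path / "oracle.gro"
        write_gro(frame, p)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(p))
        np.testing.assert_allclose(u.atoms.positions, frame.coordinates, atol=5e-3)
        np.testing.assert_allclose(u.dimensions[:3], frame.box.lengths, atol=1e-4)


class TestMinimumImage:
    def test_wrap_case(self):
        box = Box(10.0, 10.0, 10.0)
        d = minimum_image_displacement([1.0, 1.0, 1.0], [9.0, 9.0, 9.0], box)
        np.testing.assert_allclose(d, [-2.0, -2.0, -2.0])

    def test_identity(self):
        box = Box(10.0, 10.0, 10.0)
        np.testing.assert_allclose(
            minimum_image_displacement([3.0, 4.0, 5.0], [3.0, 4.0, 5.0], box), 0.0
        )

    def test_matches_image_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        box = Box(8.0, 11.0, 15.0)
        L = box.lengths
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        ) * L
        p = rng.uniform(-20, 20, size=(1000, 3))
        q = rng.uniform(-20, 20, size=(1000, 3))
        d = minimum_image_displacement(p, q, box)
        for i in range(1000):
            cands = (q[i] - p[i]) % L + shifts  # all 27 images of the wrapped diff
            best = np.linalg.norm(cands, axis=1).min()
            assert np.isclose(np.linalg.norm(d[i]), best, atol=1e-9)

    def test_norm_bound(self):
        rng = np.random.default_rng(1)
        box = Box(9.0, 13.0, 20.0)
        d = minimum_image_displacement(
            rng.uniform(-50, 50, (500, 3)), rng.uniform(-50, 50, (500, 3)), box
        )
        assert (np.abs(d) <= box.lengths / 2 + 1e-12).all()
        assert (np.linalg.norm(d, axis=1) <= np.sqrt(3) / 2 * 20.0 + 1e-9).all()


class TestCgMapping:
    def test_identity_and_midpoint(self):
        atoms = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [5.0, 1.0, 2.0]])
        np.testing.assert_allclose(
            map_atomistic_to_cg(atoms, [[2]]), [[5.0, 1.0, 2.0]]
        )
        np.testing.assert_allclose(
            map_atomistic_to_cg(atoms, [[0, 1]]), [[1.0, 0.0, 0.0]]
        )

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        atoms = rng.normal(size=(50, 3))
        sizes = rng.integers(1, 8, size=9)
        idx = np.arange(50)
        rng.shuffle(idx)
        groups, start = [], 0
        for s in sizes:
            groups.append(idx[start:start + s].tolist())
            start += s
        cg = map_atomistic_to_cg(atoms, groups)
        for b, grp in enumerate(groups):
            expected = sum(atoms[i] for i in grp) / len(grp)
            np.testing.assert_allclose(cg[b], expected, rtol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        atoms = rng.normal(size=(10, 3))
        grp = [0, 3, 7, 9]
        a = map_atomistic_to_cg(atoms, [grp])
        b = map_atomistic_to_cg(atoms, [grp[::-1]])
        np.testing.assert_allclose(a, b)

    def test_errors(self):
        atoms = np.zeros((4, 3))
        with pytest.raises(MappingError):
            map_atomistic_to_cg(atoms, [[]])
        with pytest.raises(IndexError):
            map_atomistic_to_cg(atoms, [[5]])


class TestDataModel:
    def test_bead_defaults_from_size_table(self):
        b = BeadSpec("X", "R", "tail")
        assert (b.mass, b.sigma) == (72.0, 4.70)
        assert BeadSpec("Y", "T", "tail").sigma == 3.40

    def test_surfactant_topology_needs_head_and_tail(self):
        from micellekit.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            MoleculeTopology("BAD", (BeadSpec("H", "R", "head"),))

    def test_trajectory_times_strictly_increasing(self, make_tail_frame):
        f0 = make_tail_frame([[1.0, 1.0, 1.0]], time=0.0)
        f1 = make_tail_frame([[1.0, 1.0, 1.0]], time=0.0)
        with pytest.raises(ValueError):
            Trajectory([f0, f1])

    def test_trajectory_json_round_trip(self, tmp_path, make_tail_frame):
        f0 = make_tail_frame([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], time=0.0)
        f1 = make_tail_frame([[1.5, 2.0, 3.0], [4.0, 5.5, 6.0]], time=2.0)
        traj = Trajectory([f0, f1])
        p = tmp_path / "traj.json"
        write_trajectory_json(traj, p)
        back = read_trajectory_json(p)
        assert len(back) == 2
        np.testing.assert_allclose(back.frames[1].coordinates, f1.coordinates)
        assert back.frames[0].topologies["SURF"].tail_indices.tolist() == [1]
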