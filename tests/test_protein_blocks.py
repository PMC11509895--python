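"""Dihedral computation, RMSDA, PB assignment and frequency profiles."""

import hashlib
import math
from importlib import resources

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import pbflex as pf

TABLE_SHA256 = "d0390518206ffe1399fa93716a6966eca5ccd3ecbe036b276266809fc40bcf8d"

angles_8 = st.lists(
    st.floats(min_value=-180.0, max_value=180.0, exclude_min=True),
    min_size=8, max_size=8,
)


def oracle_assign(window, table):
    """Exhaustive 16-way nearest-prototype search, coded independently."""
    best_label, best_dist = None, None
    for label in table.labels:
        total = 0.0
        for w, p in zip(window, table[label]):
            d = (w - p) % 360.0
            if d > 180.0:
                d -= 360.0
            total += d * d
        if best_dist is None or total < best_dist:
            best_label, best_dist = label, total
    return best_label


class TestTorsionAngle:
    def test_trans_planar_is_180(self):
        assert pf.torsion_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) \
            == pytest.approx(180.0)

    def test_cis_planar_is_0(self):
        assert pf.torsion_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_mirror_image_flips_sign(self):
        quad = [(0.1, 0.2, 0.3), (1.3, 0.1, 0.5), (1.8, 1.4, 0.2),
                (2.9, 1.7, 1.1)]
        mirrored = [(x, y, -z) for x, y, z in quad]
        assert pf.torsion_angle(*mirrored) == pytest.approx(
            -pf.torsion_angle(*quad)
        )

    def test_collinear_triple_is_undefined(self):
        val = pf.torsion_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))
        assert math.isnan(val)

    def test_agrees_with_biopython(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            expected = math.degrees(
                calc_dihedral(*(Vector(*p) for p in pts))
            )
            assert pf.torsion_angle(*pts) == pytest.approx(expected, abs=1e-9)


class TestExtractPhiPsi:
    def test_ideal_helix_recovers_build_targets(self, ideal_helix):
        d = pf.extract_phi_psi(ideal_helix)
        assert np.allclose(d.phi[0, 1:], -57.0, atol=0.5)
        assert np.allclose(d.psi[0, :-1], -47.0, atol=0.5)
        assert math.isnan(d.phi[0, 0]) and math.isnan(d.psi[0, -1])

    def test_two_residue_chain_boundary(self):
        # phi needs residue i-1, psi needs residue i+1: on a 2-residue
        # chain only phi(2) and psi(1) are defined
        helix = pf.build_ideal_conformation("helix", 5)
        two = pf.ConformationalEnsemble(
            system_label="two",
            residues=helix.residues[:2],
            atom_names=[list(a) for a in helix.atom_names[:2]],
            coords=helix.coords[:, : sum(map(len, helix.atom_names[:2]))],
        )
        d = pf.extract_phi_psi(two)
        assert math.isnan(d.phi[0, 0]) and not math.isnan(d.phi[0, 1])
        assert not math.isnan(d.psi[0, 0]) and math.isnan(d.psi[0, 1])

    def test_rigid_motion_leaves_dihedrals_unchanged(self, cys_ensemble):
        d0 = pf.extract_phi_psi(cys_ensemble)
        rot = Rotation.from_euler("zyx", [33, -70, 12], degrees=True).as_matrix()
        moved = cys_ensemble.copy()
        moved.coords = cys_ensemble.coords @ rot.T + np.array([10.0, -4.0, 2.5])
        d1 = pf.extract_phi_psi(moved)
        assert np.allclose(d0.phi, d1.phi, atol=1e-8, equal_nan=True)
        assert np.allclose(d0.psi, d1.psi, atol=1e-8, equal_nan=True)

    def test_chain_break_undefines_spanning_dihedrals(self, ideal_helix):
        broken = ideal_helix.copy()
        # translate residues 6.. away so the CA(5)-CA(6) distance exceeds 4.5 A
        offset = sum(len(a) for a in broken.atom_names[:6])
        broken.coords[:, offset:, :] += 30.0
        d = pf.extract_phi_psi(broken)
        assert math.isnan(d.psi[0, 5])  # psi(i) spans the break
        assert math.isnan(d.phi[0, 6])  # phi(i+1) spans the break
        assert not math.isnan(d.phi[0, 5])


class TestRmsda:
    def test_identity_is_zero(self, pb_table):
        proto = pb_table["h"]
        assert pf.rmsda(proto, proto) == 0.0

    def test_full_turn_shift_is_zero(self, pb_table):
        proto = pb_table["h"]
        shifted = np.where(proto + 360.0 <= 180.0, proto + 360.0, proto - 360.0)
        assert pf.rmsda(shifted, proto) == pytest.approx(0.0, abs=1e-18)

    def test_single_ten_degree_difference_scores_100(self, pb_table):
        proto = pb_table["m"].copy()
        window = proto.copy()
        window[3] += 10.0
        assert pf.rmsda(window, proto) == pytest.approx(100.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(w=angles_8, p=angles_8)
    def test_symmetric_and_nonnegative(self, w, p):
        d1 = pf.rmsda(w, p)
        d2 = pf.rmsda(p, w)
        assert d1 >= 0.0
        assert d1 == pytest.approx(d2, rel=1e-12, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(w=angles_8, p=angles_8, shift=st.integers(-2, 2))
    def test_invariant_to_360_shifts(self, w, p, shift):
        shifted = [wi + 360.0 * shift for wi in w]
        assert pf.rmsda(shifted, p) == pytest.approx(
            pf.rmsda(w, p), rel=1e-9, abs=1e-6
        )


class TestAssignPb:
    @pytest.mark.parametrize("label", list(pf.PB_LABELS))
    def test_prototype_maps_to_itself(self, pb_table, label):
        assert pf.assign_pb(pb_table[label], pb_table) == label

    def test_undefined_angle_gives_z(self, pb_table):
        window = pb_table["m"].copy()
        window[2] = np.nan
        assert pf.assign_pb(window, pb_table) == pf.UNASSIGNED

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(w=angles_8)
    def test_matches_exhaustive_oracle(self, pb_table, w):
        assert pf.assign_pb(w, pb_table) == oracle_assign(w, pb_table)


class TestAssignEnsemble:
    def test_ideal_helix_interior_is_m(self, ideal_helix, pb_table):
        pbs = pf.assign_ensemble(pf.extract_phi_psi(ideal_helix), pb_table)
        s = pbs.frame_strings()[0]
        assert s == "ZZ" + "m" * (len(s) - 4) + "ZZ"

    def test_ideal_strand_interior_is_d(self, ideal_strand, pb_table):
        s = pf.assign_ensemble(
            pf.extract_phi_psi(ideal_strand), pb_table
        ).frame_strings()[0]
        assert s == "ZZ" + "d" * (len(s) - 4) + "ZZ"

    def test_all_undefined_frame_is_all_z(self, pb_table):
        F, R = 3, 8
        nanarr = np.full((F, R), np.nan)
        series = pf.DihedralSeries(nanarr, nanarr.copy(), list(range(1, R + 1)))
        pbs = pf.assign_ensemble(series, pb_table)
        assert np.all(pbs.labels == pf.UNASSIGNED)

    def test_identical_frames_give_identical_strings(self, ideal_helix, pb_table):
        rep = ideal_helix.copy()
        rep.coords = np.repeat(rep.coords, 5, axis=0)
        strings = pf.assign_ensemble(
            pf.extract_phi_psi(rep), pb_table
        ).frame_strings()
        assert len(set(strings)) == 1

    def test_rigid_motion_invariance(self, pb_table):
        ref = pf.build_ideal_conformation("helix", 15)
        ens = pf.perturb_coordinates(ref, np.full(15, 0.1), 10, seed=2,
                                     rigid_motion=False)
        moved = ens.copy()
        rot = Rotation.from_euler("xyz", [10, 80, -45], degrees=True).as_matrix()
        moved.coords = ens.coords @ rot.T + np.array([-3.0, 7.0, 1.0])
        a = pf.assign_ensemble(pf.extract_phi_psi(ens), pb_table)
        b = pf.assign_ensemble(pf.extract_phi_psi(moved), pb_table)
        assert np.array_equal(a.labels, b.labels)

    def test_short_chain_is_all_z(self, pb_table):
        arr = np.zeros((2, 4))
        series = pf.DihedralSeries(arr, arr.copy(), [1, 2, 3, 4])
        assert np.all(
            pf.assign_ensemble(series, pb_table).labels == pf.UNASSIGNED
        )


class TestFrequencyProfile:
    def _pbs(self, column):
        """Single-position-of-interest sequence set from a list of labels."""
        F = len(column)
        labels = np.full((F, 5), "Z", dtype="<U1")
        labels[:, 2] = column
        return pf.PBSequenceSet(labels, [1, 2, 3, 4, 5])

    def test_counting(self):
        prof = pf.pb_frequency_profile(self._pbs(["m", "m", "d", "m"]))
        f = prof.frequencies[2]
        assert f[pf.PB_LABELS.index("m")] == pytest.approx(0.75)
        assert f[pf.PB_LABELS.index("d")] == pytest.approx(0.25)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_z_position_flagged_unobserved(self):
        prof = pf.pb_frequency_profile(self._pbs(["m", "m"]))
        assert prof.unobserved[0]
        assert np.all(np.isnan(prof.frequencies[0]))
        assert not prof.unobserved[2]

    def test_pooling_equal_frame_counts(self):
        p1 = pf.pb_frequency_profile(self._pbs(["m"] * 10))
        p2 = pf.pb_frequency_profile(self._pbs(["d"] * 10))
        pooled = pf.PBFrequencyProfile.pool([p1, p2])
        f = pooled.frequencies[2]
        assert f[pf.PB_LABELS.index("m")] == pytest.approx(0.5)
        assert f[pf.PB_LABELS.index("d")] == pytest.approx(0.5)

    def test_rows_sum_to_one_at_observed_positions(self, pb_table):
        cfg = pf.SyntheticEnsembleConfig(
            n_residues=10, n_frames=200, seed=1,
            segments=[pf.Segment(0, 9, {"m": 0.4, "d": 0.3, "f": 0.3})],
        )
        pbs = pf.assign_ensemble(
            pf.sample_dihedral_ensemble(cfg, pb_table), pb_table
        )
        prof = pf.pb_frequency_profile(pbs)
        sums = prof.frequencies[~prof.unobserved].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_fasta_export(self, tmp_path, ideal_helix, pb_table):
        pbs = pf.assign_ensemble(pf.extract_phi_psi(ideal_helix), pb_table)
        path = tmp_path / "pb.fasta"
        pbs.to_fasta(path, name="helix")
        lines = path.read_text().splitlines()
        assert lines[0] == ">helix_0"
        assert set(lines[1]) <= set(pf.PB_LABELS) | {"Z"}


class TestReferenceTable:
    def test_packaged_table_checksum(self):
        data = resources.files("pbflex.data").joinpath(
            "pb_reference_angles.csv"
        ).read_bytes()
        assert hashlib.sha256(data).hexdigest() == TABLE_SHA256

    def test_labels_and_shape(self, pb_table):
        assert pb_table.labels == tuple("abcdefghijklmnop")
        assert pb_table.angles.shape == (16, 8)
        assert np.all(np.abs(pb_table.angles) <= 180.0)

    def test_helix_and_strand_central_angles(self, pb_table):
        # m is the alpha-helix prototype, d the central beta-strand
        phi_m, psi_m = pb_table.central_phi_psi[pf.PB_LABELS.index("m")]
        assert -90 < phi_m < -40 and -60 < psi_m < -20
        phi_d, psi_d = pb_table.central_phi_psi[pf.PB_LABELS.index("d")]
        assert -150 < phi_d < -90 and 100 < psi_d < 180
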