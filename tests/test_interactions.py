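"""Geometric hydrogen-bond rule, frequency statistics, salt bridges,
radius of gyration, Ramachandran histograms and capping motifs."""

import numpy as np
import pytest

import swishmc as sw
from swishmc.geometry import ATOM_ORDER, Conformation, GeometryError
from swishmc.interactions import (
    MOTIFS,
    dihedral_histogram,
    geometric_hbonds,
    hbond_frequency_matrix,
    match_capping_motif,
    pair_hbond_frequency,
    radius_of_gyration,
    salt_bridges,
    scan_capping_motifs,
)
from swishmc.model import build_conformation


def synthetic_frame(n_residues=3):
    """A frame with atoms spread far apart, to be positioned explicitly."""
    coords = np.full((n_residues, 6, 3), np.nan)
    for i in range(n_residues):
        for a in range(6):
            coords[i, a] = [1000.0 * i + 100.0 * a, 0.0, 0.0]
    return coords


def place_donor_acceptor(distance, angle_deg, acceptor_slot=(2, "O")):
    """Donor N1-H1 and one acceptor heavy atom at a prescribed geometry.

    The donor N sits 1.0 A from H; the acceptor heavy atom is placed so
    that the N..acceptor distance is ``distance`` and the N-H-acceptor
    angle at H is ``angle_deg``.
    """
    coords = synthetic_frame()
    h = np.zeros(3)
    n = np.array([1.0, 0.0, 0.0])
    theta = np.radians(angle_deg)
    # solve |H-A| from the law of cosines given |N-A| and the angle at H
    b = -2 * 1.0 * np.cos(theta)
    c = 1.0 - distance**2
    ha = (-b + np.sqrt(b * b - 4 * c)) / 2
    acceptor = ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    coords[0, ATOM_ORDER.index("N")] = n
    coords[0, ATOM_ORDER.index("H")] = h
    res, name = acceptor_slot
    coords[res - 1, ATOM_ORDER.index(name)] = acceptor
    return Conformation(coords)


class TestGeometricRule:
    @pytest.mark.parametrize("distance, angle, bonded", [
        (3.4, 150.0, True),     # inside both cutoffs
        (3.6, 170.0, False),    # fails the distance rule
        (3.5, 120.0, False),    # angle boundary is exclusive
        (3.5, 120.1, True),     # distance boundary is inclusive
        (3.49, 179.0, True),
        (3.51, 179.0, False),
    ])
    def test_boundary_semantics(self, distance, angle, bonded):
        frame = place_donor_acceptor(distance, angle)
        bonds = geometric_hbonds(frame, [(1, "N")], [(2, "O")])
        assert bool(bonds) == bonded
        if bonded:
            assert bonds[0].heavy_distance == pytest.approx(distance, abs=1e-9)
            assert bonds[0].angle == pytest.approx(angle, abs=1e-6)

    def test_donor_without_hydrogen_names_atom(self, alpha_conf):
        with pytest.raises(GeometryError, match="residue 1"):
            geometric_hbonds(alpha_conf, [(1, "N")], [(5, "O")])

    def test_acetylated_lysine_cannot_donate(self):
        seq = sw.parse_modified_sequence(sw.HTT_N19, ["acLys6"])
        conf = sw.make_ideal_structure(seq, "alpha")
        with pytest.raises(GeometryError, match="residue 6"):
            geometric_hbonds(conf, [(6, "SC")], [(2, "O")], seq=seq)

    def test_self_pairs_excluded(self):
        frame = place_donor_acceptor(3.0, 150.0, acceptor_slot=(1, "N"))
        assert geometric_hbonds(frame, [(1, "N")], [(1, "N")]) == []

    def test_rigid_invariance_and_determinism(self, wt_seq, alpha_conf):
        donors = [(i, "N") for i in range(2, 20)]
        acceptors = [(i, "O") for i in range(1, 20)]
        ref = geometric_hbonds(alpha_conf, donors, acceptors)
        from conftest import random_rigid_transform
        rot, trans = random_rigid_transform(np.random.default_rng(3))
        moved = Conformation(alpha_conf.coords @ rot.T + trans)
        got = geometric_hbonds(moved, donors, acceptors)
        assert [(b.donor, b.acceptor) for b in got] == \
               [(b.donor, b.acceptor) for b in ref]


class TestFrequencyMatrix:
    def test_static_helix_matrix(self, wt_seq, alpha_conf):
        m = hbond_frequency_matrix([alpha_conf] * 3)
        L = len(wt_seq)
        for i in range(2, L - 4):
            assert m.cell(i, 4) == 1.0
        assert np.nansum(m.values[0]) == 0.0  # k = 1 never bonds
        assert np.nansum(m.values[1]) == 0.0  # k = 2 never bonds
        assert np.isnan(m.cell(L - 1, 4))     # masked beyond the chain

    def test_half_frames_give_half_frequency(self, wt_seq, alpha_conf,
                                             extended_conf):
        m = hbond_frequency_matrix([alpha_conf, extended_conf])
        full = hbond_frequency_matrix([alpha_conf])
        for i in range(1, len(wt_seq) - 4):
            if full.cell(i, 4) == 1.0:
                assert m.cell(i, 4) == 0.5

    def test_empty_bond_set_gives_zero_matrix(self, extended_conf):
        m = hbond_frequency_matrix([extended_conf])
        assert np.nansum(m.values) == 0.0

    def test_cells_equal_mean_of_pair_frequencies(self, wt_seq, alpha_conf,
                                                  extended_conf):
        traj = [alpha_conf, extended_conf, alpha_conf]
        m = hbond_frequency_matrix(traj)
        for i in (3, 6, 9):
            f = pair_hbond_frequency(traj, [(i + 4, "N")], [(i, "O")])
            assert m.cell(i, 4) == pytest.approx(f)


class TestPairFrequency:
    def test_quarter_frequency(self, alpha_conf, extended_conf):
        traj = [alpha_conf, extended_conf, extended_conf, extended_conf]
        f = pair_hbond_frequency(traj, [(6, "N")], [(2, "O")])
        assert f == 0.25

    def test_same_group_on_same_residue_is_zero(self, alpha_conf):
        assert pair_hbond_frequency([alpha_conf], [(5, "SC")], [(5, "SC")]) == 0.0

    def test_union_semantics_over_multi_atom_group(self):
        # two acceptors, each bonding in a disjoint half of the frames
        f1 = place_donor_acceptor(3.2, 150.0, acceptor_slot=(2, "O"))
        f2 = place_donor_acceptor(3.2, 150.0, acceptor_slot=(3, "O"))
        group = [(2, "O"), (3, "O")]
        assert pair_hbond_frequency([f1], [(1, "N")], [(2, "O")]) == 1.0
        assert pair_hbond_frequency([f2], [(1, "N")], [(2, "O")]) == 0.0
        assert pair_hbond_frequency([f1, f2], [(1, "N")], group) == 1.0


class TestSaltBridges:
    def test_contact_pair_is_a_bridge(self):
        seq = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3"])
        conf = sw.make_ideal_structure(seq, "alpha")
        coords = conf.coords.copy()
        sc = ATOM_ORDER.index("SC")
        coords[5, sc] = coords[2, sc] + [3.5, 0.0, 0.0]
        pairs = {p for p, _ in salt_bridges(Conformation(coords), seq)}
        assert ("T3:SC", "K6:SC") in pairs

    def test_acetylation_removes_the_bridge(self):
        seq = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3", "acLys6"])
        conf = sw.make_ideal_structure(seq, "alpha")
        coords = conf.coords.copy()
        sc = ATOM_ORDER.index("SC")
        coords[5, sc] = coords[2, sc] + [3.5, 0.0, 0.0]
        pairs = {p for p, _ in salt_bridges(Conformation(coords), seq)}
        assert not any("K6" in a or "K6" in b for a, b in pairs)

    def test_like_charges_never_bridge(self):
        seq = sw.parse_modified_sequence("MEDEM", cterm_charged=False,
                                        nterm_charged=False)
        conf = sw.make_ideal_structure(seq, "alpha")
        coords = conf.coords.copy()
        sc = ATOM_ORDER.index("SC")
        coords[3, sc] = coords[1, sc] + [3.0, 0.0, 0.0]
        assert salt_bridges(Conformation(coords), seq) == []


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_equal_masses(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0)

    def test_square_side_a(self):
        a = 3.7
        pts = np.array([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]], float)
        assert radius_of_gyration(pts) == pytest.approx(a / np.sqrt(2))

    def test_mass_weighting_changes_the_result(self, wt_seq, alpha_conf):
        rw = radius_of_gyration(alpha_conf, wt_seq, mass_weighting=True)
        ru = radius_of_gyration(alpha_conf, wt_seq, mass_weighting=False)
        assert rw > 0 and ru > 0 and rw != pytest.approx(ru, abs=1e-6)

    def test_explicit_masses(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        # all mass on one point -> zero spread
        assert radius_of_gyration(pts, masses=[1.0, 0.0]) == pytest.approx(0.0)


class TestDihedralHistogram:
    def test_static_trajectory_single_bin(self, wt_seq, alpha_conf):
        counts, _, _ = dihedral_histogram([alpha_conf] * 7, 5, bin_width=10.0)
        assert counts.sum() == 7
        assert (counts > 0).sum() == 1

    def test_single_bin_width(self, alpha_conf):
        counts, _, _ = dihedral_histogram([alpha_conf], 5, bin_width=360.0)
        assert counts.shape == (1, 1) and counts[0, 0] == 1

    def test_terminal_residue_raises(self, alpha_conf):
        # a frame of measured coordinates has no phi for residue 1
        frame = Conformation(alpha_conf.coords)
        with pytest.raises(GeometryError):
            dihedral_histogram([frame], 1, bin_width=10.0)

    def test_uniform_angles_fill_uniformly(self, wt_seq):
        from swishmc.diagnostics import chisquare_vs_expected
        rng = np.random.default_rng(17)
        frames = []
        for _ in range(600):
            dih = rng.uniform(-179.99, 180.0, size=(3, 2))
            frames.append(build_conformation(
                sw.parse_modified_sequence("AAA"), dih))
        counts, _, _ = dihedral_histogram(frames, 2, bin_width=90.0)
        flat = counts.ravel()
        _, p = chisquare_vs_expected(flat, np.full(flat.size, 1 / flat.size))
        assert p > 0.01


class TestCappingMotifs:
    @pytest.mark.parametrize("ncap, motif", [(2, "Ib"), (4, "IIa"), (11, "Ia")])
    def test_reference_peptide_claims(self, wt_seq, ncap, motif):
        m = match_capping_motif(wt_seq, ncap, MOTIFS[motif], motif_id=motif)
        assert m.matched, m.reason

    def test_trivial_pattern_matches_anywhere_inside(self, wt_seq):
        for pos in range(2, len(wt_seq) + 1):
            assert match_capping_motif(wt_seq, pos, "x-x").matched

    def test_out_of_range_window_is_not_matched(self, wt_seq):
        m = match_capping_motif(wt_seq, 1, "h-xpxph")
        assert not m.matched and "range" in m.reason
        m = match_capping_motif(wt_seq, 18, "h-xpxph")
        assert not m.matched and "range" in m.reason

    def test_mismatch_reports_offending_residue(self, wt_seq):
        # Ib at N-cap 3: the 'p' two after the boundary falls on Leu4
        m = match_capping_motif(wt_seq, 3, "h-xpxph")
        assert not m.matched
        assert "L4" in m.reason

    def test_pattern_validation(self, wt_seq):
        with pytest.raises(ValueError):
            match_capping_motif(wt_seq, 2, "hxxp")
        with pytest.raises(ValueError):
            match_capping_motif(wt_seq, 2, "h-z-p")

    def test_scan_contains_exactly_the_three_claims_at_their_positions(self, wt_seq):
        df = scan_capping_motifs(wt_seq)
        hits = {(r.position, r.motif) for r in df.itertuples() if r.matched}
        assert {(2, "Ib"), (4, "IIa"), (11, "Ia")} <= hits
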