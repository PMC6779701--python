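"""Cartesian building from internal coordinates and the lambda-scalable
energy model (linearity, brute-force oracle, invariances)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swishmc as sw
from swishmc.geometry import (
    ATOM_ORDER,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
    Conformation,
    GeometryError,
)
from swishmc.model import (
    EnergyParameters,
    bead_exposures,
    build_conformation,
    energy_decomposition,
    pack_system,
    total_energy,
)
from conftest import random_rigid_transform


def angle(a, b, c):
    v1, v2 = a - b, c - b
    return np.degrees(np.arccos(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))


class TestBuild:
    def test_ideal_internal_geometry(self, wt_seq, alpha_conf):
        c = alpha_conf
        for i in range(1, len(wt_seq) + 1):
            assert np.linalg.norm(c.atom(i, "CA") - c.atom(i, "N")) == pytest.approx(BOND_N_CA, abs=1e-6)
            assert np.linalg.norm(c.atom(i, "C") - c.atom(i, "CA")) == pytest.approx(BOND_CA_C, abs=1e-6)
            assert np.linalg.norm(c.atom(i, "O") - c.atom(i, "C")) == pytest.approx(BOND_C_O, abs=1e-6)
            if i > 1:
                assert np.linalg.norm(c.atom(i, "N") - c.atom(i - 1, "C")) == pytest.approx(BOND_C_N, abs=1e-6)
                assert np.linalg.norm(c.atom(i, "H") - c.atom(i, "N")) == pytest.approx(1.0, abs=1e-6)
        assert angle(c.atom(3, "N"), c.atom(3, "CA"), c.atom(3, "C")) == pytest.approx(111.2, abs=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_dihedral_round_trip(self, wt_seq, seed):
        rng = np.random.default_rng(seed)
        dih = rng.uniform(-179.9, 180.0, size=(len(wt_seq), 2))
        conf = build_conformation(wt_seq, dih)
        measured = Conformation(conf.coords).dihedrals
        # phi_1 is undefined by construction
        assert np.isnan(measured[0, 0])
        measured[0, 0] = dih[0, 0]
        assert np.allclose(measured, dih, atol=1e-8)

    def test_extended_has_no_helical_contacts(self, wt_seq, extended_conf):
        for i in range(1, len(wt_seq) - 4 + 1):
            d = np.linalg.norm(extended_conf.atom(i, "O") - extended_conf.atom(i + 4, "H"))
            assert d > 3.5

    def test_length_mismatch_raises(self, wt_seq):
        with pytest.raises(GeometryError, match="19"):
            build_conformation(wt_seq, [(-57.0, -47.0)] * 18)

    def test_angle_out_of_range_raises(self, wt_seq):
        dih = [(-57.0, -47.0)] * 19
        dih[3] = (181.0, 0.0)
        with pytest.raises(GeometryError, match="-180, 180"):
            build_conformation(wt_seq, dih)


def reference_energy(conf, seq, params):
    """Independent double-loop evaluation of (U0, W) in plain Python."""
    arrays = pack_system(seq, params)
    coords = conf.coords
    dih = conf.dihedrals
    basins = [(params.helix_center, params.helix_width, params.helix_depth),
              (params.extended_center, params.extended_width, params.extended_depth)]

    def wrap(d):
        return (d + 180.0) % 360.0 - 180.0

    u_tors = 0.0
    for i in range(1, len(seq) - 1):
        for (c0, c1), w, d in basins:
            dphi, dpsi = wrap(dih[i, 0] - c0), wrap(dih[i, 1] - c1)
            u_tors -= d * np.exp(-(dphi**2 + dpsi**2) / (2 * w**2))

    beads = [(arrays.bead_res[k], coords[arrays.bead_res[k], arrays.bead_atom[k]],
              arrays.bead_eps[k], arrays.bead_sigma[k], arrays.bead_apolar[k])
             for k in range(len(arrays.bead_res))]
    u_lj = 0.0
    for a in range(len(beads)):
        for b in range(a + 1, len(beads)):
            if abs(beads[a][0] - beads[b][0]) < 2:
                continue
            r = np.linalg.norm(beads[a][1] - beads[b][1])
            eps = np.sqrt(beads[a][2] * beads[b][2])
            sig = 0.5 * (beads[a][3] + beads[b][3])
            u_lj += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)

    u_coul = 0.0
    S = len(arrays.site_q)
    for a in range(S):
        for b in range(a + 1, S):
            if (arrays.site_res[a] == arrays.site_res[b]
                    and arrays.site_atom[a] == arrays.site_atom[b]):
                continue
            pa = coords[arrays.site_res[a], arrays.site_atom[a]]
            pb = coords[arrays.site_res[b], arrays.site_atom[b]]
            r = max(np.linalg.norm(pa - pb), params.coulomb_saturation)
            u_coul += (params.coulomb_k * arrays.site_q[a] * arrays.site_q[b]
                       * np.exp(-r / params.debye_length)
                       / (params.dielectric * r))

    main = beads[:arrays.n_main]
    W = 0.0
    for a, (res_a, xa, _, _, apolar) in enumerate(main):
        if not apolar:
            continue
        n = sum(1 for b, (res_b, xb, _, _, _) in enumerate(main)
                if b != a and res_b != res_a
                and np.linalg.norm(xa - xb) <= params.neighbor_cutoff)
        W += params.dispersion_s * max(0.0, params.n_max - n)
    return u_tors + u_lj + u_coul, W


class TestEnergy:
    def test_linearity_identity_and_2x2_recovery(self, wt_seq, params, alpha_conf):
        dec = energy_decomposition(alpha_conf, wt_seq, params)
        assert total_energy(alpha_conf, wt_seq, params, 1.0) == pytest.approx(dec.U0 + dec.W)
        u1 = total_energy(alpha_conf, wt_seq, params, 0.85)
        u2 = total_energy(alpha_conf, wt_seq, params, 1.10)
        W = (u2 - u1) / 0.25
        U0 = u1 - 0.85 * W
        assert W == pytest.approx(dec.W, rel=1e-9)
        assert U0 == pytest.approx(dec.U0, rel=1e-9)

    def test_lambda_shift_equals_spacing_times_w(self, wt_seq, params, extended_conf):
        dec = energy_decomposition(extended_conf, wt_seq, params)
        du = (total_energy(extended_conf, wt_seq, params, 1.10)
              - total_energy(extended_conf, wt_seq, params, 0.85))
        assert du == pytest.approx(0.25 * dec.W, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle_agreement(self, seed, wt_seq, params):
        rng = np.random.default_rng(seed)
        while True:  # draw until clash-free
            dih = rng.uniform(-179.0, 179.0, size=(len(wt_seq), 2))
            conf = build_conformation(wt_seq, dih)
            dec = energy_decomposition(conf, wt_seq, params)
            if np.isfinite(dec.U0):
                break
        u0_ref, w_ref = reference_energy(conf, wt_seq, params)
        assert dec.U0 == pytest.approx(u0_ref, rel=1e-10)
        assert dec.W == pytest.approx(w_ref, rel=1e-10)

    def test_rigid_body_invariance(self, wt_seq, params, alpha_conf):
        dec = energy_decomposition(alpha_conf, wt_seq, params)
        rng = np.random.default_rng(42)
        for _ in range(3):
            rot, trans = random_rigid_transform(rng)
            moved = Conformation(alpha_conf.coords @ rot.T + trans)
            dec2 = energy_decomposition(moved, wt_seq, params)
            assert dec2.U0 == pytest.approx(dec.U0, abs=1e-8)
            assert dec2.W == pytest.approx(dec.W, abs=1e-8)

    def test_isolated_apolar_bead_exposure(self, params):
        xyz = np.zeros((1, 3))
        expo = bead_exposures(xyz, np.zeros(1, dtype=np.int64),
                              params.neighbor_cutoff, float(params.n_max))
        assert expo[0] == params.n_max
        assert params.dispersion_s * expo[0] == pytest.approx(
            params.dispersion_s * params.n_max)

    def test_overlapping_beads_give_infinite_energy(self, wt_seq, params, alpha_conf):
        coords = alpha_conf.coords.copy()
        coords[0, ATOM_ORDER.index("SC")] = coords[4, ATOM_ORDER.index("SC")]
        dec = energy_decomposition(Conformation(coords), wt_seq, params)
        assert np.isinf(dec.U0)

    def test_lambda_must_be_positive(self, wt_seq, params, alpha_conf):
        with pytest.raises(ValueError):
            total_energy(alpha_conf, wt_seq, params, 0.0)


class TestMechanisticKnob:
    """The phosphate(-2)/Lys6-amine(+1) attraction and its removal by
    acetylation -- the interaction the whole PTM story hinges on."""

    def test_phosphate_lysine_pair_is_attractive_in_helix(self, params):
        seq = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3"])
        conf = sw.make_ideal_structure(seq, "alpha")
        r = max(np.linalg.norm(conf.atom(3, "SC") - conf.atom(6, "SC")),
                params.coulomb_saturation)
        e_pair = (params.coulomb_k * (-2) * (+1) * np.exp(-r / params.debye_length)
                  / (params.dielectric * r))
        assert e_pair < -0.1

    def test_acetylation_removes_the_lysine_charge_site(self, params):
        seq_p = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3"])
        seq_pa = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3", "acLys6"])
        sites_p = pack_system(seq_p, params)
        sites_pa = pack_system(seq_pa, params)
        assert 5 in sites_p.site_res  # Lys6, 0-based
        assert 5 not in sites_pa.site_res

    def test_acetylation_raises_pair_energy_to_zero(self, params):
        seq_p = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3"])
        seq_pa = sw.parse_modified_sequence(sw.HTT_N19, ["pThr3", "acLys6"])
        dih = np.tile((-57.0, -47.0), (19, 1))
        u_p = energy_decomposition(build_conformation(seq_p, dih), seq_p, params).U0
        u_pa = energy_decomposition(build_conformation(seq_pa, dih), seq_pa, params).U0
        # removing the attractive phosphate-amine term raises the energy
        assert u_pa > u_p


class TestParameterFile:
    def test_shipped_defaults_round_trip(self, tmp_path, params):
        import importlib.resources as resources
        with resources.as_file(resources.files("swishmc") / "params"
                               / "default.yaml") as path:
            assert EnergyParameters.from_file(path) == params
        out = tmp_path / "p.yaml"
        custom = EnergyParameters(helix_depth=3.0, dispersion_s=-0.05)
        custom.to_file(out)
        assert EnergyParameters.from_file(out) == custom

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EnergyParameters(helix_width=-1.0)
        with pytest.raises(ValueError):
            EnergyParameters(debye_length=0.0)
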