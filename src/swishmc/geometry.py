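"""Coarse-grained peptide geometry.

Each residue carries five backbone sites (N, H, CA, C, O) and a single
side-chain bead (SC) placed along the canonical C-beta direction.  Only the
backbone dihedrals (phi, psi) are degrees of freedom; bond lengths, bond
angles and the omega torsion (180 deg, trans) are fixed at ideal peptide
values, so a conformation is fully determined by its dihedral list and the
Cartesian build is a deterministic natural-extension (NeRF) chain starting
from a canonical frame on residue 1.

The amide hydrogen of residue i (i >= 2) sits 1.0 A from N_i along the
unit vector C_{i-1} - O_{i-1}; residue 1 carries no amide hydrogen and can
never act as a backbone hydrogen-bond donor.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ATOM_ORDER",
    "Conformation",
    "GeometryError",
    "build_backbone",
    "measure_dihedrals",
    "sidechain_distance",
]

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _numba_njit

    def _njit(fn):
        return _numba_njit(cache=False, fastmath=False)(fn)
except Exception:  # pragma: no cover
    def _njit(fn):
        return fn


class GeometryError(ValueError):
    """Invalid dihedral input or malformed coordinates."""


# atom slot order within each residue's (6, 3) coordinate block
ATOM_ORDER = ("N", "H", "CA", "C", "O", "SC")
IDX_N, IDX_H, IDX_CA, IDX_C, IDX_O, IDX_SC = range(6)

# ideal internal geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.0
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

# distance (A) of the side-chain bead from CA, a rough per-residue
# side-chain centroid distance
_SC_DISTANCE = {
    "G": 1.0, "A": 1.5, "S": 1.9, "C": 2.1, "T": 1.9, "V": 2.0,
    "P": 1.9, "I": 2.3, "L": 2.6, "M": 2.9, "F": 3.4, "W": 3.9,
    "Y": 3.8, "D": 2.5, "E": 3.1, "N": 2.5, "Q": 3.1, "K": 3.5,
    "R": 4.1, "H": 3.1,
}

ATOM_MASSES = {"N": 14.007, "H": 1.008, "CA": 12.011, "C": 12.011, "O": 15.999}

# side-chain masses (Da); SC bead mass of a residue
SIDECHAIN_MASSES = {
    "G": 1.01, "A": 15.03, "S": 31.03, "C": 47.10, "T": 45.04, "V": 43.09,
    "P": 42.08, "I": 57.12, "L": 57.12, "M": 75.15, "F": 91.13, "W": 130.17,
    "Y": 107.13, "D": 59.04, "E": 73.07, "N": 58.06, "Q": 72.09, "K": 72.13,
    "R": 100.14, "H": 81.10,
}
PHOSPHO_MASS = 79.98
ACETYL_MASS = 42.04


def sidechain_distance(code: str) -> float:
    return _SC_DISTANCE[code]


@_njit
def _place_atom(a, b, c, bond, theta, chi):
    """NeRF placement of atom D bonded to c, given angle B-C-D and torsion A-B-C-D."""
    d2 = np.empty(3)
    d2[0] = -bond * np.cos(theta)
    d2[1] = bond * np.sin(theta) * np.cos(chi)
    d2[2] = bond * np.sin(theta) * np.sin(chi)
    bc = c - b
    bc = bc / np.sqrt(bc[0] ** 2 + bc[1] ** 2 + bc[2] ** 2)
    ab = b - a
    n = np.empty(3)
    n[0] = ab[1] * bc[2] - ab[2] * bc[1]
    n[1] = ab[2] * bc[0] - ab[0] * bc[2]
    n[2] = ab[0] * bc[1] - ab[1] * bc[0]
    n = n / np.sqrt(n[0] ** 2 + n[1] ** 2 + n[2] ** 2)
    m = np.empty(3)
    m[0] = n[1] * bc[2] - n[2] * bc[1]
    m[1] = n[2] * bc[0] - n[0] * bc[2]
    m[2] = n[0] * bc[1] - n[1] * bc[0]
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@_njit
def build_backbone(dihedrals, sc_dist):
    """Build (L, 6, 3) coordinates [N, H, CA, C, O, SC] from (L, 2) phi/psi.

    phi of residue 1 is ignored (canonical frame); the H slot of residue 1
    is NaN.  Angles are degrees.
    """
    L = dihedrals.shape[0]
    deg = np.pi / 180.0
    coords = np.full((L, 6, 3), np.nan)
    # canonical frame for residue 1
    coords[0, IDX_N] = np.zeros(3)
    coords[0, IDX_CA, 0] = BOND_N_CA
    coords[0, IDX_CA, 1] = 0.0
    coords[0, IDX_CA, 2] = 0.0
    # place C1 so that angle N-CA-C = ANGLE_N_CA_C, in the xy-plane
    ang = (180.0 - ANGLE_N_CA_C) * deg
    coords[0, IDX_C, 0] = BOND_N_CA + BOND_CA_C * np.cos(ang)
    coords[0, IDX_C, 1] = BOND_CA_C * np.sin(ang)
    coords[0, IDX_C, 2] = 0.0
    for i in range(L):
        if i > 0:
            # N_i from psi_{i-1}
            coords[i, IDX_N] = _place_atom(
                coords[i - 1, IDX_N], coords[i - 1, IDX_CA], coords[i - 1, IDX_C],
                BOND_C_N, ANGLE_CA_C_N * deg, dihedrals[i - 1, 1] * deg)
            # CA_i via omega = 180
            coords[i, IDX_CA] = _place_atom(
                coords[i - 1, IDX_CA], coords[i - 1, IDX_C], coords[i, IDX_N],
                BOND_N_CA, ANGLE_C_N_CA * deg, OMEGA * deg)
            # C_i from phi_i
            coords[i, IDX_C] = _place_atom(
                coords[i - 1, IDX_C], coords[i, IDX_N], coords[i, IDX_CA],
                BOND_CA_C, ANGLE_N_CA_C * deg, dihedrals[i, 0] * deg)
        # O_i opposite the next amide nitrogen: torsion psi_i + 180
        coords[i, IDX_O] = _place_atom(
            coords[i, IDX_N], coords[i, IDX_CA], coords[i, IDX_C],
            BOND_C_O, ANGLE_CA_C_O * deg, (dihedrals[i, 1] + 180.0) * deg)
        # SC bead along the canonical C-beta direction
        b = coords[i, IDX_CA] - coords[i, IDX_N]
        c = coords[i, IDX_C] - coords[i, IDX_CA]
        a = np.empty(3)
        a[0] = b[1] * c[2] - b[2] * c[1]
        a[1] = b[2] * c[0] - b[0] * c[2]
        a[2] = b[0] * c[1] - b[1] * c[0]
        raw = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c
        nrm = np.sqrt(raw[0] ** 2 + raw[1] ** 2 + raw[2] ** 2)
        coords[i, IDX_SC] = coords[i, IDX_CA] + raw * (sc_dist[i] / nrm)
    # amide hydrogens (residue 1 has none)
    for i in range(1, L):
        v = coords[i - 1, IDX_C] - coords[i - 1, IDX_O]
        v = v / np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        coords[i, IDX_H] = coords[i, IDX_N] + BOND_N_H * v
    return coords


@_njit
def _dihedral(p0, p1, p2, p3):
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.empty(3)
    n1[0] = b0[1] * b1[2] - b0[2] * b1[1]
    n1[1] = b0[2] * b1[0] - b0[0] * b1[2]
    n1[2] = b0[0] * b1[1] - b0[1] * b1[0]
    n2 = np.empty(3)
    n2[0] = b1[1] * b2[2] - b1[2] * b2[1]
    n2[1] = b1[2] * b2[0] - b1[0] * b2[2]
    n2[2] = b1[0] * b2[1] - b1[1] * b2[0]
    m = np.empty(3)
    nb1 = np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    m[0] = n1[1] * b1[2] - n1[2] * b1[1]
    m[1] = n1[2] * b1[0] - n1[0] * b1[2]
    m[2] = n1[0] * b1[1] - n1[1] * b1[0]
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = (m[0] * n2[0] + m[1] * n2[1] + m[2] * n2[2]) / nb1
    out = -np.arctan2(y, x) * 180.0 / np.pi
    if out <= -180.0:
        out += 360.0
    return out


@_njit
def measure_dihedrals(coords):
    """(L, 2) phi/psi in degrees from coordinates.

    phi_1 is NaN (no preceding carbonyl); psi_L is recovered from the
    terminal carbonyl oxygen (placed at torsion psi + 180).
    """
    L = coords.shape[0]
    out = np.full((L, 2), np.nan)
    for i in range(L):
        if i > 0:
            out[i, 0] = _dihedral(coords[i - 1, IDX_C], coords[i, IDX_N],
                                  coords[i, IDX_CA], coords[i, IDX_C])
        if i < L - 1:
            out[i, 1] = _dihedral(coords[i, IDX_N], coords[i, IDX_CA],
                                  coords[i, IDX_C], coords[i + 1, IDX_N])
        else:
            psi = _dihedral(coords[i, IDX_N], coords[i, IDX_CA],
                            coords[i, IDX_C], coords[i, IDX_O]) - 180.0
            if psi <= -180.0:
                psi += 360.0
            out[i, 1] = psi
    return out


class Conformation:
    """Per-residue backbone + side-chain bead coordinates of one frame.

    Built either from (phi, psi) internal coordinates (deterministic
    canonical frame) or from externally supplied Cartesian coordinates
    (e.g. a PDB model), in which case dihedrals are measured on demand.
    """

    def __init__(self, coords: np.ndarray, dihedrals: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (6, 3):
            raise GeometryError("coords must have shape (L, 6, 3)")
        self.coords = coords
        self._dihedrals = None if dihedrals is None else np.asarray(dihedrals, float)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def dihedrals(self) -> np.ndarray:
        if self._dihedrals is None:
            self._dihedrals = measure_dihedrals(self.coords)
        return self._dihedrals

    def atom(self, res_index: int, name: str) -> np.ndarray:
        """Coordinates of one atom; ``res_index`` is 1-based."""
        return self.coords[res_index - 1, ATOM_ORDER.index(name)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Rigid-body transformed copy (dihedrals are preserved)."""
        rot = np.asarray(rotation, float)
        out = self.coords @ rot.T + np.asarray(translation, float)
        return Conformation(out, dihedrals=self._dihedrals)


def conformation_from_dihedrals(dihedrals, sc_dist) -> Conformation:
    """Deterministic Cartesian build from (L, 2) phi/psi degrees."""
    dihedrals = np.asarray(dihedrals, dtype=float)
    if dihedrals.ndim != 2 or dihedrals.shape[1] != 2:
        raise GeometryError("dihedrals must have shape (L, 2)")
    if np.any(dihedrals <= -180.0) or np.any(dihedrals > 180.0):
        raise GeometryError("dihedral angles must lie in (-180, 180] degrees")
    sc_dist = np.asarray(sc_dist, dtype=float)
    if sc_dist.shape[0] != dihedrals.shape[0]:
        raise GeometryError("sc_dist length must match dihedral list")
    coords = build_backbone(dihedrals, sc_dist)
    return Conformation(coords, dihedrals=dihedrals)
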