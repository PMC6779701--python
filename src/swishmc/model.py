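"""Coarse-grained, lambda-scalable peptide energy model.

The total energy splits exactly as ``U(lambda) = U0 + lambda * W``:

* ``U0`` (lambda-independent): backbone torsion potential (two Gaussian
  basins, helical at (-57, -47) and extended at (-135, 135)), bead
  Lennard-Jones interactions between CA/C/SC beads of residues at least
  two apart in sequence, and Debye-Hueckel screened Coulomb interactions
  between formally charged groups (charged side-chain beads plus the two
  termini).
* ``W`` (lambda-coupled): a solvent-dispersion analogue of the
  water/apolar-carbon Lennard-Jones attraction.  Each apolar bead (CA and
  C of every residue, SC of hydrophobic-class residues) contributes its
  solvent exposure, estimated as ``max(0, n_max - n_neighbors)`` with a
  6.5 A neighbor cutoff.  The coefficient ``dispersion_s`` is negative --
  water/apolar dispersion is attractive -- so scaling with lambda > 1
  rewards solvent-exposed extended states and lambda < 1 favors
  hydrophobically collapsed ones.

Energies are kcal/mol, distances Angstrom, angles degrees.  Overlapping
beads closer than the hard-core distance make the energy +inf (the move
is simply rejected by any Metropolis sampler); no exception is raised.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .geometry import (
    Conformation,
    GeometryError,
    IDX_C,
    IDX_CA,
    IDX_N,
    IDX_O,
    IDX_SC,
    _njit,
    conformation_from_dihedrals,
    sidechain_distance,
)
from .sequence import ModifiedSequence

__all__ = [
    "KB_KCAL",
    "EnergyDecomposition",
    "EnergyParameters",
    "SystemArrays",
    "bead_exposures",
    "build_conformation",
    "energy_decomposition",
    "pack_system",
    "total_energy",
]

#: Boltzmann constant in kcal/mol/K (k_B * 300 K = 0.5961 kcal/mol)
KB_KCAL = 0.0019872041


@dataclass
class EnergyParameters:
    """Tunable constants of the coarse-grained model (kcal/mol, A, deg, K).

    Defaults are calibrated so that the unmodified Htt(1-19) peptide at
    300 K and lambda = 1 is mostly coil with transient helical stretches.
    """

    # torsion basins: (phi, psi) centers, widths, well depths
    helix_center: tuple = (-57.0, -47.0)
    helix_width: float = 20.0
    helix_depth: float = 2.5
    extended_center: tuple = (-135.0, 135.0)
    extended_width: float = 25.0
    extended_depth: float = 1.6
    # bead Lennard-Jones (per bead class)
    eps_ca: float = 0.20
    sigma_ca: float = 4.4
    eps_c: float = 0.05
    sigma_c: float = 3.6
    eps_sc_h: float = 0.30
    eps_sc_p: float = 0.12
    sigma_sc: float = 4.5
    # backbone N/O excluded volume (keeps hydrogen-bond geometry sane)
    eps_no: float = 0.05
    sigma_no: float = 2.8
    hard_core: float = 1.2
    # electrostatics: Debye-Hueckel, 100 mM ionic strength at 300 K
    dielectric: float = 78.5
    debye_length: float = 9.6
    coulomb_k: float = 332.0636
    # flat-bottom radius: charged groups sit on flexible side-chain arms,
    # so the bead-bead interaction saturates below the arm reach
    coulomb_saturation: float = 6.0
    # solvent-dispersion coupling (negative: water/apolar attraction)
    dispersion_s: float = -0.08
    neighbor_cutoff: float = 6.5
    n_max: int = 10
    # thermodynamic / sampling defaults
    temperature: float = 300.0
    delta_max: float = 25.0

    def __post_init__(self) -> None:
        if self.helix_width <= 0 or self.extended_width <= 0:
            raise ValueError("torsion widths must be positive")
        if min(self.sigma_ca, self.sigma_c, self.sigma_sc) <= 0:
            raise ValueError("LJ sigmas must be positive")
        if self.debye_length <= 0:
            raise ValueError("Debye length must be positive")

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    def to_file(self, path) -> None:
        doc = asdict(self)
        doc["helix_center"] = list(self.helix_center)
        doc["extended_center"] = list(self.extended_center)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "EnergyParameters":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "helix_center" in doc:
            doc["helix_center"] = tuple(doc["helix_center"])
        if "extended_center" in doc:
            doc["extended_center"] = tuple(doc["extended_center"])
        return cls(**doc)


@dataclass(frozen=True)
class EnergyDecomposition:
    """Exact linear split ``U(lambda) = U0 + lambda * W``."""

    U0: float
    W: float

    def at(self, lam: float) -> float:
        return self.U0 + lam * self.W


@dataclass
class SystemArrays:
    """Flat per-sequence arrays consumed by the numba energy kernel.

    The first ``n_main`` beads are the CA/C/SC coarse-grained beads (used
    for both Lennard-Jones and the exposure proxy); beads beyond that are
    the backbone N/O excluded-volume sites (Lennard-Jones only).
    """

    sc_dist: np.ndarray        # (L,)
    torsion_mask: np.ndarray   # (L,) uint8, residues with torsion energy
    bead_res: np.ndarray       # (B,) residue index (0-based) of each bead
    bead_atom: np.ndarray      # (B,) atom slot within the residue block
    bead_eps: np.ndarray       # (B,)
    bead_sigma: np.ndarray     # (B,)
    bead_apolar: np.ndarray    # (B,) uint8
    n_main: int
    site_res: np.ndarray       # (S,) charged-site residue (0-based)
    site_atom: np.ndarray      # (S,) charged-site atom slot
    site_q: np.ndarray         # (S,) formal charges


#: side-chain bead extension for PTMs (the phosphate / acetyl group sits
#: beyond the unmodified side-chain centroid)
PHOSPHO_SC_EXTENSION = 1.2
ACETYL_SC_EXTENSION = 1.0


def _sc_distances(seq: ModifiedSequence) -> np.ndarray:
    out = np.empty(len(seq))
    for i, r in enumerate(seq.residues):
        d = sidechain_distance(r.code)
        if r.phospho:
            d += PHOSPHO_SC_EXTENSION
        if r.acetyl:
            d += ACETYL_SC_EXTENSION
        out[i] = d
    return out


def pack_system(seq: ModifiedSequence, params: EnergyParameters) -> SystemArrays:
    L = len(seq)
    sc_dist = _sc_distances(seq)
    torsion_mask = np.zeros(L, dtype=np.uint8)
    torsion_mask[1:L - 1] = 1

    bead_res, bead_atom, bead_eps, bead_sigma, bead_apolar = [], [], [], [], []
    for r in seq.residues:
        i = r.index - 1
        for atom, eps, sigma in (
                (IDX_CA, params.eps_ca, params.sigma_ca),
                (IDX_C, params.eps_c, params.sigma_c),
                (IDX_SC, params.eps_sc_h if r.in_h else params.eps_sc_p,
                 params.sigma_sc)):
            bead_res.append(i)
            bead_atom.append(atom)
            bead_eps.append(eps)
            bead_sigma.append(sigma)
            name = {IDX_CA: "CA", IDX_C: "C", IDX_SC: "SC"}[atom]
            bead_apolar.append(1 if name in r.apolar_beads else 0)
    n_main = len(bead_res)
    for r in seq.residues:
        i = r.index - 1
        for atom in (IDX_N, IDX_O):
            bead_res.append(i)
            bead_atom.append(atom)
            bead_eps.append(params.eps_no)
            bead_sigma.append(params.sigma_no)
            bead_apolar.append(0)

    site_res, site_atom, site_q = [], [], []
    if seq.nterm_charge != 0:
        site_res.append(0)
        site_atom.append(IDX_N)
        site_q.append(float(seq.nterm_charge))
    for r in seq.residues:
        if r.formal_charge != 0:
            site_res.append(r.index - 1)
            site_atom.append(IDX_SC)
            site_q.append(float(r.formal_charge))
    if seq.cterm_charge != 0:
        site_res.append(L - 1)
        site_atom.append(IDX_C)
        site_q.append(float(seq.cterm_charge))

    return SystemArrays(
        sc_dist=sc_dist,
        torsion_mask=torsion_mask,
        bead_res=np.array(bead_res, dtype=np.int64),
        bead_atom=np.array(bead_atom, dtype=np.int64),
        bead_eps=np.array(bead_eps, dtype=np.float64),
        bead_sigma=np.array(bead_sigma, dtype=np.float64),
        bead_apolar=np.array(bead_apolar, dtype=np.uint8),
        n_main=n_main,
        site_res=np.array(site_res, dtype=np.int64),
        site_atom=np.array(site_atom, dtype=np.int64),
        site_q=np.array(site_q, dtype=np.float64),
    )


@_njit
def _wrap(d):
    while d > 180.0:
        d -= 360.0
    while d <= -180.0:
        d += 360.0
    return d


@_njit
def bead_exposures(bead_xyz, bead_res, cutoff, n_max):
    """Per-bead solvent exposure ``max(0, n_max - n_neighbors)``.

    Neighbors are all other beads within ``cutoff``, excluding beads of
    the same residue; a fully isolated bead has exposure ``n_max``.
    """
    B = bead_xyz.shape[0]
    out = np.empty(B)
    c2 = cutoff * cutoff
    for i in range(B):
        n = 0
        for j in range(B):
            if j == i or bead_res[j] == bead_res[i]:
                continue
            dx = bead_xyz[i, 0] - bead_xyz[j, 0]
            dy = bead_xyz[i, 1] - bead_xyz[j, 1]
            dz = bead_xyz[i, 2] - bead_xyz[j, 2]
            if dx * dx + dy * dy + dz * dz <= c2:
                n += 1
        e = n_max - n
        out[i] = e if e > 0.0 else 0.0
    return out


@_njit
def _energy_kernel(coords, dihedrals, torsion_mask,
                   basin_c, basin_w, basin_d,
                   bead_res, bead_atom, bead_eps, bead_sigma, bead_apolar,
                   n_main, site_res, site_atom, site_q,
                   dielectric, debye, coulomb_k, coulomb_sat,
                   dispersion_s, cutoff, n_max, hard_core):
    L = coords.shape[0]
    # --- torsion ---
    u_tors = 0.0
    for i in range(L):
        if torsion_mask[i] == 0:
            continue
        for b in range(basin_c.shape[0]):
            dphi = _wrap(dihedrals[i, 0] - basin_c[b, 0])
            dpsi = _wrap(dihedrals[i, 1] - basin_c[b, 1])
            w2 = basin_w[b] * basin_w[b]
            u_tors -= basin_d[b] * np.exp(-(dphi * dphi + dpsi * dpsi) / (2.0 * w2))
    # --- bead coordinates ---
    B = bead_res.shape[0]
    bead_xyz = np.empty((B, 3))
    for k in range(B):
        bead_xyz[k, 0] = coords[bead_res[k], bead_atom[k], 0]
        bead_xyz[k, 1] = coords[bead_res[k], bead_atom[k], 1]
        bead_xyz[k, 2] = coords[bead_res[k], bead_atom[k], 2]
    # --- Lennard-Jones over beads >= 2 residues apart ---
    u_lj = 0.0
    hc2 = hard_core * hard_core
    for a in range(B):
        for b in range(a + 1, B):
            sep = bead_res[b] - bead_res[a]
            if sep < 0:
                sep = -sep
            if sep < 2:
                continue
            dx = bead_xyz[a, 0] - bead_xyz[b, 0]
            dy = bead_xyz[a, 1] - bead_xyz[b, 1]
            dz = bead_xyz[a, 2] - bead_xyz[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < hc2:
                return np.inf, 0.0
            eps = np.sqrt(bead_eps[a] * bead_eps[b])
            sig = 0.5 * (bead_sigma[a] + bead_sigma[b])
            s2 = sig * sig / r2
            s6 = s2 * s2 * s2
            u_lj += 4.0 * eps * (s6 * s6 - s6)
    # --- screened Coulomb over charged sites ---
    u_coul = 0.0
    S = site_res.shape[0]
    for a in range(S):
        for b in range(a + 1, S):
            if site_res[a] == site_res[b] and site_atom[a] == site_atom[b]:
                continue
            dx = coords[site_res[a], site_atom[a], 0] - coords[site_res[b], site_atom[b], 0]
            dy = coords[site_res[a], site_atom[a], 1] - coords[site_res[b], site_atom[b], 1]
            dz = coords[site_res[a], site_atom[a], 2] - coords[site_res[b], site_atom[b], 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < hard_core:
                return np.inf, 0.0
            if r < coulomb_sat:
                r = coulomb_sat
            u_coul += coulomb_k * site_q[a] * site_q[b] * np.exp(-r / debye) / (dielectric * r)
    # --- lambda-coupled solvent dispersion (CA/C/SC beads only) ---
    expo = bead_exposures(bead_xyz[:n_main], bead_res[:n_main], cutoff, n_max)
    total = 0.0
    for k in range(n_main):
        if bead_apolar[k] == 1:
            total += expo[k]
    W = dispersion_s * total
    return u_tors + u_lj + u_coul, W


def _basin_arrays(params: EnergyParameters):
    centers = np.array([params.helix_center, params.extended_center], dtype=float)
    widths = np.array([params.helix_width, params.extended_width], dtype=float)
    depths = np.array([params.helix_depth, params.extended_depth], dtype=float)
    return centers, widths, depths


def _decompose_raw(coords, dihedrals, arrays: SystemArrays,
                   params: EnergyParameters):
    centers, widths, depths = _basin_arrays(params)
    return _energy_kernel(
        coords, dihedrals, arrays.torsion_mask,
        centers, widths, depths,
        arrays.bead_res, arrays.bead_atom, arrays.bead_eps,
        arrays.bead_sigma, arrays.bead_apolar, arrays.n_main,
        arrays.site_res, arrays.site_atom, arrays.site_q,
        params.dielectric, params.debye_length, params.coulomb_k,
        params.coulomb_saturation, params.dispersion_s,
        params.neighbor_cutoff, float(params.n_max), params.hard_core)


def build_conformation(seq: ModifiedSequence, dihedrals) -> Conformation:
    """Deterministic Cartesian build of a sequence at given (phi, psi).

    ``dihedrals`` is a length-L list of (phi, psi) pairs in degrees within
    (-180, 180]; phi of residue 1 only fixes the (unused) torsional
    coordinate, the first residue sits in a canonical frame.
    """
    dihedrals = np.asarray(dihedrals, dtype=float)
    if dihedrals.ndim != 2 or dihedrals.shape[0] != len(seq) or dihedrals.shape[1] != 2:
        raise GeometryError(
            f"expected {len(seq)} (phi, psi) pairs, got shape {dihedrals.shape}")
    return conformation_from_dihedrals(dihedrals, _sc_distances(seq))


def energy_decomposition(conf: Conformation, seq: ModifiedSequence,
                         params: EnergyParameters,
                         arrays: SystemArrays | None = None) -> EnergyDecomposition:
    """Split the energy of a conformation into (U0, W)."""
    if len(conf) != len(seq):
        raise GeometryError("conformation and sequence lengths differ")
    if arrays is None:
        arrays = pack_system(seq, params)
    U0, W = _decompose_raw(conf.coords, conf.dihedrals, arrays, params)
    return EnergyDecomposition(U0=float(U0), W=float(W))


def total_energy(conf: Conformation, seq: ModifiedSequence,
                 params: EnergyParameters, lam: float,
                 arrays: SystemArrays | None = None) -> float:
    """``U(lambda) = U0 + lambda * W`` for a scaling coefficient lambda > 0."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    dec = energy_decomposition(conf, seq, params, arrays=arrays)
    return dec.at(lam)
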