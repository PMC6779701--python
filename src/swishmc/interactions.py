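"""Geometric hydrogen bonds, salt bridges, compactness and capping motifs.

The geometric hydrogen-bond rule is the one used for trajectory analysis
of the huntingtin peptides: two electronegative heavy atoms, one carrying
a covalently bound hydrogen, are bonded iff the heavy-heavy distance is
<= 3.5 A (inclusive) AND the heavy-H-heavy angle exceeds 120 degrees
(exclusive).  Backbone amides donate through their placed hydrogen; the
single side-chain bead of donor-capable residues is given an implicit
hydrogen 1.0 A outward along the CA -> SC direction.  Acetylated lysine
side chains are not hydrogen-bond donors; phosphorylated Ser/Thr side
chains donate nothing but accept (phosphate oxygens).

Helix N-capping motifs follow the Aurora-Rose patterns over hydrophobic
(h), polar (p) and indifferent (x) residue classes with '-' marking the
helix boundary: Ia = h-xpxhx, Ib = h-xpxph, IIa = hp-xpxhx.  Characters
before '-' apply to the residues immediately preceding the N-cap; the
first character after '-' is the N-cap residue itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    ACETYL_MASS,
    ATOM_MASSES,
    ATOM_ORDER,
    Conformation,
    GeometryError,
    PHOSPHO_MASS,
    SIDECHAIN_MASSES,
)
from .sequence import ModifiedSequence

__all__ = [
    "CapMotifMatch",
    "HBond",
    "HBondFrequencyMatrix",
    "MOTIFS",
    "dihedral_histogram",
    "geometric_hbonds",
    "hbond_frequency_matrix",
    "match_capping_motif",
    "pair_hbond_frequency",
    "radius_of_gyration",
    "salt_bridges",
    "scan_capping_motifs",
]

DISTANCE_CUTOFF = 3.5   # A, inclusive
ANGLE_CUTOFF = 120.0    # degrees, exclusive
SALT_BRIDGE_CUTOFF = 4.0  # A between charged beads

# side chains able to donate / accept a hydrogen bond (unmodified state)
SC_DONORS = frozenset("KRSTNQWYH")
SC_ACCEPTORS = frozenset("DENQSTHY")

MOTIFS = {"Ia": "h-xpxhx", "Ib": "h-xpxph", "IIa": "hp-xpxhx"}


@dataclass(frozen=True)
class HBond:
    """A qualifying donor -> acceptor contact in one frame."""

    donor: tuple[int, str]      # (residue index, atom role)
    acceptor: tuple[int, str]
    heavy_distance: float
    angle: float


def _sc_can_donate(seq: ModifiedSequence | None, res_index: int) -> bool:
    if seq is None:
        return True
    r = seq.residues[res_index - 1]
    if r.phospho or r.acetyl:
        return False
    return r.code in SC_DONORS


def _donor_atoms(frame: Conformation, seq: ModifiedSequence | None,
                 ref: tuple[int, str]) -> tuple[np.ndarray, np.ndarray]:
    res, role = ref
    if role == "N":
        heavy = frame.atom(res, "N")
        h = frame.atom(res, "H")
        if np.isnan(h).any():
            raise GeometryError(f"donor N of residue {res} has no hydrogen")
        return heavy, h
    if role == "SC":
        if not _sc_can_donate(seq, res):
            raise GeometryError(f"donor SC of residue {res} has no hydrogen")
        heavy = frame.atom(res, "SC")
        ca = frame.atom(res, "CA")
        v = heavy - ca
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise GeometryError(f"degenerate SC bead at residue {res}")
        return heavy, heavy + v / nrm
    raise GeometryError(f"unknown donor role {role!r}")


def _acceptor_atom(frame: Conformation, ref: tuple[int, str]) -> np.ndarray:
    res, role = ref
    if role not in ATOM_ORDER:
        raise GeometryError(f"unknown acceptor role {role!r}")
    xyz = frame.atom(res, role)
    if np.isnan(xyz).any():
        raise GeometryError(f"acceptor {role} of residue {res} is missing")
    return xyz


def _qualifies(heavy_d, h, heavy_a, distance_cutoff, angle_cutoff):
    d = float(np.linalg.norm(heavy_a - heavy_d))
    if d > distance_cutoff:
        return None
    v1 = heavy_d - h
    v2 = heavy_a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if ang <= angle_cutoff:
        return None
    return d, ang


def geometric_hbonds(frame: Conformation, donors, acceptors,
                     seq: ModifiedSequence | None = None,
                     distance_cutoff: float = DISTANCE_CUTOFF,
                     angle_cutoff: float = ANGLE_CUTOFF) -> list[HBond]:
    """All qualifying hydrogen bonds between donor and acceptor atom refs.

    ``donors``/``acceptors`` are lists of ``(residue_index, role)`` with
    donor roles ``"N"`` (backbone amide) or ``"SC"``, acceptor roles any
    atom name (typically ``"O"`` or ``"SC"``).  Self-pairs (identical
    heavy atom) are excluded.  Boundary semantics: distance inclusive,
    angle exclusive.
    """
    out: list[HBond] = []
    for dref in donors:
        heavy_d, h = _donor_atoms(frame, seq, tuple(dref))
        for aref in acceptors:
            aref = tuple(aref)
            if tuple(dref)[0] == aref[0] and tuple(dref)[1] == aref[1]:
                continue  # identical atom
            heavy_a = _acceptor_atom(frame, aref)
            hit = _qualifies(heavy_d, h, heavy_a, distance_cutoff, angle_cutoff)
            if hit is not None:
                out.append(HBond(donor=tuple(dref), acceptor=aref,
                                 heavy_distance=hit[0], angle=hit[1]))
    return out


@dataclass(frozen=True)
class HBondFrequencyMatrix:
    """Backbone CO(i) -> NH(i+k) bond frequencies, offsets k = 1..4.

    ``values[k-1, i-1]`` is the fraction of frames in which the carbonyl
    of residue i bonds the amide of residue i+k; cells with i+k beyond the
    chain are masked NaN.
    """

    values: np.ndarray   # (4, L)
    n_frames: int

    def cell(self, residue: int, offset: int) -> float:
        return float(self.values[offset - 1, residue - 1])

    def to_table(self) -> pd.DataFrame:
        L = self.values.shape[1]
        df = pd.DataFrame(self.values,
                          index=[f"k={k}" for k in range(1, 5)],
                          columns=np.arange(1, L + 1))
        df.index.name = "offset"
        return df


def _frames(trajectory):
    frames = list(trajectory)
    if not frames:
        raise ValueError("empty trajectory")
    return frames


def hbond_frequency_matrix(trajectory) -> HBondFrequencyMatrix:
    """Frequency of backbone CO(i) -> NH(i+k) geometric bonds, k in 1..4."""
    frames = _frames(trajectory)
    L = len(frames[0])
    counts = np.zeros((4, L))
    for frame in frames:
        for i in range(1, L + 1):
            for k in range(1, 5):
                j = i + k
                if j > L or j < 2:
                    continue
                heavy_d, h = _donor_atoms(frame, None, (j, "N"))
                heavy_a = _acceptor_atom(frame, (i, "O"))
                if _qualifies(heavy_d, h, heavy_a,
                              DISTANCE_CUTOFF, ANGLE_CUTOFF) is not None:
                    counts[k - 1, i - 1] += 1
    values = counts / len(frames)
    for i in range(1, L + 1):
        for k in range(1, 5):
            if i + k > L:
                values[k - 1, i - 1] = np.nan
    return HBondFrequencyMatrix(values=values, n_frames=len(frames))


def pair_hbond_frequency(trajectory, donor_group, acceptor_group,
                         seq: ModifiedSequence | None = None) -> float:
    """Fraction of frames in which ANY donor/acceptor atom pair qualifies.

    Groups are lists of atom refs; a frame counts once no matter how many
    pairs bond (any-pair union semantics, the natural pooling for
    multi-oxygen groups like a phosphate).
    """
    frames = _frames(trajectory)
    hits = 0
    for frame in frames:
        if geometric_hbonds(frame, donor_group, acceptor_group, seq=seq):
            hits += 1
    return hits / len(frames)


def _charged_sites(seq: ModifiedSequence):
    sites = []
    if seq.nterm_charge != 0:
        sites.append(("Nterm", 1, "N", seq.nterm_charge))
    for r in seq.residues:
        if r.formal_charge != 0:
            sites.append((f"{r.code}{r.index}:SC", r.index, "SC", r.formal_charge))
    if seq.cterm_charge != 0:
        sites.append(("Cterm", len(seq), "C", seq.cterm_charge))
    return sites


def salt_bridges(frame: Conformation, seq: ModifiedSequence,
                 cutoff: float = SALT_BRIDGE_CUTOFF):
    """Opposite-charge group pairs within ``cutoff`` (default 4.0 A).

    Returns ``[((site_a, site_b), distance), ...]`` where sites are
    labeled charged groups (charged side-chain beads and the termini).
    """
    sites = _charged_sites(seq)
    out = []
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            la, ra, atom_a, qa = sites[a]
            lb, rb, atom_b, qb = sites[b]
            if qa * qb >= 0:
                continue
            d = float(np.linalg.norm(frame.atom(ra, atom_a) - frame.atom(rb, atom_b)))
            if d <= cutoff:
                out.append(((la, lb), d))
    return out


def radius_of_gyration(frame, seq: ModifiedSequence | None = None,
                       mass_weighting: bool = True,
                       masses=None) -> float:
    """Root-mean-square distance of atoms from their (weighted) centroid.

    ``frame`` may be a :class:`Conformation` (atom masses derived from the
    sequence when given) or a raw (N, 3) point array with optional
    explicit ``masses``.  With ``mass_weighting=False`` all points weigh
    equally.
    """
    if isinstance(frame, Conformation):
        pts, m = [], []
        for i in range(1, len(frame) + 1):
            for name in ATOM_ORDER:
                xyz = frame.atom(i, name)
                if np.isnan(xyz).any():
                    continue
                pts.append(xyz)
                if name == "SC":
                    if seq is not None:
                        r = seq.residues[i - 1]
                        mass = SIDECHAIN_MASSES[r.code]
                        if r.phospho:
                            mass += PHOSPHO_MASS
                        if r.acetyl:
                            mass += ACETYL_MASS
                    else:
                        mass = 12.011
                else:
                    mass = ATOM_MASSES[name]
                m.append(mass)
        pts = np.asarray(pts)
        m = np.asarray(m)
    else:
        pts = np.atleast_2d(np.asarray(frame, dtype=float))
        m = np.ones(len(pts)) if masses is None else np.asarray(masses, float)
    if len(pts) == 0:
        raise ValueError("need at least one atom")
    if not mass_weighting:
        m = np.ones(len(pts))
    w = m / m.sum()
    center = (pts * w[:, None]).sum(axis=0)
    sq = ((pts - center) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum()))


def dihedral_histogram(trajectory, residue_index: int, bin_width: float = 10.0):
    """2-D (phi, psi) count grid over [-180, 180)^2 for one residue.

    Returns ``(counts, phi_edges, psi_edges)``; the total count equals the
    number of frames.  Terminal residues lacking the angle raise.
    """
    if bin_width <= 0 or 360.0 % bin_width > 1e-9 and abs(360.0 % bin_width - bin_width) > 1e-9:
        raise ValueError("bin width must divide 360")
    frames = _frames(trajectory)
    phis, psis = [], []
    for frame in frames:
        phi, psi = frame.dihedrals[residue_index - 1]
        if np.isnan(phi) or np.isnan(psi):
            raise GeometryError(
                f"residue {residue_index} lacks a defined phi/psi angle")
        # fold the (-180, 180] convention onto [-180, 180) bins
        phis.append(-180.0 if phi == 180.0 else phi)
        psis.append(-180.0 if psi == 180.0 else psi)
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, pe, se = np.histogram2d(phis, psis, bins=(edges, edges))
    return counts, pe, se


@dataclass(frozen=True)
class CapMotifMatch:
    """Result of matching one N-capping pattern at one position."""

    ncap_position: int
    motif_id: str
    pattern: str
    matched: bool
    window: str = ""
    reason: str = ""


def match_capping_motif(seq: ModifiedSequence, ncap_position: int,
                        pattern: str, motif_id: str = "") -> CapMotifMatch:
    """Match an Aurora-Rose h/p/x pattern around an N-cap position.

    The characters before the single ``'-'`` (helix boundary) apply to
    the residues immediately preceding ``ncap_position``; the first
    character after it is the N-cap residue.  A window extending beyond
    the sequence yields ``matched=False`` with a reason, not an error.
    """
    if pattern.count("-") != 1:
        raise ValueError("pattern must contain exactly one '-'")
    if any(c not in "hpx-" for c in pattern):
        raise ValueError(f"invalid pattern {pattern!r}")
    pre, post = pattern.split("-")
    first = ncap_position - len(pre)
    last = ncap_position + len(post) - 1
    if first < 1 or last > len(seq):
        return CapMotifMatch(ncap_position=ncap_position, motif_id=motif_id,
                             pattern=pattern, matched=False,
                             reason="window out of range")
    window = seq.sequence[first - 1:last]
    for offset, ch in enumerate(pre + post):
        res = seq.residues[first - 1 + offset]
        if ch == "x":
            continue
        if ch == "h" and not res.in_h:
            return CapMotifMatch(ncap_position, motif_id, pattern, False,
                                 window, f"{res.code}{res.index} not hydrophobic")
        if ch == "p" and not res.in_p:
            return CapMotifMatch(ncap_position, motif_id, pattern, False,
                                 window, f"{res.code}{res.index} not polar")
    return CapMotifMatch(ncap_position, motif_id, pattern, True, window, "")


def scan_capping_motifs(seq: ModifiedSequence,
                        motifs: dict | None = None) -> pd.DataFrame:
    """Match every named motif at every N-cap position of a sequence."""
    motifs = MOTIFS if motifs is None else motifs
    rows = []
    for pos in range(1, len(seq) + 1):
        for mid, pattern in motifs.items():
            m = match_capping_motif(seq, pos, pattern, motif_id=mid)
            rows.append({"position": pos, "motif": mid, "pattern": pattern,
                         "matched": m.matched, "window": m.window})
    return pd.DataFrame(rows)
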