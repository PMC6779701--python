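"""Kabsch-Sander hydrogen bonds and DSSP-style helical assignment.

Only the helical classes matter for the observable of record -- the
fraction of residues assigned alpha (H) or 3-10 (G) helix, averaged over a
trajectory -- so the assignment implemented here is the helical core of
DSSP: an n-turn at residue i exists when the backbone carbonyl of i is
hydrogen-bonded (Kabsch-Sander energy < -0.5 kcal/mol) to the backbone
amide of i+n, n in {3, 4}; two consecutive 4-turns at i-1 and i make
residues i..i+3 an alpha-helix (H), two consecutive 3-turns make residues
i..i+2 a 3-10 helix (G, with alpha priority on overlap); residues covered
by an isolated turn are labeled T, everything else C.  Beta classes and
the pi helix are deliberately out of scope.

The Kabsch-Sander electrostatic bond energy is

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

over the donor N-H and acceptor C=O groups; a bond exists iff
E < -0.5 kcal/mol.  Amide hydrogens missing from an input frame (external
PDB trajectories rarely store them) are placed 1.0 A from N_i along the
C_{i-1} -> O_{i-1} direction; residue 1 gets no hydrogen and is never a
donor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    BOND_N_H,
    Conformation,
    GeometryError,
    IDX_C,
    IDX_CA,
    IDX_H,
    IDX_N,
    IDX_O,
)

__all__ = [
    "HelicityProfile",
    "KS_COUPLING",
    "KS_THRESHOLD",
    "assign_ss",
    "helicity",
    "ks_hbond_energy",
    "ks_bond_matrix",
    "place_amide_hydrogens",
]

KS_COUPLING = 0.084 * 332.0   # kcal/mol * A
KS_THRESHOLD = -0.5           # kcal/mol
_MIN_DIST = 0.5               # below this any pair is malformed geometry


def place_amide_hydrogens(coords: np.ndarray) -> np.ndarray:
    """Fill missing amide-H slots of an (L, 6, 3) coordinate block.

    For i >= 2 the hydrogen sits ``1.0 A`` from N_i along the unit vector
    ``C_{i-1} - O_{i-1}``; residue 1 keeps a NaN hydrogen (it cannot act
    as a Kabsch-Sander donor).  Frames that already contain hydrogens are
    returned unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    L = coords.shape[0]
    for name, idx in (("N", IDX_N), ("CA", IDX_CA), ("C", IDX_C), ("O", IDX_O)):
        bad = np.isnan(coords[:, idx]).any(axis=1)
        if bad.any():
            raise GeometryError(
                f"missing backbone atom {name} at residue {int(np.where(bad)[0][0]) + 1}")
    out = coords.copy()
    for i in range(1, L):
        if not np.isnan(out[i, IDX_H]).any():
            continue
        v = out[i - 1, IDX_C] - out[i - 1, IDX_O]
        out[i, IDX_H] = out[i, IDX_N] + BOND_N_H * v / np.linalg.norm(v)
    return out


def ks_hbond_energy(donor_n, donor_h, acceptor_c, acceptor_o) -> float:
    """Kabsch-Sander electrostatic energy of one N-H...O=C contact."""
    n = np.asarray(donor_n, float)
    h = np.asarray(donor_h, float)
    c = np.asarray(acceptor_c, float)
    o = np.asarray(acceptor_o, float)
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        raise GeometryError("malformed geometry: inter-atom distance < 0.5 A")
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def ks_bond_matrix(frame: Conformation | np.ndarray) -> np.ndarray:
    """(L, L) boolean matrix: entry (i, j) true iff CO(i+1) -> NH(j+1) bonds.

    Row index is the acceptor (carbonyl) residue, column the donor (amide)
    residue, both 0-based; residue 1 (no amide hydrogen) never donates,
    and adjacent/identical residues are excluded as in DSSP.
    """
    coords = frame.coords if isinstance(frame, Conformation) else np.asarray(frame, float)
    coords = place_amide_hydrogens(coords)
    L = coords.shape[0]
    bonds = np.zeros((L, L), dtype=bool)
    for j in range(1, L):  # donor residue (has H)
        if np.isnan(coords[j, IDX_H]).any():
            continue
        for i in range(L):  # acceptor residue
            if abs(i - j) < 2:
                continue
            e = ks_hbond_energy(coords[j, IDX_N], coords[j, IDX_H],
                                coords[i, IDX_C], coords[i, IDX_O])
            bonds[i, j] = e < KS_THRESHOLD
    return bonds


def assign_ss(frame: Conformation | np.ndarray) -> str:
    """Per-residue labels over {H, G, T, C} for one frame."""
    coords = frame.coords if isinstance(frame, Conformation) else np.asarray(frame, float)
    L = coords.shape[0]
    if L < 3:
        raise GeometryError("need at least 3 residues for assignment")
    bonds = ks_bond_matrix(coords)
    turn3 = np.zeros(L, dtype=bool)
    turn4 = np.zeros(L, dtype=bool)
    for i in range(L - 3):
        turn3[i] = bonds[i, i + 3]
    for i in range(L - 4):
        turn4[i] = bonds[i, i + 4]

    labels = ["C"] * L
    # alpha helix: two consecutive 4-turns at i-1, i -> residues i..i+3
    for i in range(1, L - 4):
        if turn4[i - 1] and turn4[i]:
            for k in range(i, i + 4):
                labels[k] = "H"
    # 3-10 helix: two consecutive 3-turns, alpha priority on overlap
    for i in range(1, L - 3):
        if turn3[i - 1] and turn3[i]:
            for k in range(i, i + 3):
                if labels[k] != "H":
                    labels[k] = "G"
    # isolated turns
    for i in range(L):
        for n, turn in ((3, turn3), (4, turn4)):
            if i < L - n and turn[i]:
                for k in range(i + 1, i + n):
                    if labels[k] == "C":
                        labels[k] = "T"
    return "".join(labels)


@dataclass(frozen=True)
class HelicityProfile:
    """Per-residue helix fractions plus the overall helicity scalar."""

    h_fraction: np.ndarray     # fraction of frames labeled H, per residue
    g_fraction: np.ndarray     # fraction of frames labeled G, per residue
    n_frames: int

    @property
    def helical_fraction(self) -> np.ndarray:
        return self.h_fraction + self.g_fraction

    @property
    def overall(self) -> float:
        """Fraction of residue-frames labeled helical (H or G)."""
        return float(np.mean(self.helical_fraction))

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.overall

    def to_table(self, sequence: str | None = None) -> pd.DataFrame:
        """Per-residue profile, percentages to one decimal."""
        L = len(self.h_fraction)
        codes = list(sequence) if sequence else [""] * L
        return pd.DataFrame({
            "residue": np.arange(1, L + 1),
            "code": codes,
            "pct_H": np.round(100.0 * self.h_fraction, 1),
            "pct_G": np.round(100.0 * self.g_fraction, 1),
            "pct_helical": np.round(100.0 * self.helical_fraction, 1),
        })


def _frame_labels(trajectory) -> list[str]:
    labels = []
    for frame in trajectory:
        if isinstance(frame, str):
            labels.append(frame)
        else:
            labels.append(assign_ss(frame))
    return labels


def helicity(trajectory, equilibration_fraction: float = 0.1) -> HelicityProfile:
    """Helicity of a trajectory of frames or of pre-assigned label strings.

    The first ``equilibration_fraction`` of frames is discarded before
    averaging.  Overall helicity is the mean over residues of
    (H-fraction + G-fraction), identically the residue-frame average.
    """
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    frames = list(trajectory)
    start = int(len(frames) * equilibration_fraction)
    frames = frames[start:]
    if not frames:
        raise ValueError("no frames left after equilibration discard")
    labels = _frame_labels(frames)
    L = len(labels[0])
    if any(len(s) != L for s in labels):
        raise ValueError("inconsistent residue counts across frames")
    arr = np.array([list(s) for s in labels])
    h = (arr == "H").mean(axis=0)
    g = (arr == "G").mean(axis=0)
    return HelicityProfile(h_fraction=h, g_fraction=g, n_frames=len(labels))
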