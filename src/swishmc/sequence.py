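"""Peptide sequences with post-translational modifications.

The huntingtin N-terminal peptide Htt(1-19), MATLEKLMKAFESLKSFQQ, is the
reference system of this package.  Its helical propensity is modulated by
phosphorylation of Thr3/Ser13/Ser16, side-chain acetylation of Lys6, and
N-terminal acetylation.  This module turns a one-letter sequence plus a
list of canonical modification labels ("pThr3", "acLys6", "acMet1", ...)
into a :class:`ModifiedSequence` carrying per-residue formal charges and
hydrophobic/polar class membership, the inputs to both the coarse-grained
energy model and the N-capping motif matcher.

Charge conventions (configurable where noted):

* Asp/Glu side chain: -1; Lys/Arg side chain: +1; all other unmodified
  side chains: 0.  His is treated as neutral at pH 7.
* Free N-terminus: +1; free C-terminus: -1 (both switchable, terminal
  chemistry of synthetic peptides varies).
* Phosphorylation sets the Ser/Thr side-chain charge to ``phosphate_charge``
  (default -2, the dominant state at physiological pH; -1 selectable).
* Side-chain acetylation neutralizes the Lys epsilon-amine (+1 -> 0).
* N-terminal acetylation neutralizes the N-terminal amine (+1 -> 0).

Hydrophobic (h) / polar (p) classes follow the Aurora-Rose alphabet used
for helix N-capping motifs: h covers the canonical hydrophobics plus the
alkyl portion of the Lys/Arg side chains, so Lys and Arg belong to both
classes.  Class membership is a pure function of (residue code, PTM state)
and never of sequence position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "AMINO_ACIDS",
    "ModifiedSequence",
    "PTMSpec",
    "ResidueSpec",
    "SequenceError",
    "HTT_N19",
    "PTM_PEPTIDE_PANEL",
    "parse_mod_label",
    "parse_modified_sequence",
    "residue_class",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

# Aurora-Rose h/p alphabet; Lys and Arg belong to both classes.
HYDROPHOBIC = frozenset("AVLIMFWYC") | frozenset("KR")
POLAR = frozenset("STNQDEH") | frozenset("KR")

_SIDECHAIN_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

#: Htt(1-19), the wild-type peptide studied throughout.
HTT_N19 = "MATLEKLMKAFESLKSFQQ"

#: The ten Htt(1-19) modification variants studied by CD and simulation
#: (name, one-letter sequence, modification labels).
PTM_PEPTIDE_PANEL = [
    ("WT", HTT_N19, []),
    ("pThr3", HTT_N19, ["pThr3"]),
    ("pThr3_pSer13", HTT_N19, ["pThr3", "pSer13"]),
    ("pThr3_pSer16", HTT_N19, ["pThr3", "pSer16"]),
    ("pThr3_pSer13_pSer16", HTT_N19, ["pThr3", "pSer13", "pSer16"]),
    ("pSer16", HTT_N19, ["pSer16"]),
    ("pThr3_acLys6", HTT_N19, ["pThr3", "acLys6"]),
    ("acLys6", HTT_N19, ["acLys6"]),
    ("pThr3_acMet1", HTT_N19, ["pThr3", "acMet1"]),
    ("acMet1", HTT_N19, ["acMet1"]),
]


class SequenceError(ValueError):
    """Invalid sequence text, modification label, or label/residue mismatch."""


@dataclass(frozen=True)
class PTMSpec:
    """One post-translational modification.

    kind is one of ``phospho``, ``acetyl_sidechain``, ``acetyl_nterm``;
    ``target`` is the 1-based residue index (1 for acetyl_nterm).
    """

    kind: str
    target: int
    label: str

    _KINDS = ("phospho", "acetyl_sidechain", "acetyl_nterm")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise SequenceError(f"unknown PTM kind {self.kind!r}")


@dataclass(frozen=True)
class ResidueSpec:
    """A residue with its PTM-dependent physical classes.

    ``formal_charge`` is the side-chain formal charge in elementary
    charges; terminal charges live on :class:`ModifiedSequence`.
    ``apolar_beads`` names the coarse-grained beads of this residue that
    count as apolar for solvent-dispersion lambda-scaling.
    """

    index: int
    code: str
    formal_charge: int
    in_h: bool
    in_p: bool
    apolar_beads: tuple[str, ...]
    phospho: bool = False
    acetyl: bool = False


def residue_class(res: ResidueSpec) -> dict:
    """Hydrophobic/polar class membership flags of a residue."""
    return {"in_h": res.in_h, "in_p": res.in_p}


def _make_residue(index: int, code: str, phospho: bool, acetyl: bool,
                  phosphate_charge: int) -> ResidueSpec:
    if code not in AMINO_ACIDS:
        raise SequenceError(f"unknown residue code {code!r} at position {index}")
    charge = _SIDECHAIN_CHARGE.get(code, 0)
    in_h = code in HYDROPHOBIC
    in_p = code in POLAR
    if phospho:
        charge = phosphate_charge
        # phosphorylated Ser/Thr stay polar
        in_p = True
    if acetyl:
        # Lys epsilon-amine neutralized; the alkyl chain keeps h-membership
        charge = 0
    apolar = ("CA", "C") + (("SC",) if in_h else ())
    return ResidueSpec(index=index, code=code, formal_charge=charge,
                       in_h=in_h, in_p=in_p, apolar_beads=apolar,
                       phospho=phospho, acetyl=acetyl)


_LABEL_RE = re.compile(r"^(p|ac)([A-Z][a-z]{2})(\d+)$")


def parse_mod_label(label: str) -> tuple[str, int, str]:
    """Parse a canonical modification label.

    Returns ``(kind, target_index, expected_one_letter_code)``.  Grammar:
    ``("p"|"ac") + three-letter residue name + 1-based index``; the special
    labels ``acMet1`` (when the first residue is Met) and its synonym
    ``acNterm`` denote N-terminal acetylation.
    """
    if label == "acNterm":
        return "acetyl_nterm", 1, ""
    m = _LABEL_RE.match(label)
    if m is None:
        raise SequenceError(f"malformed modification label {label!r}")
    prefix, resname, idx = m.group(1), m.group(2), int(m.group(3))
    if resname not in _THREE_TO_ONE:
        raise SequenceError(f"unknown residue name {resname!r} in label {label!r}")
    code = _THREE_TO_ONE[resname]
    if prefix == "p":
        if code not in "ST":
            raise SequenceError(
                f"phosphorylation label {label!r} targets {resname}, not Ser/Thr")
        return "phospho", idx, code
    # acetylation: Lys side chain, or the N-terminal amine when index == 1
    if code == "K":
        return "acetyl_sidechain", idx, code
    if idx == 1:
        return "acetyl_nterm", 1, code
    raise SequenceError(
        f"acetylation label {label!r} targets {resname}{idx}; only Lys side "
        "chains or the N-terminal residue (index 1) can be acetylated")


def format_mod_label(kind: str, target: int, code: str) -> str:
    """Canonical label for a (kind, target, residue code) triple."""
    if kind == "acetyl_nterm":
        return f"ac{_ONE_TO_THREE[code]}1" if code else "acNterm"
    prefix = "p" if kind == "phospho" else "ac"
    return f"{prefix}{_ONE_TO_THREE[code]}{target}"


@dataclass(frozen=True)
class ModifiedSequence:
    """A peptide sequence with applied PTMs and terminal charge state."""

    residues: tuple[ResidueSpec, ...]
    ptms: tuple[PTMSpec, ...]
    name: str = ""
    nterm_charge: int = +1
    cterm_charge: int = -1
    phosphate_charge: int = -2

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def mod_labels(self) -> list[str]:
        return [p.label for p in self.ptms]

    def charge_vector(self) -> tuple[int, ...]:
        """Per-site formal charges: N-terminus, each side chain, C-terminus."""
        return (self.nterm_charge,
                *(r.formal_charge for r in self.residues),
                self.cterm_charge)

    @property
    def total_charge(self) -> int:
        return sum(self.charge_vector())

    def apply_ptm(self, label: str) -> "ModifiedSequence":
        """Return a new sequence with one more modification applied."""
        return parse_modified_sequence(
            self.sequence, self.mod_labels + [label], name=self.name,
            phosphate_charge=self.phosphate_charge,
            nterm_charged=self._base_nterm_charged(),
            cterm_charged=self.cterm_charge != 0)

    def remove_ptm(self, label: str) -> "ModifiedSequence":
        """Return a new sequence with the named modification removed."""
        labels = self.mod_labels
        if label not in labels:
            raise SequenceError(f"{label!r} is not applied to this sequence")
        labels.remove(label)
        return parse_modified_sequence(
            self.sequence, labels, name=self.name,
            phosphate_charge=self.phosphate_charge,
            nterm_charged=self._base_nterm_charged(),
            cterm_charged=self.cterm_charge != 0)

    def _base_nterm_charged(self) -> bool:
        # underlying (pre-PTM) N-terminal state
        if any(p.kind == "acetyl_nterm" for p in self.ptms):
            return True
        return self.nterm_charge != 0


def parse_modified_sequence(seq_text: str, mod_labels: list[str] | None = None,
                            name: str = "", phosphate_charge: int = -2,
                            nterm_charged: bool = True,
                            cterm_charged: bool = True) -> ModifiedSequence:
    """Build a :class:`ModifiedSequence` from one-letter text plus labels.

    Raises :class:`SequenceError` on unknown residue codes, malformed or
    wrongly-targeted labels, out-of-range indices, or duplicate PTMs of the
    same kind on one residue.
    """
    mod_labels = list(mod_labels or [])
    seq_text = seq_text.strip().upper()
    if not seq_text:
        raise SequenceError("empty sequence")
    for i, c in enumerate(seq_text, start=1):
        if c not in AMINO_ACIDS:
            raise SequenceError(f"unknown residue code {c!r} at position {i}")
    if phosphate_charge not in (-1, -2):
        raise SequenceError("phosphate_charge must be -1 or -2")

    ptms: list[PTMSpec] = []
    seen: set[tuple[str, int]] = set()
    phospho: set[int] = set()
    acetyl: set[int] = set()
    nterm_acetyl = False
    for label in mod_labels:
        kind, target, code = parse_mod_label(label)
        if not (1 <= target <= len(seq_text)):
            raise SequenceError(f"label {label!r}: index {target} out of range "
                                f"for a {len(seq_text)}-mer")
        if code and seq_text[target - 1] != code:
            raise SequenceError(
                f"label {label!r} expects {code} at position {target}, "
                f"sequence has {seq_text[target - 1]}")
        if (kind, target) in seen:
            raise SequenceError(f"duplicate modification {label!r}")
        seen.add((kind, target))
        if kind == "phospho":
            phospho.add(target)
        elif kind == "acetyl_sidechain":
            acetyl.add(target)
        else:
            nterm_acetyl = True
        canonical = format_mod_label(
            kind, target, seq_text[0] if kind == "acetyl_nterm" else code)
        ptms.append(PTMSpec(kind=kind, target=target, label=canonical))

    ptms.sort(key=lambda p: (p.target, p.kind))  # canonical order
    residues = tuple(
        _make_residue(i, c, phospho=i in phospho, acetyl=i in acetyl,
                      phosphate_charge=phosphate_charge)
        for i, c in enumerate(seq_text, start=1))
    nterm = +1 if (nterm_charged and not nterm_acetyl) else 0
    cterm = -1 if cterm_charged else 0
    return ModifiedSequence(residues=residues, ptms=tuple(ptms), name=name,
                            nterm_charge=nterm, cterm_charge=cterm,
                            phosphate_charge=phosphate_charge)


def read_fasta(path) -> tuple[str, str]:
    """Read the first record of a FASTA file -> (header, sequence)."""
    header, chunks = "", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if chunks:
                    break
                header = line[1:].strip()
            else:
                chunks.append(line)
    if not chunks:
        raise SequenceError(f"no sequence record in {path}")
    return header, "".join(chunks)


def read_mod_list(path) -> list[str]:
    """Read a sidecar modification list (one canonical label per line)."""
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                labels.append(line)
    return labels
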