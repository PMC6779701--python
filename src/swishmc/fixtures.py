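"""Deterministic generators for test structures and exactly enumerable
toy systems.

Ideal dihedral values: alpha helix (-57, -47); 3-10 helix (-49, -26);
extended strand (-135, 135).  ``make_ideal_structure`` builds whole-chain
or per-segment ideal conformations; ``make_enumerable_system`` produces a
tiny discrete system (<= 256 microstates) whose exact Boltzmann
distribution at any lambda is computable by direct summation -- the
brute-force oracle for the replica-exchange acceptance criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import Conformation, build_backbone
from .model import (
    KB_KCAL,
    EnergyParameters,
    _decompose_raw,
    build_conformation,
    pack_system,
)
from .sequence import ModifiedSequence

__all__ = [
    "IDEAL_DIHEDRALS",
    "DiscreteState",
    "DiscreteSystem",
    "EnumerableToySystem",
    "make_enumerable_system",
    "make_ideal_structure",
    "make_label_trajectory",
    "toy_system_from_model",
]

IDEAL_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "three_ten": (-49.0, -26.0),
    "extended": (-135.0, 135.0),
}

MAX_MICROSTATES = 256


def make_ideal_structure(seq: ModifiedSequence, kind: str = "alpha",
                         segments=None) -> Conformation:
    """Ideal conformation of a sequence.

    ``kind`` is one of ``alpha``, ``three_ten``, ``extended``, or
    ``mixed``; for ``mixed``, ``segments`` is a list of
    ``(start, end, kind)`` 1-based inclusive ranges (non-overlapping) and
    residues outside every segment are extended.
    """
    L = len(seq)
    if kind != "mixed":
        if kind not in IDEAL_DIHEDRALS:
            raise ValueError(f"unknown structure kind {kind!r}")
        dihedrals = np.tile(IDEAL_DIHEDRALS[kind], (L, 1))
        return build_conformation(seq, dihedrals)
    if not segments:
        raise ValueError("mixed structures need a segment list")
    dihedrals = np.tile(IDEAL_DIHEDRALS["extended"], (L, 1))
    claimed = np.zeros(L, dtype=bool)
    for start, end, seg_kind in segments:
        if not (1 <= start <= end <= L):
            raise ValueError(f"segment ({start}, {end}) out of range")
        if claimed[start - 1:end].any():
            raise ValueError(f"segment ({start}, {end}) overlaps another segment")
        claimed[start - 1:end] = True
        dihedrals[start - 1:end] = IDEAL_DIHEDRALS[seg_kind]
    return build_conformation(seq, dihedrals)


def make_label_trajectory(n_residues: int, frame_labels) -> list[str]:
    """A synthetic stream of per-frame label strings (bypasses geometry).

    Feeds the helicity / frequency operations directly for arithmetic
    tests; every string must cover all residues.
    """
    labels = [str(s) for s in frame_labels]
    for s in labels:
        if len(s) != n_residues:
            raise ValueError(
                f"label string {s!r} does not cover {n_residues} residues")
    return labels


@dataclass(frozen=True)
class EnumerableToySystem:
    """A discrete system small enough for exhaustive Boltzmann sums.

    ``n_slots`` degrees of freedom each taking ``n_symbols`` values;
    microstate x is the mixed-radix tuple of slot values and carries
    exact energies ``U0[x]`` and ``W[x]``.
    """

    n_slots: int
    n_symbols: int
    U0: np.ndarray   # (n_symbols ** n_slots,)
    W: np.ndarray

    def __post_init__(self) -> None:
        n = self.n_symbols ** self.n_slots
        if n > MAX_MICROSTATES:
            raise ValueError(f"{n} microstates exceed the enumerable limit "
                             f"{MAX_MICROSTATES}")
        if self.U0.shape != (n,) or self.W.shape != (n,):
            raise ValueError("energy tables must cover every microstate")

    @property
    def n_microstates(self) -> int:
        return self.n_symbols ** self.n_slots

    def microstate_index(self, slots) -> int:
        idx = 0
        for s in slots:
            idx = idx * self.n_symbols + int(s)
        return idx

    def exact_distribution(self, lam: float, T: float) -> np.ndarray:
        """Exact Boltzmann probabilities of ``U0 + lam * W`` at T."""
        if T <= 0:
            raise ValueError("temperature must be positive")
        u = self.U0 + lam * self.W
        w = np.exp(-(u - u.min()) / (KB_KCAL * T))
        return w / w.sum()


def make_enumerable_system(U0, W=None, n_slots: int = 1,
                           n_symbols: int | None = None) -> EnumerableToySystem:
    """Wrap explicit per-microstate energy tables into a toy system."""
    U0 = np.asarray(U0, dtype=float)
    W = np.zeros_like(U0) if W is None else np.asarray(W, dtype=float)
    if n_symbols is None:
        n_symbols = round(len(U0) ** (1.0 / n_slots))
    return EnumerableToySystem(n_slots=n_slots, n_symbols=int(n_symbols),
                               U0=U0, W=W)


def toy_system_from_model(seq: ModifiedSequence, params: EnergyParameters,
                          alphabet=None) -> EnumerableToySystem:
    """Enumerable system built from the coarse-grained model itself.

    Each residue's (phi, psi) is restricted to a small discrete alphabet
    (default: the ideal alpha and extended values); every combination is
    built in Cartesian space and its exact (U0, W) recorded.
    """
    if alphabet is None:
        alphabet = [IDEAL_DIHEDRALS["alpha"], IDEAL_DIHEDRALS["extended"]]
    L = len(seq)
    n_symbols = len(alphabet)
    if n_symbols ** L > MAX_MICROSTATES:
        raise ValueError("alphabet^L exceeds the enumerable limit")
    arrays = pack_system(seq, params)
    U0 = np.empty(n_symbols ** L)
    W = np.empty_like(U0)
    for slots in itertools.product(range(n_symbols), repeat=L):
        dihedrals = np.array([alphabet[s] for s in slots], dtype=float)
        coords = build_backbone(dihedrals, arrays.sc_dist)
        idx = 0
        for s in slots:
            idx = idx * n_symbols + s
        u0, w = _decompose_raw(coords, dihedrals, arrays, params)
        U0[idx], W[idx] = u0, w
    return EnumerableToySystem(n_slots=L, n_symbols=n_symbols, U0=U0, W=W)


@dataclass
class DiscreteState:
    """Sampler state of a toy system: slot values plus cached energies."""

    slots: np.ndarray
    U0: float
    W: float


class DiscreteSystem:
    """Adapter exposing an :class:`EnumerableToySystem` to ``run_swish``.

    One sweep proposes, for each slot in order, a uniformly random symbol
    (symmetric proposal) accepted by the Metropolis rule on
    ``U0 + lambda * W``.
    """

    def __init__(self, toy: EnumerableToySystem, initial_slots=None):
        self.toy = toy
        if initial_slots is None:
            initial_slots = np.zeros(toy.n_slots, dtype=np.int64)
        self._init = np.asarray(initial_slots, dtype=np.int64)

    def _energies(self, slots) -> tuple[float, float]:
        idx = self.toy.microstate_index(slots)
        return float(self.toy.U0[idx]), float(self.toy.W[idx])

    def initial_state(self, rng: np.random.Generator) -> DiscreteState:
        slots = self._init.copy()
        u0, w = self._energies(slots)
        return DiscreteState(slots=slots, U0=u0, W=w)

    def sweep(self, state: DiscreteState, lam: float, kT: float,
              rng: np.random.Generator) -> tuple[int, int]:
        n_acc = 0
        for slot in range(self.toy.n_slots):
            proposal = int(rng.integers(self.toy.n_symbols))
            old = int(state.slots[slot])
            if proposal == old:
                n_acc += 1
                continue
            state.slots[slot] = proposal
            u0n, wn = self._energies(state.slots)
            du = (u0n + lam * wn) - (state.U0 + lam * state.W)
            if du <= 0.0 or rng.random() < np.exp(-du / kT):
                state.U0, state.W = u0n, wn
                n_acc += 1
            else:
                state.slots[slot] = old
        return n_acc, self.toy.n_slots

    def decomposition(self, state: DiscreteState) -> tuple[float, float]:
        return state.U0, state.W

    def snapshot(self, state: DiscreteState) -> int:
        return self.toy.microstate_index(state.slots)
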