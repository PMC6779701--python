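"""Metropolis Monte Carlo in dihedral space plus SWISH Hamiltonian replica
exchange across a solvent-scaling lambda ladder.

The production ladder of record scales the solvent-dispersion term between
0.85 and 1.10 in steps of 0.05 (6 replicas); a wider pilot ladder runs from
0.6 to 1.3 in steps of 0.1 (8 replicas).  Adjacent rungs attempt exchanges
every ``swap_interval`` sweeps (the sweep-count analogue of the 5 ps swap
period of the molecular-dynamics protocol) on alternating even/odd pairs.

Because every replica shares the temperature and the energies decompose
linearly, ``U_k(x) = U0(x) + lambda_k W(x)``, the same-temperature
Hamiltonian-exchange acceptance exponent

    delta = beta * [(U_m(x_n) + U_n(x_m)) - (U_m(x_m) + U_n(x_n))]
          = (lambda_m - lambda_n) * (W_n - W_m) / kT

so only the cached ``W`` values of the two rungs are needed; acceptance is
``min(1, exp(-delta))``, which preserves the Boltzmann distribution of
``U0 + lambda_k W`` at every rung.  Statistics of record are taken from the
unscaled rung (lambda = 1.0).

Conformations travel with their replica on an accepted swap; only the
rung assignment (equivalently lambda) is exchanged.  Each replica owns an
independent RNG stream keyed to its permanent identity, so exchanges never
touch random-number state and runs are bit-reproducible given (seed,
configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, NamedTuple, Protocol, Sequence

import numpy as np

from .geometry import _njit, build_backbone
from .model import (
    KB_KCAL,
    EnergyParameters,
    SystemArrays,
    _basin_arrays,
    _decompose_raw,
    _energy_kernel,
    pack_system,
)
from .sequence import ModifiedSequence

__all__ = [
    "ExchangeAttempt",
    "Frame",
    "LadderError",
    "LambdaLadder",
    "DemuxError",
    "PeptideState",
    "PeptideSystem",
    "ReplicaState",
    "SwishRun",
    "build_ladder",
    "demux",
    "mc_sweep",
    "remux",
    "run_swish",
    "swap_exponent",
]


class LadderError(ValueError):
    """Non-commensurate ladder bounds/step."""


class DemuxError(ValueError):
    """Gap or inconsistency in an exchange log."""


@dataclass(frozen=True)
class LambdaLadder:
    """Strictly increasing lambda schedule; rung 1.0 is the reporting rung."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if not v:
            raise LadderError("empty ladder")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise LadderError("ladder values must be strictly increasing")
        if any(x <= 0 for x in v):
            raise LadderError("lambda values must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]

    @property
    def reporting_index(self) -> int | None:
        """Index of the unscaled (lambda = 1.0) rung, or None."""
        for i, x in enumerate(self.values):
            if abs(x - 1.0) < 1e-12:
                return i
        return None


def build_ladder(lambda_min: float, lambda_max: float, step: float) -> LambdaLadder:
    """Uniform ladder ``lambda_min, lambda_min + step, ..., lambda_max``.

    Bounds must be commensurate with the step; no silent truncation.
    """
    if step <= 0:
        raise LadderError("step must be positive")
    if lambda_max < lambda_min:
        raise LadderError("lambda_max must be >= lambda_min")
    n = (lambda_max - lambda_min) / step
    if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
        raise LadderError(
            f"({lambda_min}, {lambda_max}) is not an integer number of steps {step}")
    n = int(round(n))
    values = [lambda_min + k * step for k in range(n + 1)]
    values[-1] = lambda_max
    # snap the reporting rung exactly onto 1.0 when commensurate
    for i, x in enumerate(values):
        if abs(x - 1.0) < 1e-9:
            values[i] = 1.0
    return LambdaLadder(values=tuple(values))


def swap_exponent(lam_m: float, lam_n: float, W_m: float, W_n: float,
                  T: float) -> float:
    """Exchange exponent for two same-temperature rungs; accept with
    probability ``min(1, exp(-delta))``."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return (lam_m - lam_n) * (W_n - W_m) / (KB_KCAL * T)


# ---------------------------------------------------------------------------
# sampled systems
# ---------------------------------------------------------------------------

class SampledSystem(Protocol):
    """Anything run_swish can propagate: a sweep move plus (U0, W)."""

    def initial_state(self, rng: np.random.Generator) -> Any: ...

    def sweep(self, state: Any, lam: float, kT: float,
              rng: np.random.Generator) -> tuple[int, int]: ...

    def decomposition(self, state: Any) -> tuple[float, float]: ...

    def snapshot(self, state: Any) -> Any: ...


@_njit
def _peptide_sweep_kernel(dihedrals, sc_dist, U0, W, lam, kT, delta_max,
                          rand_delta, rand_accept, torsion_mask,
                          basin_c, basin_w, basin_d,
                          bead_res, bead_atom, bead_eps, bead_sigma,
                          bead_apolar, n_main, site_res, site_atom, site_q,
                          dielectric, debye, coulomb_k, coulomb_sat,
                          dispersion_s, cutoff, n_max, hard_core):
    L = dihedrals.shape[0]
    n_accept = 0
    m = 0
    for i in range(L):
        for a in range(2):
            old = dihedrals[i, a]
            delta = (2.0 * rand_delta[m] - 1.0) * delta_max
            new = old + delta
            while new > 180.0:
                new -= 360.0
            while new <= -180.0:
                new += 360.0
            dihedrals[i, a] = new
            coords = build_backbone(dihedrals, sc_dist)
            U0n, Wn = _energy_kernel(
                coords, dihedrals, torsion_mask, basin_c, basin_w, basin_d,
                bead_res, bead_atom, bead_eps, bead_sigma, bead_apolar,
                n_main, site_res, site_atom, site_q, dielectric, debye,
                coulomb_k, coulomb_sat, dispersion_s, cutoff, n_max, hard_core)
            dU = (U0n + lam * Wn) - (U0 + lam * W)
            accept = False
            if dU <= 0.0:
                accept = True
            elif rand_accept[m] < np.exp(-dU / kT):
                accept = True
            if accept:
                U0 = U0n
                W = Wn
                n_accept += 1
            else:
                dihedrals[i, a] = old
            m += 1
    return U0, W, n_accept


@dataclass
class PeptideState:
    """Mutable sampler state: dihedrals plus cached energy split."""

    dihedrals: np.ndarray
    U0: float
    W: float


class PeptideSystem:
    """The coarse-grained peptide as a sampled system.

    Moves are single-dihedral perturbations, uniform in
    ``[-delta_max, +delta_max]`` (symmetric, so plain Metropolis
    acceptance applies); one sweep is one pass over all phi/psi angles in
    residue order.
    """

    def __init__(self, seq: ModifiedSequence, params: EnergyParameters,
                 initial_dihedrals=None, delta_max: float | None = None):
        self.seq = seq
        self.params = params
        self.arrays: SystemArrays = pack_system(seq, params)
        self.delta_max = params.delta_max if delta_max is None else float(delta_max)
        if initial_dihedrals is None:
            initial_dihedrals = np.tile((-135.0, 135.0), (len(seq), 1))
        self._init = np.array(initial_dihedrals, dtype=float)
        if self._init.shape != (len(seq), 2):
            raise ValueError("initial dihedrals must have shape (L, 2)")
        self._basins = _basin_arrays(params)

    def _decompose(self, dihedrals: np.ndarray) -> tuple[float, float]:
        coords = build_backbone(dihedrals, self.arrays.sc_dist)
        return _decompose_raw(coords, dihedrals, self.arrays, self.params)

    def initial_state(self, rng: np.random.Generator) -> PeptideState:
        dih = self._init.copy()
        U0, W = self._decompose(dih)
        return PeptideState(dihedrals=dih, U0=float(U0), W=float(W))

    def sweep(self, state: PeptideState, lam: float, kT: float,
              rng: np.random.Generator) -> tuple[int, int]:
        L = state.dihedrals.shape[0]
        n_moves = 2 * L
        rand_delta = rng.random(n_moves)
        rand_accept = rng.random(n_moves)
        basin_c, basin_w, basin_d = self._basins
        arr = self.arrays
        p = self.params
        U0, W, n_acc = _peptide_sweep_kernel(
            state.dihedrals, arr.sc_dist, state.U0, state.W, lam, kT,
            self.delta_max, rand_delta, rand_accept, arr.torsion_mask,
            basin_c, basin_w, basin_d,
            arr.bead_res, arr.bead_atom, arr.bead_eps, arr.bead_sigma,
            arr.bead_apolar, arr.n_main, arr.site_res, arr.site_atom, arr.site_q,
            p.dielectric, p.debye_length, p.coulomb_k, p.coulomb_saturation,
            p.dispersion_s, p.neighbor_cutoff, float(p.n_max), p.hard_core)
        state.U0, state.W = float(U0), float(W)
        return int(n_acc), n_moves

    def decomposition(self, state: PeptideState) -> tuple[float, float]:
        return state.U0, state.W

    def snapshot(self, state: PeptideState) -> np.ndarray:
        return state.dihedrals.copy()


def mc_sweep(system: SampledSystem, state: Any, lam: float, T: float,
             rng: np.random.Generator) -> tuple[Any, int, int]:
    """One Metropolis pass over all degrees of freedom at fixed lambda.

    Returns ``(state, n_accepted, n_attempted)``; the state is updated in
    place and also returned for convenience.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    n_acc, n_moves = system.sweep(state, lam, KB_KCAL * T, rng)
    return state, n_acc, n_moves


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

class ExchangeAttempt(NamedTuple):
    """One adjacent-pair exchange attempt at the end of a sweep."""

    step: int
    pair: tuple[int, int]   # (state_index, state_index + 1)
    delta: float
    accepted: bool


class Frame(NamedTuple):
    """One recorded frame of a per-rung (state-continuous) stream."""

    sweep: int
    replica_id: int
    payload: Any


@dataclass
class ReplicaState:
    """Bookkeeping for one replica (permanent identity, current rung).

    The RNG stream is keyed to ``replica_id``, never to the rung, so
    accepted exchanges do not perturb random-number state.
    """

    replica_id: int
    state_index: int
    state: Any
    rng: np.random.Generator

    @property
    def W_cached(self) -> float:
        """Lambda-coupled energy of the current configuration (cached)."""
        return float(self.state.W)


@dataclass
class SwishRun:
    """Everything a SWISH run produces, per rung plus the exchange log."""

    ladder: LambdaLadder
    frames: list[list[Frame]]          # frames[k] = stream of rung k
    exchange_log: list[ExchangeAttempt]
    replicas: list[ReplicaState]
    n_sweeps: int
    swap_interval: int
    record_interval: int
    temperature: float
    seed: int
    acceptance: float                   # overall MC move acceptance
    warnings: list[str] = field(default_factory=list)

    @property
    def reporting_index(self) -> int | None:
        return self.ladder.reporting_index

    def reporting_frames(self) -> list[Frame]:
        """The lambda = 1.0 state-continuous stream (the physical ensemble)."""
        k = self.reporting_index
        if k is None:
            raise ValueError("ladder has no lambda = 1.0 rung")
        return self.frames[k]

    def payload_series(self, state_index: int,
                       equilibration_fraction: float = 0.0) -> list[Any]:
        frames = self.frames[state_index]
        start = int(len(frames) * equilibration_fraction)
        return [f.payload for f in frames[start:]]


def run_swish(system: SampledSystem, ladder: LambdaLadder, n_sweeps: int,
              swap_interval: int, T: float, seed: int,
              record_interval: int = 1) -> SwishRun:
    """Propagate one replica per ladder rung with periodic adjacent swaps.

    Replica r starts on rung r.  Every ``swap_interval`` sweeps the
    adjacent pairs of alternating parity (even phase: (0,1), (2,3), ...;
    odd phase: (1,2), (3,4), ...) attempt an exchange with acceptance
    ``min(1, exp(-delta))``; on success the two replicas trade rungs and
    their conformations travel with them.  Frames are recorded per rung
    every ``record_interval`` sweeps, after the exchange phase.
    """
    if n_sweeps < 1 or swap_interval < 1 or record_interval < 1:
        raise ValueError("n_sweeps, swap_interval, record_interval must be >= 1")
    if T <= 0:
        raise ValueError("temperature must be positive")
    n_rungs = len(ladder)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_rungs + 1)
    exch_rng = np.random.default_rng(children[-1])

    replicas: list[ReplicaState] = []
    for r in range(n_rungs):
        rng = np.random.default_rng(children[r])
        replicas.append(ReplicaState(replica_id=r, state_index=r,
                                     state=system.initial_state(rng), rng=rng))

    warnings: list[str] = []
    if ladder.reporting_index is None:
        warnings.append("ladder contains no lambda = 1.0 rung; "
                        "no reporting ensemble will be recorded")

    kT = KB_KCAL * T
    frames: list[list[Frame]] = [[] for _ in range(n_rungs)]
    log: list[ExchangeAttempt] = []
    n_acc_total = 0
    n_moves_total = 0
    replica_at_state = list(range(n_rungs))   # rung -> replica index

    for sweep in range(1, n_sweeps + 1):
        for rep in replicas:
            lam = ladder[rep.state_index]
            n_acc, n_mv = system.sweep(rep.state, lam, kT, rep.rng)
            n_acc_total += n_acc
            n_moves_total += n_mv
        if sweep % swap_interval == 0:
            phase = (sweep // swap_interval - 1) % 2
            for k in range(phase, n_rungs - 1, 2):
                rep_m = replicas[replica_at_state[k]]
                rep_n = replicas[replica_at_state[k + 1]]
                _, W_m = system.decomposition(rep_m.state)
                _, W_n = system.decomposition(rep_n.state)
                delta = swap_exponent(ladder[k], ladder[k + 1], W_m, W_n, T)
                if delta <= 0.0:
                    accepted = True
                else:
                    accepted = exch_rng.random() < math.exp(-delta)
                log.append(ExchangeAttempt(step=sweep, pair=(k, k + 1),
                                           delta=delta, accepted=accepted))
                if accepted:
                    rep_m.state_index, rep_n.state_index = (
                        rep_n.state_index, rep_m.state_index)
                    replica_at_state[k], replica_at_state[k + 1] = (
                        replica_at_state[k + 1], replica_at_state[k])
            # rung <-> replica assignment must stay a bijection
            assert sorted(r.state_index for r in replicas) == list(range(n_rungs))
        if sweep % record_interval == 0:
            for k in range(n_rungs):
                rep = replicas[replica_at_state[k]]
                frames[k].append(Frame(sweep=sweep, replica_id=rep.replica_id,
                                       payload=system.snapshot(rep.state)))

    acc = n_acc_total / n_moves_total if n_moves_total else 0.0
    return SwishRun(ladder=ladder, frames=frames, exchange_log=log,
                    replicas=replicas, n_sweeps=n_sweeps,
                    swap_interval=swap_interval, record_interval=record_interval,
                    temperature=T, seed=seed, acceptance=acc, warnings=warnings)


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def _validate_log(exchange_log: Sequence[ExchangeAttempt], n_states: int,
                  swap_interval: int | None) -> None:
    prev = 0
    expected = swap_interval
    for entry in exchange_log:
        step, (i, j) = entry.step, entry.pair
        if step < prev:
            raise DemuxError(f"exchange log steps go backwards at step {step}")
        if j != i + 1 or not (0 <= i < n_states - 1):
            raise DemuxError(f"invalid pair {entry.pair} at step {step}")
        if swap_interval is not None:
            if step % swap_interval != 0:
                raise DemuxError(
                    f"step {step} is not a multiple of swap_interval {swap_interval}")
            if step > prev and prev:
                # every phase logs attempts when >2 rungs; with 2 rungs the
                # odd phases have no adjacent pair of that parity
                max_gap = swap_interval if n_states > 2 else 2 * swap_interval
                if step - prev > max_gap:
                    missing = prev + swap_interval
                    raise DemuxError(
                        f"gap in exchange log: no attempts at step {missing}")
        prev = step


def _replay(exchange_log: Sequence[ExchangeAttempt], n_states: int):
    """Yield (step, rung -> replica map after all swaps at that step)."""
    mapping = list(range(n_states))
    grouped: dict[int, list[ExchangeAttempt]] = {}
    for e in exchange_log:
        grouped.setdefault(e.step, []).append(e)
    for step in sorted(grouped):
        for e in grouped[step]:
            if e.accepted:
                i, j = e.pair
                mapping[i], mapping[j] = mapping[j], mapping[i]
        yield step, list(mapping)


def demux(exchange_log: Sequence[ExchangeAttempt],
          per_state_frames: Sequence[Sequence[Frame]],
          swap_interval: int | None = None) -> list[list[Frame]]:
    """Convert per-rung streams into replica-continuous trajectories.

    The rung <-> replica map is reconstructed by replaying accepted swaps
    from the identity assignment; a malformed or gapped log raises
    :class:`DemuxError` naming the first bad step.  If frames carry
    replica ids they are cross-checked against the replay.
    """
    n_states = len(per_state_frames)
    _validate_log(exchange_log, n_states, swap_interval)
    checkpoints = list(_replay(exchange_log, n_states))
    out: list[list[Frame]] = [[] for _ in range(n_states)]
    ci = 0
    mapping = list(range(n_states))
    n_frames = {len(s) for s in per_state_frames}
    if len(n_frames) > 1:
        raise DemuxError("per-state streams have unequal frame counts")
    for fi in range(n_frames.pop() if n_frames else 0):
        sweep = per_state_frames[0][fi].sweep
        while ci < len(checkpoints) and checkpoints[ci][0] <= sweep:
            mapping = checkpoints[ci][1]
            ci += 1
        for k in range(n_states):
            frame = per_state_frames[k][fi]
            if frame.sweep != sweep:
                raise DemuxError(f"inconsistent frame sweeps at step {frame.sweep}")
            rid = mapping[k]
            if frame.replica_id >= 0 and frame.replica_id != rid:
                raise DemuxError(
                    f"log inconsistent with frames at step {sweep}: "
                    f"rung {k} expected replica {rid}, found {frame.replica_id}")
            out[rid].append(Frame(sweep=sweep, replica_id=rid,
                                  payload=frame.payload))
    return out


def remux(per_replica_frames: Sequence[Sequence[Frame]],
          exchange_log: Sequence[ExchangeAttempt],
          swap_interval: int | None = None) -> list[list[Frame]]:
    """Inverse of :func:`demux`: rebuild per-rung streams from replica paths."""
    n_states = len(per_replica_frames)
    _validate_log(exchange_log, n_states, swap_interval)
    checkpoints = list(_replay(exchange_log, n_states))
    out: list[list[Frame]] = [[] for _ in range(n_states)]
    ci = 0
    mapping = list(range(n_states))
    n_frames = {len(s) for s in per_replica_frames}
    if len(n_frames) > 1:
        raise DemuxError("per-replica streams have unequal frame counts")
    for fi in range(n_frames.pop() if n_frames else 0):
        sweep = per_replica_frames[0][fi].sweep
        while ci < len(checkpoints) and checkpoints[ci][0] <= sweep:
            mapping = checkpoints[ci][1]
            ci += 1
        for k in range(n_states):
            rid = mapping[k]
            frame = per_replica_frames[rid][fi]
            out[k].append(Frame(sweep=frame.sweep, replica_id=rid,
                                payload=frame.payload))
    return out
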