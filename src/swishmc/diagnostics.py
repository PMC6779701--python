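"""Replica-exchange health metrics and error estimation.

Adequate mixing across the lambda ladder is what justifies trusting the
unscaled-rung ensemble: each replica should visit every rung (uniform
occupancy in the long run) and complete round trips between the bottom
and top rungs.  This module counts exchange acceptances per adjacent
pair, per-replica rung occupancy and full min->max->min round trips from
the exchange log, and provides block averaging for error bars on
trajectory observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sampler import DemuxError, ExchangeAttempt, _replay, _validate_log

__all__ = [
    "ExchangeSummary",
    "block_average",
    "chisquare_vs_expected",
    "summarize_exchanges",
]

#: below this global mean acceptance the ladder is probably too coarse
LOW_ACCEPTANCE_WARNING = 0.1


@dataclass
class ExchangeSummary:
    """Counts derived from an exchange log."""

    attempts: np.ndarray          # (n_pairs,) attempts per adjacent pair
    acceptances: np.ndarray       # (n_pairs,)
    occupancy: np.ndarray         # (n_replicas, n_states) intervals spent
    round_trips: np.ndarray       # (n_replicas,) full min->max->min traversals
    n_replicas: int
    warnings: list[str] = field(default_factory=list)

    @property
    def acceptance_fractions(self) -> np.ndarray:
        """Per-pair acceptance fraction; NaN where nothing was attempted."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0,
                            self.acceptances / np.maximum(self.attempts, 1),
                            np.nan)

    @property
    def mean_acceptance(self) -> float:
        total = self.attempts.sum()
        return float(self.acceptances.sum() / total) if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "attempts": self.attempts.tolist(),
            "acceptances": self.acceptances.tolist(),
            "acceptance_fractions": [
                None if np.isnan(x) else float(x)
                for x in self.acceptance_fractions],
            "mean_acceptance": None if np.isnan(self.mean_acceptance)
            else self.mean_acceptance,
            "occupancy": self.occupancy.tolist(),
            "round_trips": self.round_trips.tolist(),
            "warnings": list(self.warnings),
        }


def summarize_exchanges(exchange_log, n_replicas: int,
                        acceptance_warning: float = LOW_ACCEPTANCE_WARNING
                        ) -> ExchangeSummary:
    """Exact counting of attempts, occupancy and round trips from a log.

    Accepts :class:`~swishmc.sampler.ExchangeAttempt` records or
    equivalent ``(step, (i, j), delta, accepted)`` tuples; malformed rows
    raise :class:`~swishmc.sampler.DemuxError` with their position.
    """
    log: list[ExchangeAttempt] = []
    for n, row in enumerate(exchange_log, start=1):
        try:
            e = ExchangeAttempt(step=int(row[0]),
                                pair=(int(row[1][0]), int(row[1][1])),
                                delta=float(row[2]), accepted=bool(row[3]))
        except (TypeError, ValueError, IndexError) as exc:
            raise DemuxError(f"malformed exchange log row {n}: {row!r}") from exc
        log.append(e)
    _validate_log(log, n_replicas, None)

    n_pairs = max(n_replicas - 1, 0)
    attempts = np.zeros(n_pairs, dtype=int)
    acceptances = np.zeros(n_pairs, dtype=int)
    for e in log:
        attempts[e.pair[0]] += 1
        if e.accepted:
            acceptances[e.pair[0]] += 1

    occupancy = np.zeros((n_replicas, n_replicas), dtype=int)
    round_trips = np.zeros(n_replicas, dtype=int)
    # milestone per replica: 0 = needs bottom, 1 = needs top, 2 = needs bottom again
    milestone = np.zeros(n_replicas, dtype=int)
    state_of = np.arange(n_replicas)

    def _credit():
        for r in range(n_replicas):
            k = state_of[r]
            occupancy[r, k] += 1
            if milestone[r] == 0 and k == 0:
                milestone[r] = 1
            elif milestone[r] == 1 and k == n_replicas - 1:
                milestone[r] = 2
            elif milestone[r] == 2 and k == 0:
                round_trips[r] += 1
                milestone[r] = 1

    _credit()  # the initial identity assignment counts as one interval
    for _, mapping in _replay(log, n_replicas):
        inv = np.empty(n_replicas, dtype=int)
        for k, r in enumerate(mapping):
            inv[r] = k
        state_of = inv
        _credit()

    warnings = []
    mean_acc = (acceptances.sum() / attempts.sum()) if attempts.sum() else None
    if mean_acc is not None and mean_acc < acceptance_warning:
        warnings.append(
            f"mean exchange acceptance {mean_acc:.3f} below {acceptance_warning}")
    return ExchangeSummary(attempts=attempts, acceptances=acceptances,
                           occupancy=occupancy, round_trips=round_trips,
                           n_replicas=n_replicas, warnings=warnings)


def block_average(series, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and standard error from contiguous block means.

    The series is split into ``n_blocks`` equal contiguous blocks (any
    remainder at the end is dropped); the standard error is the sample
    standard deviation of the block means divided by sqrt(n_blocks), a
    standard guard against serial correlation.
    """
    x = np.asarray(list(series), dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} is too short for "
                         f"{n_blocks} blocks")
    blen = len(x) // n_blocks
    blocks = x[:blen * n_blocks].reshape(n_blocks, blen).mean(axis=1)
    mean = float(blocks.mean())
    se = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
    return mean, se


def chisquare_vs_expected(counts, probs, min_expected: float = 5.0):
    """Chi-square goodness of fit with low-expectation bins pooled.

    Bins whose expected count falls below ``min_expected`` are merged
    into a single pooled bin before the test.  Returns ``(stat, pvalue)``.
    """
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    n = counts.sum()
    expected = n * probs
    keep = expected >= min_expected
    if keep.sum() < len(counts):
        c = np.append(counts[keep], counts[~keep].sum())
        e = np.append(expected[keep], expected[~keep].sum())
    else:
        c, e = counts, expected
    if len(c) < 2:
        raise ValueError("too few bins with adequate expected counts")
    stat, p = stats.chisquare(c, f_exp=e * (c.sum() / e.sum()))
    return float(stat), float(p)
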