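"""Scoring detector output against benchmark ground truth.

On a planted-deletion set the per-sequence classification follows the
benchmark protocol: a significant sequence counts as "within" when any of
its calls lies inside a closed +-window (default 50 nt) of the true
position, "outside" otherwise; power is the within fraction of the whole
set.  On a null set (no truth) only the significant count matters (type-I
behaviour).  The compensating-shift statistic pairs consecutive calls
whose phase changes cancel (sum = 0 mod 3) and reports their separation as
a fraction of sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ErrorRateReport", "CompensationReport", "score_against_truth", "compensation_distances"]


@dataclass(frozen=True)
class ErrorRateReport:
    n_sequences: int
    n_significant: int
    n_within: int
    n_outside: int
    total_shifts: int
    window: int

    @property
    def power(self) -> float:
        return self.n_within / self.n_sequences if self.n_sequences else 0.0

    @property
    def significant_rate(self) -> float:
        return self.n_significant / self.n_sequences if self.n_sequences else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_sequences": self.n_sequences,
                    "n_significant": self.n_significant,
                    f"within_{self.window}": self.n_within,
                    f"out_{self.window}": self.n_outside,
                    "total_shifts": self.total_shifts,
                    "power": round(self.power, 4),
                }
            ]
        )


@dataclass(frozen=True)
class CompensationReport:
    pairs: tuple  # (id, pos1, pos2, fraction)

    @property
    def fractions(self):
        return [p[3] for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["id", "pos1", "pos2", "fraction"])


def score_against_truth(results, truth: dict | None, window: int = 50) -> ErrorRateReport:
    """Tally significant / within / outside counts against planted positions.

    ``truth`` maps sequence id to the true indel position; pass ``None``
    for a null set.  Ids in results must be covered by truth when given.
    """
    n_sig = n_within = n_outside = total = 0
    for res in results:
        if not res.significant:
            continue
        n_sig += 1
        total += len(res.calls)
        if truth is None:
            continue
        if res.id not in truth:
            raise KeyError(f"no ground truth for sequence {res.id!r}")
        pos = truth[res.id]
        if any(abs(c.position - pos) <= window for c in res.calls):
            n_within += 1
        else:
            n_outside += 1
    return ErrorRateReport(
        n_sequences=len(results),
        n_significant=n_sig,
        n_within=n_within,
        n_outside=n_outside,
        total_shifts=total,
        window=window,
    )


def compensation_distances(results) -> CompensationReport:
    """Separations of consecutive compensating call pairs, per sequence.

    Two consecutive calls compensate when their phase changes sum to 0
    modulo 3 (the original reading frame is restored); each pair
    contributes |pos2 - pos1| / N.
    """
    pairs = []
    for res in results:
        calls = sorted(res.calls, key=lambda c: c.position)
        for a, b in zip(calls, calls[1:]):
            delta = (a.phase_after - a.phase_before) + (b.phase_after - b.phase_before)
            if delta % 3 == 0:
                pairs.append((res.id, a.position, b.position, abs(b.position - a.position) / res.N))
    return CompensationReport(pairs=tuple(pairs))
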