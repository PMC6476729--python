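"""Codon-shuffle null threshold V0 and frameshift calling.

For a sequence whose decomposition shows phase-shift evidence
(V2 + V3 > 0), a null set of codon-shuffled copies (the SR set) is built;
codon shuffling preserves the MT statistics exactly while destroying any
phase shift.  V0 is the smallest threshold such that at most
``allowed_exceedances`` null copies reach V2 + V3 >= V0 (2% of the set at
the default 20 / 1,000).  The sequence is called significant when its own
V2 + V3 reaches V0, and each gap event of its alignment whose length is
not a multiple of 3 becomes a frameshift call with the phase before/after.

Two modes are provided for scoring the null copies: ``fast`` re-aligns
each shuffle against the sequence's already-optimized matrix W1 (default);
``faithful`` runs the full GA optimization per shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .align import AlignmentResult, PhaseDecomposition, global_align, phase_decompose
from .ga import GAConfig, optimize
from .matrices import NormalizedWeightMatrix, derive_skip_matrices
from .sequence import CodingSequence, build_mt, shuffle_codons, tp_level_x

__all__ = [
    "SignificanceConfig",
    "FrameshiftCall",
    "SignificanceResult",
    "null_v23",
    "threshold_v0",
    "call_frameshifts",
    "analyze_sequence",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = (
    "id",
    "N",
    "X",
    "mFmax",
    "V1",
    "V2",
    "V3",
    "V0",
    "mode",
    "n_calls",
    "calls",
)


@dataclass(frozen=True)
class SignificanceConfig:
    """Null-set settings.

    When ``n_shuffles`` differs from 1,000 and ``allowed_exceedances`` is
    not given explicitly, the allowance is scaled to keep the 2% rate.
    """

    n_shuffles: int = 1000
    allowed_exceedances: int | None = None
    mode: str = "fast"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("fast", "faithful"):
            raise ValueError("mode must be 'fast' or 'faithful'")
        if self.allowed_exceedances is None:
            object.__setattr__(
                self,
                "allowed_exceedances",
                max(1, int(round(20 * self.n_shuffles / 1000))),
            )
        if not 0 < self.allowed_exceedances < self.n_shuffles:
            raise ValueError("need 0 < allowed_exceedances < n_shuffles")


@dataclass(frozen=True)
class FrameshiftCall:
    id: str
    position: int
    phase_before: int
    phase_after: int
    kind: str  # "ins" or "del"
    length: int


@dataclass
class SignificanceResult:
    id: str
    N: int
    X: float
    mfmax: float
    decomposition: PhaseDecomposition
    alignment: AlignmentResult
    v0: float | None
    significant: bool
    calls: list
    mode: str
    null_v23: np.ndarray | None = None

    def to_row(self) -> dict:
        calls = ";".join(
            f"{c.position}:{c.phase_before}>{c.phase_after}" for c in self.calls
        )
        dec = self.decomposition
        return {
            "id": self.id,
            "N": self.N,
            "X": round(self.X, 4),
            "mFmax": round(self.mfmax, 4),
            "V1": round(dec.V1, 4),
            "V2": round(dec.V2, 4),
            "V3": round(dec.V3, 4),
            "V0": "" if self.v0 is None else round(self.v0, 4),
            "mode": self.mode,
            "n_calls": len(self.calls),
            "calls": calls,
        }


def _v23_of_alignment(shuffled, w1, derived, d, h):
    aln = global_align(shuffled, w1, derived, d, h)
    return phase_decompose(aln, shuffled).v23


def null_v23(
    seq: CodingSequence,
    w1: NormalizedWeightMatrix,
    d: float,
    config: SignificanceConfig,
    ga_config: GAConfig | None = None,
    h: int = 50,
) -> np.ndarray:
    """V2+V3 of each codon-shuffled copy of ``seq`` (the SR null set)."""
    rng = np.random.default_rng(config.seed)
    derived = derive_skip_matrices(w1)
    out = np.empty(config.n_shuffles)
    for m in range(config.n_shuffles):
        shuffled = shuffle_codons(seq, int(rng.integers(0, 2**31 - 1)))
        if config.mode == "fast":
            out[m] = _v23_of_alignment(shuffled, w1, derived, d, h)
        else:
            sub_cfg = replace(ga_config, seed=int(rng.integers(0, 2**31 - 1)))
            _, aln, _ = optimize(shuffled, sub_cfg, d)
            out[m] = phase_decompose(aln, shuffled).v23
    return out


def select_v0(null: np.ndarray, allowed: int) -> float:
    """Smallest V0 with at most ``allowed`` null values >= V0.

    Walks the unique null values in ascending order; if even the maximum is
    exceeded by too many ties, V0 is the next representable value above it.
    """
    null = np.asarray(null, dtype=float)
    for v in np.unique(null):
        if int(np.sum(null >= v)) <= allowed:
            return float(v)
    return float(np.nextafter(null.max(), np.inf))


def threshold_v0(
    seq: CodingSequence,
    w1: NormalizedWeightMatrix,
    d: float,
    config: SignificanceConfig,
    ga_config: GAConfig | None = None,
    h: int = 50,
):
    """(V0, null distribution) for ``seq``; requires V2+V3 > 0 upstream."""
    null = null_v23(seq, w1, d, config, ga_config=ga_config, h=h)
    return select_v0(null, config.allowed_exceedances), null


def call_frameshifts(
    seq: CodingSequence,
    alignment: AlignmentResult,
    decomposition: PhaseDecomposition,
    v0: float | None,
) -> SignificanceResult:
    """Turn the alignment's gap events into frameshift calls if significant.

    Only events whose length is not a multiple of 3 change the TP phase and
    are reported.  Phases are the cyclically relabeled model-vs-codon
    classes of the aligned bases flanking the event.
    """
    v23 = decomposition.v23
    significant = v0 is not None and v23 >= v0
    calls = []
    if significant:
        rot = decomposition.rotation
        for ev in alignment.indels:
            if ev.length % 3 == 0:
                continue
            before = ev.rel_before if ev.rel_before is not None else ev.rel_after
            after = ev.rel_after if ev.rel_after is not None else ev.rel_before
            if before is None or after is None or before == after:
                continue
            calls.append(
                FrameshiftCall(
                    id=seq.id,
                    position=min(max(ev.position, 1), seq.N),
                    phase_before=(before - rot) % 3,
                    phase_after=(after - rot) % 3,
                    kind=ev.kind,
                    length=ev.length,
                )
            )
    return SignificanceResult(
        id=seq.id,
        N=seq.N,
        X=float("nan"),
        mfmax=decomposition.fmax,
        decomposition=decomposition,
        alignment=alignment,
        v0=v0,
        significant=significant,
        calls=calls,
        mode="",
    )


def analyze_sequence(
    seq: CodingSequence,
    ga_config: GAConfig,
    sig_config: SignificanceConfig,
    d: float | None = None,
    gap_table=None,
) -> SignificanceResult:
    """End-to-end analysis: optimize, align, decompose, threshold, call.

    The gap cost is taken from ``d`` if given, otherwise looked up in
    ``gap_table`` (a :class:`tpshift.calibrate.GapPenaltyTable`) at the
    sequence's TP level; the packaged default table is used when neither
    is supplied.
    """
    tp = tp_level_x(build_mt(seq))
    if d is None:
        if gap_table is None:
            from .calibrate import default_gap_table

            gap_table = default_gap_table()
        d = gap_table.lookup(tp.X)
    w1, alignment, state = optimize(seq, ga_config, d)
    decomposition = phase_decompose(alignment, seq)
    if decomposition.v23 <= 0.0:
        result = call_frameshifts(seq, alignment, decomposition, None)
        result.null_v23 = None
    else:
        v0, null = threshold_v0(
            seq, w1, d, sig_config, ga_config=ga_config, h=ga_config.h
        )
        result = call_frameshifts(seq, alignment, decomposition, v0)
        result.null_v23 = null
    result.X = tp.X
    result.mode = sig_config.mode
    return result
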