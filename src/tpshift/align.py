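"""Global path-dependent alignment, path rescoring and phase decomposition.

The global DP aligns a cds against the periodic 3-column model of a
normalized weight matrix, allowing at most ``h`` single-base gaps on either
side (gap cost ``d`` per unit, linear).  Each gap whose length is not a
multiple of 3 shifts the model phase relative to the codon frame -- the
signature of a reading frameshift.  The alignment score mass is decomposed
into V1/V2/V3 by the model-vs-codon phase class of every aligned base;
after a cyclic relabeling that makes V1 the largest class, V2+V3 measures
the evidence for phase shifts and V1+V2+V3 - k*d = Fmax exactly (k = gap
units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dp
from .matrices import DerivedMatrices, NormalizedWeightMatrix, TripletWeightMatrix
from .sequence import CodingSequence, codon_position

__all__ = [
    "Move",
    "IndelEvent",
    "AlignmentResult",
    "LocalAlignmentResult",
    "PhaseDecomposition",
    "global_align",
    "rescore_path",
    "local_align_wt",
    "phase_decompose",
    "dump_alignment",
]

_MOVE_NAMES = {_dp.MOVE_DIAG: "diag", _dp.MOVE_SKIP_S: "skip_s", _dp.MOVE_SKIP_MODEL: "skip_model"}


@dataclass(frozen=True)
class Move:
    """One alignment step: the move type and the cell (i, j) it enters.

    ``weight`` is the score delta applied (matrix weight for diagonal moves,
    -d for gaps) and ``matrix`` names the matrix it was read from.
    """

    move: int
    i: int
    j: int
    weight: float
    matrix: str


@dataclass(frozen=True)
class IndelEvent:
    """A merged run of gap units.

    ``kind`` is "ins" when sequence bases are left unaligned (the sequence
    carries extra bases relative to the model) and "del" when model columns
    are skipped.  ``position`` is the 1-based sequence position immediately
    left of the gap (clamped to 1).  ``rel_before``/``rel_after`` are the
    raw model-vs-codon phase classes of the aligned bases flanking the gap
    (None when the gap touches an alignment end).
    """

    position: int
    kind: str
    length: int
    rel_before: int | None
    rel_after: int | None


@dataclass
class AlignmentResult:
    fmax: float
    i_start: int
    i_end: int
    path: list  # list[Move]
    indels: list  # list[IndelEvent]
    model_index: np.ndarray  # a(i) per aligned S position, 0 where unaligned
    d: float
    h: int

    @property
    def gap_units(self) -> int:
        return sum(e.length for e in self.indels)


@dataclass(frozen=True)
class LocalAlignmentResult:
    emax: float
    i0: int
    j0: int
    imax: int
    jmax: int


@dataclass(frozen=True)
class PhaseDecomposition:
    """Score mass per phase class after cyclic relabeling (V1 largest)."""

    V1: float
    V2: float
    V3: float
    k: int  # gap units
    d: float
    fmax: float
    rotation: int  # raw phase class relabeled to V1

    @property
    def v23(self) -> float:
        return self.V2 + self.V3


def _model_pos(i: int) -> int:
    """a(i): 1, 2, 3, 1, 2, ... for i = 1, 2, 3, 4, 5, ..."""
    return (i - 1) % 3 + 1


def _walk(path, i_start, s, w2t, skip1, skip2, boundary, d):
    """Apply the scoring rules along an explicit path.

    Yields (move, weight, matrix_name) per step; raises on malformed paths.
    Maintains the same state the DP propagates: last aligned base and
    pending model-skip count.
    """
    ci, cj = i_start, 0
    lastk = 0
    vgap = 0
    for mv in path:
        if mv.move == _dp.MOVE_DIAG:
            if mv.i != ci + 1 or mv.j != cj + 1:
                raise ValueError(f"malformed path: diag into ({mv.i},{mv.j}) from ({ci},{cj})")
            ai = _model_pos(mv.i) - 1
            sj = int(s[mv.j - 1])
            if lastk == 0:
                w = boundary[ai, sj - 1]
                name = "boundary"
            else:
                n = int(s[lastk - 1]) + 4 * (sj - 1)
                q = vgap % 3
                if q == 0:
                    w, name = w2t[ai, n - 1], "w2t"
                elif q == 1:
                    w, name = skip1[ai, n - 1], "skip1"
                else:
                    w, name = skip2[ai, n - 1], "skip2"
            lastk = mv.j
            vgap = 0
            yield mv, float(w), name
        elif mv.move == _dp.MOVE_SKIP_S:
            if mv.i != ci or mv.j != cj + 1:
                raise ValueError(f"malformed path: skip_s into ({mv.i},{mv.j}) from ({ci},{cj})")
            yield mv, -d, "gap"
        elif mv.move == _dp.MOVE_SKIP_MODEL:
            if mv.i != ci + 1 or mv.j != cj:
                raise ValueError(
                    f"malformed path: skip_model into ({mv.i},{mv.j}) from ({ci},{cj})"
                )
            vgap += 1
            yield mv, -d, "gap"
        else:
            raise ValueError(f"unknown move code {mv.move}")
        ci, cj = mv.i, mv.j


def _matrices(w2t, derived):
    w = w2t.weights if isinstance(w2t, NormalizedWeightMatrix) else np.asarray(w2t, float)
    return (
        np.ascontiguousarray(w),
        np.ascontiguousarray(derived.skip1),
        np.ascontiguousarray(derived.skip2),
        np.ascontiguousarray(derived.boundary),
    )


def global_align(
    seq: CodingSequence,
    w2t: NormalizedWeightMatrix | np.ndarray,
    derived: DerivedMatrices,
    d: float,
    h: int = 50,
) -> AlignmentResult:
    """Global alignment of ``seq`` against the periodic model of ``w2t``.

    Returns the traceback path (with per-move weights), the merged indel
    events and Fmax = max F(N..N+h, N) (ties toward the smallest i).
    """
    if d <= 0:
        raise ValueError("gap cost d must be positive")
    if h < 0:
        raise ValueError("indel budget h must be non-negative")
    if seq.N < 3:
        raise ValueError("sequence shorter than one codon")
    if seq.N > _dp.MAX_N or h > _dp.MAX_H:
        raise ValueError(f"sequence length limited to {_dp.MAX_N} nt and h to {_dp.MAX_H}")
    w, s1, s2, bnd = _matrices(w2t, derived)
    s = seq.codes
    F, state = _dp.fill_global(s, w, s1, s2, bnd, float(d), int(h))
    N = seq.N
    i_end = N
    fmax = F[N, N]
    for i in range(N + 1, N + h + 1):
        if F[i, N] > fmax:
            fmax = F[i, N]
            i_end = i
    # traceback to column 0
    moves = []
    ci, cj = i_end, N
    while cj > 0:
        mv = (int(state[ci, cj]) >> 20) & 3
        if mv == _dp.MOVE_NONE:
            raise RuntimeError("traceback hit an unreachable cell")
        moves.append((mv, ci, cj))
        if mv == _dp.MOVE_DIAG:
            ci, cj = ci - 1, cj - 1
        elif mv == _dp.MOVE_SKIP_S:
            cj -= 1
        else:
            ci -= 1
    i_start = ci
    moves.reverse()
    bare = [Move(m, i, j, 0.0, "") for (m, i, j) in moves]
    path = [
        Move(mv.move, mv.i, mv.j, wt, name)
        for mv, wt, name in _walk(bare, i_start, s, w, s1, s2, bnd, float(d))
    ]
    model_index = np.zeros(N, dtype=np.int8)
    for mv in path:
        if mv.move == _dp.MOVE_DIAG:
            model_index[mv.j - 1] = _model_pos(mv.i)
    indels = _indel_events(path)
    return AlignmentResult(
        fmax=float(fmax),
        i_start=i_start,
        i_end=i_end,
        path=path,
        indels=indels,
        model_index=model_index,
        d=float(d),
        h=int(h),
    )


def _rel_class(i: int, j: int) -> int:
    """Raw phase class of a diagonal move: (codon_position(j) - a(i)) mod 3.

    Matches the TP-phase convention Fa: inserting n bases into the sequence
    shifts the class of downstream bases by +n mod 3.
    """
    return (codon_position(j) - _model_pos(i)) % 3


def _indel_events(path) -> list:
    """Merge adjacent gap units of one type into events with flanking phases."""
    events = []
    last_aligned = 0
    last_rel = None
    run_kind = None
    run_len = 0
    run_pos = 0
    run_rel_before = None

    def close(rel_after):
        if run_kind is not None:
            events.append(
                IndelEvent(
                    position=max(run_pos, 1),
                    kind=run_kind,
                    length=run_len,
                    rel_before=run_rel_before,
                    rel_after=rel_after,
                )
            )

    for mv in path:
        if mv.move == _dp.MOVE_DIAG:
            rel = _rel_class(mv.i, mv.j)
            if run_kind is not None:
                close(rel)
                run_kind = None
                run_len = 0
            last_aligned = mv.j
            last_rel = rel
        else:
            kind = "ins" if mv.move == _dp.MOVE_SKIP_S else "del"
            if run_kind != kind:
                if run_kind is not None:
                    # type change inside a gap run: split into two events
                    close(None)
                run_kind = kind
                run_len = 0
                run_pos = (mv.j - 1) if kind == "ins" else last_aligned
                run_rel_before = last_rel
            run_len += 1
    if run_kind is not None:
        close(None)
    return events


def rescore_path(
    seq: CodingSequence,
    w2t,
    derived: DerivedMatrices,
    d: float,
    path,
    i_start: int = 0,
) -> float:
    """Independent rescoring of an explicit path with the same matrix rules.

    Equals ``fmax`` for the traceback of :func:`global_align`.
    """
    w, s1, s2, bnd = _matrices(w2t, derived)
    return float(
        sum(wt for _, wt, _ in _walk(path, i_start, seq.codes, w, s1, s2, bnd, float(d)))
    )


def local_align_wt(
    seq: CodingSequence, wt: TripletWeightMatrix, d: float, h: int = 50
) -> LocalAlignmentResult:
    """Local alignment of ``seq`` against the periodic WT(3, 4) model.

    Standard floor-0 local DP.  Because the model is 3-periodic, the maximum
    is attained at many i offsets; ties are broken toward the smallest
    |i - j| (zero net model offset), then the smallest (i, j).
    """
    if d <= 0:
        raise ValueError("gap cost d must be positive")
    E, ptr = _dp.fill_local_wt(seq.codes, np.ascontiguousarray(wt.weights), float(d), int(h))
    emax = float(E.max())
    if emax <= 0.0:
        return LocalAlignmentResult(emax=0.0, i0=0, j0=0, imax=0, jmax=0)
    cand = np.argwhere(E == emax)
    order = np.lexsort((cand[:, 0], cand[:, 1], np.abs(cand[:, 0] - cand[:, 1])))
    imax, jmax = (int(v) for v in cand[order[0]])
    ci, cj = imax, jmax
    i0, j0 = ci, cj
    while ptr[ci, cj] != _dp.MOVE_NONE:
        i0, j0 = ci, cj
        mv = int(ptr[ci, cj])
        if mv == _dp.MOVE_DIAG:
            ci, cj = ci - 1, cj - 1
        elif mv == _dp.MOVE_SKIP_S:
            cj -= 1
        else:
            ci -= 1
    return LocalAlignmentResult(emax=emax, i0=i0, j0=j0, imax=imax, jmax=jmax)


def phase_decompose(result: AlignmentResult, seq: CodingSequence) -> PhaseDecomposition:
    """Attribute the diagonal score mass to the three phase classes.

    Classes are cyclically relabeled so V1 is the largest; the identity
    V1 + V2 + V3 - k*d = Fmax holds exactly by construction.
    """
    v = np.zeros(3)
    k = 0
    for mv in result.path:
        if mv.move == _dp.MOVE_DIAG:
            v[_rel_class(mv.i, mv.j)] += mv.weight
        else:
            k += 1
    rot = int(np.argmax(v))
    v1, v2, v3 = v[rot], v[(rot + 1) % 3], v[(rot + 2) % 3]
    return PhaseDecomposition(
        V1=float(v1), V2=float(v2), V3=float(v3), k=k, d=result.d, fmax=result.fmax, rotation=rot
    )


def dump_alignment(result: AlignmentResult) -> str:
    """Debug dump: one line per move (type, i, j, matrix, weight)."""
    lines = ["move\ti\tj\tmatrix\tweight"]
    for mv in result.path:
        lines.append(
            f"{_MOVE_NAMES[mv.move]}\t{mv.i}\t{mv.j}\t{mv.matrix}\t{mv.weight:.6f}"
        )
    return "\n".join(lines) + "\n"
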