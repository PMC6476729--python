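"""Generators for the benchmark sets used in calibration and testing.

A sequence "at TP level X" is sampled base-by-base from three per-codon-
position base profiles.  A random profile is drawn per position and mixed
with the uniform profile; the mixing weight is solved by bisection so the
*expected* MT count matrix of the sequence has TP level X.  Benchmark
kinds:

* ``RN`` -- codon-shuffled copies of source cds (null set, no phase shift);
* ``RD`` -- codon-shuffled copies of sources longer than 500 nt with one
  planted single-base deletion at least 100 nt from both ends;
* ``MP`` -- generated sequences at a target TP level with one planted
  single-base deletion (gap-penalty calibration sets);
* ``Gr`` -- 400 random + 400 periodic (X = 6.2) + 400 random nt
  (local-alignment boundary sets for the K0 calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import (
    CodingSequence,
    codon_position,
    shuffle_codons,
    tp_level_from_expected,
)

__all__ = [
    "PeriodicModel",
    "replace_stop_codons",
    "BenchmarkMember",
    "BenchmarkSet",
    "generate_tp_sequence",
    "plant_indel",
    "make_benchmark_set",
]

GR_BLOCK = 400
GR_PERIODIC_X = 6.2


@dataclass(frozen=True)
class PeriodicModel:
    """Per-codon-position base profiles defining a periodic source.

    ``profiles[i-1, b-1]`` is the probability of base code b at codon
    position i.  ``lam`` is the contrast (mixing weight with the uniform
    profile) that realises the target TP level.
    """

    profiles: np.ndarray  # (3, 4), rows sum to 1
    lam: float
    target_x: float

    def expected_mt(self, length: int) -> np.ndarray:
        """Expected MT(3, 4) counts of a sampled sequence of this length."""
        pos_counts = np.array([len(range(i, length, 3)) for i in range(3)], dtype=float)
        return self.profiles * pos_counts[:, None]

    def expected_m16(self, length: int) -> np.ndarray:
        """Expected M(3, 16) counts (adjacent positions are independent)."""
        counts = np.zeros((3, 16))
        prev_of = {1: 3, 2: 1, 3: 2}
        for col in (1, 2, 3):
            n_slots = sum(1 for j in range(2, length + 1) if codon_position(j) == col)
            pf = self.profiles[prev_of[col] - 1]
            ps = self.profiles[col - 1]
            pair = np.outer(ps, pf).reshape(-1)  # n-1 = (first-1) + 4*(second-1)
            counts[col - 1] = n_slots * pair
        return counts

    def stationary(self) -> np.ndarray:
        """Overall base composition: mean of the three position profiles."""
        return self.profiles.mean(axis=0)

    def sample(self, length: int, rng: np.random.Generator, id: str = "tp") -> CodingSequence:
        codes = np.empty(length, dtype=np.int8)
        for i in range(3):
            idx = np.arange(i, length, 3)
            codes[idx] = rng.choice(4, size=idx.size, p=self.profiles[i]) + 1
        return CodingSequence(id=id, codes=codes)


def _mix(raw: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * 0.25 + lam * raw


def _model_for_target(length, target_x, rng, max_redraws=50):
    best_attainable = -np.inf
    for _ in range(max_redraws):
        # concentration 0.5 gives contrasty profiles; the uniform mixing
        # weight lam dilutes them down to any weaker target level
        raw = rng.dirichlet(np.full(4, 0.5), size=3)
        if target_x <= 0.0:
            return PeriodicModel(profiles=_mix(raw, 0.0), lam=0.0, target_x=target_x)

        def x_of(lam):
            model = _mix(raw, lam)
            pos_counts = np.array([len(range(i, length, 3)) for i in range(3)], float)
            return tp_level_from_expected(model * pos_counts[:, None])

        x_hi = x_of(1.0)
        best_attainable = max(best_attainable, x_hi)
        if x_hi < target_x:
            continue  # this draw is too weak; redraw the profile
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if x_of(mid) < target_x:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
        return PeriodicModel(profiles=_mix(raw, lam), lam=lam, target_x=target_x)
    raise ValueError(
        f"target TP level X={target_x} unreachable at length {length}; "
        f"best attainable over redraws was X={best_attainable:.2f}"
    )


def generate_tp_sequence(length: int, target_x: float, seed: int, id: str = "tp"):
    """Sample a sequence whose expected MT has TP level ``target_x``.

    Returns ``(CodingSequence, PeriodicModel)``.  Profiles too weak to
    reach the target at this length are redrawn; a genuinely unreachable
    target raises with the best attainable level.
    """
    if length < 60:
        raise ValueError("length must be at least 60 nt")
    if target_x < 0:
        raise ValueError("target TP level must be non-negative")
    rng = np.random.default_rng(seed)
    model = _model_for_target(length, target_x, rng)
    return model.sample(length, rng, id=id), model


def plant_indel(
    seq: CodingSequence, kind: str, length: int, min_margin: int, seed: int
):
    """Plant one indel at a uniform position respecting the end margins.

    ``kind`` is "del" (remove ``length`` bases starting at the returned
    1-based position) or "ins" (insert ``length`` random bases after it).
    Returns ``(mutated_sequence, position)``.
    """
    if kind not in ("del", "ins"):
        raise ValueError("kind must be 'del' or 'ins'")
    if seq.N <= 2 * min_margin + length:
        raise ValueError("sequence too short for the requested margins")
    rng = np.random.default_rng(seed)
    lo = min_margin + 1
    hi = seq.N - min_margin - length  # inclusive
    pos = int(rng.integers(lo, hi + 1))
    if kind == "del":
        codes = np.delete(seq.codes, np.s_[pos - 1 : pos - 1 + length])
    else:
        ins = rng.integers(1, 5, size=length).astype(np.int8)
        codes = np.insert(seq.codes, pos, ins)
    return CodingSequence(id=seq.id, codes=codes), pos


#: stop codons as base-code triplets (taa, tag, tga)
_STOP_CODONS = {(2, 1, 1), (2, 1, 4), (2, 4, 1)}


def replace_stop_codons(seq: CodingSequence, from_position: int, seed: int):
    """Replace frame-0 stop codons at or after ``from_position`` (1-based).

    A frameshift typically creates premature stops downstream; this
    benchmark variant swaps each for a random coding (non-stop) codon.
    Returns ``(sequence, n_replaced)``.
    """
    rng = np.random.default_rng(seed)
    codes = seq.codes.copy()
    n_replaced = 0
    for start in range(0, 3 * (seq.N // 3), 3):
        if start + 1 < from_position:
            continue
        if tuple(int(c) for c in codes[start : start + 3]) in _STOP_CODONS:
            while True:
                cand = tuple(int(v) for v in rng.integers(1, 5, size=3))
                if cand not in _STOP_CODONS:
                    break
            codes[start : start + 3] = cand
            n_replaced += 1
    return CodingSequence(id=seq.id, codes=codes), n_replaced


@dataclass(frozen=True)
class BenchmarkMember:
    seq: CodingSequence
    truth: dict  # ground-truth annotation (position/kind/length, boundaries, model)


@dataclass(frozen=True)
class BenchmarkSet:
    kind: str
    members: tuple
    params: dict
    seed: int
    skipped: tuple = ()


def make_benchmark_set(
    kind: str,
    seed: int,
    sources=None,
    n_members: int = 100,
    length: int = 600,
    target_x: float = 6.2,
    min_margin: int = 100,
    replace_stops: bool = False,
) -> BenchmarkSet:
    """Build one of the RN / RD / MP / Gr benchmark sets (seed-reproducible).

    ``replace_stops`` applies the benchmark variant that swaps frame-0 stop
    codons downstream of a planted indel for random coding codons (RD and
    MP kinds only; by default frameshift-created stops are left in place).
    """
    rng = np.random.default_rng(seed)
    members = []
    skipped = []
    if kind == "RN":
        if sources is None:
            raise ValueError("RN needs source sequences")
        for src in sources:
            s = shuffle_codons(src, int(rng.integers(0, 2**31 - 1)))
            members.append(BenchmarkMember(seq=s, truth={}))
    elif kind == "RD":
        if sources is None:
            raise ValueError("RD needs source sequences")
        for src in sources:
            if src.N <= 500:
                skipped.append(src.id)
                continue
            s = shuffle_codons(src, int(rng.integers(0, 2**31 - 1)))
            mutated, pos = plant_indel(s, "del", 1, min_margin, int(rng.integers(0, 2**31 - 1)))
            if replace_stops:
                mutated, _ = replace_stop_codons(mutated, pos, int(rng.integers(0, 2**31 - 1)))
            members.append(
                BenchmarkMember(seq=mutated, truth={"position": pos, "kind": "del", "length": 1})
            )
    elif kind == "MP":
        for m in range(n_members):
            seq, model = generate_tp_sequence(
                length, target_x, int(rng.integers(0, 2**31 - 1)), id=f"mp{target_x:g}_{m}"
            )
            mutated, pos = plant_indel(
                seq, "del", 1, min_margin, int(rng.integers(0, 2**31 - 1))
            )
            if replace_stops:
                mutated, _ = replace_stop_codons(mutated, pos, int(rng.integers(0, 2**31 - 1)))
            members.append(
                BenchmarkMember(
                    seq=mutated,
                    truth={"position": pos, "kind": "del", "length": 1, "model": model},
                )
            )
    elif kind == "Gr":
        for m in range(n_members):
            sub = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
            model = _model_for_target(GR_BLOCK, GR_PERIODIC_X, sub)
            left = sub.integers(1, 5, size=GR_BLOCK).astype(np.int8)
            mid = model.sample(GR_BLOCK, sub).codes
            right = sub.integers(1, 5, size=GR_BLOCK).astype(np.int8)
            seq = CodingSequence(id=f"gr_{m}", codes=np.concatenate([left, mid, right]))
            members.append(
                BenchmarkMember(
                    seq=seq,
                    truth={"start": GR_BLOCK, "end": 2 * GR_BLOCK, "model": model},
                )
            )
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    params = {
        "n_members": len(members),
        "length": length,
        "target_x": target_x,
        "min_margin": min_margin,
    }
    return BenchmarkSet(
        kind=kind, members=tuple(members), params=params, seed=seed, skipped=tuple(skipped)
    )
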