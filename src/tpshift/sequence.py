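"""Coding-sequence representation, codon-position arithmetic and count matrices.

A coding sequence (cds) is held as a vector of integer base codes
(a=1, t=2, c=3, g=4).  Triplet periodicity (TP) is summarised either by the
classical ``MT(3, 4)`` matrix -- base counts per codon position -- or by the
richer ``M(3, 16)`` matrix of adjacent base-pair counts per codon-position
pair (columns 3-1, 1-2 and 2-3), which also captures the correlation of
neighbouring bases.  The TP strength of an ``MT`` matrix is expressed as a
standard-normal argument ``X`` derived from the mutual information between
base identity and codon position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

BASES = "atcg"
#: integer coding of the four bases: a=1, t=2, c=3, g=4
BASE_CODE = {b: i + 1 for i, b in enumerate(BASES)}
CODE_BASE = {i + 1: b for i, b in enumerate(BASES)}

#: dinucleotide row labels of M(3, 16), row n = first + 4*(second - 1)
PAIR_LABELS = tuple(BASES[(n - 1) % 4] + BASES[(n - 1) // 4] for n in range(1, 17))

__all__ = [
    "BASES",
    "BASE_CODE",
    "CODE_BASE",
    "PAIR_LABELS",
    "CodingSequence",
    "TripletCountMatrix",
    "DinucCountMatrix",
    "TPLevel",
    "sanitize",
    "codon_position",
    "phase_after_insertion",
    "build_mt",
    "build_m16",
    "tp_level_x",
    "shuffle_nucleotides",
    "shuffle_codons",
]


@dataclass(frozen=True)
class CodingSequence:
    """A validated nucleotide sequence over {a, t, c, g}.

    Attributes
    ----------
    id : str
        Record label.
    codes : numpy.ndarray
        Integer base codes (a=1, t=2, c=3, g=4), 1-based positions map to
        ``codes[j - 1]``.
    """

    id: str
    codes: np.ndarray

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int8)
        if codes.ndim != 1 or codes.size == 0:
            raise ValueError("sequence must be a non-empty 1-d base vector")
        if codes.min() < 1 or codes.max() > 4:
            raise ValueError("base codes must lie in 1..4 (a=1, t=2, c=3, g=4)")
        object.__setattr__(self, "codes", codes)

    @property
    def N(self) -> int:
        return int(self.codes.size)

    @property
    def bases(self) -> str:
        return "".join(CODE_BASE[int(c)] for c in self.codes)

    @classmethod
    def from_string(cls, seq: str, id: str = "seq") -> "CodingSequence":
        seq = seq.strip().lower()
        try:
            codes = np.fromiter((BASE_CODE[b] for b in seq), dtype=np.int8, count=len(seq))
        except KeyError as exc:
            raise ValueError(
                f"non-acgt symbol {exc.args[0]!r} in sequence {id!r}; sanitize first"
            ) from None
        return cls(id=id, codes=codes)

    def base_probabilities(self) -> np.ndarray:
        """Frequencies p(l) of the four bases, indexed by code-1."""
        q = np.bincount(self.codes, minlength=5)[1:5]
        return q / self.N


@dataclass(frozen=True)
class TripletCountMatrix:
    """MT(3, 4): base counts per codon position (rows: positions 1..3)."""

    counts: np.ndarray  # shape (3, 4)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 4) or counts.min() < 0:
            raise ValueError("MT must be a non-negative (3, 4) count matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def x(self) -> np.ndarray:
        """Row sums x(i): symbols per codon position."""
        return self.counts.sum(axis=1)

    @property
    def y(self) -> np.ndarray:
        """Column sums y(j): totals per base."""
        return self.counts.sum(axis=0)

    @property
    def L(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DinucCountMatrix:
    """M(3, 16): adjacent base-pair counts per codon-position pair.

    Column i (1..3) holds pairs whose second base sits at codon position i,
    i.e. the position pairs 3-1, 1-2 and 2-3.  Row n = first + 4*(second-1).
    Stored as ``counts[i - 1, n - 1]``.
    """

    counts: np.ndarray  # shape (3, 16)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 16) or counts.min() < 0:
            raise ValueError("M(3,16) must be a non-negative (3, 16) count matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TPLevel:
    """Triplet-periodicity level as a standard-normal argument.

    ``I`` is the mutual information (nats) between base identity and codon
    position in an MT matrix; ``2 L I`` is asymptotically chi-square with
    6 degrees of freedom and is mapped onto the standard-normal quantile X.
    """

    X: float
    I: float
    L: int


def sanitize(raw: str, seed: int, id: str = "seq"):
    """Replace every non-{a,t,c,g} symbol by a random base.

    Case is folded.  Returns ``(CodingSequence, replacements)`` where
    ``replacements`` is a list of ``(position_1based, original, substitute)``
    suitable for a sanitization log.
    """
    raw = raw.strip()
    if not raw:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed)
    chars = list(raw.lower())
    replacements = []
    for idx, ch in enumerate(chars):
        if ch not in BASE_CODE:
            sub = BASES[rng.integers(0, 4)]
            replacements.append((idx + 1, raw[idx], sub))
            chars[idx] = sub
    return CodingSequence.from_string("".join(chars), id=id), replacements


def codon_position(j: int) -> int:
    """Codon position (1, 2 or 3) of the 1-based sequence index ``j``.

    The arithmetic ``j - 3*int(j/3)`` yields 0 at multiples of 3; 0 is read
    as position 3 so that the M(3,16) columns mean 3-1, 1-2 and 2-3.
    """
    if j < 1:
        raise ValueError("positions are 1-based")
    return (j - 1) % 3 + 1


def phase_after_insertion(n: int) -> int:
    """TP phase Fa in {0,1,2} created by inserting ``n`` bases: n - 3*int(n/3)."""
    return n % 3


def build_mt(seq: CodingSequence) -> TripletCountMatrix:
    """Count bases per codon position: MT(i, b) over j = 1..N."""
    if seq.N < 3:
        raise ValueError("need at least one full codon")
    pos = np.arange(seq.N) % 3  # 0-based codon position
    counts = np.zeros((3, 4), dtype=np.int64)
    np.add.at(counts, (pos, seq.codes - 1), 1)
    return TripletCountMatrix(counts)


def build_m16(seq: CodingSequence) -> DinucCountMatrix:
    """Count adjacent base pairs per codon-position pair, j from 2 to N.

    For each j the cell (codon_position(j), s(j-1) + 4*(s(j) - 1)) is
    incremented; the total count is N - 1.
    """
    if seq.N < 2:
        raise ValueError("need at least two bases")
    s = seq.codes.astype(np.int64)
    j = np.arange(2, seq.N + 1)
    col = (j - 1) % 3  # 0-based codon position of j
    row = s[:-1] + 4 * (s[1:] - 1) - 1  # 0-based row n-1
    counts = np.zeros((3, 16), dtype=np.int64)
    np.add.at(counts, (col, row), 1)
    return DinucCountMatrix(counts)


# Wilson-Hilferty constants for chi-square with 6 df
_WH_K = 6.0
_WH_MU = 1.0 - 2.0 / (9.0 * _WH_K)
_WH_SD = np.sqrt(2.0 / (9.0 * _WH_K))


def _wilson_hilferty(chi2_value: float) -> float:
    return ((chi2_value / _WH_K) ** (1.0 / 3.0) - _WH_MU) / _WH_SD


def tp_level_x(mt: TripletCountMatrix) -> TPLevel:
    """TP level of an MT matrix as a standard-normal argument X.

    The mutual information I between codon position and base is computed
    over non-zero cells (0*ln 0 = 0); 2*L*I is treated as chi-square with
    6 df and mapped to the standard-normal quantile.  Where the exact
    quantile map saturates in floating point the Wilson-Hilferty cube-root
    approximation is used instead.
    """
    L = mt.L
    if L <= 0:
        raise ValueError("empty MT matrix")
    counts = mt.counts.astype(float)
    x = mt.x.astype(float)
    y = mt.y.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts * L / np.outer(x, y)
        logs = np.log(ratio, where=counts > 0, out=np.zeros_like(ratio))
        terms = np.where(counts > 0, counts / L * logs, 0.0)
    info = float(np.sum(terms))
    info = max(info, 0.0)
    chi = 2.0 * L * info
    X = float(stats.norm.isf(stats.chi2.sf(chi, 6)))
    if not np.isfinite(X):
        X = float(_wilson_hilferty(chi))
    return TPLevel(X=X, I=info, L=L)


def tp_level_from_expected(expected_mt: np.ndarray) -> float:
    """X of a real-valued expected MT matrix (used by generators/calibration)."""
    counts = np.asarray(expected_mt, dtype=float)
    L = counts.sum()
    x = counts.sum(axis=1)
    y = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts * L / np.outer(x, y)
        logs = np.log(ratio, where=counts > 0, out=np.zeros_like(ratio))
        terms = np.where(counts > 0, counts / L * logs, 0.0)
    info = max(float(np.sum(terms)), 0.0)
    chi = 2.0 * L * info
    X = float(stats.norm.isf(stats.chi2.sf(chi, 6)))
    if not np.isfinite(X):
        X = float(_wilson_hilferty(chi))
    return X


def shuffle_nucleotides(seq: CodingSequence, seed: int) -> CodingSequence:
    """Random permutation of the bases.

    A random key sequence of the same length is sorted and the memorised
    permutation is applied to the sequence, preserving base composition.
    """
    rng = np.random.default_rng(seed)
    keys = rng.random(seq.N)
    perm = np.argsort(keys, kind="stable")
    return CodingSequence(id=seq.id, codes=seq.codes[perm])


def shuffle_codons(seq: CodingSequence, seed: int) -> CodingSequence:
    """Uniformly permute the consecutive triplets of the sequence.

    Destroys any TP phase shift while preserving the codon multiset (and
    hence MT exactly).  If N is not divisible by 3 the trailing 1-2 bases
    stay in place.
    """
    if seq.N < 3:
        raise ValueError("need at least one full codon to shuffle")
    rng = np.random.default_rng(seed)
    k = seq.N // 3
    head = seq.codes[: 3 * k].reshape(k, 3)
    perm = rng.permutation(k)
    codes = np.concatenate([head[perm].reshape(-1), seq.codes[3 * k :]])
    return CodingSequence(id=seq.id, codes=codes)
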