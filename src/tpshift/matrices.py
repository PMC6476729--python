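"""Position-weight matrices for triplet-periodicity alignment.

The raw ``W2(3, 16)`` matrix is the standardized-residual (binomial z-score)
transform of a dinucleotide count matrix built from a nucleotide-shuffled
copy of the analysed sequence.  Every matrix entering the alignment is
affinely rescaled so that its sum of squares equals ``R0`` and its expected
per-step score equals ``K0``; this makes the alignment score comparable
across matrices, which is what lets the genetic algorithm use the raw
similarity ``Fmax`` as a fitness.  From the normalized matrix three derived
matrices are computed: two "skip" matrices scoring base pairs separated by
one or two model columns, and a 3x4 boundary matrix used for the first
aligned base, where no previous base exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sequence import PAIR_LABELS, DinucCountMatrix, TripletCountMatrix

#: packaged defaults for the (R0, K0) normalization targets
R0_DEFAULT = 1050.0
K0_DEFAULT = -1.8

__all__ = [
    "R0_DEFAULT",
    "K0_DEFAULT",
    "WeightMatrix",
    "NormalizedWeightMatrix",
    "DerivedMatrices",
    "TripletWeightMatrix",
    "build_w2",
    "matrix_stats",
    "normalize_to",
    "derive_skip_matrices",
    "build_wt",
    "shift_wt_to_kd",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


@dataclass(frozen=True)
class WeightMatrix:
    """Raw 3x16 weight matrix with the base/pair probabilities it was built from."""

    weights: np.ndarray  # (3, 16)
    p: np.ndarray  # (4,) base probabilities
    p2: np.ndarray  # (16,) pair probabilities p2(n) = p(first) * p(second)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        p = np.asarray(self.p, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        if w.shape != (3, 16):
            raise ValueError("weights must be (3, 16)")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "p2", p2)


@dataclass(frozen=True)
class NormalizedWeightMatrix:
    """W2t: a 3x16 matrix rescaled to sum-of-squares R0 and expected score K0."""

    weights: np.ndarray  # (3, 16)
    p2: np.ndarray  # (16,)
    r0: float
    k0: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "p2", np.asarray(self.p2, dtype=float))
        r2, kd = matrix_stats(w, self.p2)
        if abs(r2 - self.r0) > 1e-6 * abs(self.r0) or abs(kd - self.k0) > 1e-6 * abs(self.k0):
            raise ValueError(
                f"matrix does not satisfy its normalization targets: "
                f"R2={r2:.6g} (target {self.r0}), Kd={kd:.6g} (target {self.k0})"
            )


@dataclass(frozen=True)
class DerivedMatrices:
    """Skip and boundary matrices derived from one normalized W2t.

    ``skip1``/``skip2`` score pairs separated by one/two skipped model
    columns (selected by the skip length q: q mod 3 = 1 -> skip1,
    q mod 3 = 2 -> skip2, q mod 3 = 0 -> the parent W2t itself);
    ``boundary`` (3x4) scores a base with no aligned predecessor.
    """

    skip1: np.ndarray  # (3, 16)
    skip2: np.ndarray  # (3, 16)
    boundary: np.ndarray  # (3, 4)


@dataclass(frozen=True)
class TripletWeightMatrix:
    """WT(3, 4): standardized-residual transform of an MT matrix."""

    weights: np.ndarray  # (3, 4)
    p_base: np.ndarray  # (4,) column marginals y(j)/L of the source MT


def build_w2(m2: DinucCountMatrix, p: np.ndarray, N: int) -> WeightMatrix:
    """Binomial z-score transform of a dinucleotide count matrix.

    W2(i, k) = (M2(i, k) - (N-1) p2(k)) / sqrt((N-1) p2(k) (1 - p2(k)))
    with p2(k) = p(first) p(second).  Cells whose pair probability is 0 or 1
    cannot be standardized and get weight 0 with a warning: such pairs can
    never be scored in the alignment of that sequence.
    """
    p = np.asarray(p, dtype=float)
    first = np.arange(16) % 4
    second = np.arange(16) // 4
    p2 = p[first] * p[second]
    counts = m2.counts.astype(float)
    total = float(N - 1)
    usable = (p2 > 0.0) & (p2 < 1.0)
    if not np.all(usable):
        warnings.warn(
            "pair probabilities of 0 or 1 encountered; those cells get weight 0",
            stacklevel=2,
        )
    w = np.zeros((3, 16))
    denom = np.sqrt(total * p2[usable] * (1.0 - p2[usable]))
    w[:, usable] = (counts[:, usable] - total * p2[usable]) / denom
    return WeightMatrix(weights=w, p=p, p2=p2)


def matrix_stats(weights: np.ndarray, p2: np.ndarray):
    """(R2, Kd) of a 3x16 matrix: sum of squares and expected per-step score.

    Kd weighs each cell by 1/3 (model-position probability) times the pair
    probability p2(k).
    """
    w = np.asarray(weights, dtype=float)
    r2 = float(np.sum(w * w))
    kd = float(np.sum(w * (np.asarray(p2, dtype=float) / 3.0)[None, :]))
    return r2, kd


def normalize_to(
    w: WeightMatrix, r0: float = R0_DEFAULT, k0: float = K0_DEFAULT
) -> NormalizedWeightMatrix:
    """Affine rescale w' = a*w + b (a > 0) so that (R2, Kd)(w') = (r0, k0).

    Kd is affine and R2 quadratic in (a, b); eliminating b = k0 - a*Kd
    leaves a quadratic in a whose positive root is taken.  A matrix that is
    constant (zero variance around its Kd) cannot be normalized.
    """
    weights = w.weights
    p2 = w.p2
    r2, kd = matrix_stats(weights, p2)
    sw = float(weights.sum())
    ncells = weights.size
    # a^2 (R2 - 2 Kd Sw + n Kd^2) + a (2 k0 Sw - 2 n k0 Kd) + n k0^2 - r0 = 0
    qa = r2 - 2.0 * kd * sw + ncells * kd * kd
    qb = 2.0 * k0 * sw - 2.0 * ncells * k0 * kd
    qc = ncells * k0 * k0 - r0
    if qa <= 0.0:
        raise ValueError("degenerate (constant) weight matrix cannot be normalized")
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0.0:
        raise ValueError("no real rescaling reaches the requested (R0, K0)")
    roots = ((-qb + np.sqrt(disc)) / (2.0 * qa), (-qb - np.sqrt(disc)) / (2.0 * qa))
    a = max(roots)
    if a <= 0.0:
        raise ValueError("no positive rescaling reaches the requested (R0, K0)")
    b = k0 - a * kd
    return NormalizedWeightMatrix(weights=a * weights + b, p2=p2, r0=r0, k0=k0)


def renormalize(weights: np.ndarray, p2: np.ndarray, r0: float, k0: float) -> np.ndarray:
    """normalize_to on a bare array; returns the rescaled (3, 16) array."""
    wm = WeightMatrix(weights=weights, p=np.zeros(4), p2=p2)
    return normalize_to(wm, r0, k0).weights


def derive_skip_matrices(w2t: NormalizedWeightMatrix | np.ndarray) -> DerivedMatrices:
    """Skip and boundary matrices of a normalized 3x16 matrix.

    skip1(x, i+4(l-1)) = 0.25 * sum_j (w(x, i+4(j-1)) + w(x, j+4(l-1))) / 2
    skip2(x, i+4(l-1)) = 0.0625 * sum_{j,k} (w(x, i+4(j-1)) + w(x, k+4(l-1))) / 2
    boundary(x, n)     = 0.25 * sum_i w(x, i+4(n-1))

    The pair (i)(l) separated by skipped columns is scored by averaging the
    intersecting adjacent pairs (i)(j) and (j)(l) (resp. (i)(j), (k)(l)).
    """
    w = w2t.weights if isinstance(w2t, NormalizedWeightMatrix) else np.asarray(w2t, float)
    # reshape (3, 16) -> (3, second, first): n - 1 = (first-1) + 4*(second-1)
    cube = w.reshape(3, 4, 4)
    sum_over_second = cube.sum(axis=1)  # (3, first): sum_j w(x, i + 4(j-1))
    sum_over_first = cube.sum(axis=2)  # (3, second): sum_j w(x, j + 4(l-1))
    skip1 = 0.25 * (sum_over_second[:, None, :] + sum_over_first[:, :, None]) / 2.0
    skip2 = 0.0625 * (
        4.0 * sum_over_second[:, None, :] + 4.0 * sum_over_first[:, :, None]
    ) / 2.0
    boundary = 0.25 * sum_over_first  # (3, 4) indexed by the base at position j
    return DerivedMatrices(
        skip1=skip1.reshape(3, 16), skip2=skip2.reshape(3, 16), boundary=boundary
    )


def build_wt(mt: TripletCountMatrix) -> TripletWeightMatrix:
    """Standardized-residual transform of an MT(3, 4) matrix (real-valued input ok).

    WT(i, j) = (MT(i, j) - L p(i, j)) / sqrt(L p(i, j) (1 - p(i, j))) with
    p(i, j) = x(i) y(j) / L^2.
    """
    counts = np.asarray(mt.counts if isinstance(mt, TripletCountMatrix) else mt, float)
    L = counts.sum()
    x = counts.sum(axis=1)
    y = counts.sum(axis=0)
    if L <= 0 or np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("MT matrix has a zero marginal; WT undefined")
    p = np.outer(x, y) / (L * L)
    w = (counts - L * p) / np.sqrt(L * p * (1.0 - p))
    return TripletWeightMatrix(weights=w, p_base=y / L)


#: default sum-of-squares target for a WT(3, 4): same per-cell magnitude as
#: a (3, 16) matrix at R0 (12/48 of the cells)
R0_WT_DEFAULT = R0_DEFAULT * 12.0 / 48.0


def shift_wt_to_kd(wt: TripletWeightMatrix, k0: float) -> TripletWeightMatrix:
    """Shift a WT matrix so its expected per-step score Kd equals k0.

    Kd = sum_{i,j} wt(i, j) * (1/3) * p_base(j); an additive constant c
    changes Kd by exactly c, so the shift is closed-form.
    """
    kd = float(np.sum(wt.weights * (wt.p_base / 3.0)[None, :]))
    return TripletWeightMatrix(weights=wt.weights + (k0 - kd), p_base=wt.p_base)


def normalize_wt_to(
    wt: TripletWeightMatrix, r0: float = R0_WT_DEFAULT, k0: float = K0_DEFAULT
) -> TripletWeightMatrix:
    """Affine rescale of a WT matrix to sum-of-squares r0 and per-step score k0.

    The same transform as :func:`normalize_to`, with the model-position
    weight 1/3 and the base probabilities of the source MT; it puts WT
    scores on the same per-cell magnitude as the (3, 16) matrices so one
    K0 is meaningful for both.
    """
    w = wt.weights
    pk = wt.p_base / 3.0  # (4,), summed over 3 positions gives total 1
    kd = float(np.sum(w * pk[None, :]))
    sw = float(w.sum())
    ncells = w.size
    qa = float(np.sum(w * w)) - 2.0 * kd * sw + ncells * kd * kd
    qb = 2.0 * k0 * sw - 2.0 * ncells * k0 * kd
    qc = ncells * k0 * k0 - r0
    if qa <= 0.0:
        raise ValueError("degenerate (constant) WT matrix cannot be normalized")
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0.0:
        raise ValueError("no real rescaling reaches the requested (R0, K0)")
    a = max((-qb + np.sqrt(disc)) / (2.0 * qa), (-qb - np.sqrt(disc)) / (2.0 * qa))
    if a <= 0.0:
        raise ValueError("no positive rescaling reaches the requested (R0, K0)")
    return TripletWeightMatrix(weights=a * w + (k0 - a * kd), p_base=wt.p_base)


def write_matrix_tsv(path, weights: np.ndarray, fmt: str = "%.6g") -> None:
    """Write a 3x16 matrix as a 16-row TSV with dinucleotide row labels.

    Dialect: header ``pair n 1 2 3``; rows ordered aa, ta, ca, ga, at, ...,
    gg (n = first + 4*(second-1)).
    """
    w = np.asarray(weights, dtype=float)
    with open(path, "w") as fh:
        fh.write("pair\tn\t1\t2\t3\n")
        for n in range(1, 17):
            vals = "\t".join(fmt % w[i, n - 1] for i in range(3))
            fh.write(f"{PAIR_LABELS[n - 1]}\t{n}\t{vals}\n")


def read_matrix_tsv(path) -> np.ndarray:
    """Read a matrix written by :func:`write_matrix_tsv`; returns (3, 16)."""
    w = np.zeros((3, 16))
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pair"):
            raise ValueError("not a matrix TSV (missing 'pair' header)")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"malformed matrix row: {line!r}")
            n = int(fields[1])
            if PAIR_LABELS[n - 1] != fields[0]:
                raise ValueError(f"row label {fields[0]!r} does not match n={n}")
            w[:, n - 1] = [float(v) for v in fields[2:]]
    return w
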