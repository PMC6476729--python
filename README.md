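# tpshift

Ab initio detection of potential reading frameshifts in protein-coding
nucleotide sequences (cds), using nothing but the sequence itself.

## The idea

Coding sequences carry *triplet periodicity* (TP): base usage depends on
the position within the codon. The classical summary is the matrix
MT(3, 4) of base counts per codon position; this package works with the
richer M(3, 16) matrix of adjacent base-*pair* counts classified by the
codon-position pair they span (3-1, 1-2, 2-3), which also captures the
correlation of neighbouring bases. An insertion or deletion of n bases
with n mod 3 ≠ 0 shifts the *phase* of this periodic structure at the
indel position: downstream of the event, codon position i corresponds to
matrix column i + Fa (cyclically), with Fa = n − 3·int(n/3).

The detector needs no training set. For each sequence S of length N it:

1. builds random 3×16 position-weight matrices from nucleotide shuffles of
   S (binomial z-scores, `W2(i,k) = (M2(i,k) − (N−1)p2(k)) /
   sqrt((N−1)p2(k)(1−p2(k)))`), each rescaled so that ΣW² = R0 = 1050 and
   the expected per-step score Kd = K0 = −1.8, which makes alignment
   scores comparable across matrices;
2. optimizes the matrix with a genetic algorithm whose fitness is the
   similarity Fmax of a global, gap-allowing alignment of S against the
   periodic 3-column model of the matrix
   (`F(i,j) = max(F(i−1,j−1) + W(a(i), n), F(i,j−1) − d, F(i−1,j) − d)`,
   with the dinucleotide row n = s(k) + 4(s(j)−1) read path-dependently
   from the previous aligned base k, and substitute matrices for skipped
   model columns);
3. splits the final alignment score into V1 + V2 + V3 − k·d = Fmax by the
   model-vs-codon phase class of every aligned base, relabelled so V1 is
   the largest class — V2 + V3 is the phase-shift evidence;
4. calls the shifts significant if V2 + V3 reaches V0, the threshold that
   at most 20 of 1,000 codon-shuffled copies of S (which preserve MT
   exactly but carry no phase shift) reach.

The gap cost d is calibrated per TP level of the analysed sequence
(weaker periodicity demands a larger penalty); a pre-computed d(X) table
ships with the package.

## Worked example

```python
from tpshift import (CodingSequence, GAConfig, SignificanceConfig,
                     analyze_sequence)

# {atg}x25 {tga}x25 == {atg}x50 with one base deleted at position 76
seq = CodingSequence.from_string("atg" * 25 + "tga" * 25, "toy")
res = analyze_sequence(
    seq,
    GAConfig(population_size=30, stagnation_window=10, seed=4),
    SignificanceConfig(n_shuffles=100, seed=5),
    d=40.0,
)
print(f"X={res.X:.2f} mFmax={res.mfmax:.1f} "
      f"V2+V3={res.decomposition.v23:.1f} V0={res.v0:.1f}")
for call in res.calls:
    print(f"shift at {call.position}: phase {call.phase_before} -> "
          f"{call.phase_after} ({call.kind})")
```

prints

```
X=10.00 mFmax=2071.0 V2+V3=1051.1 V0=807.6
shift at 76: phase 0 -> 2 (del)
```

The sequence's TP level X = 10.0 (a standard-normal argument; ~6 is a
typical real gene). The optimized alignment concentrates score in two
phase classes (V2+V3 = 1051.1), above the codon-shuffle threshold
V0 = 807.6, and places one deletion-type gap at position 76 — the planted
frameshift — where the TP phase changes from 0 to 2 (a 1-nt deletion
shifts the phase by −1 ≡ 2 mod 3).

Batch analysis from a shell:

```bash
tpshift analyze input.fasta calls.tsv --seed 1
tpshift translate calls.tsv input.fasta peptides.fasta
```

`analyze` writes one TSV row per cds (id, N, X, mFmax, V1, V2, V3, V0,
mode, calls); `translate` splits each called cds at its shift coordinates
and emits the alternative-frame peptides (> 60 nt subsequences, > 20 aa
peptides) for downstream homology searches.

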