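# Methods

This note records the model, the numerical conventions and the design
choices behind `tpshift`, at the level of detail a maintainer needs to
re-derive or deliberately change them.

## Model and statistics

**Sequence coding.** Bases are coded a=1, t=2, c=3, g=4; positions are
1-based and inclusive everywhere. The codon position of index j is
i = j − 3·int(j/3), with the value 0 read as position 3 so that the
columns of the pair-count matrix mean position pairs 3-1, 1-2, 2-3. The
M(3, 16) matrix is filled for j = 2..N with row n = s(j−1) + 4(s(j) − 1)
and column codon_position(j); its total is therefore N − 1, and the
idealized worked-example matrices for perfect repeats show one
boundary-affected column whose count is one less than the repeat count.

**TP level X.** The strength of triplet periodicity of an MT(3, 4) matrix
is the mutual information I between base identity and codon position
(natural log, 0·ln 0 = 0). 2·L·I is asymptotically chi-square with 6
degrees of freedom; X is the standard-normal quantile of its upper tail
(`norm.isf(chi2.sf(2LI, 6))`). Where the exact map saturates in floating
point — including 2LI = 0, whose exact image is −∞ — the Wilson–Hilferty
cube-root approximation is used, which pins the degenerate null value
near −5.0. Over nucleotide-shuffled 600-nt sequences the mean of X sits
in [−1, 1], which is the calibration sanity check the test suite runs.

**Weight matrices.** W2 is the binomial z-score transform of M(3, 16)
using the *total* pair count (N − 1) as the binomial size per cell, as the
construction prescribes, although each column holds only ≈(N−1)/3 pairs;
any constant inflation this causes is absorbed by the affine
normalization and does not affect alignment behaviour. Cells whose pair
probability is 0 or 1 (a base absent from the sequence) get weight 0 —
such pairs can never be scored. Every matrix entering an alignment is
affinely rescaled, w' = a·w + b with a > 0, to ΣW² = R0 = 1050 and
expected per-step score Kd = K0 = −1.8; eliminating b = K0 − a·Kd leaves
a quadratic in a whose positive root always exists when 48·K0² < R0 and
the matrix is not constant. The affine form is chosen because Kd is
affine and R² quadratic in (a, b), giving a closed-form solution. The
same transform is applied to WT(3, 4) matrices (target ΣW² = 1050·12/48,
so the per-cell magnitude matches), which is what makes one K0 meaningful
for both matrix shapes; the feasibility bound 12·K0² < R0 limits
candidate K0 to |K0| < 4.68 in the K0 calibration.

## The alignment recursion

The global DP aligns the sequence (j = 1..N) against a periodic model
(i = 1..N+h, a(i) cycling 1, 2, 3) with linear gap cost d per unit and a
hard budget of h = 50 gap units. The zero row and column are −10⁹
("minus infinity" that cannot overflow when d is added), except
F(0..h, 0) = 0, so the model may start at any offset up to h for free;
Fmax is the maximum of F(N..N+h, N), ties resolved toward the smallest i.

The diagonal weight is *path-dependent*: the dinucleotide row needs the
previous aligned sequence base k, which is read from the stored best
predecessor of the incoming cell — one pointer per cell, fixed at fill
time, a greedy Viterbi-like convention. After q skipped model columns the
next diagonal move is scored from the skip-1 matrix (q mod 3 = 1), the
skip-2 matrix (q mod 3 = 2) or the parent matrix (q mod 3 = 0); the two
skip matrices average intersecting adjacent-pair weights and, by
construction, the two averaging formulas collapse to the same matrix —
both are computed independently and the equality is exercised by the
nested-loop oracle test. The count of pending skipped columns is carried
unchanged across sequence-side gap moves. A path's first aligned base has
no predecessor and is scored from the 3×4 boundary matrix (the parent
matrix averaged over the previous base), indexed by s(j) alone.

Tie-breaking in the max is diagonal > gap-in-sequence > gap-in-model,
biasing toward gapless alignments. Gap moves are refused once a path has
spent h units, so an over-budget alignment degrades to gapless rather
than failing. Per-cell path state (last aligned base, pending skip count
mod 3, move, gap units) is packed into one int32, which caps N at
2¹⁸ − 1 nt and h at 511 — far beyond any cds — and keeps the fill
memory-bound; the kernels are numba-compiled.

Because the recursion is greedy it is not globally optimal over paths; an
exhaustive small-instance enumeration (N ≤ 15, h ≤ 2), scoring every
monotone path with the same rules via the independent `rescore_path`
walker, verifies that the DP's score is always attained by some explicit
path and reports how often enumeration finds a better one.

**Events and phases.** Runs of adjacent gap units of one type merge into
an indel event at the 1-based position immediately left of the gap.
The phase class of an aligned base is (codon_position(j) − a(i)) mod 3,
so planting n extra bases shifts downstream classes by +n mod 3, matching
Fa = n − 3·int(n/3). V1/V2/V3 are the diagonal score mass per class,
cyclically relabelled so V1 is largest; V1+V2+V3 − k·d = Fmax holds
exactly, with k the total gap units. Only events whose length is not a
multiple of 3 change phase and become frameshift calls.

## Genetic algorithm

Organisms are normalized matrices; fitness is Fmax against the analysed
sequence; the initial population comes from nucleotide shuffles of the
sequence itself. Each iteration: two parents chosen with
fitness-increasing probability (k = 4 tournament by default; roulette on
min-shifted fitness if `tournament_k=None`), a uniform half-and-half cell
mask produces one descendant, which replaces a tournament-chosen victim
(never the current best); then one-cell mutations — replacement by a
uniform [−5, +5] draw, the natural scale since normalized cells have rms
≈ 4.7 — are proposed to ~10% of the population. Two refinements make
desk-scale populations (~60) converge within roughly 10³ alignments
rather than the ~5·10⁵ of the full-scale procedure: mutations are
accepted only when they improve their organism, and two of the proposals
per iteration always target the current best organism. Both are config
switches (`greedy_mutation`, `mutate_best`); disabling them recovers
plain dynamics, under which a population of 60 shows no best-ever
improvement within 20 iterations and the stagnation rule fires
immediately. Modified organisms are re-normalized to (R0, K0) so fitness
stays comparable, and only they are re-aligned; a test checks the cache
equals a full recompute. The run stops when the best-ever fitness has not
improved by more than `improvement_tol` (default 0.5, ≲0.1% of typical
Fmax — chasing smaller gains doubles the runtime without changing any
call) for `stagnation_window` iterations, or at `max_iterations`.

## Significance

Codon shuffling preserves MT (and the within-codon columns of M(3, 16))
exactly while destroying phase shifts, so shuffled copies of the analysed
sequence are its natural null. V0 is the smallest value such that at most
`allowed_exceedances` of `n_shuffles` null V2+V3 values reach it (20 of
1,000 by default; the allowance scales to keep 2% when the set size
changes; a constant null distribution yields the next representable value
above it). If the sequence's own V2+V3 is 0 no null set is built and the
sequence is not significant. Null copies are scored in `fast` mode by
re-aligning each against the already-optimized W1 (default), or in
`faithful` mode by a full GA per shuffle; the mode is recorded in the
output. Fast mode is mildly anti-conservative — W1 was optimized on
the analysed sequence, inflating its own V2+V3 relative to shuffles
scored with a borrowed matrix — so per-sequence false-positive rates run
somewhat above the nominal 2% (5% in a 40-run desk-scale experiment on
codon-shuffled inputs); the type-I test bounds the rate with a small-
sample binomial envelope rather than asserting the nominal value.

## Calibrations

**d(X).** For each TP level x, 100 sequences of 600 nt are generated at
that level, each given one 1-nt deletion at least 100 nt from the ends,
and aligned against the *ideal* matrix of their generating model (the
z-score transform of the model's expected pair counts) over an ascending
d grid; the selected d is the smallest for which at most 5% of the
predicted indel events fall outside ±50 nt of the planted deletion, a d
producing no events at all not qualifying (the criterion would hold
vacuously). The grid is 2..58 step 2, 60..295 step 5, 300..800 step 25:
R0-normalized diagonal weights are O(10), so informative d values are
tens to hundreds, and low-TP levels genuinely need d of several hundred
before spurious phase excursions die out. The table is keyed by the mean
TP level *measured on the shifted calibration sequences* — the same
quantity the detector looks up at run time (a planted shift roughly
halves the measured level relative to the generation target). Lookup is
piecewise-linear with clamping. The packaged table
(`data/d_table.yaml`, 21 generation levels, n = 100, seed 0) records its
seeds, sizes and per-level rates; every level resolves on this grid, with
near-noise levels (generation targets ≤ 4) selecting d in the hundreds —
there the surviving events are the few strongest true detections, and the
large penalty simply makes the detector conservative for sequences with
little periodic signal.

**R0.** The sum of squared W2 weights of {atg}₄₀₀ under a load of 2.0
expected substitutions per nucleotide, realised as two full passes of
per-position uniform substitution (a substitution may restore the
original base; the construction does not define the operator, and any
load interpretation lands within a factor of ~2 of the packaged constant,
which the test asserts for the seed median).

**K0.** 500-sequence scale is reduced to 100 three-block sequences
(400 random + 400 periodic at X = 6.2 + 400 random). For each candidate
K0 the WT matrix of the periodic block's generating model is normalized
to that expected per-step score and locally aligned (floor-0 DP); the
objective |i0−400| + |j0−400| + |imax−800| + |jmax−800| is reported both
summed and as a per-sequence mean, since the aggregation of the reference
figure is ambiguous. Because the model is 3-periodic the local maximum is
degenerate in i; argmax ties are broken toward the smallest |i − j| (zero
net model offset), then the smallest (i, j), which makes the model-side
boundaries meaningful. The minimizing K0 on the grid is −2.0 with the
default seed, flanked by steeply worse endpoints, consistent with the
packaged default of −1.8.

## Synthetic data

A "sequence at TP level X" draws one Dirichlet(0.5) base profile per
codon position (concentration 0.5 gives contrasty draws so that high
targets stay reachable), mixes it with the uniform profile, and solves
the mixing weight by bisection so the *expected* MT of the sequence has
level X; bases are then sampled independently per position. Profiles too
weak for the target are redrawn (up to 50 times) before an error reports
the best attainable level. Benchmark sets: RN (codon shuffles of
sources), RD (codon shuffles of > 500-nt sources plus one 1-nt deletion
with 100-nt margins), MP(x) (generated at level x plus one deletion), Gr
(the three-block local-alignment sets). Every set is exactly reproducible
from (kind, parameters, seed).

What the generator does *not* emulate: real codon-usage bias and
dicodon/hexamer structure, GC heterogeneity along a gene, exon-intron
artifacts, or between-gene TP class mixtures. Passing the planted-shift
benchmarks therefore demonstrates the method's mechanics — matrix
optimization, phase-shift localisation, null calibration — under clean
period-3 signals of controlled strength, not its error rates on real
genomes.

## Problem sizes and runtime choices

The test suite and acceptance script run the method at desk scale: GA
population 60 with stagnation window 20 (toy examples use 12–30),
calibration sets of 100 sequences per level at 3 levels, null sets of
200–1,000 shuffles, and 100 planted-deletion fixtures for the recovery
experiment. A 600-nt alignment costs ~3.5 ms (numba, single core); one
end-to-end analysis runs in a few seconds. The published full-scale
procedure (population 500, ~9·10³ iterations, 10³ shuffles per gene,
whole genomes) is supported by the same code paths via the config
defaults but is not exercised by the tests.

## Known limitations

- The greedy path-dependent recursion can miss the globally optimal
  path; the enumeration test quantifies this on small instances.
- Fast-mode significance is anti-conservative (see above); faithful mode
  is exact to the method's definition but costs a GA run per shuffle.
- Shift positions carry ±(a few nt) uncertainty by construction — the
  gap can often be placed at several adjacent positions with equal score
  — and the ±50-nt scoring convention reflects that.
- Sequences shorter than ~200 nt rarely carry enough TP signal for the
  null threshold to resolve; the detector returns "not significant"
  rather than an error.
- A single matrix models one dominant TP pattern; genes whose 5' and 3'
  halves carry genuinely different codon usage can produce spurious
  phase-shift mass.
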