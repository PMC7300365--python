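# Methods

`phagehost` implements the phage–host ecology analysis used for urban
wastewater viromes: linking viral contigs to bacterial host genera through
CRISPR spacers, summarising the resulting bipartite infection network with
nestedness and modularity statistics, and describing the viral community
with diversity, ordination and core-set computations. Because the raw
sequencing data such analyses start from is not required here, a seeded
synthetic-data generator produces inputs with the same statistical
structure, with recorded ground truth for recovery testing.

## Spacer-based host assignment

A CRISPR spacer is a short sequence a bacterium excised from a phage that
once infected it. A spacer aligning to a viral contig therefore links the
contig to the spacer's source genus.

**Matching model.** Spacers are short (tens of bases), so matching is
full-length and ungapped: every placement of the spacer (or its reverse
complement) along a contig is scored by Hamming distance, and placements
with fewer than 2 mismatches are retained (`max_mismatch=1` by default).
`N` mismatches every base, including another `N`. Indels are not modelled;
the `gaps` field exists for interface fidelity and is always 0. Score
fields follow conventional ungapped DNA scoring: reward 1, mismatch
penalty 3, Karlin–Altschul parameters λ = 1.28, K = 0.46 (all
configurable); the E value uses the spacer length times the total number
of contig bases searched. Only the *rank order* of matches matters
downstream, and for full-length ungapped matches that order reduces to
fewest-mismatches-first for any sane constants.

**Host call.** Per contig, matches are ranked by highest bit score, lowest
E value, highest percent identity, longest alignment, and fewest
mismatches + gaps. Remaining ties break deterministically by genus name
then spacer id, which makes the assignment invariant to input order. The
top match's source genus is the predicted host.

**Clustering.** Spacer/repeat cluster-size statistics use greedy
incremental clustering in the CD-HIT style: longest sequence first (ties
by id), each sequence joining the first cluster whose representative
matches at or above the identity threshold (identical positions in the
best ungapped placement of the shorter within the longer, divided by the
shorter length), default threshold 0.90. Clustering is reported as a
statistic only; host assignment uses the unclustered spacers.

**Interaction matrix.** cell(genus, VC) = 1 iff at least one contig of
that virus cluster (VC) was assigned that genus. Labels are sorted;
all-zero margins cannot arise by construction.

## Bipartite network statistics

The matrix `A` has R genus rows and C virus-cluster columns, row degrees
`k_i`, column degrees `d_j`, `m` edges and fill `m/(R·C)`.

**NODF** (overlap and decreasing fill). For each unordered pair of rows
with strictly decreasing degrees, the pair score is the overlap of the
sparser row with the denser one relative to the sparser degree;
equal-degree pairs score 0; same over columns. NODF is the grand mean over
all `C(R,2) + C(C,2)` pairs, reported on the 0–1 scale by default
(`percent=True` for the 0–100 convention). The implementation is verified
against naive pair enumeration and against `vegan::nestednodf` in R.

**Nestedness temperature.** The matrix is packed (rows and columns sorted
by decreasing degree, ties by original index, then a deterministic
hill-climb over adjacent transpositions that accepts any temperature
reduction). Each cell maps to the unit square with the densest corner at
the origin. The isocline of perfect nestedness is the superellipse
`x^p + y^p = 1`, with `p` solved so the area on the origin side equals the
fill (the area is `Γ(1+1/p)² / Γ(1+2/p)`, monotone in `p`); this family
meets the axes at the far ends of the first row and column, matching
staircase matrices with full first margins. Unexpected cells — presences
outside the isocline, absences inside it — contribute their squared
distance from the isocline measured along the cell's main diagonal,
normalised by that diagonal's length in the square (the crossing is found
by bisection; it is unique because the isocline spans corner to corner).
T = 100·U/U_max with U the mean contribution over all R·C cells and
U_max = 0.04145, clamped to [0, 100]; N_NTC = (100 − T)/100. Completely
full or empty matrices have T = 0 by definition. The isocline
parameterisation and U_max are configuration constants of the calculator,
not empirical values.

**Barber modularity.** `Qb = (1/m)·Σ_ij (A_ij − k_i d_j/m)·[g_i = h_j]`
for row labels `g` and column labels `h`. The all-in-one partition is
exactly 0; k equal complete blocks give `1 − 1/k`.

**LP-BRIM optimiser.** Each restart runs label propagation (columns start
with unique labels; nodes in seeded random order adopt the label with
maximal summed adjacency among their neighbours) and then BRIM refinement
(rows reassigned to their additive-best module among modules holding at
least one column, then columns symmetrically, until Qb stalls; each sweep
is monotone non-decreasing). Two deliberate design choices where the
procedure is genuinely open:

- *Tie-breaking in label propagation is uniform-random per restart*
  (keeping the current label when it is among the maximal candidates,
  which guarantees convergence). A deterministic smallest-label rule
  collapses dense matrices into a single module, from which BRIM — which
  can merge but never split modules — cannot escape.
- *Each restart also refines from a random initial labelling* and keeps
  the better of the two results, since label propagation proposes only a
  narrow family of partitions on near-complete matrices.

With these choices the optimiser matches exhaustive partition search on
all tested matrices up to 4×4 with up to 3 modules. Published-style Qb
values should use ≥ 20 restarts; results from a stochastic optimiser are
reproducible only for a fixed seed.

**Null model.** The equiprobable null draws every cell i.i.d.
Bernoulli(fill); draws with an empty row or column are rejected and
redrawn up to a bound (default 100 attempts). At sparse fills an empty
margin is near-certain in every draw — at fill 0.01 on a study-scale
matrix no amount of redrawing helps — so past the bound the draw is
accepted as-is and the statistics are computed margin-tolerantly
(zero-degree rows and columns contribute nothing to any pair score or
modularity term), which is what the classic unconditional equiprobable
model prescribes. The test is one-sided
(structure exceeds null) with add-one smoothing:
`p = (1 + #{null ≥ observed})/(n_iterations + 1)`; z uses the null
ensemble's mean and sample standard deviation, and is reported as missing
when the null SD is 0. Inside null draws, Qb uses 5 restarts.

## Community metrics

Per sample: richness S, Gini-Simpson `1 − Σp_i²`, Shannon
`H = −Σ p_i ln p_i`, Pielou `J = H/ln S` (undefined for S = 1, reported
as NaN and skipped in means). Beta diversity is Bray-Curtis
`Σ|x−y|/Σ(x+y)` on raw counts — no rarefaction is applied, so unlike
Gini-Simpson it is not invariant to count rescaling. Ordination is
classical scaling (PCoA): double-centre `−½·J·D²·J`, eigendecompose, scale
eigenvectors by the square root of their eigenvalue; non-positive
eigenvalue axes are dropped (their magnitude logged) and each axis's sign
is fixed so its first nonzero loading is positive.

The location effect is tested with a distance-based permutation test
using the PERMANOVA pseudo-F
(`F = (SS_between/(g−1))/(SS_within/(n−g))` from squared distances), with
seeded label permutations and the add-one tail. This is the natural
distance-based reading of an "ANOVA on beta diversity"; the pseudo-F is
cross-checked against scikit-bio's PERMANOVA in the tests.

Set intersections follow UpSet semantics: each taxon counts toward
exactly one combination of locations — the set of locations it occurs in
(a location's taxon set is the union over its samples of taxa with
nonzero counts). The all-location combination is the core virome; the
sizes over all combinations partition the union. Core features keep a
feature iff its relative abundance strictly exceeds 0.25 % in at least
⌈0.75·n⌉ samples (strict `>` on abundance, `≥` on the ceiling-rounded
prevalence count).

## Synthetic data

A single root seed fans out to per-generator child seeds through
`numpy.random.SeedSequence.generate_state` (documented counter scheme), so
every artifact is independently reproducible and byte-identical across
runs.

- **Contigs**: i.i.d. bases at a target GC fraction, lengths uniform on
  [len_min, len_max]; defaults 1–5 kb, GC 0.5.
- **Spacers**: each genus owns a disjoint subset of contigs as its
  infecting phages; spacers are 32-bp excisions on a uniform strand with
  i.i.d. substitutions at the mutation rate; truth records source contig,
  position, strand and realised substitution count. Decoys are random
  sequences attributed to a genus but with no source contig. At mutation
  rate 0 with no decoys, host recovery is exact by construction (tested).
- **Nested matrices**: the staircase of a maximally nested community —
  row thresholds taken from the temperature calculator's own isocline at
  the target fill, adjusted minimally to hit the exact edge count with no
  empty margins; cells then flip independently at the noise rate (bounded
  regeneration, default 100 retries, on empty margins). Noiseless output
  has NODF 1 on square staircases with distinct fills and temperature
  below 5 (residual discretisation only).
- **Modular matrices**: planted (rows × cols) blocks, Bernoulli(p_within)
  inside and Bernoulli(p_between) outside, partition recorded.
- **Abundance tables**: log-normal taxon intensities (σ = 2 by default),
  multinomial sampling at fixed depth per sample. The planted core taxa
  (default 38, after the 38-taxon core virome of the 16-sample NYC survey
  design shipped as `NYC_LOCATIONS`) get one guaranteed read per sample —
  keeping column sums exactly at depth — and a +3 shift in log-mean
  intensity, so every site is dominated by the same ubiquitous taxa:
  high Gini-Simpson with low evenness and low between-sample Bray-Curtis,
  the regime reported for sewage viromes. Accessory taxa are masked to
  proper subsets of locations, which makes the planted core exactly
  recoverable by the set-intersection analysis.

What the generator does *not* emulate: read-level sequencing error,
assembly artefacts, chimeric contigs, compositional biases between
extraction protocols, overdispersion of a taxon's abundance across
samples beyond multinomial noise, and phages infecting multiple genera.
Passing recovery tests therefore demonstrates correctness of the analysis
machinery under the stated model, not robustness to every failure mode of
real metagenomes.

## Numerical choices and degenerate inputs

- Statistics require at least 2×2 matrices with no empty rows or columns;
  violations raise errors naming the offending labels.
- Temperature bisection runs 60 iterations (double precision); the
  isocline exponent is solved by Brent's method to 1e-10.
- BRIM stalls are detected at 1e-12; Qb of the single-module partition is
  exactly 0 up to float summation.
- All-zero samples, non-binary adjacency cells, conflicting mappings and
  negative counts are rejected with located error messages.
- Permutation p-values can never be 0 (add-one smoothing).

## Problem sizes

Default test and demonstration sizes (matrices up to ~20×40, 16-sample
tables at 50 000 reads, null ensembles of 150–1000 draws, 1000-pair
matcher oracles) are chosen so the whole suite and the acceptance script
each run in well under a minute on one CPU while still exercising every
statistic at study-like structure; all sizes are plain function arguments
and scale up directly.

## Known limitations

- The temperature calculator's packing refinement and isocline family are
  one concrete choice within the classic calculator's family; published
  temperatures from other implementations can differ by a few degrees on
  small matrices.
- LP-BRIM is a heuristic: Qb values on large matrices are lower bounds,
  comparable across runs only at fixed seed and restart count.
- Bray-Curtis on raw counts conflates depth differences with composition
  when inputs are not equal-depth.
- The spacer matcher is exact-search, quadratic in sequence length; it is
  meant for assembled contigs and spacer libraries, not raw reads.
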