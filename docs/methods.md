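# Methods

## The demographic model

Two populations A and B of constant diploid sizes N_A and N_B descend
from an ancestor of size N_anc that split T generations ago. Migration is
unidirectional and constant: under the `*_BtoA` direction, gene flow runs
forwards in time from B into A, which backwards in time means a lineage
currently in A moves to B at probability m_e per generation. Three nested
histories are supported: DIV (m_e = 0), MIG (no split; the two
populations are infinitely old) and the full 5-parameter IM. A pair of
lineages in a population of N diploids coalesces at rate 1/(2N) per
generation; mutations arrive on a lineage at rate μ·l per generation for
a block of l callable sites (infinite-sites within the block).

The data unit is the unphased heterospecific pair-block: the four
mutation types are het_a / het_b (heterozygous in one individual only),
het_ab (heterozygous in both) and fixed_diff (opposite homozygotes).
het_ab and fixed_diff are mutually exclusive on a single genealogy:
a block showing both fails the four-gamete criterion and is excluded from
tallies. Because the model assigns those configurations zero probability,
the retained probabilities already sum to one and no renormalisation is
performed.

## Exact bSFS probabilities

Instead of symbolic generating-function algebra, the engine augments the
lineage state graph of the 2+2-haplotype sample with one capped mutation
counter per type. States are (lineage configuration, counter vector);
a mutation on a lineage subtending (i, j) haplotypes increments the
counter of that branch type; counters saturate at k+1 (the ">k" cell) and
saturated axes absorb further mutations, so folded probabilities are
exact marginals rather than residuals. The resulting finite CTMC is
solved in two phases:

* structured phase (two demes, migration): the distribution at time T is
  the action of the matrix exponential of the generator on the initial
  state, computed by the scaling-and-squaring Taylor method of
  `scipy.sparse.linalg.expm_multiply` on the sparse generator
  (~17 lineage configurations × 256 counter states at the default kmax);
* split remap: at T all lineages move to the ancestral deme;
* ancestral phase: a phase-type absorption solve
  (sparse LU of the transient block) gives the counter distribution at
  the most recent common ancestor, which *is* the folded bSFS pmf.

MIG models skip the split and run the two-deme chain to absorption; this
requires migration to connect the demes toward the coalescing
configuration, so MIG with m_e = 0 is rejected with an explanatory error.
Internally all rates are scaled to units of 2·N_ref generations
(N_ref = N_A by default); a test asserts bit-level invariance to N_ref.
Numerical guards: total mass must be within 1e-8 of one, and any negative
cell beyond -1e-10 raises; failures of the linear-algebra phase raise
`EngineError` rather than returning truncated values.

Validation is three-way: an independent Monte-Carlo oracle (a numba event
loop over the structured coalescent, sharing no code with the engine) and
the msprime-based replicate simulator must both reproduce the pmf. The
"within 3 binomial SE per cell" criterion is applied with family-wise
calibration: over 256 cells the expected maximum |z| of a *correct*
implementation is already ≈ 3.2, so the tests allow at most five cells
between 3 and 4.5 SE (null expectation below one cell) and none beyond
4.5 SE.

## Blocks, windows, tallies

Coordinates are BED-style half-open 0-based everywhere; VCF positions are
converted on ingest. Pair-blocks are cut greedily left-to-right over the
intersection of the pair's callable intervals: a candidate block of
`block_length` jointly callable sites is emitted iff its physical span is
at most `block_span` and its missing/multiallelic counts are within the
caps; on any violation the start advances by one callable site and the
packer retries (deterministic, O(n), and independent per pair — adding a
third sample never changes an existing pair's blocks). Missing means
either member of the pair lacks a called genotype; multiallelic means
more than two alleles observed in the pair; both count against their caps
and are excluded from mutation-type counts. Four-gamete-violating blocks
are stored with a flag and dropped at tally time.

Windows are fixed numbers of pair-blocks consumed in order of start
position across all heterospecific pairs, shifted by a fixed step;
trailing partial windows are not emitted. The `windowsum` scope counts a
block once per window containing it.

Summary statistics from heterospecific blocks: per-taxon heterozygosity
H = (mean het sites per block)/l; divergence per block
d_xy = (0.5·(het_a+het_b+het_ab) + fixed_diff)/l (each heterozygous site
contributes half, averaging the two haplotype pairings of unphased data);
F_ST = (d_xy − H̄)/(d_xy + H̄) with H̄ the mean of the two
heterozygosities — the pairwise-difference (Hudson) form, chosen because
it reproduces the published worked rows exactly to three decimals.
Within-taxon π from conspecific pair-blocks is reported separately from
within-individual H because the two differ under inbreeding or structure.

## Filtering

`preprocess` applies a minimal, consistent filter set to variant and
invariant sites alike: non-SNP records are removed; SNPs within `snpgap`
bp (inclusive) of a non-SNP are removed; records below `min_qual` are
removed; per-sample read depth must lie in [min_depth,
max_depth_factor × that sample's mean coverage], applied both to variant
records (FORMAT/DP) and to the callable-region BEDs (depth column).
Defaults: min_qual 1, snpgap 2, min_depth 8, max_depth_factor 3. An
optional genotype-quality floor and optional read-balance INFO thresholds
are exposed but off by default, since no standard values exist for them.

## Inference

ln CL is the dot product of tally counts with per-configuration
log-probabilities; observed configurations with zero model probability
yield −∞ and are reported (they indicate four-gamete leakage or a kmax
mismatch), never clipped. Optimization runs Nelder–Mead on
log10-transformed parameters within bounds (positivity plus scale-free
steps; adaptive simplex for > 3 free parameters), starting at the
midpoint of the log-bounded box or at a seeded random point; stopping at
a relative ln CL tolerance of 1e-6 or 10,000 evaluations. Grids are
log-uniform for sizes; the migration axis contains 0 exactly and the
global estimate m̂_e itself, both required for the barrier statistic to
be defined. Gridsearch is exhaustive (no pruning), keeps the full
per-window surface, and breaks ties toward the lowest grid index,
reporting them.

## The barrier scan

Δ_B compares the best constrained fit (m ≤ m*, any grid N) with the best
fit at the global rate (m = m̂_e, any grid N); "≤" is inclusive and
thresholds are expressed as fractions {0, 0.2, 0.5} of m̂_e. Δ_B is
non-decreasing in the threshold (growing feasible set). Under MIG models
the complete-barrier threshold is refused: with no split and m_e = 0 the
demes never share ancestry. Barrier regions are maximal unions of
windows with Δ_B > 0 whose spans actually overlap in bp; step-adjacent
but non-overlapping windows stay separate. Per-window FPRs simulate
replicates at the locally best N with m fixed to m̂_e and T to T̂, at the
window's recombination rate, and report the fraction with Δ_B > 0
(default 100 replicates per window).

## Simulation

`simulate` wraps msprime; demographies are exported through demes graphs
(MIG histories use a root placed 4·10⁴·max(N) generations deep, far
beyond any coalescence time scale in the model). Windows are contiguous
runs of blocks sharing one recombining ancestry; distinct windows are
independent; everything is seed-reproducible. Within-block recombination
is deliberately permitted — the likelihood assumes none, and simulating
with it is how that bias is measured.

Measured at the background parameter point used throughout (sizes
5.49e5 / 1.415e6 / 9.279e5, T = 4.216e6 generations, m_e = 7.41e-7,
μ = 2.9e-9, l = 64, gene flow forwards from the large into the small
population — the orientation that reproduces the published
heterozygosities and d_xy): fitting the no-recombination likelihood to
data simulated with r_bp = 1.89e-8 (per-block ρ ≈ 7 at these sizes)
biases N_anc strongly downward, N_B upward and m_e downward. The ±2 SD
parametric-bootstrap CI is therefore a *variance-only* interval: the
coverage test runs at r_bp = 1e-9 (per-block ρ ≈ 0.4) where the
likelihood is near-well-specified, and the misspecification bias at
genome-average recombination is quantified by the scan's FPR calibration
instead — which shows it does not inflate the barrier false-positive
rate (mean per-window FPR of order 1% or less at the complete-barrier
threshold, recomputed by `scripts/acceptance.py` at every run).

## Selection density

The polygenic-barrier model places barrier loci uniformly at density ν
per bp, each with selection s against migrants. A window's reduction
depends only on its nearest flanking locus on each side; with
exponential nearest-locus distances the flank expectation is
E[g] = ∫₀^∞ e^(−u) g(u, a) du with a = σ/r_bp and gene-flow factor
g = u/(u+a) (the standard linked-barrier form d/(d+s); pluggable), so
m_e/m = E[g]² depends only on σ/r_bp. The expectation is evaluated by
adaptive quadrature split at the scale of a (cross-checked against the
closed form 1 − a·eᵃ·E₁(a) and a dense-grid oracle to 1e-8). Coding
density optionally rescales σ per window, proportionally by default
(more coding sequence ⇒ denser barrier targets); an inverse switch is
provided because either reading of "scaling ν by CDS density" is
defensible. Fitting is deterministic Levenberg–Marquardt least squares
on log-parameters. Derived quantities: implied per-locus
s = σ·L/n_regions, and the drift bound on the number of loci
(σ/s_min)·L with s_min = 1/N_e by default (the convention consistent
with the published count; 1/(2N_e) gives exactly twice as many and is
available behind a flag), optionally also bounded by s > m.

## Synthetic data

The fixture generator renders simulated genotypes as standard VCF +
per-sample BED + genome/sample TSVs, laying windows on contigs separated
by uncallable gaps wider than the block span. Realism knobs: per-call
missingness, third-allele injection (multiallelic sites), low-QUAL
records, indel records (for the snpgap filter), per-sample depth and
low-depth holes. With all knobs at zero, the pipeline applied to the
rendered files reproduces the simulator's direct tallies exactly
(tested). What the fixtures do *not* emulate: linked selection, mutation
rate or recombination-rate heterogeneity along the genome, genotyping
error correlated with depth, reference bias, and repeat or annotation
masks — so green pipeline tests demonstrate correctness of the
bookkeeping and inference machinery under the model, not robustness to
real-data artefacts.

## Problem sizes

Tests and the acceptance script run at desk scale, the package's own
choice of sizes for routine verification: engine/oracle agreement at
2×10⁵ (unit) and 10⁶ (acceptance) blocks per parameter point; simulator
agreement at 1.5×10⁵–3×10⁵ blocks with a total-variation bound set at
1.5× the theoretical expectation of the binomial sampling error;
parameter recovery on 10⁶ independent blocks (three replicate fits);
scan calibration on 50 null windows of 100 blocks with 100 FPR
replicates each; ROC power with 200 replicates at window sizes 50 and
100; bootstrap coverage with 6 replicates of 40×250-block windows. The
full-scale analogues (10⁵ windows of 5×10⁴ blocks, 12×12×12×16 grids,
1000-replicate ROCs) use the identical code paths.

## Known limitations

One diploid individual per taxon per pair-block (larger samples enter
only through the composite likelihood over pairs); unidirectional
migration, constant rates, no phase information; no recombination inside
blocks in the likelihood (bias quantified, not corrected); composite
likelihood ignores linkage between blocks and pseudo-replication across
pairs, so all uncertainty comes from the parametric bootstrap, never
from the likelihood curvature.
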