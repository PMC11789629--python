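# Methods

## Coordinates and overlap semantics

All intervals are 0-based half-open (BED convention). Two intervals
overlap iff they share ≥ 1 bp; a fragment spanning k tiling bins is counted
in all k. This convention changes counts for boundary-spanning fragments
relative to midpoint assignment and is applied consistently in FRiP,
blacklist fractions, bin/peak matrices and promoter-window extraction.
Chromosome names are compared verbatim (no "chr1"/"1" aliasing). The
overlap engine counts, per query, subjects with `start < q.end` minus
subjects with `end <= q.start` on sorted endpoint arrays — O((n+m) log m)
and exactly equivalent to the all-pairs scan (property-tested).

## Per-cell QC

UMR is the number of deduplicated fragment records per barcode (fragments
are assumed deduplicated upstream). FRiP and blacklist fraction are the
fractions of a cell's fragments sharing ≥ 1 bp with the peak/blacklist
set. Two metrics have no printed definition in the protocol this package
follows, so the toolkit-standard forms are used and are config-overridable:

* **TSS enrichment** — mean per-bp fragment coverage in TSS ± 100 bp
  (aggregated over all genes) divided by mean per-bp coverage in the
  900–1000 bp flanks on both sides, with a one-fragment pseudocount in the
  denominator. Uniform coverage scores ≈ 1; a cell with no coverage in
  either window scores 0.
* **Nucleosome signal** — (# fragments of length 147–294 bp) /
  (# fragments < 147 bp + 1).

Exclusion applies the printed thresholds with strict inequalities exactly
(UMR < 1000, UMR > 100 000, FRiP < 0.25, blacklist > 0.01, nucleosome
signal > 5, TSS enrichment < 0.5); boundary values are kept; any missing
metric excludes the cell. Filtering is a pure per-cell function, hence
idempotent and order-independent.

## TF-IDF, LSI, pseudobulks, markers

TF(f,c) = count/colsum(c); IDF(f) = n_cells / n_cells-with-feature;
value = log(1 + TF·IDF·10⁴); features present in no cell get 0. LSI is a
truncated SVD computed with ARPACK and a seeded start vector, so the left
singular vectors are orthonormal to machine precision and runs are
reproducible; component 1 (depth-correlated in this data type) is dropped
by default. Pseudobulk depth equalization samples fragments without
replacement down to the smallest group total via the multivariate
hypergeometric distribution. Marker peaks use a one-vs-rest two-sided
Wilcoxon rank-sum on TF-IDF values with BH adjustment; peaks are ranked by
effect size (difference of group means) among significant peaks — the
ranking criterion was an open choice; effect size was chosen because the
top-N list feeds modules, where separation magnitude matters more than
p-value ordering. A raw-p cutoff (e.g. 0.005) is available by config.

## Chromatin-state segmentation

Binarization: a 200 bp bin is positive for a mark iff the upper-tail
Poisson p-value of its count under the mark's genome-wide mean rate is
< 10⁻⁴ (the segmentation tool's documented default; not restated in the
protocol). The HMM has K = 5 states, independent Bernoulli emissions per
mark, chromosomes as independent sequences. Baum–Welch runs from 10
seeded random initializations (Dirichlet start, diagonal-dominant random
transitions, U(0.1, 0.9) emissions), tolerance 10⁻⁶ on the log-likelihood,
max 500 iterations, with 10⁻⁶ floors on transitions/emissions to avoid
absorbing zeros; the best final likelihood wins. Decoding uses scaled
forward–backward posteriors (not Viterbi), argmax per bin, ties to the
lowest state index. The forward/backward/ξ recursions are numba-jitted;
the implementation is verified against exhaustive path enumeration
(≤ 12 bins, K ≤ 3, 10⁻¹⁰) and against an independent categorical-HMM
implementation on symbol-encoded observations.

States are labelled by thresholding each emission row at 0.5 per mark and
matching the canonical signatures (E1 = H3K4me3 only, E2 = both activating
marks, E3 = H3K27ac only, E4 = none, E5 = H3K27me3 only); non-canonical
signatures are labelled by their mark combination, duplicates suffixed
with a warning. The transition table between two conditions requires
identical tilings, excludes the E4→E4 cell from the reported table, and
reports the E4→E4 fraction separately.

## Gene integration

The promoter window is strand-oriented: 2000 bp upstream to 3000 bp
downstream of the TSS ("upstream" extends to larger coordinates for minus-
strand genes); windows leaving the chromosome are truncated with a
warning. The state category cascade: (i) with ≤ 2 promoter bins carrying
E1/E2/E3 the gene has no activating mark (heterochromatin if > 60 % of
bins are E5, else none); (ii) both marks if the modal state is E2 or the
E1:E3 balance among marked bins is within 40–60 % (the configured
"similar proportion" band); marked bins that are all E2 also count as both
marks; (iii) single mark if > 60 % of all promoter bins carry that one
state; (iv) otherwise none.

CN is the integer value of the segment containing the TSS (genes spanning
segment boundaries take the TSS-containing segment — an open choice,
fixed here), clamped into groups 1 / 2 / 3 / 4+. Expression Z-scores come
from library-size-normalized log2(x/s + 1) counts standardized per gene
across samples, replicate means collapsed per condition; this simplified
variance-stabilizing step replaces a fitted mean-dispersion transform,
which belongs to the (out-of-scope) RNA quantification stack. Median
(τ = 0.5) regression of Z on CN coded 2/3/4 is fit per state group
restricted to CN ≥ 2 (statsmodels QuantReg, IRLS; ties at the median
resolve at the solver's canonical vertex); the mean-Z difference between
CN = 4+ and CN = 2 is reported alongside. Transition–expression
enrichment classes genes up (log2FC > 1, p < 0.001) / down (log2FC < −0.5,
p < 0.001) and reports, per promoter-state transition and class, the odds
ratio with Fisher exact p and BH adjustment ("enrichment" was not pinned
down as OR vs proportion; OR chosen for its symmetry and exact test).

## Module scores and ternary gating

Modules are the top-50 marker peaks per condition. The raw deviation of
cell c for a module is d_c = (observed_c − E_c)/E_c with
E_c = cell total × module share of the grand total, making d scale-free in
depth. Backgrounds: peaks are stratified into deciles of total count and
each of 50 seeded background sets replaces every module peak with a random
same-stratum peak; Z_c standardizes d_c against the background deviations
(unbiased sd). GC-content matching used by the upstream deviation
framework is not applicable here (no sequence in the synthetic path); a
GC column can be supplied by config. Scores are computed on raw counts
(the deviation framework's expectation model assumes counts).

Ternary normalization: if any score in the cohort is negative, the
absolute value of the cohort-wide minimum is added to every score of every
cell (one constant, preserving between-cell ordering — the wording of the
shift rule leaves per-cell shifting open; a per-cell variant is available
by flag), then each cell's three scores are divided by their sum. Gating:
a cell is transitional iff both named coordinates strictly exceed 0.4; at
any threshold > 1/3 at most one two-axis gate can fire per cell. The
source description of the prePCR gate is internally inconsistent
(">0.4 Pri / <0.4 PCR" in one place, ">0.4 Pri and >0.4 PCR" in another);
the both-above form is the default because it is the one consistent with
the preMET gate, and the alternative is selectable by config. The
subpopulation report adds rank-sum confounder checks (UMR, FRiP vs the
remaining parent cells) and the ordering check remaining-parent <
transitional < progressed on the progressed module's mean score.

## Synthetic cohort

The generator inverts the fitted models. Defaults (all in
`SimulationConfig`): toy genome of 2 × 5 Mb chromosomes at 200 bp bins
(5 × 10⁴ bins) — small enough for minute-scale runs, large enough for
stable EM; a 5-state chain with a diagonal-dominant transition matrix
whose stationary distribution is ≈ 90 % unmodified (E4), emissions as in
the canonical state signatures; three conditions (PRI/MET/PCR) whose state
paths differ by re-drawing 2 % of bins; 300 cells/condition at Poisson
mean depth 3000; fragment lengths 60 % U(50, 120) / 40 % U(160, 250) bp so
the nucleosome-signal metric is exercised on both sides of its threshold;
per-condition modules of 50 disjoint 1 kb peaks with fragment-sampling
activity 8 (vs 1 for active states, 0.02 for E4), making each module the
dominant epigenetic signature of its condition — deliberately, since the
pipeline's question is whether module identity is recoverable per cell;
10 % of primary cells are planted transitional with a 50/50 mixture of the
PRI and PCR rate profiles; CN segments (~10 per chromosome, values 1–5,
diploid-dominant) multiply fragment rates by CN/2 and a deterministic
CN = 4 amplicon is planted for locus-level tests; half the genes are
placed at midpoints of active-state segments (so marks center on the TSS,
as at real promoters) and expression follows
Z = β₀ + β_CN(CN−2) + β_state·active + β_int(CN−2)·active + N(0, σ²)
with β_CN = β_int = 0.3, β_state = 0.5, σ = 0.5 over 2000 genes; replicate
counts are Poisson around 2^(base + Z). Planted QC-failure cells violate
one threshold each by ≥ 2× (depth 400 or 220 000; uniform-genome sampling
for low FRiP; 20 % blacklist fragments; mono-nucleosomal-only lengths;
flank-only placement for low TSS enrichment).

Effect sizes are chosen for testability of the pipeline's operating
characteristics and are not estimates of any real tumor's biology. The
generator omits sequencing error, doublets, batch effects, GC bias and
mappability structure; passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not robustness to those
real-data artifacts.

## Problem sizes and numerical choices

Default test/reproduction scale: 5 × 10⁴ bins, ~900 cells, ~3 × 10⁶
fragments, 2000 genes — chosen so the full suite runs in minutes on one
CPU. Posterior rows sum to 1 within 10⁻¹⁰; ternary coordinates within
10⁻¹²; transition rows within 10⁻¹². Degenerate inputs: all-identical
HMM observations warn and collapse to one effective state; zero-signal
marks produce all-zero binarized tracks with a warning; cells with zero
counts are excluded before TF-IDF; empty cells get missing deviation
scores and are excluded from gating; zero-variance genes are dropped from
Z-scoring with a count.

## Known limitations

* The Bernoulli-emission HMM ignores count magnitude beyond binarization.
* Background matching for deviation scores is accessibility-only.
* The simplified log2 transform under-stabilizes variance for very low
  counts relative to a fitted mean-dispersion transform.
* Joint multi-condition HMM fitting is supported by concatenating tracks,
  but the default workflow fits per landscape.
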