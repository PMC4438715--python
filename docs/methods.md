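# Methods

## Scope and design

`orthoscan` implements a three-species comparative selection scan as a
library of composable stages — sequence I/O and read filtering, all-vs-all
protein similarity search, 1:1:1 ortholog identification, codon-aware
pairwise alignment, dN/dS estimation, and filtering/calling/contrast — plus
a codon-model simulator that generates studies with known ground truth. The
public interface is the Python API (`orthoscan.run_pipeline` and the
per-stage functions) together with the narrative scripts in `examples/`;
there is no command-line entry point because every realistic use composes
stages programmatically.

## Simulator

Sequences evolve site-independently under a GY94 codon model on the 61 sense
codons of the standard code. Off-diagonal rates for single-nucleotide changes
are π_j · κ^[transition] · ω^[nonsynonymous]; multi-nucleotide changes have
rate 0. `gy94_rate_matrix` scales the generator to one expected substitution
per codon per unit time at stationarity and satisfies detailed balance;
transition kernels exp(Qt) are computed by symmetrized eigendecomposition.

**Branch-length scaling.** Within `simulate_study` each branch kernel is
rescaled so that the *synonymous* flux equals that of the ω = 1 model under
total-rate-1 scaling. Branch lengths are therefore "expected substitutions
per codon for a neutral gene", and an ω shift on a branch changes only its
nonsynonymous output — the natural reading of selection acting on fixation
probabilities, with the mutation input held fixed. Under per-branch
total-rate-1 scaling instead, a high-ω branch would emit *fewer* synonymous
substitutions per unit length, and the pairwise ω of a focal-shift gene
would be dragged far below the planted branch value; the synonymous scaling
makes the expected pairwise ω the branch-length-weighted mean of branch ω's.

**Default study conditions.** 200 genes per species; gene lengths log-uniform
over 150–600 codons (median 300 codons ≈ 900 bp, matching typical
transcriptome ortholog lengths); κ = 2; uniform codon frequencies (an F3×4
parameterization is available); classes neutral-low (ω = 0.1, 74%),
focal-shift (focal terminal branch ω = 1.5, elsewhere 0.1; 10%), all-high
(ω = 0.8, 10%), short (< 150 bp, 3%), internal-stop (3%); 5% paralogs created
by duplicating an extant sequence and evolving it a further 0.5 units. The
species tree ((focal, relativeA), relativeB) has branch lengths
(0.324, 0.576, 0.05, 0.526), calibrated once so all three pairwise dS land in
the 0.2–0.4 regime reported for congeneric plant transcriptome comparisons
(focal pairs ≈ 0.30, relative–relative ≈ 0.40) while the focal branch carries
36% of both focal-pair paths. The simulator omits indels (the alignment stage
is still exercised through paralogs, short genes and representative
selection), rate heterogeneity across sites, and assembly artifacts; passing
tests therefore demonstrate correctness of the statistical machinery, not
robustness to misassembly or alignment error in real transcriptomes.

**Detectability ceiling.** With the planted focal-branch ω = 1.5 diluted by
background branches, a focal-shift gene's expected pairwise ω is ≈ 0.6–0.7.
A per-pair "selected" call requires the realized ω̂ to land inside
(0.5, ω_crit), where ω_crit ≈ 0.7–0.8 is where the two-sided Fisher test
stops rejecting; at median gene lengths that window is about two standard
deviations of ω̂ wide, capping per-pair pass probability near 0.7 and joint
recovery across both focal pairs near 0.45–0.65 for any tree geometry. The
default study recovers roughly 40–50% of planted focal-shift genes as focal
candidates, with essentially no neutral false positives; this ceiling is a
property of the calling rule at these divergences and gene lengths, not of
the implementation.

## Search and orthology

The internal aligner is Smith–Waterman / Needleman–Wunsch with BLOSUM62 and
affine gaps 11/1 (a gap of length k costs 11 + k), backed by Biopython's C
implementation; 'X' scores −1 against everything. E-values use fixed
Karlin–Altschul constants (λ = 0.267, K = 0.041, bitscore = (λS − ln K)/ln 2)
— only ranking and threshold crossing matter downstream, and externally
computed 12-column hit tables can be substituted. Among co-optimal
alignments the shortest, then most 5′ on the query, of the first 64
enumerated is reported. A longest-isoform rule (Trinity-style id grouping)
reduces each isoform group to its longest protein before searching.

BBH orthology keeps a pair when each sequence is the other's unique best hit
(ties drop the query for reproducibility) with E < cutoff (default 1e-6;
1e-15 supported) and identity ≥ 60%; triplets require triangle closure
across the three pair lists, genes in more than one triangle are excluded as
multi-copy, and triplets containing an internal stop codon are excluded.
The MCL route clusters the cross-species similarity graph (edge weight
−log10 E capped at 200, self-loops at the maximum incident weight, column
normalization, expansion/inflation iterations at inflation 1.5) and reduces
each cluster to one representative per species by maximal summed bitscore
against the other species' members (ties: longer protein, then smaller id).
Full OrthoMCL — in particular its normalization of inter-species average
weights — is not replicated; clusters missing a species are excluded with
reason "missing-species".

## Codon alignment and QC

Ortholog pairs are globally aligned at the protein level (end gaps
penalized) and back-translated onto their coding sequences; terminal stop
codons are trimmed and any protein/CDS mismatch raises an integrity error
naming the gene. "Aligned length" for the 150-bp filter counts only columns
where both entries are sense codons (gap and N-containing columns excluded),
since only those columns contribute sites and differences. An automated QC
step replaces manual inspection: alignments with more than 50% gap columns
or a run of 20+ consecutive mismatching codon columns are flagged and barred
from selection candidacy; simulated (indel-free) ortholog pairs pass at 100%.

## dN/dS estimation

**NG86.** Synonymous sites per codon are Σ_positions (synonymous single-nt
changes)/3, averaged over the two sequences (changes to stops count as
nonsynonymous, so S + N = 3 × columns). Multi-position codon differences are
averaged over all minimal mutational pathways; pathways through stop codons
are discarded and, if none survive, each differing position contributes its
position-wise comparison averaged over both source contexts. Distances use
Jukes–Cantor; p ≥ 3/4 yields an `inf` saturation sentinel that the dS > 1
filter later removes.

**YN.** κ̂ comes from K80 applied separately to fourfold-degenerate and
nondegenerate site classes (positions whose degeneracy class agrees between
the two codons), weighted by class size. Site counting weights each
single-nucleotide change by κ^[ts] × F3×4 target-codon frequency,
normalized per position with stop targets in the denominator; difference
counting weights each minimal pathway by the product of its step weights,
averaged over both directions for symmetry. The multiple-hit correction
inverts the κ-parameterized K80 curve p(d; κ) numerically; at κ = 1 this is
exactly Jukes–Cantor, so with κ = 1 and uniform frequencies the whole
estimator reduces to NG86 on alignments without multi-position differences
(a tested identity). The estimate is single-pass: κ̂ is read from the
degenerate-site classes and does not depend on the weighted counts, so the
nominal weights→counts iteration is already at its fixed point.

**ML-MA.** Four candidate models (κ = 1 or free × uniform or F3×4
frequencies estimated from the pair) are fitted by maximizing
Σ_columns log(π_a P(t)_ab) with t profiled out by bounded 1-D search on a
reused eigendecomposition; κ-fixed models optimize log ω by bounded scalar
search, κ-free models run Nelder–Mead over (log ω, log κ) from a fixed
3-point start grid (determinism). Bounds: t ∈ [1e-4, 5], ω ∈ [1e-4, 10],
κ ∈ [0.1, 20]. Per model, dN and dS follow analytically from the fitted
(t, κ, ω) with sites defined at ω = 1 (the codeml convention, making the
reported ratio equal the fitted ω); dN, dS, ω and κ are averaged under AICc
weights and the best model's log-likelihood is reported. Below 50 usable
columns the ML fit is unsupported and the YN estimate is returned with a
warning.

**Fisher validity test.** The 2×2 table [[Sd, Nd], [S−Sd, N−Nd]] is rounded
half-even (the counts are fractional), negative cells clamped to zero; any
zero margin gives P = 1. The two-sided P sums hypergeometric probabilities
of tables no more probable than the observed one, with a 1e-12 relative
tolerance on the comparison so exact ties are included; the implementation
is a vectorized hypergeometric sum, checked in the tests against exact
integer enumeration. For ML estimates the table is built from the
model-expected substitution counts. No multiple-testing correction is
applied by default (raw P < 0.05), matching standard practice for this
scan; a Benjamini–Hochberg option exists.

## Filters, calling and contrast

Pairs are removed when dS < 0.01 (unreliable), dS > 1 or saturated, dN > 1,
or aligned length < 150 bp; reasons are logged in that order. The Fisher-P
condition acts at the calling stage by default — pairs with P > 0.05 remain
in the summary means but cannot be "selected" — with a `p_filter_stage`
switch to remove them outright. A cluster is a focal candidate when both
focal pairs are selected (ω > 0.5 strictly, P < 0.05, QC pass) and the
relative–relative pair is not selected; by default a filtered
relative–relative pair does not veto candidacy (the contrast's "not
positively selected" is satisfied vacuously), and a strict mode requires an
un-filtered not-selected call. Venn region counts are computed only over
clusters with all three pairs un-filtered, and both median and mean aligned
lengths are reported in summaries. Quartet congruence scores the three
unrooted topologies of (focal, relativeA, relativeB, outgroup) by Fitch
parsimony on aligned proteins; ties return "ambiguous" rather than a call.

## Numerical and testing choices

Sub-percent tolerances throughout come from closed forms (K80 inversion uses
brentq at xtol 1e-12). Test oracles are independent routes: exact-fraction
pathway enumeration for NG86, integer-arithmetic hypergeometric enumeration
for Fisher, and a hand-written Gotoh DP (itself pinned to exhaustive
alignment enumeration on tiny inputs) for both aligners. Estimator
validation uses 200 replicates of 500-codon pairs at dS ≈ 0.3 per ω ∈
{0.1, 0.5, 1.0} (60 replicates for ML in the acceptance script, whose median
is already stable at that size); the planted-signal study uses the 200-gene
default. These sizes keep the full validation under about fifteen minutes on
a single CPU while leaving medians well-determined.

## Known limitations

No indel simulation, no among-site rate variation, no frameshift-aware
alignment, no heuristic search seeding (all-vs-all is exact and quadratic),
no bootstrap support on quartet calls, and the YN00-style estimator is a
faithful simplification rather than a line-by-line reimplementation of the
published YN00 algorithm (its correction is K80-with-κ rather than
HKY-with-base-frequencies). Real-data idiosyncrasies — chimeric transcripts,
misassembly, annotation errors — are outside the simulator's vocabulary and
must be handled upstream.
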