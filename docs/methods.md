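# Methods

## Scope and model

`puregulon` analyses a paired RIP-seq / knockdown RNA-seq / co-IP-MS /
RT-qPCR study of the two Pumilio paralogues. The core quantities are
threshold-based calls and enrichment statistics rather than a fitted
parametric model, so the package is organised as a pipeline of stage
functions over typed records (transcripts, enrichment records, regulation
calls, interactor calls, a regulon graph) rather than as a
model/results-object pair.

## Target calling

**Normalization.** Abundance tables are scaled to counts-per-million per
sample. A pseudocount of 0.5 is added before every ratio or log; genes
with zero counts in every sample are dropped with a log record. Calling is
invariant to gene order and to uniform library rescaling.

**Bound mRNAs.** A gene is bound when (1) its IP/IgG and IP/transcriptome
fold changes are ≥ `min_fc` (default 2) in *every* replicate, pairing
replicates by column order (the pairing convention is a package choice;
the criteria themselves do not prescribe one), and (2) the BH-adjusted
p-value is < `alpha` (default 0.05). The per-gene p is the larger of two
two-sample tests on log2(normalized + 0.5): IP vs IgG and IP vs
transcriptome — enrichment must be supported against both references.

**Gene-wise test.** With three replicates a per-gene t-test has four
degrees of freedom, far too few for a 20 % shift to survive FDR
correction; differential-expression callers solve this by sharing variance
information across genes. The default test is therefore a moderated t:
gene-wise pooled variances are shrunk toward an empirical-Bayes prior
fitted by method of moments on log variances (the scaled-F /
inverse-chi-square prior; degrees of freedom found by inverting the
trigamma function), and the statistic is referred to t with
`df_residual + df_prior`. When gene variances are no more dispersed than
sampling alone explains, the prior df is infinite and the test reduces to
a z-test at the common variance; with a single gene it falls back to the
classic pooled t. Plain `student`/`welch` tests remain available through
the `test` argument.

**Knockdown classification.** effect = mean(kd)/mean(control) on
normalized abundance; *repressed* iff effect ≥ 1 + `threshold` (default
0.20) with q < alpha, *activated* iff effect ≤ 1 − `threshold` (i.e. ≤
0.8 — the "decreased by 20 %" reading, configurable), else *unchanged*.
Regulated targets are bound genes with a non-`unchanged` call. All
thresholds (2-fold, 20 %, 6-fold germline enrichment) are inclusive;
boundary comparisons allow a 1e−9 absolute tolerance so a ratio exactly
equal to a printed threshold is never excluded by floating-point rounding.

**Set algebra.** Venn partitions report a-only/b-only/common plus the
overlap as a percentage of the union *and* of each set, since "X % common"
figures are ambiguous about their denominator. Cumulative-distribution
shifts between target and control log2 fold changes use the two-sided
two-sample Kolmogorov–Smirnov test; the D statistic is computed directly
from the ECDFs, the p-value comes from scipy.

## Motif analysis

Sequences are handled in the RNA alphabet (T canonicalized to U);
coordinates are 0-based half-open; scanning is sense-strand only.

**IUPAC scanning** matches degenerate words exactly, counting overlapping
occurrences by default (FIMO behaviour, configurable). The implementation
is a vectorized AND of shifted per-position membership masks and is tested
for equivalence against an independent regex-with-lookahead oracle.

**PWM scanning** uses log2 odds against a background (uniform by default),
discretized to integer multiples of 1e−3. The p-value → threshold
conversion computes the exact background distribution of the integer score
by column-wise dynamic programming and returns the smallest achievable
score whose upper tail is ≤ p; the same integer representation is used
when scanning, so threshold semantics are exact. For widths ≤ 8 the DP is
verified against exhaustive enumeration of all 4^w words. Two edge cases:
p = 1 yields the minimum achievable score, and a p below the point mass of
the consensus word yields the maximum achievable score so the consensus
still matches. Degenerate columns (zero probabilities) receive a 1e−4
pseudocount before log-odds; PWMs built from IUPAC words spread
probability uniformly over allowed bases with the same pseudocount on
disallowed ones.

**Regional attribution** assigns a hit to the region (5′UTR/CDS/3′UTR)
containing its start position; hits spanning a boundary are attributed by
start. Regional percentages always sum to 100.

**Shuffles and discovery.** Dinucleotide-preserving shuffles use the
Altschul–Erickson Euler-path construction (random last-edge arborescence
into the final letter, shuffled remaining edge lists), preserving the
exact dinucleotide multiset. Discriminative word discovery is exhaustive
over fixed-width words with sequence-level presence counts and a one-sided
Fisher exact test, BH-corrected — a transparent stand-in for heuristic
discovery tools, adequate because the planted signals are exact words.

**Degenerate PBEs.** Besides the classic `UGUAHAUW`, the package
classifies "degenerate" elements as 8-mers that keep the `UGUA` core and
sit at Hamming distance 1 (within positions 5–8) from a classic word.

## Cofactors and the regulon

**Interactors.** A protein is called for a bait iff detected in every bait
replicate and in zero IgG replicates of the same ±RNase condition.
Comparing conditions: called without RNase only → RNA-*dependent*; with
RNase only → *independent*; in both → *both* (not forced into one class).
Calling is monotone: adding an IgG detection can only remove calls.

**Co-occurrence enrichment.** For each (PUM, RBP-motif) pair, hits per
sequence are compared between that PUM's regulated transcripts and
negative transcripts (neither bound nor knockdown-responsive, optionally
length-windowed and subsampled). The negative rate is multiplied by the
length-correction coefficient c = mean L(targets) / mean L(negatives)
before forming the ratio, so slightly shorter negatives are not mistaken
for depletion; a per-nucleotide-rate alternative is available via
`length_correction='per_nt'`. The negative set's enrichment is 1 by
construction. The genes carrying the signal are those whose per-sequence
hit count *strictly* exceeds the mean over the regulated set (ties at the
mean excluded); the mean is taken over the regulated set, not all scanned
mRNAs. Guards: a motif absent from the targets gives ratio 0; absent only
from the negatives gives an unbounded ratio, both with an explanatory
note.

**Term enrichment** is the hypergeometric upper tail on a flat gene→term
annotation (no hierarchy traversal), Bonferroni-corrected over the terms
actually tested (≥ 3 background genes). A term passes iff k ≥ 3,
k/|subset| ≥ 4 % and Bonferroni p ≤ 0.05.

**Regulon graph.** A layered multigraph PUM → RBP → term. Interaction
edges come from the MS calls, one edge per RNase condition observed.
A coregulation edge RBP → term requires (i) the RBP to be an interactor of
that PUM — a cofactor is an interactor by definition — (ii) the (PUM, RBP)
enrichment ratio to exceed `ratio_threshold` (default 2.0, chosen to match
the pipeline's other 2-fold conventions since "high enrichment" is
otherwise unquantified), and (iii) a passing term on the RBP's
above-average gene subset.

## RT-qPCR

ΔCt subtracts the arithmetic mean of the reference-gene Cts (ACTB and
GAPDH by default) — equivalent to geometric-mean normalization of linear
quantities; ΔΔCt subtracts the calibrator-condition mean; fold = 2^−ΔΔCt.
The point estimate is the geometric mean of replicate folds (2^−mean ΔΔCt),
so a condition against itself is exactly 1 and the whole computation is
invariant to plate-wide Ct offsets. Significance: Shapiro–Wilk per group
(a failure at α = 0.05 raises a warning flag, not an error), then an
unpaired two-sided t-test — Welch by default, pooled behind a flag — run
on ΔCt values rather than linear folds (normality-friendlier; the choice
is at the call site). Stars: * < 0.05, ** < 0.005, *** < 0.0005,
**** < 0.00005.

## Synthetic data

The generator is the package's study-conditions definition; every
parameter lives in `SyntheticConfig` and all generators are pure functions
of it, with one global seed expanded into independent per-stage substreams
(CRC-keyed `SeedSequence` children) so stages can be regenerated
independently.

* **Counts**: negative binomial with Var = μ + φμ², log-normal baseline
  means (ln-mean 6.0, ln-sd 1.0, i.e. a median ≈ 400 normalized counts),
  library-size factors uniform in [0.7, 1.4] (≤ 2× spread). The default
  dispersion φ = 0.005 encodes per-gene replicate CVs of ≈ 7–10 %: the
  study design this emulates detects 20 % shifts at FDR < 0.05 with n = 3,
  which is only possible at that noise level, and the deep-coverage,
  homogeneous-cell-line setting justifies it. φ → 0 degenerates to
  Poisson.
* **Effects**: bound genes' IP means × `ip_enrichment_fc` (4.0); repressed
  genes × (1 + `kd_effect`) in the matching knockdown, activated genes
  × (1 − `kd_effect`), with `kd_effect` = 0.5. Regulation is planted only
  in bound genes; a both-bound gene's regulator is drawn from
  {PUM1, PUM2, both}; 80 % of regulated genes are repressed, matching the
  strong repression skew of Pumilio targets.
* **Sequences**: gamma-distributed region lengths around (150, 1200, 800)
  nt; uniform base composition by default (configurable); PBE words drawn
  uniformly from the 6-word expansion planted at Poisson(2.5) per bound
  3′UTR plus an optional per-kb background rate; planted positions avoid
  overlap (up to 100 re-samples, then skip with a log record; regions
  shorter than the motif are skipped, never fatal).
* **Cofactor panel**: planted motifs for IGF2BP1 (CAUCAUC), PTBP1
  (UCUUCUU) and HNRNPF (GGGAGGG) at 2 per regulated 3′UTR, and two
  never-planted negative controls, RBPMS (CACNNCAC) and MBNL1 (YGCY). The
  panel is constructed so no control shares a matching trinucleotide with
  any planted motif — otherwise cross-matching (e.g. a CA-repeat planted
  motif partially matching a CAC-rich control) makes the "unplanted"
  controls genuinely enriched and they stop being controls.
* **MS**: planted cofactor RBPs appear by name among the proteins and are
  interactors of both paralogues (that is what planting their motifs in
  all regulated transcripts implies); further anonymous interactors are
  split across PUM1/PUM2/both. RNA-dependent interactors vanish from
  +RNase tables; all tables carry background detections at the IgG noise
  rate (0.02), and detection dropout is configurable (0 by default).
* **qPCR**: Ct = baseline − log2(relative abundance) + N(0, 0.2), with two
  reference genes unaffected by knockdown.

What the generator does **not** emulate: read-level artifacts (mapping
bias, multimapping, positional coverage), isoform structure (one
representative transcript per gene), GC/length-dependent count bias,
correlated gene-gene expression, batch effects, and real motif PWMs with
position-specific information content. Passing tests therefore demonstrate
that the inference logic is correct under the declared noise model, not
that real libraries meet that model.

## Problem sizes and numerics

Unit tests run the study at 300–1000 genes; the acceptance checks and
`scripts/acceptance.py` use 2000 genes × 3 replicates, the size at which
the whole pipeline (simulation, calling, scanning five motifs over ~4 Mnt,
enrichment, graph) completes in a few seconds. PWM score discretization is
1e−3 and exactness is enumeration-verified at width ≤ 8; hypergeometric
tails match an exact rational-arithmetic oracle to 1e−12; the KS statistic
matches the reference implementation to 1e−9.

## Known limitations

* The statistical test behind the original FPKM-pipeline's adjusted
  p-values is not reproducible from its description; the moderated t on
  log2 CPM is a principled stand-in and is pluggable.
* One transcript per gene; isoform-specific UTRs are out of scope.
* The negative-set sampling procedure (window, count) is exposed as
  parameters rather than fixed, since no single convention is canonical.
* Cofactor motif enrichment treats motifs independently; co-occurrence is
  with the regulated set, not positional co-binding with PBEs.
* GO-style annotation is consumed flat; no ontology propagation.
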