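# Methods

This note documents the models, conventions and parameter choices behind
`mirtail`, in the order data flows through the pipeline.

## Reference model

A precursor record carries a hairpin sequence, up to two mature-arm
intervals, an optional 3′ genomic flank and a family label. On-disk
coordinates are 1-based inclusive (the convention of miRBase GFF tables);
internally everything is 0-based half-open. Sequences are normalized to a
single DNA alphabet (U → T) so references and reads compare directly; all
user-facing tail strings are reported in U-space, matching how tailing
enzymology is written.

let-7-like precursors are classified on two independent axes. Group I vs II
(2-nt vs 1-nt 3′ overhang after Drosha processing) is annotation-supplied:
the overhang depends on the Drosha cut site, which a sequence-only
reference does not carry, and we deliberately do not attempt secondary-
structure prediction. CSD+ vs CSD− is the presence of the (U)GAU motif
bound by LIN28A's cold-shock domain. The parenthesized U is read as
optional (regex `U?GAU`, which reduces to the presence of `GAU`), and the
search region defaults to the terminal loop — the region presented to
LIN28A in the pre-miRNA — with a `region="precursor"` option to widen it.
The exact window in which the motif must occur is genuinely open; the loop
default is this package's convention, not a claim about any particular
annotation source.

## Read preprocessing (NEXTFlex dialect)

Reads are structured `UMI5(4) + insert + UMI3(4) + adapter(TGGAATTCTCGG
GTGCCAAGG) [+ filler]`. Adapter search follows the cutadapt 3′-adapter
model: at an internal position the full adapter must align with at most
⌊0.1 × 21⌋ = 2 mismatches; truncated adapter prefixes are considered only
where the read ends inside the adapter, down to `min_overlap = 10` bases
(mismatch budget 10% of the overlap). The leftmost acceptable position
wins. This semantics matters: allowing arbitrary ≥10-nt prefix matches at
internal positions would spuriously trim roughly 1 in 10³ random reads,
which is far above the PCR-duplicate signal the UMIs are meant to resolve.
The implementation uses an exact-substring fast path plus a pigeonhole
(chunked exact match) prefilter, and is tested for exact agreement with a
naive position-by-position oracle.

Reads without an adapter hit are discarded by default because their 3′ UMI
boundary is ambiguous. Duplicate collapsing uses exact string equality of
the (UMI5, insert, UMI3) triple — the simplest deterministic rule;
edit-distance UMI clustering is noted as future work. Insert length bounds
default to 16–28 nt, bracketing mature miRNAs plus short tails; the bounds
and the cutadapt-style error tolerance are package choices, configurable
per run.

## isomiR classification

Inserts are aligned gaplessly against every mature arm at 5′ offsets within
±2 nt, seeded by a 12-mer lookup with an exhaustive fallback when the seed
region carries an error. The 3′ end is decomposed by the **greedy
maximal-templated rule**: extend the templated match base-by-base along the
hairpin and then the 3′ flank (10 nt by default) for as long as bases
agree; the remaining suffix is the nontemplated tail. This is the most
conservative NTA call (minimal tail). Without a flank, extension past the
hairpin end counts as nontemplated.

One SNP-style mismatch inside the mature body is tolerated and recorded
(`snp_flagged` when the read is otherwise canonical) but never changes the
3′ decomposition. Crucially, the tolerance applies only to mismatches
followed by at least one downstream matching base: a trailing mismatch run
is always a tail. Without this restriction a trimmed read carrying a
nontemplated tail would be silently absorbed as a body SNP and the tail
lost. Mismatches in the templated 5′/3′ extension zones are never
tolerated.

Candidates are filtered to |5′ offset| ≤ 2, tail length ≤ 6, 3′ trim ≤ 6
and ≤ 1 body mismatch; ties across arms are resolved by minimizing
(mismatches, |5′ offset|, tail length) lexicographically, then splitting
the read's weight equally (or, in `unique` mode, keeping the
lexicographically smallest miRNA id). The whole decision procedure is
checked against an independent brute-force oracle that enumerates every
(arm, offset, split) decomposition.

Tail typology: the exact strings A, AA, AU, U, UA, UU, G, C map to their
own types; homopolymers of length ≥ 3 map to polyA/polyU; everything else
is `other`. "Any length" aggregations (used for the uridylation/adenylation
fold changes) count homopolymeric tails only — whether mixed tails ending
in U should count is not settled usage, and the homopolymer-only reading is
adopted here.

## NTA statistics

Two burden estimators are kept distinct throughout: the **mean isomiR
percent** (unweighted arithmetic mean of per-miRNA fractions; every miRNA
counts equally) and the **weighted mean ratio** (pooled tail-carrying reads
over pooled reads; depth-weighted). Per-miRNA statistics require ≥ 10 reads
by default; pooled statistics keep every assigned read.

Condition comparisons use Haldane–Anscombe-stabilized fractions
(pseudocount 0.5 reads) so zero counts stay finite. The
uridylation/adenylation fold-change quadrant is `unchanged` when both
|log2FC| fall below a 0.25 no-change band, otherwise assigned by sign; a
five-fold adenylation gain is flagged at log2FC ≥ log2 5 exactly. The
modification filter keeps miRNAs with total NTA fraction strictly > 1%.
Arm ratios are (5p + 0.5)/(3p + 0.5); an arm switch requires the dominant
arm to differ between conditions *and* both ratios to sit ≥ 1.5-fold away
from 1 — balanced precursors make no call. The band, pseudocount,
min-reads floor and switch margin are package conventions, exposed as
parameters.

## Differential expression

Size factors are median-of-ratios: the median over all-nonzero features of
the count divided by the feature's geometric mean across samples.

The DE test is a documented approximation of the negative-binomial GLM
machinery, targeting calibration rather than bit-agreement with any
particular implementation. Per feature, a method-of-moments dispersion is
estimated from within-group variances of normalized counts
(Var(K/s) = μ/s + αμ²), a mean–dispersion trend α(μ) = a₀ + a₁/μ is fitted
across features, and the per-feature estimate is shrunk geometrically
toward the trend with weight 0.1 on the per-feature value. The heavy
shrinkage reflects how noisy 8-sample moment estimates are; the weight was
fixed by a calibration study on held-out simulation seeds (null type-I
error at p < 0.05 centered near nominal for dispersions 0.05–0.1) before
any acceptance checks were run. The Wald statistic is the log2 ratio of
normalized group means (half-read stabilized) over a delta-method standard
error; BH-FDR with the study's 0.01 threshold by default. An independent
cross-check against pyDESeq2 on planted effects runs in the test suite.

k-means clustering of per-contrast log2FC vectors uses k-means++ with 25
restarts and a fixed seed (recorded in output metadata); k = 15 by default,
with let-7 family rows excluded when an annotation is present. No row
scaling is applied by default — fold changes are already on a common scale.
PCA runs on log2(normalized counts + 1) with per-feature centering and
reports variance fractions over the full rank (they sum to 1).

## Downstream

Set enrichment is the upper-tail hypergeometric test, P(X ≥ k), with BH
across sets; the background defaults to the detected features, not the
annotation universe (detection-conditioned inference, flagged in output).
Edge filtering labels each endpoint up/down/ns at the configured FDR and
keeps edges whose endpoints oppose; co-directional significant edges are
reported separately rather than discarded, since positive-correlation pairs
are informative exceptions.

Growth curves use the logistic model N(t) = K/(1 + e^(−rt)(K − N₀)/N₀)
with K the carrying capacity (% confluency), r the growth rate (per hour)
and N₀ the initial confluency. Fitting is nonlinear least squares with
K₀ = 1.1·max(N), N₀,₀ the first positive value, and r₀ from the early
log-slope; p_r is a Wald t-test on r with df = n − 3 (growthcurver-style —
the p-value construction is this package's choice). Non-convergence sets a
flag instead of raising; a perfect fit (zero residuals) has a degenerate
covariance, and the rate is then called significant only when numerically
non-zero. Relative confluency subtracts each well's earliest time point.
Wound-width series are consumed by relative/linear summaries only; no
closure model is fitted.

## Synthetic data generator

The generator is a pure function of `SimConfig.seed`: one RNG substream per
sample (so adding samples never perturbs earlier ones) plus named streams
for the reference, abundances, mRNA counts and growth noise. Reruns are
byte-identical.

What it emulates, with defaults chosen once as the study conditions:

- 50 miRNAs, 70-nt hairpins, 20–23-nt arms, a 10-nt 3′ flank; 20% flagged
  let-7-like with planted UGAU loop motifs (CSD− loops rejection-sampled to
  contain no GAU, so the motif scan recovers planted labels exactly);
- per-miRNA baseline abundance lognormal with σ = 0.8 (~500-fold 95%
  range: skewed, as real miRNA expression is, while keeping per-miRNA
  counts informative at the default depth); NB replicate dispersion 0.05;
  100 000 reads per sample, 2 conditions × 3 replicates;
- per-read templated states: 3′ extension +1/+2 with probability
  0.30/0.08, 3′ trim −1/−2 with 0.06/0.02, 5′ shift ±1 rare — shaped to a
  realistic isomiR composition in which canonical and 3′-extended reads
  dominate;
- condition tail rates: wild type {U: 0.15, A: 0.12}, catalytic knockout
  {U: 0.02, A: 0.18}, the remainder untailed — presets at the magnitudes a
  TUT4/7 loss experiment shows; per-base substitution error 10⁻³; constant
  'I' qualities (quality-aware filtering is out of scope).

Identifiability: the last two bases of each mature arm and the four
template bases downstream of each arm end are drawn from {C, G}. A planted
U/A tail therefore never coincides with the template within the ±2
trim/extend range, so the greedy decomposition recovers generative tails
exactly and parameter-recovery tests can use the configured rates directly.
Real references carry no such guarantee: on user-supplied hairpins a tail
that happens to extend the template is (correctly, under the maximal-
templated convention) absorbed as templated extension, and NTA rates are
accordingly conservative. The truth manifest always stores generative
labels, so such template-mimicking cases remain enumerable.

Not emulated: ligation bias, PCR duplication beyond exact copies, indel
errors, quality-score structure, cross-mapping between paralogous real
miRNA families, and A-to-I editing. Passing tests on this generator
therefore demonstrate correctness of the decomposition and statistics, not
robustness to every artifact of real libraries.

## Problem sizes

The test suite and the acceptance script run the full read-level study at
2 × 3 samples × 100 000 reads (≈ 6 × 10⁵ reads end-to-end through FASTQ,
preprocessing and classification), DE calibration on 2 000 features at
n = 4 vs 4, and 100-well growth-fit recovery; these sizes make the whole
suite complete in well under a minute per stage on one CPU while leaving
Monte-Carlo error far below the tested tolerances.

## Known limitations

- Multi-mapping resolution is heuristic (lexicographic tie-breaks, equal
  weight splits); no EM reassignment.
- The DE test does not implement outlier handling (Cook's distance) or
  multi-factor designs; one contrast at a time.
- UMI collisions (two true molecules drawing the same UMI pair) are
  collapsed; at 4+4-nt UMIs this loses ~n²/2·4⁻⁸ reads per identical
  insert, negligible at the depths used here but a known bias at extreme
  per-sequence depth.
- A-to-I editing and SNP calling are out of scope beyond flagging body
  mismatches.
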