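# Methods

This note records the models, estimators, numerical choices and known
limitations behind `paleoks`, in the order the pipeline runs them.

## Homology search and paralog pairing

Candidate paralogs come from an all-vs-all nucleotide self-search.
Sequences are seeded with exact 11-mers (N-free words only; words occurring
more than 200 times are skipped as repeats). Each candidate pair is
screened with an ungapped X-drop extension of its seeds (X = 20, minimum
raw score 25), and survivors are aligned with an affine-gap
Smith–Waterman: match +1, mismatch −2, a gap of length L costs 5 + 2L.
These are conventional nucleotide-search parameters; nothing downstream is
sensitive to them beyond the e-value ceiling.

Raw scores S become e-values through the classical local-alignment formula
E = K·m·n·e^(−λS) with λ = 1.28 and K = 0.46 (the published values for the
+1/−2 scheme), m the query length and n the total residues searched.
The default ceiling is **E ≤ 1e-20**. A pair is a potential paralog when
hits exist in *both* directions at the ceiling; all reciprocal pairs are
kept rather than only reciprocal best hits, because a gene retained through
several rounds of duplication legitimately has several paralogs. Self-hits
are suppressed. Both strands are searched; a pair whose only alignments are
minus-strand is an antisense artifact and is excluded from Ks estimation
(reason `antisense`).

For pairs up to 10⁶ DP cells the Smith–Waterman is run over the full
matrix, so the reported score is exactly the quadratic-time optimum (this
covers all test comparisons against the brute-force oracle). Longer pairs
use a band of ±64 diagonals around the observed seed diagonals; a banded
score is a lower bound on the exact one, and with the default word size it
is tight for any alignment whose indels do not accumulate more than 64 nt
of net offset — comfortably true for transcriptome paralogs. Scores, spans
and identities otherwise come from a full traceback.

## Ks estimation

Each transcript is first trimmed to its longest open reading frame —
the longest stop-free codon run over all six frames, ties resolved toward
the forward strand and lowest frame — because de novo assemblies are
unoriented and untrimmed. ORFs shorter than 30 codons are rejected
(`no usable ORF`): below that, site counts are too noisy to be useful.

The two translations are aligned globally (BLOSUM62, gap open −10, extend
−0.5) and the alignment is back-mapped to nucleotides, so gaps only occur
in frame-preserving multiples of three. Codon columns containing a gap, an
N, or a stop codon are excluded from counting entirely.

Site and difference counting follows Nei–Gojobori pathway averaging:

* a codon's synonymous-site content is, per position, the fraction of the
  three possible single-base changes that are synonymous (changes to stop
  codons count as non-synonymous), summed over positions. With this
  definition S + N = 3 × (counted columns) exactly, which the tests assert.
* differences between codons differing at d positions are averaged over
  all d! single-step orders; orders passing through a stop codon are
  discarded. For the rare sense-codon pairs where *every* order is blocked,
  all orders are used instead — preferable to dropping the column, and
  affecting counts only in the third decimal at realistic divergences.

The observed synonymous difference proportion p_s = Sd/S is corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p_s). At p_s ≥ 3/4 the model is
undefined and the pair is rejected as `saturated` — unrelated sequences
land here, which is what makes the reciprocal-pair net safe to cast wide.
Pairs with fewer than 10 synonymous sites (configurable) are rejected as
`too_few_sites`; there is no upper Ks ceiling below saturation. Ks is
symmetric in its arguments by construction (inputs are canonically ordered
before alignment so tie-broken gap placements cannot differ).

## Mixture peaks

The Ks sample is modelled as a finite mixture of univariate normals with
unequal variances, fitted by EM. Initialization spreads the k means over
the data quantiles with sds = sample-sd/k and uniform weights; 10 restarts
jitter the means, and the best final log-likelihood wins. EM stops at a
relative log-likelihood change below 1e-8 or 500 iterations. Component sds
are floored at 1e-4 to keep duplicated values from collapsing a component.
Model selection fits k = 1…10 (bounded by n ≥ 5k) and takes the lowest
BIC = −2·loglik + (3k−1)·ln(n), ties toward smaller k. Fitting is on raw
Ks values: the sample is nonnegative but no truncation correction is
applied, matching the plain normal-mixture reading of this analysis style;
in practice the recent-duplicate mass near 0 absorbs the boundary.

Peak means at or below the recency cutoff (default Ks = 0.1) are
"current/recent" duplications; the rest are candidate ancient events. The
cutoff is exposed because the recent/ancient boundary is a scientific
judgment, not a statistical one.

## SiZer significance map

For each grid point x and bandwidth h, the Gaussian-kernel density
derivative estimate is the sample mean of g_i = φ′((x−X_i)/h)/h², with
standard error from the sample variance of the g_i. Simultaneous (over x)
confidence intervals use the independent-blocks quantile: m(h) = range/(2h)
blocks, q = Φ⁻¹((1 + (1−α)^{1/m})/2), α = 0.05 by default. A cell is
INCREASE/DECREASE when the interval excludes zero, FLAT otherwise, and
SPARSE when fewer than 5 observations lie within ±2h of x (the
conventional effective-sample-size rule; such cells are never classified).
Default grids: 201 equal steps over [0, max Ks]; 21 log-spaced bandwidths
spanning [range/100, range/2].

A *significant peak* is an INCREASE run followed — possibly across FLAT
cells — by a DECREASE run at the same bandwidth; SPARSE cells break the
pattern. Intervals are attributed to the smallest bandwidth exhibiting
them and merged across bandwidths when they overlap. Note that a bounded
sample smoothed at large h shows genuine slope near the support edges;
that is a property of the estimand, not an artifact, and the tests only
assert flatness away from boundaries.

## Dating

Ages are `age = Ks / r` with r = 1.5×10⁻⁸ synonymous substitutions per
site per year by default (the classical dicot background rate). The
divergence here is the *pairwise* Ks, and dividing the whole pairwise
divergence by r is the convention this pipeline standardizes on; users who
prefer the per-lineage convention, where each copy accumulates r per year
so age = Ks/(2r), can pass `--per-lineage` (it exactly halves all ages).
Reported tables carry unrounded years and Myr plus a 2-significant-figure
display column.

## Ortholog scan

Cross-sample ortholog triples require all three pairwise reciprocal *best*
hits (best = lowest e-value, ties by bitscore then id) to agree. Each
triple is multiple-aligned with MAFFT (`--auto`); the consensus is a plain
per-column majority vote with gap as a votable symbol and deterministic
tie order A<C<G<T<N<gap, which makes all downstream counts independent of
input order. SNPs are non-gap mismatch columns versus the consensus,
classified synonymous/nonsynonymous by substituting the variant base into
the consensus codon in the frame anchored on a designated sequence;
columns where the frame or consensus codon is incomplete are reported but
left unclassified. Gap runs are reported separately as deletion records,
flagged in-frame when their consensus-spanning length is divisible by 3.
Shared nonsynonymous sites between a designated pair require the same
column *and* the same variant base.

## Synthetic data

`sample_ks` draws from a specified mixture of Gaussian peaks plus a
uniform background, truncated to Ks ≥ 0 by resampling. The default profile
is a seven-peak paralog-age shape — strong recent-duplicate excess below
0.1 (means 0.01/0.022/0.05), a shoulder at 0.12 and ancient peaks at
0.27/0.51/0.91 — with sds growing with age (0.005→0.10) and a 5% uniform
background, i.e. the qualitative structure of a real transcriptome-wide
Ks histogram.

`simulate_duplicated_transcriptome` plants ground truth at the sequence
level. Per family: a random stop-free CDS (ATG + uniform sense codons) and
one copy mutated to a target depth d. The number of synonymous changes is
round(p_s·S) with p_s = (3/4)(1 − e^(−4d/3)) — the Jukes–Cantor inversion
— placed only at codons where a single-base synonymous change exists, so
codon-aware counting recovers them exactly; nonsynonymous changes are
added analogously at dN = ω·d (default ω = 0.2, strong purifying
selection, which keeps the protein alignment trivially correct). At most
one change per codon. Divergence is applied to one copy only, i.e.
*pairwise*, consistent with the Ks/r dating convention. The truth table
records planted depth and the realized p_s/Ks of each pair.

What the simulator does **not** emulate: indel evolution, transcript
isoforms and assembly artifacts, gene-family birth–death (families are
independent two-copy pairs), rate variation among sites and lineages, and
codon-usage bias. Passing recovery tests therefore demonstrate estimator
and peak-detection correctness under clean divergence, not robustness to
assembly noise.

## Problem sizes and determinism

Recovery runs use 150 two-copy families per depth at depths
{0.27, 0.51, 0.91} and 500-codon genes (≈450 paralog pairs per run), which
gives mixture and SiZer enough data to resolve three ancient peaks while
keeping a full pipeline run in tens of seconds; the acceptance suite
repeats it over 20 seeds. All randomness flows through explicit seeds
(numpy `default_rng` / `SeedSequence`), and a rerun with the same
configuration is byte-identical across every output file.

## Known limitations

* Nei–Gojobori with Jukes–Cantor is the simplest consistent estimator:
  no transition/transversion weighting, no codon-frequency correction, no
  ML codon model. Ks values above ~1 are increasingly noisy as p_s nears
  saturation.
* One Hit per pair and strand is kept (the best local alignment); chained
  HSPs are not combined.
* The normal-mixture model ignores the Ks ≥ 0 boundary; peaks below
  ~2 sds of 0 will be biased outward.
* BIC with 1-D normal mixtures tends to merge heavily overlapping peaks —
  the same behavior SiZer is included to adjudicate.
* The e-value calibration uses fixed published λ, K for +1/−2 scoring; it
  is a ranking/threshold device, not a claim of exact hit statistics under
  gapped alignment.
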