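# Methods

This note documents the models and procedures implemented in `coreseq`,
their assumptions, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was open.

## Orthology and CORE derivation

**Reciprocal best hits.** Hits are 12-column tabular BLAST rows (outfmt 6),
1-based inclusive coordinates, `sstart > send` encoding a minus-strand
subject. HSPs with E-value above the cutoff (default 1e-5) are discarded;
per query, each subject is scored by the **sum** of its surviving HSP
bitscores — a single best HSP would understate split alignments, which are
routine between a fragmented de novo assembly and a full-length reference.
Ties break deterministically: minimum E-value, maximum total aligned
length, lexicographically smallest subject id.

Reciprocity is enforced at the **gene level on the de novo side**: a pair
(Trinity gene g, reference transcript t) is accepted when some isoform of g
has its best forward hit on t and t's best reverse hit lands on *any*
isoform of g. Requiring the identical isoform back would break the intended
many-isoforms-to-one-reference semantics, since the reverse search cannot
distinguish near-identical isoforms reliably. If several reference
transcripts reciprocate with one Trinity gene, the highest-scoring one is
kept, so each de novo gene appears at most once. A reference gene claimed by
several Trinity genes (assembly fragmentation) is kept but flagged.
Consequence for e-value sensitivity: accepted pairs are stable under cutoff
relaxation whenever worse-E-value hits are also lower-scoring, which is how
BLAST scores behave away from pathological borderline hits; the package does
not guarantee monotonicity for adversarial inputs.

**COREs.** Only HSPs connecting an accepted isoform to its pair's reference
transcript are used. Each HSP yields one interval per species: query
coordinates on the de novo side, subject coordinates (strand-normalized) on
the reference side, converted from 1-based inclusive to 0-based half-open
BED as (start−1, end). Intervals are merged per (transcript, pair) on each
side **independently** — filtering is per species anyway, and maintaining a
base-to-base pairing across species would add nothing downstream. Merging
coalesces book-ended intervals ([a,b) + [b,c) → [a,c)); subject-side
intervals from different isoforms of one pair are merged together because
counting is gene-level. The pair id is written in the BED name column so
filtered counts remain traceable to ortholog pairs.

**Gene-transcript map.** Ortholog isoforms map to the reference gene label
(combined mode); with augmentation (per se mode), every remaining transcript
maps to its Trinity gene so the full assembly is quantified. A transcript
claimed by two reference genes resolves to the higher-bitscore claim, with a
warning.

## Alignment filtering and counting

A record survives when it is primary and mapped and its aligned reference
span — `reference_start` to `reference_end`, i.e. CIGAR operations that
consume reference (M/D/N/=/X) — overlaps the union of its transcript's CORE
intervals by at least `min_overlap` bases (default 1) **and** at least
`min_overlap_frac` of the span (default 0). Both knobs are exposed because
the choice materially changes counts near interval edges. Records on
transcripts without CORE intervals are dropped and counted in the summary,
not treated as errors. Paired-end records are handled mate-by-mate with a
warning; the intended input is single-end (merged-read) alignments.

Counting is direct: one count per retained primary record, keyed by the
gene label of its reference transcript. Cross-isoform multi-mapping within
a gene is harmless after the gene-level collapse; cross-gene multi-mapping
resolution (EM-style abundance estimation) is deliberately out of scope.
The combined matrix is the intersection of gene labels present on both
species' sides, species-A columns first; one-sided genes are dropped with a
log entry.

## Differential expression

**Expression filter.** A gene is kept when ≥ `min_samples` samples (default
3) reach the count equivalent of `min_cpm` (default 10) computed against the
**average** library size — i.e. the threshold is one number,
`min_cpm · mean(lib)/1e6` counts, applied to all samples, matching the
convention of judging CPM against the mean depth. For deeper-replicated
per se designs, `min_samples=4` is the intended setting.

**TMM.** The reference sample is the one whose upper-quartile CPM is closest
to the mean upper-quartile. For each sample vs the reference, genes zero in
either are excluded; M = log2((x/N)/(r/R)) and A = ½·log2((x/N)(r/R)) are
doubly trimmed (30% on M, 5% on A, by ranks), and the factor is
2^(weighted mean of surviving M) with inverse-delta-method weights
w = (N−x)/(Nx) + (R−r)/(Rr). Factors are rescaled to geometric mean 1.
Degenerate samples (no shared expressed genes) get factor 1 with a warning.
Exact properties: identical libraries → all factors 1; a pure depth pair
(counts exactly doubled) → factors 1; **uniform** depth scaling of all
samples leaves factors and normalized log-ratios exactly unchanged (the
weights scale uniformly and cancel). Scaling a *single* sample changes the
depth term of its weights and moves factors at the ~10⁻³ level; this is a
property of precision-weighted trimmed means, not an implementation
artifact, and is asserted at that honest magnitude in the tests.

**Precision weights.** logCPM = log2((count+0.5)/(effective lib+1)·10⁶),
effective lib = library size × TMM factor. The +0.5/+1 offsets keep zeros
finite; they perturb logCPM by ≈ 0.7/count, so depth-scaling invariances are
exact only in the deep-count limit (the tests use deep libraries where the
perturbation is < 1e-8). A first-pass unweighted fit on the design gives
residual standard deviations; a lowess (span 0.5) of √sd on mean log2 count
is the mean-variance trend, interpolated (clamped at both ends) at each
observation's fitted log2 count and raised to the −4th power to give
inverse-variance weights, floored at 1e-6. On homoscedastic data the trend
is flat and weights are equal to within lowess noise.

**Moderation.** Per gene, weighted least squares on the design;
cell-means coding (one indicator per species×day group) is used throughout
so contrasts are explicit coefficient vectors and no intercept convention is
needed. The residual variances s²_g (d_g df) are shrunk toward a scaled
inverse-chi-square prior fitted by moment-matching log s²_g: with
s²_g ~ s₀²·F(d_g, d₀), the excess variance of log s²_g over trigamma(d_g/2)
equals trigamma(d₀/2), inverted by Newton iteration; the prior scale follows
from the mean with the matching digamma correction. All-equal variances give
d₀ = ∞ (complete pooling), the documented limit. The posterior variance is
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g); moderated t = c'β̂ / (s̃_g·√(c'(X'WX)⁻¹c))
on d₀+d_g df (normal when d₀ = ∞), two-sided p, BH step-up FDR. Setting
d₀ = 0 recovers the ordinary t exactly. Built-in contrasts: per-species
day-vs-day-0, and the combined species-by-time interaction
(A_d − A_0) − (B_d − B_0) per later day. The DE table reports the signed
linear fold change (2^|logFC| carrying the sign, so logFC −1 prints as −2),
symbol/name annotations when provided, and is sorted by p. A log-odds (B)
column is not computed: it requires an assumed DE proportion and adds
nothing to the FDR-based calls.

## Co-expression thresholding

Spearman correlation = Pearson on average-ranked rows; constant genes get
correlation 0 with everything, logged. An edge exists where |ρ| ≥ τ
(absolute value by default — sign-agnostic co-expression is the common
convention; configurable to signed). Genes with no qualifying partner are
excluded ("unused").

The threshold grid descends from 0.99 to 0.70 in steps of 0.002 (146
points; 0.914 is on the grid). Each point is scored:

- **scale-free:** least squares of log p_k on log k over observed nonzero
  degree frequencies (no binning by default; logarithmic binning available);
  pass iff the negated slope a ∈ (1,3) and R² ≥ 0.80, requiring ≥ 3 distinct
  degrees;
- **small-world:** MeanCC (mean local clustering, 0 for degree < 2) ≥
  2 × k̄/n, and MeanPath (mean shortest path over connected pairs in the
  largest component) ≤ ln n / ln k̄, the Erdős–Rényi baselines at equal size
  and mean degree (undefined when k̄ ≤ 1, which fails the point).

The **lowest** passing threshold is selected: it maximizes the share of
genes kept while still satisfying the topology, and %Used/%BigComp are
reported per point in the threshold report. The rule is configurable to
highest-passing; with no passing point the report carries an explicit
no-pass status rather than a fallback threshold.

The R² criterion is kept for threshold *selection* because it is cheap and
reproduces the established behavior, but it is not a hypothesis test — a
good R² on a log-log plot does not establish a power law, and the residuals
of such fits are heteroscedastic. The package therefore also fits the
degree tail by **discrete maximum likelihood**: p(k) = k^(−α)/ζ(α, x_min),
α by bounded scalar minimization of the exact zeta likelihood, x_min chosen
to minimize the KS distance between the tail empirical CDF and the fitted
CDF over candidate cutoffs (every distinct value leaving ≥ 10 tail
observations, thinned evenly to ≤ 80 candidates for speed). Goodness of fit
is a semi-parametric bootstrap: each replicate resamples below-x_min values
empirically and above-x_min from the fitted law, is refit with free x_min,
and contributes its KS; p is the fraction of replicate KS statistics at or
above the observed one, with 95% percentile intervals for α and x_min from
the replicates. At the default 200 replicates, p has a Monte-Carlo sd of at
most ~0.035.

## Subnetworks and factor plots

Regulator/target symbols are matched case-insensitively (species symbol
conventions differ: Dmd vs DMD). A subnetwork is the star closure of its
center: the center plus listed direct neighbors, with all induced edges —
neighbors-of-neighbors are not admitted. Subnetworks are enumerated for
every listed gene in the network, sorted by size, and flagged at ≥ 10
members. Factor-plot tables use log2(x+1) (zeros map to zero) and t-based
95% intervals, mean ± t(0.975, n−1)·s/√n — normal intervals would be
anti-conservative at the 3–4 replicates typical of these designs; single-
sample groups get an undefined interval, flagged via n.

## Assembly metrics

N50 is the smallest length L such that transcripts of length ≥ L contain at
least half the assembled bases (descending-sort convention). ExN50 ranks
transcripts by normalized expression (ties: longer first, then id) and, for
each Ex in 1..100, takes the N50 of the minimal prefix holding Ex% of total
expression; at Ex = 100 with uniform expression this reduces to the plain
N50 of all expressed transcripts.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of parameters and a seed, byte-stable
across runs.

- **Transcriptomes** (defaults: ~1 kb transcripts, 1–3 isoforms/gene,
  divergence 0.05): one ancestral sequence per gene; the reference emits it
  verbatim, de novo isoforms carry uniform-replacement substitutions
  (observed identity 1 − 0.75·divergence, since 1/4 of draws back-
  substitute) and optional single-base indels — enough to exercise HSP
  splitting without modeling realistic indel length spectra.
- **BLAST tables**: true pairs covered at 85–98% of the shorter sequence,
  optionally split into 2–3 HSPs with small gaps; ~20% of pairs minus-strand
  on the subject; decoys at `decoy_rate` with bitscores strictly below 0.8×
  the true pair's total, so RBH ground truth is unambiguous *at generation
  time* — harder regimes come from raising decoy_rate and divergence, not
  from overlapping score ranges, which would make the truth ill-defined.
  E-values are a monotone transform of bitscore (ordering is all the
  pipeline uses).
- **Alignments**: single-end 75 bp records; exactly
  round(reads·(1−off_target_frac)) per pair start and end inside CORE
  intervals, the rest wholly outside (skipped where no gap fits, so the
  planted truth in the `@CO` header is the authority, not the nominal
  fraction). No sequencing errors, soft-clips or indel CIGARs.
- **Counts** (defaults: 2000 genes, 2 species × 3 days × 4 reps, NB
  dispersion φ = 0.1, interaction logFC 2 on 10% of genes when enabled):
  var = μ + φμ², gamma-Poisson sampling, per-gene species and day main
  effects (sd 0.3 log2) so nulls are not artificially flat, library scale
  factors within a 2× band. DE genes carry the effect on the species×time
  interaction only. No gene-gene correlation, batch structure or outlier
  samples — calibration results here do not certify robustness to those.
- **Co-expression modules**: module members share a latent factor with
  loading calibrated through ρ_pearson = 2·sin(πρ_s/6) so pairwise Spearman
  ≈ `within_r`; hubs may load on several factors; background genes are
  independent noise. The default 23 samples mirrors the combined two-species
  matrix this fixture mimics; tests of the *planted construction* use 120
  samples because the Spearman sampling sd at ρ = 0.92 is ≈ 0.034 at n = 23
  (planted edges can sag below a low selected threshold by chance) versus
  ≈ 0.014 at n = 120, keeping the 5σ band above any passing threshold. The
  module-size spectrum in tests (many pairs, few large cliques) is chosen so
  clique degrees follow an approximate k⁻² law — the scale-free check then
  measures the topology, not sampling noise.
- **Power-law degrees**: exact inverse-CDF sampling of
  p(k) = k^(−α)/ζ(α, x_min), tabulated to k = 10⁵ with the asymptotic
  ζ(α,k) ≈ k^(1−α)/(α−1) inversion beyond (total far-tail mass < 10⁻³ for
  α > 1.5).

## Problem sizes and numerical choices

Test and acceptance runs use 50-gene ortholog fixtures (5 seeds), ~10⁴
alignment records, 2000-gene count matrices, 100 random graphs of ≤ 30
nodes for brute-force agreement, n = 10⁵ samples for exponent recovery, and
20 bootstrap runs of 200 replicates at n = 2000 for GOF calibration —
sizes at which every oracle is exact or its Monte-Carlo error is far below
the asserted tolerance. Key numerics: lowess span 0.5 and weight floor 1e-6
(configurable); trigamma inversion by Newton with closed-form guards at
both extremes; α search bounded in (1.001, 25); zero contrast vectors,
rank-deficient designs, out-of-range p-values and empty inputs raise
validation errors rather than propagating NaNs.

## Known limitations

- Counting after filtering is direct primary-record counting; the package
  does not re-estimate abundances with an EM model, so cross-gene
  multi-mapping is unresolved (dropped into whichever gene the primary
  record names).
- The interaction test assumes a shared dispersion structure across species
  within the combined matrix; strongly species-specific mean-variance
  behavior would partially load onto the precision weights.
- Threshold selection arbitration (lowest-passing) is an explicit,
  configurable rule, not an attempt to reproduce any particular tool's
  internal tie-breaking.
- Sample-level quality weights, random effects, spline time trends and
  batch correction are out of scope.
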