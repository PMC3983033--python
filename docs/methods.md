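# Methods

This note documents the statistical models, defaults, and design choices
behind `intbias`, and what the synthetic-data tests do and do not establish.

## Coordinates and containers

All internal coordinates are 0-based half-open; the I/O layer converts GFF
(1-based inclusive) at the boundary.  Feature tracks are fixed-bin
per-chromosome float arrays with NaN for missing data; missing values are
excluded from every window mean and their exclusion is visible in the
NaN-aware reductions rather than silently imputed.

## Matched random controls

Each integration is matched to `m = 10` random loci satisfying three
constraints: (i) the system's integration motif (TA, TTAA; none for
motif-free systems), (ii) the same distance to the nearest **upstream**
restriction site, and (iii) unique mappability.  Decisions where the
procedure is underdetermined:

- *Upstream* is interpreted relative to the sequenced junction's
  orientation (strand-aware); an orientation-agnostic mode is available for
  sonication-based libraries, and the restriction constraint can be dropped
  entirely per system (`rmap=None`), reflecting protocols without a
  digestion step.
- Distance matching is exact (`tolerance=0`) by default; a tolerance is
  exposed for sparse synthetic genomes.
- The integration's own locus is excluded from its eligible set.
- If fewer than `m` eligible loci exist, controls are drawn with
  replacement and the event is flagged (alternative: drop).  Events with an
  empty eligible set are dropped and reported, never imputed.

Mappability of position *p* means the read-length k-mer starting at *p*
occurs at exactly one genomic locus counting both strands; a brute-force
canonical-k-mer dictionary is used, which is exact and adequate at the
multi-megabase scale this package targets.  Palindromic motifs are scanned
on one strand (their reverse-strand occurrences coincide); non-palindromic
motifs are scanned on both.

## Annotation bias statistics

Region classes (genic, 1 kb TSS-upstream, 1 kb TSS-downstream, other;
transcript classes 5'UTR/3'UTR/exon/intron) may overlap and are tested
independently.  Enrichment is `log2((I/C)·(N_C/N_I))`; the null in-class
probability is the control fraction; significance is a two-sided exact
binomial with Benjamini–Hochberg FDR across tested cells.  Orientation bias
is the sense fraction (relative to the host gene) among in-class
integrations tested against the in-class control sense fraction.  The TSS
window is a flag (default 1 kb; 2 kb selectable).

Meta-gene profiles use fixed-width flank bins (5 kb) and length-normalized
body bins; genes are pre-filtered: partially overlapping pairs are both
removed, nested pairs keep the larger gene (ties: smaller start, then
lexicographic id).

The expression analysis groups genes into a zero-expression group plus
quartiles of the remainder and applies the Cochran–Armitage trend test with
equally spaced scores to the 2×5 integration/control table.  The statistic
uses the exact permutation variance (N−1 form) and a two-sided normal
p-value; no continuity correction by default (the classical statistic; it
tracks the inclusive permutation tail well at the table sizes produced
here), with a half-lattice correction available for very small tables.

TAD-interface profiles align every TAD–boundary junction at 0 (positive
axis into the TAD, negative into the boundary) and truncate counting at the
midpoint of each element, so every locus is assigned to exactly one
interface side.  Between-system comparison stratifies events within 10 kb
of interfaces by absolute distance and applies the Cochran–Mantel–Haenszel
test (via `statsmodels`, no continuity correction) to the per-stratum
system × (integration/control) tables.

## Scale-resolved association

For feature *f*, locus scores are window means (200 bp) at distance 0 and
the mean of the two window means at ±s for scales on an exponential grid
(default 100·2^k bp, k = 0..14).  Scores are rank-normalized to (0,1] per
feature, pooled across loci, scales, and the integration + control sets so
that all comparisons share one scale.  The per-scale statistic is a
two-sample t with common n (variances pooled with n−1 normalization;
selectable), treated as standard normal at the large df used here.  With
`Z_I` from the integrations and `Z_Cj` from each control pseudo-dataset,

    T = Z_I − mean_j(Z_Cj)

has null distribution Normal(0, sqrt(1 + 1/m)) by independence; two-sided
p-values follow analytically and BH-FDR is applied jointly over the
feature × scale matrix.  Degenerate zero-variance cells are reported as
missing, not infinite.  The Monte-Carlo calibration (`null_calibration`)
simulates exchangeable rank scores through the same `tscore`/`adjusted_T`
code path and reproduces Var(T) = 1.1 at m = 10 and the nominal 5%
rejection rate.

Macro/micro classification rank-normalizes each feature's smallest
significant scale within each system; macrofeatures lie above the
cross-feature mean rank in every system, microfeatures at or below it in
every system; features not significant in some system get no label.

Feature orientation bias compares the 200 bp window immediately upstream of
each oriented integration with the downstream window (positive t = higher
signal upstream); the cross-feature summary is (fraction of positive t) −
0.5 with a two-sided binomial p.

The local Hi-C contact-decay exponent (alpha) is the OLS slope of log10
mean contact frequency on log10 distance within ±400 kb of a locus on a
20 kb-binned matrix; zero-contact distances are excluded and counted.  More
negative alpha indicates faster decay (more compact chromatin).

## Conditional-independence analysis

Rows are integration loci and all matched-control loci; columns are feature
scores discretized into empirical tertiles (ties to the lower bin) plus a
binary integration indicator.  This indicator-row construction is the
default; the alternative preprocessing — dividing each integration's score
by its control mean (or subtracting on log scales) before discretization —
is implemented (`normalize_by_controls`) because the choice is genuinely
open: normalizing rows by their own controls removes the very
integration-vs-control contrast the indicator encodes, so the two
constructions answer subtly different questions and the package keeps both.

Structure learning is an annealed hill-climber over add/delete/reverse
single-edge moves with acyclicity and a parent cap (`max_parents=3`),
maximizing BDeu (ess = 1) or BIC; proposals follow the Metropolis rule
under geometric cooling (t0 = 5, rate 0.999, 3000 proposals) and the best
DAG seen is greedily polished.  The relatively hot start matters: collider
structures (e.g. an XOR-like dependence) require two coordinated edge
additions that pure greedy search cannot reach.  On 3-node problems the
search provably attains the exhaustive-enumeration optimum in the test
suite.

Bootstrapped blanket discovery resamples rows with replacement (nominal
size 20 000, capped at the dataset size with a warning), learns a network
per bootstrap, extracts the indicator's Markov blanket (parents ∪ children
∪ co-parents), and reports per feature the blanket frequency (confidence)
and the mean plug-in conditional mutual information with the indicator
given the rest of the blanket (strength, bits).  Features never entering a
blanket are omitted from the summary.

## CIS calling and spurious-CIS filtering

Tumor integrations (deduplicated per tumor at identical positions; flag
provided) are smoothed with a Gaussian kernel, reading the 30 kb "kernel
width" as the standard deviation (full-width reading selectable), on a 1 kb
evaluation grid.  The null is Monte Carlo: `R` (default 2000) screens of
equal size placed uniformly over the mappable genome.  Per-grid-point
p-values are taken against the **pooled** null height distribution (all
grid points of all replicates, exchangeable under the uniform null), and
the call threshold is the 1 − alpha/n_grid pooled quantile — Bonferroni
over grid points.  Pooling is what makes alpha/n_grid resolvable at
moderate R (minimum resolvable p is 1/(R·n_grid)); R below 10/alpha is
rejected with an instruction to raise R.  Contiguous super-threshold runs
merge into one call at their maximum; regions are runs extended by the
kernel sd on either side, clipped to the chromosome, and overlapping
regions are merged (logged) so each integration belongs to at most one CIS.

The spurious-CIS test counts tumor (n_C) and unselected (n_U) integrations
in each region and computes the one-sided upper-tail binomial p of n_C
successes in n_C + n_U trials with success probability
p0 = N_tumor/(N_tumor + N_unselected) — the marginal probability that a
region hit originates from the tumor dataset.  After BH-FDR across CISs,
q ≥ 0.05 flags the CIS as spurious (no detectable excess over the intrinsic
bias).  The test is monotone in n_C.  Activating/repressing classification
follows the peak location: intergenic peaks are activating; intragenic
peaks are activating iff ≥ 90% of region integrations share an orientation.
Nearest-TSS annotation restricts to genes with complete cross-reference ids
(a boolean flag on synthetic genes) and breaks exact ties by gene id.

## Synthetic-data generator

The generator defines the study conditions for all tests:

- **Assemblies** are i.i.d. nucleotide sequences at a set GC (default 0.42,
  mouse-like).  They reproduce motif densities but none of the long-range
  sequence structure of a real genome.
- **Annotations** place non-overlapping genes (lognormal lengths) plus a
  configurable fraction of deliberately nested/partially overlapping pairs
  to exercise the overlap filter; exon/intron/UTR pieces partition each
  gene span.  TADs and boundaries alternate and tile each chromosome; on
  megabase-scale test genomes their sizes are scaled down (defaults 300 kb /
  50 kb) to keep tens of interfaces per chromosome.
- **Feature tracks** are Gaussian-smoothed unit-variance noise with a set
  autocorrelation length (ACF = exp(−1/2) at that length), optional shared
  latent components for controlled inter-track correlation, and
  deterministic Gaussian bumps at annotation anchors.
- **Integration profiles** follow a log-linear (exponential-tilt) intensity
  log λ(p) = baseline + Σ_f β_f · f(p at scale s_f) over the eligible
  candidate set (motif sites or all mappable positions, restricted to
  restriction-recoverable sites: an upstream cut within 1 kb by default).
  This family was chosen because it produces exactly the monotone
  feature-proximity associations the association statistics are designed to
  detect, making parameter recovery well-posed.  Sampling without
  replacement uses Gumbel top-k keys, which is an exact vectorized
  equivalent of sequential weighted draws (no thinning approximation, no
  collision bookkeeping).  Orientation follows a configurable sense
  probability inside genes (1/2 elsewhere).
- **Tumor screens** draw per-tumor background integrations from the bias
  model (as one batched draw partitioned across tumors — one intensity
  evaluation per screen) plus, per planted CIS locus, a selected
  integration with probability 1 − exp(−strength), scattered N(0, 5 kb) and
  snapped to the nearest eligible motif site; activating loci keep a fixed
  orientation with probability 0.95.

What passing tests show: the statistics recover planted log-linear biases,
control their null error rates, and match independent brute-force oracles.
What they do not show: robustness to real-genome artifacts absent from the
generator — repeat structure and alignment bias beyond the k-mer
mappability model, copy-number variation, PCR amplification noise, cell
population structure, or biases not expressible as a log-linear tilt of the
supplied tracks.

## Problem sizes and numerical choices

Test and acceptance runs use megabase-scale genomes (1–10 Mb), 10³–10⁵
integrations, m = 5–10 controls, 500–2000 Monte-Carlo null screens, 50
bootstrap networks on 5000-row datasets, and 10⁵-cell null calibrations —
sizes chosen so each claim retains statistical power while a full run stays
in the minutes range on one CPU.  Other numerical choices: log-ratio
pseudocount ε = 1 normalized count (recorded in track metadata); running
means truncate at array ends (a constant track maps to itself); chromosome-
edge score windows truncate to the available side; rank normalization uses
average ranks for ties; BH-FDR throughout where "FDR" is called for;
float32 accumulation in the large Monte-Carlo calibrations (differences
from float64 are far below the Monte-Carlo noise).
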