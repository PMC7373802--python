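# Methods

## The propagation model

The node universe V joins n non-coding regulators (lncRNAs, pseudogenes)
with m gene-side nodes (alternatively spliced genes and their co-effectors:
transcription factors, splicing factors, miRNAs), N = n + m. Three
undirected evidence layers are defined over V: two bipartite layers
(co-expression and epigenetic regulation, each connecting the non-coding
side to the gene side) and one gene-side PPI layer. No layer may connect
two non-coding regulators — the model assumes no usable lncRNA–lncRNA
interaction evidence. Whether co-effectors should be vertices of the
propagated graph or folded into lncRNA–gene edges is genuinely open; they
are admitted here as gene-side vertices, which keeps curated TF/ASF/miRNA
interactions usable without re-curation.

Merging averages the per-layer edge weights over the fixed layer count K:

    E_ij = (1/K) * sum_k [E_k]_ij

The denominator is deliberately K (not the number of layers containing the
edge), so multi-layer support is rewarded and single-layer evidence is
down-weighted by construction. Binary evidence layers carry weight 1.0;
the co-expression layer can optionally carry |r| (flag, default binary).

The transition matrix column-normalizes the merged adjacency,
B_ij = A_ij / sum_k A_kj. Isolated nodes (zero column) become
self-absorbing (B_jj = 1): this preserves column-stochasticity without
teleporting their mass to non-neighbors. The walk iterates

    p(t+1) = (1 - alpha) B p(t) + alpha p_s

from p(0) = p_s. Because the map is an alpha-contraction in L1, the L1
distance between successive iterates shrinks at rate at most (1 - alpha),
total probability is conserved exactly at every step, and the fixed point
equals the closed form p = alpha (I - (1-alpha) B)^{-1} p_s, which the
package implements separately as a dense analytic cross-check.

Parameters: restart probability alpha = 0.5 (default; higher alpha keeps
mass near the seeds), L1 tolerance 1e-10, iteration cap 10,000. At
alpha = 0.5 convergence needs about log(tol)/log(0.5) ≈ 35 iterations, so
the cap is generous. The transition matrix is kept sparse (CSR); only the
closed-form cross-check densifies.

Seed vectors are normalized to a probability distribution (mass 1/|seeds|
per seed) so that the conservation invariant holds; a
`normalize_seeds=False` / `--unnormalized-seeds` mode sets each seed entry
to 1 instead, which rescales all scores by |seeds| and leaves the ranking
unchanged. Rankings are deterministic: scores sort descending with
lexicographic node-id tie-breaks, ranks consecutive from 1.

## Isoform switches

The isoform fraction IF of isoform i in sample s is its share of its
gene's total abundance; it is undefined (NaN) where the gene total is
zero, and isoforms that are zero in every sample are discarded up front.
A switch statistic compares per-sample IF values between tumor and normal
with a two-sided Welch t-test per isoform — chosen as a simple,
well-powered test at the emulated sample sizes, swappable behind the
`IsoformSwitchTester` interface — with Benjamini–Hochberg correction
across all testable isoforms. An isoform with fewer than two defined IF
values in either condition is reported untested (missing p), never
silently dropped; zero-variance isoforms with identical means get p = 1.
Significance requires |dIF| > 0.1 and q < 0.05, two-sided (fraction gain
and loss are both switches).

## Splice-event classification

Each switched isoform is compared with its gene's reference isoform — the
isoform with the highest mean IF in normal samples, ties broken by id.
Coordinates are 1-based inclusive; classification is strand-aware:

- **ATSS / ATTS**: the transcription start (strand-aware 5' end of the
  transcript) or termination coordinate differs.
- **IR**: a query exon fully spans two adjacent reference exons plus the
  intervening intron.
- **MEE**: an internal query exon lies inside a reference intron, an
  internal reference exon lies inside a query intron, the two exons do not
  overlap, and the two host introns do (i.e. the exclusive exons occupy
  the same inter-flank region).
- **ES**: an internal reference exon inside the query's span overlaps no
  query exon (and is not the MEE partner).
- **A5 / A3**: an overlapping exon pair differs at a non-terminal
  boundary; on the plus strand a right-edge (donor) difference is A5 and a
  left-edge (acceptor) difference is A3, with labels swapped on the minus
  strand. Transcript-terminal boundaries belong to ATSS/ATTS and exons
  already explained by IR are excluded.

When several patterns could explain the same exons, precedence is
ATSS/ATTS, then IR, then MEE, then ES, then A5/A3. Two symmetries follow
from the construction and are enforced by tests: relabeling the strand at
fixed coordinates swaps A5↔A3 and ATSS↔ATTS; mirroring coordinates *and*
flipping the strand cancels out and leaves all labels unchanged.

Gain/loss enrichment per event type uses Fisher's exact test on the 2×2
table [type-t gain, type-t loss; other gain, other loss], two-sided by the
standard convention (summing table probabilities no larger than the
observed one), BH-corrected across testable types; a type with zero events
is reported untestable rather than given a p-value.

## Co-expression edges

All lncRNA × target pairs are scored with Pearson r; the p-value uses the
t-transform with n − 2 degrees of freedom (exact under bivariate
normality). BH runs once over the full tested pair set — matching a
single-FDR design — after excluding zero-variance (undefined) pairs, which
reduces the correction burden m. Edges require |r| > 0.75 and q < 0.05;
the sign of r labels the lncRNA activator or inhibitor. Correlation is
computed on the matrices as given; the package's own pipelines pass
log-transformed abundances, the field's standard practice for expression
correlation.

## Evaluation

True positives are scarce relative to the negative pool, so each of 10
repetitions draws a balanced negative sample of size |TPG| without
replacement and computes the AUC by the Mann–Whitney rank formulation
(average-rank convention under ties); the reported performance is the mean
over repetitions. The scheme is balanced subsampling; the repetition count
and RNG seed are explicit, and results are bit-reproducible given the
seed. The step-ROC trapezoid area and the rank AUC are two independent
computations of the same quantity and must agree to machine precision —
this dual route is a standing test. Cross-validation is not implemented:
no fold structure over network edges is defined in this design.

### Rank-cutoff rule

"Sudden drop" needs a numerical definition. Walking down the ranking in
windows of w = 10 ranks, each window's slope ΔTPR/ΔFPR is compared with
the steepest slope seen so far; the cutoff is the last rank before the
first drop below θ = 0.1 times that maximum. Two regularizations make the
rule usable on noisy rankings: (i) for the running maximum, a window with
zero false positives gets a half-count FP floor instead of an infinite
slope — otherwise a single pure-positive window would make *any*
subsequent window look like a drop; (ii) the drop must persist for two
consecutive windows (or reach the end of the list), which keeps uniform
random interleavings from triggering spurious elbows. If no drop occurs
the full list length is returned with a warning. Both w and θ are exposed.

## Synthetic data

The network generator plants an association module: chosen lncRNAs connect
to chosen seed AS genes with probability p_in = 0.3 in both bipartite
layers, and the seed genes form a denser PPI block at the same p_in,
against Erdős–Rényi background at p_bg = 0.01, with 200 lncRNAs and 300
genes, 20 planted lncRNAs and 30 seed genes by default. These defaults
define the standard strong-signal study condition; setting p_in = p_bg
gives the matched null.

The expression generator draws per-gene log-normal abundances
(log-mean 3, log-sd 0.5 — a moderate dynamic range), splits each gene over
two isoforms by Dirichlet-distributed isoform fractions around base mean
(0.5, 0.5), shifts the tumor mean IF of switched isoforms by the planted
dIF (default 0.3), and couples lncRNA log-profiles to target genes through
a shared latent factor, target-side mixing sqrt(rho)·z + sqrt(1−rho)·ε,
so the expected log-scale Pearson correlation equals rho (default 0.9).
The Dirichlet concentration defaults to 5 (moderate IF variability,
marginal sd ≈ 0.2 at mean 0.5); `concentration_for_if_sd` converts a
target IF noise sd into a concentration (sd 0.05 ↔ concentration 99) for
low-noise scenarios. Exon structures are emitted so that each switched
isoform differs from its reference by one chosen event type, with
templates for all seven types; unswitched siblings differ only by a
termination-site shift.

What the generators do *not* emulate: read-count noise (negative-binomial
sampling, library-size variation), correlated gene–gene background
structure, scale-free degree distributions, multi-isoform (>2) genes, and
batch effects. Passing the planted-recovery tests therefore demonstrates
the correctness and calibration of the statistics under their nominal
assumptions, not robustness to the full messiness of tumor RNA-seq.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as the package's own
benchmark design: 100 random graphs up to 200 nodes for the
iterative-vs-analytic propagation check, the 500-node planted network with
10 bootstrap repetitions, 60 genes × 100 samples for switch recovery with
20 permutation-null repeats, 30 × 40 pairs at 100 samples for
co-expression recovery, 1,000 random score/label sets for the AUC
consistency check, and exhaustive Fisher validation over all 2×2 tables
with total ≤ 40 (one representative per symmetry orbit). Degenerate inputs
are handled explicitly rather than by convention: empty seed sets, unknown
ids, single-class label vectors, zero-variance profiles, and all-zero
expression rows each raise or flag as documented above.

## Known limitations

- The walk runs on the collapsed network; multiplex propagation with
  inter-layer jump rates is out of scope by design.
- The switch test treats IF values as approximately normal within
  condition; at very low gene totals the Dirichlet/ratio noise is
  heteroskedastic and a count-aware test would be preferable.
- Event classification is pairwise against a single reference isoform;
  a flagless all-pairs mode is a natural extension.
- The cutoff rule's two regularizations (FP floor, sustained-drop) are the
  package's own operationalization of an informally stated criterion;
  alternative elbow detectors (e.g. maximum-curvature) would be reasonable.
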