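# splicewalk

Network propagation for prioritizing lncRNAs that regulate alternative
splicing. Long non-coding RNAs can steer splice-site choice — directly,
through splicing factors (ASFs), or through transcription factors — but
only a handful of such regulators are experimentally characterized.
`splicewalk` ranks candidate lncRNAs by integrating three layers of
evidence over one node universe of non-coding regulators and
alternatively spliced (AS) genes:

1. **co-expression** — a bipartite layer linking lncRNAs to AS genes whose
   expression they track (Pearson |r| > 0.75, BH q < 0.05; positive r marks
   an activator, negative an inhibitor);
2. **epigenetic regulation** — a bipartite layer of physical/regulatory
   lncRNA–target interactions (curated input);
3. **splicing-pathway PPI** — protein–protein interactions among the AS
   genes and their co-effectors.

## Model

Layers are collapsed into one weighted adjacency by averaging over the
fixed layer count *K* (here 3):

$$E_{ij} = \frac{1}{K}\sum_{k=1}^{K} [E_k]_{ij}$$

so an edge supported by one layer carries 1/3 of its weight. The
column-stochastic transition matrix is $B_{ij} = A_{ij} / \sum_k A_{kj}$,
and node scores are the stationary point of a random walk with restart,

$$p^{t+1} = (1-\alpha)\,B\,p^{t} + \alpha\,p_s,\qquad \alpha = 0.5,$$

where $p_s$ places restart mass on seed genes with known AS-regulatory
roles. Candidate lncRNAs/pseudogenes are ranked by stationary probability,
evaluated by bootstrap ROC against true-positive/true-negative gene lists
(balanced negative subsamples, 10 repetitions), and a top-*n* cutoff is
chosen where the ΔTPR/ΔFPR slope of the ranking suddenly drops.

Upstream of the walk, the package detects **isoform switches** (difference
in isoform fraction |dIF| > 0.1 with Welch-test BH q < 0.05 between tumor
and normal), classifies each switched isoform's splicing pattern against
its gene's dominant normal isoform (A3, A5, ES, MEE, ATSS, ATTS, IR), and
tests gain/loss enrichment per pattern with Fisher's exact test.

The core steps are exposed as scikit-learn style estimators —
`RandomWalkRanker`, `IsoformSwitchTester`, `CoexpressionNetwork` — with
plain functions (`merge_layers`, `rwr`, `classify_as_events`,
`bootstrap_auc`, …) underneath.

## Worked example

Everything runs on synthetic data with known ground truth. Generate a
3-layer network with a planted module (20 AS-associated lncRNAs wired to
30 seed genes at edge probability 0.3 against a 0.01 background), rank,
and evaluate:

```sh
splicewalk simulate network --seed 7 --outdir fixtures
splicewalk rank \
    --layers fixtures/coexpression.tsv,fixtures/epigenetic.tsv,fixtures/ppi.tsv \
    --nodes fixtures/nodes.tsv --seeds fixtures/seed_genes.txt \
    --alpha 0.5 --out ranking.tsv
```

```
propagation: 23 iterations, converged=True
wrote 200 ranked candidates to ranking.tsv
```

`ranking.tsv` starts:

```
id      rank    score                   node_class
L0160   1       0.011151408970981446    lncRNA
L0093   2       0.010144467146279113    lncRNA
L0165   3       0.00972029874771695     lncRNA
```

The score column is the stationary restart probability: the walker's
long-run chance of sitting on that lncRNA when restarts return it to the
seed AS genes. Evaluating against the planted truth:

```sh
splicewalk evaluate --scores ranking.tsv --tpg fixtures/planted_lnc.txt \
    --tng tng.txt --reps 10 --seed 1 --out eval.json
```

```
mean AUC = 1.000 over 10 reps; chosen n = 20
```

Every balanced bootstrap repetition separates the 20 planted lncRNAs
perfectly from background (AUC 1.0), and the ΔTPR/ΔFPR elbow lands exactly
at rank 20 — the size of the planted module.

The expression side works the same way (`splicewalk simulate expression`,
then `splicewalk switches` and `splicewalk coexpress`), with planted dIF
shifts and planted lncRNA–gene correlations as the recoverable truth.

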