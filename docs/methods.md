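# Methods

## The combinatory score

The method scores each candidate gene *g* in a DEG universe by counting,
separately for levels k = 1, 2, 3, the PPI partners at shortest-path
distance exactly k that (a) belong to the DEG universe and (b) pass the
pairwise co-expression filter against *g*. Three choices deserve spelling
out because the verbal definition of the method leaves them open:

**Exclusive level assignment.** A protein reachable at distance 1 also has
2-step walks to the source, so "level 2: A–X–B" could be read as
path-existence. We assign each partner to its exact shortest-path distance
only: the level sets of one source are pairwise disjoint, and a direct
partner is never double-counted at level 2 or 3. This matches drawing the
gene-of-interest network with disjoint level-1/level-2 node classes. A
non-exclusive path-exists mode (`level_profile(..., exclusive=False)`)
exists for sensitivity analysis.

**Endpoint-only co-expression.** The retention rule tests the candidate and
the level-k partner; intermediate proteins on level-2/3 paths need only
exist in the PPI graph. They carry signal physically, not transcriptionally,
and the retention counts are defined on pairs. A strict mode
(`PlaceConfig(strict_intermediates=True)`) additionally requires some
shortest path whose interior proteins all pass the filter against the
candidate.

**Ordering.** "Descending by the number of level 1, level 2 and level 3
genes" can mean a priority order or a sum. The default is descending
lexicographic on (n1, n2, n3) — direct physical partners are the strongest
evidence — with ties broken alphabetically; `ordering="total"` ranks by
n1+n2+n3, and the pipeline's ranked table reports both ranks side by side.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| r_min | 0.5 | minimum Pearson r for retention (positive-only; `use_absolute_r` for \|r\|) |
| p_max | 0.05 | maximum two-sided p (raw; BH optional via `adjust="bh"`) |
| max_level | 3 | deepest level counted (any K ≥ 1 accepted) |
| max_percent_mt | 20.0 | QC keeps cells strictly below this mitochondrial % |
| norm scale | 1e4 | per-cell library target before log1p |
| max_padj | 0.05 | BH-adjusted Wilcoxon p for DEG calling |
| min_abs_logfc | 0.25 | \|avg log fold change\| for DEG calling, two-sided |
| logfc_base | 2 | fold-change base (base e selectable) |
| top_k | 10 | candidates reported / networks exported |

The correlation significance is the exact t-transform on n−2 degrees of
freedom; |r| within machine epsilon of 1 reports p = 0. Pairs with a
constant vector have undefined correlation; they are skipped and counted,
never fatal. Correlations are computed over all selected cells (tumor +
normal) by default; a cell subset can be passed for a tumor-only analysis —
which of the two the original analysis used is not recoverable, so the
default is the unrestricted one and is stated here.

The fold change uses the pseudocount mean-of-expm1 convention,
log((mean expm1 a + 1)/(mean expm1 b + 1)), the convention of the standard
single-cell toolkit whose printed tables use base 2 (its methods prose says
natural log; both bases are supported, base 2 is the default). The Wilcoxon
rank-sum p is exact by enumeration when both groups have ≤ 10 tie-free
observations and a tie-corrected normal approximation with continuity
correction otherwise; the two branches agree within 0.02 absolute at group
sizes ≥ 8 (asserted in the tests). The QC boundary is strict: a cell at
exactly 20% mitochondrial reads is removed.

Survival uses a median split — strictly above the median is "high",
at-or-below is "low" (configurable quantile) — and the standard two-group
log-rank statistic with the pooled risk-set convention for ties and no
continuity correction (via lifelines). Over-representation is the
hypergeometric upper tail P(X ≥ k) with the expression matrix's gene set as
the default universe and BH across sets. Bulk edge confirmation reuses the
retention thresholds (r > 0.5, p < 0.05) unless overridden; partners absent
from the cohort count in the denominator as unconfirmed by default, and the
summary line always prints the thresholds used.

## What the synthetic fixtures emulate

`make_fixture(seed)` builds an Erdős–Rényi background interactome (~180
genes, edge probability 0.05) and attaches a planted component rooted at a
key gene: 6 direct partners, 5 level-2 partners behind one intermediate,
and 4 level-3 partners behind a chain of two. The planted component is
deliberately disconnected from the background graph, so every planted
distance is exact by construction and the manifest can state the expected
score of every gene without re-simulation — the keystone end-to-end test
compares the full pipeline against these manifest values.

Counts are Poisson draws around a log-normal rate (a negative-binomial-like
scheme) for 250 tumor + 250 normal cells. The planted family (key +
partners) shares one per-cell latent Gaussian factor whose loading is set
from the target pairwise correlation ρ (default 0.9) against the per-gene
log-noise; Poisson counting noise lowers the realized r slightly (~0.8 on
log-normalized values at the default expression level), which the tests
check directly rather than assume. The family also carries a 3-fold mean
shift in tumor cells, putting its realized log2FC near 1.3 — far above the
0.25 calling threshold. Background genes are independent with no group
effect; their base expression is set high enough that the library-
composition shift induced by the planted up-regulation (tumor libraries are
slightly larger) stays near 0.03 in log2, an order of magnitude below the
calling threshold. Five MT-prefixed genes contribute ~4% of each library,
and 5% of cells get a 10× mitochondrial boost (~30%) so the QC cutoff
removes exactly the planned cells. Bernoulli dropout (rate 0.1) thins
background genes — its role is sparsity and zero-variance stress (two
all-zero genes are also included), not perturbation of the controlled
planted correlation. The bulk cohort (100 samples) reuses the shared-factor
construction on the same family and converts through the FPKM→TPM path;
survival times are exponential with hazard ∝ exp(β·standardized key-gene
log-expression), β = 1.5 by default, with independent exponential
censoring.

What the fixtures do **not** emulate: realistic scRNA-seq sparsity at
genome scale, batch effects, doublets, ambient RNA, cell-type mixtures, or
correlated survival covariates. Passing tests therefore demonstrate that
the implementation computes its definitions correctly and recovers planted
structure under controlled conditions — not that the thresholds are optimal
for any real dataset.

## Problem sizes

The default fixture is 200 genes × 500 cells with a 100-sample bulk cohort;
the end-to-end recovery check runs 20 seeded replicates, the Pearson null
calibration 1000 pairs at n = 200, and the log-rank null calibration 500
replicates at n = 60 — sizes chosen so the whole suite and the acceptance
script each finish in well under a minute on one CPU while leaving the
statistical checks with useful power.

## Numerical and degenerate-input conventions

Duplicate PPI edges in either orientation collapse; self-loops are dropped
(their nodes kept only if seen elsewhere, configurable). Identifier mapping
is case-sensitive; post-mapping collisions merge nodes with a warning.
Candidates absent from the interactome score (0, 0, 0) rather than erroring
— a DEG outside the PPI data is simply unsupported by physical evidence.
All output tables and network exports are sorted deterministically
(canonical edge orientation, alphabetical tie-breaks), so identical inputs
and config give byte-identical outputs; the core scoring path uses no
randomness. BH adjustment is the standard step-up, capped at 1. All-zero
expression samples, zero-event survival tables, and splits that empty a
group raise informative errors instead of propagating NaNs.

## Known limitations

Pairwise Pearson on log-normalized counts is sensitive to library-size
artifacts and detects only linear, positive (by default) co-expression.
Level counts ignore edge confidence — one low-evidence PPI edge changes a
shortest path. The exact Wilcoxon branch is limited to small groups by
combinatorics. The enrichment step is plain ORA, not a ranked method. None
of these change the method's definition; they bound its interpretation.
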