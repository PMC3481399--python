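# Methods

## Scope and data model

dgconnect computes the quantitative core of a disease–gene–drug
connectivity analysis from four inputs: a confidence-weighted undirected
PPI network (TSV/SIF edge list, conf ∈ (0, 1]), a disease seed-gene list,
two term-annotated abstract corpora (JSONL; one record per abstract with
pre-annotated drug and protein term sets), and per-abstract drug→protein
direction evidence (TSV). Term extraction, name mapping and differential
expression analysis are upstream concerns: the toolkit consumes their
outputs. Expression state enters as a per-gene status table
(over/under/unchanged) or a logFC table thresholded symmetrically at a
user-chosen cut-off.

## Network relevance score

Seeds are expanded by breadth-first search to a configurable hop depth
(default 1 — partner proteins of the seeds) and the subgraph induced on
the reached node set is scored. For protein *p* with partners *q* in the
subnetwork,

    r_p = k * ln(sum_q conf(p, q)) - ln(deg(p)),

with k = 2 by default. Both sums run over the expanded subnetwork, not the
full network, so scores reflect the disease context. Properties used as
tests: with all conf = 1, r_p = ln(deg); adding a unit-confidence edge to
a node with Σconf ≥ 1 strictly increases r_p; scores are invariant to
edge-list order (partner confidences are accumulated with `math.fsum`
over lexicographically sorted partners, so the floating-point sum is
order-independent). Degree-0 proteins have no defined score (log 0) and
are excluded from rankings rather than pinned at −∞; ranking ties break
lexicographically. Scores are kept at full double precision; the 2-decimal
rounding seen in report tables is applied only by writers.

Duplicate undirected edges keep the maximum confidence (consistent with
upstream "keep interactions above a confidence grade" filtering);
self-loops are dropped with a warning since the score counts interaction
partners.

## Literature enrichment statistic

For drug term *d*, the document frequency df(d | S) of a document set S is
the fraction of its records whose drug-term set contains *d*. Each corpus
is reduced to per-sample dfs, then to a mean and variance, and the two
corpora are compared by Welch's statistic

    delta = (mean_net - mean_bg) / sqrt(var_net/N_net + var_bg/N_bg),

where N is the number of resampled sets per corpus (default 100), with a
two-sided p-value from the t distribution at Welch–Satterthwaite degrees
of freedom. Degenerate inputs are defined explicitly: both variances zero
with equal means gives delta = 0 (p = 1); with unequal means a signed
infinity sentinel (p = 0).

**Resampling design.** The default scheme partitions each corpus into
N disjoint, equally sized blocks (block size ⌊n/N⌋; a remainder smaller
than N is left out) and takes each block's df as one sample. Because
documents are independent draws, disjoint blocks are independent, and the
Welch test on block dfs is calibrated: simulated type-I error at α = 0.05
over 500 null terms lies within the 3-SE binomial band for every seed
tested. Bootstrap resampling with replacement is also provided
(`method="bootstrap"`, `sample_corpus(replace=True)`) but deliberately not
used for testing: resample means of a *fixed* corpus concentrate around
that corpus's df at rate 1/N, while the corpus-level sampling noise in
mean_net − mean_bg does not shrink, so under the null the statistic is
inflated by roughly sqrt(N) (measured type-I ≈ 0.85 at α = 0.05 with
N = 100 on 200-document corpora). The bootstrap path is appropriate only
for descriptive df distributions.

Each corpus's resampling RNG is seeded from the run seed *and* the
corpus's document ids. This makes resamples a function of the corpus
rather than of argument position, with two exact consequences used as
invariants: swapping retrieved and background negates delta and preserves
p exactly, and comparing a corpus with itself yields delta = 0, p = 1 for
every term (a partition's block-df mean equals the corpus df exactly).

No multiple-testing correction is applied by default (drug-level p < 0.05
is the conventional reporting cut-off here); a Benjamini–Hochberg helper
is available. `-log10(p)` is exposed as a convenience `association` score —
an artifact definition of this package, not a published quantity.
Top drug-protein pairs are selected among pairs with at least one
co-mentioning abstract, ordered by (drug p ascending, protein r_p
descending), truncated to n (default 500).

## Directionality aggregation

Evidence categories map to votes: activation/up-regulated → +1,
inhibition/down-regulated → −1, indirect/ambiguous/unknown → 0. Zero
votes do not influence the outcome but are counted (n_other), so record
counts are conserved. A pair's direction is sign(n_up − n_down); labels
are only-up / only-down when one side is unopposed, primarily-up /
primarily-down for a strict majority with at least one dissent, ambiguous
on ties (including all-zero evidence). "Primarily" is a strict majority,
not a supermajority — the smallest assumption consistent with
majority-vote curation. Manual tie-breaking by tracing original references
or tissue context is not automatable; conflicting symmetric evidence stays
ambiguous.

## Drug-effect classification and net score

The direction × status truth table has nine cells: 2 therapeutic
(+1/under, −1/over), 2 toxic (+1/over, −1/under), 2 neutral
(±1/unchanged) and 3 ambiguous (direction 0). Annotated partners that are
not differentially expressed get an explicit *neutral* label rather than
being silently dropped, so effect counts always sum to the number of
annotated pairs. The table is symmetric under simultaneously flipping
over↔under and the direction sign.

A drug's net score is Σ r_p over therapeutic pairs minus Σ r_p over toxic
pairs — proteins weigh in proportion to their network relevance, and
neutral/ambiguous pairs contribute nothing, making the score additive
over disjoint annotation subsets. The overall call thresholds the net
score at ±τ (default 0); published overall judgements are qualitative, so
τ is a user dial, not a fitted constant. Per-pair evidence counts are
carried through but do not weight the score.

## Evaluation metrics

sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
F = harmonic mean of PPV and sensitivity, ACC = (TP+TN)/|universe|; PPV
and F are defined as 0 when no positives are predicted. From
(sens, spec, PPV) alone, prevalence follows from Bayes' rule via
π/(1−π) = PPV(1−spec)/(sens(1−PPV)), and ACC = sens·π + spec·(1−π); this
inversion is used to check published metric tables for internal
consistency. The packaged nine-cancer performance table is consistent to
±0.01 percentage points — one unit in the last printed digit, the
tightest check its 2-decimal inputs support.

## Synthetic data

Generators are pure functions of (parameters, seed), using one
`numpy.random.Generator` per call:

* **gen_network** — Erdős–Rényi topology; confidences Beta(4, 1.5)
  (mass concentrated near 1, mimicking a database filtered to reliable
  interaction grades), clipped away from exact 0.
* **gen_corpus_pair** — each document includes each vocabulary term
  independently at a corpus-specific rate; planted terms get
  (rate_net, rate_bg), others a shared base rate (default 0.1). Test
  conditions follow the statistical acceptance setup: 200 documents per
  corpus, 100 resample blocks, planted enrichment 0.6 vs 0.05.
* **gen_evidence** — each record repeats the pair's true direction with
  probability 1 − flip_prob, else the opposite (true 0 stays 0);
  flip_prob < 0.5 keeps the majority vote consistent. At flip_prob = 0.2
  and 9 records/pair the majority is wrong with probability
  P(Bin(9, 0.2) ≥ 5) ≈ 0.020, so ≥ 95% recovery over 500 pairs is the
  tested bound (expected ≈ 98%).
* **gen_expression** — exactly round(frac·n) genes per differential
  status, assigned by a seeded permutation.

What the generators do *not* emulate: real corpora have correlated term
occurrences (a drug co-occurs with its targets), networks are scale-free
rather than Erdős–Rényi, evidence noise is not symmetric, and expression
calls carry their own error. Passing tests therefore demonstrate the
correctness and calibration of the computations under the stated
independence assumptions, not performance on real literature or
expression data.

## Fixtures

Packaged under `dgconnect/data/` as plain TSV, doubling as format
documentation: the nine-abstract Tamoxifen–ESR1 evidence set (7
inhibition, 2 activation), the 17-row Tamoxifen/Plicamycin directionality
table with r_p scores, the luminal A and basal-like expression statuses
over those partners, and the nine-cancer performance metric table. The
r_p values in the directionality table are inputs transcribed from the
published case study — they depend on a proprietary interaction database
snapshot and are never recomputed here. The expression-status fixtures
encode the published subtype assignments; the underlying microarray
differential analysis is out of scope.

## Problem sizes and determinism

Default test and acceptance problem sizes — 200-document corpora, 100
resample blocks, 500 null terms, 20-seed power panels, 500 evidence pairs,
≤ 25-node oracle graphs — were chosen so the statistical assertions have
comfortable margins (3-SE bands, binomial tails below 1/50 of the bound)
while the whole suite runs in seconds. All randomness flows through
explicit seeds; pipeline outputs embed no timestamps, so a rerun with the
same config and seed is byte-identical (verified by manifest checksums).

## Known limitations

* Evidence aggregation treats abstracts as independent, equally credible
  votes; context (tissue, subtype, dose) is not modelled.
* The net score's linear r_p weighting is a design choice, not a fitted
  model; overall therapeutic/toxic calls at τ = 0 are descriptive, not
  clinical predictions.
* The enrichment test assumes documents are exchangeable within a corpus;
  retrieval bias (e.g. query-dependent abstract selection) is not
  corrected.
* Star-grade style confidence conventions vary by source database; any
  conf ∈ (0, 1] is accepted and the mapping is left to the user.
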