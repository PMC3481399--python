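"""Drug-term enrichment in a retrieved corpus versus a background corpus.

For each drug term d the statistic compares the term's average document
frequency between resampled subsets of the disease-specific ("retrieved")
corpus and of a background corpus:

    delta = (mean_df_net - mean_df_bg) /
            sqrt(var_df_net / n_net + var_df_bg / n_bg)

i.e. Welch's two-sample t statistic on the per-sample document-frequency
vectors, with a two-sided p-value from the t distribution at
Welch–Satterthwaite degrees of freedom.

Resampling scheme
-----------------
The default scheme ("partition") randomly splits each corpus into
``n_samples`` disjoint, equally sized blocks and uses each block's
document frequency as one sample. Because documents are independent,
disjoint blocks give independent df samples and the Welch test is
calibrated (type-I error ~ alpha under the null). Bootstrap resampling
with replacement ("bootstrap") is also available but is *not* calibrated
for significance testing: the variance of resample means shrinks with
the number of resamples while the corpus-level sampling noise in the
mean difference does not, which inflates |delta| roughly by
sqrt(n_samples) under the null. Use the bootstrap only for descriptive
df distributions.
"""

from __future__ import annotations

import logging
import math
import zlib

import numpy as np
from scipy import stats

from .errors import ValidationError
from .model_io import Corpus, DocRecord, DrugEnrichment, RankedProtein

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 100


def document_frequency(drug: str, docs: list[DocRecord]) -> float:
    """Fraction of documents whose drug-term set contains ``drug``."""
    if not docs:
        raise ValidationError("document list is empty")
    return sum(drug in d.drug_terms for d in docs) / len(docs)


def sample_corpus(
    corpus: Corpus,
    n_samples: int,
    sample_size: int,
    seed: int | None = None,
    replace: bool = True,
) -> list[list[DocRecord]]:
    """Draw ``n_samples`` random document lists of ``sample_size`` each.

    Sampling is with replacement by default; without replacement it
    requires ``sample_size <= len(corpus)``. Reproducible per seed.
    """
    if n_samples < 1 or sample_size < 1:
        raise ValidationError("n_samples and sample_size must be >= 1")
    if not replace and sample_size > len(corpus):
        raise ValidationError(
            f"sample_size {sample_size} exceeds corpus size {len(corpus)} "
            "when sampling without replacement"
        )
    rng = np.random.default_rng(seed)
    records = corpus.records
    return [
        [records[i] for i in rng.choice(len(records), size=sample_size, replace=replace)]
        for _ in range(n_samples)
    ]


def corpus_rng(corpus: Corpus, seed: int | None) -> np.random.Generator:
    """RNG bound to (seed, corpus content).

    Seeding resample draws with the corpus's document ids as well as the
    run seed makes each corpus's resampling independent of the order in
    which corpora are processed, so swapping the retrieved and
    background arguments negates delta *exactly* and comparing a corpus
    against itself is exactly null.
    """
    if seed is None:
        return np.random.default_rng()
    crc = zlib.crc32("\n".join(sorted(r.doc_id for r in corpus.records)).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, crc]))


def partition_corpus(
    corpus: Corpus, n_samples: int, seed: int | None = None
) -> list[list[DocRecord]]:
    """Randomly split a corpus into ``n_samples`` disjoint equal blocks.

    Block size is ``len(corpus) // n_samples``; a remainder of fewer
    than ``n_samples`` documents is left out of the partition. The same
    (seed, corpus) always yields the same partition.
    """
    idx = _partition_indices(len(corpus), n_samples, corpus_rng(corpus, seed))
    return [[corpus.records[i] for i in block] for block in idx]


def _partition_indices(n_docs: int, n_samples: int, rng) -> np.ndarray:
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if n_samples > n_docs:
        raise ValidationError(
            f"cannot partition {n_docs} documents into {n_samples} blocks"
        )
    size = n_docs // n_samples
    perm = rng.permutation(n_docs)[: n_samples * size]
    return perm.reshape(n_samples, size)


def enrichment_statistic(
    mean_net: float,
    mean_bg: float,
    var_net: float,
    var_bg: float,
    n_net: int,
    n_bg: int,
) -> float:
    """Welch-type statistic on mean document frequencies.

    Degenerate zero-variance inputs return 0 when the means agree and a
    signed infinity sentinel when they differ.
    """
    if n_net < 2 or n_bg < 2:
        raise ValidationError("sample counts must be >= 2")
    if var_net < 0 or var_bg < 0:
        raise ValidationError("variances must be non-negative")
    se2 = var_net / n_net + var_bg / n_bg
    diff = mean_net - mean_bg
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(se2)


def welch_df(var_net: float, var_bg: float, n_net: int, n_bg: int) -> float:
    """Welch–Satterthwaite degrees of freedom (1.0 when both variances vanish)."""
    a = var_net / n_net
    b = var_bg / n_bg
    denom = a * a / (n_net - 1) + b * b / (n_bg - 1)
    if denom == 0.0:
        return 1.0
    return (a + b) ** 2 / denom


def drug_pvalue(
    delta: float, n_net: int, n_bg: int, var_net: float, var_bg: float
) -> float:
    """Two-sided t-test p-value for an enrichment statistic."""
    if n_net < 2 or n_bg < 2:
        raise ValidationError("sample counts must be >= 2")
    if math.isinf(delta):
        return 0.0
    if delta == 0.0:
        return 1.0
    df = welch_df(var_net, var_bg, n_net, n_bg)
    return float(2.0 * stats.t.sf(abs(delta), df))


def _membership(corpus: Corpus, vocab: list[str]) -> np.ndarray:
    """Boolean docs x vocab term-presence matrix."""
    index = {t: j for j, t in enumerate(vocab)}
    m = np.zeros((len(corpus), len(vocab)), dtype=bool)
    for i, rec in enumerate(corpus.records):
        for t in rec.drug_terms:
            j = index.get(t)
            if j is not None:
                m[i, j] = True
    return m


def enrich_drugs(
    retrieved: Corpus,
    background: Corpus,
    vocabulary: set[str],
    n_samples: int = DEFAULT_N_SAMPLES,
    sample_size: int | None = None,
    seed: int | None = None,
    method: str = "partition",
) -> list[DrugEnrichment]:
    """Score every vocabulary term's enrichment in the retrieved corpus.

    Per corpus, per-sample document frequencies are reduced to a mean
    and variance, from which the Welch statistic and two-sided p-value
    follow. ``rel_freq`` is the term's df over the whole retrieved
    corpus. Results are sorted by ascending p, then descending delta,
    then term. ``sample_size`` applies to the bootstrap method only
    (default ``min(1000, corpus size)``); the partition method derives
    block size from ``n_samples``.
    """
    if method not in ("partition", "bootstrap"):
        raise ValidationError(f"unknown resampling method {method!r}")
    if not vocabulary:
        logger.warning("empty drug vocabulary; nothing to enrich")
        return []
    vocab = sorted(vocabulary)

    m_net = _membership(retrieved, vocab)
    m_bg = _membership(background, vocab)
    dfs = []
    for corpus, m in ((retrieved, m_net), (background, m_bg)):
        rng = corpus_rng(corpus, seed)
        n_docs = m.shape[0]
        if method == "partition":
            idx = _partition_indices(n_docs, n_samples, rng)
        else:
            size = sample_size if sample_size is not None else min(1000, n_docs)
            if size < 1:
                raise ValidationError("sample_size must be >= 1")
            idx = rng.integers(0, n_docs, size=(n_samples, size))
        dfs.append(m[idx].mean(axis=1))  # (n_samples, n_terms)
    df_net, df_bg = dfs

    mean_net = df_net.mean(axis=0)
    mean_bg = df_bg.mean(axis=0)
    var_net = df_net.var(axis=0, ddof=1)
    var_bg = df_bg.var(axis=0, ddof=1)
    rel_freq = m_net.mean(axis=0)

    results = []
    for j, term in enumerate(vocab):
        delta = enrichment_statistic(
            mean_net[j], mean_bg[j], var_net[j], var_bg[j], n_samples, n_samples
        )
        p = drug_pvalue(delta, n_samples, n_samples, var_net[j], var_bg[j])
        results.append(
            DrugEnrichment(
                drug=term,
                delta=float(delta),
                p_value=p,
                mean_df_net=float(mean_net[j]),
                mean_df_bg=float(mean_bg[j]),
                var_df_net=float(var_net[j]),
                var_df_bg=float(var_bg[j]),
                n_net=n_samples,
                n_bg=n_samples,
                rel_freq=float(rel_freq[j]),
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.delta, r.drug))
    return results


def benjamini_hochberg(results: list[DrugEnrichment]) -> dict[str, float]:
    """Optional BH-adjusted q-values keyed by drug term (off by default
    in the pipeline)."""
    if not results:
        return {}
    pvals = np.array([r.p_value for r in results])
    order = np.argsort(pvals)
    m = len(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, pvals[i] * m / rank)
        q[i] = prev
    return {results[i].drug: float(q[i]) for i in range(m)}


def co_mention_counts(corpus: Corpus) -> dict[tuple[str, str], int]:
    """Count documents co-mentioning each (drug term, protein term) pair."""
    counts: dict[tuple[str, str], int] = {}
    for rec in corpus:
        for d in rec.drug_terms:
            for p in rec.protein_terms:
                counts[(d, p)] = counts.get((d, p), 0) + 1
    return counts


def select_top_pairs(
    ranked_proteins: list[RankedProtein],
    enriched_drugs: list[DrugEnrichment],
    pair_evidence_counts: dict[tuple[str, str], int],
    n: int,
) -> list[tuple[str, str]]:
    """Top drug-protein pairs with literature co-mention support.

    Pairs require at least one co-mentioning document and are ordered by
    (drug p-value ascending, protein r_p descending), then
    lexicographically, truncated to ``n``.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    pvals = {e.drug: e.p_value for e in enriched_drugs}
    scores = {r.protein_id: r.r_p for r in ranked_proteins}
    pairs = [
        (drug, protein)
        for (drug, protein), count in pair_evidence_counts.items()
        if count >= 1 and drug in pvals and protein in scores
    ]
    pairs.sort(key=lambda dp: (pvals[dp[0]], -scores[dp[1]], dp[0], dp[1]))
    return pairs[:n]
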