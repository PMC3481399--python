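"""Seeded generators for every input type the pipeline consumes.

The generators emulate the statistical structure the method assumes —
sparse confidence-weighted PPI graphs, corpora with planted drug-term
enrichment in the retrieved subcorpus, per-pair direction evidence with
a dominant direction plus curation noise, and expression profiles with
fixed over/under fractions — so every stage is testable offline. Each
generator is a pure function of its parameters and seed.

``load_fixture`` serves the packaged transcriptions of the published
breast-cancer case-study tables (Tamoxifen–ESR1 evidence, the
Tamoxifen/Plicamycin directionality table with r_p scores, the
luminal A and basal-like expression statuses, and the nine-cancer
performance table).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model_io import (
    Corpus,
    DocRecord,
    EvidenceRecord,
    ExpressionProfile,
    WeightedNetwork,
    read_evidence,
    read_expression,
)

FIXTURES = (
    "table3_tamoxifen_esr1",
    "table5_directionality",
    "luminalA_status",
    "basal_status",
    "performance_table",
)


def gen_network(
    n_nodes: int,
    edge_prob: float,
    conf_dist_params: tuple[float, float] = (4.0, 1.5),
    seed: int | None = None,
) -> WeightedNetwork:
    """Erdős–Rényi topology with Beta-distributed confidences in (0, 1].

    The default Beta(4, 1.5) concentrates mass near high confidence,
    mimicking an interaction database filtered to its more reliable
    grades. Nodes are named ``P0001`` ...
    """
    if not (0.0 < edge_prob <= 1.0):
        raise ValidationError(f"edge_prob must be in (0, 1], got {edge_prob}")
    if n_nodes < 1:
        raise ValidationError("n_nodes must be >= 1")
    a, b = conf_dist_params
    if a <= 0 or b <= 0:
        raise ValidationError("Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    names = [f"P{i + 1:04d}" for i in range(n_nodes)]
    net = WeightedNetwork()
    for name in names:
        net.add_node(name)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                conf = float(rng.beta(a, b))
                # Beta mass at exactly 0 is null; guard for float underflow
                conf = min(max(conf, 1e-12), 1.0)
                net.add_edge(names[i], names[j], conf)
    return net


def gen_corpus_pair(
    n_docs_each: int,
    vocab: list[str],
    enriched_terms: dict[str, tuple[float, float]],
    base_rate: float = 0.1,
    seed: int | None = None,
    protein_vocab: list[str] | None = None,
    protein_rate: float = 0.0,
) -> tuple[Corpus, Corpus]:
    """Generate (retrieved, background) corpora with planted enrichment.

    Every document includes each vocabulary term independently at its
    corpus-specific rate: ``enriched_terms[term] = (rate_net, rate_bg)``
    for planted terms, ``base_rate`` in both corpora otherwise. Protein
    terms, when requested, are included at ``protein_rate`` in both
    corpora (enough structure for co-mention counting).
    """
    if n_docs_each < 1:
        raise ValidationError("n_docs_each must be >= 1")
    if not (0.0 <= base_rate <= 1.0):
        raise ValidationError("base_rate must be in [0, 1]")
    for term, (r_net, r_bg) in enriched_terms.items():
        if not (0.0 <= r_net <= 1.0 and 0.0 <= r_bg <= 1.0):
            raise ValidationError(f"rates for {term!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    protein_vocab = protein_vocab or []

    def make(label: str, prefix: str, which: int) -> Corpus:
        records = []
        for i in range(n_docs_each):
            drugs = {
                t
                for t in vocab
                if rng.random() < enriched_terms.get(t, (base_rate, base_rate))[which]
            }
            proteins = {p for p in protein_vocab if rng.random() < protein_rate}
            records.append(
                DocRecord(
                    doc_id=f"{prefix}{i + 1:07d}",
                    drug_terms=frozenset(drugs),
                    protein_terms=frozenset(proteins),
                )
            )
        return Corpus(records, label=label)

    return make("retrieved", "NET", 0), make("background", "BG", 1)


def gen_evidence(
    pairs: list[tuple[str, str]],
    true_direction: dict[tuple[str, str], int],
    n_records_per_pair: int = 9,
    flip_prob: float = 0.2,
    seed: int | None = None,
) -> list[EvidenceRecord]:
    """Noisy per-abstract evidence around each pair's true direction.

    Each record carries the pair's true direction with probability
    ``1 - flip_prob`` and the opposite direction otherwise (a true
    direction of 0 stays 0). ``flip_prob`` must be below 0.5 so the
    majority vote is consistent.
    """
    if not (0.0 <= flip_prob < 0.5):
        raise ValidationError(f"flip_prob must be in [0, 0.5), got {flip_prob}")
    if n_records_per_pair < 1:
        raise ValidationError("n_records_per_pair must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    doc = 0
    for drug, protein in pairs:
        true = true_direction[(drug, protein)]
        if true not in (-1, 0, 1):
            raise ValidationError(f"true direction for ({drug}, {protein}) invalid")
        for _ in range(n_records_per_pair):
            doc += 1
            direction = true
            if true != 0 and rng.random() < flip_prob:
                direction = -true
            records.append(
                EvidenceRecord(
                    drug=drug,
                    protein=protein,
                    doc_id=f"SYN{doc:07d}",
                    direction=direction,
                )
            )
    return records


def gen_expression(
    genes: list[str],
    frac_over: float,
    frac_under: float,
    seed: int | None = None,
) -> ExpressionProfile:
    """Assign over/under/unchanged statuses at exact fractions.

    ``round(frac * n)`` genes get each differential status, drawn
    without replacement from a seeded permutation.
    """
    if frac_over < 0 or frac_under < 0 or frac_over + frac_under > 1:
        raise ValidationError("fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    n_over = int(round(frac_over * n))
    n_under = int(round(frac_under * n))
    order = rng.permutation(n)
    statuses = {g: "unchanged" for g in genes}
    for i in order[:n_over]:
        statuses[genes[i]] = "over"
    for i in order[n_over : n_over + n_under]:
        statuses[genes[i]] = "under"
    return ExpressionProfile(statuses)


def _fixture_path(name: str):
    return resources.files("dgconnect.data").joinpath(f"{name}.tsv")


def load_fixture(name: str):
    """Load a packaged case-study fixture by name.

    Returns typed records: evidence records for
    ``table3_tamoxifen_esr1``, a DataFrame (drug, protein, r_p,
    direction) for ``table5_directionality``, expression profiles for
    ``luminalA_status``/``basal_status``, and a DataFrame of published
    percent metrics for ``performance_table``.
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; known: {FIXTURES}")
    path = _fixture_path(name)
    with resources.as_file(path) as p:
        if name == "table3_tamoxifen_esr1":
            return read_evidence(p)
        if name in ("luminalA_status", "basal_status"):
            return read_expression(p)
        return pd.read_csv(p, sep="\t")
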