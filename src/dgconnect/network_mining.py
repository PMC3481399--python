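"""Seed-list expansion over a PPI network and relevance-score ranking.

A disease is represented by a seed list of proteins. The seed set is
expanded over the confidence-weighted interaction network by breadth-
first search up to a small hop depth, and every protein in the induced
subnetwork is scored by its network relevance

    r_p = k * ln(sum_q conf(p, q)) - ln(deg(p)),

where the sums run over p's interaction partners q in the subnetwork,
``conf`` is the interaction confidence in (0, 1] and ``k`` is an
empirical constant (default 2). When every confidence is 1 the score
reduces to ``ln(deg(p))``; with k = 2 it rewards many high-confidence
partners and penalises promiscuous low-confidence hubs. Scores may be
negative; isolated proteins have no score (log of zero) and are
excluded from rankings.
"""

from __future__ import annotations

import logging
import math

import networkx as nx

from .errors import ValidationError
from .model_io import RankedProtein, SeedList, WeightedNetwork

logger = logging.getLogger(__name__)

DEFAULT_K = 2.0


def expand_subnetwork(
    seeds: SeedList, network: WeightedNetwork, depth: int = 1
) -> WeightedNetwork:
    """Induce the subnetwork on the seeds and everything within ``depth`` hops.

    Seeds absent from the network are kept as isolated nodes (and
    logged); ``depth=0`` induces on the seeds alone.
    """
    if depth < 0:
        raise ValidationError(f"depth must be >= 0, got {depth}")
    if not seeds.genes:
        raise ValidationError("empty seed list")
    present = [g for g in seeds.genes if g in network]
    missing = [g for g in seeds.genes if g not in network]
    if missing:
        logger.warning(
            "%d seed(s) absent from network, kept as isolated nodes: %s",
            len(missing), ", ".join(missing[:10]),
        )
    reached: set[str] = set(seeds.genes)
    if depth > 0:
        for g in present:
            reached.update(
                nx.single_source_shortest_path_length(
                    network.graph, g, cutoff=depth
                )
            )
    sub = network.graph.subgraph(n for n in reached if n in network).copy()
    sub.add_nodes_from(missing)
    return WeightedNetwork(sub)


def relevance_score(
    protein: str, subnetwork: WeightedNetwork, k: float = DEFAULT_K
) -> float:
    """Network relevance r_p = k·ln(Σ conf) − ln(degree) of one protein."""
    if protein not in subnetwork:
        raise ValidationError(f"protein {protein!r} not in subnetwork")
    degree = subnetwork.degree(protein)
    if degree == 0:
        raise ValidationError(
            f"protein {protein!r} has no interactions; r_p is undefined"
        )
    # fsum over sorted partners: exact invariance to edge-list order
    total_conf = math.fsum(
        subnetwork.conf(protein, q) for q in sorted(subnetwork.neighbors(protein))
    )
    return k * math.log(total_conf) - math.log(degree)


def rank_proteins(
    subnetwork: WeightedNetwork,
    k: float = DEFAULT_K,
    seeds: SeedList | None = None,
) -> list[RankedProtein]:
    """Rank every connected protein by descending r_p (ties: lexicographic).

    Degree-0 nodes are omitted with a warning; ``seeds`` only sets the
    ``is_seed`` flag on the output records.
    """
    if len(subnetwork) == 0:
        raise ValidationError("subnetwork is empty")
    seed_set = set(seeds.genes) if seeds is not None else set()
    isolated = [p for p in subnetwork.nodes if subnetwork.degree(p) == 0]
    if isolated:
        logger.warning(
            "%d isolated protein(s) excluded from ranking: %s",
            len(isolated), ", ".join(sorted(isolated)[:10]),
        )
    ranked = [
        RankedProtein(p, relevance_score(p, subnetwork, k=k), is_seed=p in seed_set)
        for p in subnetwork.nodes
        if subnetwork.degree(p) > 0
    ]
    ranked.sort(key=lambda r: (-r.r_p, r.protein_id))
    return ranked
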