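"""Therapeutic/toxic classification of drug-protein pairs and net efficacy.

The working hypothesis is expression reversal: a good drug pushes a
disease expression profile back toward the healthy range. A drug acting
on a protein is therefore

* **therapeutic** when it opposes the disease change — activates an
  under-expressed protein or inhibits an over-expressed one;
* **toxic** when it reinforces the change — activates an over-expressed
  protein or inhibits an under-expressed one;
* **ambiguous** when the direction of action is unknown (direction 0);
* **neutral** when the partner is not differentially expressed.

A drug's overall assessment weights each pair by the protein's network
relevance r_p: ``net_score = sum r_p(therapeutic) - sum r_p(toxic)``,
called therapeutic when the score exceeds +tau, toxic below -tau, else
neutral.
"""

from __future__ import annotations

from collections import Counter
import logging
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .model_io import (
    DirectionalityAnnotation,
    DrugEffectAssessment,
    ExpressionProfile,
    PairEffect,
    STATUSES,
)

logger = logging.getLogger(__name__)

_EFFECT_TABLE = {
    (1, "under"): "therapeutic",
    (-1, "over"): "therapeutic",
    (1, "over"): "toxic",
    (-1, "under"): "toxic",
    (1, "unchanged"): "neutral",
    (-1, "unchanged"): "neutral",
    (0, "over"): "ambiguous",
    (0, "under"): "ambiguous",
    (0, "unchanged"): "ambiguous",
}


def classify_effect(direction: int, status: str) -> str:
    """Classify one (drug direction, expression status) combination."""
    if direction not in (-1, 0, 1):
        raise ValidationError(f"direction must be -1, 0 or 1, got {direction!r}")
    if status not in STATUSES:
        raise ValidationError(f"status must be one of {STATUSES}, got {status!r}")
    return _EFFECT_TABLE[(direction, status)]


def assess_drug(
    drug: str,
    annotations: Sequence[DirectionalityAnnotation],
    profile: ExpressionProfile,
    scores: Mapping[str, float],
    tau: float = 0.0,
) -> DrugEffectAssessment:
    """Assess one drug against an expression profile.

    ``annotations`` may contain other drugs; they are ignored. Proteins
    missing from the profile count as unchanged; proteins missing from
    ``scores`` get r_p = 0 with a warning.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    mine = [a for a in annotations if a.drug == drug]
    if not mine:
        raise ValidationError(f"no directionality annotations for drug {drug!r}")
    pairs = []
    for a in mine:
        if a.protein not in scores:
            logger.warning("no r_p score for %r; using 0", a.protein)
        status = profile.status(a.protein)
        pairs.append(
            PairEffect(
                protein=a.protein,
                r_p=float(scores.get(a.protein, 0.0)),
                direction=a.direction,
                status=status,
                effect=classify_effect(a.direction, status),
            )
        )
    counts = Counter(p.effect for p in pairs)
    counts = {e: counts.get(e, 0) for e in ("therapeutic", "toxic", "neutral", "ambiguous")}
    net = sum(p.r_p for p in pairs if p.effect == "therapeutic") - sum(
        p.r_p for p in pairs if p.effect == "toxic"
    )
    if net > tau:
        overall = "therapeutic"
    elif net < -tau:
        overall = "toxic"
    else:
        overall = "neutral"
    return DrugEffectAssessment(
        drug=drug, pairs=pairs, counts=counts, net_score=net, overall=overall, tau=tau
    )


def build_drug_subnetwork(assessment: DrugEffectAssessment) -> nx.Graph:
    """Star graph drug→partners with display attributes.

    Node attributes: the drug node gets ``shape=hexagon``; protein
    nodes carry ``size`` (r_p), ``status`` and ``color`` (over→red,
    under→green). Edges carry ``direction``, ``effect`` and ``color``
    (activate→red, inhibit→green).
    """
    if not assessment.pairs:
        raise ValidationError("assessment contains no drug-protein pairs")
    status_color = {"over": "red", "under": "green", "unchanged": "grey"}
    direction_color = {1: "red", -1: "green", 0: "grey"}
    g = nx.Graph()
    g.add_node(assessment.drug, kind="drug", shape="hexagon")
    for p in assessment.pairs:
        g.add_node(
            p.protein,
            kind="protein",
            size=p.r_p,
            status=p.status,
            color=status_color[p.status],
        )
        g.add_edge(
            assessment.drug,
            p.protein,
            direction=p.direction,
            effect=p.effect,
            color=direction_color[p.direction],
        )
    return g


def annotations_from_frame(df: pd.DataFrame) -> list[DirectionalityAnnotation]:
    """Build single-vote annotations from a (drug, protein, direction) table.

    Intended for curated tables that record only the consensus
    direction: each row becomes an annotation with one vote on the
    corresponding side.
    """
    out = []
    for row in df.itertuples(index=False):
        d = int(row.direction)
        out.append(
            DirectionalityAnnotation(
                drug=row.drug,
                protein=row.protein,
                direction=d,
                n_up=1 if d == 1 else 0,
                n_down=1 if d == -1 else 0,
                n_other=1 if d == 0 else 0,
                label={1: "only-up", -1: "only-down", 0: "ambiguous"}[d],
            )
        )
    return out


def scores_from_frame(df: pd.DataFrame) -> dict[str, float]:
    """Extract a protein→r_p map from a table with protein and r_p columns."""
    return {row.protein: float(row.r_p) for row in df.itertuples(index=False)}
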