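"""Majority-vote aggregation of per-abstract drug→protein direction evidence.

Each abstract contributes one vote: +1 (activation/up-regulation), −1
(inhibition/down-regulation) or 0 (indirect/ambiguous/unknown — counted
but non-voting). A pair's direction is the sign of the vote margin, and
its label records unanimity: "only-up"/"only-down" when one side is
unopposed, "primarily-up"/"primarily-down" for a strict majority with
dissent, "ambiguous" on a tie (including all-zero evidence).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Sequence

from .errors import ValidationError
from .model_io import DirectionalityAnnotation, EvidenceRecord


def _label(n_up: int, n_down: int) -> str:
    if n_up > 0 and n_down == 0:
        return "only-up"
    if n_down > 0 and n_up == 0:
        return "only-down"
    if n_up > n_down:
        return "primarily-up"
    if n_down > n_up:
        return "primarily-down"
    return "ambiguous"


def aggregate_direction(records: Sequence[EvidenceRecord]) -> DirectionalityAnnotation:
    """Aggregate all evidence records of a single (drug, protein) pair."""
    if not records:
        raise ValidationError("no evidence records to aggregate")
    pairs = {(r.drug, r.protein) for r in records}
    if len(pairs) != 1:
        raise ValidationError(
            f"records span {len(pairs)} (drug, protein) pairs; expected one"
        )
    (drug, protein) = next(iter(pairs))
    votes = Counter(r.direction for r in records)
    n_up, n_down, n_other = votes[1], votes[-1], votes[0]
    direction = (n_up > n_down) - (n_down > n_up)
    return DirectionalityAnnotation(
        drug=drug,
        protein=protein,
        direction=direction,
        n_up=n_up,
        n_down=n_down,
        n_other=n_other,
        label=_label(n_up, n_down),
    )


def aggregate_all(records: Sequence[EvidenceRecord]) -> list[DirectionalityAnnotation]:
    """One annotation per distinct (drug, protein) pair, sorted by pair."""
    groups: dict[tuple[str, str], list[EvidenceRecord]] = defaultdict(list)
    for r in records:
        groups[(r.drug, r.protein)].append(r)
    return [aggregate_direction(groups[key]) for key in sorted(groups)]


def directionality_summary(
    annotations: Sequence[DirectionalityAnnotation],
) -> dict[str, int]:
    """Histogram over labels plus the count of directed (non-zero) pairs."""
    counts = Counter(a.label for a in annotations)
    summary = {label: counts.get(label, 0) for label in (
        "only-up", "only-down", "primarily-up", "primarily-down", "ambiguous"
    )}
    summary["directed"] = sum(1 for a in annotations if a.direction != 0)
    return summary
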