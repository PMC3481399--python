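"""Confusion-matrix metrics for benchmarking drug identification.

Given a predicted drug set, a gold-standard set and the universe of
candidate drugs:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        ACC = (TP + TN) / |universe|
    F           = 2 * PPV * Sens / (PPV + Sens)

PPV and F fall back to 0 when their denominators vanish. The module
also inverts the metric algebra: from (sensitivity, specificity, PPV)
alone the implied prevalence pi and accuracy follow from Bayes' rule,

    PPV = Sens*pi / (Sens*pi + (1 - Spec)*(1 - pi))
    ACC = Sens*pi + Spec*(1 - pi),

useful as a consistency check on published metric tables.
"""

from __future__ import annotations

from .errors import ValidationError
from .model_io import ConfusionMetrics


def confusion_metrics(predicted: set, gold: set, universe: set) -> ConfusionMetrics:
    """Compute metrics for a predicted set against a gold standard."""
    predicted, gold, universe = set(predicted), set(gold), set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not gold <= universe:
        raise ValidationError("gold standard must be a subset of the universe")
    if not predicted <= universe:
        raise ValidationError("predicted set must be a subset of the universe")
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(universe) - tp - fp - fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    acc = (tp + tn) / len(universe)
    return ConfusionMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, f_score=f, acc=acc
    )


def f_score(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV (0 when both vanish)."""
    if sensitivity + ppv == 0:
        return 0.0
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def implied_prevalence_acc(sens: float, spec: float, ppv: float) -> tuple[float, float]:
    """Invert PPV for the prevalence pi, then return (pi, implied ACC).

    All inputs must lie strictly in (0, 1); the inversion
    pi/(1-pi) = PPV*(1-Spec) / (Sens*(1-PPV)) then always has a unique
    solution in (0, 1).
    """
    for name, v in (("sens", sens), ("spec", spec), ("ppv", ppv)):
        if not (0.0 < v < 1.0):
            raise ValidationError(f"{name} must be strictly inside (0, 1), got {v}")
    odds = ppv * (1.0 - spec) / (sens * (1.0 - ppv))
    pi = odds / (1.0 + odds)
    acc = sens * pi + spec * (1.0 - pi)
    return pi, acc
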