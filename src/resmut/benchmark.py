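"""Evaluation of predicted resistance calls against experimental labels.

Deep-mutational-scanning style benchmarks provide a binary resistant /
sensitive label per mutant (mutants requiring three base exchanges and
mutations to Pro are excluded upstream, mirroring how such datasets are
pruned before comparison).  Besides the standard confusion-matrix cells,
two workflow-specific rates are reported: the fraction of
predicted-resistant mutants confirmed by experiment (tp_rate), and the
fraction of residues carrying at least one experimentally resistant mutant
at which the workflow predicts at least one resistant mutant
(residue_discovery_rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = ["ConfusionMatrix", "evaluate_against_labels"]

Key = tuple[int, str, str]  # (position, wt_aa, mut_aa)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    residue_discovery_rate: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def tp_rate(self) -> float:
        """Fraction of predicted-resistant mutants confirmed by experiment."""
        predicted_positive = self.tp + self.fp
        if predicted_positive == 0:
            return math.nan
        return self.tp / predicted_positive

    @property
    def sensitivity(self) -> float:
        """Fraction of experimentally resistant mutants recovered."""
        positives = self.tp + self.fn
        if positives == 0:
            return math.nan
        return self.tp / positives

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "n": self.n,
            "accuracy": self.accuracy,
            "tp_rate": self.tp_rate,
            "sensitivity": self.sensitivity,
            "residue_discovery_rate": self.residue_discovery_rate,
        }


def evaluate_against_labels(
    predictions: Mapping[Key, bool], labels: Mapping[Key, bool]
) -> ConfusionMatrix:
    """Score binary resistance predictions against experimental labels.

    Both mappings must be keyed by identical (position, wt_aa, mut_aa)
    triples; a key present on one side only raises with the missing keys
    listed.
    """
    missing_pred = sorted(set(labels) - set(predictions))
    missing_lab = sorted(set(predictions) - set(labels))
    if missing_pred or missing_lab:
        raise KeyError(
            f"keys without prediction: {missing_pred}; "
            f"keys without label: {missing_lab}"
        )
    if not labels:
        raise ValueError("empty label set")
    tp = tn = fp = fn = 0
    resistant_residues: set[int] = set()
    discovered: set[int] = set()
    predicted_residues: set[int] = set()
    for key, labeled in labels.items():
        predicted = predictions[key]
        if predicted:
            predicted_residues.add(key[0])
        if labeled:
            resistant_residues.add(key[0])
        if predicted and labeled:
            tp += 1
        elif predicted and not labeled:
            fp += 1
        elif not predicted and labeled:
            fn += 1
        else:
            tn += 1
    discovered = resistant_residues & predicted_residues
    rate = (
        len(discovered) / len(resistant_residues)
        if resistant_residues
        else math.nan
    )
    return ConfusionMatrix(
        tp=tp, tn=tn, fp=fp, fn=fn, residue_discovery_rate=rate
    )
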