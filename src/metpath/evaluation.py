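"""Jackknife evaluation: ordered accuracies, coverage and label-count stats.

Each labeled node is scored with its own labels withheld (leave-one-out over
labels; all other nodes' labels stay available).  Because the likelihood of a
node never consults its own labels, the jackknife is exact, not approximate.

Statistics
----------
ordered accuracy   ACC_j = CM_j / N, where CM_j counts samples whose j-th
                   ranked class is *any* of their true classes.
coverage           L_m = sum_i S_i,m / sum_i N_i, with S_i,m the number of
                   sample i's true classes among its first m ranked classes
                   and N_i its true class count.  By default m = ceil(M).
average labels     M = sum_i N_i / N, kept as an exact fraction.
random guess       a uniformly guessed class is correct with probability M/11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from .classes import N_CLASSES
from .network import COMPOUND, ENZYME, HybridNetwork, LabelTable
from .predictor import LikelihoodVector, RankedPrediction, likelihood, rank


def _resolve_subset(labels: LabelTable, subset: Iterable[str] | str | None) -> list[str]:
    if subset is None or subset == "all":
        return sorted(labels)
    if subset == "compounds":
        return sorted(s for s in labels if labels.kind(s) == COMPOUND)
    if subset == "enzymes":
        return sorted(s for s in labels if labels.kind(s) == ENZYME)
    ids = [s.upper() for s in subset]
    missing = [s for s in ids if s not in labels]
    if missing:
        raise ValueError(f"subset contains unlabeled node(s): {missing[:5]}")
    return ids


def jackknife(
    net: HybridNetwork,
    labels: LabelTable,
    subset: Iterable[str] | str | None = None,
) -> dict[str, RankedPrediction]:
    """Leave-one-out ranked predictions for every evaluated sample.

    ``subset`` may be ``None``/``"all"``, ``"compounds"``, ``"enzymes"`` or an
    explicit iterable of node ids.  Nodes absent from the network (possible
    when labels cover more nodes than the edge list) are scored as isolated:
    an all-zero vector ranked M1..M11.
    """
    results: dict[str, RankedPrediction] = {}
    for s in _resolve_subset(labels, subset):
        if s in net:
            results[s] = rank(likelihood(net, labels, s))
        else:
            results[s] = rank(LikelihoodVector(query=s, values=(0,) * N_CLASSES))
    return results


def ordered_accuracy(
    results: Mapping[str, RankedPrediction], labels: LabelTable
) -> tuple[Fraction, ...]:
    """ACC_1..ACC_11 over the evaluated samples (exact fractions).

    A sample counts toward CM_j when its j-th ranked class is one of its true
    classes; the denominator N is the full sample count at every order.
    """
    n = len(results)
    if n == 0:
        raise ValueError("no samples to evaluate")
    correct = [0] * N_CLASSES
    for s, pred in results.items():
        true = labels[s]
        for j, cls in enumerate(pred.order):
            if cls in true:
                correct[j] += 1
    return tuple(Fraction(c, n) for c in correct)


def coverage(
    results: Mapping[str, RankedPrediction],
    labels: LabelTable,
    m: int | None = None,
) -> Fraction:
    """L_m: the fraction of all true class memberships found in the top m.

    When ``m`` is omitted it defaults to the ceiling of the average label
    count of the evaluated samples.
    """
    if m is None:
        m = math.ceil(average_label_count(labels, results.keys()))
    if not 1 <= m <= N_CLASSES:
        raise ValueError(f"m must be in 1..{N_CLASSES}, got {m}")
    hit = 0
    total = 0
    for s, pred in results.items():
        true = labels[s]
        total += len(true)
        hit += sum(1 for cls in pred.order[:m] if cls in true)
    if total == 0:
        raise ValueError("no true labels among evaluated samples")
    return Fraction(hit, total)


def average_label_count(
    labels: LabelTable, subset: Iterable[str] | str | None = None
) -> Fraction:
    """M: average number of pathway classes per sample, as an exact fraction."""
    ids = _resolve_subset(labels, subset)
    if not ids:
        raise ValueError("empty subset")
    return Fraction(sum(len(labels[s]) for s in ids), len(ids))


def random_guess_rate(m_avg: Fraction | float) -> Fraction:
    """Expected success rate of a single uniform random class guess: M/11."""
    if not 1 <= m_avg <= N_CLASSES:
        raise ValueError(f"average label count must be in 1..{N_CLASSES}")
    if isinstance(m_avg, Fraction):
        return m_avg / N_CLASSES
    return Fraction(m_avg) / N_CLASSES


@dataclass
class EvaluationReport:
    """Bundle of all jackknife statistics for one evaluated subset."""

    ordered_accuracy: tuple[Fraction, ...]
    coverage: Fraction
    m_used: int
    avg_labels: Fraction
    random_guess: Fraction
    n_samples: int
    per_sample: dict[str, RankedPrediction] = field(repr=False, default_factory=dict)


def evaluate(
    net: HybridNetwork,
    labels: LabelTable,
    subset: Iterable[str] | str | None = None,
    m: int | None = None,
) -> EvaluationReport:
    """Run the jackknife and assemble the full evaluation report."""
    results = jackknife(net, labels, subset)
    avg = average_label_count(labels, results.keys())
    m_used = m if m is not None else math.ceil(avg)
    return EvaluationReport(
        ordered_accuracy=ordered_accuracy(results, labels),
        coverage=coverage(results, labels, m_used),
        m_used=m_used,
        avg_labels=avg,
        random_guess=random_guess_rate(avg),
        n_samples=len(results),
        per_sample=results,
    )
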