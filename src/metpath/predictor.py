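"""Neighbor-weighted likelihood scoring and full ranked class prediction.

The likelihood that a query node ``s`` belongs to pathway class ``Mj`` is the
sum of the confidence scores of the edges joining ``s`` to neighbors that
carry label ``Mj``:

    F(s, Mj) = sum over t in N(s), Mj in labels(t) of Q(s, t)

The query's own labels are never consulted, which makes leave-one-out
evaluation exact: scoring a labeled node already *is* its jackknife
prediction.  Likelihoods are unnormalized integer sums and are kept so.

A prediction is the full permutation of the 11 classes by descending
likelihood; among equal values (including zeros) the class with the smaller
index comes first, so every query always receives a complete, deterministic
1-st .. 11-th order ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classes import N_CLASSES, PATHWAY_CLASSES, PathwayClass
from .network import HybridNetwork, LabelTable


@dataclass(frozen=True)
class LikelihoodVector:
    """The 11 nonnegative integer class scores of one query node.

    ``values[j-1]`` is the likelihood that the query belongs to class Mj; it
    is zero exactly when no labeled neighbor carries that class.
    """

    query: str
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} values, got {len(self.values)}")

    def value(self, cls: PathwayClass) -> int:
        return self.values[cls.index - 1]


@dataclass(frozen=True)
class RankedPrediction:
    """A full (or truncated) ordering of the pathway classes for one query.

    ``order[k-1]`` is the k-th order predicted pathway class and
    ``values[k-1]`` its likelihood; values are non-increasing.
    """

    query: str
    order: tuple[PathwayClass, ...]
    values: tuple[int, ...]

    @property
    def first(self) -> PathwayClass:
        return self.order[0]

    def top(self, k: int) -> tuple[PathwayClass, ...]:
        return self.order[:k]


def likelihood(net: HybridNetwork, labels: LabelTable, s: str) -> LikelihoodVector:
    """Compute the class-likelihood vector of ``s`` from its labeled neighbors.

    Integer-exact; unlabeled neighbors contribute nothing; the labels of
    ``s`` itself are not an input.
    """
    values = [0] * N_CLASSES
    for nb in net.neighbors(s):
        classes = labels.get(nb.id)
        if not classes:
            continue
        for cls in classes:
            values[cls.index - 1] += nb.score
    return LikelihoodVector(query=s.upper(), values=tuple(values))


def rank(v: LikelihoodVector) -> RankedPrediction:
    """Order all 11 classes by descending likelihood, ascending index on ties."""
    ordered = sorted(PATHWAY_CLASSES, key=lambda c: (-v.values[c.index - 1], c.index))
    return RankedPrediction(
        query=v.query,
        order=tuple(ordered),
        values=tuple(v.values[c.index - 1] for c in ordered),
    )


def predict(
    net: HybridNetwork, labels: LabelTable, s: str, top: int = N_CLASSES
) -> RankedPrediction:
    """Ranked prediction for ``s`` truncated to the first ``top`` positions."""
    if not 1 <= top <= N_CLASSES:
        raise ValueError(f"top must be in 1..{N_CLASSES}, got {top}")
    full = rank(likelihood(net, labels, s))
    return RankedPrediction(
        query=full.query, order=full.order[:top], values=full.values[:top]
    )
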