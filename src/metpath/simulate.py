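"""Synthetic labeled hybrid networks with controlled statistical structure.

The generator emulates the gross statistics of a yeast chemical/enzyme
interaction benchmark at reduced size: 11 pathway classes, a roughly 5:1
compound:enzyme ratio, a cc:cp:pp edge-kind mix of about 66:20:14, integer
confidence scores in [1, 999], and a multi-label rate of ~15%.  Two knobs
drive everything the predictor and its evaluation statistics can detect:

homophily h
    the probability that an edge joins two nodes sharing a class -- the
    structural assumption (interacting molecules tend to share pathways)
    that makes guilt-by-association prediction work at all.  At h = 1 with
    single labels every non-isolated node is 1-st order correct; at h = 0
    accuracy collapses toward chance.

score model
    concordant edges draw their score from a high range with probability
    ``p_high_given_concordant`` (else the low range); discordant edges
    always draw from the low range.  Coupling score to concordance makes
    the contribution-rate curves rise with the score threshold, the
    qualitative behaviour seen in real confidence-scored networks.

All randomness flows from one integer seed; identical configs produce
byte-identical edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import CLASS_BY_INDEX, N_CLASSES
from .network import COMPOUND, ENZYME, HybridNetwork, LabelTable

_KIND_ENDPOINTS = {
    "cc": (COMPOUND, COMPOUND),
    "cp": (COMPOUND, ENZYME),
    "pp": (ENZYME, ENZYME),
}


@dataclass(frozen=True)
class ScoreModel:
    """Integer score ranges (inclusive) and the concordant-high probability."""

    low_range: tuple[int, int] = (1, 699)
    high_range: tuple[int, int] = (700, 999)
    p_high_given_concordant: float = 0.8

    def __post_init__(self) -> None:
        for lo, hi in (self.low_range, self.high_range):
            if not (1 <= lo <= hi <= 999):
                raise ValueError(f"score range ({lo}, {hi}) not within [1, 999]")
        if not 0 <= self.p_high_given_concordant <= 1:
            raise ValueError("p_high_given_concordant must be a probability")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic benchmark.

    Defaults mirror the real benchmark's gross statistics at 400 nodes;
    ``mean_degree`` is kept moderate so the enzyme-enzyme subgraph stays
    sparse as it is in real interactomes.
    """

    n_compounds: int = 333
    n_enzymes: int = 67
    n_classes: int = N_CLASSES
    mean_degree: float = 12.0
    homophily: float = 0.6
    multi_label_rate: float = 0.15
    score_model: ScoreModel = field(default_factory=ScoreModel)
    kind_mix: tuple[float, float, float] = (0.66, 0.20, 0.14)  # cc, cp, pp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 0 or self.n_enzymes < 0:
            raise ValueError("node counts must be nonnegative")
        if not 1 <= self.n_classes <= N_CLASSES:
            raise ValueError(f"n_classes must be in 1..{N_CLASSES}")
        for p, name in (
            (self.homophily, "homophily"),
            (self.multi_label_rate, "multi_label_rate"),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability, got {p}")
        if abs(sum(self.kind_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.kind_mix):
            raise ValueError("kind_mix must be nonnegative and sum to 1")
        n = self.n_compounds + self.n_enzymes
        if n > 1 and self.mean_degree >= n - 1:
            raise ValueError(
                f"mean_degree {self.mean_degree} infeasible for {n} nodes"
            )
        if self.mean_degree < 0:
            raise ValueError("mean_degree must be nonnegative")


def _compound_id(i: int) -> str:
    return f"C9{i:04d}"  # KEGG-style id => inferred kind 'compound'


def _enzyme_id(i: int) -> str:
    return f"YSIM{i:04d}"


def generate(
    config: SimulationConfig,
) -> tuple[HybridNetwork, LabelTable, dict]:
    """Generate one labeled hybrid network under the given study conditions.

    Returns ``(network, labels, meta)`` where ``meta`` records the realized
    structure (edge counts per kind, concordant-edge fraction, seed) for
    downstream checks.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ids = [_compound_id(i) for i in range(config.n_compounds)] + [
        _enzyme_id(i) for i in range(config.n_enzymes)
    ]
    kinds = [COMPOUND] * config.n_compounds + [ENZYME] * config.n_enzymes

    labels = LabelTable()
    class_sets: dict[str, frozenset[int]] = {}
    for node_id, kind in zip(ids, kinds):
        primary = int(rng.integers(1, config.n_classes + 1))
        classes = {primary}
        if config.multi_label_rate and rng.random() < config.multi_label_rate:
            second = int(rng.integers(1, config.n_classes))
            if second >= primary:  # uniform over the other classes
                second += 1
            classes.add(second)
        class_sets[node_id] = frozenset(classes)
        labels.set(node_id, {CLASS_BY_INDEX[j] for j in classes}, kind=kind)

    net = HybridNetwork()
    for node_id, kind in zip(ids, kinds):
        net.add_node(node_id, kind=kind)

    pools = {
        COMPOUND: [i for i, k in zip(ids, kinds) if k == COMPOUND],
        ENZYME: [i for i, k in zip(ids, kinds) if k == ENZYME],
    }
    n_total = len(ids)
    target_edges = int(round(config.mean_degree * n_total / 2))
    placed: set[tuple[str, str]] = set()
    n_concordant = 0
    kind_counts = {k: 0 for k in _KIND_ENDPOINTS}
    kind_names = list(_KIND_ENDPOINTS)
    failures = 0
    max_failures = 20 * max(target_edges, 1)
    while len(placed) < target_edges and failures < max_failures:
        kind = kind_names[int(rng.choice(3, p=list(config.kind_mix)))]
        ka, kb = _KIND_ENDPOINTS[kind]
        pool_a, pool_b = pools[ka], pools[kb]
        if not pool_a or not pool_b or (ka == kb and len(pool_a) < 2):
            failures += 1
            continue
        want_concordant = bool(rng.random() < config.homophily)
        # hold kind + concordance fixed while retrying, so duplicate
        # collisions cannot bias the realized concordant fraction
        key = None
        for _ in range(60):
            a = pool_a[int(rng.integers(len(pool_a)))]
            candidates = [
                b
                for b in pool_b
                if b != a and bool(class_sets[a] & class_sets[b]) == want_concordant
            ]
            if not candidates:
                continue
            b = candidates[int(rng.integers(len(candidates)))]
            cand = (a, b) if a < b else (b, a)
            if cand not in placed:
                key = cand
                break
        if key is None:
            failures += 1
            continue
        a, b = key
        placed.add(key)
        concordant = bool(class_sets[a] & class_sets[b])
        sm = config.score_model
        if concordant and rng.random() < sm.p_high_given_concordant:
            lo, hi = sm.high_range
        else:
            lo, hi = sm.low_range
        score = int(rng.integers(lo, hi + 1))
        net.add_edge(a, b, score)
        kind_counts[kind] += 1
        n_concordant += concordant

    n_edges = net.n_edges
    meta = {
        "seed": config.seed,
        "n_nodes": n_total,
        "n_edges": n_edges,
        "target_edges": target_edges,
        "edge_kind_counts": kind_counts,
        "concordant_fraction": (n_concordant / n_edges) if n_edges else float("nan"),
        "class_sets": class_sets,
    }
    return net, labels, meta
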