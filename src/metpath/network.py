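"""Data model and TSV I/O for labeled hybrid chemical-protein networks.

A hybrid network is an undirected graph whose nodes are small molecules
(compounds) and enzymes (proteins).  Each edge carries an integer interaction
confidence score in [1, 999] and one of three kinds: chemical-chemical
(``cc``), chemical-protein (``cp``) or protein-protein (``pp``).  A score of 0
is never stored -- an absent edge *is* the zero-confidence case.

File dialect
------------
Edge TSV:   ``node_a<TAB>node_b<TAB>score[<TAB>kind]``
Label TSV:  ``node_id<TAB>kind<TAB>M5,M8``  (tags comma-separated)

Lines starting with ``#`` are comments in both files.  Node ids are
normalized to upper case on load.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .classes import CLASS_BY_TAG, PATHWAY_CLASSES, PathwayClass

logger = logging.getLogger(__name__)

COMPOUND = "compound"
ENZYME = "enzyme"

EDGE_KINDS = ("cc", "cp", "pp")

_COMPOUND_ID_RE = re.compile(r"C\d{5}")

MIN_SCORE = 1
MAX_SCORE = 999


class NetworkFormatError(ValueError):
    """Malformed edge or label file (message names the offending line)."""


class UnknownNodeError(KeyError):
    """A query referenced a node id that is not in the network."""


def infer_kind(node_id: str) -> str:
    """Infer node kind from its id: KEGG-style ``C`` + 5 digits is a compound."""
    return COMPOUND if _COMPOUND_ID_RE.fullmatch(node_id) else ENZYME


def edge_kind(kind_a: str, kind_b: str) -> str:
    """Edge kind implied by its endpoint kinds (cc / cp / pp)."""
    n_compounds = (kind_a == COMPOUND) + (kind_b == COMPOUND)
    return ("pp", "cp", "cc")[n_compounds]


@dataclass(frozen=True)
class Node:
    id: str
    kind: str  # compound | enzyme


@dataclass(frozen=True)
class Interaction:
    """An undirected scored interaction; (a, b) and (b, a) are the same edge."""

    a: str
    b: str
    score: int
    kind: str  # cc | cp | pp


@dataclass(frozen=True)
class Neighbor:
    id: str
    score: int
    kind: str  # edge kind


class HybridNetwork:
    """Undirected weighted multi-kind interaction graph.

    Thin wrapper over :class:`networkx.Graph` that enforces the domain
    invariants: no self loops, integer scores in [1, 999], edge kind
    consistent with endpoint kinds, max-score deduplication of repeated
    unordered pairs.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, kind: str | None = None) -> None:
        node_id = node_id.upper()
        if not node_id:
            raise ValueError("empty node id")
        kind = kind or infer_kind(node_id)
        if kind not in (COMPOUND, ENZYME):
            raise ValueError(f"unknown node kind: {kind!r}")
        existing = self._g.nodes.get(node_id)
        if existing is not None and existing["kind"] != kind:
            raise ValueError(
                f"node {node_id} declared with conflicting kinds "
                f"{existing['kind']!r} and {kind!r}"
            )
        self._g.add_node(node_id, kind=kind)

    def add_edge(self, a: str, b: str, score: int) -> None:
        """Add an interaction; repeated unordered pairs keep the max score."""
        a, b = a.upper(), b.upper()
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a}")
        if isinstance(score, bool) or not isinstance(score, int):
            raise ValueError(f"score must be an integer, got {score!r}")
        if not MIN_SCORE <= score <= MAX_SCORE:
            raise ValueError(f"score {score} outside [{MIN_SCORE}, {MAX_SCORE}]")
        for n in (a, b):
            if n not in self._g:
                self.add_node(n)
        kind = edge_kind(self._g.nodes[a]["kind"], self._g.nodes[b]["kind"])
        if self._g.has_edge(a, b):
            score = max(score, self._g.edges[a, b]["score"])
        self._g.add_edge(a, b, score=score, kind=kind)

    # -- queries ----------------------------------------------------------
    @property
    def node_ids(self) -> set[str]:
        return set(self._g.nodes)

    def nodes(self) -> Iterator[Node]:
        for n, data in self._g.nodes(data=True):
            yield Node(n, data["kind"])

    def node_kind(self, node_id: str) -> str:
        node_id = node_id.upper()
        if node_id not in self._g:
            raise UnknownNodeError(node_id)
        return self._g.nodes[node_id]["kind"]

    def edges(self) -> Iterator[Interaction]:
        for a, b, data in self._g.edges(data=True):
            yield Interaction(a, b, data["score"], data["kind"])

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id.upper() in self._g

    def score(self, a: str, b: str) -> int:
        """Confidence score of the pair; 0 when no interaction exists."""
        a, b = a.upper(), b.upper()
        if self._g.has_edge(a, b):
            return self._g.edges[a, b]["score"]
        return 0

    def neighbors(self, s: str) -> frozenset[Neighbor]:
        """All interaction partners of ``s`` with their scores and edge kinds."""
        s = s.upper()
        if s not in self._g:
            raise UnknownNodeError(s)
        return frozenset(
            Neighbor(t, data["score"], data["kind"])
            for t, data in self._g.adj[s].items()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HybridNetwork):
            return NotImplemented
        return nx.utils.graphs_equal(self._g, other._g)

    def copy(self) -> "HybridNetwork":
        out = HybridNetwork()
        out._g = self._g.copy()
        return out

    def remove_edge(self, a: str, b: str) -> None:
        self._g.remove_edge(a.upper(), b.upper())

    # -- I/O ---------------------------------------------------------------
    def write_edges_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# node_a\tnode_b\tscore\tkind\n")
            for e in sorted(self.edges(), key=lambda e: (e.a, e.b)):
                fh.write(f"{e.a}\t{e.b}\t{e.score}\t{e.kind}\n")


class LabelTable(Mapping[str, frozenset[PathwayClass]]):
    """Per-node subsets of the 11 pathway classes.

    Behaves as a read-only mapping ``node id -> frozenset[PathwayClass]``;
    every stored node has at least one class.
    """

    def __init__(self, mapping: Mapping[str, Iterable[PathwayClass]] | None = None):
        self._m: dict[str, frozenset[PathwayClass]] = {}
        self._kinds: dict[str, str] = {}
        if mapping:
            for node_id, classes in mapping.items():
                self.set(node_id, classes)

    def set(
        self, node_id: str, classes: Iterable[PathwayClass], kind: str | None = None
    ) -> None:
        node_id = node_id.upper()
        cs = frozenset(classes)
        if not cs:
            raise ValueError(f"node {node_id} must have at least one class")
        self._m[node_id] = cs
        self._kinds[node_id] = kind or infer_kind(node_id)

    def drop(self, node_id: str) -> None:
        node_id = node_id.upper()
        del self._m[node_id]
        del self._kinds[node_id]

    def kind(self, node_id: str) -> str:
        return self._kinds[node_id.upper()]

    def membership_vector(self, node_id: str) -> tuple[int, ...]:
        """The 11-dimensional 0/1 vector: entry j-1 is 1 iff the node is in Mj."""
        cs = self._m[node_id.upper()]
        return tuple(1 if c in cs else 0 for c in PATHWAY_CLASSES)

    def __getitem__(self, node_id: str) -> frozenset[PathwayClass]:
        return self._m[node_id.upper()]

    def __iter__(self) -> Iterator[str]:
        return iter(self._m)

    def __len__(self) -> int:
        return len(self._m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        return self._m == other._m and self._kinds == other._kinds

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# node_id\tkind\tclasses\n")
            for node_id in sorted(self._m):
                tags = ",".join(c.tag for c in sorted(self._m[node_id]))
                fh.write(f"{node_id}\t{self._kinds[node_id]}\t{tags}\n")


# -- parsing ---------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_score(text: str, path: str | Path, lineno: int) -> int:
    text = text.strip()
    try:
        value = float(text)
    except ValueError:
        raise NetworkFormatError(
            f"{path}:{lineno}: score {text!r} is not a number"
        ) from None
    if value != int(value):
        raise NetworkFormatError(
            f"{path}:{lineno}: fractional score {text!r} (scores are integers 1-999)"
        )
    score = int(value)
    if not MIN_SCORE <= score <= MAX_SCORE:
        raise NetworkFormatError(
            f"{path}:{lineno}: score {score} outside [{MIN_SCORE}, {MAX_SCORE}]"
        )
    return score


def load_labels(label_path: str | Path) -> LabelTable:
    """Read a label TSV (``node_id<TAB>kind<TAB>classes``)."""
    table = LabelTable()
    for lineno, fields in _data_lines(label_path):
        if len(fields) != 3:
            raise NetworkFormatError(
                f"{label_path}:{lineno}: expected 3 tab-separated columns, "
                f"got {len(fields)}"
            )
        node_id, kind, tags_field = (f.strip() for f in fields)
        if kind not in (COMPOUND, ENZYME):
            raise NetworkFormatError(
                f"{label_path}:{lineno}: unknown node kind {kind!r}"
            )
        classes = []
        for tag in tags_field.split(","):
            tag = tag.strip()
            if tag not in CLASS_BY_TAG:
                raise NetworkFormatError(
                    f"{label_path}:{lineno}: unknown pathway class tag {tag!r}"
                )
            classes.append(CLASS_BY_TAG[tag])
        if not classes:
            raise NetworkFormatError(f"{label_path}:{lineno}: empty class list")
        table.set(node_id, classes, kind=kind)
    return table


def load_network(
    edge_path: str | Path, label_path: str | Path
) -> tuple[HybridNetwork, LabelTable]:
    """Load and deduplicate a labeled hybrid network from the two TSV files.

    Edges with an unlabeled endpoint can never contribute to any likelihood,
    so they are dropped (with a logged count) rather than kept inert.
    Repeated unordered pairs keep the maximum score.
    """
    labels = load_labels(label_path)
    net = HybridNetwork()
    for node_id in labels:
        net.add_node(node_id, kind=labels.kind(node_id))

    dropped = 0
    for lineno, fields in _data_lines(edge_path):
        if len(fields) not in (3, 4):
            raise NetworkFormatError(
                f"{edge_path}:{lineno}: expected 3 or 4 tab-separated columns, "
                f"got {len(fields)}"
            )
        a, b = fields[0].strip().upper(), fields[1].strip().upper()
        if not a or not b:
            raise NetworkFormatError(f"{edge_path}:{lineno}: empty node id")
        score = _parse_score(fields[2], edge_path, lineno)
        if a == b:
            raise NetworkFormatError(f"{edge_path}:{lineno}: self-interaction {a}")
        if a not in labels or b not in labels:
            dropped += 1
            continue
        net.add_edge(a, b, score)
        if len(fields) == 4:
            declared = fields[3].strip()
            if declared not in EDGE_KINDS:
                raise NetworkFormatError(
                    f"{edge_path}:{lineno}: unknown edge kind {declared!r}"
                )
            actual = edge_kind(labels.kind(a), labels.kind(b))
            if declared != actual:
                raise NetworkFormatError(
                    f"{edge_path}:{lineno}: edge kind {declared!r} inconsistent "
                    f"with endpoint kinds (expected {actual!r})"
                )
    if dropped:
        logger.info("dropped %d edge(s) with unlabeled endpoints", dropped)
    return net, labels
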