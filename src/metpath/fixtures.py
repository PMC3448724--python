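"""Bundled worked-example networks.

Two small labeled networks ship with the package as plain TSV data:

``table2``
    the interaction partners of compound C07277 (6 partners) and enzyme
    YLL058W (11 partners), the canonical worked example of the likelihood
    calculation and its ranked prediction.

``table6``
    the 23 distinct interaction partners of compound C00439, a misclassified
    sample: its true class is M5 (likelihood 7,210) but the top-ranked class
    is M8 (likelihood 10,115).  Partners C00101 and C00025 belong to both
    classes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .network import HybridNetwork, LabelTable, load_network

FIXTURE_NAMES = ("table2", "table6")


def fixture_paths(name: str) -> tuple[Path, Path]:
    """Filesystem paths of the bundled ``(edges, labels)`` TSVs."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    data = resources.files("metpath") / "data"
    return Path(str(data / f"{name}_edges.tsv")), Path(str(data / f"{name}_labels.tsv"))


def load_fixture(name: str) -> tuple[HybridNetwork, LabelTable]:
    """Load one bundled fixture network by name (``table2`` or ``table6``)."""
    edges, labels = fixture_paths(name)
    return load_network(edges, labels)


def paper_fixtures() -> dict[str, tuple[HybridNetwork, LabelTable]]:
    """All bundled worked-example networks, keyed by fixture name."""
    return {name: load_fixture(name) for name in FIXTURE_NAMES}
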