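"""The fixed vocabulary of the 11 major KEGG metabolic pathway classes.

Every predictor, evaluation and analysis routine in this package ranks the
same 11 classes, tagged ``M1`` .. ``M11``.  The index <-> tag <-> name mapping
is a fixed bijection and is never extended at run time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction


@dataclass(frozen=True, order=True)
class PathwayClass:
    """One of the 11 major KEGG metabolic pathway classes.

    Ordering follows ``index`` (1..11), which is also the deterministic
    tie-break order used when ranking predictions.
    """

    index: int
    tag: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.tag


PATHWAY_CLASSES: tuple[PathwayClass, ...] = (
    PathwayClass(1, "M1", "Carbohydrate Metabolism"),
    PathwayClass(2, "M2", "Energy Metabolism"),
    PathwayClass(3, "M3", "Lipid Metabolism"),
    PathwayClass(4, "M4", "Nucleotide Metabolism"),
    PathwayClass(5, "M5", "Amino Acid Metabolism"),
    PathwayClass(6, "M6", "Metabolism of Other Amino Acids"),
    PathwayClass(7, "M7", "Glycan Biosynthesis and Metabolism"),
    PathwayClass(8, "M8", "Metabolism of Cofactors and Vitamins"),
    PathwayClass(9, "M9", "Metabolism of Terpenoids and Polyketides"),
    PathwayClass(10, "M10", "Biosynthesis of Other Secondary Metabolites"),
    PathwayClass(11, "M11", "Xenobiotics Biodegradation and Metabolism"),
)

N_CLASSES: int = len(PATHWAY_CLASSES)

CLASS_BY_TAG: dict[str, PathwayClass] = {c.tag: c for c in PATHWAY_CLASSES}
CLASS_BY_INDEX: dict[int, PathwayClass] = {c.index: c for c in PATHWAY_CLASSES}

# Published distribution of the yeast benchmark over the 11 classes:
# tag -> (number of small molecules, number of enzymes).  Multi-label samples
# are counted once per class, so the columns sum to more than the number of
# distinct samples.
YEAST_CLASS_COUNTS: dict[str, tuple[int, int]] = {
    "M1": (394, 198),
    "M2": (151, 146),
    "M3": (399, 84),
    "M4": (133, 107),
    "M5": (489, 158),
    "M6": (156, 44),
    "M7": (47, 18),
    "M8": (350, 87),
    "M9": (507, 18),
    "M10": (509, 17),
    "M11": (709, 21),
}

#: distinct samples in the yeast benchmark, by kind
YEAST_SAMPLE_COUNTS: dict[str, int] = {"compound": 3348, "enzyme": 654}


def benchmark_membership_total(kind: str | None = None) -> int:
    """Total class memberships in the yeast benchmark (3,844 + 898 = 4,742).

    ``kind`` restricts to ``"compound"`` or ``"enzyme"``; ``None`` sums both.
    """
    if kind is None:
        return sum(c + e for c, e in YEAST_CLASS_COUNTS.values())
    if kind == "compound":
        return sum(c for c, _ in YEAST_CLASS_COUNTS.values())
    if kind == "enzyme":
        return sum(e for _, e in YEAST_CLASS_COUNTS.values())
    raise ValueError(f"unknown kind: {kind!r}")


def benchmark_average_label_count(kind: str | None = None) -> Fraction:
    """Average number of pathway classes per benchmark sample, exact.

    3844/3348 for compounds, 898/654 for enzymes, 4742/4002 overall.
    """
    n = sum(YEAST_SAMPLE_COUNTS.values()) if kind is None else YEAST_SAMPLE_COUNTS[kind]
    return Fraction(benchmark_membership_total(kind), n)
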