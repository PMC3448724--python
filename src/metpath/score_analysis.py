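"""Confidence-score contribution curves and misclassification diagnosis.

Contribution curves quantify how informative high-confidence interactions
are: for each edge kind (cc, cp, pp) and each threshold k in [1, 999],

    R_k = IM_k / I_k

where I_k is the number of edges of that kind with score >= k and IM_k the
number of those whose two endpoints share at least one pathway class.  An
ascending curve means higher-confidence interactions are more often
class-concordant, i.e. contribute more reliably to neighbor-vote prediction.

The diagnosis examines samples whose 1-st order predicted class is wrong and
asks *why* the wrong class won: either it simply had more contributing
neighbor edges ("sum terms") than every true class (situation 1), or more
high-confidence ones, score > 700 by default (situation 2).  "More" can be
read as a count of terms or as their total score; both interpretations are
implemented and recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .classes import PATHWAY_CLASSES, PathwayClass
from .network import EDGE_KINDS, MAX_SCORE, HybridNetwork, LabelTable
from .predictor import RankedPrediction

HIGH_CONFIDENCE_THRESHOLD = 700

INTERPRETATIONS = ("count", "sum")


@dataclass(frozen=True)
class ContributionCurve:
    """R_k = IM_k / I_k over k = 1..999 for one edge kind.

    ``i[k-1]`` and ``im[k-1]`` are I_k and IM_k; ``r[k-1]`` is their ratio,
    NaN where I_k = 0.
    """

    kind: str
    i: np.ndarray
    im: np.ndarray
    r: np.ndarray

    def at(self, k: int) -> tuple[int, int, float]:
        """(I_k, IM_k, R_k) for one threshold; R_k is NaN when I_k = 0."""
        if not 1 <= k <= MAX_SCORE:
            raise ValueError(f"k must be in 1..{MAX_SCORE}")
        return int(self.i[k - 1]), int(self.im[k - 1]), float(self.r[k - 1])


def contribution_curves(
    net: HybridNetwork, labels: LabelTable
) -> dict[str, ContributionCurve]:
    """Compute the cc, cp and pp contribution curves of a labeled network.

    An edge is *concordant* when its endpoints share at least one pathway
    class; edges with an unlabeled endpoint count as discordant (they can
    never contribute to a prediction).
    """
    scores: dict[str, list[int]] = {k: [] for k in EDGE_KINDS}
    concordant: dict[str, list[bool]] = {k: [] for k in EDGE_KINDS}
    for e in net.edges():
        la, lb = labels.get(e.a, frozenset()), labels.get(e.b, frozenset())
        scores[e.kind].append(e.score)
        concordant[e.kind].append(bool(la & lb))

    curves = {}
    ks = np.arange(1, MAX_SCORE + 1)
    for kind in EDGE_KINDS:
        sc = np.asarray(scores[kind], dtype=np.int64)
        co = np.asarray(concordant[kind], dtype=bool)
        # I_k = #edges with score >= k, via a tail-cumulative histogram
        i_k = (sc[None, :] >= ks[:, None]).sum(axis=1) if sc.size else np.zeros(
            MAX_SCORE, dtype=np.int64
        )
        im_k = (
            (sc[None, co] >= ks[:, None]).sum(axis=1)
            if sc.size
            else np.zeros(MAX_SCORE, dtype=np.int64)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r_k = np.where(i_k > 0, im_k / np.maximum(i_k, 1), np.nan)
        curves[kind] = ContributionCurve(kind=kind, i=i_k, im=im_k, r=r_k)
    return curves


def write_curves_tsv(curves: Mapping[str, ContributionCurve], path) -> None:
    """Emit ``kind<TAB>k<TAB>I_k<TAB>IM_k<TAB>R_k`` rows for plotting."""
    with open(path, "w") as fh:
        fh.write("kind\tk\tI_k\tIM_k\tR_k\n")
        for kind in EDGE_KINDS:
            c = curves[kind]
            for k in range(1, MAX_SCORE + 1):
                i, im, r = c.at(k)
                r_txt = "NA" if np.isnan(r) else f"{r:.6f}"
                fh.write(f"{kind}\t{k}\t{i}\t{im}\t{r_txt}\n")


@dataclass(frozen=True)
class MisclassificationDiagnosis:
    """Why a sample's 1-st order prediction beat every one of its true classes.

    Only defined for samples whose top-ranked class is not in their true set.
    ``fits_situation1``: the predicted class out-"terms" every true class
    over all contributing neighbor edges; ``fits_situation2``: the same
    restricted to high-confidence edges (score > threshold).
    """

    sample: str
    predicted_first: PathwayClass
    true_classes: frozenset[PathwayClass]
    fits_situation1: bool
    fits_situation2: bool
    interpretation: str
    high_conf_threshold: int


def _class_terms(
    net: HybridNetwork, labels: LabelTable, s: str, cls: PathwayClass
) -> list[int]:
    """Scores of the neighbor edges of ``s`` contributing to class ``cls``."""
    return [
        nb.score for nb in net.neighbors(s) if cls in labels.get(nb.id, frozenset())
    ]


def diagnose_misclassified(
    results: Mapping[str, RankedPrediction],
    net: HybridNetwork,
    labels: LabelTable,
    threshold: int = HIGH_CONFIDENCE_THRESHOLD,
    interpretation: str = "count",
) -> tuple[list[MisclassificationDiagnosis], dict[str, float]]:
    """Diagnose every 1-st-order-incorrect sample in the jackknife results.

    Under ``interpretation="count"`` the predicted class must have strictly
    more contributing terms than *every* true class (situation 1), or more
    terms with score > ``threshold`` (situation 2); under ``"sum"`` term
    counts are replaced by total scores.  Returns the per-sample diagnoses
    and summary fractions (over the misclassified samples) of those fitting
    situation 1, situation 2 and at least one of the two.
    """
    if interpretation not in INTERPRETATIONS:
        raise ValueError(f"interpretation must be one of {INTERPRETATIONS}")

    measure = len if interpretation == "count" else sum
    diagnoses: list[MisclassificationDiagnosis] = []
    for s, pred in results.items():
        true = labels[s]
        if pred.first in true:
            continue
        if s in net:
            pred_terms = _class_terms(net, labels, s, pred.first)
        else:
            pred_terms = []
        pred_all = measure(pred_terms)
        pred_high = measure([t for t in pred_terms if t > threshold])
        fits1 = True
        fits2 = True
        for cls in true:
            true_terms = _class_terms(net, labels, s, cls) if s in net else []
            if not pred_all > measure(true_terms):
                fits1 = False
            if not pred_high > measure([t for t in true_terms if t > threshold]):
                fits2 = False
        diagnoses.append(
            MisclassificationDiagnosis(
                sample=s,
                predicted_first=pred.first,
                true_classes=true,
                fits_situation1=fits1,
                fits_situation2=fits2,
                interpretation=interpretation,
                high_conf_threshold=threshold,
            )
        )

    n = len(diagnoses)
    summary = {
        "n_misclassified": float(n),
        "fraction_situation1": (sum(d.fits_situation1 for d in diagnoses) / n) if n else 0.0,
        "fraction_situation2": (sum(d.fits_situation2 for d in diagnoses) / n) if n else 0.0,
        "fraction_either": (
            sum(d.fits_situation1 or d.fits_situation2 for d in diagnoses) / n
        )
        if n
        else 0.0,
    }
    return diagnoses, summary


def misclassified_by_class(
    results: Mapping[str, RankedPrediction], labels: LabelTable
) -> dict[str, int]:
    """Per-class tally of 1-st-order-incorrect samples.

    A misclassified sample increments the count of *every* class it truly
    belongs to, so the total can exceed the number of misclassified samples.
    """
    counts: dict[str, int] = {}
    for cls in PATHWAY_CLASSES:
        counts[cls.tag] = 0
    for s, pred in results.items():
        true = labels[s]
        if pred.first in true:
            continue
        for cls in true:
            counts[cls.tag] += 1
    return counts
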