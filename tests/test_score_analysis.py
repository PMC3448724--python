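"""Contribution-rate curves and misclassification diagnosis."""

from __future__ import annotations

import math

import numpy as np
import pytest

from metpath import (
    HybridNetwork,
    LabelTable,
    SimulationConfig,
    contribution_curves,
    diagnose_misclassified,
    generate,
    jackknife,
    misclassified_by_class,
)
from metpath.classes import CLASS_BY_TAG
from metpath.network import EDGE_KINDS


def toy_network():
    """Three cc edges: 100 concordant, 500 discordant, 900 concordant."""
    net = HybridNetwork()
    for i in range(1, 7):
        net.add_node(f"C0000{i}")
    net.add_edge("C00001", "C00002", 100)
    net.add_edge("C00003", "C00004", 500)
    net.add_edge("C00005", "C00006", 900)
    labels = LabelTable(
        {
            "C00001": {CLASS_BY_TAG["M1"]},
            "C00002": {CLASS_BY_TAG["M1"]},
            "C00003": {CLASS_BY_TAG["M2"]},
            "C00004": {CLASS_BY_TAG["M3"]},
            "C00005": {CLASS_BY_TAG["M4"]},
            "C00006": {CLASS_BY_TAG["M4"]},
        }
    )
    return net, labels


class TestContributionCurves:
    def test_toy_network_rates(self):
        net, labels = toy_network()
        cc = contribution_curves(net, labels)["cc"]
        assert cc.at(1) == (3, 2, pytest.approx(2 / 3))
        assert cc.at(501) == (1, 1, 1.0)
        i_901, im_901, r_901 = cc.at(901)
        assert (i_901, im_901) == (0, 0)
        assert math.isnan(r_901)

    def test_threshold_one_counts_every_edge(self, table2):
        net, labels = table2
        curves = contribution_curves(net, labels)
        totals = {k: 0 for k in EDGE_KINDS}
        for e in net.edges():
            totals[e.kind] += 1
        for kind in EDGE_KINDS:
            assert curves[kind].at(1)[0] == totals[kind]

    def test_monotone_and_bounded(self, small_synthetic):
        net, labels, _ = small_synthetic(2)
        for curve in contribution_curves(net, labels).values():
            assert (np.diff(curve.i) <= 0).all()
            assert (curve.im <= curve.i).all()
            defined = curve.i > 0
            assert ((curve.r[defined] >= 0) & (curve.r[defined] <= 1)).all()

    def test_score_concordance_coupling_raises_curve(self):
        """With high scores reserved for concordant edges, R_k rises to ~1."""
        net, labels, _ = generate(SimulationConfig(seed=21))
        cc = contribution_curves(net, labels)["cc"]
        assert cc.at(701)[2] > 0.99  # high range is concordant-only
        assert cc.at(701)[2] > cc.at(1)[2]

    def test_brute_force_recount(self, small_synthetic):
        net, labels, _ = small_synthetic(4)
        curves = contribution_curves(net, labels)
        edges = list(net.edges())
        for kind in EDGE_KINDS:
            for k in (1, 250, 500, 750, 999):
                i = sum(1 for e in edges if e.kind == kind and e.score >= k)
                im = sum(
                    1
                    for e in edges
                    if e.kind == kind
                    and e.score >= k
                    and labels[e.a] & labels[e.b]
                )
                assert curves[kind].at(k)[:2] == (i, im)


class TestDiagnosis:
    def test_misclassified_worked_example_fits_both_situations(self, table6):
        net, labels = table6
        results = jackknife(net, labels, subset=["C00439"])
        diagnoses, summary = diagnose_misclassified(results, net, labels)
        assert len(diagnoses) == 1
        d = diagnoses[0]
        assert d.predicted_first.tag == "M8"
        assert {c.tag for c in d.true_classes} == {"M5"}
        # 14 contributing terms for M8 vs 11 for M5; 10 high-confidence
        # (score > 700) terms vs 6
        assert d.fits_situation1 and d.fits_situation2
        assert summary["fraction_either"] == 1.0

    def test_worked_example_term_counts(self, table6):
        net, labels = table6
        m5, m8 = CLASS_BY_TAG["M5"], CLASS_BY_TAG["M8"]
        terms = {
            cls: [nb.score for nb in net.neighbors("C00439") if cls in labels[nb.id]]
            for cls in (m5, m8)
        }
        assert len(terms[m8]) == 14 and len(terms[m5]) == 11
        assert sum(1 for t in terms[m8] if t > 700) == 10
        assert sum(1 for t in terms[m5] if t > 700) == 6

    def test_fits_sum_but_not_count(self):
        """Fewer, larger predicted-class terms: fits 'sum' but not 'count'."""
        net = HybridNetwork()
        net.add_node("C00010")
        partners = {
            "C00011": (999, "M2"),
            "C00012": (900, "M2"),
            "C00013": (800, "M1"),
            "C00014": (790, "M1"),
            "C00015": (100, "M1"),
        }
        labels = LabelTable({"C00010": {CLASS_BY_TAG["M1"]}})
        for pid, (score, tag) in partners.items():
            net.add_edge("C00010", pid, score)
            labels.set(pid, {CLASS_BY_TAG[tag]})
        results = jackknife(net, labels, subset=["C00010"])
        assert results["C00010"].first.tag == "M2"  # 1899 beats 1690

        by_count, _ = diagnose_misclassified(results, net, labels, interpretation="count")
        assert not by_count[0].fits_situation1  # 2 terms vs 3
        assert not by_count[0].fits_situation2  # 2 high-conf vs 2

        by_sum, _ = diagnose_misclassified(results, net, labels, interpretation="sum")
        assert by_sum[0].fits_situation1  # 1899 > 1690
        assert by_sum[0].fits_situation2  # 1899 > 1590

    def test_interpretation_validated(self, table6):
        net, labels = table6
        results = jackknife(net, labels, subset=["C00439"])
        with pytest.raises(ValueError):
            diagnose_misclassified(results, net, labels, interpretation="magnitude")

    def test_summary_fraction_ordering(self):
        net, labels, _ = generate(SimulationConfig(homophily=0.3, seed=17))
        results = jackknife(net, labels)
        _, summary = diagnose_misclassified(results, net, labels)
        assert summary["n_misclassified"] > 0
        for key in ("fraction_situation1", "fraction_situation2", "fraction_either"):
            assert 0 <= summary[key] <= 1
        assert summary["fraction_either"] >= max(
            summary["fraction_situation1"], summary["fraction_situation2"]
        )


class TestMisclassifiedByClass:
    def test_all_correct_gives_zero_counts(self):
        net, labels, _ = generate(
            SimulationConfig(homophily=1.0, multi_label_rate=0.0, seed=4)
        )
        results = jackknife(net, labels)
        results = {s: r for s, r in results.items() if r.first in labels[s]}
        counts = misclassified_by_class(results, labels)
        assert all(v == 0 for v in counts.values())

    def test_multi_label_sample_counted_in_every_true_class(self):
        labels = LabelTable({"C00020": {CLASS_BY_TAG["M2"], CLASS_BY_TAG["M5"]}})
        net = HybridNetwork()
        net.add_node("C00020")
        net.add_node("C00021")
        net.add_edge("C00020", "C00021", 500)
        labels.set("C00021", {CLASS_BY_TAG["M7"]})
        results = jackknife(net, labels, subset=["C00020"])
        assert results["C00020"].first.tag == "M7"
        counts = misclassified_by_class(results, labels)
        assert counts["M2"] == 1 and counts["M5"] == 1
        assert sum(counts.values()) == 2

    def test_total_at_least_number_misclassified(self):
        net, labels, _ = generate(SimulationConfig(homophily=0.4, seed=23))
        results = jackknife(net, labels)
        n_wrong = sum(1 for s, r in results.items() if r.first not in labels[s])
        counts = misclassified_by_class(results, labels)
        assert sum(counts.values()) >= n_wrong
        recount = {tag: 0 for tag in counts}
        for s, r in results.items():
            if r.first not in labels[s]:
                for cls in labels[s]:
                    recount[cls.tag] += 1
        assert counts == recount
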