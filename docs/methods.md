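# Methods

## Model

The predictor is a weighted guilt-by-association vote on an undirected hybrid
network whose nodes are small molecules (compounds) and enzymes and whose
edges carry integer interaction-confidence scores in [1, 999]. Edge kinds
(cc, cp, pp) are implied by the endpoint kinds and are retained for the
score-analysis module only — the vote itself treats all kinds identically.
The likelihood that query *s* belongs to pathway class Mj is

    F(s, Mj) = sum over neighbors t of s with Mj in labels(t) of Q(s, t),

computed in exact integer arithmetic. An absent interaction is score 0 by
convention, so only stored edges can ever contribute; F(s, Mj) = 0 iff no
labeled neighbor carries Mj. The prediction is the full permutation of the 11
classes by descending F.

Underlying assumption: interacting molecules tend to participate in common
pathways (network homophily), and higher-confidence interactions do so more
often. The contribution curves R_k = IM_k / I_k quantify the second clause on
any given network; the method's accuracy degrades gracefully as homophily
weakens (demonstrated by the parameter-recovery tests).

## Deterministic conventions

- **Tie-breaking.** Classes with equal likelihood (including all zero-valued
  classes) are ordered by ascending class index. Any fixed order works; a
  deterministic one makes jackknife results exactly reproducible.
- **Full ranking.** Zero-likelihood classes are still ranked, after all
  positive ones, so every sample has a complete 1-st..11-th order prediction
  and ordered accuracy is well defined out to order 11 (L_11 = 1 always).
- **Own labels withheld.** F never reads the query's own labels, so the
  leave-one-out jackknife is exact rather than approximate, and evaluating a
  node is identical to predicting it.
- **Duplicate edges.** Input files repeating an unordered pair keep the
  maximum score: interaction databases report one confidence per pair, and
  max is conservative and deterministic. (How the original curated dumps
  reconciled duplicates is unknowable from the data; this is the package's
  own convention.)
- **Unlabeled endpoints.** Edges touching a node absent from the label table
  are dropped at load with a logged count — such edges contribute zero to
  every class, so dropping them changes nothing downstream.
- **Scores are integers.** Fractional scores are rejected at parse time; all
  likelihoods and accuracy counts are exact (`fractions.Fraction` for the
  reported statistics, decimal renderings only at the output layer).

## Evaluation statistics

- Ordered accuracy ACC_j counts a sample as correct at order j when its j-th
  ranked class is **any** of its true classes (the only reading consistent
  with multi-label samples whose top two predictions are both "true"). The
  denominator is the full sample count at every order.
- Coverage L_m uses m = ceil(M) by default, with M the exact average label
  count of the evaluated subset; both are reported as exact fractions plus
  2-d.p. percentages.
- The random-guess baseline M/11 is the expected success rate of a single
  uniform class guess on a sample with M labels on average.
- The `--subset compounds|enzymes|all` switch evaluates any of the three
  populations under the same leave-one-out protocol; all labels (from both
  populations) remain available to the vote either way.

## Misclassification diagnosis

For each sample whose 1-st order class is not in its true set, the diagnosis
asks whether the winning class beat **every** true class (strictly) on
(situation 1) its number of contributing neighbor edges, and (situation 2)
its number of contributing edges with score above a high-confidence threshold
(default 700, the conventional STRING/STITCH high-confidence cut). The phrase
"more sum terms" admits two operationalizations — a count of terms or their
total score — so both are implemented (`interpretation=count|sum`) and the
choice is recorded in every output row; `count` is the default because it is
the reading under which the bundled misclassified worked example (C00439,
14 vs 11 terms, 10 vs 6 above 700) fits both situations while remaining
distinct from the trivial fact that the winner's total is larger.

## Synthetic generator

`simulate.generate` emulates the gross statistics of the yeast benchmark the
method was developed on, at reduced size. Defaults (chosen once):

| parameter | default | rationale |
|---|---|---|
| n_compounds : n_enzymes | 333 : 67 | ≈5:1 compound:enzyme ratio of the benchmark, at 400 nodes |
| n_classes | 11 | the fixed class vocabulary |
| mean_degree | 12 | middle ground between the benchmark's mean degree (~50) and its edge density (~1.3%); matching degree verbatim at 400 nodes would make the enzyme–enzyme subgraph >60% dense, structurally unrealistic |
| kind_mix (cc, cp, pp) | 0.66, 0.20, 0.14 | the benchmark's 66,942 / 19,695 / 14,117 split of 100,754 interactions |
| homophily h | 0.6 | over half of real interactions join class-sharing endpoints |
| multi_label_rate | 0.15 | reproduces an average label count near the benchmark's 1.18 |
| score model | low (1, 699), high (700, 999), p(high given concordant) = 0.8 | couples confidence to concordance so contribution curves rise with k, the qualitative behaviour of the real curves; discordant edges always draw low |

Edges are placed by rejection sampling: each edge first draws its kind and
its concordance (concordant with probability h), then retries endpoint pairs
holding both fixed, so duplicate collisions cannot bias the realized
concordant fraction away from h. Scores are drawn after placement. All
randomness flows from a single `numpy` generator seeded by `config.seed`;
identical configs give byte-identical output files.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: the heavy-tailed degree distribution of real
interactomes, the empirical STITCH/STRING score calibration (real scores are
not two uniform blocks), correlated annotations between interacting hub
classes, and annotation noise/incompleteness. Synthetic results validate the
*implementation* (exactness, invariants, parameter recovery), not the
biological accuracy figures attainable on curated data.

## Problem sizes

The bundled worked examples have 19 and 24 nodes. Synthetic checks use
50-node networks for brute-force oracle comparisons, 400-node benchmarks
(≈2,400 edges) for pipeline-level statistics, and 20 seeds per condition for
the homophily parameter-recovery comparison; the full 400-node pipeline
(jackknife, accuracies, coverage, curves, diagnosis) runs in about a second.

## Known limitations

- Likelihoods are unnormalized sums: they are comparable across classes for
  one query but not across queries, and no probabilistic calibration is
  attempted.
- Nodes with no labeled neighbors receive an all-zero vector and the
  index-order ranking M1..M11 — a deterministic but uninformative fallback.
- The evaluation offers only the leave-one-out jackknife; there is no k-fold
  or held-out split.
- Organism handling is out of scope: node ids are opaque strings, with a
  single heuristic (`C` + five digits ⇒ compound) when the kind column is
  absent.
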