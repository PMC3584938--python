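# gopred

Homology-based Gene Ontology (GO) function prediction from sequence-search
results, together with the CAFA-style assessment machinery needed to compare
such predictors — as a tested Python library and command-line tool that runs
at desk scale on synthetic benchmarks.

## Who this is for

Given a new protein sequence, the standard way to guess its function is to
search an annotated database (BLAST / PSI-BLAST) and transfer GO terms from
the hits. Several classic scorers refine that idea, and community assessments
(CAFA) defined how to judge them. `gopred` reimplements both sides of that
story over parsed inputs — an OBO ontology, a GAF annotation database and
12-column BLAST tabular hit lists — without ever running a search itself:

* **PFP** — accumulates, over every hit *i* and each of its annotations
  *f<sub>j</sub>*, the score contribution
  `s(f_a) = Σ_i Σ_j (−log10 E_i + b) · P(f_a | f_j)` with *b* = 2
  (= log₁₀ 100, the E-value ceiling), where `P(f_a|f_j)` is the
  co-occurrence probability of the two terms across single-protein
  annotations. Raw scores are shared root-ward in proportion to term
  frequencies, and can be calibrated into confidences via term-specific
  empirical p-values and benchmark correctness rates at GO edge distances
  0/2/4.
* **ESG** — two-level iterative search: every hit gets weight
  `−log10(E) / Σ −log10(E)` within its search; a hit with a second-level
  search splits its weight between its own annotations and its level-2
  hits'. Scores lie in [0, 1].
* **GOtcha** — sums `max(0, −log10 E)` onto each hit's propagated
  annotation set and normalizes by the root's mass (the *I-score*).
* **BLAST baseline** — max percent identity over hits annotated with a term.
* **Prior** — target-independent ranking by database frequency with a
  pseudocount of 1: `(freq(c)+1)/(freq(root)+1)`; also usable to *enrich*
  PFP/ESG predictions with frequent terms they missed.

Evaluation implements the four CAFA metric families — threshold sweeps
(precision/recall/specificity on root-propagated sets at cutoffs 0.01–1.00),
top-N sweeps (N = 1–20 with ties, plus a 1–1000-by-5 rank sweep for
unbounded raw scores), information-content-weighted precision/recall
(IC(c) = −log₁₀ p(c) with the recursive frequency
`freq(c) = annot(c) + Σ_children freq`), and shared-ancestor semantic
similarity/precision/recall — plus the term-centric max-F1 analysis
(`F1 = 2PR/(P+R)` maximized over cutoffs) for terms annotating enough
targets.

A synthetic fixture generator (`gopred.fixtures`) produces ontologies,
annotation databases, targets with held-out truth and two-level hit graphs
with a planted homology signal, so the whole pipeline is testable offline;
the hand-checked five-term `D0` dataset used in the worked examples ships
with the package.

## Worked example

Score the D0 database with PFP for a target with a single hit on protein
`p2` (annotated with terms A1 and B) at E = 10⁻³:

```python
from gopred.fixtures import d0_dag, d0_db
from gopred.annotations import CooccurrenceTable
from gopred.ontology import compute_term_stats
from gopred.predictors import pfp_raw_scores, pfp_parent_transfer
from gopred.search_io import Hit

dag, db = d0_dag(), d0_db()
stats = compute_term_stats(dag, db.direct_counts(dag, "BP"))
cooc = CooccurrenceTable.build(db, dag, "BP")
raw = pfp_raw_scores([Hit("T1", "p2", 80.0, 1e-3)], db, cooc, dag, "BP")
full = pfp_parent_transfer(raw, dag, stats)
```

which prints, term by term:

```
GO:0000004  term A1              raw=10.0000  final=10.0000
GO:0000003  term B               raw= 7.5000  final= 7.5000
GO:0000001  biological_process   raw= 0.0000  final= 6.8750
GO:0000002  term A               raw= 0.0000  final= 6.6667
```

The hit contributes the factor −log₁₀(10⁻³) + 2 = 5 through each of its two
annotations: A1 collects 5·(P(A1|A1) + P(A1|B)) = 5·(1 + 1) = 10 and B
collects 5·(0.5 + 1) = 7.5. The parent A then receives 10·freq(A1)/freq(A) =
10·2/3 ≈ 6.67 and the root 10·2/4 + 7.5·1/4 = 6.875 — unannotated ancestors
enter purely through the frequency-proportional transfer.

The same pipeline from the shell, on a simulated benchmark:

```bash
gopred simulate --seed 7 --n-targets 8 --n-proteins 80 --out bundle
gopred predict --method gotcha --obo bundle/ontology.obo \
    --gaf bundle/annotations.gaf --hits bundle/hits.tsv --out gotcha.tsv
gopred evaluate --metric threshold --obo bundle/ontology.obo \
    --truth bundle/truth.tsv --pred gotcha.tsv --out eval
```

`gotcha.tsv` starts with the root and near-root terms at I-score 1.0 (the
normalization anchor), and `eval/summary.json` reports the maximum harmonic
mean of the averaged precision/recall over the threshold sweep:

```
T000001 GO:7000001  1.000000
T000001 GO:7000004  1.000000
T000001 GO:7000002  0.762716
{"fmax": 0.6819, "metric": "threshold", "n_rows": 100, "n_targets": 8}
```

Methods: `pfp`, `pfp-raw`, `esg`, `gotcha`, `blast`, `prior`, `pfp+prior`,
`esg+prior`. Metrics: `threshold`, `topn`, `topk`, `weighted`, `semantic`,
`term-f1`. See `docs/methods.md` for the model details, parameter defaults
and design choices.

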