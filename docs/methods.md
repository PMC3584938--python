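# Methods

## Ontology model

The GO is represented as a directed acyclic graph over `is_a` edges only,
one rooted component per namespace (BP / MF). `part_of` and other
relationship types are ignored at parse time (logged); obsolete terms and
terms outside the requested namespaces are dropped. Whether historical GO
ancestor computations included `part_of` varies between tools; fixing
`is_a`-only keeps propagation, edge distances and frequency recursion on a
single well-defined graph. An `is_a` reference to a term never defined as a
live stanza is treated as a hard error rather than silently creating a
placeholder node, as is a cycle. Roots are the parentless terms; when a
namespace has several parentless terms, the one named like the namespace
(e.g. `biological_process`) is taken as the root and everything must reach
it.

Annotation with a term implies all of its ancestors, so evaluation
propagates term sets to the root. The root itself is excluded from counted
sets by default: it is implied by every non-empty prediction, and counting
it would uniformly inflate precision for all methods (literal inclusion is
available via the `universe` argument).

## Term statistics

Frequencies follow the recursive definition

    freq(c) = annot(c) + Σ_{h ∈ children(c)} freq(h)

with `annot(c)` the number of gene products directly annotated with `c`.
This recursion deliberately counts a gene product once per parent path under
multi-parent descendants; it is implemented literally because that is the
quantity the weighted metrics and the Prior are defined on. An alternative
`unique` mode counts distinct proteins annotated at or below each term, for
users who want a set-semantics frequency. Probabilities are
`p(c) = freq(c)/freq(root)` per namespace and information content is
`IC(c) = −log10 p(c)` (base 10 throughout, matching the E-value logarithms).
Terms with zero frequency have undefined `p`/`IC` (NaN) and are excluded
from IC-based metrics.

## Predictors

**Co-occurrence.** `P(f_a | f_j)` is the fraction of proteins directly
annotated with `f_j` that also carry `f_a`, computed within one namespace on
*direct* (unpropagated) annotations — propagation would push every ancestor
conditional toward 1. "Annotated with `f_j`" is read inclusively (the
protein may carry other terms too); the exclusive reading would make
`P(f|f)` ill-defined for multi-annotated proteins. This is the single most
consequential interpretation in the annotations module.

**PFP.** The accumulation `s(f_a) = Σ_i Σ_j (−log10 E_i + b)·P(f_a|f_j)`
runs over hits below the E-value ceiling (default 100) with `b = 2 =
log10(ceiling)` keeping every factor positive; E-values of 0 are clamped at
a floor of 1e−180 before the logarithm. Since `P(f|f) = 1`, direct
annotations of hits contribute fully. Parent transfer adds
`s(f_a)·freq(f_a)/freq(f_p)` from each scored term directly to *every*
proper ancestor `f_p` (rather than chaining child→parent→grandparent); the
wording of the original description admits either reading, and the direct
form keeps the transfer independent of path multiplicity.

Raw scores are optionally converted to confidences. Each term's raw score is
ranked against a background of raw scores for the same term collected from a
benchmark run (terms with fewer than 5 background samples fall back to the
pooled background). The empirical p-value is the inclusive upper tail
`#{bg ≥ x}/n`, floored at `1/(n+1)` when the score exceeds every background
sample. The confidence is the fraction of benchmark predictions at that
p-value level whose term lay within edge distance k of a true term,
estimated in 10 equal-width p-value bins and pooled isotonically
(scikit-learn, decreasing) so confidence never increases with p. The three
correctness radii k ∈ {0, 2, 4} are all computed; ranking uses k = 0 (exact
term) by default — the strictest choice, which avoids inflating confidence
with near-miss credit.

**ESG.** Within one search, weights are `−log10(E)` normalized to sum to 1
over the hits of that search; hits with E ≥ 1 would contribute negative mass
and are excluded from the weight computation (they stay in the graph with
weight 0). A level-1 hit with a usable level-2 search splits its weight
`a : (1−a)` between its own annotations and its level-2 hits' annotations
(default a = 0.5, configurable — the mixing constant is not pinned down by
the method description); a hit without a level-2 search (or whose level-2
hits all have E ≥ 1) gives its full weight to its own annotations, which
keeps scores in [0, 1] and makes one-level operation well defined.

**GOtcha.** Contributions `−log10(E)` are clamped at 0 (hits with E > 1
would otherwise push I-scores negative), summed over each hit's propagated
annotation set, and normalized by the root's total; the root's I-score is 1
whenever any hit scored, and an all-weak hit list yields an empty
prediction set.

**Prior and enrichment.** The Prior scores every namespace term
`(freq+1)/(freq(root)+1)` and assigns the identical top-1000 list to every
target. Enrichment imports prior terms missing from a method's list: for
confidence-scaled PFP the imported scores are linearly mapped from the prior
list's [min, max] onto the target's own [min, max] (so an imported term can
tie, but not beat, the method's top score — a consequence of the literal
min/max mapping, configurable in principle); for ESG both scales already
live in [0, 1] and scores are kept as-is. When the prior scores are all
equal the map is degenerate and imports land at the target's minimum; a
target with no predictions of its own receives the prior list unrescaled.
All lists are truncated to the 1000 highest-scoring terms, boundary ties
broken by term id.

## Evaluation conventions

"Above the threshold" is `score ≥ τ`, so τ = 1.0 retains scores of exactly
1 (the Prior's root and GOtcha's root anchor). Precision is averaged only
over targets with a non-empty prediction set at the cutoff (0/0 is
undefined); recall counts such targets as 0; specificity uses all namespace
terms minus the root as the negative universe (whether only annotated terms
should form the universe is unspecified in the assessment tradition; the
full namespace is the default here). Top-N inclusion takes every term tied
with the N-th score. Semantic metrics operate on *unpropagated* predicted
and true sets — pairwise IC differences over propagated sets degenerate
because every pair then shares its near-root ancestors — and drop terms with
undefined IC; per-target values average over all (true, predicted) pairs and
are then averaged over targets with a non-empty prediction set at the
cutoff.

The term-centric F1 counts a target as a true positive for term `c` at
cutoff τ when its propagated prediction set at τ contains `c`, restricted to
terms contained in the propagated truth of at least `min_targets` targets
(default 25); the reported value is the maximum over cutoffs of
`2PR/(P+R)`.

## Synthetic benchmark

The generator emulates the setting all five predictors assume: homologs of
the target exist in the annotated database and share its function. Each
target's truth comes from a hidden donor protein excluded from the
searchable database; signal hits are database proteins sharing a direct
truth term (E log-uniform in [1e−50, 1e−10], identity 60–95%), noise hits
are arbitrary proteins (E log-uniform in [1e−2, 10] — some above 1, to
exercise the clamping rules; identity 20–40%). Defaults: a balanced
branching-3 depth-4 BP ontology (121 terms, 10% of deep nodes given a second
shallower parent), 200 proteins with 1–3 annotations each (70% leaf-biased,
10% IEA evidence), 50 targets, 10 hits per target, signal strength 0.9,
level-2 fan-out 3. One seeded generator per artifact (ontology /
annotations / searches) makes outputs byte-reproducible and independently
regenerable. These sizes keep every test and the end-to-end pipeline in the
seconds range.

What passing tests on these fixtures show: the scorers rank planted-homology
terms far above chance and above the frequency baseline under realistic
E-value contrast. What they do not show: behavior on real GO topology
(25k+ terms, deep multi-parent tangles), real annotation bias, or real
E-value distributions — there are no sequences anywhere.

**Ranking AUC.** The signal-recovery check uses per-target ROC AUC over all
namespace terms minus the root, scoring unpredicted terms 0, with the
target's *direct* (unpropagated) donor terms as positives. This choice is
deliberate: with propagated labels, any scorer correlated with term depth —
including the target-independent Prior — exceeds AUC 0.5 for purely
structural reasons, because shallow terms are simultaneously high-scoring
and present in almost every propagated truth set. Direct labels give an
uninformed ranking an expected AUC of 1/2, so "signal present / signal
absent" is readable from the number.

## Numerical choices and degenerate inputs

* E-value floor 1e−180 before any `−log10`; E-ceiling filter strictly below
  100 (a hit exactly at the ceiling would contribute `−2 + 2 = 0` anyway).
* Ranked lists order by score descending, term id ascending; all tie-breaks
  are therefore deterministic.
* Propagated prediction sets along a threshold sweep are cached per ranked
  prefix, so the 100-cutoff sweep costs one closure per distinct score.
* Empty hit lists, empty graphs and all-weak hit lists yield empty score
  maps, never errors; empty truth sets are skipped (with a log message) in
  curve averaging and are an error in single-target calls, where recall is
  undefined.
* GAF rows with fewer than 15 columns: error naming the line in strict mode
  (default), skip-with-log in lenient mode. NOT-qualified rows and excluded
  evidence codes (default {IEA}) are dropped at parse.

## Known limitations

* No `part_of`/`regulates` semantics, no `alt_id` resolution, no taxon
  filtering.
* The PFP confidence calibration is only as good as the benchmark truth
  supplied to it; with the small synthetic benchmarks the isotonic fit is
  coarse (10 bins).
* The raw-score rank sweep reports rank cutoffs, not thresholds; mixing it
  with threshold-based curves from other methods requires care in
  interpretation.
* Co-occurrence tables are dense in the number of annotated terms per
  conditioning term; at real SWISS-PROT scale they would need sparse
  storage and on-demand computation beyond what the current cache does.
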