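# Methods

## Effect inference and consensus labelling

An observation records one perturbation experiment: the direction of effect
on protein product/activity (`increase`/`decrease`), the approach
(`genetic` for germline, conditional or knock-in modifications; `exogenous`
for drugs, antibodies, proteins and transient knock-down), the OA model
class, and the observed effect on joint-damage severity. The inferred
gene-level effect flips the observed direction exactly when activity was
decreased; `no_effect` and `mixed` observations pass through unchanged. The
rule is total over the enum domain and antisymmetric in the activity
direction for directional observations — both properties are tested.

Consensus labelling is set-based and therefore invariant to observation
order and duplication: the presence of both directions gives `ambiguous`; a
single direction supersedes any number of `no_effect` observations; `mixed`
surfaces only when no directional evidence exists. An empty observation
list is an error rather than a default label.

Edge cases the consistency statistics must decide:

- A gene is *consistent* within a stratum if its directional inferred
  effects never contain both `protective` and `detrimental`. Genes with
  only `no_effect` (or only `mixed`) observations count as consistent —
  the supersede rule implies absence of conflict, not absence of signal.
  `mixed` observations never create or destroy consistency.
- Cross-approach agreement compares the per-approach consensus labels
  (equality of labels, including `ambiguous == ambiguous`). An alternative
  that pools raw directional effects across both approaches is available
  via `consistency_report(..., method="observations")`.
- Cross-model agreement is restricted to genes whose per-model consensus is
  *directional* in both the spontaneous and the surgical stratum. Whether a
  `no_effect` consensus should qualify as "unambiguous" is genuinely open;
  requiring a direction makes the statistic a statement about effect
  direction rather than effect existence, which is what the comparison is
  for.

The intervention → activity-direction dictionary
(`src/oatargets/data/interventions.yaml`) is editable user configuration;
it is consulted only for rows whose activity column is empty, since curated
tables normally record the protein-level direction explicitly.

## Expression overlap statistics

Thresholds are inclusive on both boundaries (|log2FC| ≥ log2 1.5,
adjusted p ≤ 0.05) and the fold-change column dialect (log2 vs signed
linear) is declared per file. Duplicate gene rows keep the largest
|log2FC|. Ortholog mapping drops unmapped symbols rather than passing
source-species identifiers through, and removes miRNA identifiers by
configurable prefix because the expression compendium contains no
small-RNA assays.

The Fisher overlap test is one-sided toward enrichment: depletion of
curated genes in a DE set is not the question being asked. The test
universe is the per-dataset measured gene set (each platform measures a
different universe); a shared global universe can be supplied instead by
the caller. The odds ratio is the sample cross-product ratio with a 0.5
Haldane correction applied only when a cell is empty. The χ²
effect-proportion test uses no continuity correction (1 df); a zero margin
is reported as `testable=False` with NaN statistic rather than a silent
p = 1, so downstream BH families exclude it explicitly. BH families follow
the reporting structure: overlap p-values are corrected across datasets in
a run, proportion p-values across all dataset × direction cells.

## Network diffusion

The adjacency is built over the largest connected component (size ties
broken toward the component containing the lexicographically smallest
label — a deterministic, if arbitrary, rule), after removing self-loops and
duplicate edges. `W` is the column-normalised (random-walk) adjacency;
since the retained graph is connected there are no dangling columns, and
`F ← (1−r)WF + rF₀` conserves total mass exactly — the tested invariant
that scores sum to 1 at every iteration. Symmetric normalisation
`D^{-1/2} A D^{-1/2}` would weight hubs differently but forfeits this
conservation law.

Defaults: restart probability `r = 0.3` (the common random-walk-with-
restart operating point; cross-validation is the instrument for tuning it
per network), L1 convergence tolerance `1e-8`, iteration cap 1000 (hit only
on adversarial inputs; the result is then flagged, not silently returned).
The closed-form solve `F = r(I − (1−r)W)⁻¹F₀` is exposed separately and the
two routes are required to agree to L∞ ≤ 10·tol in tests.

Ranks are averaged over ties and, when seeds are excluded, computed over
the non-seed domain only — a held-out gene competes against every gene that
could have been nominated, matching the "rank out of all network genes"
framing. Cross-validation partitions the seed list (sorted, then shuffled
by a seeded generator) into k folds per repeat; every never-labelled node's
rank is recorded per fold (desk-scale networks make subsampling
unnecessary). Identical seeds give bit-identical results.

The rank-significance test is a one-sided Wilcoxon signed-rank test against
the null median `(n+1)/2`, exact for ≤ 25 non-zero differences and normal
approximation beyond; a rank-sum variant against the uniform grid is
available because "Wilcoxon" is ambiguous between the two in common usage.
Differences of exactly zero are dropped (classical convention), and a test
with nothing left is an error.

The candidate filter keeps unlabelled genes with ≥ 3 human DE datasets,
≥ 4 curated-gene interactions, and sorts by network rank. Both thresholds
are parameters; the defaults reflect the intuition that one dysregulated
dataset or one interacting partner is anecdote, several are a pattern.

## Synthetic data: what it emulates, what it does not

`synth_observations` emulates the schema and marginal structure of a
curated perturbation corpus: geometric observation counts per gene (most
genes studied once), ~63% genetic observations, surgical and spontaneous
models dominating, directional true effects for 85% of genes. The
`consistency_rate` q is defined at the gene level: with probability q all
of a gene's observations report its true effect; otherwise the gene's
reports alternate between the two directions within each approach stratum.
This makes the expected consistent fraction among multi-studied genes equal
q exactly — the property the recovery tests check. (Independent
per-observation flips would instead give `1 − 2q(1−q)` for pairs, an
awkward quantity to reason about.) What it does not emulate: publication
bias toward positive results, correlated follow-up studies from one group,
tissue-specific effect heterogeneity, or real gene symbols.

`synth_network` plants a module inside a Barabási–Albert graph by adding
each missing intra-module edge with probability `intra_module_edge_prob`
(0 = invisible module, the negative control). Real PPI networks have
higher clustering and degree assortativity than BA graphs; passing the CV
recovery test here shows the algorithm exploits planted density, not that
any particular real network contains recoverable OA modules.

`synth_de_tables` generates adjusted p-values directly — uniform for
nulls, Beta(1, 50) for signal — rather than simulating counts through a DE
tool, because the pipeline consumes result tables, not raw expression.
Enrichment is parameterised on the odds scale so `enrichment_odds = 1`
reduces planted genes exactly to nulls (the calibration control under
which overlap p-values are uniform).

## Problem sizes and numerical checks

The test suite and the acceptance script run entirely on generated data:
500-gene corpora, 2000-node networks with 50-gene modules and 40 seeds,
five-dataset DE batteries — sizes at which the planted effects are
comfortably detectable yet a full run takes seconds. Diffusion/closed-form
equivalence is checked on 200 random connected graphs of ≤ 50 nodes at
L∞ ≤ 1e−7; Fisher p-values are checked against direct hypergeometric tail
enumeration exhaustively for universes ≤ 25 and on 1000 sampled tables up
to 60; BH against a textbook step-up implementation on 1000 random
vectors; the signed-rank tail against full 2⁹ sign-vector enumeration.

## Known limitations

- Consensus treats every observation equally: no weighting by study size,
  scoring system, tissue specificity or publication independence.
- The diffusion kernel is unweighted; edge confidences present in PPI
  downloads are ignored (with a warning) rather than used.
- `ambiguous` and `mixed` genes are included in the default seed set (they
  do have an effect on severity); excluding them is a flag
  (`seed_set: directional`), and which choice is better on real data is
  untested here.
- The pipeline does not bundle any pathway-enrichment step, ortholog
  retrieval or tractability lookup; those arrive as user-supplied tables.
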