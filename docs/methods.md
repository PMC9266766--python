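# Methods

## The data model

Text-mined interactomes are typed multigraphs: a pair of genes can be linked
simultaneously by a physical interaction, an expression-regulation edge and
an activity-regulation edge, each with its own direction and sign. The
package keeps that multiset intact (`GeneNetwork`) and defines every
topology statistic on the deduplicated unordered-pair projection
(`SimpleGraph`). This split is forced by arithmetic: a 430-gene network can
carry ~47,000 typed interactions while its average neighbor count is ~85,
which is only consistent if "interactions" count parallel typed edges and
"neighbors" count unique adjacent genes.

Gene symbols are normalized to uppercase and matched exactly; alias
resolution (mapping synonyms onto HGNC symbols) is deliberately out of
scope — published gene lists mix symbols and aliases, and silently guessing
mappings corrupts set operations. Self-edges are rejected at parse time:
none of the analyses here have a meaningful autoregulation semantics, and
the centrality/density conventions below assume simple graphs.

## Topology statistics

**Betweenness centrality.** Unweighted, undirected, endpoints excluded, on
the simple projection. Raw scores are pair-weighted shortest-path counts
(each unordered pair contributes the fraction of its shortest paths through
the node); normalized scores divide by (n−1)(n−2)/2. The computation is
delegated to networkx's Brandes implementation and validated against an
independent path-enumeration oracle on hundreds of random graphs of ≤ 8
nodes. Hub rankings are identical under either normalization, so the choice
does not affect any reported ranking.

**Crosstalk specificity.** CTS = K/M with K the simple degree in the
analyzed subnetwork and M the simple degree in the global network. Defined
only for genes with K ≥ 1 (module-isolated genes carry no crosstalk signal
and are omitted from CTS tables); the subnetwork precondition (every node
and pair present globally) is enforced, so CTS ∈ (0, 1]. Rankings break
exact ratio ties lexicographically — ratios are compared as exact fractions
so that 1/3 and 2/6 tie deterministically rather than by float accident.

**Network summaries.** avg_neighbors = 2·|pairs|/n. Density is
avg_neighbors/(2(n−1)), i.e. half the textbook undirected convention; this
is the unique simple convention that reproduces both published pairs
(n=430, k̄=84.764 → 0.1 and n=332, k̄=4.322 → 0.007), so it is adopted
package-wide and its range is [0, 0.5]. Centralization is Freeman degree
centralization, (n/(n−2))·(k_max−k̄)/(n−1), the NetworkAnalyzer-style
summary: exactly 1 for a star, 0 for degree-regular graphs; networks with
fewer than 3 nodes report 0. The analysis tool behind the published
centralization values (0.61, 0.046) does not document its formula, and
those values depend on unpublished network files, so they are checked only
through the closed-form limits, not reproduced.

## Enrichment

The overlap statistic is the one-sided upper-tail hypergeometric test
P(X ≥ k). All tail sums run in log-space via log-gamma and logsumexp; the
linear-scale p-value may underflow to 0.0 but `log10_p` is finite for every
valid input (validated up to overlaps where p ≈ 10⁻³⁰⁰⁰). k = 0 returns
p = 1 exactly. The implementation is cross-checked against exact rational
enumeration on the complete valid (N, K, n, k) grid for N ≤ 20 and against
scipy's survival function at larger sizes.

The universe size N is an explicit parameter defaulting to the loaded
global network's node count. Published enrichment p-values from proprietary
interactomes depend on universe sizes that are never printed, so exact
reproduction is not attempted; instead the package verifies bounds (e.g. a
planted K=147 / k=34 / n=430 overlap in a 30,000-gene universe yields
log₁₀ p < −24, matching the magnitude reported for the corresponding real
overlap).

Term enrichment applies the same test per term with Benjamini–Hochberg
adjustment across terms (delegated to statsmodels, validated against a
direct step-up-rule oracle on small permutations). BH is used because "FDR
correction" without a named procedure conventionally means BH, and it is
the default of the DAVID-style tools this reimplements. The EASE variant
(tail at k−1, floored at 0) is offered as an option because DAVID applies
it; the default is the plain hypergeometric. One caveat folded into the
test suite: BH adjusted q-values are *not* invariant under duplicating a
term (m changes), so the suite asserts the defensible properties instead —
duplicated terms share a q-value, and the rejection set at any level equals
the textbook step-up rule.

## Crosstalk operations

Crosstabs classify the genes shared between a condition module and a
target's interactor set along two axes: relation to the condition
(upregulated/downregulated by it, promoting/opposing it, other) and
relation to the target (upregulated/downregulated by the target,
upregulating/downregulating the target, other). Both axes are closed
five-value sets and a gene may occupy several cells; the headline number is
the *distinct* gene count across cells. The four published hyperglycemia
grids (ACE2, DPP4, CTSB, CTSL) ship with the package and reproduce the
published distinct totals 34, 48, 48 and 22.

Feedback-loop detection enumerates simple directed cycles of length 2 and 3
over regulatory arcs (directed edges; undirected interaction/association
edges are excluded). Parallel directed edges between an ordered pair are
collapsed to one arc — with their common sign if they agree, otherwise
unsigned. The loop sign is the algebraic product of step signs; any
unsigned step makes it "undetermined". Length is capped at 3 because the
motifs discussed in comorbidity analyses are 2-cycles and small triads, and
exhaustive enumeration beyond that grows combinatorially. One convention
deserves note: a mutual-inhibition 2-loop is algebraically *positive* (two
negatives multiply out), yet in narrative accounts such motifs are often
called amplifying because inhibiting one member releases the other. The
package keeps the algebraic sign and reports these motifs separately
(`mutual_inhibition_loops`) rather than bending the sign convention.

## Synthetic data

The generators emulate the *shape* of text-mined interactome studies, not
their content:

- `generate_global` — a Barabási–Albert skeleton (m = round(mean_degree/2))
  giving the heavy-tailed, hub-dominated degree structure of real
  interactomes, overlaid with typed edges drawn from a configurable relation
  mixture (default: 50% interaction, 15% association, 20% expression
  regulation, 9% activity regulation, 6% transport/degradation) and
  parallel second edges on 15% of pairs. Parallel edges share the primary
  edge's orientation so duplicates never fabricate 2-cycles.
- `plant_condition_module` — samples module members without replacement and
  assigns relation categories in exact requested counts (defaults mirror
  the published hyperglycemia tallies 179/75/44/54 of 430; the remainder is
  "other").
- `plant_enriched_target` — wires a fresh target to exactly k module genes
  and K−k outside genes (defaults K=147, k=34).
- `plant_hub`, `plant_loops` — a half-wired betweenness hub and signed 2-/3-
  cycles; loop planting refuses conflicting sign requests for an ordered
  pair.

Each generator draws from its own named RNG stream spawned from the single
study seed, so fixtures are reproducible byte-for-byte and adding a
generator never shifts another's stream. The `paper_hg_preset` bundles all
of the above at published scale: 30,000 genes stand in for the unpublished
global universe, 430-gene module, K=147/k=34 target, and loops planted on
module genes chosen (deterministically) to be free of pre-existing signed
regulation so the planted loop set is recovered exactly.

What the generators do **not** emulate: literature-mining noise and citation
bias, realistic GO term structure (term maps are random covers), gene-symbol
aliasing, and the correlation between degree and annotation richness seen in
curated databases. Passing the recovery suite therefore demonstrates the
correctness of the algorithms under controlled conditions, not robustness
to the artifacts of real text-mined data.

## Null calibration

Drawing the overlap k at the hypergeometric null and re-testing it must
reject at no more than the nominal level. The acceptance check uses
(N, K, n) = (5000, 500, 500) — an expected overlap of 50, rich enough
support that the discrete test's largest achievable level sits close to
0.05 — over 600 replicates and requires the empirical rate within three
binomial standard errors of 0.05. At sparse-support configurations (e.g.
expected overlap ≈ 2) the discrete test is strongly conservative by
construction, which the suite asserts separately as a one-sided bound.

## Problem sizes and determinism

The default validation sizes — full enumeration grid N ≤ 20, 200 random
graphs ≤ 8 nodes for betweenness, 200 random digraphs ≤ 7 nodes for loops,
one 30,000-gene preset, 600 calibration replicates — were chosen so the
whole suite completes in well under a minute while exercising every code
path at or above the scales the analyses target. All stochastic tests are
seeded or derandomized; the pipeline writes byte-identical reports on
re-run and records a config + input hash in its provenance block.

## Known limitations

- No directed or weighted shortest paths; betweenness is defined on the
  undirected simple projection only.
- No GO DAG propagation or annotation download; term maps are generic.
- Exact reproduction of published enrichment p-values, centralization
  values and interaction counts is impossible without the underlying
  database state; the package reproduces conventions, magnitudes and the
  printed-table arithmetic instead.
- Gene identity is string-normalized symbols; no Entrez/Ensembl mapping.
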