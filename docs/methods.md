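# Methods

## Problem setting

A multi-component formula is modelled as a bipartite component–target
network coupled to a disease context given by a weighted gene list and a
PPI. The pipeline's job is to compress the formula: first to a *function
response space* (FRS) — the high-degree component subnetwork whose targets
are most relevant to the disease — and then to a minimal *key group of
effective components* (KGEC) whose union of targets covers every effective
protein. Everything downstream of the input tables is deterministic given
the configured seed.

## Screening

The Lipinski rules are applied with the boundary semantics stated in their
prose form: MW strictly below 500 Da; donors ≤ 5; acceptors strictly
below 10; cLogP in the closed interval [−2, 5]; rotatable bonds ≤ 10.
Components with missing properties are loaded and flagged rather than
dropped; in strict mode (default) an unknown property blocks a pass, in
lenient mode it is ignored, so the lenient active set always contains the
strict one. Screening is per-component, with no coupling across the list.
Literature-sourced "known bioactive" compounds get no bypass.

## Weighted disease network

Disease genes are induced on the merged PPI; node weight is
√(relevance_score × literature_count), the geometric mean of association
strength and literature support, which damps the heavy right tail of both
inputs. Duplicate disease-gene rows merge by keeping the maximum score and
summing counts (a score is a ceiling of evidence; publications are
additive across sources). Mapped genes with no intra-set edge are dropped
by default (`keep_isolates` retains them). PPI sources merge as a union,
keyed on the unordered symbol pair, keeping the source-label set and the
maximum confidence; a 0.7 confidence cutoff applies only where a score
column exists.

## Goal program and FRS

Deviation variables split each goal into under- and over-attainment, with
preemptive priorities p₁ > p₂ > p₃ minimizing (d₁⁻, d₂⁻, d₃⁺)
lexicographically; a weighted mode accepts explicit (p₁, p₂, p₃). The
third constraint is an inequality; we treat it as a soft cap on the
selected component count whose *overshoot* d₃⁺ is penalized, matching the
objective, and C_overlap counts unique gene symbols. Goal coefficients
default to a₁ = 0.70, a₂ = 0.80, a₃ = 0.40.

Because the total degree of a component subset is separable, the maximal-
degree subset of size k is exactly the k components of largest degree
(ties by id ascending, which also makes the chosen subset the
lexicographically first optimum). In the default *induced* mode, C_tar′ is
not a free variable: for each k it is the number of targets actually
induced by the top-k subset, and k is scanned over the full 1..C_com range
— linear after one sort, and provably identical to exhaustive enumeration
over k and subsets (the test suite checks this against brute force for
C_com ≤ 12). The *analytic* mode instead solves the pure goal program with
C_tar′ free, which zeroes d₁⁻ by construction. Degenerate inputs: an empty
component side, or zero overlap between disease genes and the PPI, are
fatal errors rather than silent empty results.

## Genetic knapsack and KGEC

Items are the FRS components; default value vᵢ = number of effective
proteins component i targets, default weight wᵢ = 1 so the capacity C
counts components (molecular weight or assay concentration can be swapped
in as weights). Two fitness modes exist: `sumvalue` (Σvᵢxᵢ, the printed
knapsack objective) and `coverage` (fraction of effective proteins in the
selection's target union), the pipeline default because the key group is
defined by complete coverage.

GA mechanics: population of 100 random binary chromosomes; roulette-wheel
selection proportional to fitness (uniform when all fitness is zero);
single-point crossover at rate 0.8 on consecutive pairs; one mutation
locus per chromosome, applied with probability 0.02; elitism of 1.
Infeasible chromosomes are repaired by repeatedly dropping the selected
item with the lowest value density vᵢ/wᵢ (ties by index) until W ≤ C —
with unit weights this is simply the lowest-value item. Repair rather than
penalty keeps roulette fitness non-negative and interpretable. Termination:
"capacity saturated" (best W = C) is read as *stop once the knapsack is
full and stagnant*, guarded by a 25-generation no-improvement window,
since W = C alone can hold indefinitely while fitness still improves; a
coverage of 1.0 stops a coverage-mode run immediately; `max_generations`
(500) bounds everything. On 100 random instances with n ≤ 15 the GA
matches the dynamic-programming optimum ≥ 95 % of the time and can never
exceed it (feasibility is enforced, so its value is a lower bound).

`select_kgec` searches the capacity: starting from the greedy set-cover
size it steps up until the GA first reaches full coverage, then walks down
to the smallest capacity that still covers everything. Each capacity's GA
run gets its own seed derived from the master seed via a spawn-keyed seed
sequence, so the whole search is one deterministic function of the seed.

## Enrichment

Over-representation uses the one-sided hypergeometric tail P(X ≥ k)
(`scipy.stats.hypergeom.sf`), with the background defaulting to the union
of all annotation genes, and Benjamini–Hochberg adjustment
(`statsmodels`) across tested terms. The significance cutoff for coverage
statistics is raw p < 0.05 by default, with an adjusted-p mode exposed
(and recommended when many terms are tested); pathway coverage is the
fraction of the reference query's significant terms recovered by the other
query. Note BH adjustment is *not* idempotent in general; what the suite
asserts is boundedness, p_adj ≥ p and rank preservation.

## Synthetic fixtures

The generator emulates the statistical shape of the real inputs, not their
content:

* **PPI** — preferential attachment (two seed nodes, each later node
  attaches `ppi_attachment` = 2 degree-proportional edges), giving exactly
  1 + 2(n − 2) edges and a heavy-tailed degree distribution; confidence
  uniform on [0.4, 1.0].
* **Disease genes** — 60 by default, 15 % off-network to emulate the
  mapping loss seen when curated disease lists meet a PPI; lognormal(1.0,
  0.75) scores and 1 + Poisson(5) literature counts.
* **C–T table** — 40 components over a 200-protein effective set hiding a
  planted 5-component *exact partition* (chunk sizes differ by ≤ 1 when
  uneven); non-planted components draw Zipf(2) target counts capped below
  the planted chunk size, so the planted cover is the unambiguous optimum.
  5 % of the protein set reuses disease-gene symbols, mirroring the small
  shared-gene fraction typical of real formula/disease pairs, so the goal
  program stays selective. Each Lipinski rule fails independently with
  probability 0.10 on non-planted components; planted components always
  pass.
* **Annotations** — 3 planted 20-gene terms drawn from the effective set
  (guaranteed enrichable) plus 20 decoy terms over a universe padded with
  300 background genes.

What passing on these fixtures shows: the machinery recovers a known
optimum under realistic degree/score shapes. What it does not show:
behaviour under correlated ADME properties, overlapping real pathway
structure, or PPI noise models — none of which the generator attempts. In
particular the CAP reference query on synthetic bundles is small (~10
genes), so its pathway-coverage statistic is coarse (often 0, ½ or 1) and
is reported as null when no reference term is significant.

## Numerical and reporting choices

Printed mean degrees are rounded half-up to two decimals, as composition
tables round. Tie-breaks are lexicographic on identifiers everywhere
(degree ranking, subset choice, repair order, greedy cover), making every
stage deterministic given its inputs. Graph exports are GraphML (full
attributes, round-trippable) and SIF (relations only); all loaders are
idempotent on their own writers' output. Run manifests record content
checksums of inputs and outputs; resume mode skips a stage only when its
recorded input checksum still matches.

## Problem sizes

The bundled benchmark sizes — 40 components, 200 effective proteins,
planted cover 5, GA population 100 with ≤ 500 generations, 100 knapsack
instances with n ≤ 15 against the exact DP, 50 goal-program fixtures with
≤ 12 components against brute force — were chosen so each suite probes the
full combinatorial structure (exhaustive oracles stay exact) while a
complete test run finishes in well under a minute on one core.

## Known limitations

* No gene-symbol alias resolution; symbol hygiene is the caller's job.
* The goal program's component importance is degree only; betweenness and
  closeness appear in reports but do not drive the FRS.
* The capacity walk in `select_kgec` stops at the first capacity where the
  GA fails, which is a heuristic minimum (the GA, not an exact cover
  solver, certifies each capacity).
* Live database clients (GeneCards/DisGeNET/STRING, KEGG/GO) are out of
  scope by design; annotations and targets are always user-supplied files.
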