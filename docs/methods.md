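# Methods

## Activity model

The unit of analysis is a binary call: gene g is *active* in sample s
iff at least one probe of g carries a Present (P) detection call in s.
Marginal (M) calls count as inactive — only P is ever defined as
active, and M is ambiguous in MAS5 practice, so the conservative
reading is used. Collapsing probes to genes is a logical OR, hence
monotone: adding a probe can only keep or increase a gene's
active-sample count. When two platforms are merged
(`merge_pma_tables`), probes absent from one platform are treated as
Absent (inactive) in that platform's samples; `require_all=True`
instead drops probes not shared by both platforms. Every column of the
call table is treated as an independent sample; technical duplicates
are not collapsed.

## Differential testing

Both gene-level and pathway-level tests are one-tailed Fisher exact
tests, i.e. hypergeometric tail probabilities with all margins of the
2×2 table fixed. A table with a zero row or column margin carries no
information and returns p = 1. The two tails overlap on the observed
table, so p_left + p_right ≥ 1 and a gene can never be significant in
both directions; a *pathway* can, because its two tests use different
count pairs (mp vs mm).

Deliberate choices:

* **No multiplicity correction by default** at either step — the method
  thresholds raw p < α (default 0.05). An `fdr=True` switch applies BH
  within a step for users who want it.
* **Universe** N = measured genes (those with ≥ 1 mapped probe), the
  standard enrichment background; `--universe pathway-union` restricts
  N to the union of pathway members instead.
* Genes in a GMT set but not measured are dropped at read time, so m
  counts measured members only.

Because Fisher's exact test is conservative for discrete tables, the
per-tail false-call rate under a global null sits visibly below α
(≈ 0.033 at α = 0.05 with 43 + 43 samples); the acceptance script
recomputes this.

## Alteration patterns

For a pair (A, B), each sample's joint state is a two-bit string
(first bit A). The 12 ordered transitions partition into type 2 (one
bit changes; 8), type 3 (concordant 00↔11; 2) and type 4 (inverse
01↔10; 2). A transition X→Y is tested on the 2×2 table
[[c1[X], c1[Y]], [c2[X], c2[Y]]] (greater tail on the first cell) —
conditioning on samples in the two states only, exactly the S1–S4
construction of the inverse pattern, applied uniformly to all
transitions. All 12 are tested for eligible pairs because observed
worked examples report significance for one-bit and concordant
transitions alongside inverse ones; the full scan is the superset-safe
choice. Eligibility gate: a pair with both genes non-differential is
assigned the no-change pattern without testing (`gate=False` lifts
this). Among significant transitions the minimal p wins; exact ties
break lexicographically on (from, to). The tie rule is an arbitrary
but deterministic convention; note it is not invariant under group
swap, which only matters at exact p-ties.

## Structure learning

`ges_fit` is a faithful greedy equivalence search at desk scale
(~hundreds of nodes): a forward phase applying the best valid Insert
operator while the score improves, a backward phase applying the best
valid Delete, operator validity per the classical conditions
(clique/blocking-path for Insert, clique for Delete), and the
equivalence class re-completed after each move by Dor–Tarsi consistent
extension followed by v-structure extraction and Meek R1–R3 closure.
Ties between operators break lexicographically by (source, target,
subset), so the search is deterministic given the data.

The local model is a **saturated Bernoulli conditional table** — the
natural model for binary activity calls, which are this package's
native data:

    score(v | Pa) = max-loglik − PD · (2^|Pa| / 2) · ln n

with one free parameter per parent configuration. The penalty discount
PD multiplies the BIC penalty term (TETRAD/pcalg convention; default
6); `depth` caps parent-set size during Insert (−1 = unlimited,
default). This score is decomposable and score-equivalent (equivalent
DAGs have equal dimension for saturated binary tables), so the search
is well defined over CPDAGs. Constant genes carry no structure and are
dropped with a warning, reappearing as isolated nodes. Enumerated
neighbour subsets per operator are capped at 8, ample below a few
hundred nodes.

## Expansion and crosstalk

Expansion is adjacency-based in both directions: directed edges either
way *and* undirected CPDAG edges count as neighbours, since an
undirected edge is merely an orientation the data cannot determine.
The k-step expanded set is therefore the k-ball of the raw set in the
network skeleton. Re-testing expanded collections reuses the unchanged
gene classes and universe, which is why significance inflates with
steps — pathway membership grows while the background stays fixed.
Default reports use one step; deeper expansions are produced (3 steps,
7 collections) but should be read as network-dominated.

The crosstalk test draws from nall = |union of all pathway gene sets|
(not the measured universe), per the overlap model's wording. The
default p-value is the standard upper hypergeometric tail
P(X ≥ nab); an `as_printed` variant reproduces the literal published
summation starting at i = 1, which exceeds the standard value by
exactly P(X = 0) — both are implemented so the discrepancy is
testable, and the standard form is the default because the test is
named a hypergeometric test. The BH family is the set of pairs
actually tested: unordered pairs of step-2-significant pathways.

## Robustness

Balanced subsampling draws without replacement from the larger group
(the procedure text governs over the word "bootstrap"), keeps the
smaller group whole, and reruns both steps. The correlation reported
is Pearson on −log10 pathway p-values per direction — the only
continuous per-pathway quantity the method produces. Overlap
proportion is the fraction of subsample calls recovered in the
full-data calls.

## Synthetic data

`simulate_activity` draws per-gene, per-sample independent Bernoulli
activity — exactly the exchangeability the Fisher tests assume. Planted
genes shift one group's rate by `effect` (half in each direction);
defaults are 1000 genes, balanced 43/43 groups, base rate 0.3, effect
0.4, 50 planted genes. `simulate_pathways` plants enrichment by drawing
`enrichment_frac` (default 0.5) of 5 of 50 sets' members (sizes 10–25)
from the planted pool. `simulate_pma` adds a probe layer that the OR
rule inverts exactly at zero noise; spurious-Present noise at rate f
yields a per-gene false-activity rate of 1 − (1 − f)^probes.
`simulate_from_dag`/`simulate_dag_data` sample binary data ancestrally
from a known DAG (roots fair coins; children follow the parent
majority with probability `cpd_strength`, default 0.9).

The imbalanced robustness design uses 600 genes with 200 planted
(150 vs 43 samples, subsample 43). The planted fraction is high by
design: it emulates a regime where differential calls are dominated by
genuine differences (as in strongly heterogeneous real comparisons),
which is what makes high subsample/full overlap achievable at all —
with a large null-gene majority, irreproducible false positives
arithmetically cap the overlap proportion no matter how good the
method is.

What the generators do **not** model: intensity distributions, probe
affinity, batch effects, gene–gene correlation outside the DAG
sampler, and overlapping direction mixtures within one gene. Passing
tests therefore certify the statistical machinery and its calibration
under the stated model, not performance on any particular real
dataset.

## Problem sizes and numerics

Tests and the acceptance script run at reduced scale chosen as the
package's own verification sizes: 20-seed batches for recovery rates,
200 × 2000 null replicates for calibration, n = 2000 samples for
3-node structure recovery, 10 subsampling iterations. Exact-test
implementations are checked against exhaustive integer-combinatorics
enumeration (to 1e-12 for the Fisher tails); BH against an independent
step-up; expansion against a BFS k-ball oracle; GES against exhaustive
scoring of all 25 three-node DAGs. Degenerate inputs: zero-margin
tables → p = 1; empty edge sets, empty pair lists and single-pathway
networks are valid and yield empty outputs rather than errors.

## Known limitations

* GES is exponential in the undirected neighbourhood size through
  subset enumeration; the cap of 8 trades exactness in ultra-dense
  graphs for bounded runtime.
* The gene test conditions on both margins; for very small groups the
  discreteness makes it markedly conservative.
* Expanded-collection significance is not comparable across steps
  (membership grows against a fixed background) — compare within a
  step, as the default one-step reports do.
* Pattern tie-breaking is conventional; report consumers should treat
  equal-p transitions as equally supported.
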