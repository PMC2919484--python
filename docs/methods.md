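# Methods

## Network construction

A stoichiometric model consists of the signed metabolites × reactions matrix
`S`, the reactions × genes binary association `E`, and per-metabolite
compartment labels. SBML ingestion (via cobra, with an XML pre-scan for
`boundaryCondition` flags) excludes boundary pseudo-species and any reaction
left without metabolites. Boolean gene–protein–reaction rules are flattened:
`E[r, e] = 1` whenever gene `e` appears anywhere in the rule. The rule's
AND/OR structure (complexes vs isozymes) is deliberately ignored — the
scores only ask whether reaction `r` can involve gene `e`, and no defensible
weighting of complexes follows from topology alone.

The bipartite graph takes `M^T = Ŝ E` with `Ŝ = |S| > 0`; both reactants and
products count and direction is ignored. The metabolite degree `k_m` is the
number of reactions the metabolite participates in. Zero-degree metabolites
and edge-less genes are dropped from the index sets.

**Compartment merging** sums the rows of `S` over metabolites with the same
base identifier (tag parsing accepts `atp[c]`-style brackets and `atp_c`
suffixes; unrecognized ids are their own base). Because a pure transport
reaction `A[e] → A[c]` cancels to a zero row, the merged model carries an
explicit binary participation matrix (OR of the pre-merge participations)
that the graph builder uses instead of `|S| > 0`. Without this, every
transporter would silently lose its edges, and transporter–synthesis
associations are precisely one of the interesting outputs.

**Hub removal** takes either an explicit degree cutoff or a top fraction;
the fractional cutoff is the degree at rank `⌊f·n⌋` of the descending sort,
with all ties at that degree included. It exists to reproduce the classical
preprocessing baseline; the degree-corrected scores are the recommended
alternative to using it.

## Local scores

For an enzyme pair: `n` metabolites in the scored graph, `n_tot` binary
edges, neighbourhood sizes `n₁`, `n₂`, overlap `n₁₂`, and the degree lists of
the two neighbourhoods. `n` and `n_tot` always refer to the graph as scored
(after any merging/filtering), so scores and null models stay consistent.

- Hypergeometric: `−log` of the upper-tail probability of `≥ n₁₂` shared
  metabolites; computed term-wise with log-gamma and `logsumexp`, so scores
  survive tails far below double-precision underflow.
- Bayes: contingency-table log likelihood ratio with the printed constant
  factors; the score grows for deviation in either direction, so below the
  null mean `n₁n₂/n` it is reflected (`s − |s − s(n₁n₂/n)|`) to keep only
  enrichment. The reflection point is non-integer; binomial coefficients use
  the continuous log-gamma extension.
- Poisson family: `n₁₂ log(n₁₂/λ) − |n₁₂ − λ|` with `0·log 0 := 0` (the
  continuous limit; an unconnected pair scores `−λ`, not `−∞`). The flat
  null is `λ = n₁n₂/n_tot`. The degree-corrected null sums
  `1 − exp(−kᵢ n₂/n_tot)` over one neighbourhood and averages with the
  reverse direction. The sequential ("metabolite association") variant
  builds the null distribution of the shared count by a recursion over the
  neighbourhood metabolites in ascending-degree order (fixing the order
  makes runs bit-reproducible; the distribution itself is order-independent
  up to floating-point accumulation). Read literally, the connect and miss
  probabilities at a given occupancy are complementary, so the recursion is
  a proper Markov chain and the distribution sums to one — a property the
  test suite asserts against exhaustive pattern enumeration.

Pairs with no shared metabolite are structurally unscorable by local logic;
they are kept with the method's exact `n₁₂ = 0` value (0 for the
hypergeometric, `−λ` for the Poisson family) rather than dropped, because
ROC evaluation needs a total ordering over a fixed pair universe.

`score_all_pairs` vectorizes the count-based methods with matrix algebra
(`M̂M̂ᵀ` for overlaps, an `exp` outer product for the degree-corrected
rates); the hypergeometric, Bayes and sequential variants run per pair. The
sequential recursion is O(n₁·n₂) per pair and is the slow member of the
family, as expected.

## Diffusion kernel

The block adjacency stacks metabolites then enzymes with `M̂` (or the
integer `M`, for the reaction-weighted variant) in the off-diagonal blocks.
Zero-degree nodes are removed — `D^{−1/2}` is undefined for them and an
isolated node carries no diffusion signal — with an id map retained. The
kernel `K = [(1+γ)I − D^{−1/2}AD^{−1/2}]^{−1}` is computed by dense Cholesky
solve (the normalized adjacency has spectral radius ≤ 1, so the system is
positive definite for every γ > 0; a Cholesky failure therefore signals a
malformed adjacency, and is raised as such). Above ~5000 nodes the code
solves only against the enzyme columns instead of forming the full inverse.
The inverse is analytically symmetric; the numerical result is symmetrized
after a 1e−8 asymmetry check. The weighted variant applies the identical
formula to the weighted adjacency with weighted degrees.

Default γ = 1. Raw kernel entries drive rankings; reported values use a
display scale of 10⁴, and the discordance thresholds below are on that
display scale.

## Evaluation

Positives: synthetic-lethal plus synthetic-growth-defect pairs with both
genes in the universe, order-normalized and deduplicated. Negatives: pairs
where each gene has ≥ 1 such interaction anywhere in the table and at least
one of the two has ≥ 5 as the query of a high-throughput screen — a proxy
for "tested but not interacting". How a source database encodes "query" is
not fully standardized; this package takes interactor A of a
high-throughput genetic record as the query, and documents rather than
asserts that mapping.

Curves use one threshold bucket per distinct score value (the convention of
standard ROC tooling); AUC by trapezoid, F as the maximum harmonic mean of
precision and recall over thresholds. AUC is checked against the
Mann–Whitney statistic in the tests. Curve downsampling affects only written
point sets, never the statistics.

The compartment analysis assigns each gene the union of compartments over
the metabolites of its reactions (the only definition derivable from the
model), cross-tabulates compartment sharing against SL status over all
universe pairs, and tests the 2×2 table. Fisher's exact test is the default;
a continuity-corrected chi-square is provided, and for the reference yeast
counts it is the chi-square that reproduces the published p-value — worth
knowing when comparing against older literature, where the chi-square was
the default choice.

## GO consistency and semantic similarity

Annotations are propagated to ancestors along `is_a`/`part_of` edges before
any term size or common parent is computed; "closest parent" is otherwise
ill-defined. A term is eligible when its propagated universe gene count lies
in `[min_size, max_size)` (default 5–100). The observed statistic is the
mean pairwise coupling score among the term's genes; the null permutes gene
identities over whole annotation profiles — one global permutation per
iteration, shared by all terms — which preserves exactly both the per-term
gene counts and the per-gene annotation counts, and preserves the
between-term dependence structure. Empirical `p = (r+1)/(n_perm+1)`;
Benjamini–Hochberg at FDR 0.05 is the operative correction (Bonferroni
available behind a flag). Default `n_perm` = 10,000 for production runs;
tests use a few hundred.

Semantic similarity is `ln(N_T/N_P)` with `N_P` the smallest propagated gene
count over terms annotating both genes in an ontology, summarized by the
maximum over BP, MF and CC. `N_T` defaults to 6310, the annotated yeast gene
total of the reference snapshot, and is configurable (synthetic sets use
their own gene count). A pair with no shared annotated ontology scores 0 and
is flagged unannotated rather than dropped — those pairs are exactly the
"missing annotation" category the discordance mining is meant to surface.
Discordant pairs are those with display-scale diffusion score ≥ 50 and max
similarity ≤ 2 (equivalently a common parent of ≥ ~854 genes); the package
extracts the candidate list with unannotated flags and leaves biological
classification to the user.

## Synthetic data

The generator emulates the statistical regime the methods target, not any
particular organism's chemistry. Metabolite degrees follow a discrete power
law with exponent 2.5 truncated to `[1, n_enzymes]` — the long-tail shape
typical of metabolic networks; the exponent is exposed and its recovery is
tested by maximum likelihood over seeds. Hubs (water/ATP analogues) attach
to enzyme samples drawn with replacement, so the weighted graph has genuine
multi-reaction edges. Planted modules of enzymes share module-private
metabolites at density 0.8. Each enzyme's incidences are chunked into
reactions of 1–3 metabolites with ±1 coefficients; duplicate incidences go
to distinct reactions, keeping metabolite reaction-degrees equal to their
drawn values.

Defaults: 120 enzymes, 300 metabolites, 5 hubs of degree 60, 6 modules of 8
enzymes. Interaction labels are Bernoulli — 0.5 within modules, 0.005
background — a strong but not deterministic signal. High-throughput screens
are emulated by a designated query gene per module plus background queries;
designated queries also receive genome-wide off-network hits, since real
interaction tables are not restricted to network genes and the negatives
rule counts a gene's interactions table-wide. Annotations mirror the
modules (one term per module per ontology under a small DAG), with a few
genes left deliberately unannotated.

What the generator does **not** emulate: real reaction stoichiometry and
mass balance, compartment-specific biology, correlated annotation noise,
and literature-biased interaction ascertainment. Passing tests demonstrate
that the statistics behave as designed in the regime they model — long
tails, hubs, modular signal — not that any particular AUC transfers to a
real reconstruction.

## Problem sizes and determinism

The test and acceptance workloads use networks of 40–200 enzymes and
150–2000 metabolites, 20-seed replicate batteries, a few hundred
permutations per consistency run, and 300 stub-matching replicates for the
null-rate calibration — sizes at which every check runs comfortably on one
CPU while keeping Monte-Carlo error well below the asserted margins. All
randomness flows through seeded `numpy` generators; identical seeds give
byte-identical serialized outputs.

The calibration check builds its replicates by stub matching (each
metabolite's edge stubs land on enzyme stubs independently), which is the
random-graph model the degree-corrected null actually linearizes, and uses
metabolite degrees 10–20: at small degrees, conditioning on the observed
edge consumes one stub and biases the comparison by a factor ~`k/(k−1)`,
which is a property of the approximation being validated, not of the
implementation.

## Known limitations

- Flattened gene rules overcount associations for large complexes.
- The Bayes score's constant factors are implemented as printed for the
  reference form; their derivation is not re-derived here.
- The sequential null variant is quadratic per pair and adds little over
  the degree-corrected rate in practice; it is included for completeness.
- GO consistency percentages depend on the annotation snapshot; absolute
  percentages are not comparable across snapshots and are not asserted.
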