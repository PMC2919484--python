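# metcouple

Functional-association scores for enzyme pairs in bipartite metabolite–enzyme
networks, for people working with genome-scale metabolic reconstructions who
want fast topology-based predictions of genetic interaction and shared
function — without flux sampling, and without deleting hub metabolites first.

## The problem and the methods

A metabolic reconstruction defines a bipartite graph: metabolites and enzymes
as the two vertex classes, with an edge wherever an enzyme catalyzes a
reaction involving the metabolite (`M^T = Ŝ E`, where `Ŝ` is the binarized
stoichiometric matrix and `E` the flattened reaction–gene association).
Enzymes sharing metabolites tend to be functionally related, but currency
metabolites such as water and ATP connect hundreds of unrelated enzymes.
Classical fixes either count shared metabolites (implicitly assuming a flat
metabolite degree distribution) or delete high-degree metabolites at an
arbitrary cutoff.

`metcouple` implements scores that use the degree distribution instead:

- **Local scores** for a pair with `n₁`, `n₂` metabolite neighbours and
  `n₁₂` shared: raw count, hypergeometric tail `−log Σₖ C(n₁,k)C(n−n₁,n₂−k)/C(n,n₂)`,
  a contingency-table Bayes score, and a Poisson log-likelihood-ratio family
  `n₁₂·log(n₁₂/λ) − |n₁₂ − λ|`. The flat null uses `λ = n₁n₂/n_tot`; the
  degree-corrected null uses
  `λ₁₂ = Σᵢ [1 − exp(−kᵢ n₂/n_tot)]` over the neighbourhood's metabolite
  degrees `kᵢ` (averaged with the reverse direction), so sharing a
  high-degree metabolite contributes almost nothing. A further variant
  builds the full null distribution of the shared count by a sequential
  connection recursion.
- **Global scores** from a graph diffusion kernel
  `K = [(1+γ)I − D^{−1/2} A D^{−1/2}]^{−1}` on the block bipartite
  adjacency: a sum over walks of all lengths, a `d`-step walk discounted by
  `e^{−γd}`, with degree normalization playing the hub-robustness role.
  Enzyme–enzyme entries of `K` score all pairs, including enzymes that share
  no metabolite (γ = 1 by default; rankings are insensitive to γ over
  0.5–120).

Around the scores sit the evaluation machinery: a synthetic-lethality
benchmark built from genetic-interaction tables (BioGRID format) with the
presumed-tested negatives rule, ROC/AUC and precision–recall/max-F curves,
a shared-compartment × synthetic-lethality contingency analysis, a GO-term
consistency permutation test with Benjamini–Hochberg control,
information-content semantic similarity `ln(N_T/N_P)`, and mining of
high-diffusion-score / low-annotation-similarity discordant pairs.
A synthetic-data module generates networks with long-tailed metabolite
degrees, planted enzyme modules, interaction labels and annotation sets, so
everything is testable with no downloads.

## Worked example

```python
import metcouple as mc

spec = mc.SyntheticSpec(seed=0)              # 120 enzymes, 300 metabolites
model = mc.generate_network(spec)
graph = mc.build_bipartite(model)

bench = mc.build_benchmark(mc.generate_interactions(model, spec),
                           set(graph.enzymes))
for method in ("shared", "poisson_metdeg"):
    curves = mc.evaluate(mc.score_all_pairs(graph, method), bench)
    print(f"{method:15s} AUC = {curves.auc:.3f}  max F = {curves.max_f:.3f}")
curves = mc.evaluate(mc.gdk_scores(graph, gamma=1.0), bench)
print(f"{'gdk':15s} AUC = {curves.auc:.3f}  max F = {curves.max_f:.3f}")
```

prints

```
shared          AUC = 0.834  max F = 0.621
poisson_metdeg  AUC = 0.854  max F = 0.673
gdk             AUC = 0.846  max F = 0.697
```

The benchmark (107 planted synthetic-lethal positives, 940 presumed-tested
negatives) is ranked best by the degree-corrected Poisson score and the
diffusion kernel; the raw shared-metabolite count trails because the ten
planted hub metabolites inflate sharing between unrelated enzymes.

The same pipeline runs from the shell on real inputs:

```sh
metcouple simulate --out fixtures --seed 7          # or bring your own SBML
metcouple score --sbml fixtures/network.xml --method gdk --gamma 1 --out gdk.tsv
metcouple evaluate --scores gdk.tsv --interactions fixtures/interactions.tsv --out bench
metcouple go-consistency --scores gdk.tsv --gaf fixtures/annotations.gaf \
    --obo fixtures/ontology.obo --out go.tsv
```

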