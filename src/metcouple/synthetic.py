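"""Synthetic bipartite networks, interaction tables and annotation sets.

The generator emulates the statistical setting the coupling scores are
designed for: a metabolite-enzyme network with a long-tailed metabolite
degree distribution and a few very-high-degree "currency" hubs (water/ATP
analogues), plus planted enzyme modules that share module-private
metabolites.  Module membership drives both the synthetic-lethality labels
(within-module pairs interact at a higher Bernoulli rate than background)
and the synthetic GO annotations (one term per module under a small DAG),
so the benchmark and ontology machinery can be exercised end to end with no
external downloads.

Everything is deterministic for a fixed ``(spec, seed)``; no attempt is made
to mimic any specific reconstruction's reaction chemistry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .evaluation import InteractionTable
from .go_assess import ONTOLOGIES, AnnotationSet
from .network import StoichiometricModel

_COMP_CODES = ("c", "m", "e", "x", "n", "g", "r", "v")


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic study system.

    Defaults describe a mid-sized network: 120 enzymes, 300 metabolites with
    a power-law degree tail (exponent 2.5, the shape typical of metabolic
    networks), 5 hubs each touching half the enzymes, and 6 planted modules
    of 8 enzymes whose private metabolites connect members with probability
    0.8.  Within-module pairs are synthetic lethal at rate 0.5 against a
    0.005 background, a strong but not deterministic signal.
    """

    n_enzymes: int = 120
    n_metabolites: int = 300
    degree_tail: float = 2.5
    n_hubs: int = 5
    hub_degree: int = 60
    n_modules: int = 6
    module_size: int = 8
    module_density: float = 0.8
    mets_per_module: int = 6
    sl_rate_in_module: float = 0.5
    sl_rate_background: float = 0.005
    n_background_terms: int = 8
    background_term_size: int = 10
    n_compartments: int = 3
    duplicate_rate: float = 0.2
    seed: int = 0

    @classmethod
    def scaled(cls, n_enzymes: int, n_metabolites: int, seed: int = 0,
               **overrides) -> "SyntheticSpec":
        """Spec with planted-structure sizes scaled to fit the network."""
        module_size = overrides.pop("module_size", min(8, max(2, n_enzymes // 6)))
        defaults = dict(
            n_enzymes=n_enzymes, n_metabolites=n_metabolites, seed=seed,
            hub_degree=max(2, n_enzymes // 2),
            n_hubs=min(5, max(1, n_metabolites // 60)),
            module_size=module_size,
            n_modules=min(6, max(1, n_enzymes // (2 * module_size))),
            mets_per_module=min(6, max(2, n_metabolites // 50)),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self) -> None:
        for r in (self.module_density, self.sl_rate_in_module,
                  self.sl_rate_background, self.duplicate_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_modules * self.module_size > self.n_enzymes:
            raise ValueError("planted modules do not fit within n_enzymes")
        if (self.n_hubs + self.n_modules * self.mets_per_module
                > self.n_metabolites):
            raise ValueError("planted metabolites do not fit within n_metabolites")
        if self.hub_degree > self.n_enzymes:
            raise ValueError("hub_degree cannot exceed n_enzymes")


def module_members(spec: SyntheticSpec) -> list[list[str]]:
    """Planted module membership (deterministic: leading enzyme blocks)."""
    genes = gene_ids(spec)
    return [genes[m * spec.module_size:(m + 1) * spec.module_size]
            for m in range(spec.n_modules)]


def gene_ids(spec: SyntheticSpec) -> list[str]:
    return [f"g{i:04d}" for i in range(spec.n_enzymes)]


def _truncated_power_law(rng: np.random.Generator, alpha: float,
                         k_max: int, size: int) -> np.ndarray:
    """Discrete power law P(k) ~ k^-alpha on [1, k_max] via inverse CDF."""
    ks = np.arange(1, k_max + 1, dtype=float)
    p = ks ** (-alpha)
    p /= p.sum()
    return rng.choice(np.arange(1, k_max + 1), size=size, p=p)


def generate_network(spec: SyntheticSpec) -> StoichiometricModel:
    """Build the synthetic stoichiometric model.

    Metabolite-enzyme incidences are laid down first (hubs to uniform enzyme
    samples, module metabolites to their module at ``module_density``,
    background metabolites to power-law-many uniform enzymes); each enzyme's
    incidences are then chunked into reactions of 1-3 metabolites with unit
    stoichiometric coefficients (first metabolite the reactant).  A fraction
    of background metabolites reuses an earlier base id in another
    compartment, to exercise compartment merging.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_ids(spec)
    modules = module_members(spec)

    # --- metabolite ids, compartments, target degrees
    comps = _COMP_CODES[:max(1, spec.n_compartments)]
    met_ids: list[str] = []
    met_comp: list[str] = []
    kinds: list[tuple[str, int]] = []  # ("hub"|"module"|"bg", module index or -1)
    for h in range(spec.n_hubs):
        met_ids.append(f"hub{h:03d}_{comps[0]}")
        met_comp.append(comps[0])
        kinds.append(("hub", -1))
    for m in range(spec.n_modules):
        for p in range(spec.mets_per_module):
            comp = comps[int(rng.integers(len(comps)))]
            met_ids.append(f"mod{m:02d}p{p:02d}_{comp}")
            met_comp.append(comp)
            kinds.append(("module", m))
    n_bg = spec.n_metabolites - len(met_ids)
    base_counter = 0
    prev_base: str | None = None
    for _ in range(n_bg):
        if prev_base is not None and rng.random() < spec.duplicate_rate:
            base = prev_base
            used = {c for mid, c in zip(met_ids, met_comp)
                    if mid.startswith(base + "_")}
            free = [c for c in comps if c not in used]
            comp = free[0] if free else comps[int(rng.integers(len(comps)))]
            prev_base = None
        else:
            base = f"met{base_counter:04d}"
            base_counter += 1
            comp = comps[int(rng.integers(len(comps)))]
            prev_base = base
        mid = f"{base}_{comp}"
        if mid in met_ids:  # same base+comp collision: mint a fresh base
            base = f"met{base_counter:04d}"
            base_counter += 1
            mid = f"{base}_{comp}"
            prev_base = base
        met_ids.append(mid)
        met_comp.append(comp)
        kinds.append(("bg", -1))

    bg_degrees = _truncated_power_law(rng, spec.degree_tail, spec.n_enzymes, n_bg)

    # --- incidences: metabolite -> set of enzymes
    incident: list[np.ndarray] = []
    bg_i = 0
    for (kind, mod) in kinds:
        if kind == "hub":
            # with replacement: an enzyme can use a hub in several reactions,
            # giving the weighted graph its multi-reaction edges
            enz = rng.choice(spec.n_enzymes, size=spec.hub_degree, replace=True)
        elif kind == "module":
            members = np.array([genes.index(g) for g in modules[mod]])
            mask = rng.random(len(members)) < spec.module_density
            if not mask.any():
                mask[rng.integers(len(members))] = True
            enz = members[mask]
        else:
            enz = rng.choice(spec.n_enzymes, size=int(bg_degrees[bg_i]), replace=True)
            bg_i += 1
        incident.append(np.sort(enz))

    # --- chunk each enzyme's incidences into reactions
    per_enzyme: dict[int, list[int]] = {e: [] for e in range(spec.n_enzymes)}
    for mi, enz in enumerate(incident):
        for e in enz:
            per_enzyme[int(e)].append(mi)
    reactions: list[tuple[list[int], int]] = []  # (metabolite rows, gene col)
    for e in range(spec.n_enzymes):
        mets = per_enzyme[e]
        rng.shuffle(mets)
        chunk: list[int] = []
        target = int(rng.integers(1, 4))
        for mi in mets:
            if mi in chunk or len(chunk) >= target:
                # duplicate incidences go to distinct reactions, so every
                # incidence contributes one reaction to the metabolite degree
                reactions.append((chunk, e))
                chunk = []
                target = int(rng.integers(1, 4))
            chunk.append(mi)
        if chunk:
            reactions.append((chunk, e))

    rxn_ids = [f"r{j:05d}" for j in range(len(reactions))]
    S = np.zeros((len(met_ids), len(reactions)))
    E = np.zeros((len(reactions), spec.n_enzymes), dtype=np.int8)
    for j, (mets, e) in enumerate(reactions):
        for pos, mi in enumerate(mets):
            S[mi, j] += -1.0 if pos == 0 else 1.0
        E[j, e] = 1

    comp_of = dict(zip(met_ids, met_comp))
    return StoichiometricModel(met_ids, rxn_ids, list(genes), S, E, comp_of)


def generate_interactions(model: StoichiometricModel,
                          spec: SyntheticSpec) -> InteractionTable:
    """Label gene pairs as synthetic lethal with module-dependent rates.

    Within-module pairs are SL with ``sl_rate_in_module``; all other pairs
    with ``sl_rate_background``.  High-throughput screens are emulated by a
    designated query gene per module (plus a few background queries): records
    involving a designated query carry high-throughput metadata with that
    gene as the query, concentrating query counts the way real screens do,
    so the negatives rule of the benchmark is exercisable.
    """
    rng = np.random.default_rng(spec.seed + 1)
    modules = module_members(spec)
    mod_of = {g: m for m, members in enumerate(modules) for g in members}
    queries = {members[0] for members in modules}
    background = [g for g in model.gene_ids if g not in mod_of]
    if background:
        n_extra = max(1, len(background) // 10)
        queries |= set(rng.choice(background, size=n_extra, replace=False))
    rows = []
    for a, b in itertools.combinations(model.gene_ids, 2):
        same = mod_of.get(a, -1) == mod_of.get(b, -2)
        rate = spec.sl_rate_in_module if same else spec.sl_rate_background
        if rng.random() < rate:
            in_q = [g for g in (a, b) if g in queries]
            query = in_q[int(rng.integers(len(in_q)))] if in_q else ""
            rows.append({"gene_a": a, "gene_b": b,
                         "interaction_type": "synthetic_lethality"
                         if rng.random() < 0.6 else "synthetic_growth_defect",
                         "is_high_throughput": bool(in_q), "query_gene": query})
    # genome-wide screen hits outside the metabolic network: real interaction
    # tables are not restricted to network genes, and these off-network
    # records dominate a query gene's interaction count
    for qi, q in enumerate(sorted(queries)):
        for h in range(5 + int(rng.poisson(3.0))):
            rows.append({"gene_a": q, "gene_b": f"offnet{qi:03d}_{h:02d}",
                         "interaction_type": "synthetic_lethality",
                         "is_high_throughput": True, "query_gene": q})
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "interaction_type",
                                     "is_high_throughput", "query_gene"])
    return InteractionTable(df)


def generate_annotations(model: StoichiometricModel,
                         spec: SyntheticSpec) -> AnnotationSet:
    """Annotations mirroring the planted modules, under a three-root DAG.

    Each ontology gets a root, an intermediate "metabolic" term, one leaf
    term per planted module annotating that module's genes, and
    ``n_background_terms`` leaf terms over random gene samples.  One gene
    per module beyond the first is left unannotated to exercise the
    unannotated flag downstream.
    """
    rng = np.random.default_rng(spec.seed + 2)
    modules = module_members(spec)
    dag = nx.DiGraph()
    direct: dict[str, set[str]] = {g: set() for g in model.gene_ids}
    unannotated = {members[-1] for members in modules[1:]}

    for o in ONTOLOGIES:
        root = f"{o}:root"
        mid = f"{o}:metabolic"
        dag.add_node(root, namespace=o)
        dag.add_node(mid, namespace=o)
        dag.add_edge(mid, root)
        for m, members in enumerate(modules):
            term = f"{o}:module{m:02d}"
            dag.add_node(term, namespace=o)
            dag.add_edge(term, mid)
            for g in members:
                if g not in unannotated:
                    direct[g].add(term)
        for t in range(spec.n_background_terms):
            term = f"{o}:bg{t:02d}"
            dag.add_node(term, namespace=o)
            dag.add_edge(term, root)
            size = min(spec.background_term_size, len(model.gene_ids))
            for g in rng.choice(model.gene_ids, size=size, replace=False):
                if g not in unannotated:
                    direct[str(g)].add(term)
        # every annotated gene at least reaches the root
        for g in model.gene_ids:
            if g not in unannotated:
                direct[g].add(root)
    return AnnotationSet(direct, dag)


# ---------------------------------------------------------------------------
# File-format writers (fixtures for round-trip and CLI tests)
# ---------------------------------------------------------------------------

def write_sbml(model: StoichiometricModel, path: str) -> None:
    """Emit the model as SBML (via a COBRA model with flattened gene rules)."""
    import cobra

    cm = cobra.Model("synthetic")
    mets = {}
    for mid in model.metabolite_ids:
        m = cobra.Metabolite(mid, compartment=model.compartment_of.get(mid) or "c")
        mets[mid] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid, lower_bound=-1000.0, upper_bound=1000.0)
        rxns.append(r)
    cm.add_reactions(rxns)
    for j, r in enumerate(rxns):
        stoich = {mets[model.metabolite_ids[i]]: float(model.S[i, j])
                  for i in np.flatnonzero(np.abs(model.S[:, j]) > 0)}
        r.add_metabolites(stoich)
        genes = [model.gene_ids[k] for k in np.flatnonzero(model.E[j])]
        if genes:
            r.gene_reaction_rule = " or ".join(genes)
    cobra.io.write_sbml_model(cm, str(path))


def write_biogrid_tab2(table: InteractionTable, path: str) -> None:
    """Write the interaction table in a BioGRID tab2-style layout."""
    type_names = {"synthetic_lethality": "Synthetic Lethality",
                  "synthetic_growth_defect": "Synthetic Growth Defect",
                  "other": "Negative Genetic"}
    df = table.records
    out = pd.DataFrame({
        "Official Symbol Interactor A": df.query_gene if "query_gene" in df else df.gene_a,
        "Official Symbol Interactor B": [b if q == a else a for a, b, q in
                                         zip(df.gene_a, df.gene_b,
                                             df.get("query_gene", df.gene_a))],
        "Experimental System": df.interaction_type.map(type_names),
        "Experimental System Type": "genetic",
        "Throughput": np.where(df.get("is_high_throughput", False),
                               "High Throughput", "Low Throughput"),
    })
    out.to_csv(path, sep="\t", index=False)


def write_gaf(annots: AnnotationSet, path: str) -> None:
    """Write direct annotations as GAF 2.2."""
    aspect = {"BP": "P", "MF": "F", "CC": "C"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(annots.direct):
            for term in sorted(annots.direct[gene]):
                o = annots.ontology_of(term)
                fh.write("\t".join([
                    "SYN", gene, gene, "", term, "SYN:0", "IDA", "",
                    aspect.get(o, "P"), "", "", "gene", "taxon:4932",
                    "20100101", "SYN", "", ""]) + "\n")


def write_obo(annots: AnnotationSet, path: str) -> None:
    """Write the term DAG as a minimal OBO 1.2 document."""
    ns_long = {"BP": "biological_process", "MF": "molecular_function",
               "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(annots.dag.nodes):
            ns = annots.ontology_of(term)
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {ns_long.get(ns, ns)}\n")
            for parent in sorted(annots.dag.successors(term)):
                fh.write(f"is_a: {parent} ! {parent}\n")


def write_fixture_set(spec: SyntheticSpec, out_dir: str) -> dict[str, str]:
    """Generate the full fixture set (SBML, interactions, GAF, OBO) on disk."""
    import json
    import os
    from dataclasses import asdict

    os.makedirs(out_dir, exist_ok=True)
    model = generate_network(spec)
    table = generate_interactions(model, spec)
    annots = generate_annotations(model, spec)
    paths = {
        "sbml": os.path.join(out_dir, "network.xml"),
        "interactions": os.path.join(out_dir, "interactions.tsv"),
        "gaf": os.path.join(out_dir, "annotations.gaf"),
        "obo": os.path.join(out_dir, "ontology.obo"),
        "spec": os.path.join(out_dir, "spec.json"),
    }
    write_sbml(model, paths["sbml"])
    write_biogrid_tab2(table, paths["interactions"])
    write_gaf(annots, paths["gaf"])
    write_obo(annots, paths["obo"])
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return paths
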