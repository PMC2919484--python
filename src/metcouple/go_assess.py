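"""GO-term consistency testing and information-content semantic similarity.

A GO term is *consistent* with a coupling score when the mean pairwise score
among its member genes exceeds what random annotation assignment produces.
The null is built by permuting gene identities over whole annotation
profiles, which exactly preserves both the per-term gene counts and the
per-gene annotation counts; empirical p-values over many permutations are
corrected with Benjamini-Hochberg.

Semantic similarity between two genes is ``ln(N_T / N_P)`` where ``N_T`` is
the total number of annotated genes (6310 for yeast in the reference
snapshot) and ``N_P`` the gene count of the most specific term annotating
both genes, after propagating annotations up the ontology.  The pair value
is the maximum over the biological process, molecular function and cellular
component ontologies.  Pairs with a high diffusion-kernel score but low
semantic similarity are candidate disagreements between network structure
and curated annotation (transport-vs-synthesis enzymes, pathway-boundary
splits, missing annotations).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .local import PairScoreTable

ONTOLOGIES = ("BP", "MF", "CC")
_NAMESPACE_MAP = {
    "biological_process": "BP", "molecular_function": "MF",
    "cellular_component": "CC",
    "P": "BP", "F": "MF", "C": "CC", "BP": "BP", "MF": "MF", "CC": "CC",
}
#: GAF relations treated as hierarchy edges when propagating annotations
PROPAGATE_RELATIONS = ("is_a", "part_of")

YEAST_TOTAL_GENES = 6310


@dataclass(frozen=True)
class SemSimParams:
    """Parameters of the ``ln(N_T / N_P)`` similarity.

    ``n_total`` defaults to the annotated yeast gene count of the reference
    snapshot; pass ``None`` to use the annotation set's own gene count.
    """

    n_total: int | None = YEAST_TOTAL_GENES


class AnnotationSet:
    """Gene -> GO-term associations plus the term DAG.

    Parameters
    ----------
    direct:
        gene -> set of directly annotated term ids (any ontology).
    dag:
        Directed graph with child -> parent edges (``is_a``/``part_of``)
        and a ``namespace`` attribute per term node.
    """

    def __init__(self, direct: dict[str, set[str]], dag: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("term DAG contains a cycle")
        self.dag = dag
        self.direct = {g: set(ts) & set(dag.nodes) for g, ts in direct.items()}
        self._closed: dict[str, dict[str, set[str]]] | None = None
        self._term_genes: dict[str, set[str]] | None = None

    def ontology_of(self, term: str) -> str:
        ns = self.dag.nodes[term].get("namespace", "")
        return _NAMESPACE_MAP.get(ns, ns)

    @lru_cache(maxsize=None)
    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus all its ancestors along child->parent edges."""
        return frozenset({term} | nx.descendants(self.dag, term))

    def _propagate(self) -> None:
        closed: dict[str, dict[str, set[str]]] = {o: {} for o in ONTOLOGIES}
        term_genes: dict[str, set[str]] = {}
        for gene, terms in self.direct.items():
            full: set[str] = set()
            for t in terms:
                full |= self.ancestors(t)
            for o in ONTOLOGIES:
                sub = {t for t in full if self.ontology_of(t) == o}
                if sub:
                    closed[o][gene] = sub
            for t in full:
                term_genes.setdefault(t, set()).add(gene)
        self._closed = closed
        self._term_genes = term_genes

    def closed_terms(self, gene: str, ontology: str) -> set[str]:
        """Ancestor-closed annotation set of a gene within one ontology."""
        if self._closed is None:
            self._propagate()
        return self._closed[ontology].get(gene, set())

    def term_genes(self, term: str) -> set[str]:
        """Genes annotated to the term, after upward propagation."""
        if self._term_genes is None:
            self._propagate()
        return self._term_genes.get(term, set())

    def term_size(self, term: str) -> int:
        return len(self.term_genes(term))

    @property
    def genes(self) -> set[str]:
        return set(self.direct)

    @property
    def n_annotated_genes(self) -> int:
        return sum(1 for ts in self.direct.values() if ts)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_gaf_obo(cls, gaf_path: str, obo_path: str) -> "AnnotationSet":
        """Load a GAF 2.x association file against an OBO 1.2/1.4 ontology."""
        import obonet
        from Bio.UniProt import GOA

        raw = obonet.read_obo(obo_path, ignore_obsolete=True)
        dag = nx.DiGraph()
        for node, data in raw.nodes(data=True):
            dag.add_node(node, namespace=data.get("namespace", ""))
        for child, parent, key in raw.edges(keys=True):
            if key in PROPAGATE_RELATIONS:
                dag.add_edge(child, parent)
        rel_edges = [(c, d.get("relationship", [])) for c, d in raw.nodes(data=True)]
        for child, rels in rel_edges:
            for rel in rels:
                parts = rel.split()
                if len(parts) == 2 and parts[0] in PROPAGATE_RELATIONS:
                    dag.add_edge(child, parts[1])

        direct: dict[str, set[str]] = {}
        with open(gaf_path) as handle:
            for rec in GOA.gafiterator(handle):
                gene = rec["DB_Object_Symbol"] or rec["DB_Object_ID"]
                if rec["GO_ID"] in dag:
                    direct.setdefault(gene, set()).add(rec["GO_ID"])
        return cls(direct, dag)


# ---------------------------------------------------------------------------
# Consistency permutation test
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    """Per-term permutation test results and per-ontology consistency rates."""

    table: pd.DataFrame  # term, ontology, n_genes, observed, p_value, significant
    percent_consistent: dict[str, float]
    n_perm: int
    fdr: float

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def eligible_terms(annots: AnnotationSet, universe: set[str],
                   min_size: int = 5, max_size: int = 100) -> list[str]:
    """Terms annotating at least ``min_size`` and fewer than ``max_size``
    universe genes (half-open interval, boundary at the top excluded)."""
    out = []
    for term in annots.dag.nodes:
        k = len(annots.term_genes(term) & universe)
        if min_size <= k < max_size:
            out.append(term)
    return sorted(out)


def go_consistency(scores: PairScoreTable, annots: AnnotationSet,
                   universe: set[str] | None = None, n_perm: int = 10_000,
                   fdr: float = 0.05, seed: int | None = None,
                   min_size: int = 5, max_size: int = 100,
                   adjust: str = "bh") -> ConsistencyResult:
    """Permutation test of per-term mean coupling scores.

    For each eligible term the observed statistic is the mean pairwise score
    over its universe genes.  Each permutation relabels the genes (one global
    permutation per iteration, shared by all terms), preserving every term's
    gene count and every gene's annotation count; ``p = (r + 1)/(n_perm + 1)``
    with ``r`` the number of permuted means >= observed.  ``adjust`` selects
    Benjamini-Hochberg (``"bh"``, operative default) or Bonferroni
    (``"bonferroni"``).
    """
    if universe is None:
        universe = set(scores.enzymes)
    genes = sorted(universe & set(scores.enzymes))
    gidx = {g: i for i, g in enumerate(genes)}
    eidx = {e: i for i, e in enumerate(scores.enzymes)}
    rows = np.array([eidx[g] for g in genes])
    V = scores.values[np.ix_(rows, rows)]

    terms, members = [], []
    for term in eligible_terms(annots, set(genes), min_size, max_size):
        idx = np.array(sorted(gidx[g] for g in annots.term_genes(term) & set(genes)))
        if len(idx) < 2:
            continue
        terms.append(term)
        members.append(idx)
    if not terms:
        raise ValueError("no eligible terms with >= 2 universe genes")

    iu_cache = {len(m): np.triu_indices(len(m), k=1) for m in members}

    def term_mean(idx: np.ndarray) -> float:
        iu = iu_cache[len(idx)]
        sub = V[np.ix_(idx, idx)]
        return float(np.nanmean(sub[iu]))

    observed = np.array([term_mean(m) for m in members])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(len(genes))
        for t, idx in enumerate(members):
            if term_mean(perm[idx]) >= observed[t]:
                exceed[t] += 1
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    if adjust == "bh":
        significant = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    elif adjust == "bonferroni":
        significant = pvals <= fdr / len(pvals)
    else:
        raise ValueError("adjust must be 'bh' or 'bonferroni'")

    onts = [annots.ontology_of(t) for t in terms]
    table = pd.DataFrame({
        "term": terms, "ontology": onts,
        "n_genes": [len(m) for m in members],
        "observed_mean": observed, "p_value": pvals, "significant": significant,
    })
    pct = {"overall": 100.0 * table.significant.mean()}
    for o in ONTOLOGIES:
        sub = table[table.ontology == o]
        if len(sub):
            pct[o] = 100.0 * sub.significant.mean()
    return ConsistencyResult(table, pct, n_perm, fdr)


def permutation_preserves_marginals(annots: AnnotationSet, genes: list[str],
                                    perm: np.ndarray) -> bool:
    """Check that relabeling genes keeps term sizes and per-gene counts."""
    before_term = {t: len(annots.term_genes(t) & set(genes))
                   for t in annots.dag.nodes}
    relabel = {genes[i]: genes[perm[i]] for i in range(len(genes))}
    after_term = {t: len({relabel.get(g, g) for g in annots.term_genes(t) & set(genes)})
                  for t in annots.dag.nodes}
    before_gene = sorted(len(annots.direct.get(g, ())) for g in genes)
    after_gene = sorted(len(annots.direct.get(genes[perm[i]], ())) for i in range(len(genes)))
    return before_term == after_term and before_gene == after_gene


# ---------------------------------------------------------------------------
# Semantic similarity
# ---------------------------------------------------------------------------

def semantic_similarity(gene1: str, gene2: str, annots: AnnotationSet,
                        params: SemSimParams = SemSimParams()) -> dict:
    """Information-content similarity ``ln(N_T / N_P)`` per ontology.

    ``N_P`` is the minimum propagated gene count over the terms annotating
    both genes within an ontology; ontologies where either gene is
    unannotated contribute nothing.  Returns per-ontology values, their
    maximum (0 when no ontology is shared), and an ``unannotated`` flag for
    genes lacking annotation in all three ontologies.
    """
    n_total = params.n_total or annots.n_annotated_genes
    per: dict[str, float | None] = {}
    for o in ONTOLOGIES:
        t1 = annots.closed_terms(gene1, o)
        t2 = annots.closed_terms(gene2, o)
        common = t1 & t2
        if not common:
            per[o] = None
            continue
        n_p = min(annots.term_size(t) for t in common)
        n_p = max(1, min(n_p, n_total))
        per[o] = math.log(n_total / n_p)
    vals = [v for v in per.values() if v is not None]
    annotated1 = any(annots.closed_terms(gene1, o) for o in ONTOLOGIES)
    annotated2 = any(annots.closed_terms(gene2, o) for o in ONTOLOGIES)
    per["max"] = max(vals) if vals else 0.0
    per["unannotated"] = not (annotated1 and annotated2)
    return per


def semantic_similarity_value(n_total: int, n_parent: int) -> float:
    """The bare formula ``ln(N_T / N_P)``."""
    if not 1 <= n_parent <= n_total:
        raise ValueError("require 1 <= N_P <= N_T")
    return math.log(n_total / n_parent)


def discordant_pairs(gdk: PairScoreTable, annots: AnnotationSet,
                     params: SemSimParams = SemSimParams(),
                     gdk_min: float = 50.0, sem_max: float = 2.0) -> pd.DataFrame:
    """Pairs with high diffusion-kernel score but low semantic similarity.

    ``gdk_min`` applies on the display scale (raw kernel values times the
    table's ``display_scale``); candidates are returned with per-gene
    unannotated flags for downstream curation.
    """
    scale = float(gdk.options.get("display_scale", 1.0e4))
    rows = []
    n = len(gdk.enzymes)
    disp = gdk.values * scale
    for i, j in itertools.combinations(range(n), 2):
        if not disp[i, j] >= gdk_min:
            continue
        a, b = gdk.enzymes[i], gdk.enzymes[j]
        sim = semantic_similarity(a, b, annots, params)
        if sim["max"] <= sem_max:
            rows.append({
                "enzyme_a": a, "enzyme_b": b,
                "gdk_display": disp[i, j], "semantic_similarity": sim["max"],
                "unannotated_a": not any(annots.closed_terms(a, o) for o in ONTOLOGIES),
                "unannotated_b": not any(annots.closed_terms(b, o) for o in ONTOLOGIES),
            })
    cols = ["enzyme_a", "enzyme_b", "gdk_display", "semantic_similarity",
            "unannotated_a", "unannotated_b"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("gdk_display", ascending=False).reset_index(drop=True)
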