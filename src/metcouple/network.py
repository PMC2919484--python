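"""Bipartite metabolite-enzyme networks from genome-scale metabolic reconstructions.

A compartmentalized stoichiometric model (metabolites x reactions matrix ``S``
plus a reaction-gene association matrix ``E``) is projected onto a bipartite
graph whose two vertex classes are metabolites and enzymes.  The integer edge
weight between enzyme ``e`` and metabolite ``m`` is the number of distinct
reactions that link them, ``M^T = S_hat E`` where ``S_hat`` is the binarized
``|S|``.  All coupling scores downstream operate on ``M`` or its binary form.

The module also implements the two standard topology manipulations used when
analysing such networks: collapsing compartment-duplicated metabolites (adding
the rows of ``S``) and removing high-degree "currency" hub metabolites such as
water and ATP.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("metcouple")

#: compartment tag at the end of a metabolite id: "atp[c]", "atp_c", "atp-c"
DEFAULT_COMPARTMENT_REGEX = r"^(?P<base>.+?)(?:\[(?P<tag1>[A-Za-z0-9]+)\]|_(?P<tag2>[A-Za-z0-9]{1,2}))$"


class SBMLParseError(ValueError):
    """Raised when an SBML file cannot be turned into a stoichiometric model."""


@dataclass
class StoichiometricModel:
    """Compartmentalized metabolic reconstruction.

    Attributes
    ----------
    metabolite_ids, reaction_ids, gene_ids:
        Unique identifier lists; row/column order of ``S`` and ``E``.
    S:
        Metabolites x reactions signed stoichiometric coefficients.
    E:
        Reactions x genes binary association; ``E[r, e] = 1`` when reaction
        ``r`` can be catalyzed by gene ``e`` (Boolean gene rules flattened).
    compartment_of:
        Metabolite id -> compartment label.
    participation:
        Optional metabolites x reactions binary matrix overriding ``|S| > 0``
        as the definition of "metabolite participates in reaction".  Set by
        :func:`merge_compartments` so that pure-transport reactions (whose net
        stoichiometry cancels after merging) keep their bipartite edges.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    gene_ids: list[str]
    S: np.ndarray
    E: np.ndarray
    compartment_of: dict[str, str]
    participation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.E = np.asarray(self.E, dtype=np.int8)
        nm, nr, ng = len(self.metabolite_ids), len(self.reaction_ids), len(self.gene_ids)
        if self.S.shape != (nm, nr):
            raise ValueError(f"S has shape {self.S.shape}, expected {(nm, nr)}")
        if self.E.shape != (nr, ng):
            raise ValueError(f"E has shape {self.E.shape}, expected {(nr, ng)}")
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids),
                          ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        if not np.isin(self.E, (0, 1)).all():
            raise ValueError("E entries must be 0/1")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def participation_matrix(self) -> np.ndarray:
        """Binary metabolites x reactions incidence (``S_hat``)."""
        if self.participation is not None:
            return (self.participation != 0).astype(np.int8)
        return (np.abs(self.S) > 0).astype(np.int8)


@dataclass
class BipartiteGraph:
    """Metabolite-enzyme bipartite graph.

    ``M`` is enzymes x metabolites with integer weights (number of distinct
    reactions linking the pair); ``met_degree`` is the number of reactions
    each metabolite participates in, as reactant or product.
    """

    metabolites: list[str]
    enzymes: list[str]
    M: np.ndarray
    met_degree: np.ndarray
    compartment_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.met_degree = np.asarray(self.met_degree, dtype=np.int64)
        if self.M.shape != (len(self.enzymes), len(self.metabolites)):
            raise ValueError("M shape does not match index sets")
        if len(self.met_degree) != len(self.metabolites):
            raise ValueError("met_degree length mismatch")
        if (self.met_degree < 1).any():
            raise ValueError("every retained metabolite must have degree >= 1")

    @property
    def M_hat(self) -> np.ndarray:
        """Binary form of ``M``."""
        return (self.M > 0).astype(np.int8)

    @property
    def n_edges_total(self) -> int:
        """Total number of metabolite-enzyme binary edges (``n_tot``)."""
        return int(np.count_nonzero(self.M))

    @property
    def enz_met_count(self) -> np.ndarray:
        """Number of distinct metabolites connected to each enzyme."""
        return self.M_hat.sum(axis=1).astype(np.int64)

    def metabolite_degree_table(self) -> "DegreeTable":
        return DegreeTable(dict(zip(self.metabolites, self.met_degree.tolist())))

    def enzyme_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.enzymes)}


@dataclass(frozen=True)
class DegreeTable:
    """Entity -> nonnegative integer degree, with quantile queries."""

    degrees: dict[str, int]

    def __post_init__(self) -> None:
        if any(d < 0 or int(d) != d for d in self.degrees.values()):
            raise ValueError("degrees must be nonnegative integers")

    def as_series(self) -> pd.Series:
        return pd.Series(self.degrees, dtype=int).sort_values(ascending=False)

    def quantile(self, q: float) -> float:
        """Empirical degree quantile; ``quantile(1.0)`` is the max degree."""
        vals = np.sort(np.fromiter(self.degrees.values(), dtype=float))
        return float(np.quantile(vals, q))


# ---------------------------------------------------------------------------
# SBML ingestion
# ---------------------------------------------------------------------------

def _boundary_species_ids(path: str) -> set[str]:
    # cobra keeps boundaryCondition="true" species; scan the raw XML for them.
    from lxml import etree

    flagged: set[str] = set()
    try:
        for _event, elem in etree.iterparse(str(path), events=("end",)):
            tag = etree.QName(elem.tag).localname
            if tag == "species" and elem.get("boundaryCondition", "false") in ("true", "1"):
                sid = elem.get("id")
                if sid:
                    flagged.add(sid)
                    if sid.startswith("M_"):
                        flagged.add(sid[2:])
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"unreadable SBML file {path!r}: {exc}") from exc
    return flagged


def load_sbml(path: str) -> StoichiometricModel:
    """Read an SBML reconstruction into a :class:`StoichiometricModel`.

    Gene associations (COBRA-style ``GENE_ASSOCIATION`` notes or SBML-fbc
    gene products) are flattened: ``E[r, e] = 1`` whenever gene ``e`` appears
    anywhere in the Boolean rule of reaction ``r``.  Species flagged
    ``boundaryCondition=true`` are excluded, as are reactions left without
    any metabolite (typically auto-generated boundary exchanges).
    """
    import cobra.io

    boundary = _boundary_species_ids(path)
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of types
        raise SBMLParseError(f"unreadable SBML file {path!r}: {exc}") from exc

    met_ids = [m.id for m in cmodel.metabolites if m.id not in boundary]
    met_index = {m: i for i, m in enumerate(met_ids)}
    compartment_of = {m.id: (m.compartment or "") for m in cmodel.metabolites
                      if m.id in met_index}

    reactions, rxn_ids = [], []
    for rxn in cmodel.reactions:
        stoich = {met_index[m.id]: c for m, c in rxn.metabolites.items()
                  if m.id in met_index}
        if not stoich:
            continue  # boundary-only exchange
        reactions.append((stoich, sorted(g.id for g in rxn.genes)))
        rxn_ids.append(rxn.id)

    gene_ids = sorted({g for _, genes in reactions for g in genes})
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    S = np.zeros((len(met_ids), len(reactions)))
    E = np.zeros((len(reactions), len(gene_ids)), dtype=np.int8)
    for j, (stoich, genes) in enumerate(reactions):
        for i, c in stoich.items():
            S[i, j] += c
        if not genes:
            logger.warning("reaction %s has no parseable gene association", rxn_ids[j])
        for g in genes:
            E[j, gene_index[g]] = 1

    return StoichiometricModel(met_ids, rxn_ids, gene_ids, S, E, compartment_of)


# ---------------------------------------------------------------------------
# Graph construction and topology manipulations
# ---------------------------------------------------------------------------

def build_bipartite(model: StoichiometricModel) -> BipartiteGraph:
    """Project a stoichiometric model onto the metabolite-enzyme graph.

    ``M^T = S_hat E``; metabolites with zero degree and genes with no edges
    are dropped from the index sets.  Reactants and products both count and
    reaction direction is ignored.
    """
    if model.n_metabolites == 0 or model.n_reactions == 0 or model.n_genes == 0:
        raise ValueError("cannot build a bipartite graph from an empty model")
    S_hat = model.participation_matrix()
    met_degree = S_hat.sum(axis=1)
    M = (S_hat @ model.E).T.astype(np.int64)  # enzymes x metabolites

    keep_m = np.flatnonzero(met_degree > 0)
    keep_e = np.flatnonzero(M.sum(axis=1) > 0)
    metabolites = [model.metabolite_ids[i] for i in keep_m]
    enzymes = [model.gene_ids[i] for i in keep_e]
    comp = {m: model.compartment_of.get(m, "") for m in metabolites}
    return BipartiteGraph(metabolites, enzymes,
                          M[np.ix_(keep_e, keep_m)], met_degree[keep_m], comp)


def split_compartment_tag(met_id: str,
                          regex: str = DEFAULT_COMPARTMENT_REGEX,
                          known_tags: set[str] | None = None) -> tuple[str, str]:
    """Split ``"atp[c]"`` / ``"atp_c"`` into ``("atp", "c")``.

    Ids without a recognizable tag are their own base id with an empty tag.
    """
    m = re.match(regex, met_id)
    if m:
        tag = m.group("tag1") or m.group("tag2")
        if tag and (known_tags is None or tag in known_tags):
            return m.group("base"), tag
    return met_id, ""


def merge_compartments(model: StoichiometricModel,
                       regex: str = DEFAULT_COMPARTMENT_REGEX) -> StoichiometricModel:
    """Collapse compartment-duplicated metabolites by adding rows of ``S``.

    Metabolites with the same base id (compartment tag stripped) become one
    row.  Binary participation is merged by OR, so a transport reaction
    ``A[e] -> A[c]`` whose net stoichiometry cancels still links its gene to
    the merged metabolite ``A``.
    """
    known = set(model.compartment_of.values()) - {""} or None
    bases: list[str] = []
    base_index: dict[str, int] = {}
    row_of = np.empty(model.n_metabolites, dtype=int)
    for i, mid in enumerate(model.metabolite_ids):
        base, tag = split_compartment_tag(mid, regex, known)
        if not tag and model.compartment_of.get(mid):
            logger.info("metabolite %r has no parseable compartment tag; kept as-is", mid)
        if base not in base_index:
            base_index[base] = len(bases)
            bases.append(base)
        row_of[i] = base_index[base]

    S = np.zeros((len(bases), model.n_reactions))
    P = np.zeros((len(bases), model.n_reactions), dtype=np.int8)
    old_part = model.participation_matrix()
    for i in range(model.n_metabolites):
        S[row_of[i]] += model.S[i]
        P[row_of[i]] |= old_part[i]
    comp = {b: "" for b in bases}
    return StoichiometricModel(bases, list(model.reaction_ids), list(model.gene_ids),
                               S, model.E.copy(), comp, participation=P)


def hub_cutoff_degree(met_degree: np.ndarray, top_fraction: float) -> int:
    """Degree cutoff for the top ``top_fraction`` of metabolites by degree.

    The cutoff is the degree at rank ``floor(top_fraction * n)`` of the
    descending degree sort; all metabolites at that degree are included.
    """
    n = len(met_degree)
    k = int(np.floor(top_fraction * n))
    if k < 1:
        return int(met_degree.max()) + 1
    return int(np.sort(met_degree)[::-1][k - 1])


def remove_hub_metabolites(graph: BipartiteGraph,
                           top_fraction: float | None = None,
                           min_degree: int | None = None,
                           ) -> tuple[BipartiteGraph, pd.DataFrame]:
    """Remove high-degree (currency) metabolites from the graph.

    Exactly one of ``top_fraction`` / ``min_degree`` must be given; with
    ``top_fraction`` the degree cutoff includes every metabolite tied at the
    cutoff degree.  Returns the filtered graph and the removal list, in
    decreasing degree order.
    """
    if (top_fraction is None) == (min_degree is None):
        raise ValueError("give exactly one of top_fraction / min_degree")
    if top_fraction is not None:
        min_degree = hub_cutoff_degree(graph.met_degree, top_fraction)
    removed_mask = graph.met_degree >= min_degree
    if removed_mask.all():
        raise ValueError(f"cutoff degree {min_degree} would remove every metabolite")
    removed = pd.DataFrame({
        "metabolite": [graph.metabolites[i] for i in np.flatnonzero(removed_mask)],
        "degree": graph.met_degree[removed_mask],
    }).sort_values(["degree", "metabolite"], ascending=[False, True]).reset_index(drop=True)

    keep = np.flatnonzero(~removed_mask)
    M = graph.M[:, keep]
    keep_e = np.flatnonzero(M.sum(axis=1) > 0)
    sub = BipartiteGraph(
        [graph.metabolites[i] for i in keep],
        [graph.enzymes[i] for i in keep_e],
        M[keep_e], graph.met_degree[keep],
        {graph.metabolites[i]: graph.compartment_of.get(graph.metabolites[i], "")
         for i in keep},
    )
    return sub, removed


def graph_summary(graph: BipartiteGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolite and enzyme summary tables (id, compartment, degree / count)."""
    mets = pd.DataFrame({
        "metabolite": graph.metabolites,
        "compartment": [graph.compartment_of.get(m, "") for m in graph.metabolites],
        "degree": graph.met_degree,
    })
    enz = pd.DataFrame({"enzyme": graph.enzymes, "n_metabolites": graph.enz_met_count})
    return mets, enz


def write_graph_summary(graph: BipartiteGraph, met_path: str, enz_path: str) -> None:
    mets, enz = graph_summary(graph)
    mets.to_csv(met_path, sep="\t", index=False)
    enz.to_csv(enz_path, sep="\t", index=False)
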