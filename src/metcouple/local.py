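"""Shared-metabolite coupling scores for enzyme pairs.

All local scores are functions of the pair context: the graph-wide counts
``n`` (metabolites) and ``n_tot`` (metabolite-enzyme edges), the enzyme
neighbourhood sizes ``n1``, ``n2``, the shared-metabolite count ``n12``, and
(for the degree-corrected variants) the reaction degrees of the metabolites
in each neighbourhood.

Scores
------
``shared``            raw shared-metabolite count ``n12`` (matrix form
                      ``M_hat M_hat^T``)
``shared_nohub``      the same after removing high-degree metabolites
``hypergeom``         -log upper-tail hypergeometric probability of ``n12``
``bayes``             log likelihood ratio from a 2x2 contingency model,
                      folded to one-sided enrichment
``poisson``           Poisson log likelihood ratio with a flat null
                      ``lambda = n1 n2 / n_tot``
``poisson_metdeg``    Poisson score with the null rate corrected by the
                      degrees of the metabolites in each neighbourhood
``poisson_metassoc``  Poisson score whose null rate comes from a sequential
                      connection model over the neighbourhood metabolites

The Poisson family uses the convention ``0 * log 0 = 0`` and an
absolute-value penalty so that large scores signal enrichment, never
depletion, of shared metabolites.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .network import BipartiteGraph, remove_hub_metabolites

LOCAL_METHODS = ("shared", "shared_nohub", "hypergeom", "bayes",
                 "poisson", "poisson_metdeg", "poisson_metassoc")


@dataclass
class PairContext:
    """Counts describing one enzyme pair within a bipartite graph."""

    n: int          # total metabolites in the graph
    n_tot: int      # total metabolite-enzyme binary edges
    n1: int         # metabolites connected to enzyme 1
    n2: int         # metabolites connected to enzyme 2
    n12: int        # metabolites connected to both
    k_list1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    k_list2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.k_list1 = np.asarray(self.k_list1, dtype=int)
        self.k_list2 = np.asarray(self.k_list2, dtype=int)
        if not (0 <= self.n12 <= min(self.n1, self.n2) <= self.n):
            raise ValueError("require 0 <= n12 <= min(n1, n2) <= n")
        for k_list, n_i in ((self.k_list1, self.n1), (self.k_list2, self.n2)):
            if k_list.size and (len(k_list) != n_i or (k_list < 1).any()):
                raise ValueError("k_list length must equal n_i with every degree >= 1")


def _log_binom(a, b):
    """log C(a, b) by continuous log-gamma extension (valid for real a, b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def shared_count(ctx: PairContext) -> int:
    """Raw number of shared metabolites."""
    return int(ctx.n12)


def hypergeometric_score(ctx: PairContext) -> float:
    """-log upper-tail hypergeometric probability of sharing >= n12 metabolites.

    Computed in log space with log-gamma terms, so scores remain finite far
    into the tail where the probability underflows a double.
    """
    n, n1, n2, n12 = ctx.n, ctx.n1, ctx.n2, ctx.n12
    if n12 > min(n1, n2):
        raise ValueError("impossible configuration: n12 > min(n1, n2)")
    if n12 == 0:
        return 0.0
    ks = np.arange(n12, min(n1, n2) + 1)
    log_terms = _log_binom(n1, ks) + _log_binom(n - n1, n2 - ks) - _log_binom(n, n2)
    # C(n-n1, n2-k) is zero when n2-k > n-n1
    log_terms = log_terms[n2 - ks <= n - n1]
    if log_terms.size == 0:
        raise ValueError("impossible configuration: empty hypergeometric support")
    return float(-logsumexp(log_terms))


def _bayes_raw(n: int, n1: int, n2: int, x: float) -> float:
    return float(np.log(n + 1.0) + _log_binom(n, n2)
                 - np.log((n + 2.0) * (n + 3.0)) - _log_binom(n1, x)
                 - _log_binom(n - n1, n2 - x))


def bayes_score(ctx: PairContext) -> float:
    """Contingency-table log likelihood ratio, folded to enrichment.

    The raw score grows when ``n12`` deviates from the null expectation
    ``n1 n2 / n`` in either direction; below the null mean the score is
    reflected (``s(n12) - |s(n12) - s(n1 n2 / n)|``) so only enrichment
    ranks high.  The reflection point is generally non-integer, handled by
    the continuous log-gamma extension of the binomial coefficient.
    """
    n, n1, n2, n12 = ctx.n, ctx.n1, ctx.n2, ctx.n12
    if n2 - n12 > n - n1:
        raise ValueError("impossible contingency table: n2 - n12 > n - n1")
    s = _bayes_raw(n, n1, n2, n12)
    null_mean = n1 * n2 / n
    if n12 < null_mean:
        s_null = _bayes_raw(n, n1, n2, null_mean)
        s = s - abs(s - s_null)
    return s


def _poisson_llr(n12: float, lam: float) -> float:
    """``n12 log(n12/lam) - |n12 - lam|`` with ``0 log 0 = 0``."""
    if lam <= 0:
        return 0.0 if n12 == 0 else float("inf")
    term = 0.0 if n12 == 0 else n12 * np.log(n12 / lam)
    return float(term - abs(n12 - lam))


def poisson_score(ctx: PairContext) -> float:
    """Poisson log likelihood ratio with the flat null ``lambda = n1 n2 / n_tot``."""
    if ctx.n_tot <= 0:
        raise ValueError("n_tot must be positive")
    return _poisson_llr(ctx.n12, ctx.n1 * ctx.n2 / ctx.n_tot)


def degree_corrected_rate(k_list: np.ndarray, n_other: int, n_tot: int) -> float:
    """Expected number of one enzyme's metabolites also linked to the other.

    Each metabolite of degree ``k`` connects to an enzyme of neighbourhood
    size ``n_other`` with probability ``1 - exp(-k n_other / n_tot)`` under
    the degree-corrected random-attachment null; the rate is the sum over
    the neighbourhood.
    """
    k = np.asarray(k_list, dtype=float)
    return float(np.sum(1.0 - np.exp(-k * n_other / n_tot)))


def poisson_score_metdeg(ctx: PairContext) -> float:
    """Poisson score with the metabolite-degree-corrected null rate.

    ``lambda_null`` is the arithmetic mean of the two directional rates
    computed by :func:`degree_corrected_rate`; high-degree metabolites are
    expected to be shared and therefore contribute little evidence.
    """
    lam12 = degree_corrected_rate(ctx.k_list1, ctx.n2, ctx.n_tot)
    lam21 = degree_corrected_rate(ctx.k_list2, ctx.n1, ctx.n_tot)
    return _poisson_llr(ctx.n12, 0.5 * (lam12 + lam21))


def metassoc_distribution(k_list: np.ndarray, n_other: int, n_tot: int,
                          k_max: int | None = None) -> np.ndarray:
    """Null distribution of the shared count from the sequential model.

    Processes the neighbourhood metabolites one at a time (ascending degree,
    for bit-reproducibility); the probability that the partner enzyme is
    connected to the next metabolite depends on how many connections ``k``
    it has already made:

    ``P(connect | k-1) = 1 - exp(-k_i (n_other - k + 1) / n_tot)``
    ``P(miss    | k)   = exp(-k_i (n_other - k) / n_tot)``

    with base cases ``P(k=-1 | .) = 0`` and ``P(k=0 | -) = 1``.
    """
    k_list = np.sort(np.asarray(k_list, dtype=float))
    if k_max is None:
        k_max = min(len(k_list), n_other)
    P = np.zeros(k_max + 1)
    P[0] = 1.0
    ks = np.arange(k_max + 1, dtype=float)
    rate = np.maximum(n_other - ks, 0.0)  # n_E - k, also n_E - (k-1) one step later
    for ki in k_list:
        p_miss = np.exp(-ki * rate / n_tot)       # P(miss | k existing)
        p_conn = 1.0 - p_miss                     # P(connect | k existing)
        new = P * p_miss
        new[1:] += P[:-1] * p_conn[:-1]
        P = new
    if (P < -1e-12).any() or (P > 1 + 1e-9).any():
        raise ArithmeticError("sequential-model probabilities left [0, 1]; bad inputs")
    return P


def poisson_score_metassoc(ctx: PairContext) -> float:
    """Poisson score with the null rate from the sequential connection model.

    The null rate is the mean of the expected shared counts computed from
    each enzyme's neighbourhood distribution (truncated at ``min(n1, n2)``).
    """
    k_max = min(ctx.n1, ctx.n2)
    pa = metassoc_distribution(ctx.k_list1, ctx.n2, ctx.n_tot, k_max)
    pb = metassoc_distribution(ctx.k_list2, ctx.n1, ctx.n_tot, k_max)
    ks = np.arange(k_max + 1, dtype=float)
    lam = 0.5 * float(ks @ pa) + 0.5 * float(ks @ pb)
    return _poisson_llr(ctx.n12, lam)


_SCALAR_SCORERS = {
    "shared": shared_count,
    "hypergeom": hypergeometric_score,
    "bayes": bayes_score,
    "poisson": poisson_score,
    "poisson_metdeg": poisson_score_metdeg,
    "poisson_metassoc": poisson_score_metassoc,
}


# ---------------------------------------------------------------------------
# Pair score tables
# ---------------------------------------------------------------------------

@dataclass
class PairScoreTable:
    """Symmetric enzyme-pair -> score map for one scoring method.

    ``values`` is a symmetric enzymes x enzymes matrix with ``nan`` on the
    diagonal; ``covered`` marks pairs the method could score from direct
    structure (for local methods, pairs sharing at least one metabolite).
    Structurally-unscored pairs carry the method's exact ``n12 = 0`` value so
    every ranking is total.
    """

    method: str
    enzymes: list[str]
    values: np.ndarray
    covered: np.ndarray | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.enzymes)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over the enzyme set")
        if self.covered is None:
            self.covered = ~np.eye(n, dtype=bool)
        np.fill_diagonal(self.values, np.nan)

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    def score(self, a: str, b: str) -> float:
        idx = {e: i for i, e in enumerate(self.enzymes)}
        if a == b:
            raise ValueError("self-pairs are not scored")
        return float(self.values[idx[a], idx[b]])

    def pair_series(self) -> pd.Series:
        """Scores as a Series indexed by lexicographically ordered pairs."""
        order = np.argsort(np.asarray(self.enzymes, dtype=object))
        names = [self.enzymes[i] for i in order]
        iu = np.triu_indices(len(names), k=1)
        vals = self.values[np.ix_(order, order)][iu]
        idx = pd.MultiIndex.from_arrays(
            [np.asarray(names, dtype=object)[iu[0]],
             np.asarray(names, dtype=object)[iu[1]]],
            names=["enzyme_a", "enzyme_b"])
        return pd.Series(vals, index=idx, name=self.method)

    def reindex(self, enzymes: list[str], fill_value: float) -> "PairScoreTable":
        """Re-express the table over a new enzyme universe.

        Pairs involving enzymes absent from this table get ``fill_value``
        and are marked uncovered.
        """
        n = len(enzymes)
        vals = np.full((n, n), fill_value)
        cov = np.zeros((n, n), dtype=bool)
        old = {e: i for i, e in enumerate(self.enzymes)}
        present = [(j, old[e]) for j, e in enumerate(enzymes) if e in old]
        if present:
            new_idx, old_idx = map(np.array, zip(*present))
            vals[np.ix_(new_idx, new_idx)] = self.values[np.ix_(old_idx, old_idx)]
            cov[np.ix_(new_idx, new_idx)] = self.covered[np.ix_(old_idx, old_idx)]
        return PairScoreTable(self.method, list(enzymes), vals, cov, dict(self.options))

    def to_tsv(self, path: str, sidecar: str | None = None) -> None:
        ser = self.pair_series()
        df = ser.reset_index()
        df.columns = ["enzyme_a", "enzyme_b", "score"]
        with open(path, "w") as fh:
            fh.write(f"# method={self.method}\n")
            df.to_csv(fh, sep="\t", index=False)
        if sidecar:
            with open(sidecar, "w") as fh:
                json.dump({"method": self.method, "options": self.options}, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str) -> "PairScoreTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        enzymes = sorted(set(df["enzyme_a"]) | set(df["enzyme_b"]))
        idx = {e: i for i, e in enumerate(enzymes)}
        vals = np.full((len(enzymes),) * 2, np.nan)
        for a, b, s in df.itertuples(index=False):
            vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = s
        method = "unknown"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# method="):
                method = first.strip().split("=", 1)[1]
        return cls(method, enzymes, vals)


def pair_context(graph: BipartiteGraph, i: int, j: int) -> PairContext:
    """Build the :class:`PairContext` for enzymes at rows ``i`` and ``j``."""
    Mi, Mj = graph.M_hat[i] > 0, graph.M_hat[j] > 0
    return PairContext(
        n=len(graph.metabolites), n_tot=graph.n_edges_total,
        n1=int(Mi.sum()), n2=int(Mj.sum()), n12=int((Mi & Mj).sum()),
        k_list1=graph.met_degree[Mi], k_list2=graph.met_degree[Mj])


def score_all_pairs(graph: BipartiteGraph, method: str, **options) -> PairScoreTable:
    """Score every enzyme pair of the graph with the chosen local method.

    ``shared_nohub`` removes hub metabolites first (``hub_top_fraction``,
    default 0.05, or ``hub_min_degree``) and re-expresses the result over the
    original enzyme universe with 0 for enzymes that lost all edges.
    """
    if method not in LOCAL_METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(LOCAL_METHODS)}")

    if method == "shared_nohub":
        frac = options.get("hub_top_fraction")
        mindeg = options.get("hub_min_degree")
        if frac is None and mindeg is None:
            frac = 0.05
        sub, removed = remove_hub_metabolites(graph, top_fraction=frac, min_degree=mindeg)
        tab = score_all_pairs(sub, "shared")
        out = tab.reindex(graph.enzymes, fill_value=0.0)
        out.method = "shared_nohub"
        out.options = {"hub_top_fraction": frac, "hub_min_degree": mindeg,
                       "n_hubs_removed": len(removed)}
        return out

    Mh = graph.M_hat.astype(np.int64)
    C = Mh @ Mh.T                       # shared counts n12
    n_vec = Mh.sum(axis=1)              # n_i per enzyme
    n = len(graph.metabolites)
    n_tot = graph.n_edges_total
    n_enz = len(graph.enzymes)
    covered = C > 0
    np.fill_diagonal(covered, False)

    if method == "shared":
        vals = C.astype(float)
    elif method == "poisson":
        lam = np.outer(n_vec, n_vec) / n_tot
        vals = _poisson_matrix(C, lam)
    elif method == "poisson_metdeg":
        # L[i, j] = sum_{m in N(i)} 1 - exp(-k_m * n_j / n_tot)
        expo = np.exp(-np.outer(graph.met_degree, n_vec / n_tot))  # mets x enz
        L = Mh @ (1.0 - expo)                                      # enz x enz
        vals = _poisson_matrix(C, 0.5 * (L + L.T))
    elif method in ("hypergeom", "bayes", "poisson_metassoc"):
        scorer = _SCALAR_SCORERS[method]
        vals = np.zeros((n_enz, n_enz))
        for i, j in itertools.combinations(range(n_enz), 2):
            ctx = PairContext(n=n, n_tot=n_tot, n1=int(n_vec[i]), n2=int(n_vec[j]),
                              n12=int(C[i, j]),
                              k_list1=graph.met_degree[Mh[i] > 0],
                              k_list2=graph.met_degree[Mh[j] > 0])
            vals[i, j] = vals[j, i] = scorer(ctx)
    else:  # pragma: no cover
        raise AssertionError(method)

    return PairScoreTable(method, list(graph.enzymes), vals.astype(float),
                          covered, dict(options))


def _poisson_matrix(C: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Vectorized ``n12 log(n12/lam) - |n12 - lam|`` with ``0 log 0 = 0``."""
    C = C.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(C > 0, C * np.log(np.where(C > 0, C, 1.0) / lam), 0.0)
    return term - np.abs(C - lam)
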