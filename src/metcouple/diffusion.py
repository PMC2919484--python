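"""Graph diffusion kernel scores on the bipartite metabolite-enzyme graph.

The kernel sums contributions of random walks of every length between node
pairs, with a d-step walk discounted by ``e^(-gamma d)``:

    K = [(1 + gamma) I - D^(-1/2) A D^(-1/2)]^(-1)

where ``A`` is the block bipartite adjacency (no metabolite-metabolite or
enzyme-enzyme edges) and ``D`` its diagonal degree matrix.  The degree
normalization down-weights walks through high-degree hub metabolites, which
is what makes the kernel robust to currency metabolites without any hub
threshold.  Enzyme-enzyme entries of ``K`` are the global coupling scores;
for display they are conventionally multiplied by 10^4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .local import PairScoreTable
from .network import BipartiteGraph

DISPLAY_SCALE = 1.0e4
#: above this node count the dense inverse is replaced by a columnwise solve
DENSE_LIMIT = 5000


@dataclass
class KernelSpec:
    """Adjacency, degrees, and (once computed) the diffusion kernel.

    Node order is metabolites first, then enzymes; ``node_ids`` records the
    retained ids after zero-degree nodes are dropped.
    """

    node_ids: list[str]
    n_met: int
    n_enz: int
    A: np.ndarray
    degrees: np.ndarray
    weighted: bool = False
    gamma: float | None = None
    K: np.ndarray | None = None
    display_scale: float = DISPLAY_SCALE
    options: dict = field(default_factory=dict)

    @property
    def enzymes(self) -> list[str]:
        return self.node_ids[self.n_met:]

    @property
    def metabolites(self) -> list[str]:
        return self.node_ids[:self.n_met]


def build_adjacency(graph: BipartiteGraph, weighted: bool = False) -> KernelSpec:
    """Assemble the block adjacency from ``M_hat`` (or ``M`` when weighted).

    Zero-degree nodes are removed before the degree matrix is formed
    (``D^(-1/2)`` is undefined for them and isolated nodes carry no
    diffusion signal); an id map is retained through ``node_ids``.
    """
    if not graph.enzymes or not graph.metabolites:
        raise ValueError("graph is empty")
    B = (graph.M if weighted else graph.M_hat).astype(float)  # enz x met
    keep_e = np.flatnonzero(B.sum(axis=1) > 0)
    keep_m = np.flatnonzero(B.sum(axis=0) > 0)
    B = B[np.ix_(keep_e, keep_m)]
    n_m, n_e = len(keep_m), len(keep_e)
    A = np.zeros((n_m + n_e, n_m + n_e))
    A[:n_m, n_m:] = B.T
    A[n_m:, :n_m] = B
    node_ids = ([graph.metabolites[i] for i in keep_m]
                + [graph.enzymes[i] for i in keep_e])
    return KernelSpec(node_ids, n_m, n_e, A, A.sum(axis=1), weighted=weighted)


def normalized_adjacency(spec: KernelSpec) -> np.ndarray:
    d_inv_sqrt = 1.0 / np.sqrt(spec.degrees)
    return spec.A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def diffusion_kernel(spec: KernelSpec, gamma: float = 1.0) -> KernelSpec:
    """Compute ``K = [(1+gamma) I - D^(-1/2) A D^(-1/2)]^(-1)``.

    The spectral radius of the normalized adjacency is at most 1, so the
    system is positive definite for every ``gamma > 0``; a Cholesky
    factorization both certifies this and solves the system.  ``K`` is
    symmetrized after inversion (the analytic inverse is symmetric; the
    numerical one is symmetric to ~1e-10).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    N = normalized_adjacency(spec)
    L = (1.0 + gamma) * np.eye(N.shape[0]) - N
    try:
        if N.shape[0] <= DENSE_LIMIT:
            c, low = scipy.linalg.cho_factor(L)
            K = scipy.linalg.cho_solve((c, low), np.eye(N.shape[0]))
        else:
            # columnwise solve against the enzyme block only
            cols = np.zeros((N.shape[0], spec.n_enz))
            cols[spec.n_met:, :] = np.eye(spec.n_enz)
            c, low = scipy.linalg.cho_factor(L)
            K_cols = scipy.linalg.cho_solve((c, low), cols)
            K = np.full((N.shape[0], N.shape[0]), np.nan)
            K[:, spec.n_met:] = K_cols
            K[spec.n_met:, :] = K_cols.T
    except np.linalg.LinAlgError as exc:
        raise ValueError("diffusion system not positive definite; "
                         "adjacency is malformed") from exc
    asym = np.nanmax(np.abs(K - K.T))
    if asym > 1e-8:
        raise ValueError(f"kernel asymmetry {asym:.2e} exceeds tolerance")
    K = 0.5 * (K + K.T)
    spec.gamma = gamma
    spec.K = K
    return spec


def kernel_series(spec: KernelSpec, gamma: float, n_terms: int = 200) -> np.ndarray:
    """Truncated walk-sum form ``sum_d (1+gamma)^-(d+1) N^d`` of the kernel.

    Independent of the inverse-based route; used as a cross-check.
    """
    N = normalized_adjacency(spec)
    term = np.eye(N.shape[0]) / (1.0 + gamma)
    total = term.copy()
    for _ in range(1, n_terms):
        term = term @ N / (1.0 + gamma)
        total += term
    return total


def enzyme_kernel_scores(spec: KernelSpec) -> PairScoreTable:
    """Extract the enzyme-enzyme block of the kernel as a pair score table.

    Raw kernel values are stored (rankings are invariant to the display
    scale); ``display_scale`` rides along in the options for reporting.
    """
    if spec.K is None:
        raise ValueError("kernel not computed; call diffusion_kernel first")
    block = spec.K[spec.n_met:, spec.n_met:].copy()
    method = "gdk_weighted" if spec.weighted else "gdk"
    return PairScoreTable(method, list(spec.enzymes), block,
                          options={"gamma": spec.gamma,
                                   "display_scale": spec.display_scale,
                                   "weighted": spec.weighted})


def gdk_scores(graph: BipartiteGraph, gamma: float = 1.0,
               weighted: bool = False) -> PairScoreTable:
    """Convenience route: adjacency -> kernel -> enzyme pair table.

    Enzymes dropped as zero-degree are restored with score 0 so the table
    covers the full enzyme universe of the graph.
    """
    spec = diffusion_kernel(build_adjacency(graph, weighted=weighted), gamma)
    tab = enzyme_kernel_scores(spec)
    if len(tab.enzymes) != len(graph.enzymes):
        tab = tab.reindex(list(graph.enzymes), fill_value=0.0)
    return tab
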