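"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import metcouple as mc


@pytest.fixture(scope="session")
def small_spec() -> mc.SyntheticSpec:
    """A compact synthetic study system used across modules."""
    return mc.SyntheticSpec(n_enzymes=60, n_metabolites=150, n_hubs=3,
                            hub_degree=30, n_modules=5, module_size=6,
                            mets_per_module=5, seed=11)


@pytest.fixture(scope="session")
def small_model(small_spec) -> mc.StoichiometricModel:
    return mc.generate_network(small_spec)


@pytest.fixture(scope="session")
def small_graph(small_model) -> mc.BipartiteGraph:
    return mc.build_bipartite(small_model)


@pytest.fixture(scope="session")
def small_interactions(small_model, small_spec) -> mc.InteractionTable:
    return mc.generate_interactions(small_model, small_spec)


@pytest.fixture(scope="session")
def small_annotations(small_model, small_spec) -> mc.AnnotationSet:
    return mc.generate_annotations(small_model, small_spec)


@pytest.fixture(scope="session")
def small_benchmark(small_interactions, small_model) -> mc.InteractionBenchmark:
    return mc.build_benchmark(small_interactions, set(small_model.gene_ids))


def toy_graph(M: np.ndarray, met_degree=None) -> mc.BipartiteGraph:
    """Graph from an explicit enzymes x metabolites weight matrix.

    Unless given, metabolite reaction-degrees are taken as the column sums
    of M (each enzyme-metabolite incidence counted once per reaction).
    """
    M = np.asarray(M)
    n_e, n_m = M.shape
    if met_degree is None:
        met_degree = M.sum(axis=0)
    return mc.BipartiteGraph(
        metabolites=[f"m{i}" for i in range(n_m)],
        enzymes=[f"e{i}" for i in range(n_e)],
        M=M, met_degree=np.asarray(met_degree))
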