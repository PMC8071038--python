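"""Shared fixtures: small synthetic cohorts and a weighted-graph library."""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pytest

from brainwcn import schema as sc
from brainwcn import synth


def small_schema():
    """~67 base features: the smallest schema whose 15%-density network
    stays connected for cohorts of a few dozen subjects."""
    return synth.make_schema(
        cortical_regions=synth.CORTICAL_REGIONS[:6],
        cortical_suffixes=("volume", "area", "thickness", "meancurv"),
        subcortical_bilateral=synth.SUBCORTICAL_BILATERAL[:4],
        subcortical_other=synth.SUBCORTICAL_OTHER[:3])


def medium_schema():
    """6 regions x all 6 cortical measures (~91 base features)."""
    return synth.make_schema(
        cortical_regions=synth.CORTICAL_REGIONS[:6],
        subcortical_bilateral=synth.SUBCORTICAL_BILATERAL[:4],
        subcortical_other=synth.SUBCORTICAL_OTHER[:3])


@pytest.fixture(scope="session")
def cohort():
    """Null two-group cohort on the small schema (40 case / 60 control)."""
    cfg = synth.SynthConfig(n_case=40, n_control=60, schema=small_schema(),
                            seed=7)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared(cohort):
    """Normalized + augmented table and the per-group subtables."""
    table, pheno = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepped = sc.augment_lr(sc.normalize_features(table))
    by_group = {
        grp: prepped.select_subjects(
            list(pheno.loc[pheno.group == grp, "subject_id"]))
        for grp in ("case", "control")}
    return prepped, by_group, pheno


def _weighted(graph, seed):
    rng = np.random.default_rng(seed)
    A = nx.to_numpy_array(graph, weight=None)
    n = A.shape[0]
    W = np.zeros_like(A)
    iu = np.triu_indices(n, k=1)
    w = rng.uniform(0.4, 1.0, size=len(iu[0]))
    W[iu] = w
    W = W + W.T
    W *= A
    return A, W


def graph_library():
    """Connected graphs with <= 7 nodes and seeded random weights."""
    graphs = {
        "path4": nx.path_graph(4),
        "triangle": nx.complete_graph(3),
        "star5": nx.star_graph(4),
        "complete5": nx.complete_graph(5),
        "cycle6": nx.cycle_graph(6),
        "lollipop": nx.lollipop_graph(4, 3),
        "bridge": nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3), (3, 4),
                            (4, 5), (5, 3)]),
    }
    rng = np.random.default_rng(42)
    for k in range(3):
        while True:
            g = nx.gnp_random_graph(7, 0.45, seed=int(rng.integers(1e6)))
            if nx.is_connected(g):
                graphs[f"random7_{k}"] = g
                break
    return {name: _weighted(g, seed=hash(name) % (2 ** 31))
            for name, g in graphs.items()}


@pytest.fixture(scope="session")
def graphs():
    return graph_library()
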