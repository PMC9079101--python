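"""Shared fixtures and independent oracles.

The oracles here are deliberately naive — exhaustive path enumeration for
betweenness, triple-loop voxel counting for region overlap — so they share
no code path with the implementations they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest


def brute_force_betweenness(graph: nx.Graph, weighted: bool = False) -> dict:
    """Exhaustive-path betweenness: enumerate every simple path between every
    unordered pair, keep the minimal-length ones, credit interior nodes
    fractionally. Endpoints excluded; unreachable pairs contribute nothing.

    Edge length is 1/weight when ``weighted`` (matching the package's
    tractography convention), else 1 per edge.
    """
    bc = {v: 0.0 for v in graph.nodes}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_simple_paths(graph, s, t))
        if weighted:
            lengths = [
                sum(1.0 / graph[u][v]["weight"] for u, v in zip(p, p[1:])) for p in paths
            ]
        else:
            lengths = [len(p) - 1 for p in paths]
        best = min(lengths)
        tol = 1e-12 * max(1.0, abs(best))
        shortest = [p for p, l in zip(paths, lengths) if l - best <= tol]
        credit = 1.0 / len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += credit
    return bc


def overlap_oracle(lesion: np.ndarray, parcellation: np.ndarray) -> dict:
    """Triple-loop voxel counting of per-region lesioned proportions."""
    hit: dict = {}
    total: dict = {}
    ni, nj, nk = parcellation.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                lab = int(parcellation[i, j, k])
                if lab > 0:
                    total[lab] = total.get(lab, 0) + 1
                    if lesion[i, j, k]:
                        hit[lab] = hit.get(lab, 0) + 1
    return {lab: hit.get(lab, 0) / total[lab] for lab in total}


def random_connected_graph(rng: np.random.Generator, n: int, p: float, weighted: bool) -> nx.Graph:
    """Erdos-Renyi draw forced connected by chaining components."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    for c1, c2 in zip(comps, comps[1:]):
        g.add_edge(c1[0], c2[0])
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.2, 3.0)) if weighted else 1.0
    return g


def toy_parcellation(shape=(10, 10, 10)) -> np.ndarray:
    """Four cuboid regions stacked along the first axis, background elsewhere."""
    parc = np.zeros(shape, dtype=np.int32)
    q = shape[0] // 4
    for r in range(4):
        parc[r * q : (r + 1) * q, 2:8, 2:8] = r + 1
    return parc


def spherical_lesion(shape, center, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@pytest.fixture
def toy_atlas_inputs():
    """(lesion, parcellation, centrality) on a 10^3 grid with 4 regions."""
    parc = toy_parcellation()
    lesion = spherical_lesion(parc.shape, center=(3, 5, 5), radius=3)
    centrality = pd.Series([5.0, 9.0, 2.0, 4.0], index=[1, 2, 3, 4], name="centrality")
    centrality.index.name = "region_id"
    return lesion, parc, centrality


@pytest.fixture
def small_cohort() -> pd.DataFrame:
    """Hand-built long cohort table exercising all classification branches."""
    from netimpact.cognition import DOMAIN_COLUMNS

    def row(pid, visit, days, domains, moca=np.nan, instrument="full_battery", **kw):
        base = {
            "patient_id": pid,
            "visit": visit,
            "days_post_stroke": days,
            "moca_percentile": moca,
            "instrument": instrument,
            "age_years": kw.get("age", 67.0),
            "sex": kw.get("sex", "female"),
            "education_category": kw.get("edu", "high_school"),
            "prior_stroke": kw.get("prior", 0),
            "infarct_volume_ml": kw.get("vol", 3.7),
            "site_id": kw.get("site", "site_01"),
        }
        for col, val in zip(DOMAIN_COLUMNS, domains):
            base[col] = val
        return base

    nanx6 = [np.nan] * 6
    rows = [
        # recovery: PSCI at day 60, no_PSCI at day 200
        row("A", 1, 60, [3.0, 50, 60, np.nan, np.nan, np.nan]),
        row("A", 2, 200, [40, 50, 60, 70, np.nan, np.nan]),
        # decline: no_PSCI day 40, PSCI day 400
        row("B", 1, 40, [20, 30, 40, 50, 60, 70], sex="male"),
        row("B", 2, 400, [2.0, 30, 40, 50, 60, 70], sex="male"),
        # single visit -> not evaluable
        row("C", 1, 60, [10, 20, 30, np.nan, np.nan, np.nan]),
        # indeterminate baseline (2 domains, unimpaired)
        row("D", 1, 30, [50, 60, np.nan, np.nan, np.nan, np.nan]),
        row("D", 2, 300, [50, 60, 70, np.nan, np.nan, np.nan]),
        # MoCA-only patient, stable no_PSCI
        row("E", 1, 10, nanx6, moca=60.0, instrument="moca"),
        row("E", 2, 500, nanx6, moca=55.0, instrument="moca"),
    ]
    return pd.DataFrame(rows)
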