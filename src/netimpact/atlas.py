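"""Network atlas construction: betweenness centrality bound to a parcellation.

The network atlas is a fixed lookup from grey-matter region to betweenness
centrality, derived once from a structural connectome (in the original
biomarker, whole-brain tractography in healthy adults) and then reused for
every patient. This module builds that lookup: it holds the connectome,
computes per-region betweenness centrality, and validates the binding
between centrality values and the integer labels of a parcellation volume.

Conventions
-----------
* Graphs are undirected; each unordered source-target pair is counted once.
* Betweenness is *unnormalized* (raw shortest-path counts, endpoints
  excluded, ties credited fractionally). Because the downstream impact
  score uses centrality only through a product, a maximum and a log, any
  positive rescaling of the centrality column shifts every log score by
  the same additive constant and leaves all association models unchanged.
* For weighted graphs, shortest paths use length = 1/weight: a stronger
  structural connection is a shorter path, the standard convention for
  tractography-derived connectomes.
* Disconnected graphs are allowed; unreachable pairs contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BindingError, DegenerateGraphError, ValidationError

__all__ = [
    "Connectome",
    "BoundAtlas",
    "betweenness_centrality",
    "bind_centrality",
    "read_centrality_csv",
    "write_centrality_csv",
]


@dataclass
class Connectome:
    """Undirected weighted region-to-region connectivity graph.

    Nodes are region identifiers (the same integers used as labels in the
    parcellation volume). Edge weights are connection strengths and must be
    strictly positive; self-loops are rejected.
    """

    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() < 2:
            raise DegenerateGraphError(
                f"connectome needs >= 2 nodes, got {self.graph.number_of_nodes()}"
            )
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = data.get("weight", 1.0)
            if not np.isfinite(w) or w <= 0:
                raise ValidationError(f"non-positive weight {w!r} on edge ({u!r}, {v!r})")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def node_labels(self) -> list:
        return sorted(self.graph.nodes())

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(cls, edges, n_nodes=None, node_labels=None) -> "Connectome":
        """Build from an iterable of (node_i, node_j, weight) triples.

        ``node_labels`` (or ``range(1, n_nodes + 1)``) adds isolated nodes
        not mentioned in any edge, so the node set can match a parcellation
        even when some regions are unconnected.
        """
        g = nx.Graph()
        if node_labels is not None:
            g.add_nodes_from(node_labels)
        elif n_nodes is not None:
            g.add_nodes_from(range(1, n_nodes + 1))
        for i, j, w in edges:
            g.add_edge(i, j, weight=float(w))
        return cls(g)

    @classmethod
    def from_edgelist_csv(cls, path) -> "Connectome":
        """Read a three-column CSV edge list: node_i, node_j, weight."""
        df = pd.read_csv(path)
        if df.shape[1] < 3:
            raise ValidationError(f"edge list {path} needs 3 columns, got {df.shape[1]}")
        cols = df.columns[:3]
        return cls.from_edges(df[cols].itertuples(index=False, name=None))

    @classmethod
    def from_matrix_csv(cls, path) -> "Connectome":
        """Read a square adjacency matrix CSV whose header row holds region ids."""
        df = pd.read_csv(path)
        labels = [int(c) for c in df.columns]
        mat = df.to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise ValidationError(f"adjacency matrix {path} is not square: {mat.shape}")
        if not np.allclose(mat, mat.T):
            raise ValidationError("adjacency matrix is not symmetric")
        g = nx.Graph()
        g.add_nodes_from(labels)
        n = len(labels)
        for a in range(n):
            for b in range(a + 1, n):
                if mat[a, b] != 0:
                    g.add_edge(labels[a], labels[b], weight=float(mat[a, b]))
        return cls(g)

    def to_edgelist_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d.get("weight", 1.0))
            for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1]))
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def betweenness_centrality(connectome: Connectome, weighted: bool = True) -> pd.Series:
    """Unnormalized node betweenness centrality of the connectome.

    For each node, counts the shortest source-target paths (over all
    unordered pairs of *other* nodes) that pass through it, crediting ties
    fractionally. When ``weighted``, path length of an edge is 1/weight.

    Returns a :class:`pandas.Series` indexed by region id (the centrality
    table), sorted by id. Deterministic for a fixed graph.
    """
    g = connectome.graph
    if g.number_of_nodes() < 2:
        raise DegenerateGraphError("betweenness needs >= 2 nodes")
    weight_key = None
    if weighted:
        g = g.copy()
        for u, v, data in g.edges(data=True):
            data["length"] = 1.0 / data.get("weight", 1.0)
        weight_key = "length"
    bc = nx.betweenness_centrality(g, normalized=False, weight=weight_key, endpoints=False)
    table = pd.Series(bc, name="centrality").sort_index()
    table.index.name = "region_id"
    return table


def validate_centrality_table(table: pd.Series) -> pd.Series:
    """Check centrality-table invariants: non-negative, at least one positive."""
    values = np.asarray(table, dtype=float)
    if values.size == 0:
        raise ValidationError("centrality table is empty")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValidationError("centrality values must be finite and >= 0")
    if not np.any(values > 0):
        raise ValidationError("centrality table has no positive value")
    if table.index.duplicated().any():
        raise ValidationError("duplicate region ids in centrality table")
    return table


@dataclass
class BoundAtlas:
    """Validated (parcellation, centrality) pair ready for lesion scoring.

    ``region_sizes`` caches the voxel count of every nonzero label so batch
    scoring counts each region's denominator once. ``extra_regions`` lists
    table entries absent from the volume (harmless; reported for audit).
    """

    parcellation: np.ndarray = field(repr=False)
    centrality: pd.Series = field(repr=False)
    region_sizes: pd.Series = field(repr=False)
    extra_regions: tuple = ()

    @property
    def region_ids(self) -> np.ndarray:
        return self.region_sizes.index.to_numpy()


def bind_centrality(parcellation: np.ndarray, table: pd.Series) -> BoundAtlas:
    """Bind a centrality table to the labels of a parcellation volume.

    Every nonzero label in the volume must have a centrality entry;
    otherwise a :class:`BindingError` lists the missing labels. Table
    entries for regions absent from the volume are allowed and reported.
    """
    validate_centrality_table(table)
    parc = np.asarray(parcellation)
    if not np.issubdtype(parc.dtype, np.integer):
        raise ValidationError(f"parcellation must be integer-labelled, got {parc.dtype}")
    if parc.min() < 0:
        raise ValidationError("parcellation labels must be non-negative")
    labels, counts = np.unique(parc[parc > 0], return_counts=True)
    if labels.size == 0:
        raise ValidationError("parcellation contains no nonzero labels")
    table_ids = set(int(i) for i in table.index)
    missing = [int(l) for l in labels if int(l) not in table_ids]
    if missing:
        raise BindingError(
            f"parcellation labels missing from centrality table: {missing}",
            missing_labels=missing,
        )
    extra = tuple(sorted(table_ids - set(int(l) for l in labels)))
    sizes = pd.Series(counts, index=labels.astype(int), name="n_voxels")
    sizes.index.name = "region_id"
    cent = table.reindex(sizes.index).astype(float)
    return BoundAtlas(
        parcellation=parc,
        centrality=cent,
        region_sizes=sizes,
        extra_regions=extra,
    )


def read_centrality_csv(path) -> pd.Series:
    """Read a two-column (region_id, centrality) CSV into a centrality table."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"centrality CSV {path} needs 2 columns")
    table = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float),
        index=df.iloc[:, 0].to_numpy(dtype=int),
        name="centrality",
    )
    table.index.name = "region_id"
    return validate_centrality_table(table.sort_index())


def write_centrality_csv(table: pd.Series, path) -> None:
    df = table.rename("centrality").rename_axis("region_id").reset_index()
    df.to_csv(path, index=False, float_format="%.12g")
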