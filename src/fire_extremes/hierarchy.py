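"""Nested ecoregion hierarchy with an adjacency graph for ICAR priors.

Regions come in three nested levels (L3 nested in L2 nested in L1),
mirroring the EPA ecoregion classification of the contiguous United States.
The finest level (L3) carries an adjacency structure used by the intrinsic
conditional autoregressive (ICAR) spatial prior, which requires a connected
graph so that a single sum-to-zero constraint identifies the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class HierarchyError(ValueError):
    """Raised when a hierarchy violates its structural invariants."""


@dataclass(frozen=True)
class EcoregionHierarchy:
    """Three-level nested region hierarchy with L3 adjacency and areas.

    Parameters
    ----------
    l3_ids
        Ordered L3 region identifiers (ints). The ordering defines the
        row/column order of all adjacency matrices and spatial vectors.
    parent_l2
        Map from each L3 id to its (unique) L2 parent id.
    parent_l1
        Map from each L2 id to its (unique) L1 parent id.
    adjacency
        Unordered pairs of adjacent L3 ids; symmetric, no self-loops, and
        the induced graph must be connected (when there is more than one
        region).
    area
        Map from L3 id to its strictly positive area in km^2. Areas enter
        the count model as a known offset (log a), making it a rate model.
    """

    l3_ids: tuple[int, ...]
    parent_l2: dict[int, int]
    parent_l1: dict[int, int]
    adjacency: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    area: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.l3_ids)) != len(self.l3_ids):
            raise HierarchyError("duplicate L3 ids")
        missing = [r for r in self.l3_ids if r not in self.parent_l2]
        if missing:
            raise HierarchyError(f"L3 regions without an L2 parent: {missing}")
        orphans = [u for u in set(self.parent_l2.values()) if u not in self.parent_l1]
        if orphans:
            raise HierarchyError(f"L2 regions without an L1 parent: {orphans}")
        for i, j in self.adjacency:
            if i == j:
                raise HierarchyError(f"self-loop at region {i}")
            if i not in self.parent_l2 or j not in self.parent_l2:
                raise HierarchyError(f"adjacency references unknown region: ({i}, {j})")
        bad_area = {r: a for r, a in self.area.items() if not a > 0}
        if set(self.area) != set(self.l3_ids) or bad_area:
            raise HierarchyError("every L3 region needs a strictly positive area")
        if self.n_l3 > 1 and not nx.is_connected(self.graph()):
            raise HierarchyError("L3 adjacency graph is not connected")

    # -- basic queries ---------------------------------------------------

    @property
    def n_l3(self) -> int:
        return len(self.l3_ids)

    @property
    def l2_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.parent_l2.values())))

    @property
    def l1_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.parent_l1.values())))

    @property
    def n_l2(self) -> int:
        return len(self.l2_ids)

    @property
    def n_l1(self) -> int:
        return len(self.l1_ids)

    def l1_of_l3(self, l3: int) -> int:
        return self.parent_l1[self.parent_l2[l3]]

    def index_of(self, l3: int) -> int:
        return self.l3_ids.index(l3)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.l3_ids)
        g.add_edges_from(self.adjacency)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency in ``l3_ids`` order."""
        idx = {r: k for k, r in enumerate(self.l3_ids)}
        a = np.zeros((self.n_l3, self.n_l3))
        for i, j in self.adjacency:
            a[idx[i], idx[j]] = a[idx[j], idx[i]] = 1.0
        return a

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian Q = D - A, the ICAR precision structure."""
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def areas(self) -> np.ndarray:
        return np.array([self.area[r] for r in self.l3_ids])

    # -- IO --------------------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (nesting table, adjacency edge list) as DataFrames."""
        nest = pd.DataFrame(
            {
                "l3": self.l3_ids,
                "l2": [self.parent_l2[r] for r in self.l3_ids],
                "l1": [self.l1_of_l3(r) for r in self.l3_ids],
                "area_km2": [self.area[r] for r in self.l3_ids],
            }
        )
        edges = pd.DataFrame(sorted(self.adjacency), columns=["l3_a", "l3_b"])
        return nest, edges

    @classmethod
    def from_frames(cls, nest: pd.DataFrame, edges: pd.DataFrame) -> "EcoregionHierarchy":
        parent_l2 = dict(zip(nest["l3"].astype(int), nest["l2"].astype(int)))
        parent_l1 = dict(zip(nest["l2"].astype(int), nest["l1"].astype(int)))
        adjacency = frozenset(
            tuple(sorted((int(a), int(b)))) for a, b in zip(edges["l3_a"], edges["l3_b"])
        )
        area = dict(zip(nest["l3"].astype(int), nest["area_km2"].astype(float)))
        return cls(tuple(nest["l3"].astype(int)), parent_l2, parent_l1, adjacency, area)


def generate_hierarchy(
    n_l1: int,
    n_l2: int,
    n_l3: int,
    seed: int,
    mean_log_area: float = np.log(9.0e4),
    sd_log_area: float = 0.5,
) -> EcoregionHierarchy:
    """Generate a nested hierarchy with a connected planar-style adjacency.

    L3 regions are placed uniformly at random in the unit square and joined
    to their spatial neighbours (each region to its 3 nearest neighbours);
    a minimum spanning tree over inter-point distances is added so the
    graph is always connected, as the ICAR prior requires. L3 regions are
    assigned to L2 parents (and L2 to L1) by splitting the spatial ordering
    into contiguous groups, so sibling regions tend to be adjacent, loosely
    emulating how real ecoregion levels nest.

    Areas are lognormal; the default location matches the order of
    magnitude of real L3 ecoregions (~9e4 km^2 for the contiguous US split
    into ~84 regions).
    """
    if not (1 <= n_l1 <= n_l2 <= n_l3):
        raise HierarchyError(
            f"need 1 <= n_l1 <= n_l2 <= n_l3, got ({n_l1}, {n_l2}, {n_l3})"
        )
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n_l3, 2))
    l3_ids = tuple(range(1, n_l3 + 1))

    # order regions along a space-filling-ish sweep so parent groups are
    # spatially coherent
    order = np.argsort(pts[:, 0] + 0.25 * pts[:, 1])
    groups_l2 = np.array_split(order, n_l2)
    parent_l2 = {}
    for u, members in enumerate(groups_l2, start=1):
        for m in members:
            parent_l2[l3_ids[m]] = u
    groups_l1 = np.array_split(np.arange(1, n_l2 + 1), n_l1)
    parent_l1 = {}
    for v, members in enumerate(groups_l1, start=1):
        for u in members:
            parent_l1[int(u)] = v

    edges: set[tuple[int, int]] = set()
    if n_l3 > 1:
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        k = min(3, n_l3 - 1)
        for i in range(n_l3):
            nearest = np.argsort(d[i])[1 : k + 1]
            for j in nearest:
                edges.add(tuple(sorted((l3_ids[i], l3_ids[int(j)]))))
        g = nx.Graph()
        g.add_weighted_edges_from(
            (l3_ids[i], l3_ids[j], d[i, j]) for i in range(n_l3) for j in range(i + 1, n_l3)
        )
        mst = nx.minimum_spanning_tree(g)
        edges.update(tuple(sorted(e)) for e in mst.edges())

    area = {
        r: float(np.exp(rng.normal(mean_log_area, sd_log_area))) for r in l3_ids
    }
    return EcoregionHierarchy(l3_ids, parent_l2, parent_l1, frozenset(edges), area)
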