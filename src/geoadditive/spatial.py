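"""District adjacency and the structured / unstructured spatial components.

Districts are neighbours when their polygons share a boundary segment of
positive length (rook contiguity; a corner touch does not count).  The
structured spatial effect carries an intrinsic CAR (Markov random field)
prior with precision proportional to K_s = diag(n_i) - A: conditionally,
each district's effect is Gaussian around the average of its neighbours'
effects with variance tau^2_str / n_i.  The unstructured effect is i.i.d.
Gaussian across districts — spatial variation local to a district rather
than shared with its neighbours.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import mapping, shape

log = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "neighbors_from_polygons",
    "icar_precision",
    "mrf_conditional",
    "UnstructuredPrior",
    "sample_icar",
    "read_geojson",
    "write_geojson",
    "read_adjacency",
    "write_adjacency",
]


@dataclass
class AdjacencyGraph:
    """Districts plus symmetric shared-boundary neighbour pairs.

    ``labels`` fixes the district order (position 0..S-1); ``edges`` holds
    index pairs (i, j), i < j, with no self-pairs.
    """

    labels: list
    edges: list = field(default_factory=list)

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-pair ({i},{j}) in adjacency")
        self.edges = sorted({(min(i, j), max(i, j)) for i, j in self.edges})

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n, self.n))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency_matrix().sum(axis=1)

    def neighbors(self, i: int) -> list[int]:
        return sorted([j for a, j in self.edges if a == i] + [a for a, j in self.edges if j == i])

    def components(self) -> np.ndarray:
        A = csr_matrix(self.adjacency_matrix())
        _, labels = connected_components(A, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        return int(self.components().max()) + 1 if self.n else 0

    def isolated(self) -> list:
        deg = self.degrees()
        return [self.labels[i] for i in np.flatnonzero(deg == 0)]


def neighbors_from_polygons(polygons: dict, rule: str = "rook") -> AdjacencyGraph:
    """Contiguity graph from district polygons.

    ``polygons`` maps district label -> shapely geometry.  Under the default
    rook rule an edge requires a shared boundary of positive length, so
    polygons meeting only at a corner are not neighbours; ``rule='queen'``
    admits any touching geometries.  Isolated districts are kept but flagged
    with a warning (a disconnected map needs the per-component constraint
    policy downstream).
    """
    labels = list(polygons)
    geoms = []
    for lab in labels:
        g = polygons[lab]
        if g is None or g.is_empty:
            raise ValueError(f"district {lab!r}: invalid or empty geometry")
        geoms.append(g)
    edges = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = geoms[i], geoms[j]
            if not gi.intersects(gj):
                continue
            if rule == "queen":
                edges.append((i, j))
            else:
                inter = gi.boundary.intersection(gj.boundary)
                if inter.length > 0:
                    edges.append((i, j))
    graph = AdjacencyGraph(labels=labels, edges=edges)
    for lab in graph.isolated():
        log.warning("district %r has no neighbours (isolated on the map)", lab)
    return graph


def icar_precision(graph: AdjacencyGraph) -> np.ndarray:
    """Intrinsic CAR structure matrix K_s = diag(n_i) - A.

    Rows sum to zero; rank is S minus the number of connected components.
    """
    A = graph.adjacency_matrix()
    return np.diag(A.sum(axis=1)) - A


def mrf_conditional(f, i: int, graph: AdjacencyGraph, tau2_str: float):
    """Full conditional moments of the structured effect of district ``i``.

    mean = average of the neighbours' effects, variance = tau^2_str / n_i.
    Undefined for an isolated district (handled by the constraint policy,
    not here).
    """
    nbrs = graph.neighbors(i)
    if not nbrs:
        raise ValueError(
            f"district {graph.labels[i]!r} has no neighbours; conditional undefined"
        )
    f = np.asarray(f, dtype=float)
    return float(f[nbrs].mean()), tau2_str / len(nbrs)


@dataclass(frozen=True)
class UnstructuredPrior:
    """Exchangeable district effects: independent N(0, tau2) per district."""

    n_districts: int
    tau2: float

    def covariance(self) -> np.ndarray:
        return self.tau2 * np.eye(self.n_districts)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        shape = (self.n_districts,) if size is None else (size, self.n_districts)
        return np.sqrt(self.tau2) * rng.standard_normal(shape)


def sample_icar(
    graph: AdjacencyGraph, tau2: float, rng: np.random.Generator, size=None
) -> np.ndarray:
    """Draw from the sum-to-zero-constrained intrinsic CAR prior.

    The improper ICAR density exp(-f'K_s f / (2 tau^2)) is proper on the
    subspace orthogonal to each component's constant vector; draws are built
    from the positive-eigenvalue pairs of K_s, giving component-wise mean
    zero by construction.
    """
    K = icar_precision(graph)
    w, V = np.linalg.eigh(K)
    pos = w > 1e-10 * max(w.max(), 1.0)
    sd = np.sqrt(tau2 / w[pos])
    m = int(pos.sum())
    z = rng.standard_normal(m if size is None else (size, m))
    return (z * sd) @ V[:, pos].T


# ---------------------------------------------------------------------------
# I/O: GeoJSON polygons, plain-text adjacency, edge-list export


def read_geojson(path) -> dict:
    """District polygons from a GeoJSON FeatureCollection (property 'district_id')."""
    with open(path) as fh:
        gj = json.load(fh)
    polys = {}
    for feat in gj["features"]:
        props = feat.get("properties", {})
        lab = props.get("district_id", props.get("id"))
        if lab is None:
            raise ValueError("GeoJSON feature lacks a district_id property")
        polys[lab] = shape(feat["geometry"])
    return polys


def write_geojson(polygons: dict, path, properties: dict | None = None) -> None:
    """Write polygons (+ optional per-district property dicts) as GeoJSON."""
    feats = []
    for lab, geom in polygons.items():
        props = {"district_id": lab}
        if properties and lab in properties:
            props.update(properties[lab])
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_adjacency(path) -> AdjacencyGraph:
    """Plain-text adjacency: one line per district: label degree nbr1 nbr2 ...

    Labels are read as integers when possible, else kept as strings.
    """

    def _parse(tok):
        try:
            return int(tok)
        except ValueError:
            return tok

    rows = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            lab, deg, nbrs = _parse(toks[0]), int(toks[1]), [_parse(t) for t in toks[2:]]
            if deg != len(nbrs):
                raise ValueError(f"district {lab!r}: declared degree {deg} != {len(nbrs)} listed")
            rows.append((lab, nbrs))
    labels = [lab for lab, _ in rows]
    idx = {lab: i for i, lab in enumerate(labels)}
    edges = []
    for lab, nbrs in rows:
        for nb in nbrs:
            if nb not in idx:
                raise ValueError(f"district {lab!r} lists unknown neighbour {nb!r}")
            edges.append((idx[lab], idx[nb]))
    return AdjacencyGraph(labels=labels, edges=edges)


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(graph.labels):
            nbrs = [graph.labels[j] for j in graph.neighbors(i)]
            fh.write(" ".join([str(lab), str(len(nbrs))] + [str(n) for n in nbrs]) + "\n")


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    """Adjacency as an edge-list CSV (district_a,district_b)."""
    with open(path, "w") as fh:
        fh.write("district_a,district_b\n")
        for i, j in graph.edges:
            fh.write(f"{graph.labels[i]},{graph.labels[j]}\n")
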