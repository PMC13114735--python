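"""Network construction and per-compartment layer decomposition.

A rumor spreads over a contact network whose edges need not carry every
compartment: each edge is labelled with the non-empty subset of {S, I, R}
allowed to diffuse across it (seven classes, conventionally colored
red={S}, green={I}, blue={R}, yellow={S,I}, magenta={S,R}, cyan={I,R},
black={S,I,R}).  Decomposing by label yields three single-compartment
layers whose Laplacians A, B, C drive the diffusion of S, I and R.

Laplacians here follow the semi-negative-definite sign convention:
L = adjacency - degree diagonal, so every eigenvalue is <= 0 and the
eigenvalues play the role of -k^2 wavenumbers in the dispersion analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AdjacencySpec",
    "EdgePermission",
    "LayeredNetwork",
    "PERMISSION_TOKENS",
    "laplacian_from_adjacency",
    "build_lattice",
    "build_er",
    "build_ba",
    "assign_edge_permissions",
    "decompose_layers",
    "save_edge_list",
    "load_edge_list",
]

#: Canonical order of the seven permission subsets and their edge-list tokens.
PERMISSION_TOKENS: dict[str, frozenset[str]] = {
    "S": frozenset("S"),
    "I": frozenset("I"),
    "R": frozenset("R"),
    "SI": frozenset("SI"),
    "SR": frozenset("SR"),
    "IR": frozenset("IR"),
    "SIR": frozenset("SIR"),
}

_SUBSET_TO_TOKEN = {v: k for k, v in PERMISSION_TOKENS.items()}


class NetworkInputError(ValueError):
    """Invalid network specification (self-loop, bad index, bad permission)."""


class EdgeListParseError(ValueError):
    """Malformed edge-list file; message carries the offending line number."""


@dataclass(frozen=True)
class AdjacencySpec:
    """An unweighted simple graph given by node count and edge set.

    Edges are unordered 0-based index pairs; self-loops and duplicates are
    rejected at construction.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]

    def __init__(self, n_nodes: int, edges) -> None:
        if n_nodes <= 0:
            raise NetworkInputError(f"n_nodes must be positive, got {n_nodes}")
        norm = set()
        for u, v in edges:
            if u == v:
                raise NetworkInputError(f"self-loop at node {u}")
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise NetworkInputError(f"edge ({u},{v}) out of range [0,{n_nodes})")
            e = (min(u, v), max(u, v))
            if e in norm:
                raise NetworkInputError(f"duplicate edge {e}")
            norm.add(e)
        object.__setattr__(self, "n_nodes", int(n_nodes))
        object.__setattr__(self, "edges", frozenset(norm))

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "AdjacencySpec":
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        return cls(g.number_of_nodes(), {(mapping[u], mapping[v]) for u, v in g.edges()})


@dataclass(frozen=True)
class EdgePermission:
    """A single edge together with the compartments allowed to cross it."""

    edge: tuple[int, int]
    allowed: frozenset[str]

    def __post_init__(self) -> None:
        e = (min(self.edge), max(self.edge))
        object.__setattr__(self, "edge", e)
        allowed = frozenset(self.allowed)
        if not allowed or not allowed <= frozenset("SIR"):
            raise NetworkInputError(
                f"permission must be a non-empty subset of {{S,I,R}}, got {set(self.allowed)}"
            )
        object.__setattr__(self, "allowed", allowed)

    @property
    def token(self) -> str:
        return _SUBSET_TO_TOKEN[self.allowed]


@dataclass
class LayeredNetwork:
    """Per-compartment Laplacians A (for S), B (for I), C (for R).

    Each Laplacian is symmetric with zero row sums, off-diagonal entries in
    {0, 1}, diagonal equal to minus the layer degree, hence semi-negative
    definite.  ``permissions`` is retained when the layers came from an
    edge-labelled decomposition; homogeneous networks have A = B = C.
    """

    n_nodes: int
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    permissions: list[EdgePermission] | None = None

    def __post_init__(self) -> None:
        for name, L in (("A", self.A), ("B", self.B), ("C", self.C)):
            L = np.asarray(L, dtype=float)
            if L.shape != (self.n_nodes, self.n_nodes):
                raise NetworkInputError(f"layer {name} has shape {L.shape}, expected square {self.n_nodes}")
            setattr(self, name, L)

    @property
    def degrees_A(self) -> np.ndarray:
        return -np.diag(self.A)

    @property
    def degrees_B(self) -> np.ndarray:
        return -np.diag(self.B)

    @property
    def degrees_C(self) -> np.ndarray:
        return -np.diag(self.C)

    @property
    def is_homogeneous(self) -> bool:
        return np.array_equal(self.A, self.B) and np.array_equal(self.B, self.C)

    @classmethod
    def homogeneous(cls, adj: AdjacencySpec) -> "LayeredNetwork":
        L = laplacian_from_adjacency(adj)
        return cls(adj.n_nodes, L, L.copy(), L.copy())


def laplacian_from_adjacency(adj: AdjacencySpec) -> np.ndarray:
    """Laplacian under the sign convention L = adjacency - Diag(degrees).

    Symmetric, zero row sums, all eigenvalues <= 0; for a connected graph
    the single zero eigenvalue has the constant eigenvector.
    """
    n = adj.n_nodes
    L = np.zeros((n, n))
    for u, v in adj.edges:
        L[u, v] = L[v, u] = 1.0
    np.fill_diagonal(L, -L.sum(axis=1))
    return L


def _lattice_offsets(degree: int) -> list[tuple[int, int]]:
    if degree == 4:
        return [(1, 0), (0, 1)]
    if degree == 6:
        # von-Neumann plus one diagonal pair: each node also links (+1,+1)
        return [(1, 0), (0, 1), (1, 1)]
    if degree == 8:
        return [(1, 0), (0, 1), (1, 1), (1, -1)]
    raise NetworkInputError(f"lattice degree must be 4, 6 or 8, got {degree}")


def build_lattice(rows: int, cols: int, degree: int = 4, boundary: str = "periodic") -> LayeredNetwork:
    """Regular lattice network: quadrilateral (4), hexagonal (6) or octagonal (8).

    With periodic (toroidal) boundary every node has exactly the nominal
    degree; ``boundary="open"`` truncates at the lattice border instead.
    """
    offsets = _lattice_offsets(degree)
    if boundary not in ("periodic", "open"):
        raise NetworkInputError(f"boundary must be 'periodic' or 'open', got {boundary!r}")
    if boundary == "periodic" and (rows < 3 or cols < 3):
        raise NetworkInputError("periodic lattices need rows, cols >= 3 to stay simple")
    if rows < 1 or cols < 1:
        raise NetworkInputError("lattice dimensions must be positive")

    def idx(i: int, j: int) -> int:
        return i * cols + j

    edges = set()
    for i in range(rows):
        for j in range(cols):
            for di, dj in offsets:
                ni, nj = i + di, j + dj
                if boundary == "periodic":
                    ni, nj = ni % rows, nj % cols
                elif not (0 <= ni < rows and 0 <= nj < cols):
                    continue
                u, v = idx(i, j), idx(ni, nj)
                if u != v:
                    edges.add((min(u, v), max(u, v)))
    return LayeredNetwork.homogeneous(AdjacencySpec(rows * cols, edges))


def build_er(n: int, p: float, seed: int) -> LayeredNetwork:
    """Erdős–Rényi G(n, p) network; warns when the sample is disconnected."""
    if not 0.0 <= p <= 1.0:
        raise NetworkInputError(f"p must lie in [0,1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = LayeredNetwork.homogeneous(AdjacencySpec.from_graph(g))
    n_components = nx.number_connected_components(g)
    if n_components > 1:
        warnings.warn(
            f"ER sample is disconnected ({n_components} components; the Laplacian "
            f"has {n_components} zero eigenvalues)",
            stacklevel=2,
        )
    return net


def build_ba(n: int, m: int, seed: int) -> LayeredNetwork:
    """Barabási–Albert preferential-attachment network.

    Growth starts from a complete seed graph on m nodes, each of the n - m
    subsequent nodes attaching m edges, so the edge count is
    C(m,2) + (n - m) * m exactly.
    """
    if not 1 <= m < n:
        raise NetworkInputError(f"need 1 <= m < n, got m={m}, n={n}")
    g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=nx.complete_graph(m))
    return LayeredNetwork.homogeneous(AdjacencySpec.from_graph(g))


def assign_edge_permissions(
    adj: AdjacencySpec,
    scheme: str = "uniform7",
    fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> list[EdgePermission]:
    """Label every edge with one of the seven compartment-permission subsets.

    ``uniform7`` draws uniformly over the seven classes; ``fractions`` draws
    from user-given class probabilities (tokens as in PERMISSION_TOKENS),
    which must sum to 1.
    """
    tokens = list(PERMISSION_TOKENS)
    if scheme == "uniform7":
        probs = np.full(7, 1.0 / 7.0)
    elif scheme == "fractions":
        if fractions is None:
            raise NetworkInputError("scheme='fractions' requires a fractions mapping")
        unknown = set(fractions) - set(tokens)
        if unknown:
            raise NetworkInputError(f"unknown permission tokens {sorted(unknown)}")
        probs = np.array([fractions.get(t, 0.0) for t in tokens], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise NetworkInputError(f"fractions sum to {probs.sum()}, expected 1")
    else:
        raise NetworkInputError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    edges = sorted(adj.edges)
    draws = rng.choice(len(tokens), size=len(edges), p=probs)
    return [EdgePermission(e, PERMISSION_TOKENS[tokens[k]]) for e, k in zip(edges, draws)]


def decompose_layers(adj: AdjacencySpec, permissions: list[EdgePermission]) -> LayeredNetwork:
    """Split an edge-labelled network into three per-compartment Laplacians."""
    perm_edges = [p.edge for p in permissions]
    if len(set(perm_edges)) != len(perm_edges):
        raise NetworkInputError("duplicate permission entries")
    if set(perm_edges) != set(adj.edges):
        missing = set(adj.edges) - set(perm_edges)
        extra = set(perm_edges) - set(adj.edges)
        raise NetworkInputError(
            f"permissions must cover exactly the edges of the graph "
            f"(missing {sorted(missing)[:3]}, extraneous {sorted(extra)[:3]})"
        )
    layers = {}
    for comp in "SIR":
        sub = AdjacencySpec(adj.n_nodes, {p.edge for p in permissions if comp in p.allowed})
        layers[comp] = laplacian_from_adjacency(sub)
    return LayeredNetwork(adj.n_nodes, layers["S"], layers["I"], layers["R"], list(permissions))


# ---------------------------------------------------------------------------
# Edge-list persistence: tab-separated "u<TAB>v<TAB>token", '#' comments,
# 0-based indices.  Lossless for topology + permission labels.
# ---------------------------------------------------------------------------

def save_edge_list(net: LayeredNetwork, path) -> None:
    perms = net.permissions
    if perms is None:
        if not net.is_homogeneous:
            raise NetworkInputError("heterogeneous network without permission labels cannot be serialized")
        adj_A = net.A - np.diag(np.diag(net.A))
        us, vs = np.nonzero(np.triu(adj_A))
        perms = [EdgePermission((int(u), int(v)), frozenset("SIR")) for u, v in zip(us, vs)]
    with open(path, "w") as fh:
        fh.write(f"# turingnet edge list: n_nodes={net.n_nodes}\n")
        fh.write("# u\tv\tpermission\n")
        for p in sorted(perms, key=lambda p: p.edge):
            fh.write(f"{p.edge[0]}\t{p.edge[1]}\t{p.token}\n")


def load_edge_list(path) -> LayeredNetwork:
    n_nodes = None
    perms: list[EdgePermission] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                if "n_nodes=" in line:
                    try:
                        n_nodes = int(line.split("n_nodes=")[1].split()[0])
                    except (IndexError, ValueError):
                        raise EdgeListParseError(f"line {lineno}: malformed n_nodes header")
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise EdgeListParseError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListParseError(f"line {lineno}: non-integer node index")
            token = parts[2].strip()
            if token not in PERMISSION_TOKENS:
                raise EdgeListParseError(f"line {lineno}: unknown permission token {token!r}")
            e = (min(u, v), max(u, v))
            if e in seen:
                raise EdgeListParseError(f"line {lineno}: duplicate edge {e}")
            seen.add(e)
            perms.append(EdgePermission(e, PERMISSION_TOKENS[token]))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in seen), default=-1)
        if n_nodes == 0:
            raise EdgeListParseError("empty edge list with no n_nodes header")
    try:
        adj = AdjacencySpec(n_nodes, seen)
    except NetworkInputError as exc:
        raise EdgeListParseError(str(exc))
    return decompose_layers(adj, perms)
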