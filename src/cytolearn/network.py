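"""Disordered 2-D spring networks: generation, geometry, selection, relaxation.

The network caricatures a patch of actomyosin cortex: nodes are crosslink
hubs, edges are filament bundles modelled as (optionally nonlinear) springs
that also carry motor and mechanosensitive-protein densities. Strain uses
the extension convention ϵ = L − L0 (length units, *not* L/L0 − 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .params import ModelParams, steady_state

__all__ = [
    "NetworkState",
    "TaskGeometry",
    "generate_disordered_network",
    "select_edges_by_y",
    "relax",
    "equilibrium_pre_strain",
]


@dataclass
class NetworkState:
    """Geometry plus per-edge mechanical and chemical state.

    Arrays are index-aligned: ``edges[e]`` is the unordered node pair of edge
    ``e`` and every per-edge array has one entry per edge. A severed edge
    exerts no force and its chemical state is frozen.
    """

    positions: np.ndarray        # (N, 2) float
    edges: np.ndarray            # (E, 2) int, each pair sorted, unique
    stiffness: np.ndarray        # (E,) >= 0
    rest_length: np.ndarray      # (E,) > 0
    motor: np.ndarray            # (E,) >= 0, bound motor density m
    protein: np.ndarray          # (E,) >= 0, mechanosensitive protein density n
    prev_strain: np.ndarray      # (E,) cache for the backward-difference strain rate
    severed: np.ndarray          # (E,) bool
    pinned: np.ndarray           # (N,) bool — positions externally imposed
    boundary_nodes: np.ndarray   # node ids on the convex hull
    rng_seed: int = 0
    initial_rest_length: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        if self.initial_rest_length is None:
            self.initial_rest_length = self.rest_length.copy()
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite node coordinates")
        if self.edges.size:
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-edge present")
            keys = {tuple(sorted(e)) for e in self.edges.tolist()}
            if len(keys) != len(self.edges):
                raise ValueError("duplicate edge present")
        if np.any(self.rest_length <= 0):
            raise ValueError("rest lengths must be > 0")
        if np.any(self.stiffness < 0):
            raise ValueError("stiffness must be >= 0")
        if np.any(self.motor < 0) or np.any(self.protein < 0):
            raise ValueError("densities must be >= 0")

    # -- derived geometry ----------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_vectors(self) -> np.ndarray:
        """(E, 2) vectors from first to second endpoint."""
        return self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def strains(self) -> np.ndarray:
        """ϵ = L − L0 for every edge (severed edges included, informational)."""
        return self.lengths() - self.rest_length

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.positions[self.edges[:, 0]] + self.positions[self.edges[:, 1]])

    def active_edges(self) -> np.ndarray:
        return ~self.severed

    def copy(self) -> "NetworkState":
        return NetworkState(
            positions=self.positions.copy(),
            edges=self.edges.copy(),
            stiffness=self.stiffness.copy(),
            rest_length=self.rest_length.copy(),
            motor=self.motor.copy(),
            protein=self.protein.copy(),
            prev_strain=self.prev_strain.copy(),
            severed=self.severed.copy(),
            pinned=self.pinned.copy(),
            boundary_nodes=self.boundary_nodes.copy(),
            rng_seed=self.rng_seed,
            initial_rest_length=self.initial_rest_length.copy(),
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "cytolearn-network-v1",
            "rng_seed": int(self.rng_seed),
            "nodes": [
                {"id": i, "x": float(p[0]), "y": float(p[1]),
                 "pinned": bool(self.pinned[i]),
                 "boundary": bool(i in set(self.boundary_nodes.tolist()))}
                for i, p in enumerate(self.positions)
            ],
            "edges": [
                {"id": e, "j": int(self.edges[e, 0]), "k": int(self.edges[e, 1]),
                 "stiffness": float(self.stiffness[e]),
                 "rest_length": float(self.rest_length[e]),
                 "initial_rest_length": float(self.initial_rest_length[e]),
                 "motor": float(self.motor[e]),
                 "protein": float(self.protein[e]),
                 "prev_strain": float(self.prev_strain[e]),
                 "severed": bool(self.severed[e])}
                for e in range(self.n_edges)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkState":
        if d.get("format") != "cytolearn-network-v1":
            raise ValueError(f"unrecognised network format: {d.get('format')!r}")
        nodes = sorted(d["nodes"], key=lambda n: n["id"])
        edges = sorted(d["edges"], key=lambda e: e["id"])
        return cls(
            positions=np.array([[n["x"], n["y"]] for n in nodes]),
            edges=np.array([[e["j"], e["k"]] for e in edges], dtype=int).reshape(-1, 2),
            stiffness=np.array([e["stiffness"] for e in edges]),
            rest_length=np.array([e["rest_length"] for e in edges]),
            motor=np.array([e["motor"] for e in edges]),
            protein=np.array([e["protein"] for e in edges]),
            prev_strain=np.array([e["prev_strain"] for e in edges]),
            severed=np.array([e["severed"] for e in edges], dtype=bool),
            pinned=np.array([n["pinned"] for n in nodes], dtype=bool),
            boundary_nodes=np.array([n["id"] for n in nodes if n["boundary"]], dtype=int),
            rng_seed=d.get("rng_seed", 0),
            initial_rest_length=np.array([e["initial_rest_length"] for e in edges]),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "NetworkState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_graphml(self, path) -> None:
        g = nx.Graph(rng_seed=int(self.rng_seed))
        for i, p in enumerate(self.positions):
            g.add_node(i, x=float(p[0]), y=float(p[1]), pinned=bool(self.pinned[i]),
                       boundary=bool(i in set(self.boundary_nodes.tolist())))
        for e in range(self.n_edges):
            g.add_edge(int(self.edges[e, 0]), int(self.edges[e, 1]),
                       edge_id=e, stiffness=float(self.stiffness[e]),
                       rest_length=float(self.rest_length[e]),
                       initial_rest_length=float(self.initial_rest_length[e]),
                       motor=float(self.motor[e]), protein=float(self.protein[e]),
                       prev_strain=float(self.prev_strain[e]), severed=bool(self.severed[e]))
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path) -> "NetworkState":
        g = nx.read_graphml(path, node_type=int)
        nodes = sorted(g.nodes(data=True))
        edata = sorted((d["edge_id"], j, k, d) for j, k, d in g.edges(data=True))
        return cls(
            positions=np.array([[d["x"], d["y"]] for _, d in nodes]),
            edges=np.array([sorted((j, k)) for _, j, k, _ in edata], dtype=int).reshape(-1, 2),
            stiffness=np.array([d["stiffness"] for *_, d in edata]),
            rest_length=np.array([d["rest_length"] for *_, d in edata]),
            motor=np.array([d["motor"] for *_, d in edata]),
            protein=np.array([d["protein"] for *_, d in edata]),
            prev_strain=np.array([d["prev_strain"] for *_, d in edata]),
            severed=np.array([d["severed"] for *_, d in edata], dtype=bool),
            pinned=np.array([d["pinned"] for _, d in nodes], dtype=bool),
            boundary_nodes=np.array([i for i, d in nodes if d["boundary"]], dtype=int),
            rng_seed=int(g.graph.get("rng_seed", 0)),
            initial_rest_length=np.array([d["initial_rest_length"] for *_, d in edata]),
        )


@dataclass
class TaskGeometry:
    """Source/target edge assignment for a learning task.

    ``source_edges[i]`` carries the imposed strain ``eps_source[i]`` (the
    input); ``target_edges[i]`` has the desired strain ``eps_target[i]``
    (the output). Protected edges are excluded from turnover.
    """

    source_edges: list[int]
    target_edges: list[int]
    eps_source: list[float]
    eps_target: list[float]
    protected_edges: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.source_edges) & set(self.target_edges):
            raise ValueError("source and target edge sets must be disjoint")
        if len(self.source_edges) != len(self.eps_source):
            raise ValueError("one imposed strain per source edge required")
        if len(self.target_edges) != len(self.eps_target):
            raise ValueError("one desired strain per target edge required")
        if not self.protected_edges:
            self.protected_edges = list(self.source_edges) + list(self.target_edges)

    def validate_against(self, state: NetworkState) -> None:
        for e in list(self.source_edges) + list(self.target_edges):
            if not (0 <= e < state.n_edges):
                raise ValueError(f"task references nonexistent edge {e}")
            if state.severed[e]:
                raise ValueError(f"task references severed edge {e}")


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _triangular_points(n_side: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    dy = np.sqrt(3.0) / 2.0
    pts = []
    for row in range(n_side):
        x0 = 0.5 * (row % 2)
        for col in range(n_side):
            pts.append((x0 + col, dy * row))
    pts = np.array(pts, dtype=float)
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points)
    pairs = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            pairs.add(tuple(sorted((int(simplex[a]), int(simplex[b])))))
    return np.array(sorted(pairs), dtype=int)


def generate_disordered_network(
    n_side: int,
    jitter: float = 0.3,
    seed: int = 0,
    stiffness: float = 1.0,
    params: ModelParams | None = None,
) -> NetworkState:
    """Generate a disordered patch: jittered triangular lattice + Delaunay.

    Nodes sit on an ``n_side`` × ``n_side`` triangular-lattice patch, each
    displaced by a uniform jitter (fraction of the lattice spacing); edges
    come from the Delaunay triangulation with edges longer than 1.5× the
    mean pruned. Rest lengths equal the realized lengths, so the generated
    network is strain-free, and motor/protein densities start at their
    chemical steady state. Deterministic for a fixed seed.
    """
    if n_side < 3:
        raise ValueError("n_side must be >= 3")
    if not (0 <= jitter < 0.5):
        raise ValueError("jitter must be in [0, 0.5)")
    params = params or ModelParams()
    last_err: Exception | None = None
    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        points = _triangular_points(n_side, jitter, rng)
        try:
            edges = _delaunay_edges(points)
            hull = ConvexHull(points)
        except QhullError as err:  # collinear / degenerate configuration
            last_err = err
            continue
        lengths = np.linalg.norm(points[edges[:, 1]] - points[edges[:, 0]], axis=1)
        keep = lengths <= 1.5 * lengths.mean()
        edges, lengths = edges[keep], lengths[keep]
        # pruning must not disconnect the patch
        g = nx.Graph(edges.tolist())
        g.add_nodes_from(range(len(points)))
        if nx.number_connected_components(g) != 1:
            last_err = RuntimeError("pruning disconnected the network")
            continue
        ss = steady_state(params)
        ne = len(edges)
        # boundary = outer lattice ring; the convex hull alone misses
        # border nodes jittered inward and is too sparse for edge selection
        ring = [row * n_side + col
                for row in range(n_side) for col in range(n_side)
                if row in (0, n_side - 1) or col in (0, n_side - 1)]
        boundary = sorted(set(ring) | set(int(v) for v in hull.vertices))
        return NetworkState(
            positions=points,
            edges=edges,
            stiffness=np.full(ne, float(stiffness)),
            rest_length=lengths.copy(),
            motor=np.full(ne, ss.m0),
            protein=np.full(ne, ss.n0),
            prev_strain=np.zeros(ne),
            severed=np.zeros(ne, dtype=bool),
            pinned=np.zeros(len(points), dtype=bool),
            boundary_nodes=np.array(boundary, dtype=int),
            rng_seed=seed,
        )
    raise RuntimeError(
        f"failed to generate a valid network after 10 attempts (seed={seed}): {last_err}"
    )


# ----------------------------------------------------------------------
# edge selection
# ----------------------------------------------------------------------

def peripheral_edges(state: NetworkState) -> np.ndarray:
    """Edges with at least one endpoint on the convex hull of the node set."""
    hull = np.zeros(state.n_nodes, dtype=bool)
    hull[state.boundary_nodes] = True
    return np.where(hull[state.edges[:, 0]] | hull[state.edges[:, 1]])[0]


def select_edges_by_y(
    state: NetworkState, side: str, count: int, disjoint: bool = True
) -> list[int]:
    """Pick ``count`` peripheral edges on one side, ordered by midpoint y.

    ``side`` is ``"left"`` or ``"right"`` of the network's x-centroid. The
    chosen edges are spread evenly along the side and returned sorted
    ascending by midpoint y-coordinate (S1 … Sn from bottom to top). With
    ``disjoint`` (default) the edges share no nodes, so all of them can be
    pinned as independent sources.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if count < 1:
        raise ValueError("count must be >= 1")
    periph = peripheral_edges(state)
    if periph.size == 0:
        raise ValueError("network has no peripheral edges")
    mids = state.midpoints()[periph]
    x_center = state.positions[:, 0].mean()
    mask = mids[:, 0] < x_center if side == "left" else mids[:, 0] >= x_center
    candidates = periph[mask]
    order = candidates[np.argsort(state.midpoints()[candidates][:, 1], kind="stable")]
    if disjoint:
        used: set[int] = set()
        picked: list[int] = []
        for e in order:  # ascending y: the lowest edge is always taken
            a, b = (int(x) for x in state.edges[e])
            if a in used or b in used:
                continue
            picked.append(int(e))
            used.update((a, b))
        order = np.array(picked, dtype=int)
    if len(order) < count:
        raise ValueError(
            f"only {len(order)} usable peripheral edges on the {side} side, need {count}"
        )
    idx = np.unique(np.round(np.linspace(0, len(order) - 1, count)).astype(int))
    if len(idx) < count:  # rounding collision guard
        idx = np.arange(count)
    return [int(e) for e in order[idx]]


# ----------------------------------------------------------------------
# elastic relaxation
# ----------------------------------------------------------------------

def relax(
    state: NetworkState,
    params: ModelParams,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> NetworkState:
    """Relax unpinned nodes to mechanical equilibrium with chemistry at rest.

    At the chemical steady state the net active force vanishes (motor
    density sits at m0), so the overdamped node dynamics is gradient
    descent on the total elastic energy; we minimise that energy directly
    (L-BFGS-B with the analytic gradient) over the unpinned coordinates.
    Modifies and returns a copy of ``state``.
    """
    st = state.copy()
    free = ~st.pinned
    if not free.any():
        return st
    act = st.active_edges()
    edges = st.edges[act]
    k = st.stiffness[act]
    L0 = st.rest_length[act]
    k2, k3 = params.k2, params.k3
    pos = st.positions.copy()
    free_idx = np.where(free)[0]

    def energy_grad(x: np.ndarray):
        pos[free_idx] = x.reshape(-1, 2)
        vec = pos[edges[:, 1]] - pos[edges[:, 0]]
        L = np.linalg.norm(vec, axis=1)
        eps = L - L0
        e = 0.5 * k * eps**2 + (k2 / 3.0) * eps**3 + (k3 / 4.0) * eps**4
        tension = k * eps + k2 * eps**2 + k3 * eps**3
        # dE/dr_a = tension * (r_a - r_b)/L
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(L[:, None] > 0, vec / L[:, None], 0.0)
        g = np.zeros_like(pos)
        contrib = tension[:, None] * unit
        np.add.at(g, edges[:, 0], -contrib)
        np.add.at(g, edges[:, 1], contrib)
        return float(e.sum()), g[free_idx].ravel()

    res = minimize(
        energy_grad, pos[free_idx].ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-16},
    )
    pos[free_idx] = res.x.reshape(-1, 2)
    _, g = energy_grad(res.x)
    residual = float(np.abs(g).max()) if g.size else 0.0
    if residual > max(100 * tol, 1e-6):
        raise RuntimeError(
            f"relaxation did not converge: max |force| = {residual:.3e}"
        )
    st.positions = pos
    st.prev_strain = st.strains()
    return st


def equilibrium_pre_strain(state: NetworkState, params: ModelParams) -> np.ndarray:
    """Per-edge strain at mechanical equilibrium with no source clamps.

    Pre-strain is the signature of rest-length-trained networks: learned
    rest lengths are mutually incompatible, so the relaxed geometry leaves
    residual edge strain even without any input. Stiffness-trained networks
    keep their original (compatible) rest lengths and show none.
    """
    st = state.copy()
    st.pinned[:] = False
    relaxed = relax(st, params)
    return relaxed.strains()
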