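"""Reading, writing and topological reduction of spatial tree reconstructions.

A reconstruction is a rooted tree embedded in 3-D Euclidean space: vertices
carry positions (conventionally in micrometres, though all downstream geometry
is unit-agnostic), an integer structure label (SWC type codes: 1 soma, 2 axon,
3 basal dendrite, 4 apical dendrite), a radius, and a parent link.  Two
carriers are supported: the standard 7-column SWC text format used by
Neuromorpho.org-style neuron reconstructions, and a generic edge-list format
(id, x, y, z, parent) for non-neuronal skeletons such as branching corals.

Sampled polylines are reduced to their topological skeleton --- root, branch
points and terminal tips --- before bifurcation extraction; degree-2 sample
points are collapsed into per-link chains that remain addressable for
"first segment" endpoint measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SOMA_LABEL = 1

__all__ = [
    "SpatialTree",
    "ReducedTree",
    "TreeValidationError",
    "SWCParseError",
    "read_swc",
    "read_edge_list",
    "write_swc",
    "reduce_topology",
    "filter_structure_types",
]


class TreeValidationError(ValueError):
    """The vertex/parent table does not describe a single valid rooted tree."""


class SWCParseError(ValueError):
    """A line of an input file could not be parsed; carries the line number."""


@dataclass
class SpatialTree:
    """A rooted tree embedded in 3-D space.

    Parameters
    ----------
    ids
        Integer vertex identifiers, unique, in file order.
    positions
        ``(n, 3)`` float array of coordinates.
    labels
        Integer structure codes (SWC convention; 0 when unknown).
    radii
        Non-negative radii (0 when unknown).
    parents
        Parent *identifier* per vertex; ``-1`` marks the root.
    """

    ids: np.ndarray
    positions: np.ndarray
    labels: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.ids)

    @property
    def root_id(self) -> int:
        return int(self.ids[self.parents == -1][0])

    def index_of(self, vertex_id: int) -> int:
        return self._index[int(vertex_id)]

    def position_of(self, vertex_id: int) -> np.ndarray:
        return self.positions[self.index_of(vertex_id)]

    def children_map(self) -> dict[int, list[int]]:
        """Map vertex id -> list of child ids, in file order."""
        out: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for vid, pid in zip(self.ids, self.parents):
            if pid != -1:
                out[int(pid)].append(int(vid))
        return out

    def edges(self) -> np.ndarray:
        """``(n-1, 2)`` array of (child index, parent index) pairs."""
        mask = self.parents != -1
        child_idx = np.nonzero(mask)[0]
        parent_idx = np.array([self._index[int(p)] for p in self.parents[mask]])
        return np.column_stack([child_idx, parent_idx])

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(
            self.positions[e[:, 0]] - self.positions[e[:, 1]], axis=1
        )

    def copy(self) -> "SpatialTree":
        return SpatialTree(
            self.ids.copy(),
            self.positions.copy(),
            self.labels.copy(),
            self.radii.copy(),
            self.parents.copy(),
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_vertices == 0:
            raise TreeValidationError("tree has no vertices")
        if len(np.unique(self.ids)) != self.n_vertices:
            seen: set[int] = set()
            for i in self.ids:
                if int(i) in seen:
                    raise TreeValidationError(f"duplicate vertex id {int(i)}")
                seen.add(int(i))
        if not np.all(np.isfinite(self.positions)):
            raise TreeValidationError("non-finite vertex position")
        if self.positions.shape != (self.n_vertices, 3):
            raise TreeValidationError("positions must be an (n, 3) array")
        roots = self.ids[self.parents == -1]
        if len(roots) == 0:
            raise TreeValidationError("no root vertex (parent == -1)")
        if len(roots) > 1:
            raise TreeValidationError(
                f"multiple roots: {', '.join(str(int(r)) for r in roots)}"
            )
        idset = self._index
        for vid, pid in zip(self.ids, self.parents):
            if pid != -1 and int(pid) not in idset:
                raise TreeValidationError(
                    f"vertex {int(vid)} references missing parent {int(pid)}"
                )
        # Acyclicity + connectivity: every vertex must reach the root by
        # parent links without revisiting itself.
        depth = {int(roots[0]): 0}
        for vid in self.ids:
            path = []
            v = int(vid)
            while v not in depth:
                path.append(v)
                v = int(self.parents[self._index[v]])
                if v in path:
                    raise TreeValidationError(f"cycle through vertex {v}")
            base = depth[v]
            for k, u in enumerate(reversed(path)):
                depth[u] = base + k + 1


@dataclass
class ReducedTree:
    """Topological skeleton of a :class:`SpatialTree`.

    ``nodes`` are the ids of the root, branch points (>= 2 children) and
    terminals of the original tree.  ``parent`` maps each non-root node to the
    nearest ancestral node.  ``chains[child]`` lists the degree-2 sample ids
    strictly between ``parent[child]`` and ``child``, ordered parent->child.
    """

    tree: SpatialTree
    nodes: list[int]
    parent: dict[int, int]
    chains: dict[int, list[int]]
    multifurcation_count: int

    def children_of(self, node_id: int) -> list[int]:
        return [c for c, p in self.parent.items() if p == node_id]

    @property
    def root_id(self) -> int:
        return self.tree.root_id

    def node_position(self, node_id: int) -> np.ndarray:
        return self.tree.position_of(node_id)

    def n_links(self) -> int:
        return len(self.parent)


# ---------------------------------------------------------------------------
# parsing


def _parse_rows(rows, path):
    ids, labels, pos, radii, parents = [], [], [], [], []
    for lineno, fields in rows:
        try:
            ids.append(int(fields[0]))
            labels.append(int(fields[1]))
            pos.append([float(fields[2]), float(fields[3]), float(fields[4])])
            radii.append(float(fields[5]))
            parents.append(int(fields[6]))
        except (ValueError, IndexError) as exc:
            raise SWCParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
    if not ids:
        raise SWCParseError(f"{path}: no vertices")
    return SpatialTree(
        np.array(ids), np.array(pos), np.array(labels), np.array(radii),
        np.array(parents),
    )


def read_swc(path) -> SpatialTree:
    """Read a standard 7-column SWC file into a validated :class:`SpatialTree`.

    Lines starting with ``#`` and blank lines are skipped.  Vertex order in
    the file is arbitrary (two-pass: the parent table is resolved only after
    all rows are read).  A parent of ``-1`` marks the root.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    return _parse_rows(rows, path)


def read_edge_list(path) -> SpatialTree:
    """Read a whitespace- or comma-separated edge list (id, x, y, z, parent).

    A header row is permitted and detected by a non-numeric first field.
    Parent empty or ``-1`` marks the root.  Labels default to 0, radii to 0.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace(",", " ").split() if f]
            if lineno == 1 or not rows:
                # allow one header row
                try:
                    int(fields[0])
                except ValueError:
                    continue
            if len(fields) < 4:
                raise SWCParseError(
                    f"{path}:{lineno}: expected id,x,y,z[,parent], got "
                    f"{len(fields)} fields"
                )
            if len(fields) == 4:
                fields = fields + ["-1"]
            # reorder into SWC column convention (id type x y z radius parent)
            rows.append(
                (lineno, [fields[0], "0", fields[1], fields[2], fields[3], "0",
                          fields[4] if fields[4] != "" else "-1"])
            )
    if not rows:
        raise SWCParseError(f"{path}: no vertices")
    return _parse_rows(rows, path)


def write_swc(tree: SpatialTree, path) -> None:
    """Write a :class:`SpatialTree` as SWC with 17-significant-digit floats,
    so a read/write round trip is lossless to double precision."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(tree.n_vertices):
            x, y, z = tree.positions[k]
            fh.write(
                f"{int(tree.ids[k])} {int(tree.labels[k])} "
                f"{x:.17g} {y:.17g} {z:.17g} "
                f"{tree.radii[k]:.17g} {int(tree.parents[k])}\n"
            )


# ---------------------------------------------------------------------------
# structure filtering and reduction


def filter_structure_types(tree: SpatialTree, types) -> SpatialTree:
    """Keep only vertices whose label is in ``types`` (soma and root always
    kept); any vertex whose parent is dropped is dropped with it."""
    allowed = set(int(t) for t in types)
    root = tree.root_id
    keep: set[int] = set()
    order = _topological_order(tree)
    for vid in order:
        k = tree.index_of(vid)
        pid = int(tree.parents[k])
        own = vid == root or int(tree.labels[k]) in allowed | {SOMA_LABEL}
        if own and (pid == -1 or pid in keep):
            keep.add(vid)
    mask = np.array([int(i) in keep for i in tree.ids])
    return SpatialTree(
        tree.ids[mask], tree.positions[mask], tree.labels[mask],
        tree.radii[mask], tree.parents[mask],
    )


def _topological_order(tree: SpatialTree) -> list[int]:
    children = tree.children_map()
    order, stack = [], [tree.root_id]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    return order


def reduce_topology(tree: SpatialTree) -> ReducedTree:
    """Collapse degree-2 sample points into chains between topological nodes.

    Nodes of the reduced tree are the root, every vertex with >= 2 children,
    and every terminal.  Vertices with more than 2 children are counted in
    ``multifurcation_count``; they remain nodes of the reduced tree but are
    never emitted as bifurcations downstream.
    """
    children = tree.children_map()
    root = tree.root_id
    nodes = [
        int(v) for v in _topological_order(tree)
        if v == root or len(children[v]) != 1
    ]
    node_set = set(nodes)
    parent: dict[int, int] = {}
    chains: dict[int, list[int]] = {}
    for v in nodes:
        if v == root:
            continue
        chain: list[int] = []
        u = int(tree.parents[tree.index_of(v)])
        while u not in node_set:
            chain.append(u)
            u = int(tree.parents[tree.index_of(u)])
        parent[v] = u
        chains[v] = chain[::-1]  # parent -> child order
    multi = sum(1 for v in nodes if len(children[v]) > 2)
    return ReducedTree(tree, nodes, parent, chains, multi)
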