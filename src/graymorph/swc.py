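"""SWC reconstruction I/O, validation and preprocessing.

The SWC format describes a neural reconstruction as a rooted tree of
labelled nodes.  Each data line carries seven whitespace-separated columns::

    id  type  x  y  z  radius  parent_id

with coordinates and radii in micrometres, radius (not diameter), and
``parent_id == -1`` marking the root.  Type codes follow the de-facto
convention: 1 = soma, 2 = axon, 3 = basal dendrite, 4 = apical dendrite,
>= 5 = custom (e.g. explicitly labelled spines).

This module reads and writes that format, removes axonal subtrees and
dendritic spines prior to morphometry, and runs the quality checks used to
reject unusable reconstructions (disconnected graphs, flat 2D traces,
constant nominal radii).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "SwcNode",
    "CellReconstruction",
    "ValidationReport",
    "SwcError",
    "MalformedLineError",
    "DuplicateNodeError",
    "DanglingParentError",
    "CycleError",
    "MultipleRootsError",
    "read_swc",
    "write_swc",
    "strip_axon",
    "strip_spines",
    "validate",
]

SOMA, AXON, BASAL_DENDRITE, APICAL_DENDRITE = 1, 2, 3, 4


class SwcError(ValueError):
    """Base class for SWC structural errors."""


class MalformedLineError(SwcError):
    """A data line has fewer than 7 columns or a non-numeric field."""


class DuplicateNodeError(SwcError):
    """Two data lines share the same node id."""


class DanglingParentError(SwcError):
    """A node references a parent id that does not exist."""


class CycleError(SwcError):
    """The node graph contains a cycle (not a tree)."""


class MultipleRootsError(SwcError):
    """More or fewer than exactly one root (parent_id = -1) node."""


@dataclass
class SwcNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None  # None for the root

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class CellReconstruction:
    """A rooted tree of SWC nodes; the universal input of the pipeline."""

    nodes: dict[int, SwcNode]
    root_id: int
    metadata: dict = field(default_factory=dict)

    @property
    def root(self) -> SwcNode:
        return self.nodes[self.root_id]

    def children_map(self) -> dict[int, list[int]]:
        """Adjacency: node id -> ordered child ids (file order)."""
        order = self.metadata.get("node_order")
        ids = order if order is not None else sorted(self.nodes)
        children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for nid in ids:
            node = self.nodes.get(nid)
            if node is not None and node.parent_id is not None:
                children[node.parent_id].append(nid)
        return children

    def n_nodes(self) -> int:
        return len(self.nodes)

    def coords(self) -> np.ndarray:
        order = self.metadata.get("node_order") or sorted(self.nodes)
        return np.array([self.nodes[i].xyz for i in order if i in self.nodes])

    def subtree_ids(self, start_id: int) -> list[int]:
        """All node ids in the subtree rooted at ``start_id`` (inclusive)."""
        children = self.children_map()
        out, stack = [], [start_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(children[nid])
        return out

    def copy(self) -> "CellReconstruction":
        return CellReconstruction(
            nodes={i: SwcNode(**vars(n)) for i, n in self.nodes.items()},
            root_id=self.root_id,
            metadata=dict(self.metadata),
        )


@dataclass
class ValidationReport:
    passed: bool
    issues: list[tuple[str, str, list[int]]]
    constant_radius_flag: bool

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "issues": [
                {"code": c, "message": m, "node_ids": ids} for c, m, ids in self.issues
            ],
            "constant_radius_flag": self.constant_radius_flag,
        }


def _parse_line(line: str, lineno: int) -> SwcNode:
    cols = line.split()
    if len(cols) < 7:
        raise MalformedLineError(
            f"line {lineno}: expected 7 columns, got {len(cols)}"
        )
    if len(cols) > 7:
        warnings.warn(f"line {lineno}: ignoring {len(cols) - 7} trailing column(s)")
    try:
        nid = int(cols[0])
        tcode = int(cols[1])
        x, y, z, r = (float(c) for c in cols[2:6])
        pid = int(cols[6])
    except ValueError as exc:
        raise MalformedLineError(f"line {lineno}: non-numeric field ({exc})") from exc
    return SwcNode(nid, tcode, x, y, z, r, None if pid < 0 else pid)


def read_swc(source: str | IO[str]) -> CellReconstruction:
    """Parse an SWC text stream into a :class:`CellReconstruction`.

    Accepts a string or an open text file.  ``#`` lines and blank lines are
    ignored; both spaces and tabs separate columns.  Units are taken as µm
    unchanged.  Raises a distinct :class:`SwcError` subclass for each
    structural defect (duplicate ids, dangling parents, cycles, malformed
    lines, not-exactly-one root).
    """
    text = source if isinstance(source, str) else source.read()
    nodes: dict[int, SwcNode] = {}
    order: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        node = _parse_line(line, lineno)
        if node.id in nodes:
            raise DuplicateNodeError(f"duplicate node id {node.id} (line {lineno})")
        nodes[node.id] = node
        order.append(node.id)
    if not nodes:
        raise MalformedLineError("no data lines in SWC source")

    roots = [n.id for n in nodes.values() if n.parent_id is None]
    for n in nodes.values():
        if n.parent_id is not None and n.parent_id not in nodes:
            raise DanglingParentError(
                f"node {n.id} references missing parent {n.parent_id}"
            )
    if len(roots) != 1:
        raise MultipleRootsError(f"expected exactly 1 root, found {len(roots)}")
    root_id = roots[0]

    # cycle / connectivity check by walking up from every node
    for n in nodes.values():
        seen = set()
        cur: int | None = n.id
        while cur is not None:
            if cur in seen:
                raise CycleError(f"cycle detected through node {cur}")
            seen.add(cur)
            cur = nodes[cur].parent_id

    cell = CellReconstruction(nodes=nodes, root_id=root_id, metadata={"node_order": order})
    if cell.root.type_code != SOMA:
        warnings.warn(f"root node {root_id} has type {cell.root.type_code}, not soma")
    return cell


def write_swc(cell: CellReconstruction, header: str | None = None) -> str:
    """Serialise a cell to SWC text.

    Node ids are renumbered 1..N in parent-before-child (preorder) order;
    coordinates and radii are printed with 17 significant digits so that a
    read/write round trip reproduces them exactly.
    """
    children = cell.children_map()
    new_id: dict[int, int] = {}
    lines: list[str] = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    stack = [cell.root_id]
    counter = 0
    while stack:
        nid = stack.pop()
        counter += 1
        new_id[nid] = counter
        n = cell.nodes[nid]
        pid = -1 if n.parent_id is None else new_id[n.parent_id]
        lines.append(
            f"{counter} {n.type_code} {n.x:.17g} {n.y:.17g} {n.z:.17g} "
            f"{n.radius:.17g} {pid}"
        )
        stack.extend(reversed(children[nid]))
    return "\n".join(lines) + "\n"


def _remove_ids(cell: CellReconstruction, ids: Iterable[int]) -> CellReconstruction:
    drop = set(ids)
    nodes = {i: n for i, n in cell.nodes.items() if i not in drop}
    meta = dict(cell.metadata)
    if meta.get("node_order"):
        meta["node_order"] = [i for i in meta["node_order"] if i not in drop]
    return CellReconstruction(nodes=nodes, root_id=cell.root_id, metadata=meta)


def strip_axon(cell: CellReconstruction) -> tuple[CellReconstruction, int]:
    """Remove every axonal (type 2) node together with its descendant subtree.

    Axonal reconstructions are typically absent or truncated, so the whole
    analysis is restricted to dendritic projections.  Returns the stripped
    cell and the number of nodes removed.
    """
    children = cell.children_map()
    drop: set[int] = set()
    stack = [cell.root_id]
    while stack:
        nid = stack.pop()
        if cell.nodes[nid].type_code == AXON:
            drop.update(cell.subtree_ids(nid))
        else:
            stack.extend(children[nid])
    out = _remove_ids(cell, drop)
    if out.n_nodes() <= 1:
        warnings.warn("axon removal left only the root node")
    return out, len(drop)


def strip_spines(
    cell: CellReconstruction,
    max_spine_length: float = 3.0,
    max_spine_radius: float = 0.3,
) -> tuple[CellReconstruction, int]:
    """Remove dendritic spines.

    A terminal side branch is classified as a spine when its total path
    length is <= ``max_spine_length`` µm, its mean node radius is
    <= ``max_spine_radius`` µm, and it attaches to a non-terminal dendritic
    node (so genuine short terminal tips of the dendrite proper are kept).
    Nodes whose type code is listed in ``metadata['spine_type_codes']`` are
    always removed.  Returns the cell and the number of spines removed.
    """
    children = cell.children_map()
    drop: set[int] = set()
    n_spines = 0

    explicit = set(cell.metadata.get("spine_type_codes", ()))
    if explicit:
        stack = [cell.root_id]
        while stack:
            nid = stack.pop()
            if cell.nodes[nid].type_code in explicit and nid != cell.root_id:
                sub = cell.subtree_ids(nid)
                drop.update(sub)
                n_spines += 1
            else:
                stack.extend(children[nid])

    # heuristic pass: short, thin, terminal side-branches
    for nid, kids in children.items():
        if nid == cell.root_id or nid in drop:
            continue
        if len(kids) < 2:
            continue  # spine must branch off a through-going dendrite
        for kid in kids:
            if kid in drop:
                continue
            sub = cell.subtree_ids(kid)
            if any(len(children[s]) > 1 for s in sub):
                continue  # side branch itself bifurcates: not a spine
            length = 0.0
            for s in sub:
                node = cell.nodes[s]
                parent = cell.nodes[node.parent_id]
                length += float(np.linalg.norm(node.xyz - parent.xyz))
            mean_r = float(np.mean([cell.nodes[s].radius for s in sub]))
            if length <= max_spine_length and mean_r <= max_spine_radius:
                drop.update(sub)
                n_spines += 1

    return _remove_ids(cell, drop), n_spines


def validate(cell: CellReconstruction) -> ValidationReport:
    """Quality-control a parsed cell.

    Checks connectivity, positive radii, genuine 3D extent (non-zero
    variance on all three axes) and flags reconstructions whose dendritic
    radii are all identical — the signature of a nominal fixed diameter
    rather than a measured one, which disqualifies the cell from
    radius-dependent morphometry.
    """
    issues: list[tuple[str, str, list[int]]] = []

    bad_r = [i for i, n in cell.nodes.items() if n.radius <= 0]
    if bad_r:
        issues.append(("nonpositive_radius", "nodes with radius <= 0", bad_r))

    # connectivity (all nodes reach the root)
    reachable = set(cell.subtree_ids(cell.root_id))
    orphans = [i for i in cell.nodes if i not in reachable]
    if orphans:
        issues.append(("disconnected", "nodes not reachable from root", orphans))

    coords = cell.coords()
    if len(coords) > 1:
        var = coords.var(axis=0)
        flat_axes = [ax for ax, v in zip("xyz", var) if v < 1e-12]
        if flat_axes:
            issues.append(
                ("not_3d", f"zero variance along axis {','.join(flat_axes)}", [])
            )

    dend_r = [
        n.radius for n in cell.nodes.values() if n.type_code != SOMA
    ]
    constant = len(dend_r) > 1 and math.isclose(min(dend_r), max(dend_r))
    if constant:
        issues.append(
            ("constant_radius", "all dendritic radii identical (nominal diameter)", [])
        )

    fatal = {"nonpositive_radius", "disconnected", "not_3d", "constant_radius"}
    passed = not any(code in fatal for code, _, _ in issues)
    return ValidationReport(passed=passed, issues=issues, constant_radius_flag=constant)
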