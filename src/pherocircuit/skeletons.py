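"""Neuron skeletons (SWC) and their point/tangent ("dot-properties") representation.

A traced neuron is a rooted tree of 3D nodes in a common registration space
(coordinates in micrometres).  For morphological comparison the tree topology is
discarded and the neuron is reduced to an unordered cloud of points, each
carrying the local heading of the neurite as a unit tangent vector estimated by
principal-component analysis of its spatial neighbourhood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NeuronSkeleton",
    "DotProps",
    "SkeletonError",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "resample_skeleton",
    "to_dotprops",
]

NODE_COLUMNS = ["node_id", "parent_id", "x", "y", "z", "radius"]

ROOT_PARENT = -1


class SkeletonError(ValueError):
    """Invalid skeleton structure (dangling parent, cycle, non-finite coordinate)."""


class SWCParseError(ValueError):
    """Malformed SWC content; message names the offending line number."""


@dataclass
class NeuronSkeleton:
    """Rooted tree (forest) of 3D nodes, typically parsed from an SWC file.

    ``nodes`` is a DataFrame with columns node_id, parent_id, x, y, z, radius;
    coordinates are micrometres.  ``space_tag`` names the registration space the
    coordinates live in; it is metadata only and never affects computation.
    """

    nodes: pd.DataFrame
    label: str = ""
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.nodes = pd.DataFrame(self.nodes, columns=NODE_COLUMNS).reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n = self.nodes
        ids = n["node_id"].to_numpy()
        if len(ids) == 0:
            raise SkeletonError("skeleton has no nodes")
        if len(np.unique(ids)) != len(ids):
            raise SkeletonError("node_ids are not unique")
        coords = n[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise SkeletonError("non-finite coordinate in skeleton")
        parents = n["parent_id"].to_numpy()
        id_set = set(int(i) for i in ids)
        for pid in parents:
            if int(pid) != ROOT_PARENT and int(pid) not in id_set:
                raise SkeletonError(f"dangling parent_id {int(pid)}")
        # cycle check: walk up from every node; a forest terminates at a root
        parent_of = dict(zip((int(i) for i in ids), (int(p) for p in parents)))
        state: dict[int, int] = {}  # 0=visiting, 1=done
        for start in parent_of:
            path = []
            node = start
            while node != ROOT_PARENT and state.get(node) != 1:
                if state.get(node) == 0:
                    raise SkeletonError("cycle detected in parent links")
                state[node] = 0
                path.append(node)
                node = parent_of[node]
            for v in path:
                state[v] = 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(float)

    def cable_length(self) -> float:
        """Total cable length (μm): sum of parent-child edge lengths."""
        n = self.nodes
        pos = {int(r.node_id): np.array([r.x, r.y, r.z]) for r in n.itertuples()}
        total = 0.0
        for r in n.itertuples():
            if int(r.parent_id) != ROOT_PARENT:
                total += float(np.linalg.norm(pos[int(r.node_id)] - pos[int(r.parent_id)]))
        return total


@dataclass
class DotProps:
    """Point cloud with unit tangent vectors — the input to the similarity score."""

    points: np.ndarray
    tangents: np.ndarray
    source_label: str = ""
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, float))
        if self.points.shape != self.tangents.shape or self.points.shape[1] != 3:
            raise ValueError("points and tangents must both be N x 3 with identical N")
        if len(self.points) < 1:
            raise ValueError("DotProps needs at least one point")
        if not (np.all(np.isfinite(self.points)) and np.all(np.isfinite(self.tangents))):
            raise ValueError("non-finite values in DotProps")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("tangents must be unit vectors (|norm - 1| <= 1e-6)")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.points, self.tangents]),
            columns=["x", "y", "z", "tx", "ty", "tz"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source_label: str = "") -> "DotProps":
        df = pd.read_csv(path)
        return cls(
            points=df[["x", "y", "z"]].to_numpy(float),
            tangents=df[["tx", "ty", "tz"]].to_numpy(float),
            source_label=source_label or str(path),
        )


def read_swc(path, label: str = "", space_tag: str = "") -> NeuronSkeleton:
    """Parse a 7-column SWC file (``#`` comments, parent -1 marks roots)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from exc
            rows.append((nid, pid, x, y, z, r))
    if not rows:
        raise SWCParseError("no data rows in SWC file")
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return NeuronSkeleton(nodes=nodes, label=label or str(path), space_tag=space_tag)


def write_swc(skel: NeuronSkeleton, path):
    """Write standard 7-column SWC.  read_swc(write_swc(s)) is identity on the node table."""
    skel.validate()
    with open(path, "w") as fh:
        fh.write(f"# {skel.label}\n# node_id type x y z radius parent_id\n")
        for r in skel.nodes.itertuples():
            fh.write(
                f"{int(r.node_id)} 0 {r.x:.17g} {r.y:.17g} {r.z:.17g} "
                f"{r.radius:.17g} {int(r.parent_id)}\n"
            )
    return path


def resample_skeleton(skel: NeuronSkeleton, step: float) -> NeuronSkeleton:
    """Subdivide every edge so no parent-child edge is longer than ``step`` μm.

    Original nodes (hence branch and end points) are kept exactly; intermediate
    nodes are linearly interpolated, so total cable length is conserved.  Node
    ids are rewritten 1..N in topological order.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    n = skel.nodes
    pos = {int(r.node_id): np.array([r.x, r.y, r.z]) for r in n.itertuples()}
    rad = {int(r.node_id): float(r.radius) for r in n.itertuples()}
    parent = {int(r.node_id): int(r.parent_id) for r in n.itertuples()}
    children: dict[int, list[int]] = {}
    roots = []
    for nid, pid in parent.items():
        if pid == ROOT_PARENT:
            roots.append(nid)
        else:
            children.setdefault(pid, []).append(nid)

    out_rows: list[tuple] = []
    new_id_of: dict[int, int] = {}
    counter = 0

    def add_node(xyz, radius, new_parent) -> int:
        nonlocal counter
        counter += 1
        out_rows.append((counter, new_parent, xyz[0], xyz[1], xyz[2], radius))
        return counter

    stack = [(r, ROOT_PARENT) for r in reversed(roots)]
    while stack:
        nid, new_parent = stack.pop()
        if new_parent == ROOT_PARENT:
            new_id_of[nid] = add_node(pos[nid], rad[nid], ROOT_PARENT)
        else:
            p_old = parent[nid]
            a, b = pos[p_old], pos[nid]
            length = float(np.linalg.norm(b - a))
            pieces = max(1, math.ceil(length / step - 1e-12))
            prev = new_parent
            for k in range(1, pieces):
                f = k / pieces
                prev = add_node(a + f * (b - a), rad[p_old] + f * (rad[nid] - rad[p_old]), prev)
            new_id_of[nid] = add_node(b, rad[nid], prev)
        for c in reversed(children.get(nid, [])):
            stack.append((c, new_id_of[nid]))

    nodes = pd.DataFrame(out_rows, columns=NODE_COLUMNS)
    return NeuronSkeleton(nodes=nodes, label=skel.label, space_tag=skel.space_tag)


def _canonical_sign(t: np.ndarray) -> np.ndarray:
    # first nonzero component made nonnegative (x, then y, then z)
    for c in t:
        if c > 0:
            return t
        if c < 0:
            return -t
    return t


def to_dotprops(skel: NeuronSkeleton, k_neighbors: int = 5) -> DotProps:
    """Convert a skeleton to its point/tangent representation.

    The tangent at each node is the first principal axis of the ``k_neighbors``
    nearest nodes (the node itself included), sign-normalized so the first
    nonzero component (x, then y, then z) is nonnegative.
    """
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    coords = skel.coords()
    if len(coords) < k_neighbors:
        raise ValueError(
            f"skeleton has {len(coords)} nodes, fewer than k_neighbors={k_neighbors}"
        )
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_neighbors)
    tangents = np.empty_like(coords)
    for i in range(len(coords)):
        nb = coords[idx[i]]
        centered = nb - nb.mean(axis=0)
        # first right-singular vector = dominant direction of the neighbourhood
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        tangents[i] = _canonical_sign(vt[0])
    return DotProps(
        points=coords,
        tangents=tangents,
        source_label=skel.label,
        space_tag=skel.space_tag,
    )
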