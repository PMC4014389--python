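"""SWC morphologies and the tree metrics used throughout the pipeline.

A granule-cell reconstruction is held as a :class:`MorphTree`: a rooted tree
of 3D points with radii following SWC semantics (structure codes 1 soma,
2 axon, 3 basal dendrite, 4 apical dendrite).  All distances are *path*
distances in micrometres, measured along the cable from the soma root, not
straight-line distances.  Basal dendrites and axons are retained when present
but carry no synapses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SWCParseError",
    "StructureError",
    "MorphTree",
    "DendriteSection",
    "read_swc",
    "write_swc",
    "path_distance",
    "max_dendritic_extent",
    "sectionize",
    "section_table",
]

# SWC structure codes
SOMA = 1
AXON = 2
BASAL = 3
APICAL = 4

_TAG_NAMES = {SOMA: "soma", AXON: "axon", BASAL: "basal_dendrite", APICAL: "apical_dendrite"}


class SWCParseError(ValueError):
    """Malformed SWC content (reported with the offending line number)."""


class StructureError(ValueError):
    """Tree-structure invariant violated (orphan parent, cycle, no soma...)."""


@dataclass
class MorphTree:
    """Rooted morphology: struct-of-arrays over nodes, root at index 0.

    Parameters
    ----------
    structure : (N,) int array of SWC structure codes.
    xyz : (N, 3) float array, micrometres.
    radius : (N,) float array, micrometres, > 0.
    parent : (N,) int array of *positional* parent indices; -1 for the root.
        Every non-root parent index is smaller than the child index.
    name : source name (file stem or generator label).
    population : one of {"mature", "young_control", "young_pilo", ""}.
    """

    structure: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    name: str = ""
    population: str = ""
    _pathlen: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.structure = np.asarray(self.structure, dtype=np.int32)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        n = len(self.structure)
        if self.xyz.shape != (n, 3) or len(self.radius) != n or len(self.parent) != n:
            raise StructureError("node arrays have inconsistent lengths")
        if n == 0:
            raise StructureError("empty morphology")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise StructureError(f"expected exactly one root at index 0, got roots {roots}")
        idx = np.arange(n)
        if np.any(self.parent[1:] >= idx[1:]):
            raise StructureError("parent indices must precede children (no cycles)")
        if np.any(self.radius <= 0):
            raise StructureError("all radii must be positive")
        if self.structure[0] != SOMA:
            raise StructureError("root node must be soma")

    # ---- basic metrics -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.structure)

    @property
    def soma_center(self) -> np.ndarray:
        return self.xyz[0]

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of the segment joining each node to its parent (root: 0)."""
        seg = np.zeros(self.n_nodes)
        p = self.parent[1:]
        seg[1:] = np.linalg.norm(self.xyz[1:] - self.xyz[p], axis=1)
        return seg

    def path_lengths(self) -> np.ndarray:
        """Path distance from the soma root to every node, micrometres."""
        if self._pathlen is None:
            seg = self.segment_lengths()
            out = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):
                out[i] = out[self.parent[i]] + seg[i]
            self._pathlen = out
        return self._pathlen

    def children_counts(self) -> np.ndarray:
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(cnt, self.parent[1:], 1)
        return cnt

    def is_dendrite(self) -> np.ndarray:
        return (self.structure == BASAL) | (self.structure == APICAL)

    def is_apical(self) -> np.ndarray:
        return self.structure == APICAL

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n_nodes + 1),
                "structure": self.structure,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent": np.where(self.parent < 0, -1, self.parent + 1),
            }
        )


@dataclass(frozen=True)
class DendriteSection:
    """Maximal unbranched run of dendritic nodes.

    ``nodes`` are positional indices ordered proximal -> distal; the proximal
    attachment point (soma or branch node) is not included in ``nodes``.
    ``path_start``/``path_end`` are path distances (µm from soma) of the
    section's proximal and distal ends.
    """

    section_id: int
    nodes: tuple
    path_start: float
    path_end: float
    parent_section: int  # -1 when attached at the soma
    structure: int       # BASAL or APICAL

    @property
    def length(self) -> float:
        return self.path_end - self.path_start


# ---- SWC I/O -----------------------------------------------------------


def read_swc(path, population: str = "", collapse_soma: bool = True) -> MorphTree:
    """Read a standard 7-column SWC file into a :class:`MorphTree`.

    Multi-point somas are collapsed to their centroid (with area-equivalent
    radius) so that path distances have a single, well-defined origin; nodes
    attached to any soma point re-attach to the collapsed root.
    """
    ids, structs, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                structs.append(int(parts[1]))
                xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
                radii.append(float(parts[5]))
                parents.append(int(parts[6]))
            except ValueError as exc:
                raise SWCParseError(f"{path}: line {lineno}: {exc}") from None
    if not ids:
        raise SWCParseError(f"{path}: no SWC records found")

    id_to_pos: dict[int, int] = {}
    for pos, i in enumerate(ids):
        if i in id_to_pos:
            raise StructureError(f"{path}: duplicate node id {i}")
        id_to_pos[i] = pos
    parent_pos = np.empty(len(ids), dtype=np.int64)
    for pos, p in enumerate(parents):
        if p == -1:
            parent_pos[pos] = -1
        else:
            if p not in id_to_pos:
                raise StructureError(f"{path}: node {ids[pos]} references absent parent {p}")
            parent_pos[pos] = id_to_pos[p]
            if parent_pos[pos] >= pos:
                raise StructureError(f"{path}: node {ids[pos]} precedes its parent {p}")

    structure = np.array(structs, dtype=np.int32)
    xyz = np.array(xyz, dtype=float)
    radius = np.array(radii, dtype=float)

    name = str(path).rsplit("/", 1)[-1].removesuffix(".swc")
    if collapse_soma and np.count_nonzero(structure == SOMA) > 1:
        structure, xyz, radius, parent_pos = _collapse_soma(structure, xyz, radius, parent_pos)
    return MorphTree(structure, xyz, radius, parent_pos, name=name, population=population)


def _collapse_soma(structure, xyz, radius, parent):
    soma_mask = structure == SOMA
    soma_idx = np.flatnonzero(soma_mask)
    centroid = xyz[soma_mask].mean(axis=0)
    # area-equivalent sphere radius for the merged soma
    r_eq = float(np.sqrt(np.mean(radius[soma_mask] ** 2)))
    keep = ~soma_mask
    old_to_new = np.full(len(structure), -1, dtype=np.int64)
    old_to_new[keep] = np.arange(1, keep.sum() + 1)
    soma_set = set(soma_idx.tolist())
    new_structure = np.concatenate([[SOMA], structure[keep]])
    new_xyz = np.vstack([centroid, xyz[keep]])
    new_radius = np.concatenate([[r_eq], radius[keep]])
    new_parent = np.empty(keep.sum() + 1, dtype=np.int64)
    new_parent[0] = -1
    for new_i, old_i in enumerate(np.flatnonzero(keep), start=1):
        p = parent[old_i]
        new_parent[new_i] = 0 if (p in soma_set or p < 0) else old_to_new[p]
    return new_structure, new_xyz, new_radius, new_parent


def write_swc(tree: MorphTree, path) -> None:
    """Write a :class:`MorphTree` as standard 7-column SWC."""
    with open(path, "w") as fh:
        fh.write(f"# {tree.name} population={tree.population}\n")
        for i in range(tree.n_nodes):
            p = -1 if tree.parent[i] < 0 else tree.parent[i] + 1
            x, y, z = tree.xyz[i]
            fh.write(
                f"{i + 1} {tree.structure[i]} {x:.6g} {y:.6g} {z:.6g} "
                f"{tree.radius[i]:.6g} {p}\n"
            )


# ---- metrics -----------------------------------------------------------


def path_distance(tree: MorphTree, node: int) -> float:
    """Path distance (µm) from the soma root to ``node`` (positional index)."""
    if not 0 <= node < tree.n_nodes:
        raise KeyError(f"node {node} not in tree of {tree.n_nodes} nodes")
    return float(tree.path_lengths()[node])


def max_dendritic_extent(tree: MorphTree) -> float:
    """Maximal path distance over apical dendritic terminal nodes, µm."""
    apical = tree.is_apical()
    if not apical.any():
        raise ValueError(f"{tree.name or 'tree'} has no apical dendritic nodes")
    terminals = tree.children_counts() == 0
    pick = apical & terminals
    if not pick.any():  # apical nodes exist but none terminal (soma-capped): use all apical
        pick = apical
    return float(tree.path_lengths()[pick].max())


def sectionize(tree: MorphTree) -> list[DendriteSection]:
    """Partition the dendritic nodes into maximal unbranched sections.

    Section boundaries are the soma, branch points (nodes with >= 2 children)
    and terminals.  A branch node closes the section it terminates; its
    children open new sections.  Every dendritic node belongs to exactly one
    section.
    """
    nchild = tree.children_counts()
    pl = tree.path_lengths()
    is_dend = tree.is_dendrite()
    children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i in range(1, tree.n_nodes):
        children[tree.parent[i]].append(i)

    sections: list[DendriteSection] = []
    # stack of (start_node, parent_section_id)
    stack = [(c, -1) for c in reversed(children[0]) if is_dend[c]]
    # also dendrite roots hanging off non-dendritic nodes (rare)
    for i in range(1, tree.n_nodes):
        p = tree.parent[i]
        if is_dend[i] and not is_dend[p] and p != 0:
            stack.append((i, -1))
    while stack:
        start, parent_sec = stack.pop()
        run = [start]
        node = start
        while nchild[node] == 1:
            nxt = children[node][0]
            if not is_dend[nxt]:
                break
            run.append(nxt)
            node = nxt
        sec_id = len(sections)
        p_start = pl[tree.parent[start]] if tree.parent[start] >= 0 else 0.0
        sections.append(
            DendriteSection(
                section_id=sec_id,
                nodes=tuple(run),
                path_start=float(p_start),
                path_end=float(pl[node]),
                parent_section=parent_sec,
                structure=int(tree.structure[start]),
            )
        )
        if nchild[node] >= 2:
            for c in reversed(children[node]):
                if is_dend[c]:
                    stack.append((c, sec_id))
    return sections


def section_table(tree: MorphTree) -> pd.DataFrame:
    """Section summary as a DataFrame (exportable to CSV)."""
    secs = sectionize(tree)
    return pd.DataFrame(
        {
            "section_id": [s.section_id for s in secs],
            "parent": [s.parent_section for s in secs],
            "structure": [_TAG_NAMES.get(s.structure, "other") for s in secs],
            "path_start": [s.path_start for s in secs],
            "path_end": [s.path_end for s in secs],
            "n_nodes": [len(s.nodes) for s in secs],
        }
    )
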