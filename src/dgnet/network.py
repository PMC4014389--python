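"""Dentate gyrus network construction.

Builds the ring-topology network (GC/BC/MC/HC with fixed efferent quotas),
adds recurrent mossy fiber sprouting (MFS) onto inner-molecular-layer sites
of neighbouring GCs, replaces random subsets of mature GCs with newborn
morphologies, and applies the two spine-loss wiring algorithms:

* **SL1** — every afferent edge onto a newborn PILO GC is deleted with the
  configured probability and re-targeted to a mature GC within the
  presynaptic cell's span, preserving each presynaptic out-degree exactly
  (divergence/convergence maintained).  At high newborn fractions no valid
  mature target remains and construction raises
  :class:`SpineLossInfeasibleError`.
* **SL2** — deletions are left uncompensated (in-degree of PILO cells drops,
  total edge count shrinks).

Construction is a pure function of (config, morphology pools, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .biophysics import (
    CellSpec,
    ChannelDensityTable,
    apply_spine_loss_membrane_correction,
    build_cell,
    build_prototype_cell,
    default_gc_table,
)
from .config import NetworkConfig, full_scale
from .layers import (
    LayerPartition,
    SynapseSite,
    branch_point_thresholds,
    classify_dendrites,
    compute_layer_partition,
    place_synapse_sites,
)
from .morphology import max_dendritic_extent

__all__ = [
    "Edge",
    "CellSlot",
    "NetworkGraph",
    "FamilySpec",
    "FAMILIES",
    "ConstructionError",
    "SpineLossInfeasibleError",
    "MorphologyPools",
    "default_pools",
    "build_base_network",
    "add_mossy_fiber_sprouting",
    "insert_newborn",
    "apply_spine_loss_wiring",
    "build_family_network",
    "degree_audit",
    "edge_table",
]


class ConstructionError(RuntimeError):
    pass


class SpineLossInfeasibleError(ConstructionError):
    """SL1 cannot maintain divergence/convergence (too few mature GCs)."""


@dataclass(frozen=True)
class Edge:
    pre: int          # global cell index; -1 for external (perforant path)
    post: int
    kind: str         # projection label, e.g. "MC->GC", "MFS", "PP->GC"
    receptor: str
    weight: float     # µS
    delay: float      # ms
    comp: int         # compartment index within the postsynaptic cell
    layer: str        # IML/MML/OML for GC molecular-layer sites; soma/dend else


@dataclass
class CellSlot:
    index: int
    cell_type: str              # GC/BC/MC/HC
    population: str             # mature/young_control/young_pilo ("" for interneurons)
    spec: CellSpec
    sites: list = None          # molecular-layer SynapseSite list (GCs only)
    ring: float = 0.0           # position on the unit ring


@dataclass
class NetworkGraph:
    cells: list
    edges: list
    config: NetworkConfig
    partition: LayerPartition       # mature-sample virtual molecular layer
    thresholds: dict                # population tag -> (t1, t2)
    seed: int
    mfs_percent: float = 0.0
    newborn_fraction: float = 0.0
    newborn_tag: str = ""
    spine_loss: str = ""            # "", "SL1", "SL2"
    spine_reduction: float = 0.0
    membrane_corrected: bool = False

    def counts(self) -> dict:
        out = {t: 0 for t in ("GC", "BC", "MC", "HC")}
        for c in self.cells:
            out[c.cell_type] += 1
        return out

    def indices(self, cell_type: str) -> list:
        return [c.index for c in self.cells if c.cell_type == cell_type]

    def gc_slots(self) -> list:
        return [c for c in self.cells if c.cell_type == "GC"]

    def copy(self) -> "NetworkGraph":
        out = copy.copy(self)
        out.cells = [copy.copy(c) for c in self.cells]
        out.edges = list(self.edges)
        return out


# ---- morphology pools --------------------------------------------------


@dataclass
class MorphologyPools:
    """Built cells and synapse-site tables per population, shared by slots."""

    trees: dict                    # tag -> list[MorphTree]
    specs: dict                    # tag -> list[CellSpec]
    sites: dict                    # tag -> list[list[SynapseSite]]
    partition: LayerPartition      # from the mature sample
    thresholds: dict               # tag -> (t1, t2)


def default_pools(
    seed: int,
    n_mature: int = 74,
    n_young: int = 20,
    table: ChannelDensityTable | None = None,
    iml_fraction: float = 0.17,
) -> MorphologyPools:
    """Generate the default synthetic samples and compile them to cells.

    Sample sizes mirror the study (74 mature, 20 newborn control, 20 newborn
    PILO).  Mature cells place synapses in the sample-average molecular
    layer; each newborn cell uses its own measured molecular-layer thickness.
    Newborn PILO cells are classified with the thresholds derived from the
    newborn-control sample.
    """
    from .synthetic import generate_population

    table = table or default_gc_table()
    trees = {
        "mature": generate_population("mature", n_mature, seed),
        "young_control": generate_population("young_control", n_young, seed),
        "young_pilo": generate_population("young_pilo", n_young, seed),
    }
    partition = compute_layer_partition(trees["mature"], iml_fraction)
    thr_m = branch_point_thresholds(trees["mature"])
    thr_y = branch_point_thresholds(trees["young_control"])
    thresholds = {"mature": thr_m, "young_control": thr_y, "young_pilo": thr_y}

    specs: dict = {}
    sites: dict = {}
    for tag, pool in trees.items():
        specs[tag] = []
        sites[tag] = []
        for t in pool:
            cm = classify_dendrites(t, thresholds[tag])
            spec = build_cell(t, cm, table)
            if tag == "mature":
                part = partition
            else:  # per-cell molecular layer for newborn models
                part = LayerPartition(max_dendritic_extent(t), partition.iml_fraction)
            specs[tag].append(spec)
            sites[tag].append(place_synapse_sites(t, part))
    return MorphologyPools(trees, specs, sites, partition, thresholds)


# ---- construction helpers ----------------------------------------------


def _span_window(center: float, n_post: int, span_fraction: float) -> np.ndarray:
    """Indices of the post ring inside the topographic window around center."""
    if span_fraction >= 1.0 or n_post <= 1:
        return np.arange(n_post)
    half = max(1, int(round(span_fraction * n_post / 2.0)))
    c = int(round(center * n_post))
    return np.unique((c + np.arange(-half, half + 1)) % n_post)


def _site_for(rng, slot: CellSlot, kind: str) -> tuple[int, str]:
    """(compartment, layer) for an edge of projection class ``kind``."""
    if slot.cell_type != "GC":
        if kind.split("->")[0] in ("BC", "HC"):  # inhibitory: perisomatic
            return 0, "soma"
        return int(rng.integers(1, slot.spec.n_comp)), "dend"
    sites = slot.sites or []
    by_layer = {L: [s for s in sites if s.layer == L] for L in ("IML", "MML", "OML")}
    pre = kind.split("->")[0]
    if kind == "PP->GC":
        prefs = ("OML",)        # strict: short cells receive no PP drive
    elif kind in ("MFS", "GC->GC"):
        prefs = ("IML",)        # sprouted mossy fibres land in the IML
    elif pre == "MC":
        prefs = ("IML", "MML", "OML")
    elif pre == "HC":
        prefs = ("OML", "MML", "IML")
    elif pre == "BC":
        return 0, "soma"
    else:
        prefs = ("IML", "MML", "OML")
    for L in prefs:
        if by_layer[L]:
            s: SynapseSite = by_layer[L][rng.integers(len(by_layer[L]))]
            return slot.spec.node_to_comp[s.node], L
    return -1, ""  # no eligible site


def build_base_network(
    pools: MorphologyPools,
    config: NetworkConfig | None = None,
    seed: int = 0,
) -> NetworkGraph:
    """Construct the all-mature ring network with exact efferent quotas.

    Pre- and postsynaptic partners and the specific dendritic site receiving
    each contact are raffled uniformly (within the projection's topographic
    span); at most one contact per ordered cell pair except MC->GC (and,
    later, sprouted GC->GC), which may carry multiplicity.
    """
    config = config or full_scale()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    scale = config.scale

    cells: list[CellSlot] = []
    idx = 0
    n_mat = len(pools.specs["mature"])
    for i in range(scale.n_gc):
        k = i % n_mat
        cells.append(
            CellSlot(idx, "GC", "mature", pools.specs["mature"][k],
                     sites=pools.sites["mature"][k], ring=i / scale.n_gc)
        )
        idx += 1
    for ctype, n in (("BC", scale.n_bc), ("MC", scale.n_mc), ("HC", scale.n_hc)):
        proto = build_prototype_cell(ctype)
        for j in range(n):
            cells.append(CellSlot(idx, ctype, "", proto, ring=(j + 0.5) / n))
            idx += 1

    by_type = {t: [c for c in cells if c.cell_type == t] for t in ("GC", "BC", "MC", "HC")}
    edges: list[Edge] = []
    for kind, par in config.projections.items():
        pre_t, post_t = kind.split("->")
        if par.quota <= 0 or kind == "GC->GC":
            continue  # sprouting is added separately
        posts = by_type[post_t]
        for pre_slot in by_type[pre_t]:
            window = _span_window(pre_slot.ring, len(posts), par.span_fraction)
            cand = [posts[i].index for i in window if posts[i].index != pre_slot.index]
            if not par.multi and len(cand) < par.quota:
                raise ConstructionError(
                    f"{kind}: quota {par.quota} unsatisfiable within span "
                    f"({len(cand)} candidates)"
                )
            if par.multi:
                chosen = rng.choice(cand, size=par.quota, replace=True)
            else:
                chosen = rng.choice(cand, size=par.quota, replace=False)
            for post_idx in chosen:
                post_slot = cells[post_idx]
                comp, layer = _site_for(rng, post_slot, kind)
                if comp < 0:
                    comp, layer = 0, "soma"  # degenerate fixture cells
                edges.append(
                    Edge(pre_slot.index, int(post_idx), kind, par.receptor,
                         par.weight, par.delay, comp, layer)
                )

    return NetworkGraph(
        cells=cells, edges=edges, config=config, partition=pools.partition,
        thresholds=pools.thresholds, seed=int(seed),
    )


def add_mossy_fiber_sprouting(
    net: NetworkGraph, mfs_percent: float, seed: int | None = None
) -> NetworkGraph:
    """Add ``round(mfs_percent/100 * max_sprout)`` GC->GC contacts per GC.

    Sprouted synapses land on inner-molecular-layer sites of ring-neighbour
    GCs; a GC may contact the same neighbour more than once.
    """
    if not 0 <= mfs_percent <= 100:
        raise ValueError("mfs_percent must be in [0, 100]")
    out = net.copy()
    out.mfs_percent = float(mfs_percent)
    n_sprout = round(mfs_percent / 100.0 * net.config.max_sprout)
    if n_sprout == 0:
        return out
    rng = np.random.default_rng(
        np.random.SeedSequence([net.seed if seed is None else int(seed), 202])
    )
    par = net.config.projections["GC->GC"]
    gcs = out.gc_slots()
    n_gc = len(gcs)
    for pre_slot in gcs:
        window = _span_window(pre_slot.ring, n_gc, par.span_fraction)
        cand = [gcs[i].index for i in window if gcs[i].index != pre_slot.index]
        if not cand:
            raise ConstructionError("MFS: no eligible neighbouring GC in span")
        for _ in range(n_sprout):
            comp = -1
            for _attempt in range(100):
                post_idx = int(rng.choice(cand))
                comp, layer = _site_for(rng, out.cells[post_idx], "MFS")
                if comp >= 0:
                    break
            if comp < 0:
                raise ConstructionError("MFS: no IML-eligible neighbour found")
            out.edges.append(
                Edge(pre_slot.index, post_idx, "MFS", par.receptor,
                     par.weight, par.delay, comp, layer)
            )
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def insert_newborn(
    net: NetworkGraph,
    fraction: float,
    tag: str,
    pools: MorphologyPools,
    seed: int | None = None,
) -> NetworkGraph:
    """Replace ``round(fraction * n_GC)`` mature GCs with newborn models.

    Replaced slots are chosen uniformly at random over the whole GC ring.
    Every afferent edge onto a replaced cell has its dendritic site re-drawn
    on the new morphology (using the newborn cell's own molecular-layer
    partition); cells too short for a band lose eligibility for the
    corresponding afferents (perforant-path eligibility is re-derived when
    stimulation is attached).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if tag not in ("young_control", "young_pilo"):
        raise KeyError(f"unknown newborn tag {tag!r}")
    out = net.copy()
    out.newborn_fraction = float(fraction)
    out.newborn_tag = tag
    n_replace = _round_half_up(fraction * len(out.gc_slots()))
    if n_replace == 0:
        return out
    rng = np.random.default_rng(
        np.random.SeedSequence([net.seed if seed is None else int(seed), 303])
    )
    gc_idx = [c.index for c in out.gc_slots()]
    chosen = rng.choice(gc_idx, size=n_replace, replace=False)
    pool_specs = pools.specs[tag]
    pool_sites = pools.sites[tag]
    order = rng.permutation(len(pool_specs))
    for j, ci in enumerate(sorted(int(c) for c in chosen)):
        k = order[j % len(pool_specs)]
        slot = out.cells[ci]
        slot.population = tag
        slot.spec = pool_specs[k]
        slot.sites = pool_sites[k]
    # re-draw dendritic sites of afferent edges onto replaced cells
    replaced = {int(c) for c in chosen}
    new_edges = []
    for e in out.edges:
        if e.post in replaced:
            comp, layer = _site_for(rng, out.cells[e.post], e.kind)
            if comp < 0:
                comp, layer = 0, "soma"
            e = replace(e, comp=comp, layer=layer)
        new_edges.append(e)
    out.edges = new_edges
    return out


def apply_spine_loss_wiring(
    net: NetworkGraph,
    mode: str,
    reduction: float,
    seed: int | None = None,
) -> NetworkGraph:
    """Thin afferent connections of newborn PILO GCs (spine loss).

    Spine loss removes dendritic synaptic sites, so every afferent edge onto
    a newborn PILO GC — mossy-cell, basket, HIPP and recurrent sprouted
    mossy-fibre contacts alike — is independently deleted with probability
    ``reduction`` (perforant-path synapses, attached at stimulation time, are
    thinned by the same rule there).  Under SL1 every deleted edge is
    re-targeted to a mature GC inside the presynaptic span not already
    contacted by that presynaptic cell (MC->GC and GC->GC keep their
    multiplicity exception), restoring presynaptic out-degrees exactly;
    running out of valid mature targets raises
    :class:`SpineLossInfeasibleError`.  Under SL2 deletions are
    uncompensated.
    """
    if mode not in ("SL1", "SL2"):
        raise ValueError("mode must be SL1 or SL2")
    if not 0 < reduction < 1:
        raise ValueError("reduction must be in (0, 1)")
    pilo = {c.index for c in net.gc_slots() if c.population == "young_pilo"}
    if not pilo:
        raise ConstructionError("network contains no newborn PILO GCs")
    rng = np.random.default_rng(
        np.random.SeedSequence([net.seed if seed is None else int(seed), 404])
    )
    out = net.copy()
    out.spine_loss = mode
    out.spine_reduction = float(reduction)

    mature_set = {c.index for c in out.gc_slots() if c.population == "mature"}
    gcs = out.gc_slots()
    n_gc = len(gcs)

    kept: list[Edge] = []
    deleted: list[Edge] = []
    for e in out.edges:
        if e.post in pilo and e.pre >= 0:
            if rng.random() < reduction:
                deleted.append(e)
                continue
        kept.append(e)

    if mode == "SL2":
        out.edges = kept
        return out

    # SL1: re-target every deleted edge to a mature GC in the span
    targets_of: dict[int, set] = {}
    for e in kept:
        targets_of.setdefault(e.pre, set()).add(e.post)
    for e in deleted:
        pre_slot = out.cells[e.pre]
        par = out.config.projections["GC->GC" if e.kind == "MFS" else e.kind]
        window = _span_window(pre_slot.ring, n_gc, par.span_fraction)
        cand = [gcs[i].index for i in window if gcs[i].index in mature_set]
        if not par.multi:
            used = targets_of.setdefault(e.pre, set())
            cand = [c for c in cand if c not in used]
        if not cand:
            raise SpineLossInfeasibleError(
                f"SL1: no mature GC available to re-target a {e.kind} edge "
                f"of cell {e.pre} (newborn fraction {net.newborn_fraction:.0%})"
            )
        post_idx = int(rng.choice(cand))
        comp, layer = _site_for(rng, out.cells[post_idx], e.kind)
        if comp < 0:
            comp, layer = 0, "soma"
        kept.append(replace(e, post=post_idx, comp=comp, layer=layer))
        targets_of.setdefault(e.pre, set()).add(post_idx)
    out.edges = kept
    return out


# ---- families ----------------------------------------------------------


FAMILIES = ("Mature", "MY", "MP", "MPSL1", "MPSL2", "MPSL1c", "MPSL2c")


@dataclass(frozen=True)
class FamilySpec:
    """One experimental condition: family name + sweep parameters.

    Spine-loss parameters act only in MPSL* families and the membrane
    correction only in the *c variants, mirroring the family table.
    """

    family: str
    newborn_fraction: float = 0.0
    mfs_percent: float = 10.0
    spine_reduction: float = 0.50
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 <= self.newborn_fraction <= 1:
            raise ValueError("newborn_fraction must be in [0, 1]")
        if self.family.startswith("MPSL") and not 0 < self.spine_reduction < 1:
            raise ValueError("spine_reduction must be in (0, 1) for MPSL* families")

    @property
    def newborn_tag(self) -> str | None:
        if self.family == "Mature":
            return None
        if self.family == "MY":
            return "young_control"
        return "young_pilo"

    @property
    def spine_mode(self) -> str | None:
        if self.family.startswith("MPSL1"):
            return "SL1"
        if self.family.startswith("MPSL2"):
            return "SL2"
        return None

    @property
    def membrane_correction(self) -> bool:
        return self.family.endswith("c")


def build_family_network(
    spec: FamilySpec,
    pools: MorphologyPools,
    config: NetworkConfig | None = None,
) -> NetworkGraph:
    """Assemble one network realisation of a family condition."""
    net = build_base_network(pools, config, seed=spec.seed)
    net = add_mossy_fiber_sprouting(net, spec.mfs_percent)
    if spec.newborn_tag and spec.newborn_fraction > 0:
        use_pools = pools
        if spec.membrane_correction:
            use_pools = _corrected_pools(pools, spec.newborn_tag)
        net = insert_newborn(net, spec.newborn_fraction, spec.newborn_tag, use_pools)
        if spec.spine_mode:
            net = apply_spine_loss_wiring(net, spec.spine_mode, spec.spine_reduction)
            net.membrane_corrected = spec.membrane_correction
    return net


def _corrected_pools(pools: MorphologyPools, tag: str) -> MorphologyPools:
    """Pools with spine-loss membrane corrections applied to one population."""
    specs = dict(pools.specs)
    specs[tag] = [apply_spine_loss_membrane_correction(s) for s in pools.specs[tag]]
    return MorphologyPools(pools.trees, specs, pools.sites, pools.partition, pools.thresholds)


# ---- audits ------------------------------------------------------------


def degree_audit(net: NetworkGraph) -> dict:
    """Degree tables: per-cell out/in-degree by projection plus multiplicity.

    Returns ``{"out": DataFrame, "in": DataFrame, "multiplicity": DataFrame}``
    where the out/in tables have one row per (cell, projection kind) and the
    multiplicity table counts ordered pairs by contact count.
    """
    if not net.edges:
        empty = pd.DataFrame(columns=["cell", "cell_type", "kind", "degree"])
        return {"out": empty, "in": empty.copy(),
                "multiplicity": pd.DataFrame(columns=["kind", "contacts", "n_pairs"])}
    df = pd.DataFrame(
        {
            "pre": [e.pre for e in net.edges],
            "post": [e.post for e in net.edges],
            "kind": [e.kind for e in net.edges],
        }
    )
    df = df[df.pre >= 0]  # exclude external (PP) drives
    type_of = {c.index: c.cell_type for c in net.cells}
    df["pre_type"] = df.pre.map(type_of)
    df["post_type"] = df.post.map(type_of)
    out = (
        df.groupby(["pre", "pre_type", "kind"]).size().reset_index(name="degree")
        .rename(columns={"pre": "cell", "pre_type": "cell_type"})
    )
    inn = (
        df.groupby(["post", "post_type", "kind"]).size().reset_index(name="degree")
        .rename(columns={"post": "cell", "post_type": "cell_type"})
    )
    mult = (
        df.groupby(["kind", "pre", "post"]).size().reset_index(name="contacts")
        .groupby(["kind", "contacts"]).size().reset_index(name="n_pairs")
    )
    return {"out": out, "in": inn, "multiplicity": mult}


def edge_table(net: NetworkGraph) -> pd.DataFrame:
    """Edge list for CSV export."""
    return pd.DataFrame(
        {
            "pre": [e.pre for e in net.edges],
            "post": [e.post for e in net.edges],
            "kind": [e.kind for e in net.edges],
            "receptor": [e.receptor for e in net.edges],
            "weight": [e.weight for e in net.edges],
            "delay": [e.delay for e in net.edges],
            "comp": [e.comp for e in net.edges],
            "layer": [e.layer for e in net.edges],
        }
    )
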