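"""Compartmental cell models: channel tables, cell construction, single-cell
excitability protocols.

Every granule cell in a run shares one :class:`ChannelDensityTable`: passive
properties and maximal channel densities per dendritic region (soma, GCLD,
PD, MD, DD — the pruned-distance-1 classes).  The numeric defaults are this
package's own conventions (HH-style Na/K mechanism set, see
:mod:`dgnet.engine`); they are chosen so granule cells rest stably near
-75 mV, spike with a rheobase in the tens-to-hundreds of pA, and preserve
the qualitative excitability contrast between large mature and small newborn
morphologies.  Dendritic membrane carries a spine load factor (higher Cm,
lower Rm than the soma); the spine-loss membrane correction removes it by
setting dendritic Rm and Cm equal to their somatic values.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import engine
from .layers import DendriteClassMap, LayerPartition
from .morphology import AXON, SOMA, MorphTree

__all__ = [
    "ChannelDensityTable",
    "CellSpec",
    "default_gc_table",
    "default_interneuron_table",
    "build_cell",
    "build_prototype_cell",
    "apply_spine_loss_membrane_correction",
    "simulate_cell",
    "rheobase",
    "synaptic_train_response",
    "RheobaseSearchError",
]

GC_REGIONS = ("soma", "GCLD", "PD", "MD", "DD")
_DENSITY_KEYS = ("na", "kdr", "kdr_slow", "ka")
_PASSIVE_KEYS = ("rm", "cm", "ra", "e_leak")


@dataclass
class ChannelDensityTable:
    """Per-region maximal conductances (S/cm²) and passive parameters.

    ``regions`` maps a region label to a dict with keys ``na``, ``kdr``,
    ``kdr_slow``, ``ka`` (S/cm²), ``rm`` (Ω·cm²), ``cm`` (µF/cm²), ``ra``
    (Ω·cm) and ``e_leak`` (mV).  Missing density keys default to 0.
    """

    regions: dict

    def __post_init__(self):
        for label, entry in self.regions.items():
            for k in _PASSIVE_KEYS:
                if k not in entry:
                    raise ValueError(f"region {label!r} missing passive key {k!r}")
            for k in _DENSITY_KEYS:
                entry.setdefault(k, 0.0)
                if entry[k] < 0:
                    raise ValueError(f"region {label!r}: conductance {k} must be >= 0")
            extra = set(entry) - set(_DENSITY_KEYS) - set(_PASSIVE_KEYS)
            if extra:
                raise ValueError(f"region {label!r}: unknown mechanism keys {sorted(extra)}")

    def require(self, labels) -> None:
        missing = [r for r in labels if r not in self.regions]
        if missing:
            raise KeyError(f"channel table missing regions {missing}")

    def copy(self) -> "ChannelDensityTable":
        return ChannelDensityTable(copy.deepcopy(self.regions))


def default_gc_table() -> ChannelDensityTable:
    """Granule-cell defaults: excitable soma, weakly excitable spiny dendrites."""
    soma = dict(na=0.15, kdr=0.08, kdr_slow=0.01, ka=0.002,
                rm=40000.0, cm=1.0, ra=200.0, e_leak=-75.0)
    gcld = dict(na=0.004, kdr=0.010, ka=0.004,
                rm=40000.0, cm=1.0, ra=200.0, e_leak=-75.0)
    spiny = dict(na=0.004, kdr=0.008, ka=0.006,
                 rm=25000.0, cm=1.6, ra=200.0, e_leak=-75.0)
    return ChannelDensityTable(
        {
            "soma": soma,
            "GCLD": gcld,
            "PD": dict(spiny),
            "MD": dict(spiny),
            "DD": dict(spiny),
            "basal": dict(rm=25000.0, cm=1.6, ra=200.0, e_leak=-75.0),
        }
    )


def default_interneuron_table(cell_type: str) -> ChannelDensityTable:
    """Reduced-model parameters for basket, mossy and HIPP cells."""
    if cell_type == "BC":  # fast-spiking perisomatic interneuron
        soma = dict(na=0.20, kdr=0.10, rm=10000.0, cm=1.0, ra=150.0, e_leak=-65.0)
        dend = dict(na=0.02, kdr=0.01, rm=10000.0, cm=1.0, ra=150.0, e_leak=-65.0)
    elif cell_type == "MC":  # hilar excitatory mossy cell, depolarised rest
        soma = dict(na=0.12, kdr=0.06, kdr_slow=0.002, ka=0.002,
                    rm=40000.0, cm=1.0, ra=150.0, e_leak=-62.0)
        dend = dict(na=0.015, kdr=0.008, rm=40000.0, cm=1.0, ra=150.0, e_leak=-62.0)
    elif cell_type == "HC":  # hilar perforant-path associated interneuron
        soma = dict(na=0.15, kdr=0.08, rm=30000.0, cm=1.0, ra=150.0, e_leak=-65.0)
        dend = dict(na=0.02, kdr=0.01, rm=30000.0, cm=1.0, ra=150.0, e_leak=-65.0)
    else:
        raise KeyError(f"unknown interneuron type {cell_type!r}")
    return ChannelDensityTable({"soma": soma, "dend": dend})


@dataclass
class CellSpec:
    """Simulable compartmental cell (one compartment per morphology node).

    ``node_to_comp`` maps morphology node indices to compartment indices
    (axonal nodes are dropped: axons are never simulated; conduction is
    represented by network-edge delays).  Fitted arrays are in engine units
    (nF, µS).
    """

    cell_type: str
    morphology: MorphTree | None
    classes: DendriteClassMap | None
    region: np.ndarray            # region label per compartment (object array)
    parent: np.ndarray
    area_cm2: np.ndarray
    rm: np.ndarray
    cm: np.ndarray
    ra: np.ndarray
    e_leak: np.ndarray
    density: dict                 # mechanism -> per-comp S/cm²
    g_ax: np.ndarray              # µS to parent
    node_to_comp: dict
    spine_corrected: bool = False
    name: str = ""

    @property
    def n_comp(self) -> int:
        return len(self.parent)

    @property
    def soma_comp(self) -> int:
        return 0

    def engine_arrays(self) -> dict:
        area = self.area_cm2
        out = {
            "parent": self.parent,
            "c_nf": self.cm * area * 1e3,
            "g_leak": area / self.rm * 1e6,
            "e_leak": self.e_leak,
            "g_ax": self.g_ax,
        }
        for mech in engine.MECHANISMS:
            out[f"g_{mech}"] = self.density[mech] * area * 1e6
        return out

    def copy(self) -> "CellSpec":
        return CellSpec(
            self.cell_type, self.morphology, self.classes,
            self.region.copy(), self.parent.copy(), self.area_cm2.copy(),
            self.rm.copy(), self.cm.copy(), self.ra.copy(), self.e_leak.copy(),
            {k: v.copy() for k, v in self.density.items()}, self.g_ax.copy(),
            dict(self.node_to_comp), self.spine_corrected, self.name,
        )

    def input_resistance(self) -> float:
        """Somatic DC input resistance (MΩ) of the passive skeleton."""
        g_total = float(np.sum(self.area_cm2 / self.rm))  # S, ignores axial drop
        return 1e-6 / g_total


def build_cell(
    tree: MorphTree,
    classes: DendriteClassMap,
    table: ChannelDensityTable,
    cell_type: str = "GC",
) -> CellSpec:
    """Compile a morphology + class map + channel table into a CellSpec.

    Each non-axonal morphology node becomes one compartment (the cylinder
    joining it to its parent; the soma root is a sphere).  Apical
    compartments take the parameters of their section's pruned-distance-1
    region; basal dendrites take the passive ``basal`` entry (or GCLD) and
    carry no synapses downstream.
    """
    table.require(["soma"] + sorted({lab for lab in classes.labels.values()}))
    from .morphology import sectionize

    sec_of_node = {}
    for sec in sectionize(tree):
        for nd in sec.nodes:
            sec_of_node[nd] = sec.section_id

    node_to_comp = {}
    region_labels = []
    parents = []
    lengths = []
    radii = []
    for i in range(tree.n_nodes):
        if tree.structure[i] == AXON:
            continue
        comp = len(region_labels)
        node_to_comp[i] = comp
        if i == 0:
            region_labels.append("soma")
            parents.append(-1)
            lengths.append(0.0)
        else:
            p = tree.parent[i]
            while p >= 0 and p not in node_to_comp:  # hop over dropped axon nodes
                p = tree.parent[p]
            parents.append(node_to_comp[p])
            seg = float(np.linalg.norm(tree.xyz[i] - tree.xyz[tree.parent[i]]))
            lengths.append(max(seg, 0.1))
            if tree.structure[i] == SOMA:
                region_labels.append("soma")
            else:
                sec_id = sec_of_node.get(i)
                if sec_id is not None and sec_id in classes.labels:
                    region_labels.append(classes.labels[sec_id])
                elif "basal" in table.regions:
                    region_labels.append("basal")
                else:
                    region_labels.append("GCLD")
        radii.append(float(tree.radius[i]))

    n = len(region_labels)
    region = np.array(region_labels, dtype=object)
    parent = np.array(parents, dtype=np.int64)
    radii = np.array(radii)
    lengths = np.array(lengths)
    area = np.empty(n)
    area[0] = 4.0 * math.pi * radii[0] ** 2 * 1e-8
    if n > 1:
        area[1:] = 2.0 * math.pi * radii[1:] * lengths[1:] * 1e-8

    rm = np.empty(n); cm = np.empty(n); ra = np.empty(n); e_leak = np.empty(n)
    density = {mech: np.zeros(n) for mech in engine.MECHANISMS}
    for i in range(n):
        entry = table.regions[region[i]]
        rm[i], cm[i], ra[i], e_leak[i] = (entry[k] for k in _PASSIVE_KEYS)
        for mech in engine.MECHANISMS:
            density[mech][i] = entry.get(mech, 0.0)

    g_ax = np.zeros(n)
    for i in range(1, n):
        r_axial = ra[i] * lengths[i] / (math.pi * radii[i] ** 2) * 1e4  # Ω
        g_ax[i] = 1e6 / r_axial  # µS

    return CellSpec(
        cell_type=cell_type, morphology=tree, classes=classes,
        region=region, parent=parent, area_cm2=area, rm=rm, cm=cm, ra=ra,
        e_leak=e_leak, density=density, g_ax=g_ax, node_to_comp=node_to_comp,
        name=tree.name,
    )


def build_prototype_cell(cell_type: str, table: ChannelDensityTable | None = None) -> CellSpec:
    """Reduced interneuron model: spherical soma plus two 2-compartment dendrites."""
    if table is None:
        table = default_interneuron_table(cell_type)
    soma_r, dend_r, dend_l = 7.0, 1.5, 75.0
    region = np.array(["soma", "dend", "dend", "dend", "dend"], dtype=object)
    parent = np.array([-1, 0, 1, 0, 3], dtype=np.int64)
    n = len(region)
    area = np.empty(n)
    area[0] = 4.0 * math.pi * soma_r**2 * 1e-8
    area[1:] = 2.0 * math.pi * dend_r * dend_l * 1e-8
    rm = np.empty(n); cm = np.empty(n); ra = np.empty(n); e_leak = np.empty(n)
    density = {mech: np.zeros(n) for mech in engine.MECHANISMS}
    for i in range(n):
        entry = table.regions[region[i]]
        rm[i], cm[i], ra[i], e_leak[i] = (entry[k] for k in _PASSIVE_KEYS)
        for mech in engine.MECHANISMS:
            density[mech][i] = entry.get(mech, 0.0)
    g_ax = np.zeros(n)
    for i in range(1, n):
        g_ax[i] = 1e6 / (ra[i] * dend_l / (math.pi * dend_r**2) * 1e4)
    return CellSpec(
        cell_type=cell_type, morphology=None, classes=None, region=region,
        parent=parent, area_cm2=area, rm=rm, cm=cm, ra=ra, e_leak=e_leak,
        density=density, g_ax=g_ax,
        node_to_comp={0: 0, 1: 1, 2: 2, 3: 3, 4: 4}, name=f"proto_{cell_type}",
    )


def apply_spine_loss_membrane_correction(cell: CellSpec) -> CellSpec:
    """Return a copy with dendritic Rm and Cm set to their somatic values.

    Removes the spine membrane load (the paper's indirect representation of
    reduced membrane area after spine loss).  Somatic parameters are left
    untouched.  Applying the correction twice is a warned no-op.
    """
    if cell.spine_corrected:
        warnings.warn("spine-loss membrane correction already applied; no-op")
        return cell
    out = cell.copy()
    soma_rm = cell.rm[cell.soma_comp]
    soma_cm = cell.cm[cell.soma_comp]
    dend = out.region != "soma"
    out.rm[dend] = soma_rm
    out.cm[dend] = soma_cm
    out.spine_corrected = True
    return out


# ---- single-cell protocols --------------------------------------------


class RheobaseSearchError(RuntimeError):
    pass


def simulate_cell(
    cell: CellSpec,
    duration: float,
    dt: float = 0.1,
    injections: list | None = None,
    stim_synapses: list | None = None,
    v_thresh: float = 0.0,
    record: np.ndarray | None = None,
):
    """Integrate one cell. ``injections``: (comp, nA, t_on, t_off).
    ``stim_synapses``: (comp, w_uS, tau_r, tau_d, e_rev, [activation times ms])."""
    injections = injections or []
    stim_synapses = stim_synapses or []
    syn_target, syn_w, tau_r, tau_d, e_rev = [], [], [], [], []
    ev = []
    for si, (comp_i, w, tr, td, er, times) in enumerate(stim_synapses):
        syn_target.append(comp_i); syn_w.append(w)
        tau_r.append(tr); tau_d.append(td); e_rev.append(er)
        for tt in times:
            ev.append((int(round(tt / dt)), si))
    ev.sort()
    synapses = {
        "target": np.array(syn_target, dtype=np.int64),
        "w": np.array(syn_w), "tau_r": np.array(tau_r) if tau_r else np.array([1.0]),
        "tau_d": np.array(tau_d) if tau_d else np.array([2.0]),
        "e_rev": np.array(e_rev),
    }
    if not syn_target:
        synapses = {"target": np.empty(0, dtype=np.int64), "w": np.empty(0),
                    "tau_r": np.empty(0), "tau_d": np.empty(0), "e_rev": np.empty(0)}
    events = {
        "out_ptr": np.zeros(2, dtype=np.int64),
        "out_edge": np.empty(0, dtype=np.int64),
        "delay_steps": np.zeros(len(syn_target), dtype=np.int64),
        "ext_step": np.array([s for s, _ in ev], dtype=np.int64),
        "ext_edge": np.array([e for _, e in ev], dtype=np.int64),
    }
    inj = {
        "comp": np.array([i[0] for i in injections], dtype=np.int64),
        "amp_nA": np.array([i[1] for i in injections], dtype=float),
        "t_on": np.array([i[2] for i in injections], dtype=float),
        "t_off": np.array([i[3] for i in injections], dtype=float),
    }
    spikes, rec, v = engine.simulate(
        cell.engine_arrays(), {"soma_comp": np.array([0], dtype=np.int64)},
        synapses, events, inj, duration, dt, v_thresh=v_thresh, record=record,
    )
    return spikes[0], rec, v


def proximal_injection_comp(cell: CellSpec) -> int:
    """Compartment for the rheobase step: a proximal-dendrite (PD) location.

    Preferred: the most proximal PD-region compartment.  Cells whose tree
    never leaves the granule cell layer before branching may lack PD
    sections; then the dendritic compartment nearest the PD band midpoint is
    used.
    """
    pd = np.flatnonzero(cell.region == "PD")
    if len(pd):
        return int(pd[0])
    dend = np.flatnonzero(cell.region != "soma")
    if not len(dend):
        raise ValueError("cell has no dendritic compartments")
    return int(dend[0])


def distal_site_comp(cell: CellSpec, partition: LayerPartition | None = None) -> int:
    """Compartment for the synaptic-train protocol: the most distal dendrite.

    Raises ``ValueError`` when the cell does not reach the outer molecular
    layer of ``partition`` (protocol inapplicable for short newborn cells).
    """
    tree = cell.morphology
    if tree is None:
        raise ValueError("prototype cells have no distal-dendrite protocol")
    pl = tree.path_lengths()
    comps = np.array(sorted(cell.node_to_comp))
    dend_nodes = [nd for nd in comps if cell.region[cell.node_to_comp[nd]] != "soma"]
    if not dend_nodes:
        raise ValueError("cell has no dendritic compartments")
    far = max(dend_nodes, key=lambda nd: pl[nd])
    if partition is not None and pl[far] < partition.oml[0]:
        raise ValueError(
            f"{cell.name}: dendrites do not reach the outer molecular layer "
            f"({pl[far]:.1f} µm < {partition.oml[0]:.1f} µm)"
        )
    return int(cell.node_to_comp[far])


def rheobase(
    cell: CellSpec,
    comp: int | None = None,
    duration: float = 500.0,
    tol_nA: float = 0.001,
    upper_nA: float = 2.0,
    dt: float = 0.1,
) -> float:
    """Minimal 500-ms depolarising step at a proximal dendrite evoking a spike.

    Bisection over [0, ``upper_nA``] to ``tol_nA`` (default 1 pA).  Raises
    :class:`RheobaseSearchError` when even the upper bound is subthreshold.
    """
    if comp is None:
        comp = proximal_injection_comp(cell)
    t_on, margin = 10.0, 40.0
    total = t_on + duration + margin

    def n_spikes(amp):
        spk, _, _ = simulate_cell(cell, total, dt, injections=[(comp, amp, t_on, t_on + duration)])
        return len(spk)

    if n_spikes(upper_nA) == 0:
        raise RheobaseSearchError(
            f"{cell.name}: no spike at search upper bound {upper_nA} nA"
        )
    lo, hi = 0.0, upper_nA
    while hi - lo > tol_nA:
        mid = 0.5 * (lo + hi)
        if n_spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def synaptic_train_response(
    cell: CellSpec,
    comp: int | None = None,
    g_syn_uS: float = 0.03,
    n_pulses: int = 10,
    interval: float = 100.0,
    duration: float = 1000.0,
    partition: LayerPartition | None = None,
    dt: float = 0.1,
) -> int:
    """Somatic spike count for 10 synaptic-like pulses (100 ms apart) at a
    distal dendrite over 1000 ms."""
    if comp is None:
        comp = distal_site_comp(cell, partition)
    times = [5.0 + k * interval for k in range(n_pulses)]
    spk, _, _ = simulate_cell(
        cell, duration, dt,
        stim_synapses=[(comp, g_syn_uS, 0.5, 8.0, 0.0, times)],
    )
    return len(spk)
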