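"""Perforant-path stimulation, network integration and replicate batches.

The stimulation protocol is the focal entorhinal drive of the original
network study: a single synchronous synaptic-like activation delivered at
``onset`` to the perforant-path synapses of the first 100 GCs (scaled with
the network) and to the basket cells.  Perforant-path synapses sit on OML
dendritic sites, so newborn GCs whose dendrites do not reach the outer
molecular layer receive no direct drive even when they fall inside the
stimulated range.

``run_batch`` re-raffles the connectivity anew for every replicate (the
connection pattern is never reused between simulations) and records
construction infeasibility (SL1 at high newborn fractions) as missing rows
rather than failing the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .config import NetworkConfig
from .network import (
    Edge,
    FamilySpec,
    MorphologyPools,
    NetworkGraph,
    SpineLossInfeasibleError,
    build_family_network,
)

__all__ = ["StimulusProtocol", "SimResult", "attach_pp_stimulation", "run", "run_batch"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Focal perforant-path stimulation protocol."""

    n_stimulated_gc: int = 100      # the first N GCs on the ring
    stimulate_bc: bool = True
    onset: float = 5.0              # ms
    duration: float = 300.0         # ms simulated
    dt: float = 0.1                 # ms

    def __post_init__(self):
        if self.n_stimulated_gc <= 0:
            raise ValueError("stimulated GC range must be non-empty")
        if self.dt <= 0 or not self.onset < self.duration:
            raise ValueError("require dt > 0 and onset < duration")

    def scaled(self, net: NetworkGraph) -> int:
        """Stimulated GC count scaled to the network (100 of 500 by default)."""
        n_gc = len(net.gc_slots())
        return min(n_gc, max(1, round(self.n_stimulated_gc * n_gc / 500)))


@dataclass
class SimResult:
    """Per-cell spike times plus protocol and family metadata."""

    spikes: list                    # list of np.ndarray, ms, per cell index
    duration: float                 # ms
    dt: float
    cell_types: list
    populations: list
    protocol: StimulusProtocol
    seed: int
    family: str = ""
    newborn_fraction: float = 0.0
    mfs_percent: float = 0.0
    n_stimulated: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))


def attach_pp_stimulation(
    net: NetworkGraph, protocol: StimulusProtocol, seed: int | None = None
) -> NetworkGraph:
    """Add perforant-path drive edges (pre index -1) to the network.

    The entorhinal volley is spatially distributed: each of the first N GCs
    receives one PP synapse at every OML site it possesses; OML-less cells in
    the range receive none (a warning covers the all-skipped case).  Basket
    cells receive PP drive on a dendrite.  Attaching a protocol twice
    replaces the previous PP edges.

    When the network carries spine loss, perforant-path synapses (which land
    on OML spines) are thinned like the other afferents of newborn PILO GCs:
    each PP synapse onto a PILO cell is dropped with the configured
    reduction probability; under SL1 the dropped synapse is re-assigned to an
    OML site of a mature GC in the stimulated range, preserving the PP
    divergence.
    """
    out = net.copy()
    out.edges = [e for e in out.edges if e.pre >= 0]
    rng = np.random.default_rng(
        np.random.SeedSequence([net.seed if seed is None else int(seed), 505])
    )
    cfg = net.config
    n_stim = protocol.scaled(net)
    gcs = net.gc_slots()[:n_stim]
    mature_oml = [
        (slot, s) for slot in gcs if slot.population == "mature"
        for s in (slot.sites or []) if s.layer == "OML"
    ]
    n_skipped = 0
    for slot in gcs:
        oml = [s for s in (slot.sites or []) if s.layer == "OML"]
        if not oml:
            n_skipped += 1
            continue
        for s in oml:
            tgt_slot, tgt_site = slot, s
            if (
                net.spine_loss
                and slot.population == "young_pilo"
                and rng.random() < net.spine_reduction
            ):
                if net.spine_loss == "SL2" or not mature_oml:
                    continue
                tgt_slot, tgt_site = mature_oml[rng.integers(len(mature_oml))]
            out.edges.append(
                Edge(-1, tgt_slot.index, "PP->GC", "AMPA", cfg.pp_weight_gc,
                     cfg.pp_delay, tgt_slot.spec.node_to_comp[tgt_site.node], "OML")
            )
    if n_skipped == len(gcs):
        warnings.warn("no stimulated GC reaches the outer molecular layer; "
                      "no direct PP drive attached to GCs")
    if protocol.stimulate_bc:
        for slot in (c for c in net.cells if c.cell_type == "BC"):
            comp = int(rng.integers(1, slot.spec.n_comp))
            out.edges.append(
                Edge(-1, slot.index, "PP->BC", "AMPA", cfg.pp_weight_bc,
                     cfg.pp_delay, comp, "dend")
            )
    return out


def _compile(net: NetworkGraph, protocol: StimulusProtocol):
    """Flatten the network into engine arrays."""
    offsets = np.zeros(len(net.cells) + 1, dtype=np.int64)
    for i, slot in enumerate(net.cells):
        offsets[i + 1] = offsets[i] + slot.spec.n_comp
    n_comp = int(offsets[-1])

    comp = {k: np.empty(n_comp) for k in
            ("c_nf", "g_leak", "e_leak", "g_ax", "g_na", "g_kdr", "g_kdr_slow", "g_ka")}
    comp["parent"] = np.empty(n_comp, dtype=np.int64)
    for i, slot in enumerate(net.cells):
        arr = slot.spec.engine_arrays()
        sl = slice(offsets[i], offsets[i + 1])
        par = arr["parent"].copy()
        par[par >= 0] += offsets[i]
        comp["parent"][sl] = par
        for k in ("c_nf", "g_leak", "e_leak", "g_ax", "g_na", "g_kdr", "g_kdr_slow", "g_ka"):
            comp[k][sl] = arr[k]

    dt = protocol.dt
    rec_par = net.config.receptors
    target, w, tau_r, tau_d, e_rev, delay_steps, pre = [], [], [], [], [], [], []
    ext = []  # (step, edge_index) for external PP activations
    onset_step = int(round(protocol.onset / dt))
    for e in net.edges:
        tr, td, er = rec_par[e.receptor]
        ei = len(target)
        target.append(offsets[e.post] + e.comp)
        w.append(e.weight)
        tau_r.append(tr)
        tau_d.append(td)
        e_rev.append(er)
        delay_steps.append(int(round(e.delay / dt)))
        pre.append(e.pre)
        if e.pre < 0:
            ext.append((onset_step + int(round(e.delay / dt)), ei))
    ext.sort()

    n_cell = len(net.cells)
    out_lists: list[list[int]] = [[] for _ in range(n_cell)]
    for ei, p in enumerate(pre):
        if p >= 0:
            out_lists[p].append(ei)
    out_ptr = np.zeros(n_cell + 1, dtype=np.int64)
    for ci in range(n_cell):
        out_ptr[ci + 1] = out_ptr[ci] + len(out_lists[ci])
    out_edge = np.array([e for lst in out_lists for e in lst], dtype=np.int64)

    synapses = {
        "target": np.array(target, dtype=np.int64), "w": np.array(w),
        "tau_r": np.array(tau_r), "tau_d": np.array(tau_d), "e_rev": np.array(e_rev),
    }
    events = {
        "out_ptr": out_ptr, "out_edge": out_edge,
        "delay_steps": np.array(delay_steps, dtype=np.int64),
        "ext_step": np.array([s for s, _ in ext], dtype=np.int64),
        "ext_edge": np.array([e for _, e in ext], dtype=np.int64),
    }
    cells = {"soma_comp": offsets[:-1].copy()}
    return comp, cells, synapses, events


def run(
    net: NetworkGraph,
    protocol: StimulusProtocol | None = None,
    seed: int | None = None,
) -> SimResult:
    """Attach stimulation, integrate, and collect the spike record.

    Deterministic given (network, protocol, seed, dt).
    """
    protocol = protocol or StimulusProtocol()
    seed = net.seed if seed is None else int(seed)
    stim_net = attach_pp_stimulation(net, protocol, seed=seed)
    comp, cells, synapses, events = _compile(stim_net, protocol)
    inj = {"comp": np.empty(0, dtype=np.int64), "amp_nA": np.empty(0),
           "t_on": np.empty(0), "t_off": np.empty(0)}
    spikes, _, _ = engine.simulate(
        comp, cells, synapses, events, inj, protocol.duration, protocol.dt
    )
    n_stim = len({e.post for e in stim_net.edges if e.kind == "PP->GC"})
    return SimResult(
        spikes=spikes, duration=protocol.duration, dt=protocol.dt,
        cell_types=[c.cell_type for c in net.cells],
        populations=[c.population for c in net.cells],
        protocol=protocol, seed=seed,
        family="", newborn_fraction=net.newborn_fraction,
        mfs_percent=net.mfs_percent, n_stimulated=n_stim,
    )


def replicate_seed(base_seed: int, fraction_index: int, rep: int) -> int:
    """Derivable per-replicate seed (full provenance from the base seed)."""
    ss = np.random.SeedSequence([int(base_seed), fraction_index, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def run_batch(
    family: str,
    fractions,
    pools: MorphologyPools,
    config: NetworkConfig | None = None,
    protocol: StimulusProtocol | None = None,
    n_rep: int = 20,
    base_seed: int = 0,
    mfs_percent: float = 10.0,
    spine_reduction: float = 0.50,
) -> pd.DataFrame:
    """Replicate sweep of one family over newborn fractions.

    Connectivity is re-raffled before every simulation.  Rows where SL1
    construction is infeasible carry ``feasible=False`` and NaN frequency.
    """
    from .analysis import overall_frequency

    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    protocol = protocol or StimulusProtocol()
    rows = []
    for fi, frac in enumerate(fractions):
        for rep in range(n_rep):
            seed = replicate_seed(base_seed, fi, rep)
            spec = FamilySpec(
                family=family, newborn_fraction=float(frac),
                mfs_percent=mfs_percent, spine_reduction=spine_reduction, seed=seed,
            )
            try:
                net = build_family_network(spec, pools, config)
            except SpineLossInfeasibleError as exc:
                rows.append(dict(
                    family=family, fraction=float(frac), replicate=rep, seed=seed,
                    feasible=False, overall_frequency=np.nan, n_active_gc=0,
                    spikes_mature=0, spikes_newborn=0, note=str(exc)[:80],
                ))
                continue
            res = run(net, protocol, seed=seed)
            res.family = family
            gc_mask = np.array([t == "GC" for t in res.cell_types])
            active = sum(1 for i, s in enumerate(res.spikes) if gc_mask[i] and len(s))
            spk_mat = sum(len(res.spikes[i]) for i in range(res.n_cells)
                          if gc_mask[i] and res.populations[i] == "mature")
            spk_new = sum(len(res.spikes[i]) for i in range(res.n_cells)
                          if gc_mask[i] and res.populations[i] in
                          ("young_control", "young_pilo"))
            rows.append(dict(
                family=family, fraction=float(frac), replicate=rep, seed=seed,
                feasible=True, overall_frequency=overall_frequency(res),
                n_active_gc=active, spikes_mature=spk_mat, spikes_newborn=spk_new,
                note="",
            ))
    return pd.DataFrame(rows)
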