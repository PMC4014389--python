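# dgnet

Network simulation of dentate gyrus (DG) hyperexcitability after *status
epilepticus*: morphologically detailed granule cells embedded in the
classic 1:2000 ring-topology DG circuit, with mossy fiber sprouting (MFS),
graded replacement of mature granule cells by newborn cells (control or
pilocarpine morphotypes), and two spine-loss wiring algorithms.

## Who this is for

Computational neuroscientists studying epileptogenesis in the dentate
gyrus: how seizure-induced anatomical changes — recurrent GC→GC excitation
(MFS), altered apical dendritic trees of adult-born granule cells, and
dendritic spine loss — interact to raise or curb the excitability of the
circuit. The package builds, simulates and analyses these networks entirely
from code: a synthetic morphology generator stands in for downloaded
reconstructions, so everything runs offline and reproducibly from a seed
(user-supplied SWC reconstructions are supported as a drop-in).

## The model

**Cells.** Each granule cell (GC) is a multicompartment conductance-based
model built from an SWC morphology: one compartment per reconstruction
point, passive parameters and Hodgkin–Huxley-style channels (Na, fast
delayed-rectifier K, a slow M-like K current providing spike-frequency
adaptation, A-type K) with densities assigned per dendritic region. Regions
follow the pruned-distance-1 criterion: every apical section is labelled
GCLD / PD / MD / DD (granule-cell-layer, proximal, medial, distal dendrite)
by the path distance from the soma to its branching point, against
thresholds `t1 < t2`. Basket (BC), mossy (MC) and HIPP (HC) cells are
reduced compartmental models. Integration is backward Euler on the cable
tree (Hines elimination) with dt = 0.1 ms, accelerated with numba.

**Synapse geography.** A virtual molecular layer of thickness
*T* = mean maximal dendritic extent of the mature sample is split into
IML = [0, 0.17 T), and MML / OML as equal halves of the remaining 83%.
Synapses sit at the midpoint of each section's intra-band portion.
Perforant-path (PP) input lands only on OML sites, sprouted mossy fibres
only on IML sites — independently of the PD/MD/DD class. Newborn cells use
their own measured molecular-layer thickness; cells too short to reach the
OML receive no PP drive.

**Network.** 500 GC, 6 BC, 15 MC, 6 HC on a ring with fixed efferent
quotas (MC→200 GC, 1 BC, 2 HC, 3 MC; HC→160 GC, 4 BC, 4 MC; BC→100 GC,
3 MC, 2 BC; GC→1 MC, 1 BC, 2 HC); partners and dendritic sites are
raffled anew before every simulation. MFS at level *p*% adds
`round(p/100 × 100)` GC→GC contacts per GC onto IML sites of ring
neighbours. Newborn substitution replaces a random fraction of GC slots
with newborn morphologies. Spine loss deletes each afferent synapse of a
newborn pilocarpine (PILO) GC with probability 25/50/75%; **SL1**
re-targets every deletion to a mature GC (preserving convergence and
divergence — infeasible above ~80% newborn fraction), **SL2** leaves the
loss uncompensated. The excitability readout is the **overall frequency**:
total spikes of all cells divided by the simulation time, averaged over 20
re-wired replicates per condition and compared by two-way ANOVA (α = 0.01).

## Worked example

Simulate one focal perforant-path stimulation on the 1/5-GC-scale preset,
first on the healthy mature network, then with 10% MFS plus 50% newborn
control GCs:

```bash
dgsim run --preset desk --family Mature --fraction 0 --mfs 0  --seed 2 --out base
dgsim run --preset desk --family MY     --fraction 0.5 --mfs 10 --seed 2 --out combo
```

which prints (plus `spikes.txt` and `manifest.json` under each output
directory):

```
{"family": "Mature", "fraction": 0.0, "mfs_percent": 0.0, "seed": 2, "duration_ms": 300.0,
 "total_spikes": 193, "overall_frequency": 643.3, "n_stimulated": 20}
{"family": "MY", "fraction": 0.5, "mfs_percent": 10.0, "seed": 2, "duration_ms": 300.0,
 "total_spikes": 4949, "overall_frequency": 16496.7, "n_stimulated": 20}
```

Without sprouting, the 20 stimulated GCs fire and the activity dies out
(overall frequency ≈ 640 spikes/s comes almost entirely from that brief
volley). Adding 10% MFS and replacing half the mature GCs with newborn
cells drives a sustained, seizure-like state involving the whole granule
cell population — a ~25-fold rise in overall frequency. The same sweep
over families and fractions is available as `dgsim sweep`, and the Python
API (`dgnet.network`, `dgnet.simulate`, `dgnet.analysis`) exposes every
intermediate object.

## Layout

- `src/dgnet/morphology.py` — SWC I/O, path distances, sections
- `src/dgnet/synthetic.py` — synthetic GC morphology generator (three populations)
- `src/dgnet/layers.py` — molecular-layer partition, dendrite classes, synapse sites
- `src/dgnet/biophysics.py` — channel tables, compartmental cells, single-cell protocols
- `src/dgnet/engine.py` — numba backward-Euler cable/HH integrator
- `src/dgnet/network.py` — ring network, MFS, newborn substitution, SL1/SL2
- `src/dgnet/simulate.py` — PP stimulation, network runs, replicate batches
- `src/dgnet/analysis.py` — overall frequency, rasters, histograms, ANOVA
- `src/dgnet/cli.py` — the `dgsim` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
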