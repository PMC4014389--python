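# Methods

This note documents the model, the parameter choices that matter, the
synthetic data, the numerics, and the known limitations. Nothing stated
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## Granule-cell models

Each granule cell (GC) is compiled from an SWC morphology into one
compartment per reconstruction point: the soma root is a sphere (multi-point
somas are collapsed to their centroid with area-equivalent radius), every
other node the cylinder joining it to its parent. Axonal points are dropped;
axonal conduction is represented by per-edge delays at the network level.
Basal dendrites, when present, are retained as passive membrane but carry no
synapses.

Apical sections are classified by the pruned-distance-1 rule: the path
distance from the soma to the branching point a section originates from is
compared with thresholds `t1 < t2` (defaults: terciles of the
sample-averaged deepest branch point); sections originating inside the
granule cell layer (depth convention: twice the soma diameter) are GCLD,
then PD / MD / DD with ties going distal. Newborn PILO cells are classified
with the thresholds of the newborn-control sample, treating their dendrites
as end-pruned versions of control trees.

### Mechanisms and densities

The engine implements leak, transient Na (m³h), fast delayed-rectifier K
(n⁴), a slow M-like K current (single gate, V½ = −35 mV, τ = 150 ms), and
A-type K (a·b). Kinetics are standard HH-style rate functions authored for
this package; no calcium channels are included — the study's readouts are
spike-count based and the qualitative excitability orderings here do not
rely on Ca-dependent dynamics (a known simplification, see Limitations).

Default GC densities (S/cm²), shared by every GC model in a run:

| region | Na | Kdr | K-slow | K-A | Rm (Ω·cm²) | Cm (µF/cm²) |
|---|---|---|---|---|---|---|
| soma | 0.15 | 0.08 | 0.01 | 0.002 | 40 000 | 1.0 |
| GCLD | 0.004 | 0.010 | – | 0.004 | 40 000 | 1.0 |
| PD/MD/DD | 0.004 | 0.008 | – | 0.006 | 25 000 | 1.6 |

The dendritic Cm = 1.6 / reduced Rm encode the membrane load of spines;
the spine-loss membrane correction sets dendritic Rm and Cm equal to their
somatic values (soma untouched, idempotent). Axial resistivity 200 Ω·cm,
leak reversal −75 mV, E_Na = +50 mV, E_K = −90 mV. The slow M-like
conductance is what grades sustained network firing by synaptic drive;
without it the cells either saturate near their refractory ceiling or enter
depolarization block, and connectivity changes stop mattering.

Interneurons (BC fast-spiking, MC with depolarised rest at −62 mV, HC) are
5-compartment prototypes (soma + two 2-compartment dendrites) with the same
mechanism set.

### Single-cell protocols

*Rheobase*: bisection (1 pA tolerance, upper bound 2 nA) on the amplitude of
a 500-ms step at the most proximal PD compartment that evokes ≥1 somatic
spike (0 mV upward crossing). *Synaptic train*: ten synaptic-like
conductance pulses (τ 0.5/8 ms, reversal 0 mV, peak 0.03 µS) at 100-ms
intervals at the most distal dendritic compartment; the amplitude is
calibrated so that mature models fire well below one spike per pulse while
OML-reaching newborn models fire severalfold more. Cells whose dendrites do
not reach the outer molecular layer are excluded from the train protocol,
mirroring the eligibility rule for perforant-path input.

## Synthetic morphologies

The generator emulates the three study populations so the pipeline needs no
downloads; absolute numbers are conventions chosen once (no in-text
morphometry exists to reproduce), the *orderings* are the constraint:

| population | extent (µm) | primaries | branch/µm | soma r (µm) | cone | radii (µm) |
|---|---|---|---|---|---|---|
| mature | 300 ± 40 | 2.4 | 0.005 | 6.0 | 35° | 1.5→0.5 |
| young control | 160 ± 40 | 1.8 | 0.018 | 4.5 | 30° | 1.1→0.5 |
| young PILO | 130 ± 35 | 1.6 | 0.018 | 6.0 | 18° | 0.6→0.25 |

Growth is a Galton–Watson process: fixed 25-µm steps inside a cone around
the apical axis, constant per-µm branch probability, short side branches
for newborn cells; one leader path consumes the full truncated-normal
extent draw, so the maximal dendritic extent equals the draw exactly.
Emergent properties: mature > control > PILO extents; newborn cells several
times branchier per unit cable; a minority of newborn cells (roughly 1/4 of
controls, most PILO cells) fail to reach the outer molecular layer of the
mature-sample partition, as in the study's samples. PILO cells carry the
seizure-altered phenotype — shorter and narrower dendrites with an enlarged
soma — which makes them the least excitable newborn group in network terms
(their thin dendrites still give them the lowest rheobase). Default sample
sizes: 74 mature, 20 + 20 newborn.

What the generator does **not** emulate: real morphometric distributions
(the cones are idealised), spines, basal dendrites, 3D tissue context.
Passing tests therefore show that the *pipeline and its rules* behave as
specified under realistic population contrasts, not that any quantity
matches a measured reconstruction set.

## Network

Full scale: 500 GC / 6 BC / 15 MC / 6 HC with the printed efferent quotas.
The desk-scale preset used by tests and sweeps keeps the interneuron roster
and scales only the GC ring to 100, with quotas rescaled to preserve every
afferent in-degree and ring-coverage fraction — these, not raw out-degrees,
drive both the dynamics and the SL1 feasibility geometry. Synaptic weights
and delays (see `dgnet/config.py`) are this package's conventions, fixed so
that the canonical regimes hold: no spread without MFS, limited spread for
the mature network at 10% MFS, full seizure-like spread at 50% MFS or at
10% MFS with ≥50% newborn cells, and no spread for newborn insertion
without MFS.

Site rules: PP→OML (strict; short cells get no PP drive), MFS→IML (strict),
MC→IML first, HC→distal-first, BC→soma. The PP volley is spatially
distributed: each stimulated GC receives one synapse at *every* OML site it
owns (a single distal synapse cannot charge a large cell through the thin
distal cable — the axial resistance caps the transferable current).

**Spine loss.** Every afferent synapse of a newborn PILO GC — MC, BC, HC,
recurrent MFS, and the PP synapses attached at stimulation time — is
deleted independently with the configured probability, because all of them
occupy the dendritic sites that spines provide. SL1 re-targets each deleted
edge to a uniformly drawn mature GC in the presynaptic span that the
presynaptic cell does not already contact (MC→GC and GC→GC retain their
multiplicity exception); presynaptic out-degrees are restored exactly.
With the printed HC→GC quota (160 of 500) this becomes infeasible at
newborn fractions above ~0.81 — `(1-f)(N-Q) < r·Q·f` — reproducing the
documented failure of convergence/divergence maintenance at 90–100%;
sweeps record infeasible replicates as missing rows. Exactly at 80% the
margin is within binomial noise, so sweeps may or may not produce cells
there.

## Numerics

Backward-Euler cable integration with Hines elimination (parents precede
children), channel gates advanced by exponential Euler at the staggered
voltage, dt = 0.1 ms (halving dt changes fixture spike counts by ≤1).
Synapses are event-driven double-exponential conductances with per-edge
delay queues; spike detection is the somatic upward crossing of 0 mV. A
divergence guard aborts if any |V| exceeds 200 mV. The whole loop is one
numba kernel; a desk-scale 300-ms simulation takes on the order of one
second, which is what makes 20-replicate sweeps routine.

Problem sizes: tests and the acceptance script use the desk preset with
300-ms runs; replicate counts are 20 where the study protocol is asserted
(spread dichotomy uses 3 seeds per condition; the acceptance script's
summary sweeps use 6–8 replicates). Full-scale networks are built and
audited structurally but not integrated by default.

## Design choices where the design was open

- *Distances* are along-cable path distances, not Euclidean.
- *Boundary ties* (thresholds, layer edges) go to the more distal class.
- *GCL depth* for the GCLD class: twice the soma diameter; for synapse
  placement the GCL exclusion is capped at half the IML width so that
  short-but-large-soma cells keep an inner band.
- *Newborn fraction rounding*: half-up, so sweeps are reproducible.
- *Molecular-layer thickness*: exact sample mean (no jitter); newborn cells
  use their per-cell thickness for synapse placement.
- *Two-way ANOVA*: type-II sums of squares, because MPSL1 designs are
  unbalanced once high fractions become infeasible.
- Replicate seeds derive from the base seed via `SeedSequence` — full
  provenance of every raffle.

## Limitations

- The 1/5-GC-scale ring shortens propagation paths; ignition of the
  sustained state is near-threshold and therefore bistable across
  rewirings. Replicate averages are stable, single runs can fall on either
  side. At this scale the 75%-reduction MPSL2 curve is statistically flat
  in slope but sits near half the no-spine-loss level rather than at the
  near-baseline level a full-scale network would show.
- No calcium dynamics, no explicit spines, no ion-channel alterations in
  PILO cells, no gap junctions, no hilar basal dendrites or ectopic cells.
- Interneuron models are generic prototypes; their parameters were set for
  plausible circuit function, not fitted to recordings.
- Absolute overall-frequency values are tied to this package's synaptic
  weight conventions; only comparisons between conditions are meaningful.
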