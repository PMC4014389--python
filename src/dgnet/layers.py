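"""Virtual molecular layer, dendrite classification and synapse-site placement.

Two *independent* labelings are applied to every apical dendritic section:

1. the pruned-distance-1 **dendrite class** (GCLD / PD / MD / DD), driven by
   the path distance from the soma to the branching point where the section
   originates, against two thresholds ``t1 < t2``;
2. the **molecular-layer band** (IML / MML / OML) of each synapse site,
   driven by the path distance of the site itself inside a virtual molecular
   layer of thickness ``T`` (the sample-average maximal dendritic extent):
   IML is the first 17% of ``T`` nearest the granule cell layer and the
   remaining 83% is split equally into MML and OML.

The same section may host synapses in several bands; band membership never
depends on the PD/MD/DD class.  Perforant-path afferents are eligible only at
OML sites, mossy-fiber-sprouting afferents only at IML sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import APICAL, DendriteSection, MorphTree, max_dendritic_extent, sectionize

__all__ = [
    "LayerPartition",
    "DendriteClassMap",
    "SynapseSite",
    "compute_layer_partition",
    "branch_point_thresholds",
    "classify_dendrites",
    "place_synapse_sites",
    "default_gcl_depth",
]

IML_FRACTION_DEFAULT = 0.17

#: afferent classes eligible at a site, by molecular-layer band
LAYER_AFFERENTS = {
    "IML": ("MFS", "MC"),
    "MML": ("MC", "HC"),
    "OML": ("PP", "HC"),
}


@dataclass(frozen=True)
class LayerPartition:
    """Bands of the virtual molecular layer over path distance [0, T] µm.

    IML = [0, f*T), MML = [f*T, f*T + (1-f)/2*T), OML = the remainder
    (open-ended distally so that cells longer than the sample average still
    place their distal sites in the OML).  Boundary ties go to the more
    distal band (half-open intervals).
    """

    thickness: float
    iml_fraction: float = IML_FRACTION_DEFAULT

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("molecular-layer thickness must be > 0")
        if not 0 < self.iml_fraction < 1:
            raise ValueError("iml_fraction must be in (0, 1)")

    @property
    def iml(self) -> tuple[float, float]:
        return (0.0, self.iml_fraction * self.thickness)

    @property
    def mml(self) -> tuple[float, float]:
        lo = self.iml_fraction * self.thickness
        return (lo, lo + (1.0 - self.iml_fraction) / 2.0 * self.thickness)

    @property
    def oml(self) -> tuple[float, float]:
        return (self.mml[1], np.inf)

    def band_of(self, distance: float) -> str:
        if distance < self.iml[1]:
            return "IML"
        if distance < self.mml[1]:
            return "MML"
        return "OML"


@dataclass
class DendriteClassMap:
    """section_id -> {GCLD, PD, MD, DD} plus the thresholds that produced it."""

    labels: dict[int, str]
    t1: float
    t2: float
    gcl_depth: float

    def __getitem__(self, section_id: int) -> str:
        return self.labels[section_id]


@dataclass(frozen=True)
class SynapseSite:
    """One synapse location: the midpoint of a section's intra-band portion."""

    cell: str
    section_id: int
    node: int            # positional node index carrying the site
    arc: float           # fraction along the section, in (0, 1]
    layer: str           # IML / MML / OML
    path_distance: float  # µm from soma

    @property
    def eligible(self) -> tuple[str, ...]:
        return LAYER_AFFERENTS[self.layer]


def compute_layer_partition(
    sample: list[MorphTree], iml_fraction: float = IML_FRACTION_DEFAULT
) -> LayerPartition:
    """Virtual molecular layer from a sample: T = mean maximal dendritic extent."""
    if not sample:
        raise ValueError("cannot derive a molecular layer from an empty sample")
    thickness = float(np.mean([max_dendritic_extent(t) for t in sample]))
    return LayerPartition(thickness, iml_fraction)


def branch_point_thresholds(sample: list[MorphTree]) -> tuple[float, float]:
    """Default (t1, t2): terciles of the sample-average deepest branch point.

    For each cell the deepest branching point is the largest ``path_start``
    over its apical sections; ``t1``/``t2`` split the sample average of that
    quantity into three equal distance bands (PD/MD/DD).
    """
    deepest = []
    for tree in sample:
        starts = [s.path_start for s in sectionize(tree) if s.structure == APICAL]
        if starts:
            deepest.append(max(starts))
    if not deepest:
        raise ValueError("sample has no apical sections")
    b = float(np.mean(deepest))
    if b <= 0:  # unbranched sample: fall back to extent-based bands
        b = float(np.mean([max_dendritic_extent(t) for t in sample]))
    return (b / 3.0, 2.0 * b / 3.0)


def default_gcl_depth(tree: MorphTree) -> float:
    """Granule-cell-layer depth convention: twice the soma diameter."""
    return 4.0 * float(tree.radius[0])


def classify_dendrites(
    tree: MorphTree,
    thresholds: tuple[float, float],
    gcl_depth: float | None = None,
) -> DendriteClassMap:
    """Label every apical section GCLD/PD/MD/DD from its branch-point distance.

    The classifying distance of a section is the path distance from the soma
    to the branching point it originates from (``path_start``).  Sections
    originating inside the granule cell layer are GCLD; otherwise PD below
    ``t1``, MD in ``[t1, t2)``, DD at or beyond ``t2`` (ties go distal).
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError(f"thresholds must satisfy t1 < t2, got {thresholds}")
    if gcl_depth is None:
        gcl_depth = default_gcl_depth(tree)
    labels: dict[int, str] = {}
    for sec in sectionize(tree):
        if sec.structure != APICAL:
            continue
        d = sec.path_start
        if d < gcl_depth:
            labels[sec.section_id] = "GCLD"
        elif d < t1:
            labels[sec.section_id] = "PD"
        elif d < t2:
            labels[sec.section_id] = "MD"
        else:
            labels[sec.section_id] = "DD"
    return DendriteClassMap(labels, t1, t2, gcl_depth)


def place_synapse_sites(
    tree: MorphTree,
    partition: LayerPartition,
    gcl_depth: float | None = None,
) -> list[SynapseSite]:
    """One synapse site per (apical section, molecular-layer band) overlap.

    A section spanning several bands receives one site per band, each at the
    midpoint of the portion of the section inside that band.  The granule
    cell layer itself (path distance < ``gcl_depth``) hosts no sites, so a
    tree confined to the GCL yields an empty list.  Cells whose dendrites do
    not reach the OML simply have no OML (perforant-path-eligible) sites.
    """
    if gcl_depth is None:
        gcl_depth = default_gcl_depth(tree)
    # cells with thin molecular layers (short newborns with large somas) must
    # keep an eligible inner band: never let the GCL exclusion swallow more
    # than half of the IML
    gcl_depth = min(gcl_depth, 0.5 * partition.iml[1])
    pl = tree.path_lengths()
    sites: list[SynapseSite] = []
    for sec in sectionize(tree):
        if sec.structure != APICAL:
            continue
        for layer, (lo, hi) in (
            ("IML", partition.iml), ("MML", partition.mml), ("OML", partition.oml)
        ):
            lo = max(lo, gcl_depth)
            a = max(sec.path_start, lo)
            b = min(sec.path_end, hi)
            if b - a <= 1e-9:
                continue
            mid = 0.5 * (a + b)
            length = sec.path_end - sec.path_start
            arc = (mid - sec.path_start) / length if length > 0 else 1.0
            node = min(sec.nodes, key=lambda n: abs(pl[n] - mid))
            sites.append(
                SynapseSite(
                    cell=tree.name, section_id=sec.section_id, node=int(node),
                    arc=float(arc), layer=layer, path_distance=float(mid),
                )
            )
    return sites


def sites_table(sites: list[SynapseSite]) -> pd.DataFrame:
    """Synapse-site table for CSV export."""
    return pd.DataFrame(
        {
            "cell": [s.cell for s in sites],
            "section_id": [s.section_id for s in sites],
            "node": [s.node for s in sites],
            "arc": [s.arc for s in sites],
            "layer": [s.layer for s in sites],
            "path_distance": [s.path_distance for s in sites],
        }
    )
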