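"""Synthetic granule-cell morphology generator.

Emulates the three study populations so the whole pipeline builds and tests
without any downloaded reconstructions:

* ``mature`` — large cone-shaped apical trees typical of adult GCs;
* ``young_control`` — newborn (~30-day) cells from control animals: shorter
  and more heavily branched than mature cells;
* ``young_pilo`` — newborn cells after pilocarpine-induced status
  epilepticus: shorter still, with a narrower apical cone and an enlarged
  soma (the seizure-altered phenotype), which leaves them less excitable
  than newborn controls despite their smaller trees.

Growth is a Galton–Watson branching process along the cable: dendrites are
extended in fixed steps inside a cone around the apical (+y) axis and branch
with a constant per-micrometre probability; one "leader" path per cell
consumes the full drawn extent so the maximal dendritic extent of the tree
equals the truncated-normal draw exactly.  Absolute scales are conventions
chosen to respect the qualitative population orderings (mature >
young_control > young_pilo extents; newborn branchier; a nonzero fraction of
newborn cells too short to reach the outer molecular layer), not
reproductions of any measured morphometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .morphology import APICAL, SOMA, MorphTree, max_dendritic_extent, sectionize

__all__ = [
    "PopulationParams",
    "DEFAULT_POPULATIONS",
    "generate_tree",
    "generate_population",
    "population_manifest",
]


@dataclass(frozen=True)
class PopulationParams:
    """Generator parameters for one GC population (lengths in µm)."""

    tag: str
    extent_mean: float = 300.0
    extent_sd: float = 40.0
    extent_min: float = 40.0
    n_primary_mean: float = 2.4
    n_primary_sd: float = 0.6
    branch_prob_per_um: float = 0.003
    taper_rate: float = 0.003      # µm radius lost per µm of path
    soma_radius_mean: float = 6.0
    soma_radius_sd: float = 0.8
    cone_half_angle_deg: float = 35.0
    step_um: float = 25.0
    tip_radius: float = 0.5
    base_radius: float = 1.5
    branch_len_frac: tuple = (0.4, 0.8)   # child budget as fraction of remaining length

    def __post_init__(self):
        if self.extent_mean <= 0 or self.soma_radius_mean <= 0 or self.step_um <= 0:
            raise ValueError("all mean parameters must be > 0")
        if min(self.extent_sd, self.n_primary_sd, self.soma_radius_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


#: Default parameter sets for the three study populations.  Mature cells have
#: large cones; newborn controls are short and branch several times more per unit
#: length; PILO newborns are shorter yet with a narrower cone.
DEFAULT_POPULATIONS: dict[str, PopulationParams] = {
    "mature": PopulationParams(
        tag="mature", extent_mean=300.0, extent_sd=40.0, extent_min=150.0,
        n_primary_mean=2.4, branch_prob_per_um=0.005,
        soma_radius_mean=6.0, cone_half_angle_deg=35.0,
    ),
    "young_control": PopulationParams(
        tag="young_control", extent_mean=160.0, extent_sd=40.0, extent_min=40.0,
        n_primary_mean=1.8, branch_prob_per_um=0.018,
        soma_radius_mean=4.5, soma_radius_sd=0.6, cone_half_angle_deg=30.0,
        base_radius=1.1, tip_radius=0.5, branch_len_frac=(0.2, 0.5),
    ),
    "young_pilo": PopulationParams(
        tag="young_pilo", extent_mean=130.0, extent_sd=35.0, extent_min=40.0,
        n_primary_mean=1.6, branch_prob_per_um=0.018,
        soma_radius_mean=6.0, soma_radius_sd=0.6, cone_half_angle_deg=18.0,
        base_radius=0.6, tip_radius=0.25, branch_len_frac=(0.2, 0.5),
    ),
}

#: Default sample sizes mirroring the study (74 mature reconstructions; 20
#: newborn control and 20 newborn PILO cells).
DEFAULT_SAMPLE_SIZES = {"mature": 74, "young_control": 20, "young_pilo": 20}


def _trunc_normal(rng, mean, sd, lo):
    if sd == 0:
        return max(mean, lo)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return x
    return lo + abs(rng.normal(0.0, sd))  # pathological params: reflect


def _cone_direction(rng, half_angle_rad):
    """Uniform direction within a cone around +y."""
    cos_lo = math.cos(half_angle_rad)
    c = rng.uniform(cos_lo, 1.0)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([s * math.cos(phi), c, s * math.sin(phi)])


def generate_tree(params: PopulationParams, rng: np.random.Generator) -> MorphTree:
    """Draw one synthetic apical-dendrite morphology.

    The returned tree always satisfies the :class:`~dgnet.morphology.MorphTree`
    invariants, and its :func:`~dgnet.morphology.max_dendritic_extent` equals
    the cell-level truncated-normal extent draw.
    """
    n_primary = int(round(_trunc_normal(rng, params.n_primary_mean, params.n_primary_sd, 0.5)))
    if n_primary < 1:
        raise ValueError("degenerate parameters produced zero primary dendrites")
    soma_r = _trunc_normal(rng, params.soma_radius_mean, params.soma_radius_sd, 1.0)
    extent = _trunc_normal(rng, params.extent_mean, params.extent_sd, params.extent_min)
    half_angle = math.radians(params.cone_half_angle_deg)

    structure = [SOMA]
    xyz = [np.zeros(3)]
    radius = [soma_r]
    parent = [-1]

    def add_node(p, pos, r):
        structure.append(APICAL)
        xyz.append(pos)
        radius.append(max(r, params.tip_radius))
        parent.append(p)
        return len(structure) - 1

    # stack entries: (parent_node, position, direction, path_len_done, budget)
    stack = []
    for k in range(n_primary):
        budget = extent if k == 0 else extent * rng.uniform(0.5, 0.95)
        stack.append((0, np.zeros(3), _cone_direction(rng, half_angle), 0.0, budget))

    while stack:
        pnode, pos, direction, done, budget = stack.pop()
        while budget - done > 1e-9:
            step = min(params.step_um, budget - done)
            # wobble the growth direction, then clamp back inside the cone
            direction = direction + rng.normal(0.0, 0.25, size=3)
            direction /= np.linalg.norm(direction)
            if direction[1] < math.cos(half_angle):
                direction = _cone_direction(rng, half_angle)
            pos = pos + direction * step
            done += step
            r = params.base_radius - params.taper_rate * done
            pnode = add_node(pnode, pos, r)
            remaining = budget - done
            if remaining > params.step_um and rng.random() < params.branch_prob_per_um * step:
                lo_f, hi_f = params.branch_len_frac
                child_budget = done + remaining * rng.uniform(lo_f, hi_f)
                stack.append(
                    (pnode, pos, _cone_direction(rng, half_angle), done, child_budget)
                )

    tree = MorphTree(
        np.array(structure), np.array(xyz), np.array(radius), np.array(parent),
        name=f"syn_{params.tag}", population=params.tag,
    )
    return tree


def generate_population(
    tag: str,
    n: int,
    seed: int,
    params: PopulationParams | None = None,
) -> list[MorphTree]:
    """Generate ``n`` reproducible trees for one population.

    Two calls with the same ``(tag, n, seed)`` return element-wise identical
    trees.  Unknown tags raise ``KeyError``.
    """
    if params is None:
        if tag not in DEFAULT_POPULATIONS:
            raise KeyError(f"unknown population tag {tag!r}")
        params = DEFAULT_POPULATIONS[tag]
    elif params.tag != tag:
        params = replace(params, tag=tag)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _tag_code(tag)]))
    trees = []
    for i in range(n):
        t = generate_tree(params, rng)
        t.name = f"syn_{tag}_{i:03d}"
        trees.append(t)
    return trees


def _tag_code(tag: str) -> int:
    return int.from_bytes(tag.encode()[:4].ljust(4, b"_"), "little") % (2**31)


def population_manifest(trees: list[MorphTree]) -> pd.DataFrame:
    """Population summary (cell_id, tag, extent, n_sections) for CSV export."""
    return pd.DataFrame(
        {
            "cell_id": [t.name for t in trees],
            "tag": [t.population for t in trees],
            "extent": [max_dendritic_extent(t) for t in trees],
            "n_sections": [len(sectionize(t)) for t in trees],
        }
    )
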