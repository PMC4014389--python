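"""Network-scale configuration: cell counts, degree quotas, topographic spans
and synaptic parameters.

The full-scale roster is the 1:2000 dentate gyrus: 500 granule cells (GC),
6 basket cells (BC), 15 mossy cells (MC) and 6 hilar perforant-path
associated cells (HC) on a ring, with fixed efferent quotas per cell
(MC -> 200 GC, 1 BC, 2 HC, 3 MC; HC -> 160 GC, 4 BC, 4 MC; BC -> 100 GC,
3 MC, 2 BC; GC -> 1 MC, 1 BC, 2 HC; under mossy fiber sprouting GCs also
contact neighbouring GCs).  A 1/5-scale desk preset with proportionally
scaled quotas is provided for tests and sweeps.

Synaptic weights, delays and span widths are conventions of this package
(inherited-model numbers are not printed anywhere reproducible); they are
chosen once so that the canonical network regimes hold: no spread without
sprouting, full seizure-like spread at high sprouting or at modest sprouting
combined with many newborn cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["ProjectionParams", "ScaleConfig", "NetworkConfig", "full_scale", "desk_scale"]

CELL_TYPES = ("GC", "BC", "MC", "HC")


@dataclass(frozen=True)
class ProjectionParams:
    """One projection class: quota, span, synapse parameters."""

    quota: int                  # efferent targets per presynaptic cell
    weight: float               # µS peak conductance
    delay: float                # ms (conduction delay; axons are not simulated)
    receptor: str               # AMPA or GABA
    span_fraction: float = 1.0  # topographic window as fraction of the post ring
    multi: bool = False         # multiple contacts onto the same target allowed


@dataclass
class ScaleConfig:
    n_gc: int = 500
    n_bc: int = 6
    n_mc: int = 15
    n_hc: int = 6

    @property
    def counts(self) -> dict:
        return {"GC": self.n_gc, "BC": self.n_bc, "MC": self.n_mc, "HC": self.n_hc}

    @property
    def total(self) -> int:
        return self.n_gc + self.n_bc + self.n_mc + self.n_hc


def _default_projections(scale: ScaleConfig) -> dict:
    """Degree quotas and synapse parameters.

    Quotas are scaled so that every cell's afferent in-degree (convergence)
    and every projection's ring-coverage fraction match the full-scale
    network; these, not the raw out-degrees, are what the dynamics and the
    spine-loss rewiring act on.  At full scale the quotas are exactly the
    printed ones.
    """
    counts = {"GC": scale.n_gc, "BC": scale.n_bc, "MC": scale.n_mc, "HC": scale.n_hc}
    full = {"GC": 500, "BC": 6, "MC": 15, "HC": 6}

    def q(pre, post, q_full):  # preserve in-degree: n_pre*q/n_post invariant
        scaled = q_full * (counts[post] / full[post]) * (full[pre] / counts[pre])
        return max(1, min(round(scaled), counts[post] - (1 if pre == post else 0)))

    def cap(qq, avail):
        return min(qq, avail)

    return {
        # excitatory hilar mossy cells: wide, weak feedback to GCs
        "MC->GC": ProjectionParams(q("MC", "GC", 200), 0.0006, 3.0, "AMPA", multi=True),
        "MC->BC": ProjectionParams(q("MC", "BC", 1), 0.002, 3.0, "AMPA"),
        "MC->HC": ProjectionParams(q("MC", "HC", 2), 0.002, 3.0, "AMPA"),
        "MC->MC": ProjectionParams(q("MC", "MC", 3), 0.001, 2.0, "AMPA"),
        # hilar perforant-path associated cells: distal dendritic inhibition
        "HC->GC": ProjectionParams(q("HC", "GC", 160), 0.002, 1.6, "GABA"),
        "HC->BC": ProjectionParams(q("HC", "BC", 4), 0.002, 1.6, "GABA"),
        "HC->MC": ProjectionParams(q("HC", "MC", 4), 0.002, 1.6, "GABA"),
        # basket cells: perisomatic inhibition
        "BC->GC": ProjectionParams(q("BC", "GC", 100), 0.003, 0.8, "GABA"),
        "BC->MC": ProjectionParams(q("BC", "MC", 3), 0.002, 0.8, "GABA"),
        "BC->BC": ProjectionParams(q("BC", "BC", 2), 0.002, 0.8, "GABA"),
        # granule-cell efferents (mossy fibres)
        "GC->MC": ProjectionParams(q("GC", "MC", 1), 0.003, 1.5, "AMPA"),
        "GC->BC": ProjectionParams(q("GC", "BC", 1), 0.005, 1.5, "AMPA"),
        "GC->HC": ProjectionParams(q("GC", "HC", 2), 0.002, 1.5, "AMPA"),
        # recurrent sprouted mossy fibres: local, onto IML sites (quota set by
        # the MFS level at build time; this entry carries synapse parameters)
        "GC->GC": ProjectionParams(0, 0.0015, 1.0, "AMPA", span_fraction=0.2, multi=True),
    }


@dataclass
class NetworkConfig:
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    projections: dict = None
    #: GC->GC contacts per GC at 100% of the pilocarpine-level sprouting
    max_sprout: int = 100
    #: perforant-path stimulus synapses
    pp_weight_gc: float = 0.04
    pp_weight_bc: float = 0.005
    pp_delay: float = 3.0
    #: synaptic kinetics per receptor (tau_rise, tau_decay, reversal mV)
    receptors: dict = field(
        default_factory=lambda: {"AMPA": (0.5, 3.0, 0.0), "GABA": (0.5, 6.0, -75.0)}
    )
    iml_fraction: float = 0.17

    def __post_init__(self):
        if self.projections is None:
            self.projections = _default_projections(self.scale)


    def to_yaml(self, path) -> None:
        data = {
            "scale": asdict(self.scale),
            "projections": {k: asdict(v) for k, v in self.projections.items()},
            "max_sprout": self.max_sprout,
            "pp_weight_gc": self.pp_weight_gc,
            "pp_weight_bc": self.pp_weight_bc,
            "pp_delay": self.pp_delay,
            "receptors": {k: list(v) for k, v in self.receptors.items()},
            "iml_fraction": self.iml_fraction,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        scale = ScaleConfig(**data.get("scale", {}))
        projections = {
            k: ProjectionParams(**v) for k, v in data.get("projections", {}).items()
        } or None
        cfg = cls(
            scale=scale,
            projections=projections,
            max_sprout=data.get("max_sprout", 100),
            pp_weight_gc=data.get("pp_weight_gc", 0.02),
            pp_weight_bc=data.get("pp_weight_bc", 0.005),
            pp_delay=data.get("pp_delay", 3.0),
            receptors={k: tuple(v) for k, v in data.get("receptors", {}).items()}
            or None,
            iml_fraction=data.get("iml_fraction", 0.17),
        )
        return cfg


def full_scale() -> NetworkConfig:
    """Default 1:2000 network (500 GC, 6 BC, 15 MC, 6 HC)."""
    return NetworkConfig(scale=ScaleConfig())


def desk_scale() -> NetworkConfig:
    """1/5-GC-scale preset (100 GC; interneuron roster kept at 6 BC, 15 MC,
    6 HC) with convergence-preserving quotas.

    Keeping the interneuron counts leaves every afferent in-degree and every
    projection's ring-coverage fraction identical to the full-scale network,
    so the dynamics and the SL1 feasibility geometry carry over."""
    return NetworkConfig(scale=ScaleConfig(n_gc=100, n_bc=6, n_mc=15, n_hc=6))
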