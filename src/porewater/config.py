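"""Run configuration: structured YAML in, validated dataclass out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything one analysis run needs, resolvable before any compute.

    Either ``topology`` + ``replicas`` (coordinate files per replica) or a
    ``synthetic`` section (parameters of the built-in generator; one
    replica per seed offset) must be given.  ``discard_fraction`` drops the
    leading equilibration portion of each replica before analysis.
    """

    topology: str | None = None
    replicas: list[list[str]] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)
    n_replicas: int = 3  # used with `synthetic`
    discard_fraction: float = 0.2
    stride: int = 1
    dt: float | None = None

    corner_residues: list[int] = field(default_factory=list)
    bottom_residues: list[int] = field(default_factory=list)
    top_residues: list[int] = field(default_factory=list)
    marker_residues: list[int] = field(default_factory=list)
    analysis_residues: list[int] = field(default_factory=list)
    residue_pairs: list[list] = field(default_factory=list)  # [a, b] or [a, b, atom_a, atom_b]
    updown: dict = field(default_factory=dict)  # residue, reference, threshold, atoms

    cylinder: dict = field(default_factory=dict)  # radius, n_slices, ...
    hbond: dict = field(default_factory=dict)  # max_distance, max_angle_deviation
    lifetime: dict = field(default_factory=dict)  # max_lag, origin_spacing
    median_window_ps: float | None = None  # window for the median structure
    lag: float | None = None  # MSD lag, defaults to dt

    seed: int = 0
    output: str = "porewater_out"

    def __post_init__(self) -> None:
        if not (0.0 <= self.discard_fraction < 1.0):
            raise ValueError("discard_fraction must lie in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be ≥ 1")
        if not self.synthetic and (self.topology is None or not self.replicas):
            raise ValueError("config needs either topology+replicas or a synthetic section")
        if self.synthetic and self.n_replicas < 1:
            raise ValueError("need at least one replica")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
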