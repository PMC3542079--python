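"""Configuration for the analysis pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings of :func:`lifediff.analysis.run_full_analysis`.

    Attributes
    ----------
    lam_b
        Photobleaching rate constant, 1/s.  The default 0.1 is the value
        measured on immobilized fluorophores in fixed cells; set to 0 for
        simulations without bleaching.
    eps
        Localization error SD (µm); ``None`` estimates it from the MSD
        intercept of the data.
    n_max
        Largest candidate state number for the AIC scan.
    tau
        Window width for the time-resolved fraction fits, s
        (``None`` → one frame interval).  Must be at least one frame;
        wider windows smooth fast kinetics over the window.
    bin_spacing
        Window advance, s (``None`` → one frame interval, i.e.
        overlapping windows).
    min_bin_count
        Minimum displacements per window; sparser windows are dropped.
    topology
        Transition topology for the kinetic fit: ``"chain"``, ``"full"``,
        ``"none"`` or an explicit edge list ``[(i, j), ...]`` (0-based).
        Applied when the transition test is positive; otherwise the fit
        uses ``"none"`` unless ``force_topology`` overrides this.
    t_late
        Start of the late-time region for the transition test, s, or
        ``"auto"`` to detect the slope-convergence onset from the data.
    consistency_times
        Times (s) at which position histograms are compared to the model.
    """

    lam_b: float = 0.1
    eps: Optional[float] = None
    n_max: int = 4
    tau: Optional[float] = None
    bin_spacing: Optional[float] = None
    min_bin_count: int = 50
    topology: object = "chain"
    force_topology: object = None
    t_late: object = "auto"
    consistency_times: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0)
    include_single_frame: bool = True
    compute_ci: bool = False

    def __post_init__(self):
        if self.lam_b < 0:
            raise ValueError("lam_b must be >= 0")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.min_bin_count < 1:
            raise ValueError("min_bin_count must be >= 1")

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
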