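"""Numerical tolerances and run-wide configuration.

All steady-state / bound tolerances used across the package live here so
they can be adjusted in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Tolerances:
    """Numerical tolerances shared by solvers and validators.

    steady_state : max allowed |S v| for an exact LP/QP solution
    bounds       : slack allowed outside [lb, ub] for exact solutions
    sample       : looser tolerance applied to MCMC flux samples, which are
                   only projected back onto S v = 0 periodically
    """

    steady_state: float = 1e-8
    bounds: float = 1e-9
    sample: float = 1e-6


#: package-wide default; functions take an optional ``tol`` override
DEFAULT_TOL = Tolerances()


@dataclass
class Thresholds:
    """The printed analysis thresholds, gathered in one record.

    fpkm             : expression-activity floor for context models
    de_p             : FDR-adjusted p gate for treatment-specific pruning
    p_th             : FDR-adjusted p gate for measures entering the QP (0.25)
    biomass_guard    : biomass fraction the pruned model must retain (0.5)
    biomass_fraction : biomass fraction for the reference LP (0.95)
    fva_fraction     : fraction-of-optimum for the FVA restriction (0.99)
    kd_fraction      : knockdown flux fraction (0.5)
    fc_up / fc_down  : reaction fold-change category cut-offs (1.25 / 0.75)
    """

    fpkm: float = 1.0
    de_p: float = 0.05
    p_th: float = 0.25
    biomass_guard: float = 0.5
    biomass_fraction: float = 0.95
    fva_fraction: float = 0.99
    kd_fraction: float = 0.5
    fc_up: float = 1.25
    fc_down: float = 0.75
    min_sink_flux: float = 1e-4


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class SamplingConfig:
    n_samples: int = 1000
    thinning: int = 100
    seed: int | None = None


@dataclass
class RunConfig:
    """Declarative configuration for an end-to-end pipeline run."""

    model_path: str = ""
    expression_path: str = ""
    de_path: str = ""
    metabolite_path: str = ""
    pathway_path: str | None = None
    treatment: str = ""
    control: str = ""
    thresholds: Thresholds = field(default_factory=Thresholds)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    #: list of (reaction_id, fraction-of-reference upper bound)
    drug_constraints: list[tuple[str, float]] = field(default_factory=list)
    required_metabolites: list[str] = field(default_factory=list)
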