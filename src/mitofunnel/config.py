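"""Configuration objects shared across the pipeline.

Two dataclasses hold every tunable number: :class:`PipelineConfig` for the
analysis thresholds (correlation cut-off, MCL parameters, filter levels,
trend/divergence thresholds) and :class:`SimConfig` for the synthetic-data
generator.  Both validate on construction and are immutable, so a run is
fully described by its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

#: Ordered age groups of the timecourse design.
AGES: tuple[str, ...] = ("young", "mid", "old")

#: Mitochondrial subpopulations (subcellular compartments).
COMPARTMENTS: tuple[str, ...] = ("synaptic", "non_synaptic")

#: Temporal trend classes considered age-dependent "clusters of interest".
TREND_CLASSES: tuple[str, ...] = ("steady_up", "steady_down", "late_up", "late_down")

#: Planted expression classes available to the simulator.
SIM_CLASSES: tuple[str, ...] = (
    "flat",
    "steady_up",
    "steady_down",
    "late_up",
    "late_down",
    "divergent_old",
)


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric thresholds of the analysis pipeline.

    Parameters
    ----------
    pearson_threshold
        Minimum Pearson r for an edge in correlation graphs (dimensionless,
        0 < r < 1).  Default 0.96.
    mcl_inflation
        MCL inflation exponent (> 1); controls cluster granularity.
        Default 2.2.
    mcl_expansion
        MCL expansion power (integer >= 2).  Default 2.
    mcl_prune
        Entries of the stochastic matrix below this value are zeroed each
        iteration.  Default 1e-6.
    mcl_tol
        Convergence tolerance on the max absolute change per iteration.
        Default 1e-8.
    alpha
        Significance level for ANOVA-based filters.  Default 0.05.
    power_min
        Minimum post-hoc ANOVA power for the feature filter.  Default 0.8.
    fc_min
        Minimum max/min group-mean fold change for the feature filter
        (ratio >= 1).  Default 1.2.
    min_unique_peptides
        Minimum unique peptide count for the protein filter.  Default 2.
    trend_epsilon
        Relative-change threshold for trend calls: a step counts as "up"
        when the age-to-age ratio is >= 1 + epsilon.  Default 0.2.
    concord_tau
        Maximum \\|log2 ratio\\| between compartments at mid age for the
        archetypal (concordant-then-divergent) profile.  Default log2(1.5).
    divergence_fold
        Minimum old-age cross-compartment fold change for the final
        candidate filter.  Default 2.0.
    mcl_weighted
        Use correlation weights as MCL transition mass (True) or unit
        weights (False).
    per_protein_trends
        Classify trends per protein instead of per MCL cluster.
    pooled_subtraction
        Pool all trend classes before the cross-compartment subtraction
        instead of subtracting per class.
    """

    pearson_threshold: float = 0.96
    mcl_inflation: float = 2.2
    mcl_expansion: int = 2
    mcl_prune: float = 1e-6
    mcl_tol: float = 1e-8
    alpha: float = 0.05
    power_min: float = 0.8
    fc_min: float = 1.2
    min_unique_peptides: int = 2
    trend_epsilon: float = 0.2
    concord_tau: float = math.log2(1.5)
    divergence_fold: float = 2.0
    mcl_weighted: bool = True
    per_protein_trends: bool = False
    pooled_subtraction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.pearson_threshold < 1.0:
            raise ConfigError("pearson_threshold must lie in (0, 1)")
        if self.mcl_inflation <= 1.0:
            raise ConfigError("mcl_inflation must be > 1")
        if int(self.mcl_expansion) != self.mcl_expansion or self.mcl_expansion < 2:
            raise ConfigError("mcl_expansion must be an integer >= 2")
        if self.mcl_prune < 0 or self.mcl_tol <= 0:
            raise ConfigError("mcl_prune must be >= 0 and mcl_tol > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0.0 <= self.power_min <= 1.0:
            raise ConfigError("power_min must lie in [0, 1]")
        if self.fc_min < 1.0:
            raise ConfigError("fc_min must be >= 1")
        if self.min_unique_peptides < 1:
            raise ConfigError("min_unique_peptides must be >= 1")
        if self.trend_epsilon <= 0:
            raise ConfigError("trend_epsilon must be > 0")
        if self.concord_tau < 0:
            raise ConfigError("concord_tau must be >= 0")
        if self.divergence_fold < 1.0:
            raise ConfigError("divergence_fold must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _default_fractions() -> dict[str, float]:
    # Majority of the proteome is temporally stable; the altered minority is
    # split between gradual-ageing and late-stage/vulnerability classes.
    return {
        "flat": 0.55,
        "steady_up": 0.10,
        "steady_down": 0.10,
        "late_up": 0.08,
        "late_down": 0.08,
        "divergent_old": 0.09,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic timecourse generator.

    The design mirrors the study layout: two compartments (synaptic /
    non-synaptic mitochondria) x three ordered ages (young, mid, old) x
    ``replicates_per_group`` technical replicates.

    Parameters
    ----------
    n_proteins
        Number of simulated proteins (> 0).
    replicates_per_group
        Replicates per (compartment, age) cell.  Default 3.
    class_fractions
        Proportion of proteins per planted class; must sum to 1.
    effect_size
        Fold change applied per planted step for steady/late classes
        (dimensionless ratio > 1).  Default 1.5.
    divergent_fold
        Old-age synaptic vs non-synaptic fold for the divergent class
        (> 1).  Default 2.5.
    noise_sd
        Standard deviation of the natural-log multiplicative noise
        (abundance = mean * exp(N(0, noise_sd^2))).  Default 0.1.
    baseline_range
        (low, high) bounds of baseline abundance; baselines are drawn
        log-uniformly.  Default (1e3, 1e6), spanning the dynamic range of
        label-free normalised abundances.
    frac_single_peptide
        Proportion of proteins assigned unique_peptides = 1 (exercises the
        protein filter).  Default 0.05.
    biological_sd
        Optional extra per-(protein, replicate) log-normal variance,
        emulating biological replicate scatter.  Default 0 (off): the study
        pooled animals into technical replicates.
    seed
        RNG seed; identical seed implies bit-identical output.
    """

    n_proteins: int
    replicates_per_group: int = 3
    class_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    effect_size: float = 1.5
    divergent_fold: float = 2.5
    noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (1e3, 1e6)
    frac_single_peptide: float = 0.05
    biological_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_proteins) != self.n_proteins or self.n_proteins <= 0:
            raise ConfigError("n_proteins must be a positive integer")
        if self.replicates_per_group <= 0:
            raise ConfigError("replicates_per_group must be a positive integer")
        unknown = set(self.class_fractions) - set(SIM_CLASSES)
        if unknown:
            raise ConfigError(f"unknown simulation classes: {sorted(unknown)}")
        fracs = {c: float(self.class_fractions.get(c, 0.0)) for c in SIM_CLASSES}
        if any(v < 0 for v in fracs.values()):
            raise ConfigError("class fractions must be >= 0")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions must sum to 1 (got {total!r})")
        object.__setattr__(self, "class_fractions", fracs)
        if self.noise_sd < 0 or self.biological_sd < 0:
            raise ConfigError("noise_sd and biological_sd must be >= 0")
        if self.effect_size <= 1.0:
            raise ConfigError("effect_size must be > 1")
        if self.divergent_fold <= 1.0:
            raise ConfigError("divergent_fold must be > 1")
        low, high = self.baseline_range
        if not (0 < low <= high):
            raise ConfigError("baseline_range must satisfy 0 < low <= high")
        if not 0.0 <= self.frac_single_peptide <= 1.0:
            raise ConfigError("frac_single_peptide must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_fractions"] = dict(self.class_fractions)
        d["baseline_range"] = list(self.baseline_range)
        return d
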