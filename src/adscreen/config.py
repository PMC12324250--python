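"""Configuration models for the synthetic screen and the pipeline runner.

All stochastic defaults are the study conditions the pipeline is designed
for: control stress impairment averaging 26% (heat) and 19% (bang),
climbing assessed from day 5 to day 18 post-eclosion with 6 timepoints for
the tau model and 9 for the amyloid-beta model, 4 vials of 10 females per
genotype, and vacuole counts that put normal brains well under the
15-vacuole degeneration rule.
"""

from __future__ import annotations

import zlib
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ErgParams", "ClimbingParams", "CohortParams", "SimulationConfig", "RunConfig"]


class ErgParams(BaseModel):
    """Trace-generator parameters (corneal-negative convention: the
    sustained depolarization is stored as negative voltage)."""

    model_config = ConfigDict(extra="forbid")

    baseline_mV: float = 0.0
    plateau_mV: float = 12.0       # magnitude of the sustained depolarization
    on_mV: float = 4.0             # onset excursion beyond the plateau
    off_mV: float = 5.0            # offset excursion beyond baseline
    noise_sd: float = Field(0.5, ge=0.0)
    sampling_rate_hz: float = Field(1000.0, gt=0.0)
    trace_duration_s: float = Field(2.0, gt=0.0)
    stimulus_onset_s: float = 0.5
    stimulus_offset_s: float = 1.5
    transient_width_s: float = Field(0.02, gt=0.0)
    n_flies: int = Field(5, gt=0)
    n_traces_per_fly: int = Field(5, gt=0)

    @model_validator(mode="after")
    def _window_inside_trace(self) -> "ErgParams":
        if not (0.0 < self.stimulus_onset_s < self.stimulus_offset_s < self.trace_duration_s):
            raise ValueError("stimulus window must lie strictly inside the trace span")
        return self


class ClimbingParams(BaseModel):
    """Longitudinal negative-geotaxis parameters.

    speed(age) = baseline - decline * g(age) + shift + slope_change * g(age)
    (+ vial intercept + noise), where g is the configured age transform on
    the day 5-18 grid and shift/slope_change are the modifier effects.
    """

    model_config = ConfigDict(extra="forbid")

    baseline_speed: float = Field(12.0, gt=0.0)   # mm/s at the first assay day
    decline_per_day: float = 0.5                  # mm/s per day, disease control
    age_start: float = 5.0
    age_end: float = 18.0
    n_timepoints_tau: int = Field(6, ge=2)
    n_timepoints_abeta: int = Field(9, ge=2)
    n_vials: int = Field(4, ge=2)
    flies_per_vial: int = Field(10, gt=0)
    vial_sd: float = Field(0.2, ge=0.0)           # between-vial intercept SD
    noise_sd: float = Field(0.5, ge=0.0)          # vial-mean residual SD
    modifier_shift: float = -1.5                  # mm/s, enhancer default
    modifier_slope: float = -0.10                 # mm/s/day slope change


class CohortParams(BaseModel):
    """Cohort genotype generator: dosage ~ Binomial(2, f) per SNP, with
    optional subgroup enrichment at cluster-specific SNPs."""

    model_config = ConfigDict(extra="forbid")

    n_individuals: int = Field(99, gt=1)
    baseline_frequency: float = Field(0.3, gt=0.0, lt=1.0)
    snps_per_cluster: int = Field(10, gt=0)
    enrichment_delta: float = 0.2   # added to f at the subgroup's clusters
    subgroups: bool = True          # two anticorrelated risk subgroups


class SimulationConfig(BaseModel):
    """Root configuration for :func:`adscreen.simulate.simulate_screen`.

    Invariants: probabilities in [0, 1], frequencies in (0, 1), counts
    positive; the same (config, seed) yields byte-identical tables.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(0, ge=0)
    n_genes: int = Field(20, gt=0)
    n_control_genotypes: int = Field(4, gt=0)
    frac_degenerating: float = Field(0.2, ge=0.0, le=1.0)
    frac_erg_decreased: float = Field(0.2, ge=0.0, le=1.0)
    frac_stress_sensitive: float = Field(0.1, ge=0.0, le=1.0)
    frac_modifier: float = Field(0.1, ge=0.0, le=1.0)

    vacuole_mean_normal: float = Field(5.0, gt=0.0)
    vacuole_mean_degenerating: float = Field(25.0, gt=0.0)
    heads_per_genotype: int = Field(2, ge=2)

    heat_control_p: float = Field(0.26, ge=0.0, le=1.0)
    bang_control_p: float = Field(0.19, ge=0.0, le=1.0)
    stress_sensitive_p: float = Field(0.85, ge=0.0, le=1.0)
    flies_per_trial: int = Field(10, gt=0)
    n_replicates: int = Field(5, ge=3)

    erg: ErgParams = ErgParams()
    erg_effect_ratio: float = Field(0.5, ge=0.0)  # mutant amplitude multiplier

    climbing: ClimbingParams = ClimbingParams()
    cohort: CohortParams = CohortParams()

    def rng(self, *stream: object) -> np.random.Generator:
        """Named substream of the root seed (reproducible per table)."""
        key = [self.seed] + [
            zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stream
        ]
        return np.random.default_rng(np.random.SeedSequence(key))


class RunConfig(BaseModel):
    """End-to-end pipeline run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "results/pipeline"
    stages: list[
        Literal["simulate", "erg", "histology", "stress", "climb", "integrate", "riskscore"]
    ] = ["simulate", "erg", "histology", "stress", "climb", "integrate", "riskscore"]
    seed: int = Field(0, ge=0)
    strict: bool = False
    simulation: SimulationConfig = SimulationConfig()
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    vacuole_threshold: int = Field(15, gt=0)
    stress_cutoff: float = Field(0.60, ge=0.0, le=1.0)
    min_area_fraction: float = Field(0.10, ge=0.0)
    sort_component: int = Field(2, ge=1)

    @model_validator(mode="after")
    def _sync_seed(self) -> "RunConfig":
        # the root seed overrides the simulation block's seed
        object.__setattr__(self.simulation, "seed", self.seed)
        return self
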