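"""Brain-structure and stress-resilience hit-calling.

Structure: a genotype is annotated as degenerating when every examined
head (>= 2 per genotype) carries at least 15 vacuoles; wildtype brains run
up to ~10.  Essential genes assayed with two RNAi genotypes must satisfy
the criterion in both.

Resilience: a two-stage design.  The primary screen passes genotypes whose
single heat/bang trial reaches 60% impairment (both RNAi genotypes for
essential genes); candidates are then re-assayed with independent
biological replicates (5-10 flies each) and confirmed against the control
replicates by Kruskal--Wallis + Dunn at adjusted P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from adscreen.stats import kruskal_dunn

__all__ = [
    "VacuoleObservation",
    "StressTrial",
    "StructureCall",
    "StressConfirmation",
    "call_structure",
    "impairment_fraction",
    "primary_stress_screen",
    "confirm_stress_hits",
]

VACUOLE_THRESHOLD = 15
STRESS_CUTOFF = 0.60


@dataclass(frozen=True)
class VacuoleObservation:
    """One sectioned head's vacuole count."""

    genotype: str
    head_id: str
    vacuole_count: int

    def __post_init__(self) -> None:
        if self.vacuole_count < 0:
            raise ValueError("vacuole_count must be non-negative")


@dataclass(frozen=True)
class StressTrial:
    """One heat- or bang-sensitivity trial (a vial of flies)."""

    genotype: str
    stressor: Literal["heat", "bang"]
    n_flies: int
    n_impaired: int
    stage: Literal["primary", "replicate"] = "primary"
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if not 0 <= self.n_impaired <= self.n_flies:
            raise ValueError("n_impaired must lie in [0, n_flies]")


@dataclass(frozen=True)
class StructureCall:
    gene: str
    hit: bool
    per_genotype: dict[str, bool] = field(default_factory=dict)
    counts: dict[str, list[int]] = field(default_factory=dict)


def call_structure(
    observations: Sequence[VacuoleObservation],
    gene: str,
    threshold: int = VACUOLE_THRESHOLD,
    essential: bool = False,
    rule: Literal["all_heads", "mean"] = "all_heads",
) -> StructureCall:
    """Call structural degeneration for one gene from its head counts.

    ``all_heads`` (default) requires every examined head to reach the
    threshold; ``mean`` requires the per-genotype mean to.  Essential genes
    need both RNAi genotypes to satisfy the criterion.
    """
    by_genotype: dict[str, list[int]] = {}
    for obs in observations:
        by_genotype.setdefault(obs.genotype, []).append(obs.vacuole_count)
    if not by_genotype:
        raise ValueError(f"no observations for gene {gene!r}")
    for g, counts in by_genotype.items():
        if len(counts) < 2:
            raise ValueError(f"genotype {g!r} has <2 examined heads")
    if essential and len(by_genotype) < 2:
        raise ValueError(f"essential gene {gene!r} requires two RNAi genotypes")

    per_genotype = {}
    for g, counts in by_genotype.items():
        if rule == "all_heads":
            per_genotype[g] = all(c >= threshold for c in counts)
        else:
            per_genotype[g] = float(np.mean(counts)) >= threshold
    hit = all(per_genotype.values()) if essential else any(per_genotype.values())
    return StructureCall(gene=gene, hit=hit, per_genotype=per_genotype, counts=by_genotype)


def impairment_fraction(trial: StressTrial) -> float:
    """Fraction of flies impaired after the 10-second recovery period."""
    return trial.n_impaired / trial.n_flies


def primary_stress_screen(
    trials: Sequence[StressTrial],
    genotypes_by_gene: Mapping[str, Sequence[str]],
    stressor: str,
    cutoff: float = STRESS_CUTOFF,
    essential_genes: frozenset[str] | set[str] = frozenset(),
) -> set[str]:
    """Genes passing the single-trial primary screen for one stressor.

    A gene is a candidate iff its genotype reaches the impairment cutoff
    -- both RNAi genotypes for essential genes.  A declared genotype with
    no primary trial is an error (a silent miss would drop a gene).
    """
    fractions: dict[str, float] = {}
    for t in trials:
        if t.stressor == stressor and t.stage == "primary":
            fractions[t.genotype] = impairment_fraction(t)
    candidates = set()
    for gene, genotypes in genotypes_by_gene.items():
        missing = [g for g in genotypes if g not in fractions]
        if missing:
            raise ValueError(f"missing primary {stressor} trial(s) for {missing}")
        passing = [fractions[g] >= cutoff for g in genotypes]
        ok = all(passing) if gene in essential_genes else any(passing)
        if ok:
            candidates.add(gene)
    return candidates


@dataclass(frozen=True)
class StressConfirmation:
    gene: str
    stressor: str
    confirmed: bool
    p_adjusted_by_genotype: dict[str, float] = field(default_factory=dict)
    unconfirmable: bool = False  # insufficient replicates, reported not dropped


def confirm_stress_hits(
    replicate_trials: Sequence[StressTrial],
    control_genotype: str,
    candidates_by_gene: Mapping[str, Sequence[str]],
    stressor: str,
    alpha: float = 0.05,
    essential_genes: frozenset[str] | set[str] = frozenset(),
    adjust: str = "holm",
    min_replicates: int = 3,
) -> dict[str, StressConfirmation]:
    """Replicate-stage confirmation of primary-screen candidates.

    Impairment fractions of every candidate genotype are compared with the
    control replicates in one Kruskal--Wallis + Dunn family per stressor
    batch.  A gene is confirmed iff its genotype's adjusted p < alpha and
    the impairment exceeds the control's (both genotypes for essential
    genes).  Candidates with < ``min_replicates`` replicates are reported
    as unconfirmable rather than silently dropped.
    """
    fractions: dict[str, list[float]] = {}
    for t in replicate_trials:
        if t.stressor == stressor and t.stage == "replicate":
            fractions.setdefault(t.genotype, []).append(impairment_fraction(t))
    if len(fractions.get(control_genotype, [])) < min_replicates:
        raise ValueError(f"control {control_genotype!r} has <{min_replicates} replicates")

    out: dict[str, StressConfirmation] = {}
    testable: dict[str, list[float]] = {control_genotype: fractions[control_genotype]}
    short: set[str] = set()
    for gene, genotypes in candidates_by_gene.items():
        for g in genotypes:
            reps = fractions.get(g, [])
            if len(reps) < min_replicates:
                short.add(gene)
            else:
                testable[g] = reps

    if len(testable) > 1:
        _, dunn = kruskal_dunn(testable, control=control_genotype, adjust=adjust)
    else:
        dunn = {}

    for gene, genotypes in candidates_by_gene.items():
        if gene in short:
            out[gene] = StressConfirmation(gene, stressor, False, {}, unconfirmable=True)
            continue
        padj = {g: dunn[g].p_adjusted for g in genotypes}
        sig = [dunn[g].p_adjusted < alpha and dunn[g].direction > 0 for g in genotypes]
        confirmed = all(sig) if gene in essential_genes else any(sig)
        out[gene] = StressConfirmation(gene, stressor, confirmed, padj)
    return out
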