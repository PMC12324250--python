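"""Operating-characteristic experiments for the screen's hit-calling and
scoring machinery.

Each function simulates data under stated conditions with the package's
own generator, runs the corresponding analysis end to end, and measures
how it performs.  They back the validation suite and the reproduction
script; the condition defaults are the study conditions, not tuning knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from adscreen.hits import (
    StressTrial,
    VacuoleObservation,
    call_structure,
    confirm_stress_hits,
    primary_stress_screen,
)
from adscreen.locomotor import analyze_strain, consolidate_gene
from adscreen.risk import (
    best_separating_component,
    count_risk_alleles,
    run_pca,
    standardize,
)
from adscreen.simulate import SubgroupSpec, simulate_cohort

__all__ = [
    "structure_operating_characteristics",
    "stress_null_false_positive_rate",
    "control_impairment_means",
    "modifier_recovery",
    "subgroup_recovery",
]


def structure_operating_characteristics(
    seed: int = 0,
    n_genotypes: int = 200,
    mean_degenerating: float = 25.0,
    mean_normal: float = 5.0,
    n_heads: int = 2,
) -> dict[str, float]:
    """Sensitivity/specificity of the all-heads >= 15-vacuole rule on a
    half-degenerating, half-normal Poisson screen (2 heads each)."""
    rng = np.random.default_rng(seed)
    n_true = n_genotypes // 2
    tp = fp = 0
    for i in range(n_true):
        counts = rng.poisson(mean_degenerating, n_heads)
        obs = [VacuoleObservation("t", f"h{j}", int(c)) for j, c in enumerate(counts)]
        tp += call_structure(obs, "t").hit
    for i in range(n_genotypes - n_true):
        counts = rng.poisson(mean_normal, n_heads)
        obs = [VacuoleObservation("n", f"h{j}", int(c)) for j, c in enumerate(counts)]
        fp += call_structure(obs, "n").hit
    return {
        "sensitivity": tp / n_true,
        "specificity": 1.0 - fp / (n_genotypes - n_true),
        "n": n_genotypes,
    }


def control_impairment_means(
    seed: int = 0,
    n_trials: int = 10_000,
    n_flies: int = 10,
    heat_p: float = 0.26,
    bang_p: float = 0.19,
) -> dict[str, float]:
    """Mean impairment fraction of simulated control trials (per stressor)."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, p in (("heat", heat_p), ("bang", bang_p)):
        draws = rng.binomial(n_flies, p, n_trials) / n_flies
        out[name] = float(draws.mean())
    out["n"] = n_trials
    return out


def stress_null_false_positive_rate(
    seed: int = 0,
    n_genotypes: int = 500,
    n_flies: int = 10,
    n_replicates: int = 5,
    heat_p: float = 0.26,
    bang_p: float = 0.19,
) -> dict[str, float]:
    """Confirmed-hit rate of the screen-then-replicate pipeline when every
    genotype is a null at the control impairment probabilities."""
    rng = np.random.default_rng(seed)
    confirmed = 0
    for stressor, p in (("heat", heat_p), ("bang", bang_p)):
        genotypes = [f"g{i}" for i in range(n_genotypes)]
        primary = [
            StressTrial(g, stressor, n_flies, int(rng.binomial(n_flies, p)), "primary")
            for g in genotypes
        ]
        candidates = primary_stress_screen(primary, {g: [g] for g in genotypes}, stressor)
        if not candidates:
            continue
        reps = [
            StressTrial("ctrl", stressor, n_flies, int(x), "replicate", i + 1)
            for i, x in enumerate(rng.binomial(n_flies, p, n_replicates))
        ]
        for g in candidates:
            reps += [
                StressTrial(g, stressor, n_flies, int(x), "replicate", i + 1)
                for i, x in enumerate(rng.binomial(n_flies, p, n_replicates))
            ]
        out = confirm_stress_hits(reps, "ctrl", {g: [g] for g in candidates}, stressor)
        confirmed += sum(r.confirmed for r in out.values())
    return {"false_positive_rate": confirmed / (2 * n_genotypes), "n": 2 * n_genotypes}


def _strain_frame(
    rng: np.random.Generator,
    strain: str,
    shift: float,
    slope: float,
    noise_sd: float,
    vial_sd: float,
    n_vials: int,
    ages: np.ndarray,
    baseline: float = 12.0,
    decline: float = 0.5,
) -> pd.DataFrame:
    rows = []
    for genotype, sh, sl in (("disease_control", 0.0, 0.0), (strain, shift, slope)):
        for v in range(n_vials):
            b = rng.normal(0.0, vial_sd) if vial_sd > 0 else 0.0
            mu = baseline - decline * (ages - ages[0]) + sh + sl * (ages - ages[0])
            y = mu + b + rng.normal(0.0, noise_sd, ages.size)
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": genotype,
                        "vial_id": f"{genotype}_{strain}_v{v}",
                        "age_days": ages,
                        "mean_speed": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def modifier_recovery(
    seed: int = 0,
    n_genes: int = 500,
    frac_true: float = 0.10,
    shift: float = -1.5,
    noise_sd: float = 0.5,
    vial_sd: float = 0.2,
    n_vials: int = 4,
    n_timepoints: int = 6,
    n_strains: int = 2,
) -> dict[str, float]:
    """Gene-level sensitivity and false-discovery proportion of the
    modifier pipeline on a screen with ``frac_true`` true enhancers.

    Each gene contributes ``n_strains`` independent strains (each with its
    own disease-control batch); true genes carry the configured shift in
    every strain.  A gene is called when >= 2 strains agree in direction.
    """
    rng = np.random.default_rng(seed)
    ages = np.linspace(5.0, 18.0, n_timepoints)
    n_true = int(round(frac_true * n_genes))
    tp = fp = fn = 0
    for i in range(n_genes):
        is_true = i < n_true
        strain_calls = {}
        for s in range(n_strains):
            df = _strain_frame(
                rng, f"gene{i}_s{s}", shift if is_true else 0.0, 0.0,
                noise_sd, vial_sd, n_vials, ages,
            )
            res = analyze_strain(df, "disease_control", f"gene{i}_s{s}")
            strain_calls[f"s{s}"] = res.call
        call = consolidate_gene(strain_calls, f"gene{i}", "abeta")
        positive = call.high_confidence and call.direction == "enhancer"
        if is_true:
            tp += positive
            fn += not positive
        else:
            fp += positive
    called = tp + fp
    return {
        "sensitivity": tp / n_true if n_true else float("nan"),
        "false_discovery_proportion": fp / called if called else 0.0,
        "n": n_genes,
    }


def subgroup_recovery(
    seed: int = 0,
    n_seeds: int = 50,
    n_individuals: int = 100,
    snps_per_cluster: int = 10,
    baseline_f: float = 0.3,
    enriched_f: float = 0.5,
) -> dict[str, float]:
    """Recovery of two anticorrelated risk subgroups by PCA stratification.

    Group 1 (half the cohort) is enriched at ERG+Structure SNPs, group 2
    at Bang+Heat SNPs (frequency ``enriched_f`` vs ``baseline_f``).
    Reports the median point-biserial |r| of the best separating
    component over ``n_seeds`` replicates and the fraction of replicates
    where the {ERG, Structure} loadings share a sign opposite to
    {Bang, Heat} on that component.
    """
    clusters = {
        c: [f"{c}_snp{i}" for i in range(snps_per_cluster)]
        for c in ("ERG", "Structure", "Bang", "Heat")
    }
    freqs = {s: baseline_f for ss in clusters.values() for s in ss}
    delta = enriched_f - baseline_f
    half = n_individuals // 2
    labels = [0] * half + [1] * (n_individuals - half)
    rs, patterns = [], []
    for rep in range(n_seeds):
        sgs = [
            SubgroupSpec("g1", tuple(range(half)),
                         enriched=frozenset({"ERG", "Structure"}), delta=delta),
            SubgroupSpec("g2", tuple(range(half, n_individuals)),
                         enriched=frozenset({"Bang", "Heat"}), delta=delta),
        ]
        cohort = simulate_cohort(n_individuals, clusters, freqs, sgs,
                                 seed=(seed * 1009 + rep) % (2**31 - 1))
        scores = standardize(count_risk_alleles(cohort, clusters))
        pca = run_pca(scores)
        k, r = best_separating_component(pca, labels)
        rs.append(abs(r))
        idx = {c: scores.clusters.index(c) for c in clusters}
        L = pca.loadings[:, k - 1]
        patterns.append(
            bool(
                np.sign(L[idx["ERG"]]) == np.sign(L[idx["Structure"]])
                and np.sign(L[idx["Bang"]]) == np.sign(L[idx["Heat"]])
                and np.sign(L[idx["ERG"]]) != np.sign(L[idx["Bang"]])
            )
        )
    return {
        "median_abs_r": float(np.median(rs)),
        "loading_pattern_fraction": float(np.mean(patterns)),
        "n": n_seeds,
    }
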