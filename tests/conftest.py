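"""Shared test fixtures: small simulated datasets built at test time."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest


def make_climbing_frame(
    shift: float = 0.0,
    slope: float = 0.0,
    noise_sd: float = 0.0,
    vial_sd: float = 0.0,
    n_vials: int = 4,
    n_timepoints: int = 6,
    rng: np.random.Generator | None = None,
    baseline: float = 12.0,
    decline: float = 0.5,
) -> pd.DataFrame:
    """Two-genotype balanced climbing table under the generator's speed
    model; genotype 'mut' carries the shift and slope-change effects."""
    rng = rng or np.random.default_rng(0)
    ages = np.linspace(5.0, 18.0, n_timepoints)
    rows = []
    for genotype, sh, sl in (("ctrl", 0.0, 0.0), ("mut", shift, slope)):
        for v in range(n_vials):
            b = rng.normal(0.0, vial_sd) if vial_sd > 0 else 0.0
            for a in ages:
                mu = baseline - decline * (a - 5.0) + sh + sl * (a - 5.0)
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "genotype": genotype,
                        "vial_id": f"{genotype}_v{v}",
                        "age_days": a,
                        "mean_speed": mu + b + eps,
                    }
                )
    return pd.DataFrame(rows)


def exact_permutation_pvalue(x: list[float], y: list[float]) -> float:
    """Exact two-sided permutation test on the difference of group mean
    ranks (the statistic behind Dunn's z), enumerating all labelings.

    Independent oracle for the rank-based comparisons; only feasible for
    small instances (len(x) + len(y) <= 12 or so).
    """
    from scipy.stats import rankdata

    pooled = np.array(list(x) + list(y), dtype=float)
    ranks = rankdata(pooled)
    n1 = len(x)
    idx = range(len(pooled))
    observed = abs(ranks[:n1].mean() - ranks[n1:].mean())
    count = 0
    total = 0
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        stat = abs(ranks[mask].mean() - ranks[~mask].mean())
        count += stat >= observed - 1e-12
        total += 1
    return count / total


@pytest.fixture(scope="session")
def default_sim_config():
    from adscreen.config import SimulationConfig

    return SimulationConfig(seed=7, n_genes=10, n_control_genotypes=3)
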