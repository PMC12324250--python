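"""Shared multiple-comparison machinery.

Two procedures are used throughout the screen:

* Holm's step-down correction (``holm_adjust``), applied to the three
  locomotor effect p-values within each strain;
* the Kruskal--Wallis omnibus test followed by Dunn's pairwise z-tests of
  each mutant genotype against its control (``kruskal_dunn``), used for the
  electroretinogram components and the stress-replicate confirmation stage.

Dunn's statistic compares mean ranks from the *pooled* ranking of all
groups, with the tie-corrected null variance

    var = (N(N+1)/12 - T) * (1/n_i + 1/n_j),   T = sum(t^3 - t) / (12(N-1)),

where the sum runs over tie groups of size t.  Two-sided p-values come from
the normal approximation and are then adjusted across the mutant-vs-control
family (Holm by default, Bonferroni optionally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["holm_adjust", "kruskal_dunn", "DunnResult"]


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotone non-decreasing adjusted values, cap at 1.

    Parameters
    ----------
    pvalues
        Raw p-values, each in [0, 1].

    Raises
    ------
    ValueError
        If any value lies outside [0, 1] or is not finite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return []
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adj[idx] = running
    return adj.tolist()


def _tie_correction(ranksum_values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups in the pooled sample."""
    _, counts = np.unique(ranksum_values, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


@dataclass(frozen=True)
class DunnResult:
    """One mutant-vs-control comparison from :func:`kruskal_dunn`."""

    group: str
    z: float
    p_raw: float
    p_adjusted: float
    direction: int  # sign(mutant mean - control mean), on the raw values
    degenerate: bool = False  # all observations tied across the family


def kruskal_dunn(
    values_by_group: Mapping[str, Sequence[float]],
    control: str,
    adjust: str = "holm",
) -> tuple[float, dict[str, DunnResult]]:
    """Kruskal--Wallis across all groups, then Dunn z-tests vs the control.

    Parameters
    ----------
    values_by_group
        Observations keyed by genotype; must include ``control`` and at
        least one other group, each with >= 2 observations.
    control
        Key of the control group; every other group is compared against it.
    adjust
        ``"holm"`` (default) or ``"bonferroni"``, applied across the
        mutant-vs-control comparisons.

    Returns
    -------
    (kw_pvalue, results)
        The omnibus Kruskal--Wallis p-value and one :class:`DunnResult`
        per non-control group.  If every observation in the family is tied
        the ranks are degenerate: all comparisons are flagged and reported
        with p = 1.
    """
    if control not in values_by_group:
        raise ValueError(f"control group {control!r} missing")
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups (control plus one mutant)")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    pooled = np.concatenate([arrays[g] for g in groups])
    n = {g: arrays[g].size for g in groups}
    N = pooled.size

    if np.all(pooled == pooled[0]):
        results = {
            g: DunnResult(g, 0.0, 1.0, 1.0, 0, degenerate=True)
            for g in groups
            if g != control
        }
        return 1.0, results

    kw_p = float(sps.kruskal(*[arrays[g] for g in groups]).pvalue)

    ranks = sps.rankdata(pooled)  # mid-ranks
    offsets = np.cumsum([0] + [n[g] for g in groups])
    mean_rank = {
        g: float(ranks[offsets[i] : offsets[i + 1]].mean())
        for i, g in enumerate(groups)
    }
    ties = _tie_correction(pooled)
    base_var = N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))

    mutants = [g for g in groups if g != control]
    zs, praws, dirs = [], [], []
    for g in mutants:
        se = np.sqrt(base_var * (1.0 / n[g] + 1.0 / n[control]))
        z = (mean_rank[g] - mean_rank[control]) / se if se > 0 else 0.0
        zs.append(z)
        praws.append(float(2.0 * sps.norm.sf(abs(z))))
        dirs.append(int(np.sign(arrays[g].mean() - arrays[control].mean())))

    if adjust == "holm":
        padj = holm_adjust(praws)
    elif adjust == "bonferroni":
        padj = [min(1.0, p * len(praws)) for p in praws]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    results = {
        g: DunnResult(g, z, pr, pa, d)
        for g, z, pr, pa, d in zip(mutants, zs, praws, padj, dirs)
    }
    return kw_p, results
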