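"""Longitudinal locomotor (negative-geotaxis) modifier analysis.

Climbing speed declines with age in flies pan-neuronally expressing
amyloid-beta or tau; a genetic manipulation is an *enhancer* if it worsens
that decline and a *suppressor* if it improves it.  The unit of
observation is the mean speed of the ~10 females in one vial at one age;
each genotype contributes 4 vials followed over days 5-18 (6 timepoints
for the tau model, 9 for amyloid-beta).

Model
-----
speed ~ f(age) + genotype * f(age) fixed effects (f quadratic by default)
with a random intercept per vial.  Because the design is balanced (every
vial observed at every shared age), the model decomposes into two
orthogonal error strata with *exact* F-tests under normality:

* additive effect (curve shift): one-way ANOVA of genotype on the
  per-vial mean speeds -- the between-vial stratum, F(1, V-2);
* interactive effect (slope/curvature change): F-test of the
  genotype x f(age) terms after absorbing per-vial intercepts -- the
  within-vial stratum;
* overall genotype effect: Fisher's combination of the two stratum
  p-values (independent under the model, hence exactly calibrated).

The three p-values are Holm-adjusted within each strain.  The curve-level
effect size is the signed area between the fitted mutant and disease
control curves over the shared age span (mm/s * day; positive = faster
than the disease control, the suppressor direction).  The study's manual
plot review is codified as a minimum |area| floor (default 10% of the
area under the control curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from adscreen.stats import holm_adjust

__all__ = [
    "LongitudinalFit",
    "ModifierResult",
    "GeneModifierCall",
    "fit_longitudinal",
    "test_effects",
    "area_between_curves",
    "classify_strain",
    "consolidate_gene",
    "analyze_strain",
    "estimate_power",
]

P_FLOOR = 1e-300  # reported when the F statistic is numerically unbounded
_TINY = 1e-10

Basis = Literal["quadratic", "linear", "log"]


def _basis_columns(age: np.ndarray, basis: Basis) -> np.ndarray:
    if basis == "quadratic":
        return np.column_stack([age, age**2])
    if basis == "linear":
        return age[:, None]
    if basis == "log":
        return np.log(age)[:, None]
    raise ValueError(f"unknown age basis {basis!r}")


@dataclass
class LongitudinalFit:
    """Fitted two-genotype longitudinal model (balanced design)."""

    control: str
    test: str
    basis: Basis
    coefficients: dict[str, float]     # intercept, age terms, genotype, interactions
    ages: np.ndarray                   # shared age grid
    n_vials: dict[str, int]
    # error strata
    f_additive: float
    df_additive: tuple[int, int]
    ss_additive: tuple[float, float]   # (effect SS, residual SS), between-vial
    f_interactive: float
    df_interactive: tuple[int, int]
    ss_interactive: tuple[float, float]

    def predict(self, genotype: str, ages: np.ndarray | None = None) -> np.ndarray:
        """Fitted mean speed curve for one genotype."""
        a = np.asarray(self.ages if ages is None else ages, dtype=float)
        B = _basis_columns(a, self.basis)
        c = self.coefficients
        k = B.shape[1]
        y = c["intercept"] + B @ np.array([c[f"age{j+1}"] for j in range(k)])
        if genotype == self.test:
            y = y + c["genotype"] + B @ np.array(
                [c[f"genotype:age{j+1}"] for j in range(k)]
            )
        elif genotype != self.control:
            raise KeyError(f"unknown genotype {genotype!r}")
        return y


def _stratum_p(ss_effect: float, df_effect: int, ss_resid: float, df_resid: int) -> tuple[float, float]:
    """(F, p) with degenerate-variance guards: a zero-residual stratum gives
    p = 1 when the effect SS is also zero, else a numerically floored p."""
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom in stratum")
    ms_resid = ss_resid / df_resid
    ms_effect = ss_effect / df_effect
    if ms_resid < _TINY:
        return (0.0, 1.0) if ms_effect < _TINY else (np.inf, P_FLOOR)
    f = ms_effect / ms_resid
    return f, float(sps.f.sf(f, df_effect, df_resid))


def fit_longitudinal(
    series: pd.DataFrame,
    control: str,
    test: str,
    basis: Basis = "quadratic",
) -> LongitudinalFit:
    """Fit the vial-random-intercept model for one test strain vs the
    disease control.

    ``series`` needs columns genotype, vial_id, age_days, mean_speed.
    Requires >= 3 shared timepoints and >= 2 vials per genotype; ages not
    shared by every vial are dropped (the model strata assume balance).
    """
    needed = {"genotype", "vial_id", "age_days", "mean_speed"}
    if not needed <= set(series.columns):
        raise ValueError(f"series must have columns {sorted(needed)}")
    df = series[series["genotype"].isin([control, test])].copy()
    if df["genotype"].nunique() != 2:
        raise ValueError("need data for both the control and the test genotype")

    # shared (balanced) age grid
    ages_by_vial = df.groupby("vial_id")["age_days"].apply(set)
    shared = set.intersection(*ages_by_vial.tolist())
    if len(shared) < 3:
        raise ValueError("need >= 3 timepoints shared by every vial")
    df = df[df["age_days"].isin(shared)]
    ages = np.array(sorted(shared), dtype=float)

    vials = df.groupby(["genotype", "vial_id"]).size()
    n_vials = vials.groupby("genotype").size().to_dict()
    if min(n_vials.values()) < 2:
        raise ValueError("need >= 2 vials per genotype")

    y = df["mean_speed"].to_numpy(dtype=float)
    a = df["age_days"].to_numpy(dtype=float)
    g = (df["genotype"] == test).to_numpy(dtype=float)
    vial_codes, vial_index = pd.factorize(df["vial_id"], sort=True)
    N, V = y.size, vial_index.size
    B = _basis_columns(a, basis)
    k = B.shape[1]

    # --- fixed-effect estimates: OLS on the full design (unbiased; equal to
    # GLS for the balanced random-intercept model)
    X = np.column_stack([np.ones(N), B, g, B * g[:, None]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    names = (
        ["intercept"]
        + [f"age{j+1}" for j in range(k)]
        + ["genotype"]
        + [f"genotype:age{j+1}" for j in range(k)]
    )
    coefficients = dict(zip(names, (float(c) for c in coef)))

    # --- between-vial stratum: genotype on vial means
    vm = df.groupby(["genotype", "vial_id"])["mean_speed"].mean()
    grand = vm.mean()
    group_means = vm.groupby("genotype").mean()
    counts = vm.groupby("genotype").size()
    ss_b = float(sum(counts[gn] * (group_means[gn] - grand) ** 2 for gn in counts.index))
    ss_w = float(sum((vm[gn] - group_means[gn]).pow(2).sum() for gn in counts.index))
    df_b = (1, V - 2)
    f_b, _ = _stratum_p(ss_b, df_b[0], ss_w, df_b[1])

    # --- within-vial stratum: interaction F after absorbing vial intercepts
    D = np.zeros((N, V))
    D[np.arange(N), vial_codes] = 1.0
    X_full = np.column_stack([D, B, B * g[:, None]])
    X_red = np.column_stack([D, B])
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
    df_w = (k, N - V - 2 * k)
    f_w, _ = _stratum_p(max(rss_red - rss_full, 0.0), df_w[0], rss_full, df_w[1])

    return LongitudinalFit(
        control=control,
        test=test,
        basis=basis,
        coefficients=coefficients,
        ages=ages,
        n_vials={str(kk): int(v) for kk, v in n_vials.items()},
        f_additive=f_b,
        df_additive=df_b,
        ss_additive=(ss_b, ss_w),
        f_interactive=f_w,
        df_interactive=df_w,
        ss_interactive=(max(rss_red - rss_full, 0.0), rss_full),
    )


def test_effects(fit: LongitudinalFit) -> dict[str, float]:
    """Raw p-values for the three nested effect comparisons.

    Returns ``{"genotype": p, "additive": p, "interactive": p}`` --
    overall genotype difference, curve shift, and slope/curvature change.
    """
    _, p_add = _stratum_p(*_unpack(fit.ss_additive, fit.df_additive))
    _, p_int = _stratum_p(*_unpack(fit.ss_interactive, fit.df_interactive))
    # Fisher combination over the two independent strata
    if p_add <= P_FLOOR or p_int <= P_FLOOR:
        p_gen = P_FLOOR
    else:
        chi2 = -2.0 * (np.log(p_add) + np.log(p_int))
        p_gen = float(sps.chi2.sf(chi2, 4))
    return {"genotype": p_gen, "additive": p_add, "interactive": p_int}


def _unpack(ss: tuple[float, float], dfs: tuple[int, int]):
    return ss[0], dfs[0], ss[1], dfs[1]


def area_between_curves(
    test_curve: np.ndarray, control_curve: np.ndarray, age_grid: np.ndarray
) -> float:
    """Signed trapezoidal integral of (test - control) over the age span,
    in mm/s * day.  Positive = faster than the disease control
    (suppressor direction)."""
    t = np.asarray(test_curve, float)
    c = np.asarray(control_curve, float)
    a = np.asarray(age_grid, float)
    if not (t.shape == c.shape == a.shape):
        raise ValueError("curves and grid must share one shape")
    if a.size < 2 or np.any(np.diff(a) <= 0):
        raise ValueError("age grid must be increasing with >= 2 points")
    return float(np.trapezoid(t - c, a))


@dataclass
class ModifierResult:
    """Per-strain modifier outcome (volcano-plot row)."""

    strain: str
    model: str                        # "abeta" or "tau"
    p_raw: dict[str, float]
    p_adjusted: dict[str, float]
    area: float                       # mm/s * day, test minus disease control
    control_curve_area: float
    call: Literal["enhancer", "suppressor", "none"] = "none"


def classify_strain(
    result: ModifierResult,
    alpha: float = 0.05,
    min_area_fraction: float = 0.10,
    gate: Literal["any", "interaction_only"] = "any",
) -> ModifierResult:
    """Assign enhancer/suppressor/none from the adjusted p-values and the
    area floor (the codified stand-in for manual plot review)."""
    if gate == "any":
        significant = min(result.p_adjusted.values()) < alpha
    else:
        significant = result.p_adjusted["interactive"] < alpha
    floor = min_area_fraction * abs(result.control_curve_area)
    if significant and abs(result.area) > floor and result.area != 0:
        result.call = "suppressor" if result.area > 0 else "enhancer"
    else:
        result.call = "none"
    return result


@dataclass
class GeneModifierCall:
    """Gene-level consolidation of strain calls (>= 2 consistent strains
    for high confidence)."""

    gene: str
    model: str
    high_confidence: bool
    direction: Literal["enhancer", "suppressor", "none"]
    supporting_strains: list[str] = field(default_factory=list)
    conflict: bool = False


def consolidate_gene(
    strain_calls: Mapping[str, str], gene: str, model: str, min_strains: int = 2
) -> GeneModifierCall:
    """Consolidate per-strain calls ({strain: call}) into one gene call.

    High confidence requires >= ``min_strains`` strains with the same
    direction and no strain called in the opposite direction.
    """
    if not strain_calls:
        raise ValueError("need at least one strain call")
    by_dir: dict[str, list[str]] = {"enhancer": [], "suppressor": []}
    for strain, call in strain_calls.items():
        if call in by_dir:
            by_dir[call].append(strain)
    active = {d: s for d, s in by_dir.items() if s}
    if len(active) > 1:
        return GeneModifierCall(gene, model, False, "none", conflict=True)
    if not active:
        return GeneModifierCall(gene, model, False, "none")
    direction, strains = next(iter(active.items()))
    return GeneModifierCall(
        gene,
        model,
        high_confidence=len(strains) >= min_strains,
        direction=direction if len(strains) >= min_strains else "none",
        supporting_strains=sorted(strains),
    )


def analyze_strain(
    series: pd.DataFrame,
    control: str,
    strain: str,
    model: str = "tau",
    basis: Basis = "quadratic",
    alpha: float = 0.05,
    min_area_fraction: float = 0.10,
    gate: Literal["any", "interaction_only"] = "any",
) -> ModifierResult:
    """Fit, test, Holm-adjust, compute the area, and classify one strain."""
    fit = fit_longitudinal(series, control=control, test=strain, basis=basis)
    p_raw = test_effects(fit)
    keys = list(p_raw)
    p_adj = dict(zip(keys, holm_adjust([p_raw[k] for k in keys])))
    grid = fit.ages
    ctrl_curve = fit.predict(control, grid)
    test_curve = fit.predict(strain, grid)
    result = ModifierResult(
        strain=strain,
        model=model,
        p_raw=p_raw,
        p_adjusted=p_adj,
        area=area_between_curves(test_curve, ctrl_curve, grid),
        control_curve_area=float(np.trapezoid(ctrl_curve, grid)),
    )
    return classify_strain(result, alpha=alpha, min_area_fraction=min_area_fraction, gate=gate)


def estimate_power(
    shift: float,
    slope_change: float,
    noise_sd: float,
    vial_sd: float,
    n_vials: int,
    n_timepoints: int,
    n_sims: int,
    alpha: float = 0.05,
    seed: int = 0,
    baseline: float = 12.0,
    decline: float = 0.5,
    age_start: float = 5.0,
    age_end: float = 18.0,
    gate: Literal["any", "interaction_only"] = "any",
) -> tuple[float, float]:
    """Monte-Carlo power of the per-strain test at significance ``alpha``.

    Simulates ``n_sims`` balanced two-genotype datasets under the
    generator's speed model and reports the fraction with a Holm-adjusted
    p below ``alpha``, with its binomial standard error.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    ages = np.linspace(age_start, age_end, n_timepoints)
    hits = 0
    for _ in range(n_sims):
        frames = []
        for gname, sh, sl in (("ctrl", 0.0, 0.0), ("mut", shift, slope_change)):
            for v in range(n_vials):
                b = rng.normal(0.0, vial_sd)
                mu = baseline - decline * (ages - age_start) + sh + sl * (ages - age_start)
                y = mu + b + rng.normal(0.0, noise_sd, ages.size)
                frames.append(
                    pd.DataFrame(
                        {
                            "genotype": gname,
                            "vial_id": f"{gname}_v{v}",
                            "age_days": ages,
                            "mean_speed": y,
                        }
                    )
                )
        df = pd.concat(frames, ignore_index=True)
        fit = fit_longitudinal(df, control="ctrl", test="mut")
        p_adj = holm_adjust(list(test_effects(fit).values()))
        if gate == "any":
            hit = min(p_adj) < alpha
        else:
            hit = p_adj[2] < alpha
        hits += bool(hit)
    power = hits / n_sims
    se = float(np.sqrt(power * (1 - power) / n_sims))
    return power, se
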