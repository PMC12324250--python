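"""Electroretinogram feature extraction and hit-calling.

An ERG trace has three quantified components: the light-coincident
receptor potential (LCRP, the sustained depolarization during the light
pulse), and the on/off transients (brief postsynaptic excursions at
stimulus onset and offset).  Traces follow the corneal-negative
convention -- depolarization is negative voltage -- and features are
reported as non-negative magnitudes.

Hit-calling compares each mutant genotype to its eye-color-matched control
with a Kruskal--Wallis omnibus test followed by Dunn's pairwise z-tests
(see :mod:`adscreen.stats`); a gene's overall class is ``decreased``,
``increased``, ``mixed`` or ``none`` depending on the directions of its
significant components.  Essential genes assayed with two RNAi strains
count a component only when both strains agree in significance and
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from adscreen.stats import kruskal_dunn

__all__ = [
    "ErgTrace",
    "ErgFeatures",
    "FeatureWindows",
    "ErgComponentResult",
    "ErgGeneResult",
    "average_fly_traces",
    "extract_features",
    "compare_genotypes",
    "classify_gene",
    "COMPONENTS",
]

COMPONENTS = ("lcrp_amplitude", "on_transient", "off_transient")


@dataclass(frozen=True)
class ErgTrace:
    """One voltage trace on a uniform time grid (seconds / mV)."""

    time: np.ndarray
    voltage: np.ndarray
    stimulus_onset: float
    stimulus_offset: float
    genotype: str = ""
    fly_id: str = ""
    eye_color: str = "white"  # "white" or "orange_red"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and voltage must be matching 1-d arrays")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (t[0] <= self.stimulus_onset < self.stimulus_offset <= t[-1]):
            raise ValueError("stimulus window must lie within the time span")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltage", v)


@dataclass(frozen=True)
class ErgFeatures:
    """Non-negative component magnitudes in mV."""

    lcrp_amplitude: float
    on_transient: float
    off_transient: float

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            x = getattr(self, name)
            if not np.isfinite(x) or x < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {x}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPONENTS}


@dataclass(frozen=True)
class FeatureWindows:
    """Measurement windows, all in seconds relative to the stimulus.

    baseline: this long before onset; on: this long after onset;
    plateau: trailing fraction of the stimulus; off: this long after offset.
    """

    baseline_s: float = 0.200
    on_s: float = 0.100
    plateau_fraction: float = 0.5
    off_s: float = 0.200
    lcrp_mode: Literal["plateau_mean", "peak"] = "plateau_mean"


def average_fly_traces(traces: Sequence[ErgTrace]) -> ErgTrace:
    """Pointwise mean of one fly's traces (one biological replicate).

    All traces must share the time grid and stimulus window.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    first = traces[0]
    for tr in traces[1:]:
        if tr.time.shape != first.time.shape or not np.allclose(tr.time, first.time):
            raise ValueError("mismatched time grids")
        if (tr.stimulus_onset, tr.stimulus_offset) != (
            first.stimulus_onset,
            first.stimulus_offset,
        ):
            raise ValueError("mismatched stimulus windows")
    mean_v = np.mean([tr.voltage for tr in traces], axis=0)
    return replace(first, voltage=mean_v)


_EPS = 1e-9  # float-grid tolerance for window membership


def _window_mask(
    t: np.ndarray, lo: float, hi: float, what: str, open_hi: bool = False
) -> np.ndarray:
    if lo < t[0] - _EPS or hi > t[-1] + _EPS:
        raise ValueError(f"{what} window [{lo}, {hi}] outside trace span")
    upper = (t < hi - _EPS) if open_hi else (t <= hi + _EPS)
    mask = (t >= lo - _EPS) & upper
    if not mask.any():
        raise ValueError(f"{what} window is empty on this grid")
    return mask


def extract_features(trace: ErgTrace, windows: FeatureWindows | None = None) -> ErgFeatures:
    """Measure (LCRP amplitude, on transient, off transient) off one trace.

    baseline      = mean voltage over the pre-onset window
    lcrp          = |plateau-window mean - baseline|   (or peak excursion)
    on transient  = max excursion beyond the plateau level, in the
                    depolarizing direction, within the on window
    off transient = max excursion beyond baseline, in the repolarizing
                    direction, within the off window

    Features are invariant to constant voltage offsets by construction.
    """
    w = windows or FeatureWindows()
    t, v = trace.time, trace.voltage
    on, off = trace.stimulus_onset, trace.stimulus_offset

    # the sample at the onset itself already carries the light response, so
    # the baseline window is open at its upper end
    base_mask = _window_mask(t, on - w.baseline_s, on, "baseline", open_hi=True)
    baseline = float(v[base_mask].mean())

    stim_len = off - on
    plat_lo = off - w.plateau_fraction * stim_len
    plat_mask = _window_mask(t, plat_lo, off, "plateau")
    if w.lcrp_mode == "plateau_mean":
        plateau_level = float(v[plat_mask].mean())
    else:  # peak: most extreme excursion from baseline during the stimulus
        stim_mask = _window_mask(t, on, off, "stimulus")
        excursion = v[stim_mask] - baseline
        plateau_level = baseline + float(excursion[np.argmax(np.abs(excursion))])
    lcrp = abs(plateau_level - baseline)

    # depolarizing direction: sign of (plateau - baseline); corneal-negative
    # traces give -1.  A flat trace has no depolarization; default to -1.
    direction = float(np.sign(plateau_level - baseline)) or -1.0

    on_mask = _window_mask(t, on, on + w.on_s, "on")
    on_exc = (v[on_mask] - plateau_level) * direction
    on_transient = max(0.0, float(on_exc.max()))

    off_mask = _window_mask(t, off, off + w.off_s, "off")
    off_exc = (v[off_mask] - baseline) * (-direction)
    off_transient = max(0.0, float(off_exc.max()))

    return ErgFeatures(lcrp, on_transient, off_transient)


@dataclass(frozen=True)
class ErgComponentResult:
    """Mutant-vs-control outcome for one trace component."""

    component: str
    control_ratio: float  # mutant mean / control mean
    direction: int        # sign(mutant mean - control mean)
    p_raw: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def compare_genotypes(
    features_by_genotype: Mapping[str, Sequence[ErgFeatures]],
    control_genotype: str,
    eye_color_by_genotype: Mapping[str, str] | None = None,
    adjust: str = "holm",
) -> dict[str, dict[str, ErgComponentResult]]:
    """Compare each mutant's component magnitudes against the control.

    One Kruskal--Wallis + Dunn family per component, across all genotypes
    in the call.  Mutants must share the control's eye color when
    ``eye_color_by_genotype`` is provided (the control lookup is
    eye-color-keyed upstream; this enforces the pairing).

    Returns ``{genotype: {component: ErgComponentResult}}``.
    """
    if control_genotype not in features_by_genotype:
        raise ValueError(f"control {control_genotype!r} missing")
    if eye_color_by_genotype is not None:
        control_color = eye_color_by_genotype[control_genotype]
        for g in features_by_genotype:
            if eye_color_by_genotype.get(g, control_color) != control_color:
                raise ValueError(
                    f"eye-color mismatch: {g!r} is "
                    f"{eye_color_by_genotype[g]!r}, control is {control_color!r}"
                )
    for g, feats in features_by_genotype.items():
        if len(feats) < 2:
            raise ValueError(f"genotype {g!r} needs >= 2 replicates")

    out: dict[str, dict[str, ErgComponentResult]] = {
        g: {} for g in features_by_genotype if g != control_genotype
    }
    for comp in COMPONENTS:
        values = {
            g: [getattr(f, comp) for f in feats]
            for g, feats in features_by_genotype.items()
        }
        _, dunn = kruskal_dunn(values, control=control_genotype, adjust=adjust)
        ctrl_mean = float(np.mean(values[control_genotype]))
        for g, res in dunn.items():
            mut_mean = float(np.mean(values[g]))
            ratio = mut_mean / ctrl_mean if ctrl_mean != 0 else np.nan
            out[g][comp] = ErgComponentResult(
                comp, ratio, res.direction, res.p_raw, res.p_adjusted
            )
    return out


@dataclass(frozen=True)
class ErgGeneResult:
    """Gene-level neurophysiology call.

    ``overall_class`` is ``none`` iff no component is significant and
    ``mixed`` iff significant components point in both directions.
    """

    gene: str
    component_direction: dict[str, int] = field(default_factory=dict)
    overall_class: Literal["decreased", "increased", "mixed", "none"] = "none"


def classify_gene(
    strain_results: Sequence[Mapping[str, ErgComponentResult]],
    gene: str,
    essential: bool = False,
    alpha: float = 0.05,
) -> ErgGeneResult:
    """Combine per-strain component results into one gene call.

    For essential genes (two RNAi strains) a component counts only when it
    is significant in *both* strains with the same direction.
    """
    if len(strain_results) == 0:
        raise ValueError("need results from at least one strain")
    if essential and len(strain_results) < 2:
        raise ValueError(f"essential gene {gene!r} requires two RNAi strain results")

    sig_dirs: dict[str, int] = {}
    for comp in COMPONENTS:
        per_strain = [r[comp] for r in strain_results if comp in r]
        if not per_strain:
            continue
        if essential:
            hits = [r for r in per_strain if r.p_adjusted < alpha]
            if len(hits) == len(per_strain) and len({r.direction for r in hits}) == 1:
                sig_dirs[comp] = hits[0].direction
        else:
            hits = [r for r in per_strain if r.p_adjusted < alpha]
            if hits:
                # take the direction of the strongest strain
                best = min(hits, key=lambda r: r.p_adjusted)
                sig_dirs[comp] = best.direction

    directions = set(sig_dirs.values())
    if not directions:
        cls = "none"
    elif directions == {-1}:
        cls = "decreased"
    elif directions == {1}:
        cls = "increased"
    else:
        cls = "mixed"
    return ErgGeneResult(gene=gene, component_direction=sig_dirs, overall_class=cls)
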