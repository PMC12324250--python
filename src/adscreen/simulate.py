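"""Synthetic screen and cohort generator.

Emulates the statistical structure of the screen's raw inputs under a
fixed seed:

* vacuole counts are Poisson -- mean 5 for normal brains (comfortably
  under the 15-vacuole rule, matching the observation that wildtype
  brains carry up to ~10) and 25 for degenerating genotypes;
* heat/bang impairment is Binomial per ~10-fly trial, with control
  probabilities 0.26 (heat) and 0.19 (bang), the screen-wide control
  averages the 60% primary cutoff was anchored to;
* ERG traces have a pre-stimulus baseline, a sustained depolarization
  plateau stored as negative voltage (corneal-negative convention), brief
  onset/offset transient excursions, and additive Gaussian noise;
* climbing speed declines with age from day 5 to day 18 (6 timepoints for
  tau-like runs, 9 for amyloid-beta-like), with per-vial random
  intercepts and genotype shift / slope-change modifier effects;
* cohort dosages are Binomial(2, f) per SNP, with optional anticorrelated
  risk subgroups enriched at cluster-specific SNPs.

All randomness flows from the root seed through named substreams, so any
single table is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from adscreen.config import ClimbingParams, ErgParams, SimulationConfig
from adscreen.erg import ErgTrace
from adscreen.risk import CohortGenotypes

__all__ = [
    "ScreenDataset",
    "simulate_erg_trace",
    "simulate_screen",
    "simulate_cohort",
    "SubgroupSpec",
    "write_screen_tables",
    "write_cohort_vcf",
]


@dataclass
class ScreenDataset:
    """Every table the pipeline consumes, plus the generating truth."""

    vacuole_table: pd.DataFrame    # genotype, head_id, vacuole_count
    erg_traces: list[ErgTrace]     # per-fly averaged biological replicates
    stress_trials: pd.DataFrame    # genotype, stressor, stage, replicate_id, n_flies, n_impaired
    climbing_table: pd.DataFrame   # disease_model, genotype, strain, vial_id, age_days, mean_speed
    truth: dict[str, dict] = field(default_factory=dict)  # per-genotype labels
    control_genotypes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if (self.vacuole_table["vacuole_count"] < 0).any():
            raise AssertionError("negative vacuole count")
        st = self.stress_trials
        if (st["n_impaired"] > st["n_flies"]).any():
            raise AssertionError("n_impaired exceeds n_flies")
        if (self.climbing_table["mean_speed"] < 0).any():
            raise AssertionError("negative speed")
        tabled = (
            set(self.vacuole_table["genotype"])
            | set(st["genotype"])
            | set(self.climbing_table["genotype"])
            | {t.genotype for t in self.erg_traces}
        )
        missing = set(self.truth) - tabled
        if missing:
            raise AssertionError(f"truth labels for untabled genotypes: {missing}")


def simulate_erg_trace(
    rng: np.random.Generator,
    baseline_mV: float = 0.0,
    plateau_mV: float = 12.0,
    on_mV: float = 4.0,
    off_mV: float = 5.0,
    noise_sd: float = 0.5,
    stimulus_window: tuple[float, float] = (0.5, 1.5),
    sampling_rate: float = 1000.0,
    trace_duration: float = 2.0,
    transient_width: float = 0.02,
    genotype: str = "",
    fly_id: str = "",
    eye_color: str = "white",
) -> ErgTrace:
    """One voltage trace: baseline, plateau step during the stimulus
    (depolarization negative), a brief onset excursion of magnitude
    ``on_mV`` beyond the plateau, a brief offset excursion of ``off_mV``
    beyond baseline, plus Gaussian noise.

    The transients are flat-topped so that a noiseless trace round-trips
    exactly through feature extraction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    onset, offset = stimulus_window
    if not (0.0 <= onset < offset <= trace_duration):
        raise ValueError("stimulus window must lie inside the trace span")
    eps = 1e-9
    n_samples = int(round(trace_duration * sampling_rate)) + 1
    t = np.linspace(0.0, trace_duration, n_samples)
    v = np.full_like(t, baseline_mV)

    stim = (t >= onset - eps) & (t <= offset + eps)
    v[stim] = baseline_mV - plateau_mV
    on_bump = (t >= onset - eps) & (t <= onset + transient_width + eps)
    v[on_bump] -= on_mV
    off_bump = (t > offset + eps) & (t <= offset + transient_width + eps)
    v[off_bump] = baseline_mV + off_mV

    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, t.size)
    return ErgTrace(
        time=t,
        voltage=v,
        stimulus_onset=onset,
        stimulus_offset=offset,
        genotype=genotype,
        fly_id=fly_id,
        eye_color=eye_color,
    )


def _climbing_frame(
    rng: np.random.Generator,
    params: ClimbingParams,
    genotype: str,
    strain: str,
    model: str,
    shift: float,
    slope_change: float,
) -> pd.DataFrame:
    n_tp = params.n_timepoints_tau if model == "tau" else params.n_timepoints_abeta
    ages = np.linspace(params.age_start, params.age_end, n_tp)
    frames = []
    for v in range(params.n_vials):
        b = rng.normal(0.0, params.vial_sd) if params.vial_sd > 0 else 0.0
        mu = (
            params.baseline_speed
            - params.decline_per_day * (ages - params.age_start)
            + shift
            + slope_change * (ages - params.age_start)
        )
        noise = rng.normal(0.0, params.noise_sd, n_tp) if params.noise_sd > 0 else 0.0
        speed = np.clip(mu + b + noise, 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "disease_model": model,
                    "genotype": genotype,
                    "strain": strain,
                    "vial_id": f"{strain}_v{v+1}",
                    "age_days": ages,
                    "mean_speed": speed,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_screen(config: SimulationConfig) -> ScreenDataset:
    """Generate the full synthetic screen for ``config.n_genes`` genes.

    Gene labels (degenerating / ERG-decreased / stress-sensitive /
    modifier) are drawn independently per gene from the configured
    fractions; controls and null genes are exchangeable with the control
    distributions.  Truth labels are recorded per genotype.
    """
    genes = [f"gene{i+1:03d}" for i in range(config.n_genes)]
    controls = [f"control{i+1:02d}" for i in range(config.n_control_genotypes)]

    rng_labels = config.rng("labels")
    truth: dict[str, dict] = {}
    labels = {}
    for g in genes:
        labels[g] = {
            "degenerating": bool(rng_labels.random() < config.frac_degenerating),
            "erg_decreased": bool(rng_labels.random() < config.frac_erg_decreased),
            "stress_sensitive": bool(rng_labels.random() < config.frac_stress_sensitive),
            "modifier": bool(rng_labels.random() < config.frac_modifier),
        }

    # --- vacuole counts
    rng_vac = config.rng("vacuoles")
    rows = []
    for g in genes + controls:
        lam = (
            config.vacuole_mean_degenerating
            if labels.get(g, {}).get("degenerating")
            else config.vacuole_mean_normal
        )
        for h in range(config.heads_per_genotype):
            rows.append(
                {
                    "genotype": g,
                    "head_id": f"{g}_h{h+1}",
                    "vacuole_count": int(rng_vac.poisson(lam)),
                }
            )
    vacuole_table = pd.DataFrame(rows)

    # --- ERG biological replicates (per-fly averages of 5 traces)
    rng_erg = config.rng("erg")
    e = config.erg
    traces: list[ErgTrace] = []
    for g in genes + controls:
        ratio = (
            config.erg_effect_ratio if labels.get(g, {}).get("erg_decreased") else 1.0
        )
        for f in range(e.n_flies):
            per_fly = [
                simulate_erg_trace(
                    rng_erg,
                    baseline_mV=e.baseline_mV,
                    plateau_mV=e.plateau_mV * ratio,
                    on_mV=e.on_mV * ratio,
                    off_mV=e.off_mV * ratio,
                    noise_sd=e.noise_sd,
                    stimulus_window=(e.stimulus_onset_s, e.stimulus_offset_s),
                    sampling_rate=e.sampling_rate_hz,
                    trace_duration=e.trace_duration_s,
                    transient_width=e.transient_width_s,
                    genotype=g,
                    fly_id=f"{g}_f{f+1}",
                )
                for _ in range(e.n_traces_per_fly)
            ]
            from adscreen.erg import average_fly_traces

            traces.append(average_fly_traces(per_fly))

    # --- stress trials (primary single trial + replicate stage)
    rng_stress = config.rng("stress")
    rows = []
    for stressor, ctrl_p in (("heat", config.heat_control_p), ("bang", config.bang_control_p)):
        for g in genes + controls:
            p = (
                config.stress_sensitive_p
                if labels.get(g, {}).get("stress_sensitive")
                else ctrl_p
            )
            rows.append(
                {
                    "genotype": g,
                    "stressor": stressor,
                    "stage": "primary",
                    "replicate_id": 0,
                    "n_flies": config.flies_per_trial,
                    "n_impaired": int(rng_stress.binomial(config.flies_per_trial, p)),
                }
            )
            for r in range(config.n_replicates):
                rows.append(
                    {
                        "genotype": g,
                        "stressor": stressor,
                        "stage": "replicate",
                        "replicate_id": r + 1,
                        "n_flies": config.flies_per_trial,
                        "n_impaired": int(rng_stress.binomial(config.flies_per_trial, p)),
                    }
                )
    stress_trials = pd.DataFrame(rows)

    # --- climbing (two strains per gene, both carrying the gene's effect)
    rng_climb = config.rng("climbing")
    c = config.climbing
    frames = []
    for model in ("tau", "abeta"):
        frames.append(
            _climbing_frame(rng_climb, c, f"{model}_control", f"{model}_control", model, 0.0, 0.0)
        )
        for g in genes:
            mod = labels[g]["modifier"]
            shift = c.modifier_shift if mod else 0.0
            slope = c.modifier_slope if mod else 0.0
            for s in (1, 2):
                frames.append(
                    _climbing_frame(
                        rng_climb, c, g, f"{g}_s{s}", model, shift, slope
                    )
                )
    climbing_table = pd.concat(frames, ignore_index=True)

    for g in genes:
        truth[g] = dict(labels[g])
        truth[g]["erg_direction"] = "decreased" if labels[g]["erg_decreased"] else "none"
    for g in controls:
        truth[g] = {
            "degenerating": False,
            "erg_decreased": False,
            "stress_sensitive": False,
            "modifier": False,
            "erg_direction": "none",
        }

    ds = ScreenDataset(
        vacuole_table=vacuole_table,
        erg_traces=traces,
        stress_trials=stress_trials,
        climbing_table=climbing_table,
        truth=truth,
        control_genotypes=controls,
    )
    ds.validate()
    return ds


@dataclass(frozen=True)
class SubgroupSpec:
    """One cohort subgroup: member row indices and the clusters whose SNP
    frequencies are raised/lowered by ``delta`` for those members."""

    name: str
    individuals: tuple[int, ...]
    enriched: frozenset[str] = frozenset()
    depleted: frozenset[str] = frozenset()
    delta: float = 0.2


def simulate_cohort(
    n_individuals: int,
    cluster_snps: Mapping[str, Sequence[str]],
    frequencies: Mapping[str, float],
    subgroups: Sequence[SubgroupSpec] = (),
    seed: int = 0,
    clamp: tuple[float, float] = (1e-3, 1 - 1e-3),
) -> CohortGenotypes:
    """Draw dosage ~ Binomial(2, f) per individual per SNP.

    Subgroup members use f + delta at SNPs of enriched clusters and
    f - delta at depleted ones, clamped to the open interval ``clamp``.
    Subgroups must not overlap.  Frequencies of 0 or 1 are rejected.
    """
    snps = sorted({s for ss in cluster_snps.values() for s in ss})
    for s in snps:
        if s not in frequencies:
            raise KeyError(f"no frequency for SNP {s}")
    for s, f in frequencies.items():
        if not (0.0 < f < 1.0):
            raise ValueError(f"frequency for {s} must lie in (0, 1), got {f}")
    seen: set[int] = set()
    for sg in subgroups:
        overlap = seen & set(sg.individuals)
        if overlap:
            raise ValueError(f"individuals in multiple subgroups: {sorted(overlap)}")
        seen |= set(sg.individuals)
        if any(i < 0 or i >= n_individuals for i in sg.individuals):
            raise ValueError(f"subgroup {sg.name} indexes outside the cohort")

    snp_cluster: dict[str, set[str]] = {s: set() for s in snps}
    for cluster, ss in cluster_snps.items():
        for s in ss:
            snp_cluster[s].add(cluster)

    rng = np.random.default_rng(seed)
    n, m = n_individuals, len(snps)
    fmat = np.tile([frequencies[s] for s in snps], (n, 1))
    for sg in subgroups:
        for j, s in enumerate(snps):
            if snp_cluster[s] & sg.enriched:
                fmat[list(sg.individuals), j] += sg.delta
            elif snp_cluster[s] & sg.depleted:
                fmat[list(sg.individuals), j] -= sg.delta
    fmat = np.clip(fmat, clamp[0], clamp[1])
    dosage = rng.binomial(2, fmat).astype(float)
    return CohortGenotypes(
        individual_ids=[f"ind{i+1:03d}" for i in range(n)],
        snp_ids=snps,
        dosage=dosage,
        missing=np.zeros((n, m), dtype=bool),
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_screen_tables(dataset: ScreenDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per assay plus a JSON truth-label file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("vacuoles", dataset.vacuole_table),
        ("stress", dataset.stress_trials),
        ("climbing", dataset.climbing_table),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    # per-replicate ERG features rather than raw traces (compact, lossless
    # for the downstream statistics)
    from adscreen.erg import extract_features

    rows = []
    for tr in dataset.erg_traces:
        f = extract_features(tr)
        rows.append(
            {
                "genotype": tr.genotype,
                "fly_id": tr.fly_id,
                "eye_color": tr.eye_color,
                **f.as_dict(),
            }
        )
    p = out / "erg_features.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["erg_features"] = p

    p = out / "truth.json"
    p.write_text(json.dumps(
        {"control_genotypes": dataset.control_genotypes, "genotypes": dataset.truth},
        indent=1,
    ))
    paths["truth"] = p
    return paths


def write_cohort_vcf(
    genotypes: CohortGenotypes,
    risk_alleles: Mapping[str, str],
    path: str | Path,
    ref_alt: Mapping[str, tuple[str, str]] | None = None,
) -> Path:
    """Minimal biallelic VCF v4.2, GT field only.

    Dosages are written as risk-allele counts: if the risk allele is ALT
    the GT carries that many ALT alleles, if REF then 2 - dosage.  When
    ``ref_alt`` is omitted, REF/ALT default to (A, risk-allele) or (A, G)
    so the risk allele is always ALT.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.individual_ids),
    ]
    for j, snp in enumerate(genotypes.snp_ids):
        risk = risk_alleles.get(snp, "G")
        if ref_alt and snp in ref_alt:
            ref, alt = ref_alt[snp]
        else:
            ref = "A" if risk != "A" else "C"
            alt = risk
        if risk == alt:
            alt_counts = genotypes.dosage[:, j]
        elif risk == ref:
            alt_counts = 2 - genotypes.dosage[:, j]
        else:
            raise ValueError(f"risk allele at {snp} matches neither REF nor ALT")
        gts = []
        for i, c in enumerate(alt_counts):
            if genotypes.missing[i, j]:
                gts.append("./.")
            else:
                c = int(c)
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[c])
        lines.append(
            f"1\t{1000 + j}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
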