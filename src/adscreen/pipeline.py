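"""End-to-end pipeline runner and fixture bundle.

Stages run in dependency order: simulate -> erg -> histology -> stress ->
climb -> integrate -> riskscore.  Every output lands under the run
directory, and a manifest records the configuration, seed and SHA-256
hash of each file, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from adscreen.config import RunConfig, SimulationConfig
from adscreen.erg import ErgFeatures, classify_gene, compare_genotypes
from adscreen.hits import (
    StressTrial,
    VacuoleObservation,
    call_structure,
    confirm_stress_hits,
    primary_stress_screen,
)
from adscreen.integrate import GeneRecord, assign_snp_clusters, build_profiles, count_summary
from adscreen.locomotor import analyze_strain, consolidate_gene
from adscreen.risk import center_rows, count_risk_alleles, project, run_pca, standardize
from adscreen.simulate import (
    ScreenDataset,
    SubgroupSpec,
    simulate_cohort,
    simulate_screen,
    write_cohort_vcf,
    write_screen_tables,
)

__all__ = ["run_pipeline", "make_fixtures", "StageError"]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _features_by_genotype(erg_features: pd.DataFrame) -> dict[str, list[ErgFeatures]]:
    out: dict[str, list[ErgFeatures]] = {}
    for _, row in erg_features.iterrows():
        out.setdefault(row["genotype"], []).append(
            ErgFeatures(row["lcrp_amplitude"], row["on_transient"], row["off_transient"])
        )
    return out


def _call_erg(dataset: ScreenDataset, erg_features: pd.DataFrame, alpha: float) -> dict[str, str]:
    feats = _features_by_genotype(erg_features)
    pooled_control = []
    for c in dataset.control_genotypes:
        pooled_control.extend(feats.pop(c, []))
    family = dict(feats)
    family["__control__"] = pooled_control
    results = compare_genotypes(family, control_genotype="__control__")
    return {
        g: classify_gene([results[g]], gene=g, alpha=alpha).overall_class
        for g in results
    }


def _call_structure_all(dataset: ScreenDataset, threshold: int) -> dict[str, bool]:
    out = {}
    genes = [g for g in dataset.truth if g not in dataset.control_genotypes]
    vac = dataset.vacuole_table
    for g in genes:
        obs = [
            VacuoleObservation(r["genotype"], r["head_id"], int(r["vacuole_count"]))
            for _, r in vac[vac["genotype"] == g].iterrows()
        ]
        out[g] = call_structure(obs, gene=g, threshold=threshold).hit
    return out


def _call_stress(
    dataset: ScreenDataset, cutoff: float, alpha: float
) -> dict[str, dict[str, bool]]:
    genes = [g for g in dataset.truth if g not in dataset.control_genotypes]
    genotypes_by_gene = {g: [g] for g in genes}
    trials = [
        StressTrial(
            r["genotype"], r["stressor"], int(r["n_flies"]), int(r["n_impaired"]),
            r["stage"], int(r["replicate_id"]),
        )
        for _, r in dataset.stress_trials.iterrows()
    ]
    out: dict[str, dict[str, bool]] = {}
    for stressor in ("heat", "bang"):
        candidates = primary_stress_screen(
            trials, genotypes_by_gene, stressor=stressor, cutoff=cutoff
        )
        # pool the control genotypes' replicates into one control group
        reps = [
            StressTrial("__control__", t.stressor, t.n_flies, t.n_impaired,
                        "replicate", t.replicate_id)
            if t.genotype in dataset.control_genotypes
            else t
            for t in trials
            if t.stage == "replicate"
        ]
        confirmed = confirm_stress_hits(
            reps,
            control_genotype="__control__",
            candidates_by_gene={g: [g] for g in candidates},
            stressor=stressor,
            alpha=alpha,
        )
        out[stressor] = {g: confirmed[g].confirmed if g in confirmed else False for g in genes}
    return out


def _call_modifiers(
    dataset: ScreenDataset, alpha: float, min_area_fraction: float
) -> dict[str, dict[str, bool]]:
    climb = dataset.climbing_table
    genes = sorted(set(climb["genotype"]) - {"tau_control", "abeta_control"})
    out: dict[str, dict[str, bool]] = {}
    for model in ("tau", "abeta"):
        sub = climb[climb["disease_model"] == model]
        calls: dict[str, bool] = {}
        for gene in genes:
            strains = sorted(set(sub.loc[sub["genotype"] == gene, "strain"]))
            strain_calls = {}
            for s in strains:
                strain_rows = sub[sub["strain"] == s].assign(genotype=s)
                control_rows = sub[sub["genotype"] == f"{model}_control"]
                series = pd.concat([strain_rows, control_rows], ignore_index=True)
                res = analyze_strain(
                    series, control=f"{model}_control", strain=s, model=model,
                    alpha=alpha, min_area_fraction=min_area_fraction,
                )
                strain_calls[s] = res.call
            calls[gene] = consolidate_gene(strain_calls, gene, model).high_confidence
        out[model] = calls
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory).  A stage failure raises :class:`StageError` naming
    the stage; files already written by the failed run are listed as
    invalid in the partial manifest on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": [],
        "outputs": {},
    }

    dataset: ScreenDataset | None = None
    erg_features: pd.DataFrame | None = None
    calls: dict = {}

    def record(stage: str, files: Mapping[str, Path]) -> None:
        manifest["stages"].append(stage)
        for name, p in files.items():
            manifest["outputs"][f"{stage}/{name}"] = {
                "path": str(p.relative_to(out)),
                "sha256": _sha256(p),
            }

    def fail(stage: str, exc: Exception):
        manifest["invalid"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise StageError(stage, exc) from exc

    stages = list(config.stages)
    needs_data = [s for s in stages if s != "simulate"]
    if needs_data and "simulate" not in stages:
        stages = ["simulate"] + stages

    for stage in stages:
        try:
            if stage == "simulate":
                dataset = simulate_screen(config.simulation)
                paths = write_screen_tables(dataset, out / "screen")
                erg_features = pd.read_csv(paths["erg_features"], sep="\t")
                record(stage, paths)
            elif stage == "erg":
                calls["erg"] = _call_erg(dataset, erg_features, config.alpha)
                p = out / "erg_calls.tsv"
                pd.Series(calls["erg"], name="erg_class").rename_axis("gene").to_csv(p, sep="\t")
                record(stage, {"calls": p})
            elif stage == "histology":
                calls["structure"] = _call_structure_all(dataset, config.vacuole_threshold)
                p = out / "structure_calls.tsv"
                pd.Series(calls["structure"], name="structure_hit").rename_axis("gene").to_csv(p, sep="\t")
                record(stage, {"calls": p})
            elif stage == "stress":
                stress = _call_stress(dataset, config.stress_cutoff, config.alpha)
                calls["heat"], calls["bang"] = stress["heat"], stress["bang"]
                p = out / "stress_calls.tsv"
                pd.DataFrame(stress).rename_axis("gene").to_csv(p, sep="\t")
                record(stage, {"calls": p})
            elif stage == "climb":
                mods = _call_modifiers(dataset, config.alpha, config.min_area_fraction)
                calls["tau_mod"], calls["abeta_mod"] = mods["tau"], mods["abeta"]
                p = out / "modifier_calls.tsv"
                pd.DataFrame(mods).rename_axis("gene").to_csv(p, sep="\t")
                record(stage, {"calls": p})
            elif stage == "integrate":
                genes = sorted(g for g in dataset.truth if g not in dataset.control_genotypes)
                records = [
                    GeneRecord(
                        fly_gene=g, human_gene=g.upper(),
                        locus_id=f"locus_{g}", lead_snp_id=f"rs_{g}", risk_allele="G",
                    )
                    for g in genes
                ]
                profiles = build_profiles(
                    records,
                    structure=calls.get("structure", {g: False for g in genes}),
                    erg_class=calls.get("erg", {g: "none" for g in genes}),
                    heat=calls.get("heat", {g: False for g in genes}),
                    bang=calls.get("bang", {g: False for g in genes}),
                    expression={g: "undetermined" for g in genes},
                    abeta=calls.get("abeta_mod"),
                    tau=calls.get("tau_mod"),
                )
                clusters, log = assign_snp_clusters(profiles, records)
                calls["profiles"], calls["clusters"] = profiles, clusters
                p1 = out / "profiles.tsv"
                profiles.to_csv(p1, sep="\t", index=False)
                p2 = out / "clusters.json"
                p2.write_text(json.dumps({"clusters": clusters, "log": log}, indent=1))
                p3 = out / "summary.json"
                p3.write_text(json.dumps(count_summary(profiles), indent=1))
                record(stage, {"profiles": p1, "clusters": p2, "summary": p3})
            elif stage == "riskscore":
                clusters = {c: s for c, s in calls["clusters"].items() if s}
                if len(clusters) < 2:
                    record(stage, {})
                    continue  # too few informative clusters to stratify
                freqs = {s: 0.3 for ss in clusters.values() for s in ss}
                cohort = simulate_cohort(
                    config.simulation.cohort.n_individuals,
                    clusters,
                    freqs,
                    seed=config.seed + 17,
                )
                raw = count_risk_alleles(cohort, clusters)
                scores = standardize(raw)
                pca = run_pca(scores)
                comp = min(config.sort_component, pca.loadings.shape[1])
                proj, order = project(scores, pca, component_index=comp)
                heat = center_rows(scores, order)
                p1 = out / "heatmap.tsv"
                heat.to_frame().rename_axis("individual").to_csv(p1, sep="\t")
                p2 = out / "pca.json"
                p2.write_text(json.dumps(
                    {
                        "clusters": pca.clusters,
                        "loadings": pca.loadings.tolist(),
                        "variance_explained": pca.variance_explained.tolist(),
                        "sort_component": comp,
                    },
                    indent=1,
                ))
                record(stage, {"heatmap": p1, "pca": p2})
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            fail(stage, exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the fixture bundle: the 100-gene panel map, its synthetic
    phenotype profiles and cluster map, a small demo screen, and a demo
    cohort VCF."""
    from adscreen.panel import panel_records, panel_table, synthetic_phenotype_calls

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "gene_panel.tsv"
    panel_table().to_csv(p, sep="\t", index=False)
    paths["gene_panel"] = p

    records = panel_records()
    calls = synthetic_phenotype_calls()
    profiles = build_profiles(
        records,
        structure=calls["structure"],
        erg_class=calls["erg_class"],
        heat=calls["heat"],
        bang=calls["bang"],
        expression=calls["expression"],
        abeta=calls["abeta"],
        tau=calls["tau"],
    )
    p = out / "panel_profiles.tsv"
    profiles.to_csv(p, sep="\t", index=False)
    paths["panel_profiles"] = p

    clusters, log = assign_snp_clusters(profiles, records)
    p = out / "panel_clusters.json"
    p.write_text(json.dumps({"clusters": clusters, "log": log}, indent=1))
    paths["panel_clusters"] = p

    demo = SimulationConfig(seed=seed, n_genes=6, n_control_genotypes=2)
    dataset = simulate_screen(demo)
    for name, path in write_screen_tables(dataset, out / "demo_screen").items():
        paths[f"demo_{name}"] = path

    risk_alleles = {r.lead_snp_id: r.risk_allele for r in records if r.lead_snp_id}
    freqs = {s: 0.3 for ss in clusters.values() for s in ss if s}
    cohort = simulate_cohort(
        20, {c: s for c, s in clusters.items() if s}, freqs, seed=seed
    )
    p = out / "demo_cohort.vcf"
    write_cohort_vcf(cohort, risk_alleles, p)
    paths["demo_cohort_vcf"] = p
    return paths
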