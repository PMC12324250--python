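"""Gene-level phenotype integration.

Combines the assay-level calls (brain histology, electroretinogram,
heat/bang resilience) with modifier calls and expression categories into
one profile row per gene, computes the screen's summary arithmetic
(per-assay totals, unions via inclusion-exclusion), and builds the
phenotype-cluster -> lead-SNP map consumed by oligogenic risk scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "ViabilityCall",
    "classify_viability",
    "build_profiles",
    "count_summary",
    "tally_expression",
    "assign_snp_clusters",
    "PROFILE_COLUMNS",
    "EXPRESSION_CATEGORIES",
]

EXPRESSION_CATEGORIES = ("neuron", "glia", "both", "undetermined", "not_detected")

PROFILE_COLUMNS = [
    "gene",
    "human_gene",
    "phenotyped",
    "structure",
    "erg_class",
    "function",
    "resilience_heat",
    "resilience_bang",
    "expression_category",
    "abeta_modifier",
    "tau_modifier",
]


@dataclass(frozen=True)
class GeneRecord:
    """One screened fly gene with its human mapping and assay bookkeeping."""

    fly_gene: str
    human_gene: str
    locus_id: str | None = None
    lead_snp_id: str | None = None
    risk_allele: str | None = None
    evidence_class: Literal["functional_genomic", "experimental", "rare_variant"] = (
        "functional_genomic"
    )
    viability: Literal["viable", "essential_rescuable", "essential_lethal"] = "viable"
    strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.evidence_class != "rare_variant" and self.lead_snp_id is None:
            raise ValueError(
                f"{self.fly_gene}: GWAS-derived genes must carry a lead SNP"
            )

    @property
    def phenotyping_eligible(self) -> bool:
        return self.viability != "essential_lethal"


@dataclass(frozen=True)
class ViabilityCall:
    viability: str
    eligible: bool
    genotypes: tuple[str, ...]


def classify_viability(
    gene: str,
    deficiency_viable: bool,
    rnai_viable: bool | None = None,
    rnai_strains: Sequence[str] = (),
) -> ViabilityCall:
    """Viability triage: deficiency trans-heterozygote for viable genes,
    two RNAi genotypes for essential-but-rescuable genes, exclusion from
    phenotyping (but not expression/modifier bookkeeping) when even RNAi
    knockdown is lethal."""
    if deficiency_viable:
        return ViabilityCall("viable", True, (f"{gene}^GAL4/Df",))
    if rnai_viable is None:
        raise ValueError(f"{gene}: lethal gene needs a recorded RNAi outcome")
    if rnai_viable:
        genotypes = tuple(rnai_strains) or (f"{gene}^GAL4>RNAi-1", f"{gene}^GAL4>RNAi-2")
        if len(genotypes) < 2:
            raise ValueError(f"{gene}: essential gene requires two RNAi genotypes")
        return ViabilityCall("essential_rescuable", True, genotypes)
    return ViabilityCall("essential_lethal", False, ())


def build_profiles(
    genes: Sequence[GeneRecord],
    structure: Mapping[str, bool],
    erg_class: Mapping[str, str],
    heat: Mapping[str, bool],
    bang: Mapping[str, bool],
    expression: Mapping[str, str],
    abeta: Mapping[str, bool] | None = None,
    tau: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Assemble one profile row per gene.

    Every phenotyping-eligible gene must have a call (possibly negative)
    from each of the four assays; ineligible genes carry nulls there but
    keep expression and modifier columns.  Unknown genes in any call
    mapping are an error, as are duplicate gene records.
    """
    known = [g.fly_gene for g in genes]
    if len(set(known)) != len(known):
        dupes = sorted({g for g in known if known.count(g) > 1})
        raise ValueError(f"duplicate gene records: {dupes}")
    known_set = set(known)
    for name, mapping in (
        ("structure", structure),
        ("erg", erg_class),
        ("heat", heat),
        ("bang", bang),
        ("expression", expression),
    ):
        unknown = sorted(set(mapping) - known_set)
        if unknown:
            raise ValueError(f"{name} calls for unknown gene(s): {unknown}")

    rows = []
    for g in genes:
        name = g.fly_gene
        if g.phenotyping_eligible:
            missing = [
                lbl
                for lbl, m in (
                    ("structure", structure),
                    ("erg", erg_class),
                    ("heat", heat),
                    ("bang", bang),
                )
                if name not in m
            ]
            if missing:
                raise ValueError(f"{name}: missing {missing} call(s)")
            ec = erg_class[name]
            row = {
                "gene": name,
                "human_gene": g.human_gene,
                "phenotyped": True,
                "structure": bool(structure[name]),
                "erg_class": ec,
                "function": ec != "none",
                "resilience_heat": bool(heat[name]),
                "resilience_bang": bool(bang[name]),
            }
        else:
            row = {
                "gene": name,
                "human_gene": g.human_gene,
                "phenotyped": False,
                "structure": None,
                "erg_class": None,
                "function": None,
                "resilience_heat": None,
                "resilience_bang": None,
            }
        cat = expression.get(name, "undetermined")
        if cat not in EXPRESSION_CATEGORIES:
            raise ValueError(f"unknown expression category {cat!r} for {name}")
        row["expression_category"] = cat
        row["abeta_modifier"] = bool((abeta or {}).get(name, False))
        row["tau_modifier"] = bool((tau or {}).get(name, False))
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def _assay_sets(profiles: pd.DataFrame) -> dict[str, set[str]]:
    ph = profiles[profiles["phenotyped"] == True]  # noqa: E712  (None-aware)
    return {
        "structure": set(ph.loc[ph["structure"] == True, "gene"]),  # noqa: E712
        "function": set(ph.loc[ph["function"] == True, "gene"]),  # noqa: E712
        "heat": set(ph.loc[ph["resilience_heat"] == True, "gene"]),  # noqa: E712
        "bang": set(ph.loc[ph["resilience_bang"] == True, "gene"]),  # noqa: E712
    }


def count_summary(profiles: pd.DataFrame) -> dict[str, int]:
    """Exact set arithmetic over the assay and modifier calls.

    Unions are computed directly and re-verified against the
    inclusion-exclusion identity; a mismatch raises (it would mean the set
    bookkeeping is corrupt).
    """
    sets = _assay_sets(profiles)
    union_all = set().union(*sets.values())

    # inclusion-exclusion over the four assay sets, as an internal check
    names = list(sets)
    from itertools import combinations

    ie = 0
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            ie += (-1) ** (r + 1) * len(inter)
    if ie != len(union_all):
        raise AssertionError("inclusion-exclusion mismatch against direct union")

    erg = profiles["erg_class"].fillna("none")
    abeta = set(profiles.loc[profiles["abeta_modifier"] == True, "gene"])  # noqa: E712
    tau = set(profiles.loc[profiles["tau_modifier"] == True, "gene"])  # noqa: E712

    resilience = sets["heat"] | sets["bang"]
    return {
        "n_genes": int(len(profiles)),
        "n_phenotyped": int(profiles["phenotyped"].sum()),
        "structure": len(sets["structure"]),
        "function": len(sets["function"]),
        "heat": len(sets["heat"]),
        "bang": len(sets["bang"]),
        "heat_only": len(sets["heat"] - sets["bang"]),
        "bang_only": len(sets["bang"] - sets["heat"]),
        "heat_and_bang": len(sets["heat"] & sets["bang"]),
        "resilience_union": len(resilience),
        "cns_union": len(union_all),
        "erg_decreased": int((erg == "decreased").sum()),
        "erg_increased": int((erg == "increased").sum()),
        "erg_mixed": int((erg == "mixed").sum()),
        "decreased_and_structure": len(
            set(profiles.loc[erg == "decreased", "gene"]) & sets["structure"]
        ),
        "abeta_modifiers": len(abeta),
        "tau_modifiers": len(tau),
        "dual_modifiers": len(abeta & tau),
        "modifier_union": len(abeta | tau),
    }


def tally_expression(expression: Mapping[str, str]) -> dict[str, float]:
    """Per-category counts plus percent-expressed
    ((n - not_detected) / n * 100)."""
    counts = {c: 0 for c in EXPRESSION_CATEGORIES}
    for gene, cat in expression.items():
        if cat not in counts:
            raise ValueError(f"unknown expression category {cat!r} for {gene}")
        counts[cat] += 1
    n = len(expression)
    out: dict[str, float] = dict(counts)
    out["n_genes"] = n
    out["percent_expressed"] = 100.0 * (n - counts["not_detected"]) / n if n else 0.0
    return out


def assign_snp_clusters(
    profiles: pd.DataFrame,
    records: Sequence[GeneRecord],
    erg_scope: Literal["decreased_only", "all"] = "decreased_only",
    dedup: bool = True,
) -> tuple[dict[str, list[str]], list[str]]:
    """Map the four phenotype clusters to lead-SNP sets.

    Cluster membership: ``function`` is decreased-depolarization genes by
    default (``erg_scope="all"`` includes increased/mixed), ``structure``,
    ``bang`` and ``heat`` are the corresponding positive calls.  A SNP may
    sit in several clusters; within a cluster a shared-locus SNP is
    counted once when ``dedup`` (default).  Genes without GWAS provenance
    (rare-variant-only) are excluded and returned in the log.  A cluster
    gene that should carry a SNP but does not is an error; an empty
    cluster is returned empty with a log note (scoring downstream must
    skip it).
    """
    rec = {r.fly_gene: r for r in records}
    erg = profiles["erg_class"].fillna("none")
    if erg_scope == "decreased_only":
        function_genes = set(profiles.loc[erg == "decreased", "gene"])
    else:
        function_genes = set(profiles.loc[erg != "none", "gene"])
    sets = _assay_sets(profiles)
    members = {
        "function": function_genes,
        "structure": sets["structure"],
        "bang": sets["bang"],
        "heat": sets["heat"],
    }

    log: list[str] = []
    clusters: dict[str, list[str]] = {}
    for cluster, genes in members.items():
        snps: list[str] = []
        for gene in sorted(genes):
            r = rec.get(gene)
            if r is None:
                raise KeyError(f"cluster gene {gene!r} has no record")
            if r.evidence_class == "rare_variant" or r.lead_snp_id is None:
                log.append(f"{cluster}: excluded {gene} (no GWAS lead SNP)")
                continue
            snps.append(r.lead_snp_id)
        if dedup:
            snps = sorted(set(snps))
        if not snps:
            log.append(f"{cluster}: empty SNP set; downstream scoring disabled")
        clusters[cluster] = snps
    return clusters, log
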