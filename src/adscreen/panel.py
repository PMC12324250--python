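"""The 100-gene screen panel with a synthetic demonstration phenotype
assignment.

The fly/human gene names are the conserved Drosophila homologs of
candidate Alzheimer's-disease risk genes screened by this project; every
other attribute here -- phenotype flags, viability classes, loci, lead
SNPs, risk alleles -- is SYNTHETIC demonstration data, deterministically
assigned so that the panel's set arithmetic is internally consistent
(e.g., the four assay hit sets overlap the way a real screen's do and
exactly 50 of the 100 genes carry at least one CNS phenotype).  It is a
worked-example fixture for the integration and risk-scoring stages, not a
measurement.
"""

from __future__ import annotations

import pandas as pd

from adscreen.integrate import GeneRecord

__all__ = [
    "PANEL_WITH_PHENOTYPES",
    "PANEL_WITHOUT_PHENOTYPES",
    "panel_records",
    "synthetic_phenotype_calls",
    "panel_table",
]

# (human gene(s), fly gene) -- genes with at least one CNS phenotype in the
# demonstration assignment
PANEL_WITH_PHENOTYPES: list[tuple[str, str]] = [
    ("CTSH", "CtsL1"),
    ("RTF2", "CG6443"),
    ("CCDC47", "CG17593"),
    ("PVRIG", "Motor"),
    ("ARRB2", "Arr1"),
    ("ABCA7", "CG8908"),
    ("OSBP", "CG3860"),
    ("ICA1L", "ICA69"),
    ("AKAP9", "Plp"),
    ("PSEN1, PSEN2", "Psn"),
    ("CLCN1", "ClC-a"),
    ("SNX32", "Snx6"),
    ("LRCH4", "Lrch"),
    ("REEP6", "ReepB"),
    ("MYBPC3", "Obsc"),
    ("DOC2A", "Rph"),
    ("PICALM", "lap"),
    ("C4A, C4B", "Tep4"),
    ("FMNL2", "Frl"),
    ("CASP2", "Dronc"),
    ("DLG2", "dlg1"),
    ("EFNA2", "Ephrin"),
    ("WWOX", "Wwox"),
    ("CARHSP1", "CG9705"),
    ("MEPCE", "bin3"),
    ("ECHDC3", "CG6984"),
    ("CD33", "hbs"),
    ("ADAM10", "kul"),
    ("CHRNA2", "nAChRalpha1"),
    ("MADD", "Rab3-GEF"),
    ("EFHD1", "Swip-1"),
    ("CELF1", "bru1"),
    ("PTK2B", "Fak"),
    ("RIN3", "spri"),
    ("STMN4", "stai"),
    ("TSPAN14", "Tsp26A"),
    ("INPP5D", "CG6805"),
    ("SORL1", "LpR2"),
    ("CASS4", "p130CAS"),
    ("ABCA7", "ldd"),
    ("MYO1E", "Myo31DF"),
    ("APOE", "NLaz"),
    ("ARSA", "CG32191"),
    ("ADAM17", "Tace"),
    ("SLC12A9", "CG10413"),
    ("APOE", "GLaz"),
    ("TAP2", "CG1824"),
    ("STX6", "Syx6"),
    ("CD2AP", "cindr"),
    ("BIN1", "Amph"),
]

# genes with no CNS phenotype in the demonstration assignment; the last 9
# are the essential genes that stayed lethal even under RNAi knockdown and
# were therefore never phenotyped
PANEL_WITHOUT_PHENOTYPES: list[tuple[str, str]] = [
    ("ADAMTS1, ADAMTS4", "AdamTS-A"),
    ("NR1H3", "EcR"),
    ("KAT8", "mof"),
    ("CNTNAP2", "Nrx-IV"),
    ("TSPOAP1", "Rbp"),
    ("PLCG2", "sl"),
    ("ME3", "Men-b"),
    ("CTSH", "CtsB"),
    ("CR1", "Hasp"),
    ("NOTCH4", "N"),
    ("ACHE", "Ace"),
    ("APH1B", "aph-1"),
    ("TANC2", "rols"),
    ("MTCH2", "Mtch"),
    ("ABI3", "Abi"),
    ("AP4M1", "AP-1mu"),
    ("NCK2", "dock"),
    ("PTGER2", "CG7497"),
    ("EPHA1", "Eph"),
    ("YOD1", "Yod1"),
    ("ACE", "Acer"),
    ("ALDH1A2", "CG31075"),
    ("SBNO2", "CG3491"),
    ("MAST4", "dop"),
    ("AQP9", "Drip"),
    ("SPRED2", "Spred"),
    ("SLC39A13", "Zip99C"),
    ("ZYX", "Zyx"),
    ("HS3ST1", "Hs3st-A"),
    ("STAG3", "SA2"),
    ("SPI1", "Ets98B"),
    ("AGPAT1", "Agpat1"),
    ("GIGYF2", "Gyf"),
    ("OSBP", "Osbp"),
    ("SPPL2A", "SppL"),
    ("MAF", "tj"),
    ("C4A, C4B", "Tep3"),
    ("STX4", "Syx1a"),
    ("GPRC5B", "boss"),
    ("GPR139", "CG13229"),
    ("GPC2", "dlp"),
    ("ADAM10", "kuz"),
    ("CCDC6", "Ccdc6"),
    ("GPX4", "Gtpx"),
    ("NDUFS3", "ND-30"),
    ("APP", "Appl"),
    ("MYO7B", "ck"),
    ("FERMT2", "Fit1"),
    ("STAG3", "SA1"),
    ("SLC24A4", "zyd"),
]

_BASES = "ACGT"

# synthetic rare-variant-only gene: carries no GWAS lead SNP, exercising
# the cluster-assignment exclusion path
_RARE_VARIANT_GENES = {"Plp", "Appl"}


def _panel_pairs() -> list[tuple[str, str]]:
    return PANEL_WITH_PHENOTYPES + PANEL_WITHOUT_PHENOTYPES


def panel_records() -> list[GeneRecord]:
    """All 100 :class:`GeneRecord` rows (synthetic loci/SNPs/viability).

    Viability: the last 9 panel genes are essential-lethal (excluded from
    phenotyping); a further 23 are essential-but-rescuable via two RNAi
    genotypes; the remaining 68 are viable as deficiency
    trans-heterozygotes.
    """
    pairs = _panel_pairs()
    n = len(pairs)
    records = []
    for i, (human, fly) in enumerate(pairs):
        idx = i + 1
        if idx > n - 9:
            viability = "essential_lethal"
            strains: tuple[str, ...] = ()
        elif 5 <= idx <= 13 or 51 <= idx <= 64:
            viability = "essential_rescuable"
            strains = (f"{fly}^GAL4>RNAi-1", f"{fly}^GAL4>RNAi-2")
        else:
            viability = "viable"
            strains = (f"{fly}^GAL4/Df",)
        rare = fly in _RARE_VARIANT_GENES
        records.append(
            GeneRecord(
                fly_gene=fly,
                human_gene=human,
                locus_id=None if rare else f"locus{idx:03d}",
                lead_snp_id=None if rare else f"rs{100000 + idx}",
                risk_allele=None if rare else _BASES[idx % 4],
                evidence_class="rare_variant" if rare else "functional_genomic",
                viability=viability,
                strains=strains,
            )
        )
    return records


def synthetic_phenotype_calls() -> dict[str, dict]:
    """SYNTHETIC per-gene call mappings for the demonstration panel.

    Returns mappings keyed by fly gene: ``structure``, ``erg_class``,
    ``heat``, ``bang`` (phenotyped genes only), and ``expression``,
    ``abeta``, ``tau`` (all genes).  The assignment is deterministic; its
    marginal totals and overlaps form the package's worked integration
    example.
    """
    pairs = _panel_pairs()
    fly = [f for _, f in pairs]
    with_ph = fly[:50]
    eligible = fly[: len(pairs) - 9]

    structure = {g: (i + 1 <= 18) for i, g in enumerate(with_ph)}
    erg_class = {}
    for i, g in enumerate(with_ph):
        idx = i + 1
        if 14 <= idx <= 43:
            erg_class[g] = "decreased"
        elif 44 <= idx <= 47:
            erg_class[g] = "increased"
        elif idx == 48:
            erg_class[g] = "mixed"
        else:
            erg_class[g] = "none"
    heat_idx = {1, 2, 3, 19, 44, 49, 50}
    bang_idx = {4, 19, 44}
    heat = {g: (i + 1 in heat_idx) for i, g in enumerate(with_ph)}
    bang = {g: (i + 1 in bang_idx) for i, g in enumerate(with_ph)}

    # negatively-phenotyped eligible genes complete the call sets
    for g in eligible[50:]:
        structure[g] = False
        erg_class[g] = "none"
        heat[g] = False
        bang[g] = False

    expression = {}
    for i, g in enumerate(fly):
        idx = i + 1
        if idx <= 24:
            expression[g] = "neuron"
        elif idx <= 37:
            expression[g] = "glia"
        elif idx <= 83:
            expression[g] = "both"
        elif idx <= 98:
            expression[g] = "undetermined"
        else:
            expression[g] = "not_detected"

    abeta = {g: (51 <= i + 1 <= 59) for i, g in enumerate(fly)}
    tau = {g: (57 <= i + 1 <= 78) for i, g in enumerate(fly)}
    return {
        "structure": structure,
        "erg_class": erg_class,
        "heat": heat,
        "bang": bang,
        "expression": expression,
        "abeta": abeta,
        "tau": tau,
    }


def panel_table() -> pd.DataFrame:
    """The panel as a gene-map table (fly_gene, human_gene, locus_id,
    snp_id, risk_allele, evidence_class, viability)."""
    rows = [
        {
            "fly_gene": r.fly_gene,
            "human_gene": r.human_gene,
            "locus_id": r.locus_id or "",
            "snp_id": r.lead_snp_id or "",
            "risk_allele": r.risk_allele or "",
            "evidence_class": r.evidence_class,
            "viability": r.viability,
        }
        for r in panel_records()
    ]
    return pd.DataFrame(rows)
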