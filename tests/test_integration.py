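"""Gene-level integration: viability triage, profiles, summary arithmetic,
expression tallies, cluster->SNP assignment."""

from __future__ import annotations

from itertools import combinations

import pandas as pd
import pytest

from adscreen.integrate import (
    GeneRecord,
    assign_snp_clusters,
    build_profiles,
    classify_viability,
    count_summary,
    tally_expression,
)
from adscreen.panel import panel_records, synthetic_phenotype_calls


def record(name, snp="rs1", **kw):
    return GeneRecord(fly_gene=name, human_gene=name.upper(), locus_id="L1",
                      lead_snp_id=snp, risk_allele="A", **kw)


class TestViability:
    def test_deficiency_viable_uses_trans_heterozygote(self):
        call = classify_viability("g", deficiency_viable=True)
        assert call.viability == "viable" and call.eligible
        assert call.genotypes == ("g^GAL4/Df",)

    def test_lethal_with_viable_rnai_uses_two_rnai(self):
        call = classify_viability("g", deficiency_viable=False, rnai_viable=True)
        assert call.viability == "essential_rescuable" and call.eligible
        assert len(call.genotypes) == 2

    def test_lethal_with_lethal_rnai_excluded(self):
        call = classify_viability("g", deficiency_viable=False, rnai_viable=False)
        assert call.viability == "essential_lethal" and not call.eligible

    def test_missing_rnai_outcome_is_error(self):
        with pytest.raises(ValueError):
            classify_viability("g", deficiency_viable=False)


def tiny_profiles():
    genes = [record(g) for g in ("a", "b", "c")]
    return build_profiles(
        genes,
        structure={"a": False, "b": True, "c": False},
        erg_class={"a": "decreased", "b": "none", "c": "none"},
        heat={"a": False, "b": True, "c": False},
        bang={"a": False, "b": False, "c": False},
        expression={"a": "neuron", "b": "glia", "c": "not_detected"},
    )


class TestProfiles:
    def test_single_assay_composition(self):
        prof = tiny_profiles().set_index("gene")
        a = prof.loc["a"]
        assert (a["structure"], a["function"], a["resilience_heat"], a["resilience_bang"]) == (
            False, True, False, False,
        )
        b = prof.loc["b"]
        assert (b["structure"], b["function"], b["resilience_heat"], b["resilience_bang"]) == (
            True, False, True, False,
        )

    def test_missing_call_for_phenotyped_gene_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            build_profiles(
                [record("a")],
                structure={}, erg_class={"a": "none"},
                heat={"a": False}, bang={"a": False}, expression={"a": "both"},
            )

    def test_unknown_gene_and_duplicates_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_profiles(
                [record("a")],
                structure={"a": False, "zz": True}, erg_class={"a": "none"},
                heat={"a": False}, bang={"a": False}, expression={"a": "both"},
            )
        with pytest.raises(ValueError, match="duplicate"):
            build_profiles([record("a"), record("a")], {}, {}, {}, {}, {})

    def test_excluded_gene_carries_nulls(self):
        genes = [record("a", viability="essential_lethal")]
        prof = build_profiles(genes, {}, {}, {}, {}, {"a": "both"})
        row = prof.iloc[0]
        assert not row["phenotyped"] and row["structure"] is None

    def test_tsv_round_trip_preserves_summary(self, tmp_path):
        records = panel_records()
        calls = synthetic_phenotype_calls()
        prof = build_profiles(
            records, calls["structure"], calls["erg_class"], calls["heat"],
            calls["bang"], calls["expression"], calls["abeta"], calls["tau"],
        )
        path = tmp_path / "profiles.tsv"
        prof.to_csv(path, sep="\t", index=False)
        reread = pd.read_csv(path, sep="\t")
        assert count_summary(reread) == count_summary(prof)


class TestCountSummary:
    def test_modifier_union_arithmetic(self):
        genes = [record(f"g{i}") for i in range(30)]
        abeta = {f"g{i}": i < 9 for i in range(30)}           # 9 genes
        tau = {f"g{i}": 6 <= i < 28 for i in range(30)}       # 22 genes, 3 shared
        prof = build_profiles(
            genes,
            structure={g.fly_gene: False for g in genes},
            erg_class={g.fly_gene: "none" for g in genes},
            heat={g.fly_gene: False for g in genes},
            bang={g.fly_gene: False for g in genes},
            expression={g.fly_gene: "both" for g in genes},
            abeta=abeta, tau=tau,
        )
        s = count_summary(prof)
        assert (s["abeta_modifiers"], s["tau_modifiers"], s["dual_modifiers"]) == (9, 22, 3)
        assert s["modifier_union"] == 28

    def test_resilience_venn_arithmetic(self):
        genes = [record(f"g{i}") for i in range(10)]
        heat = {f"g{i}": i < 7 for i in range(10)}             # 5 only + 2 both
        bang = {f"g{i}": i in (5, 6, 7) for i in range(10)}    # 1 only + 2 both
        prof = build_profiles(
            genes,
            structure={g.fly_gene: False for g in genes},
            erg_class={g.fly_gene: "none" for g in genes},
            heat=heat, bang=bang,
            expression={g.fly_gene: "both" for g in genes},
        )
        s = count_summary(prof)
        assert (s["heat"], s["bang"], s["heat_and_bang"]) == (7, 3, 2)
        assert (s["heat_only"], s["bang_only"], s["resilience_union"]) == (5, 1, 8)

    def test_empty_profiles_all_zero(self):
        prof = build_profiles([], {}, {}, {}, {}, {})
        s = count_summary(prof)
        assert s["cns_union"] == 0 and s["modifier_union"] == 0

    def test_inclusion_exclusion_against_direct_union(self):
        # random assay sets: the identity must hold for every pair/triple
        import numpy as np

        rng = np.random.default_rng(0)
        genes = [record(f"g{i}") for i in range(40)]
        names = [g.fly_gene for g in genes]
        sets = {
            "structure": {g: bool(rng.random() < 0.3) for g in names},
            "erg": {g: "decreased" if rng.random() < 0.4 else "none" for g in names},
            "heat": {g: bool(rng.random() < 0.2) for g in names},
            "bang": {g: bool(rng.random() < 0.15) for g in names},
        }
        prof = build_profiles(
            genes, sets["structure"], sets["erg"], sets["heat"], sets["bang"],
            expression={g: "both" for g in names},
        )
        s = count_summary(prof)  # raises internally on any mismatch
        direct = {
            "structure": {g for g in names if sets["structure"][g]},
            "function": {g for g in names if sets["erg"][g] != "none"},
            "heat": {g for g in names if sets["heat"][g]},
            "bang": {g for g in names if sets["bang"][g]},
        }
        for pair in combinations(direct, 2):
            union = direct[pair[0]] | direct[pair[1]]
            inter = direct[pair[0]] & direct[pair[1]]
            assert len(union) == len(direct[pair[0]]) + len(direct[pair[1]]) - len(inter)
        assert s["cns_union"] == len(set().union(*direct.values()))


class TestExpressionTally:
    def test_two_undetected_out_of_100_gives_98_percent(self):
        expr = {f"g{i}": "both" for i in range(98)}
        expr.update({"g98": "not_detected", "g99": "not_detected"})
        t = tally_expression(expr)
        assert t["percent_expressed"] == pytest.approx(98.0)

    def test_all_not_detected_zero_percent(self):
        t = tally_expression({"a": "not_detected", "b": "not_detected"})
        assert t["percent_expressed"] == 0.0

    def test_category_counts_total(self):
        calls = synthetic_phenotype_calls()
        t = tally_expression(calls["expression"])
        assert (t["neuron"], t["glia"], t["both"], t["undetermined"], t["not_detected"]) == (
            24, 13, 46, 15, 2,
        )
        assert t["n_genes"] == 100

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            tally_expression({"a": "mystery"})


class TestSnpClusters:
    def _profiles(self, records, structure):
        names = [r.fly_gene for r in records]
        return build_profiles(
            records,
            structure=structure,
            erg_class={g: "none" for g in names},
            heat={g: False for g in names},
            bang={g: False for g in names},
            expression={g: "both" for g in names},
        )

    def test_shared_locus_snp_deduplicated(self):
        records = [record("a", snp="rs9"), record("b", snp="rs9")]
        prof = self._profiles(records, {"a": True, "b": True})
        clusters, _ = assign_snp_clusters(prof, records)
        assert clusters["structure"] == ["rs9"]

    def test_per_gene_counting_flag(self):
        records = [record("a", snp="rs9"), record("b", snp="rs9")]
        prof = self._profiles(records, {"a": True, "b": True})
        clusters, _ = assign_snp_clusters(prof, records, dedup=False)
        assert clusters["structure"] == ["rs9", "rs9"]

    def test_gene_in_both_resilience_clusters(self):
        records = [record("a", snp="rs1")]
        names = ["a"]
        prof = build_profiles(
            records,
            structure={g: False for g in names},
            erg_class={g: "none" for g in names},
            heat={"a": True}, bang={"a": True},
            expression={g: "both" for g in names},
        )
        clusters, _ = assign_snp_clusters(prof, records)
        assert clusters["heat"] == ["rs1"] and clusters["bang"] == ["rs1"]

    def test_rare_variant_gene_excluded_with_log(self):
        records = [
            GeneRecord("p", "P", evidence_class="rare_variant"),
            record("q", snp="rs2"),
        ]
        prof = self._profiles(records, {"p": True, "q": True})
        clusters, log = assign_snp_clusters(prof, records)
        assert clusters["structure"] == ["rs2"]
        assert any("excluded p" in line for line in log)

    def test_empty_cluster_logged(self):
        records = [record("a")]
        prof = self._profiles(records, {"a": False})
        clusters, log = assign_snp_clusters(prof, records)
        assert clusters["structure"] == []
        assert any("structure" in line and "empty" in line for line in log)

    def test_erg_scope_default_decreased_only(self):
        records = [record("a", snp="rs1"), record("b", snp="rs2")]
        names = ["a", "b"]
        prof = build_profiles(
            records,
            structure={g: False for g in names},
            erg_class={"a": "decreased", "b": "increased"},
            heat={g: False for g in names},
            bang={g: False for g in names},
            expression={g: "both" for g in names},
        )
        c_default, _ = assign_snp_clusters(prof, records)
        assert c_default["function"] == ["rs1"]
        c_all, _ = assign_snp_clusters(prof, records, erg_scope="all")
        assert c_all["function"] == ["rs1", "rs2"]


class TestPanelFixture:
    def test_panel_membership_mutually_exclusive(self):
        records = panel_records()
        calls = synthetic_phenotype_calls()
        prof = build_profiles(
            records, calls["structure"], calls["erg_class"], calls["heat"],
            calls["bang"], calls["expression"], calls["abeta"], calls["tau"],
        )
        hit = prof[prof["phenotyped"] == True]  # noqa: E712
        positive = set(
            hit.loc[
                (hit["structure"] == True)  # noqa: E712
                | (hit["function"] == True)  # noqa: E712
                | (hit["resilience_heat"] == True)  # noqa: E712
                | (hit["resilience_bang"] == True),  # noqa: E712
                "gene",
            ]
        )
        negative = set(prof["gene"]) - positive
        assert positive & negative == set()
        assert len(positive) == 50 and len(negative) == 50

    def test_panel_viability_counts(self):
        records = panel_records()
        essential = [r for r in records if r.viability != "viable"]
        excluded = [r for r in records if r.viability == "essential_lethal"]
        assert len(essential) == 32 and len(excluded) == 9
        assert all(not r.phenotyping_eligible for r in excluded)
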