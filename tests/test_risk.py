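"""Oligogenic risk scores, PCA stratification, heatmap matrix, VCF I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adscreen.risk import (
    CohortGenotypes,
    ClusterScoreMatrix,
    best_separating_component,
    center_rows,
    count_risk_alleles,
    load_cohort_tsv,
    load_cohort_vcf,
    project,
    reconstruct,
    run_pca,
    standardize,
)
from adscreen.simulate import SubgroupSpec, simulate_cohort, write_cohort_vcf


def cohort(dosage, snps=None, missing=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return CohortGenotypes(
        individual_ids=[f"i{k}" for k in range(n)],
        snp_ids=snps or [f"s{k}" for k in range(m)],
        dosage=dosage,
        missing=np.zeros_like(dosage, dtype=bool) if missing is None else np.asarray(missing, bool),
    )


class TestCounting:
    def test_all_zero_dosage_zero_counts(self):
        c = cohort(np.zeros((3, 4)))
        raw = count_risk_alleles(c, {"a": ["s0", "s1"], "b": ["s2", "s3"]})
        assert (raw.to_numpy() == 0).all()

    def test_hand_tabulated_cluster(self):
        c = cohort([[2, 1, 0]])
        raw = count_risk_alleles(c, {"a": ["s0", "s1", "s2"]})
        assert raw.loc["i0", "a"] == 3

    def test_disjoint_clusters_conserve_total_dosage(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (20, 6)).astype(float)
        c = cohort(d)
        raw = count_risk_alleles(c, {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]})
        np.testing.assert_allclose(raw.sum(axis=1), d.sum(axis=1))

    def test_missing_cluster_snp_is_error(self):
        c = cohort(np.zeros((2, 2)))
        with pytest.raises(KeyError, match="s9"):
            count_risk_alleles(c, {"a": ["s0", "s9"]})

    def test_mean_imputation_of_missing(self):
        miss = [[False, False], [True, False], [False, False]]
        c = cohort([[2, 0], [0, 0], [0, 0]], missing=miss)
        raw = count_risk_alleles(c, {"a": ["s0"]})
        assert raw.loc["i1", "a"] == pytest.approx(1.0)  # mean of 2 and 0

    def test_strict_mode_rejects_missing(self):
        miss = [[True, False], [False, False]]
        c = cohort([[0, 0], [0, 0]], missing=miss)
        with pytest.raises(ValueError, match="strict"):
            count_risk_alleles(c, {"a": ["s0"]}, impute_missing=False)

    def test_carrier_mode_caps_at_one(self):
        c = cohort([[2, 1], [0, 2]])
        raw = count_risk_alleles(c, {"a": ["s0", "s1"]}, carrier_mode=True)
        assert raw["a"].tolist() == [2.0, 1.0]


class TestStandardize:
    def test_two_value_column_hand_computed(self):
        raw = pd.DataFrame({"a": [1.0, 3.0]}, index=["i0", "i1"])
        z = standardize(raw).z
        np.testing.assert_allclose(z[:, 0], [-0.70710678, 0.70710678], atol=1e-8)

    def test_constant_column_is_error_naming_cluster(self):
        raw = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(raw)

    def test_columns_mean_zero_unit_sd(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.poisson(5, (30, 4)).astype(float),
                           columns=list("abcd"))
        z = standardize(raw).z
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_population_sd_option(self):
        raw = pd.DataFrame({"a": [1.0, 3.0]})
        z = standardize(raw, ddof=0).z
        np.testing.assert_allclose(z[:, 0], [-1.0, 1.0], atol=1e-12)


def _scores(z, clusters=None):
    z = np.asarray(z, dtype=float)
    return ClusterScoreMatrix(
        individual_ids=[f"i{k}" for k in range(z.shape[0])],
        clusters=clusters or [f"c{k}" for k in range(z.shape[1])],
        raw=z.copy(),
        z=z,
    )


class TestPca:
    def test_two_by_two_brute_force_oracle(self):
        s = _scores([[1.0, -1.0], [-1.0, 1.0], [0.0, 0.0]])
        pca = run_pca(s)
        np.testing.assert_allclose(
            np.abs(pca.loadings[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-12
        )
        assert pca.loadings[0, 0] > 0  # sign convention: first loading >= 0
        np.testing.assert_allclose(pca.variance_explained, [1.0, 0.0], atol=1e-12)

    def test_single_active_axis_explains_everything(self):
        s = _scores([[1.0, 0.0], [-1.0, 0.0], [0.5, 0.0], [-0.5, 0.0], [0.0, 0.0]])
        pca = run_pca(s)
        assert pca.variance_explained[0] == pytest.approx(1.0)

    def test_spectral_identities_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(8, 40)
            raw = pd.DataFrame(
                rng.normal(size=(n, 4)) + rng.poisson(4, size=(n, 4)),
                columns=["ERG", "Structure", "Bang", "Heat"],
            )
            pca = run_pca(standardize(raw))
            L = pca.loadings
            np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-8)
            assert pca.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
            z = standardize(raw).z
            assert np.abs(reconstruct(pca) - z).max() < 1e-8

    def test_needs_more_individuals_than_clusters(self):
        with pytest.raises(ValueError):
            run_pca(_scores(np.zeros((3, 4))))


class TestProjection:
    def test_axis_projection_reads_coordinate(self):
        s = _scores([[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, -1.0],
                     [2.0, 1.0, 0.0, 0.5], [1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 0.0, 2.0]])
        pca = run_pca(s)
        pca.loadings[:, 1] = np.array([0.0, 0.0, 0.0, 1.0])
        proj, order = project(s, pca, component_index=2)
        np.testing.assert_allclose(proj, s.z[:, 3])
        assert [proj[i] for i in order] == sorted(proj)

    def test_matrix_multiply_oracle(self):
        s = _scores([[1.0, -1.0], [-1.0, 1.0], [0.0, 0.0]])
        pca = run_pca(s)
        proj, _ = project(s, pca, component_index=1)
        np.testing.assert_allclose(proj, s.z @ pca.loadings[:, 0], atol=1e-12)

    def test_sign_flip_reverses_order(self):
        rng = np.random.default_rng(3)
        s = _scores(rng.normal(size=(10, 3)))
        pca = run_pca(s)
        _, order = project(s, pca, component_index=1)
        pca.loadings[:, 0] *= -1
        _, flipped = project(s, pca, component_index=1)
        assert flipped == order[::-1]

    def test_out_of_range_component(self):
        s = _scores(np.random.default_rng(0).normal(size=(5, 2)))
        pca = run_pca(s)
        with pytest.raises(IndexError):
            project(s, pca, component_index=5)


class TestCenterRows:
    def test_constant_row_centers_to_zero(self):
        s = _scores([[1.0, 1.0, 1.0, 1.0], [2.0, 0.0, 0.0, 0.0]])
        h = center_rows(s, [0, 1])
        np.testing.assert_allclose(h.values[0], [0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(h.values[1], [1.5, -0.5, -0.5, -0.5])

    def test_all_row_sums_zero_and_order_applied(self):
        rng = np.random.default_rng(4)
        s = _scores(rng.normal(size=(8, 4)))
        order = list(range(8))[::-1]
        h = center_rows(s, order, annotations={"grp": list("aabbccdd")})
        np.testing.assert_allclose(h.values.sum(axis=1), 0.0, atol=1e-10)
        assert h.individual_ids == [f"i{k}" for k in order]
        assert h.annotations["grp"] == list("ddccbbaa")

    def test_invalid_order_rejected(self):
        s = _scores(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            center_rows(s, [0, 0, 1])


class TestSubgroupRecovery:
    def test_anticorrelated_subgroups_separated_with_expected_loading_pattern(self):
        clusters = {c: [f"{c}{i}" for i in range(10)]
                    for c in ("ERG", "Structure", "Bang", "Heat")}
        freqs = {s: 0.3 for ss in clusters.values() for s in ss}
        rs, patterns = [], []
        for seed in range(10):
            sgs = [
                SubgroupSpec("g1", tuple(range(50)),
                             enriched=frozenset({"ERG", "Structure"}), delta=0.2),
                SubgroupSpec("g2", tuple(range(50, 100)),
                             enriched=frozenset({"Bang", "Heat"}), delta=0.2),
            ]
            ch = simulate_cohort(100, clusters, freqs, sgs, seed=seed)
            scores = standardize(count_risk_alleles(ch, clusters))
            pca = run_pca(scores)
            k, r = best_separating_component(pca, [0] * 50 + [1] * 50)
            rs.append(abs(r))
            idx = {c: scores.clusters.index(c) for c in clusters}
            L = pca.loadings[:, k - 1]
            patterns.append(
                np.sign(L[idx["ERG"]]) == np.sign(L[idx["Structure"]])
                and np.sign(L[idx["Bang"]]) == np.sign(L[idx["Heat"]])
                and np.sign(L[idx["ERG"]]) != np.sign(L[idx["Bang"]])
            )
        assert np.median(rs) >= 0.8
        assert all(patterns)


class TestGenotypeIO:
    def test_vcf_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (6, 4)).astype(float)
        c = cohort(d, snps=[f"rs{i}" for i in range(4)])
        risk = {"rs0": "G", "rs1": "G", "rs2": "G", "rs3": "G"}
        path = write_cohort_vcf(c, risk, tmp_path / "c.vcf")
        back = load_cohort_vcf(path, risk)
        assert back.snp_ids == c.snp_ids
        np.testing.assert_allclose(back.dosage, c.dosage)

    def test_vcf_risk_is_ref_complement_rule(self, tmp_path):
        c = cohort([[0.0], [1.0], [2.0]], snps=["rs1"])
        path = write_cohort_vcf(c, {"rs1": "A"}, tmp_path / "c.vcf",
                                ref_alt={"rs1": ("A", "G")})
        # dosages of the A (REF) allele written as 2 - ALT count
        back = load_cohort_vcf(path, {"rs1": "A"})
        np.testing.assert_allclose(back.dosage[:, 0], [0.0, 1.0, 2.0])

    def test_vcf_missing_genotypes_masked(self, tmp_path):
        c = cohort([[1.0], [2.0]], snps=["rs1"],
                   missing=[[True], [False]])
        path = write_cohort_vcf(c, {"rs1": "G"}, tmp_path / "c.vcf")
        back = load_cohort_vcf(path, {"rs1": "G"})
        assert back.missing[0, 0] and not back.missing[1, 0]

    def test_vcf_wrong_risk_allele_rejected(self, tmp_path):
        c = cohort([[1.0]], snps=["rs1"])
        path = write_cohort_vcf(c, {"rs1": "G"}, tmp_path / "c.vcf")
        with pytest.raises(ValueError, match="neither REF nor ALT"):
            load_cohort_vcf(path, {"rs1": "T"})

    def test_tsv_loader(self, tmp_path):
        df = pd.DataFrame(
            {
                "individual": ["i0", "i0", "i1", "i1"],
                "snp": ["s0", "s1", "s0", "s1"],
                "dosage": [2.0, 0.0, 1.0, 1.0],
            }
        )
        p = tmp_path / "geno.tsv"
        df.to_csv(p, sep="\t", index=False)
        c = load_cohort_tsv(p)
        assert c.individual_ids == ["i0", "i1"]
        np.testing.assert_allclose(c.dosage, [[2.0, 0.0], [1.0, 1.0]])
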