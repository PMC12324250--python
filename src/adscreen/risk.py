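"""Oligogenic risk scores and PCA-based cohort stratification.

For each phenotype cluster (ERG/function, Structure, Bang, Heat) the score
of an individual is the tabulated number of risk alleles over the
cluster's lead SNPs.  Scores are standardized per cluster (z-scores), a
principal component analysis is run on the standardized matrix, individuals
are ordered by their projection onto a chosen component, and each row is
centered on its own mean for heatmap rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortGenotypes",
    "ClusterScoreMatrix",
    "PcaResult",
    "HeatmapMatrix",
    "count_risk_alleles",
    "standardize",
    "run_pca",
    "project",
    "center_rows",
    "best_separating_component",
    "load_cohort_vcf",
    "load_cohort_tsv",
]


@dataclass
class CohortGenotypes:
    """Individuals x SNPs risk-allele dosage matrix (0/1/2, with mask)."""

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray          # float; entries 0/1/2 where observed
    missing: np.ndarray         # bool, same shape

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = len(self.individual_ids), len(self.snp_ids)
        if self.dosage.shape != (n, m) or self.missing.shape != (n, m):
            raise ValueError("dosage/missing shape does not match ids")
        observed = self.dosage[~self.missing]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValueError("observed dosages must be 0, 1, or 2")

    def snp_index(self, snp: str) -> int:
        try:
            return self.snp_ids.index(snp)
        except ValueError:
            raise KeyError(f"SNP {snp!r} not in cohort") from None


@dataclass
class ClusterScoreMatrix:
    """Raw and standardized per-cluster risk-allele counts."""

    individual_ids: list[str]
    clusters: list[str]
    raw: np.ndarray   # individuals x clusters
    z: np.ndarray     # standardized, column mean 0 / SD 1


@dataclass
class PcaResult:
    """Eigendecomposition of the standardized score covariance.

    ``loadings[:, k]`` is the unit-norm loading vector of component k+1;
    ``variance_explained`` are eigenvalue fractions (sum to 1 over the
    retained trace); ``scores`` are per-individual projections.
    """

    clusters: list[str]
    loadings: np.ndarray            # clusters x components
    variance_explained: np.ndarray  # per component
    scores: np.ndarray              # individuals x components
    sign_convention: str = "first-positive-ERG"


@dataclass
class HeatmapMatrix:
    """Row-centered standardized scores, rows ordered by projection."""

    individual_ids: list[str]  # in render order
    clusters: list[str]
    values: np.ndarray
    annotations: dict[str, list] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.clusters)


def count_risk_alleles(
    genotypes: CohortGenotypes,
    cluster_snps: Mapping[str, Sequence[str]],
    impute_missing: bool = True,
    carrier_mode: bool = False,
) -> pd.DataFrame:
    """Tabulate risk alleles per individual per phenotype cluster.

    Missing dosages are imputed with the per-SNP mean over observed
    individuals (``impute_missing=True``, default) or rejected outright.
    ``carrier_mode`` counts each SNP as 0/1 (any risk allele) instead of
    dosage 0/1/2.
    """
    missing_snps = sorted(
        {s for snps in cluster_snps.values() for s in snps} - set(genotypes.snp_ids)
    )
    if missing_snps:
        raise KeyError(f"cluster SNPs absent from genotypes: {missing_snps}")

    dos = genotypes.dosage.copy()
    if genotypes.missing.any():
        if not impute_missing:
            raise ValueError("cohort contains missing genotypes (strict mode)")
        for j in range(dos.shape[1]):
            col_missing = genotypes.missing[:, j]
            if col_missing.any():
                observed = dos[~col_missing, j]
                dos[col_missing, j] = observed.mean() if observed.size else 0.0
    if carrier_mode:
        dos = np.minimum(dos, 1.0)

    counts = {}
    for cluster, snps in cluster_snps.items():
        idx = [genotypes.snp_index(s) for s in snps]
        counts[cluster] = dos[:, idx].sum(axis=1) if idx else np.zeros(dos.shape[0])
    return pd.DataFrame(counts, index=genotypes.individual_ids)


def standardize(raw_counts: pd.DataFrame, ddof: int = 1) -> ClusterScoreMatrix:
    """Column-wise z-scores of the raw counts (sample SD by default).

    A zero-SD cluster is an error naming the degenerate column -- a
    constant score carries no stratification signal and silently emitting
    zeros would distort the PCA.
    """
    if raw_counts.shape[0] < 2:
        raise ValueError("standardization needs at least 2 individuals")
    raw = raw_counts.to_numpy(dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=ddof)
    degenerate = [c for c, s in zip(raw_counts.columns, sd) if s == 0]
    if degenerate:
        raise ValueError(f"zero-variance cluster(s): {degenerate}")
    z = (raw - mean) / sd
    return ClusterScoreMatrix(
        individual_ids=list(raw_counts.index.astype(str)),
        clusters=list(raw_counts.columns.astype(str)),
        raw=raw,
        z=z,
    )


def run_pca(scores: ClusterScoreMatrix, ddof: int = 1) -> PcaResult:
    """PCA via eigendecomposition of the covariance of the z-matrix.

    Components are ordered by decreasing eigenvalue; negative round-off
    eigenvalues are clipped to zero (rank deficiency is reported as zero
    variance, not failure).  The eigenvector sign is arbitrary, so a fixed
    convention is applied: the ERG (first-cluster) loading of each
    component is made non-negative, ties broken by the next cluster.
    """
    z = scores.z
    n = z.shape[0]
    if n <= z.shape[1]:
        raise ValueError("need more individuals than clusters for PCA")
    cov = (z.T @ z) / (n - ddof)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    for k in range(eigvecs.shape[1]):
        v = eigvecs[:, k]
        lead = next((x for x in v if abs(x) > 1e-12), 1.0)
        if lead < 0:
            eigvecs[:, k] = -v

    total = eigvals.sum()
    frac = eigvals / total if total > 0 else np.full_like(eigvals, np.nan)
    return PcaResult(
        clusters=list(scores.clusters),
        loadings=eigvecs,
        variance_explained=frac,
        scores=z @ eigvecs,
    )


def project(
    scores: ClusterScoreMatrix, pca: PcaResult, component_index: int = 2
) -> tuple[np.ndarray, list[int]]:
    """Projection onto the chosen component (1-based) and the sort order.

    Returns (per-individual scores, row order sorted ascending by score,
    ties broken by individual id).
    """
    k = component_index - 1
    if not 0 <= k < pca.loadings.shape[1]:
        raise IndexError(f"component {component_index} out of range")
    proj = scores.z @ pca.loadings[:, k]
    order = sorted(
        range(len(proj)), key=lambda i: (proj[i], scores.individual_ids[i])
    )
    return proj, order


def center_rows(
    scores: ClusterScoreMatrix,
    order: Sequence[int],
    annotations: Mapping[str, Sequence] | None = None,
) -> HeatmapMatrix:
    """Subtract each individual's own mean score and apply the row order."""
    order = list(order)
    if sorted(order) != list(range(len(scores.individual_ids))):
        raise ValueError("order must be a permutation of the row indices")
    centered = scores.z - scores.z.mean(axis=1, keepdims=True)
    ann = {
        key: [list(vals)[i] for i in order] for key, vals in (annotations or {}).items()
    }
    return HeatmapMatrix(
        individual_ids=[scores.individual_ids[i] for i in order],
        clusters=list(scores.clusters),
        values=centered[order, :],
        annotations=ann,
    )


def best_separating_component(
    pca: PcaResult, labels: Sequence
) -> tuple[int, float]:
    """Component (1-based) whose projection best separates a binary
    labelling, with the point-biserial correlation achieved.

    The sort component defaulting to 2 reflects one cohort's observation;
    this helper reports which component separates *your* subgroups.
    """
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size != 2:
        raise ValueError("labels must be binary")
    y = (lab == uniq[1]).astype(float)
    best_k, best_r = 1, 0.0
    for k in range(pca.scores.shape[1]):
        x = pca.scores[:, k]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) > abs(best_r):
            best_k, best_r = k + 1, r
    return best_k, best_r


def reconstruct(pca: PcaResult) -> np.ndarray:
    """Z reconstructed from all components (spectral-identity check)."""
    return pca.scores @ pca.loadings.T


# ---------------------------------------------------------------------------
# cohort genotype I/O


def load_cohort_tsv(path) -> CohortGenotypes:
    """Long-format TSV: columns individual, snp, dosage ('' = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "snp": str})
    wide = df.pivot(index="individual", columns="snp", values="dosage")
    missing = wide.isna().to_numpy()
    dosage = wide.fillna(0.0).to_numpy(dtype=float)
    return CohortGenotypes(
        individual_ids=list(wide.index),
        snp_ids=list(wide.columns),
        dosage=dosage,
        missing=missing,
    )


def load_cohort_vcf(path, risk_alleles: Mapping[str, str]) -> CohortGenotypes:
    """Read risk-allele dosages from a biallelic VCF (GT field).

    ``risk_alleles`` maps SNP id -> risk base.  Dosage is the ALT count if
    the risk allele is ALT, else 2 - ALT count; the risk allele must match
    REF or ALT.  Missing genotypes are recorded in the mask.  Sites not in
    ``risk_alleles`` are ignored; multiallelic sites used by a cluster are
    an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snp_ids: list[str] = []
    rows_dosage: list[np.ndarray] = []
    rows_missing: list[np.ndarray] = []
    for variant in vcf:
        vid = variant.ID
        if vid is None or vid not in risk_alleles:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(f"site {vid} is multiallelic")
        risk = risk_alleles[vid]
        if risk == variant.ALT[0]:
            flip = False
        elif risk == variant.REF:
            flip = True
        else:
            raise ValueError(
                f"risk allele {risk!r} at {vid} matches neither REF nor ALT"
            )
        gts = variant.genotype.array()  # sample x (a1, a2, phased)
        alleles = gts[:, :2]
        miss = (alleles < 0).any(axis=1)
        alt_count = np.clip(alleles, 0, None).sum(axis=1).astype(float)
        dos = (2.0 - alt_count) if flip else alt_count
        dos[miss] = 0.0
        snp_ids.append(vid)
        rows_dosage.append(dos)
        rows_missing.append(miss)
    if not snp_ids:
        raise ValueError("no usable sites found in VCF")
    return CohortGenotypes(
        individual_ids=individuals,
        snp_ids=snp_ids,
        dosage=np.column_stack(rows_dosage),
        missing=np.column_stack(rows_missing),
    )
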