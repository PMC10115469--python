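"""Correlation estimation for the Kronecker-structured null covariance.

Under the global null, the vectorized matrix of per-trait per-SNP Wald
Z-scores is asymptotically multivariate normal with correlation

    corr(Z_jk, Z_j'k') = rho_jj' * theta_kk',

where ``rho_jj'`` is the phenotypic correlation between traits j and j' and
``theta_kk'`` is the partial correlation between the genotypes of SNPs k and
k' given the regression covariates.  Stacking the Z matrix column-wise
(SNP-major) gives the null covariance ``Delta_theta (x) Delta_rho``.

This module estimates both factors from the data a summary-statistics
analyst actually has:

* ``Delta_rho`` from the Z-scores of a large set of approximately
  independent null SNPs (SNPs with no association signal in any trait) —
  the sample Pearson correlation of the per-trait Z columns;
* ``Delta_theta`` from a reference genotype panel of the target population,
  as the Pearson correlation of dosage columns, after projecting out
  stratification covariates (principal coordinates) when the original GWAS
  adjusted for them.

Three covariate cases are distinguished: purely environmental covariates
(independent of genotype, so plain Pearson LD suffices), population
stratification axes (residualize genotypes on the axes first), and a mix of
both (environmental covariates can be ignored; identical to the second
case).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "CorrelationMatrix",
    "TraitCorrMatrix",
    "SnpCorrMatrix",
    "CovariateKind",
    "CovariateDesign",
    "NullZTable",
    "estimate_trait_correlation",
    "pearson_genotype_correlation",
    "residualize_genotypes",
    "partial_genotype_correlation",
    "compute_principal_coordinates",
    "regularize_correlation",
    "select_null_snps",
]

#: Default eigenvalue floor used when regularizing estimated correlations.
EPS_PD_DEFAULT = 1e-6

#: Minimum number of null SNPs accepted for trait-correlation estimation.
MIN_NULL_SNPS = 50


def _check_correlation_values(values: np.ndarray, labels: list[str]) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.abs(values) > 1.0 + 1e-10):
        raise ValueError("correlation entries must lie in [-1, 1]")
    return values


@dataclass
class CorrelationMatrix:
    """A labelled correlation matrix (symmetric, unit diagonal)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = _check_correlation_values(self.values, self.labels)

    @property
    def dim(self) -> int:
        return len(self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def regularize(self, eps_pd: float = EPS_PD_DEFAULT) -> "CorrelationMatrix":
        """Return a positive-definite copy (see :func:`regularize_correlation`)."""
        return type(self)(self.labels, regularize_correlation(self.values, eps_pd))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CorrelationMatrix":
        return cls(list(frame.columns), frame.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CorrelationMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


class TraitCorrMatrix(CorrelationMatrix):
    """Estimated trait correlation matrix (rho-hat), q x q."""


class SnpCorrMatrix(CorrelationMatrix):
    """Estimated (partial) genotype correlation matrix (theta-hat), m x m."""


class CovariateKind(str, enum.Enum):
    """What the original GWAS adjusted for, which decides how LD is estimated."""

    ENVIRONMENT_ONLY = "environment_only"
    STRATIFICATION = "stratification"
    MIXED = "mixed"


@dataclass
class CovariateDesign:
    """An N x (s+1) design matrix whose first column is the intercept."""

    matrix: np.ndarray
    kind: CovariateKind = CovariateKind.STRATIFICATION
    s: int = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design must be a 2-D matrix")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first design column must be the all-ones intercept")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("covariate design is rank deficient")
        self.kind = CovariateKind(self.kind)
        self.s = self.matrix.shape[1] - 1

    @classmethod
    def intercept_only(cls, n: int, kind: CovariateKind = CovariateKind.ENVIRONMENT_ONLY):
        return cls(np.ones((n, 1)), kind=kind)


@dataclass
class NullZTable:
    """Wald Z-scores of presumed-null SNPs: one row per SNP, one column per trait."""

    snps: list[str]
    traits: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.snps), len(self.traits)):
            raise ValueError("Z table shape does not match SNP/trait labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null-SNP Z table contains non-finite entries")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @classmethod
    def from_file(cls, path) -> "NullZTable":
        """Read a whitespace/tab-delimited table with header ``SNP trait1 ...``."""
        frame = pd.read_csv(path, sep=r"\s+")
        snp_col = frame.columns[0]
        return cls(
            snps=frame[snp_col].astype(str).tolist(),
            traits=list(frame.columns[1:]),
            values=frame.iloc[:, 1:].to_numpy(dtype=float),
        )

    def to_file(self, path) -> None:
        frame = pd.DataFrame(self.values, columns=self.traits)
        frame.insert(0, "SNP", self.snps)
        frame.to_csv(path, sep="\t", index=False)


def estimate_trait_correlation(
    null_z: NullZTable, min_snps: int = MIN_NULL_SNPS
) -> TraitCorrMatrix:
    """Estimate the trait correlation matrix from null-SNP Z-scores.

    Entry (j, j') is the sample Pearson correlation of the j-th and j'-th
    Z-score columns over the null SNPs; under the null the Z-scores of a
    null SNP across traits inherit exactly the phenotypic correlation, so
    this is a consistent estimator of rho_jj' as the number of independent
    null SNPs grows.
    """
    if null_z.n_snps < min_snps:
        raise ValueError(
            f"only {null_z.n_snps} null SNPs provided; at least {min_snps} are "
            "needed for a stable trait-correlation estimate — supply more "
            "approximately independent null SNPs"
        )
    variances = null_z.values.var(axis=0)
    degenerate = np.where(variances <= 0)[0]
    if degenerate.size:
        names = ", ".join(null_z.traits[j] for j in degenerate)
        raise ValueError(f"zero-variance Z column for trait(s): {names}")
    corr = np.corrcoef(null_z.values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return TraitCorrMatrix(null_z.traits, 0.5 * (corr + corr.T))


def _impute_and_check(
    panel: np.ndarray, labels: list[str] | None, max_missing: float
) -> tuple[np.ndarray, list[str]]:
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2:
        raise ValueError("genotype panel must be an N x m matrix")
    n, m = panel.shape
    if labels is None:
        labels = [f"snp{k + 1}" for k in range(m)]
    missing = np.isnan(panel)
    frac = missing.mean(axis=0)
    bad = np.where(frac > max_missing)[0]
    if bad.size:
        names = ", ".join(labels[k] for k in bad)
        raise ValueError(
            f"missing-dosage fraction exceeds {max_missing:.0%} for SNP(s): {names}"
        )
    if missing.any():
        means = np.nanmean(panel, axis=0)
        panel = np.where(missing, means[None, :], panel)
    variances = panel.var(axis=0)
    mono = np.where(variances <= 0)[0]
    if mono.size:
        names = ", ".join(labels[k] for k in mono)
        raise ValueError(f"monomorphic SNP(s) with zero dosage variance: {names}")
    return panel, list(labels)


def pearson_genotype_correlation(
    panel: np.ndarray,
    labels: list[str] | None = None,
    max_missing: float = 0.05,
) -> SnpCorrMatrix:
    """Pairwise Pearson correlation of dosage columns from a reference panel.

    This is the LD estimate appropriate when the original GWAS adjusted only
    for environmental covariates (or none): genotypes are independent of
    such covariates, so no residualization is needed.  Missing dosages are
    mean-imputed per SNP up to ``max_missing``.
    """
    panel, labels = _impute_and_check(panel, labels, max_missing)
    if panel.shape[0] < 2:
        raise ValueError("at least two individuals are required")
    corr = np.corrcoef(panel, rowvar=False)
    corr = np.clip(np.atleast_2d(corr), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SnpCorrMatrix(labels, 0.5 * (corr + corr.T))


def residualize_genotypes(panel: np.ndarray, design: CovariateDesign) -> np.ndarray:
    """Project dosage columns onto the orthogonal complement of the design.

    Each column g becomes ``(I - C (C'C)^{-1} C') g``; the output columns are
    orthogonal to every design column.  Missing dosages must be imputed by
    the caller (the public estimators do this).
    """
    panel = np.asarray(panel, dtype=float)
    c = design.matrix
    if panel.shape[0] != c.shape[0]:
        raise ValueError("panel and design have different numbers of individuals")
    if panel.shape[0] <= c.shape[1]:
        raise ValueError(
            f"need more individuals ({panel.shape[0]}) than design columns "
            f"({c.shape[1]}) to residualize"
        )
    q, _ = np.linalg.qr(c)
    return panel - q @ (q.T @ panel)


def partial_genotype_correlation(
    panel: np.ndarray,
    design: CovariateDesign,
    labels: list[str] | None = None,
    max_missing: float = 0.05,
) -> SnpCorrMatrix:
    """Partial correlation of SNP dosages given stratification covariates.

    For environment-only covariates this reduces (by construction, not
    approximation) to :func:`pearson_genotype_correlation`.  Otherwise the
    dosage columns are residualized on the design and the Pearson
    correlation of the residuals is returned — the partial correlation
    theta_kk' that the product identity for Wald-score correlations
    requires when the GWAS adjusted for stratification axes.
    """
    panel, labels = _impute_and_check(panel, labels, max_missing)
    if design.kind is CovariateKind.ENVIRONMENT_ONLY:
        return pearson_genotype_correlation(panel, labels, max_missing)
    residuals = residualize_genotypes(panel, design)
    variances = residuals.var(axis=0)
    flat = np.where(variances <= 1e-12 * max(1.0, panel.var()))[0]
    if flat.size:
        names = ", ".join(labels[k] for k in flat)
        raise ValueError(
            f"residual variance is zero for SNP(s) {names}: dosages are fully "
            "explained by the covariates"
        )
    corr = np.corrcoef(residuals, rowvar=False)
    corr = np.clip(np.atleast_2d(corr), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SnpCorrMatrix(labels, 0.5 * (corr + corr.T))


def compute_principal_coordinates(
    panel: np.ndarray, s: int, kind: CovariateKind = CovariateKind.STRATIFICATION
) -> CovariateDesign:
    """Top-``s`` principal coordinates of the panel as a covariate design.

    Classical multidimensional scaling of the pairwise Euclidean distances
    between individuals' dosage vectors.  For Euclidean distances this is
    computed exactly (and far more cheaply) as the left singular vectors of
    the row-centered dosage matrix scaled by their singular values.  Axis
    signs are fixed by making each axis's largest-magnitude SNP loading
    positive, so results are deterministic.
    """
    panel = np.asarray(panel, dtype=float)
    if np.isnan(panel).any():
        means = np.nanmean(panel, axis=0)
        panel = np.where(np.isnan(panel), means[None, :], panel)
    n = panel.shape[0]
    if s < 0:
        raise ValueError("s must be non-negative")
    if n < s + 2:
        raise ValueError(f"need at least s + 2 = {s + 2} individuals, got {n}")
    if s == 0:
        return CovariateDesign.intercept_only(n, kind=kind)
    centered = panel - panel.mean(axis=0)
    u, sing, vt = np.linalg.svd(centered, full_matrices=False)
    positive = sing > 1e-9 * max(sing[0], 1.0)
    if positive.sum() < s:
        raise ValueError(
            f"only {int(positive.sum())} positive principal-coordinate "
            f"eigenvalues available; cannot extract s={s} axes"
        )
    coords = u[:, :s] * sing[:s]
    for axis in range(s):
        lead = np.argmax(np.abs(vt[axis]))
        if vt[axis, lead] < 0:
            coords[:, axis] = -coords[:, axis]
    design = np.column_stack([np.ones(n), coords])
    return CovariateDesign(design, kind=kind)


def regularize_correlation(
    values: np.ndarray, eps_pd: float = EPS_PD_DEFAULT
) -> np.ndarray:
    """Clip eigenvalues below ``eps_pd`` and rescale to unit diagonal.

    Estimated correlation matrices can be numerically singular (duplicated
    SNPs, heavy LD); the quadratic-form statistics need invertible factors.
    Inputs that are already positive definite with smallest eigenvalue at or
    above the floor are returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    eigval, eigvec = np.linalg.eigh(0.5 * (values + values.T))
    if eigval[0] >= eps_pd:
        return values
    clipped = np.maximum(eigval, eps_pd)
    fixed = (eigvec * clipped) @ eigvec.T
    scale = 1.0 / np.sqrt(np.diag(fixed))
    fixed = fixed * scale[:, None] * scale[None, :]
    fixed = 0.5 * (fixed + fixed.T)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def select_null_snps(
    z_table: NullZTable,
    ld: SnpCorrMatrix | None = None,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.1,
) -> NullZTable:
    """Pick approximately independent null SNPs for trait-correlation estimation.

    A SNP qualifies as null when its two-sided p-value exceeds
    ``p_threshold`` in every trait.  When a reference LD matrix over the
    candidate SNPs is supplied, the qualifying set is greedily pruned so
    that no retained pair has r^2 at or above ``r2_threshold`` (candidates
    are scanned in input order, keeping each SNP unless it is in LD with an
    already-kept one).
    """
    z_crit = float(sp_stats.norm.isf(p_threshold / 2.0))
    null_mask = np.all(np.abs(z_table.values) < z_crit, axis=1)
    idx = np.where(null_mask)[0]
    if ld is not None:
        if ld.labels != z_table.snps:
            raise ValueError("LD matrix labels must match the Z-table SNPs in order")
        r2 = ld.values**2
        kept: list[int] = []
        for i in idx:
            if all(r2[i, j] < r2_threshold for j in kept):
                kept.append(int(i))
        idx = np.asarray(kept, dtype=int)
    return NullZTable(
        snps=[z_table.snps[i] for i in idx],
        traits=z_table.traits,
        values=z_table.values[idx],
    )
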