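"""Synthetic type-I-error / power studies for the Three-Way Test.

Individual-level data are generated under the linear model

    y_ij = alpha_j + sum_k g_ik beta_jk + c_i gamma_j + eps_ij,

with per-individual error vectors jointly normal with a chosen trait
correlation, a one-dimensional covariate c, and genotypes drawn from a
latent-Gaussian threshold model: each haplotype's allele indicators come
from thresholding a correlated Gaussian vector at Phi^{-1}(MAF), and the
dosage is the sum of two independent haplotypes.  This reproduces the LD
class of a real reference panel (AR(1) by default) without any external
download; a real panel matrix can be passed in instead.

Signal allocations name where the non-zero coefficients sit in the q x m
matrix B: NONE (global null), SINGLE (one entry), ROW (one trait, all SNPs),
COLUMN (one SNP, all traits — pleiotropy).

``run_scenario`` estimates empirical rejection rates at the configured
significance levels: genotypes, covariates, the estimated correlation
factors and the bootstrap calibration are fixed once per scenario, then
phenotype noise is redrawn per replication and the Wald statistics and the
Three-Way Test are evaluated in vectorized batches.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .calibration import calibrate
from .corr import (
    CovariateDesign,
    CovariateKind,
    NullZTable,
    compute_principal_coordinates,
    estimate_trait_correlation,
    partial_genotype_correlation,
    pearson_genotype_correlation,
)
from .stats import TruncationGrid, ZMatrix, twt_pvalues_batch

__all__ = [
    "SignalAllocation",
    "ScenarioConfig",
    "ar1_correlation",
    "default_trait_correlation",
    "make_coefficient_matrix",
    "generate_genotypes",
    "generate_stratified_genotypes",
    "simulate_phenotypes",
    "compute_wald_z",
    "run_scenario",
]


class SignalAllocation(str, enum.Enum):
    NONE = "NONE"
    SINGLE = "SINGLE"
    ROW = "ROW"
    COLUMN = "COLUMN"


def ar1_correlation(rho: float, dim: int) -> np.ndarray:
    """First-order autoregressive correlation matrix (rho^|i-j|)."""
    idx = np.arange(dim)
    return rho ** np.abs(idx[:, None] - idx[None, :])


# Fixed trait correlation emulating a panel of six plasma fatty-acid-like
# traits: two strongly coupled precursor/product pairs plus moderate
# cross-correlations.  Used as the default non-identity q=6 structure in the
# type-I-error study.
_TRAIT_CORR_6 = np.array(
    [
        [1.00, 0.62, 0.28, 0.35, 0.15, 0.20],
        [0.62, 1.00, 0.32, 0.25, 0.18, 0.24],
        [0.28, 0.32, 1.00, 0.30, 0.22, 0.18],
        [0.35, 0.25, 0.30, 1.00, 0.45, 0.40],
        [0.15, 0.18, 0.22, 0.45, 1.00, 0.55],
        [0.20, 0.24, 0.18, 0.40, 0.55, 1.00],
    ]
)


def default_trait_correlation(q: int = 6) -> np.ndarray:
    """A realistic non-identity trait correlation for q = 6 (see module note)."""
    if q != 6:
        raise ValueError("the built-in realistic structure is defined for q = 6")
    return _TRAIT_CORR_6.copy()


def make_coefficient_matrix(
    q: int,
    m: int,
    allocation: SignalAllocation,
    effect: float = 0.0,
    target_row: int = 0,
    target_col: int = 0,
) -> np.ndarray:
    """Coefficient matrix B with non-zeros placed per the allocation pattern."""
    allocation = SignalAllocation(allocation)
    beta = np.zeros((q, m))
    if allocation is SignalAllocation.NONE:
        return beta
    if allocation is SignalAllocation.SINGLE:
        beta[target_row, target_col] = effect
    elif allocation is SignalAllocation.ROW:
        beta[target_row, :] = effect
    else:
        beta[:, target_col] = effect
    return beta


@dataclass
class ScenarioConfig:
    """Full specification of one simulation scenario.

    ``trait_corr`` and ``ld`` accept either an explicit matrix or a scalar
    AR(1) parameter; ``maf`` accepts a scalar, a length-m vector, or a
    ``("uniform", lo, hi)`` range sampled once per scenario.  The covariate
    is standard normal ("normal") or a two-cluster mean shift
    ("two_cluster") emulating stratification; ``adjustment`` picks the
    regression design used for the Wald statistics.
    """

    n: int = 2504
    q: int = 6
    m: int = 9
    trait_corr: object = 0.5
    ld: object = 0.8
    maf: object = ("uniform", 0.05, 0.5)
    allocation: SignalAllocation = SignalAllocation.NONE
    effect: float = 0.0
    target_row: int = 0
    target_col: int = 0
    gamma: float = 0.5
    covariate: str = "normal"
    adjustment: str = "covariate"  # "covariate", "principal_coordinates", "none"
    n_axes: int = 2
    n_reps: int = 1000
    alphas: tuple[float, ...] = (1e-3, 1e-5)
    bootstrap_size: int = 100_000
    # Null-SNP supply for the trait-correlation estimate.  A genome-wide
    # scan provides on the order of 1e5 independent null SNPs after
    # pruning.  Z-scores computed against one phenotype replicate converge
    # (in the number of SNPs) to that replicate's realized residual
    # correlation, which deviates from the generating trait correlation by
    # O(1/sqrt(n)); pooling Z-scores over several independent replicates
    # removes that floor, emulating the precision a genome-wide estimate
    # has for the cohort actually being tested.
    n_null_snps: int = 2000
    n_null_reps: int = 20
    grid: TruncationGrid = field(default_factory=TruncationGrid)
    seed: int = 0
    chunk: int = 512

    def resolve_trait_corr(self) -> np.ndarray:
        if np.isscalar(self.trait_corr):
            return ar1_correlation(float(self.trait_corr), self.q)
        return np.asarray(self.trait_corr, dtype=float)

    def resolve_ld(self) -> np.ndarray:
        if np.isscalar(self.ld):
            return ar1_correlation(float(self.ld), self.m)
        return np.asarray(self.ld, dtype=float)

    def resolve_maf(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf, (tuple, list)) and len(self.maf) == 3 and self.maf[0] == "uniform":
            return rng.uniform(float(self.maf[1]), float(self.maf[2]), size=self.m)
        return np.broadcast_to(np.asarray(self.maf, dtype=float), (self.m,)).copy()

    def coefficient_matrix(self) -> np.ndarray:
        return make_coefficient_matrix(
            self.q, self.m, self.allocation, self.effect, self.target_row, self.target_col
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = TruncationGrid(tuple(raw["grid"]))
        if "allocation" in raw:
            raw["allocation"] = SignalAllocation(raw["allocation"])
        if "alphas" in raw:
            raw["alphas"] = tuple(raw["alphas"])
        return cls(**raw)


def generate_genotypes(
    n: int,
    m: int,
    ld: np.ndarray | float | None = None,
    maf: np.ndarray | float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw an n x m dosage matrix from the latent-Gaussian threshold model."""
    rng = np.random.default_rng(rng)
    if ld is None:
        ld_matrix = np.eye(m)
    elif np.isscalar(ld):
        ld_matrix = ar1_correlation(float(ld), m)
    else:
        ld_matrix = np.asarray(ld, dtype=float)
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (m,))
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    try:
        chol = np.linalg.cholesky(ld_matrix)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("LD matrix is not positive definite") from exc
    thresholds = norm.ppf(maf)
    dosage = np.zeros((n, m))
    for _ in range(2):  # two haplotypes per individual
        latent = rng.standard_normal((n, m)) @ chol.T
        dosage += latent < thresholds[None, :]
    return dosage


def generate_stratified_genotypes(
    n: int,
    m: int,
    maf_groups: tuple = (0.1, 0.4),
    ld: np.ndarray | float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-subpopulation panel (half/half) with group-specific MAFs.

    Returns the dosage matrix and the 0/1 group labels; used to exercise the
    principal-coordinate stratification-adjustment path.
    """
    rng = np.random.default_rng(rng)
    n1 = n // 2
    groups = np.repeat([0, 1], [n1, n - n1])
    g1 = generate_genotypes(n1, m, ld, maf_groups[0], rng)
    g2 = generate_genotypes(n - n1, m, ld, maf_groups[1], rng)
    return np.vstack([g1, g2]), groups


def simulate_phenotypes(
    genotypes: np.ndarray,
    scenario: ScenarioConfig,
    covariate: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One n x q phenotype replicate under the scenario's linear model."""
    rng = np.random.default_rng(rng)
    n, m = genotypes.shape
    q = scenario.q
    beta = scenario.coefficient_matrix()
    trait_corr = scenario.resolve_trait_corr()
    chol = np.linalg.cholesky(trait_corr)
    eps = rng.standard_normal((n, q)) @ chol.T
    y = genotypes @ beta.T + eps
    if covariate is not None:
        y += np.outer(covariate, np.full(q, scenario.gamma))
    return y


def _design_qr(covariates: np.ndarray | None, n: int) -> tuple[np.ndarray, int]:
    if covariates is None:
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if np.allclose(covariates[:, 0], 1.0):
            design = covariates
        else:
            design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariate design")
    q, _ = np.linalg.qr(design)
    return q, design.shape[1]


def compute_wald_z(
    phenotypes: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None = None,
    on_degenerate: str = "error",
) -> ZMatrix:
    """Per-trait, per-SNP covariate-adjusted Wald statistics.

    Z_jk is the t-statistic of the SNP coefficient in the univariate
    regression of trait j on SNP k plus the covariates (intercept always
    included).  Computed for all (j, k) at once by residualizing phenotypes
    and genotypes on the covariate design (Frisch–Waugh–Lovell), which is
    algebraically identical to fitting each full regression.

    A perfect fit (zero residual variance) yields an infinite statistic;
    ``on_degenerate`` chooses between raising ("error") and returning
    +/-inf is not allowed in a ZMatrix, so "clip" substitutes a very large
    finite value (1e8) with the correct sign.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    n, q = phenotypes.shape
    if genotypes.shape[0] != n:
        raise ValueError("phenotypes and genotypes have different sample sizes")
    m = genotypes.shape[1]
    q_mat, p_cols = _design_qr(covariates, n)
    if n <= p_cols + 1:
        raise ValueError("sample size too small for the regression design")
    e = phenotypes - q_mat @ (q_mat.T @ phenotypes)  # residualized traits, n x q
    h = genotypes - q_mat @ (q_mat.T @ genotypes)  # residualized SNPs, n x m
    hss = np.einsum("nk,nk->k", h, h)
    if np.any(hss <= 0):
        raise ValueError("a SNP is collinear with the covariate design")
    cross = e.T @ h  # q x m
    ess = np.einsum("nj,nj->j", e, e)
    df = n - p_cols - 1
    rss = ess[:, None] - cross**2 / hss[None, :]
    degenerate = rss <= 1e-12 * np.maximum(ess[:, None], 1.0)
    if degenerate.any():
        if on_degenerate == "error":
            raise FloatingPointError(
                "perfect linear fit encountered; Wald statistic is unbounded "
                "(rerun with on_degenerate='clip' to cap it)"
            )
        rss = np.where(degenerate, np.nan, rss)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = cross / np.sqrt(hss)[None, :] / np.sqrt(rss / df)
    if degenerate.any():
        z = np.where(degenerate, np.sign(cross) * 1e8, z)
    traits = [f"trait{j + 1}" for j in range(q)]
    snps = [f"snp{k + 1}" for k in range(m)]
    return ZMatrix(traits, snps, z)


def _wald_z_chunk(
    eps_chunk: np.ndarray,
    base: np.ndarray,
    q_mat: np.ndarray,
    h: np.ndarray,
    hss: np.ndarray,
    df: int,
) -> np.ndarray:
    """Vectorized Wald statistics for a chunk of phenotype replicates.

    ``eps_chunk`` is (r, n, q) noise, ``base`` the fixed n x q mean surface;
    genotype residuals ``h`` and the covariate orthonormal basis are shared
    across replicates.  Returns (r, q, m) Z statistics.
    """
    y = base[None, :, :] + eps_chunk
    proj = np.einsum("np,rnq->rpq", q_mat, y)
    e = y - np.einsum("np,rpq->rnq", q_mat, proj)
    cross = np.einsum("rnq,nk->rqk", e, h)
    ess = np.einsum("rnq,rnq->rq", e, e)
    rss = ess[:, :, None] - cross**2 / hss[None, None, :]
    return cross / np.sqrt(hss)[None, None, :] / np.sqrt(rss / df)


def run_scenario(scenario: ScenarioConfig, progress: bool = False) -> pd.DataFrame:
    """Empirical rejection rates of the Three-Way Test under one scenario.

    The workflow mirrors a real summary-statistics analysis end to end:

    1. generate a genotype panel and covariate once (they play the role of
       the fixed cohort);
    2. estimate the SNP correlation from the panel and the trait
       correlation from the Wald Z-scores of ``n_null_snps`` independent
       null SNPs computed on one phenotype replicate;
    3. fit the parametric-bootstrap calibration once for the estimated
       covariance;
    4. redraw phenotype noise ``n_reps`` times, compute covariate-adjusted
       Wald statistics and the Three-Way Test p-value for each replicate,
       and count rejections at each significance level.

    Returns a tidy table (alpha, component, rejections, reps, rate, se) for
    the final p-value and each component P1, P2, P3.
    """
    seeds = np.random.SeedSequence(scenario.seed).spawn(4)
    rng_panel, rng_nullsnp, rng_reps = (np.random.default_rng(s) for s in seeds[:3])
    calib_seed = int(seeds[3].generate_state(1)[0] % (2**31 - 1))

    n, q, m = scenario.n, scenario.q, scenario.m
    maf = scenario.resolve_maf(rng_panel)
    genotypes = generate_genotypes(n, m, scenario.resolve_ld(), maf, rng_panel)
    if scenario.covariate == "two_cluster":
        half = n // 2
        covariate = np.repeat([-1.0, 1.0], [half, n - half])
        covariate += 0.25 * rng_panel.standard_normal(n)
    else:
        covariate = rng_panel.standard_normal(n)

    snp_labels = [f"snp{k + 1}" for k in range(m)]
    if scenario.adjustment == "principal_coordinates":
        design = compute_principal_coordinates(genotypes, scenario.n_axes).matrix
        snp_corr = partial_genotype_correlation(
            genotypes,
            CovariateDesign(design, kind=CovariateKind.STRATIFICATION),
            snp_labels,
        )
        adjust = design
    elif scenario.adjustment == "none":
        snp_corr = pearson_genotype_correlation(genotypes, snp_labels)
        adjust = None
    else:
        # The SNP correlation entering the test is the partial correlation
        # given the regression covariates; residualizing on the same design
        # used for the Wald statistics matches the exact conditional
        # covariance of the Z-scores for this fixed panel and covariate.
        adjust = covariate
        snp_corr = partial_genotype_correlation(
            genotypes,
            CovariateDesign(
                np.column_stack([np.ones(n), covariate]),
                kind=CovariateKind.STRATIFICATION,
            ),
            snp_labels,
        )
    snp_corr = snp_corr.regularize()

    # Trait correlation from null-SNP Z-scores, as a real analysis would
    # estimate it genome-wide.  Pooled over independent phenotype
    # replicates (see ScenarioConfig.n_null_snps) and generated in blocks
    # so memory stays flat at large SNP counts.
    null_z_rows = []
    for _ in range(max(1, scenario.n_null_reps)):
        y0 = simulate_phenotypes(genotypes, scenario, covariate, rng_nullsnp)
        remaining = scenario.n_null_snps
        while remaining > 0:
            block = min(4000, remaining)
            null_geno = generate_genotypes(
                n, block, None, rng_nullsnp.uniform(0.05, 0.5, size=block), rng_nullsnp
            )
            null_z_rows.append(compute_wald_z(y0, null_geno, adjust).values.T)
            remaining -= block
    null_z = np.vstack(null_z_rows)
    trait_corr = estimate_trait_correlation(
        NullZTable(
            [f"null{i + 1}" for i in range(null_z.shape[0])],
            [f"trait{j + 1}" for j in range(q)],
            null_z,
        )
    ).regularize()

    calibration = calibrate(
        snp_corr,
        trait_corr,
        grid=scenario.grid,
        bootstrap_size=scenario.bootstrap_size,
        seed=calib_seed,
    )

    q_mat, p_cols = _design_qr(adjust, n)
    h = genotypes - q_mat @ (q_mat.T @ genotypes)
    hss = np.einsum("nk,nk->k", h, h)
    df = n - p_cols - 1
    base = genotypes @ scenario.coefficient_matrix().T
    base = base + np.outer(covariate, np.full(q, scenario.gamma))
    chol_rho = np.linalg.cholesky(scenario.resolve_trait_corr())

    alphas = np.asarray(scenario.alphas, dtype=float)
    components = ("TWT", "P1", "P2", "P3")
    counts = {c: np.zeros(alphas.size, dtype=int) for c in components}
    done = 0
    while done < scenario.n_reps:
        size = min(scenario.chunk, scenario.n_reps - done)
        eps = rng_reps.standard_normal((size, n, q)) @ chol_rho.T
        z_chunk = _wald_z_chunk(eps, base, q_mat, h, hss, df)
        res = twt_pvalues_batch(
            z_chunk, snp_corr, trait_corr, scenario.grid, calibration
        )
        for comp, key in zip(components, ("pvalue", "P1", "P2", "P3")):
            counts[comp] += (res[key][:, None] < alphas[None, :]).sum(axis=0)
        done += size
        if progress:
            print(f"  replications: {done}/{scenario.n_reps}", flush=True)

    rows = []
    for comp in components:
        for i, alpha in enumerate(alphas):
            k = int(counts[comp][i])
            rate = k / scenario.n_reps
            se = float(np.sqrt(rate * (1 - rate) / scenario.n_reps))
            rows.append(
                {
                    "alpha": alpha,
                    "component": comp,
                    "rejections": k,
                    "reps": scenario.n_reps,
                    "rate": rate,
                    "se": se,
                }
            )
    return pd.DataFrame(rows)
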