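"""The Three-Way Test: component statistics and the combined p-value.

Given a q x m matrix Z of per-trait per-SNP Wald statistics whose
vectorization is null-distributed as N(0, Delta_theta (x) Delta_rho), three
complementary statistics are formed:

1. per-trait row quadratic forms ``Z{j}' Delta_theta^{-1} Z{j} ~ chi2_m``
   (sensitive when several SNPs in LD act on one trait);
2. per-SNP column quadratic forms ``Z[k]' Delta_rho^{-1} Z[k] ~ chi2_q``
   (sensitive to pleiotropy — one SNP acting on several traits);
3. truncated quadratic forms over the largest-magnitude Z entries at a
   grid of truncation levels (sensitive to sparse or irregular signal
   patterns missed by whole rows or columns).

Each family of p-values is collapsed with the Cauchy combination transform
``p -> tan((0.5 - p) * pi)``, whose weighted sums remain standard-Cauchy in
the tail under arbitrary dependence, and the three resulting p-values
P1, P2, P3 are combined the same way into the final test p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import chi2

from ._quadforms import (
    kept_count,
    truncated_statistic,
    truncated_statistics_batch,
)
from .corr import SnpCorrMatrix, TraitCorrMatrix

__all__ = [
    "P_FLOOR",
    "ZMatrix",
    "TruncationGrid",
    "CCTWeights",
    "TestResult",
    "cauchy_combine",
    "row_quadratic_pvalues",
    "col_quadratic_pvalues",
    "truncated_statistic",
    "compute_P1",
    "compute_P2",
    "compute_P3",
    "twt_test",
]

#: Numerical floor applied to every p-value before a tangent transform; the
#: arctan/tan round trip cannot represent smaller probabilities in double
#: precision.
P_FLOOR = 1e-14

#: Ceiling applied before a tangent transform.  A component p-value of
#: exactly 1 (e.g. a row of all-zero Z-scores) would otherwise map to a
#: tangent of order -1e14 and veto strong evidence carried by the other
#: components; capping at 1 - 1e-6 bounds that drag while leaving the null
#: tail calibration untouched (a null p-value exceeds the cap with
#: probability 1e-6).
P_CEIL = 1.0 - 1e-6


@dataclass
class ZMatrix:
    """Labelled q x m matrix of summary Wald statistics.

    Vectorization is column-wise (SNP-major): ``vec(Z)`` stacks the columns,
    so its null covariance is ``Delta_theta (x) Delta_rho`` with the SNP
    correlation in the outer (block) position.
    """

    traits: list[str]
    snps: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.traits = list(self.traits)
        self.snps = list(self.snps)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.traits), len(self.snps)):
            raise ValueError(
                f"Z shape {self.values.shape} does not match "
                f"{len(self.traits)} traits x {len(self.snps)} SNPs"
            )
        if min(self.values.shape) < 1:
            raise ValueError("Z matrix must have at least one trait and one SNP")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Z matrix contains non-finite entries")

    @property
    def q(self) -> int:
        return len(self.traits)

    @property
    def m(self) -> int:
        return len(self.snps)

    @property
    def M(self) -> int:
        return self.q * self.m

    def vec(self) -> np.ndarray:
        """Column-stacked vectorization (Z11, Z21, ..., Zq1, Z12, ...)."""
        return self.values.ravel(order="F")


@dataclass(frozen=True)
class TruncationGrid:
    """Grid of truncation levels eta; level 1 (the full statistic) is required
    because its null law is exactly chi-square and needs no calibration."""

    etas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

    def __post_init__(self) -> None:
        if not self.etas:
            raise ValueError("truncation grid is empty")
        if any(not 0.0 < e <= 1.0 for e in self.etas):
            raise ValueError("all truncation levels must lie in (0, 1]")
        if not np.isclose(max(self.etas), 1.0):
            raise ValueError("the grid must contain eta = 1")
        object.__setattr__(self, "etas", tuple(sorted(self.etas)))

    def kept_counts(self, m_total: int) -> np.ndarray:
        return np.asarray([kept_count(e, m_total) for e in self.etas], dtype=int)

    def __len__(self) -> int:
        return len(self.etas)


@dataclass
class CCTWeights:
    """Non-negative Cauchy-combination weights summing to one."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @classmethod
    def uniform(cls, n: int) -> "CCTWeights":
        return cls(np.full(n, 1.0 / n))


@dataclass
class TestResult:
    """Component and combined p-values of one Three-Way Test invocation."""

    trait_pvalues: np.ndarray
    snp_pvalues: np.ndarray
    eta_pvalues: dict[float, float]
    P1: float
    P2: float
    P3: float
    statistic: float
    pvalue: float

    def to_record(self, gene: str = "") -> dict:
        """Flat single-row summary (suitable for a per-gene TSV)."""
        return {
            "gene": gene,
            "q": len(self.trait_pvalues),
            "m": len(self.snp_pvalues),
            "P1": self.P1,
            "P2": self.P2,
            "P3": self.P3,
            "twt_pvalue": self.pvalue,
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "trait_pvalues": list(map(float, self.trait_pvalues)),
                "snp_pvalues": list(map(float, self.snp_pvalues)),
                "eta_pvalues": {str(k): float(v) for k, v in self.eta_pvalues.items()},
                "P1": self.P1,
                "P2": self.P2,
                "P3": self.P3,
                "statistic": self.statistic,
                "twt_pvalue": self.pvalue,
            }
        )


def _clip(p: np.ndarray | float, p_floor: float = P_FLOOR) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), p_floor, P_CEIL)


def cauchy_combine(
    pvals, weights: CCTWeights | None = None, p_floor: float = P_FLOOR
) -> float:
    """Combine dependent p-values with the Cauchy combination transform.

    Returns ``0.5 - arctan(sum_j w_j tan((0.5 - p_j) pi)) / pi``.  Inputs are
    clipped to ``[p_floor, P_CEIL]`` first; the transform is its own inverse
    for a single p-value away from the clip bounds.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("cannot combine an empty set of p-values")
    if weights is None:
        weights = CCTWeights.uniform(pvals.size)
    if weights.values.size != pvals.size:
        raise ValueError(
            f"{weights.values.size} weights for {pvals.size} p-values"
        )
    stat = float(weights.values @ np.tan((0.5 - _clip(pvals, p_floor)) * np.pi))
    return float(np.clip(0.5 - np.arctan(stat) / np.pi, p_floor, 1.0))


def row_quadratic_pvalues(z: ZMatrix, snp_corr: SnpCorrMatrix) -> np.ndarray:
    """Per-trait p-values of ``Z{j}' Delta_theta^{-1} Z{j}`` against chi2_m."""
    if snp_corr.dim != z.m:
        raise ValueError("SNP correlation dimension does not match Z")
    c, low = linalg.cho_factor(snp_corr.values, lower=True)
    solved = linalg.cho_solve((c, low), z.values.T)
    stats = np.einsum("jm,mj->j", z.values, solved)
    return chi2.sf(stats, df=z.m)


def col_quadratic_pvalues(z: ZMatrix, trait_corr: TraitCorrMatrix) -> np.ndarray:
    """Per-SNP p-values of ``Z[k]' Delta_rho^{-1} Z[k]`` against chi2_q."""
    if trait_corr.dim != z.q:
        raise ValueError("trait correlation dimension does not match Z")
    c, low = linalg.cho_factor(trait_corr.values, lower=True)
    solved = linalg.cho_solve((c, low), z.values)
    stats = np.einsum("jk,jk->k", z.values, solved)
    return chi2.sf(stats, df=z.q)


def compute_P1(
    z: ZMatrix, snp_corr: SnpCorrMatrix, weights: CCTWeights | None = None
) -> float:
    """Cauchy combination of the per-trait row quadratic-form p-values."""
    return cauchy_combine(row_quadratic_pvalues(z, snp_corr), weights)


def compute_P2(
    z: ZMatrix, trait_corr: TraitCorrMatrix, weights: CCTWeights | None = None
) -> float:
    """Cauchy combination of the per-SNP column quadratic-form p-values."""
    return cauchy_combine(col_quadratic_pvalues(z, trait_corr), weights)


def eta_pvalues(
    z_vec: np.ndarray,
    delta: np.ndarray,
    grid: TruncationGrid,
    calibration,
) -> dict[float, float]:
    """p-values of the truncated statistics at every grid level.

    The full statistic (eta = 1) is referred to its exact chi2_M null law;
    every other level uses the generalized chi-square surrogate fitted by the
    parametric-bootstrap ``calibration`` (any object with a
    ``survival(eta, x)`` method, normally a
    :class:`~twt.calibration.CalibrationTable`).
    """
    z_vec = np.asarray(z_vec, dtype=float).ravel()
    m_total = z_vec.size
    counts = grid.kept_counts(m_total)
    stats = truncated_statistics_batch(z_vec[None, :], delta, counts)[0]
    out: dict[float, float] = {}
    for eta, count, stat in zip(grid.etas, counts, stats):
        if np.isclose(eta, 1.0):
            out[eta] = float(chi2.sf(stat, df=m_total))
        else:
            out[eta] = float(calibration.survival(eta, stat))
    return out


def compute_P3(
    z: ZMatrix,
    snp_corr: SnpCorrMatrix,
    trait_corr: TraitCorrMatrix,
    grid: TruncationGrid,
    calibration,
) -> float:
    """Cauchy combination of the truncated-statistic p-values over the grid."""
    delta = np.kron(snp_corr.values, trait_corr.values)
    pvals = eta_pvalues(z.vec(), delta, grid, calibration)
    return cauchy_combine(np.asarray([pvals[e] for e in grid.etas]))


@dataclass
class TWTConfig:
    """Knobs of one test invocation: truncation grid, bootstrap size used when
    no pre-computed calibration is supplied, RNG seed, and the p-value floor."""

    grid: TruncationGrid = field(default_factory=TruncationGrid)
    bootstrap_size: int = 100_000
    seed: int = 0
    p_floor: float = P_FLOOR
    eps_pd: float = 1e-6


def twt_test(
    z: ZMatrix,
    snp_corr: SnpCorrMatrix,
    trait_corr: TraitCorrMatrix,
    config: TWTConfig | None = None,
    calibration=None,
) -> TestResult:
    """Run the full Three-Way Test on one Z matrix.

    The correlation factors are regularized to positive definiteness, the
    three component p-values are computed, and the final p-value is their
    uniform-weight Cauchy combination.  A pre-computed calibration table may
    be passed to amortize the parametric bootstrap across genes or
    replications sharing the same covariance; otherwise one is fitted here.
    """
    config = config or TWTConfig()
    if snp_corr.dim != z.m or trait_corr.dim != z.q:
        raise ValueError("correlation matrix dimensions do not match Z")
    snp_corr = snp_corr.regularize(config.eps_pd)
    trait_corr = trait_corr.regularize(config.eps_pd)
    if calibration is None:
        from .calibration import calibrate  # deferred: calibration imports _quadforms only

        calibration = calibrate(
            snp_corr,
            trait_corr,
            grid=config.grid,
            bootstrap_size=config.bootstrap_size,
            seed=config.seed,
        )
    p_floor = config.p_floor
    trait_p = np.clip(row_quadratic_pvalues(z, snp_corr), p_floor, 1.0)
    snp_p = np.clip(col_quadratic_pvalues(z, trait_corr), p_floor, 1.0)
    delta = np.kron(snp_corr.values, trait_corr.values)
    etas_p = eta_pvalues(z.vec(), delta, config.grid, calibration)
    etas_p = {e: float(np.clip(p, p_floor, 1.0)) for e, p in etas_p.items()}
    p1 = cauchy_combine(trait_p, p_floor=p_floor)
    p2 = cauchy_combine(snp_p, p_floor=p_floor)
    p3 = cauchy_combine(
        np.asarray([etas_p[e] for e in config.grid.etas]), p_floor=p_floor
    )
    stat = float(np.mean(np.tan((0.5 - _clip([p1, p2, p3], p_floor)) * np.pi)))
    pvalue = float(np.clip(0.5 - np.arctan(stat) / np.pi, p_floor, 1.0))
    return TestResult(
        trait_pvalues=trait_p,
        snp_pvalues=snp_p,
        eta_pvalues=etas_p,
        P1=p1,
        P2=p2,
        P3=p3,
        statistic=stat,
        pvalue=pvalue,
    )


def twt_pvalues_batch(
    z_batch: np.ndarray,
    snp_corr: SnpCorrMatrix,
    trait_corr: TraitCorrMatrix,
    grid: TruncationGrid,
    calibration,
    p_floor: float = P_FLOOR,
) -> dict[str, np.ndarray]:
    """Vectorized Three-Way Test over a stack of Z matrices.

    ``z_batch`` has shape ``(n, q, m)``.  Returns arrays of P1, P2, P3 and
    the final p-value, one entry per stacked matrix.  Used by the simulation
    engine, where the same (regularized) covariance and calibration are
    shared across very many replications; agrees with :func:`twt_test`
    applied row by row.
    """
    z_batch = np.asarray(z_batch, dtype=float)
    n, q, m = z_batch.shape
    theta_inv = np.linalg.inv(snp_corr.values)
    rho_inv = np.linalg.inv(trait_corr.values)
    row_stats = np.einsum("rjm,mn,rjn->rj", z_batch, theta_inv, z_batch)
    col_stats = np.einsum("rjk,ji,rik->rk", z_batch, rho_inv, z_batch)
    trait_p = np.clip(chi2.sf(row_stats, df=m), p_floor, P_CEIL)
    snp_p = np.clip(chi2.sf(col_stats, df=q), p_floor, P_CEIL)
    p1 = 0.5 - np.arctan(np.tan((0.5 - trait_p) * np.pi).mean(axis=1)) / np.pi
    p2 = 0.5 - np.arctan(np.tan((0.5 - snp_p) * np.pi).mean(axis=1)) / np.pi

    delta = np.kron(snp_corr.values, trait_corr.values)
    # vec(Z) per replication: column-stacked, i.e. (Z11, Z21, ..., Zq1, Z12, ...)
    vec = np.swapaxes(z_batch, 1, 2).reshape(n, q * m)
    counts = grid.kept_counts(q * m)
    stats = truncated_statistics_batch(vec, delta, counts)
    eta_p = np.empty_like(stats)
    for i, eta in enumerate(grid.etas):
        if np.isclose(eta, 1.0):
            eta_p[:, i] = chi2.sf(stats[:, i], df=q * m)
        else:
            eta_p[:, i] = calibration.survival(eta, stats[:, i])
    eta_p = np.clip(eta_p, p_floor, P_CEIL)
    p3 = 0.5 - np.arctan(np.tan((0.5 - eta_p) * np.pi).mean(axis=1)) / np.pi

    comps = np.clip(np.stack([p1, p2, p3], axis=1), p_floor, P_CEIL)
    t0 = np.tan((0.5 - comps) * np.pi).mean(axis=1)
    pvalue = np.clip(0.5 - np.arctan(t0) / np.pi, p_floor, 1.0)
    return {
        "P1": np.clip(p1, p_floor, 1.0),
        "P2": np.clip(p2, p_floor, 1.0),
        "P3": np.clip(p3, p_floor, 1.0),
        "pvalue": pvalue,
    }
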