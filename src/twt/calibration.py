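"""Parametric-bootstrap calibration of the truncated statistics.

A truncated quadratic form (only the largest-magnitude coordinates enter)
has no classical null distribution, so its null law is approximated by a
three-parameter generalized chi-square surrogate ``a * chi2_d + b``:

1. draw B vectors from N(0, Delta_theta (x) Delta_rho);
2. compute the truncated statistic of each draw at every truncation level
   below one (the full statistic is exactly chi2_M and needs no surrogate);
3. estimate the first three cumulants of each level's sample — mean K,
   variance L, third central moment Mu — and match them:

       a = Mu / (4 L),   b = K - 2 L^2 / Mu,   d = 8 L^3 / Mu^2.

The surrogate's survival function then prices observed statistics,
including tail probabilities far smaller than 1/B, which a raw empirical
bootstrap could never resolve.  Matching requires a right-skewed sample
(Mu > 0); quadratic-form mixtures always are in practice, and a violation
raises rather than silently mis-calibrating.

A fitted :class:`CalibrationTable` depends only on the covariance factors,
so it is computed once per (Delta_theta, Delta_rho) pair and reused across
genes or simulation replications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from ._quadforms import truncated_statistics_batch
from .corr import SnpCorrMatrix, TraitCorrMatrix
from .stats import TruncationGrid

__all__ = [
    "GenChi2Params",
    "CumulantEstimates",
    "CalibrationTable",
    "estimate_cumulants",
    "match_cumulants",
    "genchi2_survival",
    "sample_null_truncated",
    "calibrate",
]

#: Smallest bootstrap size accepted; below this the cumulant estimates are
#: too noisy for tail work.
MIN_BOOTSTRAP = 1000


@dataclass(frozen=True)
class GenChi2Params:
    """Parameters of the surrogate ``a * chi2_d + b``."""

    a: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.d > 0):
            raise ValueError(f"need a > 0 and d > 0, got a={self.a}, d={self.d}")


@dataclass(frozen=True)
class CumulantEstimates:
    """Sample mean, variance and third central moment of a bootstrap sample."""

    kappa1: float
    mu2: float
    mu3: float


def estimate_cumulants(samples: np.ndarray) -> CumulantEstimates:
    samples = np.asarray(samples, dtype=float)
    kappa1 = float(samples.mean())
    centered = samples - kappa1
    return CumulantEstimates(
        kappa1=kappa1,
        mu2=float(np.mean(centered**2)),
        mu3=float(np.mean(centered**3)),
    )


def match_cumulants(samples) -> GenChi2Params:
    """Fit ``a * chi2_d + b`` to a sample by three-cumulant matching.

    Accepts either a raw sample array or pre-computed
    :class:`CumulantEstimates`.  The matching equations invert exactly: a
    sample whose moments equal those of ``a * chi2_d + b`` (mean ad + b,
    variance 2 a^2 d, third central moment 8 a^3 d) recovers (a, b, d).
    """
    cum = samples if isinstance(samples, CumulantEstimates) else estimate_cumulants(samples)
    if cum.mu2 <= 0:
        raise ValueError("sample variance is zero; cannot match cumulants")
    if cum.mu3 <= 0:
        raise ValueError(
            "left-skewed or symmetric sample; generalized chi-square matching "
            "is invalid (third central moment must be positive)"
        )
    a = cum.mu3 / (4.0 * cum.mu2)
    b = cum.kappa1 - 2.0 * cum.mu2**2 / cum.mu3
    d = 8.0 * cum.mu2**3 / cum.mu3**2
    return GenChi2Params(a=a, b=b, d=d)


def genchi2_survival(x, params: GenChi2Params):
    """Upper-tail probability ``P(a chi2_d + b > x)``; 1 wherever x <= b."""
    x = np.asarray(x, dtype=float)
    arg = np.maximum((x - params.b) / params.a, 0.0)
    out = chi2.sf(arg, df=params.d)
    return float(out) if out.ndim == 0 else out


def sample_null_truncated(
    snp_corr: SnpCorrMatrix,
    trait_corr: TraitCorrMatrix,
    grid: TruncationGrid,
    bootstrap_size: int,
    seed: int,
    chunk: int = 2000,
) -> dict[float, np.ndarray]:
    """Bootstrap samples of the truncated statistic at every grid level.

    Draws ``bootstrap_size`` vectors from N(0, Delta_theta (x) Delta_rho)
    (chunked, so memory stays flat) and returns one sample array per
    truncation level, including eta = 1, whose chi2_M behaviour is a useful
    self-check.  Fully reproducible from ``seed``.
    """
    if bootstrap_size < MIN_BOOTSTRAP:
        raise ValueError(
            f"bootstrap size {bootstrap_size} below minimum {MIN_BOOTSTRAP}"
        )
    delta = np.kron(snp_corr.values, trait_corr.values)
    m_total = delta.shape[0]
    try:
        chol = np.linalg.cholesky(delta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "null covariance is not positive definite; regularize the "
            "correlation matrices first"
        ) from exc
    counts = grid.kept_counts(m_total)
    rng = np.random.default_rng(seed)
    out = np.empty((bootstrap_size, len(counts)))
    done = 0
    while done < bootstrap_size:
        size = min(chunk, bootstrap_size - done)
        draws = rng.standard_normal((size, m_total)) @ chol.T
        out[done : done + size] = truncated_statistics_batch(draws, delta, counts)
        done += size
    return {eta: out[:, i] for i, eta in enumerate(grid.etas)}


@dataclass
class CalibrationTable:
    """Fitted surrogate parameters for every truncation level below one."""

    params: dict[float, GenChi2Params]
    bootstrap_size: int
    seed: int
    grid: TruncationGrid = field(default_factory=TruncationGrid)

    def survival(self, eta: float, x):
        """Surrogate upper-tail probability for level ``eta`` (eta < 1)."""
        key = self._key(eta)
        return genchi2_survival(x, self.params[key])

    def _key(self, eta: float) -> float:
        for key in self.params:
            if np.isclose(key, eta):
                return key
        raise KeyError(f"no calibration entry for truncation level eta={eta}")

    def to_json(self, path) -> None:
        payload = {
            "bootstrap_size": self.bootstrap_size,
            "seed": self.seed,
            "grid": list(self.grid.etas),
            "params": {
                f"{eta:g}": {"a": p.a, "b": p.b, "d": p.d}
                for eta, p in self.params.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            payload = json.load(fh)
        params = {
            float(eta): GenChi2Params(**vals)
            for eta, vals in payload["params"].items()
        }
        return cls(
            params=params,
            bootstrap_size=int(payload["bootstrap_size"]),
            seed=int(payload["seed"]),
            grid=TruncationGrid(tuple(payload["grid"])),
        )


def calibrate(
    snp_corr: SnpCorrMatrix,
    trait_corr: TraitCorrMatrix,
    grid: TruncationGrid | None = None,
    bootstrap_size: int = 100_000,
    seed: int = 0,
) -> CalibrationTable:
    """Run the parametric bootstrap and fit every sub-unity truncation level."""
    grid = grid or TruncationGrid()
    samples = sample_null_truncated(snp_corr, trait_corr, grid, bootstrap_size, seed)
    params: dict[float, GenChi2Params] = {}
    for eta in grid.etas:
        if np.isclose(eta, 1.0):
            continue
        params[eta] = match_cumulants(samples[eta])
    return CalibrationTable(
        params=params, bootstrap_size=bootstrap_size, seed=seed, grid=grid
    )
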