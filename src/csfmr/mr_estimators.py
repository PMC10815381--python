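"""Two-sample MR estimators on harmonized summary statistics.

Given harmonized per-variant effects (beta_exp, se_exp) and (beta_out,
se_out), the causal effect theta of the exposure on the outcome is
estimated by:

* the Wald ratio ``beta_out / beta_exp`` for a single instrument, with the
  first-order delta-method SE ``se_out / |beta_exp|`` — the dominant
  convention for strong instruments;
* random-effects inverse-variance weighting (IVW) of the per-variant
  ratios for multiple instruments, with Cochran's Q, I^2, and a
  multiplicative over-dispersion factor floored at 1;
* the weighted median, robust when more than half the weight comes from
  valid instruments, with a parametric-bootstrap SE.

Benjamini-Hochberg FDR control across a protein panel rounds out the
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gwas_io import Z_95
from .harmonize import HarmonizedPair

__all__ = [
    "MREstimate",
    "FDRResult",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "bh_fdr",
]


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and heterogeneity."""

    theta: float
    se: float
    pvalue: float
    method: str
    nsnp: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    Q: float | None = None
    I2: float | None = None
    protein_id: str = ""
    outcome_id: str = ""

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.theta - Z_95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.theta + Z_95 * self.se


def _two_sided_normal_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))


def _ratios(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    bx = np.array([p.beta_exp for p in pairs])
    if np.any(bx == 0):
        raise ZeroDivisionError("undefined Wald ratio: beta_exp = 0")
    by = np.array([p.beta_out for p in pairs])
    so = np.array([p.se_out for p in pairs])
    return by / bx, so / np.abs(bx)


def wald_ratio(pair: HarmonizedPair, **ids) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta SE."""
    (theta,), (se,) = _ratios([pair])
    p = 1.0 if pair.beta_out == 0 else _two_sided_normal_p(theta / se)
    return MREstimate(theta=float(theta), se=float(se), pvalue=p,
                      method="wald", nsnp=1, **ids)


def ivw(pairs: Sequence[HarmonizedPair], **ids) -> MREstimate:
    """Random-effects (multiplicative) inverse-variance-weighted estimate.

    theta = sum(w_j theta_j)/sum(w_j) with w_j = 1/se_j^2;
    Q = sum w_j (theta_j - theta)^2; I^2 = max(0, (Q - (k-1))/Q) * 100;
    the fixed-effect SE is inflated by max(1, sqrt(Q/(k-1))).
    """
    k = len(pairs)
    if k < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    theta_j, se_j = _ratios(pairs)
    w = 1.0 / se_j**2
    theta = float(w @ theta_j / w.sum())
    se_fixed = float(w.sum() ** -0.5)
    Q = float(w @ (theta_j - theta) ** 2)
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if Q > 0 else 0.0
    inflation = max(1.0, np.sqrt(Q / (k - 1)))
    se = se_fixed * inflation
    return MREstimate(theta=theta, se=se, pvalue=_two_sided_normal_p(theta / se),
                      method="ivw_re", nsnp=k, Q=Q, I2=I2, **ids)


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    """Weight-interpolated median of the ordered ratio estimates."""
    order = np.argsort(theta_j)
    t, w = theta_j[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, t))


def weighted_median(pairs: Sequence[HarmonizedPair], n_boot: int = 5000,
                    seed: int = 0, **ids) -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap SE.

    Ratio estimates are ordered by magnitude and weighted by their
    precision (inverse first-order variance); the estimate is the linear
    interpolation of the ordered values at cumulative standardized weight
    0.5.  The SE is the standard deviation of the estimator over ``n_boot``
    draws of (beta_exp, beta_out) from their reported sampling
    distributions.
    """
    k = len(pairs)
    if k < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    theta_j, se_j = _ratios(pairs)
    theta = _weighted_median_point(theta_j, 1.0 / se_j**2)

    rng = np.random.default_rng(seed)
    bx = np.array([p.beta_exp for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    so = np.array([p.se_out for p in pairs])
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, so, size=(n_boot, k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    ratios_b = by_b / bx_b
    se_b = so / np.abs(bx_b)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median_point(ratios_b[i], 1.0 / se_b[i] ** 2)
    se = float(boots.std(ddof=1))
    return MREstimate(theta=theta, se=se, pvalue=_two_sided_normal_p(theta / se),
                      method="weighted_median", nsnp=k, **ids)


@dataclass
class FDRResult:
    """Benjamini-Hochberg step-up result at level alpha."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg FDR control across one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return FDRResult(pvalues=p, qvalues=p.copy(),
                         significant=np.zeros(0, dtype=bool), alpha=alpha)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvalues, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return FDRResult(pvalues=p, qvalues=qvalues, significant=reject, alpha=alpha)
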