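"""Phenome-wide scan of one variant against many binary diagnoses.

Each eligible phenotype (at least ``min_cases`` cases) is fitted with a
covariate-adjusted logistic regression of case status on allele dosage;
the per-allele odds ratio, Wald CI and p-value are collected and the
Benjamini-Hochberg procedure is applied across the fitted family.
Non-converged or separated fits are excluded from the FDR family with a
recorded reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gwas_io import Z_95
from .mr_estimators import bh_fdr

__all__ = ["PhewasConfig", "PhewasRow", "logistic_assoc", "run_phewas"]

#: coefficient magnitude beyond which a logistic fit is treated as separated
SEPARATION_BOUND = 15.0
MAX_ITER = 100


@dataclass(frozen=True)
class PhewasConfig:
    min_cases: int = 200
    alpha_fdr: float = 0.05
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


@dataclass
class PhewasRow:
    phenotype_id: str
    n_cases: int
    n_controls: int
    converged: bool
    log_or: float = np.nan
    se: float = np.nan
    pvalue: float = np.nan
    qvalue: float = np.nan
    significant: bool = False
    reason: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_or - Z_95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_or + Z_95 * self.se))


def logistic_assoc(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float, bool]:
    """ML logistic fit of case status on additive dosage plus covariates.

    Returns (log-OR, se, p, converged) for the dosage coefficient.
    Separation (|log-OR| > 15) and IRLS non-convergence within 100
    iterations are flagged as converged=False.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=int)
    if status.min() == status.max():
        raise ValueError("status needs at least one case and one control")
    if dosage.min() == dosage.max():
        return np.nan, np.nan, np.nan, False  # constant dosage: non-estimable
    X = dosage[:, None]
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    X = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(status, X).fit(disp=0, maxiter=MAX_ITER, warn_convergence=False)
    except Exception:
        return np.nan, np.nan, np.nan, False
    log_or = float(fit.params[1])
    se = float(fit.bse[1])
    converged = bool(fit.mle_retvals.get("converged", False))
    if not np.isfinite(log_or) or not np.isfinite(se) or abs(log_or) > SEPARATION_BOUND:
        converged = False
    p = float(np.clip(fit.pvalues[1], np.finfo(float).tiny, 1.0))
    return log_or, se, p, converged


def run_phewas(
    dosage: np.ndarray,
    phenotypes: pd.DataFrame,
    covariates: np.ndarray | None,
    cfg: PhewasConfig = PhewasConfig(),
) -> list[PhewasRow]:
    """Scan one variant across a binary phenotype matrix.

    Phenotype columns with fewer than ``min_cases`` cases are skipped;
    remaining fits enter one BH-FDR family; rows are returned sorted by p
    (fitted rows first).  Accounting invariant: skipped + failed + fitted
    equals the number of phenotype columns.
    """
    dosage = np.asarray(dosage, dtype=float)
    n = len(dosage)
    if len(phenotypes) != n:
        raise ValueError("phenotype rows must align with dosage")
    rows: list[PhewasRow] = []
    for pheno_id in phenotypes.columns:
        status = phenotypes[pheno_id].to_numpy(dtype=float)
        mask = np.isfinite(status)
        n_cases = int(np.nansum(status == 1))
        n_controls = int(np.nansum(status == 0))
        row = PhewasRow(phenotype_id=str(pheno_id), n_cases=n_cases,
                        n_controls=n_controls, converged=False)
        if n_cases < cfg.min_cases:
            row.reason = "below_min_cases"
        elif n_controls < 1:
            row.reason = "no_controls"
        else:
            cov = covariates[mask] if covariates is not None else None
            log_or, se, p, ok = logistic_assoc(dosage[mask],
                                               status[mask].astype(int), cov)
            if ok:
                row.log_or, row.se, row.pvalue, row.converged = log_or, se, p, True
            else:
                row.reason = "not_converged_or_separated"
        rows.append(row)

    fitted = [r for r in rows if r.converged]
    if fitted:
        fdr = bh_fdr([r.pvalue for r in fitted], alpha=cfg.alpha_fdr)
        for r, q, sig in zip(fitted, fdr.qvalues, fdr.significant):
            r.qvalue, r.significant = float(q), bool(sig)
    else:
        warnings.warn("no eligible phenotype was fitted", stacklevel=2)
    rows.sort(key=lambda r: (not r.converged, r.pvalue if r.converged else np.inf,
                             r.phenotype_id))
    return rows


def phewas_frame(rows: list[PhewasRow]) -> pd.DataFrame:
    """Tabular form of a PheWAS scan."""
    return pd.DataFrame([
        {"phenotype_id": r.phenotype_id, "n_cases": r.n_cases,
         "n_controls": r.n_controls, "converged": r.converged,
         "odds_ratio": r.odds_ratio if r.converged else np.nan,
         "ci_low": r.ci_low if r.converged else np.nan,
         "ci_high": r.ci_high if r.converged else np.nan,
         "pvalue": r.pvalue, "qvalue": r.qvalue,
         "significant": r.significant, "reason": r.reason}
        for r in rows
    ])
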