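"""Synthetic two-sample GWAS generator with known causal architecture.

The generator emulates the data a cis-MR screen consumes: LD-structured
genotypes in a cis region, a protein trait driven by one or more cis
variants, an outcome trait with a specified causal effect of the protein,
and the per-SNP marginal summary statistics of both traits computed in two
non-overlapping samples.

The LD model is a one-parameter AR(1) Gaussian copula over haplotypes:
latent standard normals with corr(z_j, z_{j+1}) = ld_rho are thresholded at
the quantile matching each variant's minor-allele frequency, and two
independent haplotypes are summed into a dosage.  Adjacent variants then
have latent-scale correlation ld_rho and dosage correlation equal to the
corresponding tetrachoric-attenuated value; distant variants decay as
rho^|i-j|.  This is deliberately minimal: clumping and colocalization only
need realistic pairwise r.

Scenarios
---------
shared
    Outcome genetic signal flows only through the exposure: Y = theta*X + e.
distinct
    The outcome has its own direct causal variant in LD with (but different
    from) the exposure's causal variant; theta is ignored.  This induces the
    genetic-confounding violation that colocalization is meant to catch.
null_protein_effect
    The protein has its cis effect but theta = 0.
null_assoc
    The outcome is independent of all genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gwas_io import (
    GeneRegion,
    LDMatrix,
    LoadReport,
    SummaryStats,
    SUMSTATS_COLUMNS,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "GenotypeTable",
    "StudyData",
    "PanelData",
    "simulate_genotypes",
    "simulate_traits",
    "compute_sumstats",
    "sample_ld",
    "simulate_case_control",
    "simulate_study",
    "simulate_panel",
]

SCENARIOS = ("shared", "distinct", "null_protein_effect", "null_assoc")


class DegeneratePhenotypeError(RuntimeError):
    """A binary phenotype draw produced no cases or no controls."""


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cis region.

    Defaults follow the study being emulated: the protein GWAS sample is 835
    individuals, the effect unit is SD of outcome per 1 log-RFU of protein,
    and the demonstration effect size is 0.23.
    """

    scenario: str = "shared"
    n_exposure: int = 835
    n_outcome: int = 10_000
    m_variants: int = 40
    maf: float | np.ndarray = 0.3
    ld_rho: float = 0.5
    theta: float = 0.23
    var_explained_cis: float = 0.1
    exposure_causal_indices: tuple[int, ...] | None = None
    outcome_causal_idx: int | None = None
    var_explained_outcome: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 < self.var_explained_cis < 1.0:
            raise ValueError("var_explained_cis must be in (0, 1)")
        maf = np.broadcast_to(np.asarray(self.maf, dtype=float), (self.m_variants,))
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf entries must be in (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.exposure_causal_indices is None:
            self.exposure_causal_indices = (self.m_variants // 2,)
        self.exposure_causal_indices = tuple(int(i) for i in self.exposure_causal_indices)
        if self.scenario == "distinct":
            if self.m_variants < 2:
                raise ValueError("scenario=distinct needs m_variants >= 2")
            if self.outcome_causal_idx is None:
                c = self.exposure_causal_indices[0]
                self.outcome_causal_idx = c + 12 if c + 12 < self.m_variants else c - 12
            if self.outcome_causal_idx in self.exposure_causal_indices:
                raise ValueError(
                    "distinct scenario requires outcome_causal_idx different "
                    "from the exposure causal variant")

    @property
    def maf_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.maf, dtype=float),
                               (self.m_variants,)).copy()


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth against which downstream recovery is asserted."""

    theta_true: float
    exposure_causal_indices: tuple[int, ...]
    outcome_direct_causal_idx: int | None
    scenario: str


@dataclass
class GenotypeTable:
    """Dosage matrix {0,1,2} with its variant panel."""

    dosages: np.ndarray  # (n, m) int8
    panel: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, maf

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.panel["variant_id"])


def _ar1_haplotypes(rng: np.random.Generator, n_hap: int, maf: np.ndarray,
                    rho: float) -> np.ndarray:
    """Threshold an AR(1) latent Gaussian at the MAF quantile, per haplotype."""
    m = maf.shape[0]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
    thresholds = stats.norm.ppf(maf)
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(
    n: int,
    maf: float | Sequence[float] | np.ndarray,
    ld_rho: float,
    seed: int | np.random.Generator,
    *,
    m_variants: int | None = None,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 10_000,
    id_prefix: str = "var",
) -> GenotypeTable:
    """Draw n diploid dosages over an AR(1)-correlated variant panel.

    Two independent haplotypes per individual are generated by thresholding
    a zero-mean AR(1) Gaussian at the quantile matching each MAF, then
    summed.  The effect allele is the minor (thresholded) allele, coded
    additively.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maf = np.asarray(maf, dtype=float)
    if maf.ndim == 0:
        if m_variants is None:
            raise ValueError("scalar maf requires m_variants")
        maf = np.full(m_variants, float(maf))
    haps = _ar1_haplotypes(rng, 2 * n, maf, float(ld_rho))
    dosages = haps[0::2] + haps[1::2]
    m = maf.shape[0]
    panel = pd.DataFrame({
        "variant_id": [f"{id_prefix}{j:04d}" for j in range(m)],
        "chrom": chrom,
        "pos": pos_start + pos_step * np.arange(m),
        "effect_allele": "A",
        "other_allele": "G",
        "maf": maf,
    })
    return GenotypeTable(dosages=dosages, panel=panel)


def _scaled_genetic_component(g: GenotypeTable, indices: Sequence[int],
                              var_explained: float) -> np.ndarray:
    """Sum of causal dosages rescaled to the target variance share."""
    gc = g.dosages[:, list(indices)].astype(float).sum(axis=1)
    sd = gc.std()
    if sd == 0:
        raise ValueError("causal variant(s) monomorphic in this sample")
    return (gc - gc.mean()) / sd * np.sqrt(var_explained)


def simulate_traits(
    g: GenotypeTable,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, ScenarioTruth]:
    """Generate the exposure and outcome phenotypes on one genotype sample.

    The exposure X is standardized (unit variance) with the configured share
    of variance coming from the cis causal variant(s).  The outcome follows
    the scenario.  Two-sample designs should call :func:`simulate_study`,
    which draws non-overlapping samples and uses X from one and Y from the
    other.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = g.n
    x_gen = _scaled_genetic_component(g, cfg.exposure_causal_indices,
                                      cfg.var_explained_cis)
    x = x_gen + rng.standard_normal(n) * np.sqrt(1.0 - cfg.var_explained_cis)

    scenario = cfg.scenario
    theta = 0.0 if scenario in ("null_protein_effect", "null_assoc") else cfg.theta
    outcome_direct = None
    if scenario == "distinct":
        outcome_direct = int(cfg.outcome_causal_idx)
        y_gen = _scaled_genetic_component(g, [outcome_direct],
                                          cfg.var_explained_outcome)
        y = y_gen + rng.standard_normal(n) * np.sqrt(1.0 - cfg.var_explained_outcome)
        theta = 0.0
    elif scenario == "null_assoc":
        y = rng.standard_normal(n)
    else:  # shared / null_protein_effect
        noise_var = max(1.0 - theta * theta, 0.05)
        y = theta * x + rng.standard_normal(n) * np.sqrt(noise_var)

    truth = ScenarioTruth(
        theta_true=theta,
        exposure_causal_indices=cfg.exposure_causal_indices,
        outcome_direct_causal_idx=outcome_direct,
        scenario=scenario,
    )
    return x, y, truth


def compute_sumstats(g: GenotypeTable, y: np.ndarray, trait_id: str,
                     trait_type: str = "quantitative") -> SummaryStats:
    """Per-variant simple linear regression of y on dosage, vectorized.

    beta_j = cov(y, g_j)/var(g_j); the SE uses the residual variance with
    n - 2 degrees of freedom; p from the t distribution.  Monomorphic
    variants are emitted with beta 0 and infinite SE so that read-side
    validation drops them.
    """
    y = np.asarray(y, dtype=float)
    n = g.n
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match genotype rows")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    G = g.dosages.astype(float)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    poly = sxx > 0
    beta = np.zeros(g.m)
    np.divide(sxy, sxx, out=beta, where=poly)
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.full(g.m, np.inf)
    np.sqrt(sigma2 / sxx, out=se, where=poly)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)  # underflow guard
    pvals[~poly] = 1.0

    table = pd.DataFrame({
        "variant_id": g.panel["variant_id"],
        "chrom": g.panel["chrom"].astype(str),
        "pos": g.panel["pos"].astype("Int64"),
        "effect_allele": g.panel["effect_allele"],
        "other_allele": g.panel["other_allele"],
        "eaf": G.mean(axis=0) / 2.0,
        "beta": beta,
        "se": se,
        "pvalue": pvals,
        "n": float(n),
    })[SUMSTATS_COLUMNS]
    report = LoadReport(n_input=g.m, n_retained=g.m)
    return SummaryStats(trait_id=trait_id, table=table, trait_type=trait_type,
                        load_report=report)


def sample_ld(g: GenotypeTable) -> LDMatrix:
    """Sample dosage correlation matrix over the panel (signed r)."""
    G = g.dosages.astype(float)
    sd = G.std(axis=0)
    ok = sd > 0
    Gs = np.where(ok, (G - G.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
    r = Gs.T @ Gs / g.n
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return LDMatrix(g.variant_ids, r)


def simulate_case_control(
    g: GenotypeTable,
    variant_idx: int,
    log_or: float,
    covariates: np.ndarray | None,
    prevalence: float,
    seed: int | np.random.Generator,
    covariate_effects: np.ndarray | None = None,
) -> np.ndarray:
    """Draw case/control status from a logistic model on one variant.

    The intercept is solved numerically so the expected prevalence matches
    the requested value given the realized linear predictor.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = log_or * g.dosages[:, variant_idx].astype(float)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != g.n:
            covariates = covariates.T
        if covariate_effects is None:
            covariate_effects = np.full(covariates.shape[1], 0.1)
        eta = eta + covariates @ np.asarray(covariate_effects, dtype=float)

    def mean_risk(c: float) -> float:
        return float(special.expit(c + eta).mean()) - prevalence

    intercept = optimize.brentq(mean_risk, -40.0, 40.0)
    status = (rng.random(g.n) < special.expit(intercept + eta)).astype(int)
    if status.sum() in (0, g.n):
        raise DegeneratePhenotypeError(
            f"degenerate phenotype: {int(status.sum())} cases of {g.n}")
    return status


# ---------------------------------------------------------------------------
# study- and panel-level orchestration


@dataclass
class StudyData:
    """One region's two-sample study: marginal stats, LD, region, truth."""

    exposure: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix
    region: GeneRegion
    truth: ScenarioTruth
    exposure_genotypes: GenotypeTable | None = None
    outcome_genotypes: GenotypeTable | None = None


def _region_around(panel: pd.DataFrame, causal_idx: int, gene_id: str) -> GeneRegion:
    pos = int(panel["pos"].iloc[causal_idx])
    return GeneRegion(gene_id=gene_id, chrom=str(panel["chrom"].iloc[causal_idx]),
                      start=max(1, pos - 5_000), end=pos + 5_000)


def simulate_study(cfg: ScenarioConfig, *, gene_id: str = "GENE1",
                   chrom: str = "1", id_prefix: str = "var",
                   keep_genotypes: bool = False) -> StudyData:
    """Draw a full two-sample study for one cis region.

    Exposure and outcome samples are always independent, non-overlapping
    draws from the same LD model.  The LD matrix is the sample correlation
    in the (larger) outcome sample, standing in for an external reference
    panel.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_exp, rng_out = (np.random.default_rng(s) for s in ss.spawn(2))
    maf = cfg.maf_vector
    g_exp = simulate_genotypes(cfg.n_exposure, maf, cfg.ld_rho, rng_exp,
                               chrom=chrom, id_prefix=id_prefix)
    g_out = simulate_genotypes(cfg.n_outcome, maf, cfg.ld_rho, rng_out,
                               chrom=chrom, id_prefix=id_prefix)
    x_exp, _, truth = simulate_traits(g_exp, cfg, rng_exp)
    _, y_out, _ = simulate_traits(g_out, cfg, rng_out)
    exposure = compute_sumstats(g_exp, x_exp, trait_id=f"{gene_id}_csf")
    outcome = compute_sumstats(g_out, y_out, trait_id="outcome")
    region = _region_around(g_exp.panel, cfg.exposure_causal_indices[0], gene_id)
    return StudyData(
        exposure=exposure, outcome=outcome, ld=sample_ld(g_out),
        region=region, truth=truth,
        exposure_genotypes=g_exp if keep_genotypes else None,
        outcome_genotypes=g_out if keep_genotypes else None,
    )


@dataclass
class PanelData:
    """A multi-protein screen input with one shared outcome GWAS."""

    proteins: list[tuple[str, SummaryStats, GeneRegion, LDMatrix]]
    outcome: SummaryStats
    truths: dict[str, ScenarioTruth] = field(default_factory=dict)


def simulate_panel(
    thetas: Sequence[float],
    cfg: ScenarioConfig,
    seed: int,
) -> PanelData:
    """Simulate a protein panel sharing one outcome sample.

    Each protein gets its own unlinked cis region (one region per
    chromosome) and its own exposure sample; a single outcome sample of
    ``cfg.n_outcome`` individuals carries Y = sum_p theta_p * X_p + e, so the
    outcome GWAS is the concatenation of each region's marginal statistics
    against the same phenotype.  ``thetas[p]`` is protein p's causal effect
    (0 for a null protein).
    """
    n_prot = len(thetas)
    if n_prot > 22:
        raise ValueError("at most 22 proteins (one chromosome each)")
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(n_prot + 1)
    rng_y = np.random.default_rng(seeds[-1])
    maf = cfg.maf_vector

    proteins = []
    truths: dict[str, ScenarioTruth] = {}
    outcome_parts = []
    y = np.zeros(cfg.n_outcome)
    g_outs = []
    for p, theta_p in enumerate(thetas):
        pid = f"P{p:02d}"
        rng_p = np.random.default_rng(seeds[p])
        cfg_p = replace(cfg, theta=float(theta_p),
                        scenario="shared" if theta_p != 0 else "null_protein_effect")
        g_exp = simulate_genotypes(cfg.n_exposure, maf, cfg.ld_rho, rng_p,
                                   chrom=str(p + 1), id_prefix=f"{pid}_var")
        g_out = simulate_genotypes(cfg.n_outcome, maf, cfg.ld_rho, rng_p,
                                   chrom=str(p + 1), id_prefix=f"{pid}_var")
        x_exp, _, truth = simulate_traits(g_exp, cfg_p, rng_p)
        x_out = (_scaled_genetic_component(g_out, cfg_p.exposure_causal_indices,
                                           cfg_p.var_explained_cis)
                 + rng_p.standard_normal(cfg.n_outcome)
                 * np.sqrt(1.0 - cfg_p.var_explained_cis))
        y += float(theta_p) * x_out
        g_outs.append(g_out)
        exposure = compute_sumstats(g_exp, x_exp, trait_id=f"{pid}_csf")
        region = _region_around(g_exp.panel, cfg_p.exposure_causal_indices[0], pid)
        proteins.append((pid, exposure, region, sample_ld(g_out)))
        truths[pid] = truth

    theta_arr = np.asarray(thetas, dtype=float)
    noise_var = max(1.0 - float(theta_arr @ theta_arr), 0.05)
    y = y + rng_y.standard_normal(cfg.n_outcome) * np.sqrt(noise_var)
    for g_out in g_outs:
        outcome_parts.append(compute_sumstats(g_out, y, trait_id="outcome").table)
    outcome = SummaryStats(trait_id="outcome",
                           table=pd.concat(outcome_parts, ignore_index=True))
    return PanelData(proteins=proteins, outcome=outcome, truths=truths)
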