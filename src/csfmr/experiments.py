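"""Calibration and recovery experiments on the synthetic generator.

These are the package's own validation studies: they exercise the full
pipeline on scenarios with known ground truth and report recovery,
coverage, discrimination, and calibration rates.  Problem sizes are chosen
so each experiment completes in minutes on one CPU; docs/methods.md
discusses the choices.

Seeding: every experiment takes one integer seed and derives independent
per-replicate streams from a :class:`numpy.random.SeedSequence`, so results
are reproducible and replicates are uncorrelated.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .coloc import ColocPriors, coloc_abf
from .harmonize import harmonize_set, kept_pairs
from .instruments import InstrumentConfig, clump, select_cis_variants
from .mr_estimators import ivw, wald_ratio
from .phewas import logistic_assoc
from .screen import ProteinInput, ScreenConfig, run_screen
from .synthetic_data import (
    ScenarioConfig,
    simulate_genotypes,
    simulate_panel,
    simulate_study,
)

__all__ = [
    "ivw_recovery",
    "coloc_discrimination",
    "screen_null_calibration",
    "screen_power",
    "phewas_null_calibration",
    "demo_screen",
]

#: calibration-study exposure sample size.  The first-order ratio SE omits
#: the theta^2*se_exp^2 term, which is negligible only when the exposure
#: association is measured about as precisely as the outcome one; CI
#: coverage is therefore assessed with n_exposure = n_outcome (see
#: docs/methods.md), while screens elsewhere keep the 835-sample default.
CALIBRATION_N_EXPOSURE = 20_000


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def ivw_recovery(n_reps: int = 200, seed: int = 1, theta_true: float = 0.3,
                 n_outcome: int = 20_000) -> dict:
    """Multi-instrument recovery: three independent cis instruments.

    Each replicate simulates a shared-causal-variant study with three
    well-separated causal variants (total cis variance share 0.1), selects
    instruments through the full cis/significance/clumping pipeline, and
    estimates theta by IVW.  Reports the mean estimate, the empirical 95%
    CI coverage, and the fraction of replicates where all three instruments
    were recovered.
    """
    cfg = ScenarioConfig(
        scenario="shared", theta=theta_true,
        n_exposure=CALIBRATION_N_EXPOSURE, n_outcome=n_outcome,
        m_variants=60, ld_rho=0.5, var_explained_cis=0.1,
        exposure_causal_indices=(10, 30, 50),
    )
    icfg = InstrumentConfig()
    thetas, covered, n_inst = [], [], []
    for ss in _child_seeds(seed, n_reps):
        study = simulate_study(replace(cfg, seed=_seed_int(ss)))
        cands, prov = select_cis_variants(study.exposure, study.region,
                                          study.outcome, icfg)
        inst = clump(cands, study.ld, icfg, protein_id="P", region=study.region,
                     provenance=prov)
        pairs = kept_pairs(harmonize_set(inst, study.outcome)[0])
        if len(pairs) < 2:
            est = wald_ratio(pairs[0])
        else:
            est = ivw(pairs)
        thetas.append(est.theta)
        covered.append(est.ci_low <= theta_true <= est.ci_high)
        n_inst.append(len(pairs))
    return {
        "mean_theta": float(np.mean(thetas)),
        "theta_true": theta_true,
        "ci_coverage": float(np.mean(covered)),
        "mean_instruments": float(np.mean(n_inst)),
        "n_reps": n_reps,
    }


def coloc_discrimination(n_reps: int = 100, seed: int = 1) -> dict:
    """Shared vs distinct causal-variant discrimination by colocalization.

    Shared replicates should put PPH4 above 0.7; distinct replicates (two
    causal variants 12 AR(1) steps apart, |r| ~ 0.9^12 = 0.28) should rank
    PPH3 above PPH4.
    """
    base = ScenarioConfig(n_exposure=835, n_outcome=20_000, m_variants=40,
                          ld_rho=0.9, theta=0.3, var_explained_cis=0.1,
                          var_explained_outcome=0.01)
    priors = ColocPriors()
    rates = {}
    for scenario, check in (
        ("shared", lambda res: res.pph4 > 0.7),
        ("distinct", lambda res: res.pph3 > res.pph4),
    ):
        hits = 0
        for ss in _child_seeds(seed + (scenario == "distinct"), n_reps):
            cfg = replace(base, scenario=scenario, seed=_seed_int(ss))
            study = simulate_study(cfg)
            res = coloc_abf(study.exposure, study.outcome, priors)
            hits += bool(check(res))
        rates[scenario] = hits / n_reps
    return {
        "shared_pph4_gt_070_rate": rates["shared"],
        "distinct_pph3_gt_pph4_rate": rates["distinct"],
        "n_reps": n_reps,
    }


def _panel_screen(thetas, seed: int, cfg: ScenarioConfig):
    panel_data = simulate_panel(thetas, cfg, seed)
    panel = [ProteinInput(pid, exp, region, ld)
             for pid, exp, region, ld in panel_data.proteins]
    scfg = ScreenConfig(seed=seed)
    return run_screen(panel, panel_data.outcome, scfg)


def screen_null_calibration(n_reps: int = 100, seed: int = 2,
                            n_proteins: int = 20) -> dict:
    """All-null panel: how often does the screen make zero FDR discoveries?"""
    cfg = ScenarioConfig(n_exposure=835, n_outcome=20_000, m_variants=20,
                         ld_rho=0.5, var_explained_cis=0.1)
    zero = 0
    for ss in _child_seeds(seed, n_reps):
        result = _panel_screen([0.0] * n_proteins, _seed_int(ss), cfg)
        zero += result.provenance["n_fdr_significant"] == 0
    return {"zero_discovery_rate": zero / n_reps, "n_reps": n_reps,
            "n_proteins": n_proteins}


def screen_power(n_reps: int = 100, seed: int = 3, n_proteins: int = 10,
                 theta_true: float = 0.3) -> dict:
    """Two causal proteins among nulls: recovery through FDR + coloc gates."""
    cfg = ScenarioConfig(n_exposure=835, n_outcome=20_000, m_variants=20,
                         ld_rho=0.5, var_explained_cis=0.1)
    thetas = [theta_true, 0.0, 0.0, 0.0, theta_true] + [0.0] * (n_proteins - 5)
    causal_ids = {f"P{i:02d}" for i, t in enumerate(thetas) if t != 0}
    both = 0
    for ss in _child_seeds(seed, n_reps):
        result = _panel_screen(thetas, _seed_int(ss), cfg)
        recovered = {r.protein_id for r in result.proteins
                     if r.fdr_significant and r.coloc_pass}
        both += causal_ids <= recovered
    return {"both_recovered_rate": both / n_reps, "n_reps": n_reps,
            "n_proteins": n_proteins, "theta_true": theta_true}


def phewas_null_calibration(n_reps: int = 100, seed: int = 4,
                            n: int = 5000) -> dict:
    """Null logistic associations: p-values should be uniform.

    Each replicate draws an independent variant and a case/control status
    unrelated to it, fits the logistic association, and the collected
    p-values are tested against Uniform(0, 1) by Kolmogorov-Smirnov.
    """
    pvals = []
    for ss in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(ss)
        g = simulate_genotypes(n, 0.3, 0.0, rng, m_variants=1)
        status = (rng.random(n) < 0.3).astype(int)
        _, _, p, ok = logistic_assoc(g.dosages[:, 0], status)
        if ok:
            pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n_fits": len(pvals),
            "n_reps": n_reps}


def demo_screen(seed: int = 1, theta_true: float = 0.23) -> dict:
    """Worked single-protein example at the headline effect scale.

    One protein with a true effect of 0.23 SD per log-RFU, screened
    end-to-end; reports the Wald/IVW estimate, CI, p, and the
    colocalization posterior for a shared causal variant.
    """
    cfg = ScenarioConfig(n_exposure=835, n_outcome=20_000, m_variants=40,
                         ld_rho=0.9, theta=theta_true, var_explained_cis=0.1)
    result = _panel_screen([theta_true], seed, cfg)
    res = result.proteins[0]
    out = {
        "theta_true": theta_true,
        "theta_hat": res.mr.theta,
        "se": res.mr.se,
        "ci_low": res.mr.ci_low,
        "ci_high": res.mr.ci_high,
        "pvalue": res.mr.pvalue,
        "n_instruments": res.n_instruments,
        "fdr_significant": res.fdr_significant,
    }
    if res.coloc is not None:
        out["pph4"] = res.coloc.pph4
        out["lead_shared_variant"] = res.coloc.lead_shared_variant
        out["coloc_pass"] = bool(res.coloc_pass)
    return out
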