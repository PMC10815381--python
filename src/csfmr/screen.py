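"""Proteome-wide screen orchestration.

Per protein: cis instrument selection -> LD clumping -> allele
harmonization -> MR (Wald ratio for one instrument, random-effects IVW
otherwise, weighted median as a sensitivity analysis when three or more
instruments survive) -> Benjamini-Hochberg FDR across the panel ->
Bayesian colocalization for FDR-significant proteins that pass the
weighted-median concordance gate -> secondary-outcome MR for proteins that
colocalize.

The FDR family is every protein with at least one harmonized instrument;
proteins without instruments are reported with a reason and excluded from
the family.  "Consistent" weighted-median evidence is operationalized as
same sign as the primary estimate with weighted-median p < 0.05, applied
only when the method is applicable (nsnp >= 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import (
    GeneRegion,
    LDMatrix,
    SummaryStats,
    write_results_table,
)
from .instruments import InstrumentConfig, InstrumentSet, clump, select_cis_variants
from .harmonize import (
    HarmonizedPair,
    PalindromicPolicy,
    audit_frame,
    harmonize_pair,
    harmonize_set,
    kept_pairs,
)
from .mr_estimators import MREstimate, bh_fdr, ivw, wald_ratio, weighted_median
from .coloc import DEFAULT_W, ColocPriors, ColocResult, coloc_from_labf, coloc_gate, wakefield_labf

__all__ = [
    "ProteinInput",
    "SecondaryOutcome",
    "ScreenConfig",
    "ProteinResult",
    "ScreenResult",
    "run_screen",
    "run_secondary",
    "make_report",
]


@dataclass
class ProteinInput:
    protein_id: str
    exposure: SummaryStats
    region: GeneRegion
    ld: LDMatrix


@dataclass
class SecondaryOutcome:
    outcome_id: str
    stats: SummaryStats
    unit: str = "SD"


@dataclass
class ScreenConfig:
    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    priors: ColocPriors = field(default_factory=ColocPriors)
    palindromic: PalindromicPolicy = field(default_factory=PalindromicPolicy)
    coloc_window_bp: int = 1_000_000
    h4_cutoff: float = 0.70
    coloc_w_exposure: float = DEFAULT_W
    coloc_w_outcome: float = DEFAULT_W
    coloc_all: bool = False  # exploratory full-panel colocalization
    fdr_alpha: float = 0.05
    wm_n_boot: int = 2000
    seed: int = 0


@dataclass
class ProteinResult:
    protein_id: str
    n_instruments: int
    instrument_ids: list[str] = field(default_factory=list)
    reason: str = ""
    provenance: dict = field(default_factory=dict)
    harmonization: list[HarmonizedPair] = field(default_factory=list)
    mr: MREstimate | None = None
    wm: MREstimate | None = None
    wm_consistent: bool | None = None
    qvalue: float = np.nan
    fdr_significant: bool = False
    coloc: ColocResult | None = None
    coloc_pass: bool | None = None
    secondary: dict[str, MREstimate | str] = field(default_factory=dict)


@dataclass
class ScreenResult:
    proteins: list[ProteinResult]
    multiplicity: dict[int, int]
    fdr_family_size: int
    provenance: dict


def _primary_mr(pairs: list[HarmonizedPair], protein_id: str,
                outcome_id: str) -> MREstimate:
    ids = dict(protein_id=protein_id, outcome_id=outcome_id)
    if len(pairs) == 1:
        return wald_ratio(pairs[0], **ids)
    return ivw(pairs, **ids)


def _regional_coloc(protein: ProteinInput, outcome: SummaryStats,
                    cfg: ScreenConfig) -> ColocResult | None:
    """Colocalize the cis region of one protein against the outcome.

    The panel is the intersection of exposure and outcome variants inside
    the region +/- coloc_window_bp; alleles are harmonized variant-by-
    variant (the posteriors only see z^2, but harmonization keeps per-SNP
    reporting allele-consistent and excludes irreconcilable records).
    """
    lo = protein.region.start - cfg.coloc_window_bp
    hi = protein.region.end + cfg.coloc_window_bp
    exp_rows = protein.exposure.region_subset(protein.region.chrom, lo, hi)
    out_idx = outcome.indexed()
    l1, l2, ids = [], [], []
    for row in exp_rows.to_dict("records"):
        vid = row["variant_id"]
        if vid not in out_idx.index:
            continue
        pair = harmonize_pair(row, out_idx.loc[vid].to_dict(), cfg.palindromic)
        if pair.dropped:
            continue
        l1.append(wakefield_labf(pair.beta_exp, pair.se_exp, cfg.coloc_w_exposure))
        l2.append(wakefield_labf(pair.beta_out, pair.se_out, cfg.coloc_w_outcome))
        ids.append(vid)
    if not ids:
        return None
    return coloc_from_labf(np.array(l1), np.array(l2), cfg.priors, ids)


def run_screen(
    panel: list[ProteinInput],
    outcome: SummaryStats,
    cfg: ScreenConfig = ScreenConfig(),
    secondary: list[SecondaryOutcome] | None = None,
) -> ScreenResult:
    """Run the full screen over a protein panel against one primary outcome."""
    if len({p.protein_id for p in panel}) != len(panel):
        raise ValueError("protein_ids must be unique")
    results: list[ProteinResult] = []
    for protein in panel:
        candidates, prov = select_cis_variants(
            protein.exposure, protein.region, outcome, cfg.instruments)
        inst = clump(candidates, protein.ld, cfg.instruments,
                     protein_id=protein.protein_id, region=protein.region,
                     provenance=prov)
        pairs_all, counts = harmonize_set(inst, outcome, cfg.palindromic)
        pairs = kept_pairs(pairs_all)
        res = ProteinResult(
            protein_id=protein.protein_id,
            n_instruments=len(pairs),
            instrument_ids=[p.variant_id for p in pairs],
            provenance={**inst.provenance, **{f"harmonize_{k}": v
                                              for k, v in counts.items()}},
            harmonization=pairs_all,
        )
        if not pairs:
            res.reason = "no_instruments"
        else:
            res.mr = _primary_mr(pairs, protein.protein_id, outcome.trait_id)
            if len(pairs) >= 3:
                res.wm = weighted_median(pairs, n_boot=cfg.wm_n_boot,
                                         seed=cfg.seed,
                                         protein_id=protein.protein_id,
                                         outcome_id=outcome.trait_id)
                res.wm_consistent = bool(
                    np.sign(res.wm.theta) == np.sign(res.mr.theta)
                    and res.wm.pvalue < 0.05)
        results.append(res)

    # FDR across proteins with >= 1 harmonized instrument
    family = [r for r in results if r.mr is not None]
    if family:
        fdr = bh_fdr([r.mr.pvalue for r in family], alpha=cfg.fdr_alpha)
        for r, q, sig in zip(family, fdr.qvalues, fdr.significant):
            r.qvalue, r.fdr_significant = float(q), bool(sig)

    # colocalization gate
    panel_by_id = {p.protein_id: p for p in panel}
    for res in results:
        wants_coloc = res.fdr_significant and (res.wm_consistent is not False)
        if cfg.coloc_all:
            wants_coloc = res.mr is not None
        if not wants_coloc:
            continue
        res.coloc = _regional_coloc(panel_by_id[res.protein_id], outcome, cfg)
        if res.coloc is not None and res.fdr_significant:
            res.coloc_pass = coloc_gate(res.coloc, cfg.h4_cutoff)

    # secondary outcomes for coloc-passing proteins
    if secondary:
        for res in results:
            if res.coloc_pass:
                res.secondary = run_secondary(
                    panel_by_id[res.protein_id], res.instrument_ids,
                    secondary, cfg)

    multiplicity: dict[int, int] = {}
    for r in results:
        if r.mr is not None:
            multiplicity[r.n_instruments] = multiplicity.get(r.n_instruments, 0) + 1
    provenance = {
        "seed": cfg.seed,
        "fdr_alpha": cfg.fdr_alpha,
        "h4_cutoff": cfg.h4_cutoff,
        "coloc_all": cfg.coloc_all,
        "n_proteins": len(panel),
        "fdr_family_size": len(family),
        "n_fdr_significant": sum(r.fdr_significant for r in results),
        "n_coloc_pass": sum(bool(r.coloc_pass) for r in results),
        "instrument_multiplicity": {str(k): v for k, v in sorted(multiplicity.items())},
        "instrument_config": asdict(cfg.instruments),
        "coloc_priors": asdict(cfg.priors),
    }
    return ScreenResult(proteins=results, multiplicity=multiplicity,
                        fdr_family_size=len(family), provenance=provenance)


def run_secondary(
    protein: ProteinInput,
    instrument_ids: list[str],
    outcomes: list[SecondaryOutcome],
    cfg: ScreenConfig,
) -> dict[str, MREstimate | str]:
    """Re-harmonize the instrument set against each secondary outcome.

    Outcomes missing every instrument are reported as "no_instruments";
    the unit tag travels with the estimate into the report.
    """
    inst_rows = protein.exposure.table.loc[
        protein.exposure.table["variant_id"].isin(instrument_ids)]
    inst = InstrumentSet(protein_id=protein.protein_id, region=protein.region,
                         table=inst_rows.reset_index(drop=True))
    out: dict[str, MREstimate | str] = {}
    for sec in outcomes:
        pairs_all, _ = harmonize_set(inst, sec.stats, cfg.palindromic)
        pairs = kept_pairs(pairs_all)
        if not pairs:
            out[sec.outcome_id] = "no_instruments"
            continue
        est = _primary_mr(pairs, protein.protein_id, sec.outcome_id)
        out[sec.outcome_id] = est
    return out


# ---------------------------------------------------------------------------
# reporting


def _estimate_row(protein_id: str, outcome_id: str, est: MREstimate,
                  qvalue: float = np.nan, coloc: ColocResult | None = None,
                  unit: str = "SD") -> dict:
    row = {
        "protein": protein_id, "outcome": f"{outcome_id} ({unit})",
        "method": est.method, "nsnp": est.nsnp,
        "beta": est.theta, "se": est.se, "pvalue": est.pvalue, "qvalue": qvalue,
    }
    if coloc is not None:
        row.update(coloc.as_dict())
        row["lead_shared_variant"] = coloc.lead_shared_variant
    return row


def make_report(result: ScreenResult, out_dir, *,
                secondary_units: dict[str, str] | None = None) -> dict[str, Path]:
    """Write the consolidated screen report.

    Emits results.tsv (primary, weighted-median, and secondary estimate
    rows), coloc_exploratory.tsv (every computed colocalization, including
    sub-cutoff ones), harmonization_audit.tsv, and provenance.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    secondary_units = secondary_units or {}

    rows, audit_frames, coloc_rows = [], [], []
    for res in result.proteins:
        if res.mr is None:
            rows.append({"protein": res.protein_id, "outcome": "",
                         "method": res.reason or "no_instruments", "nsnp": 0})
            continue
        rows.append(_estimate_row(res.protein_id, res.mr.outcome_id, res.mr,
                                  res.qvalue, res.coloc))
        if res.wm is not None:
            rows.append(_estimate_row(res.protein_id, res.wm.outcome_id, res.wm,
                                      np.nan))
        for sec_id, est in res.secondary.items():
            if isinstance(est, str):
                rows.append({"protein": res.protein_id, "outcome": sec_id,
                             "method": est, "nsnp": 0})
            else:
                rows.append(_estimate_row(res.protein_id, sec_id, est,
                                          unit=secondary_units.get(sec_id, "SD")))
        if res.harmonization:
            audit_frames.append(audit_frame(res.harmonization, res.protein_id,
                                            res.mr.outcome_id))
        if res.coloc is not None:
            coloc_rows.append({"protein": res.protein_id,
                               **res.coloc.as_dict(),
                               "lead_shared_variant": res.coloc.lead_shared_variant,
                               "n_snps": res.coloc.n_snps,
                               "coloc_pass": res.coloc_pass})

    paths = {
        "results": out_dir / "results.tsv",
        "coloc": out_dir / "coloc_exploratory.tsv",
        "audit": out_dir / "harmonization_audit.tsv",
        "provenance": out_dir / "provenance.json",
    }
    write_results_table(rows, paths["results"])
    coloc_df = pd.DataFrame(coloc_rows, columns=[
        "protein", "pph0", "pph1", "pph2", "pph3", "pph4",
        "lead_shared_variant", "n_snps", "coloc_pass"])
    coloc_df.to_csv(paths["coloc"], sep="\t", index=False, na_rep="NA",
                    float_format="%.6g")
    audit = (pd.concat(audit_frames, ignore_index=True) if audit_frames
             else audit_frame([]))
    audit.to_csv(paths["audit"], sep="\t", index=False, na_rep="NA",
                 float_format="%.10g")
    with open(paths["provenance"], "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
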