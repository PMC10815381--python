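"""Cis instrument selection: window restriction, significance, presence in
the outcome study, and greedy distance-bounded LD clumping.

Variants are cis when they lie within ``cis_window_bp`` (default 1 Mb) of
the gene start or end, the significance filter is strict (p < 5e-8), and
clumping retains mutually near-independent variants: the smallest-p variant
is taken as an index and every remaining candidate with r^2 >= clump_r2
within clump_window_bp of it is pruned, repeatedly.  Ties on p break by
position, then lexicographic variant ID, so the output is invariant to
input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import GeneRegion, LDMatrix, SummaryStats

__all__ = ["InstrumentConfig", "InstrumentSet", "select_cis_variants", "clump"]


@dataclass(frozen=True)
class InstrumentConfig:
    cis_window_bp: int = 1_000_000
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.cis_window_bp, self.clump_window_bp) <= 0 or self.p_threshold <= 0:
            raise ValueError("window and threshold parameters must be positive")
        if not 0.0 < self.clump_r2 < 1.0:
            raise ValueError("clump_r2 must be in (0, 1)")


@dataclass
class InstrumentSet:
    """Independent cis instruments for one protein, with stage provenance."""

    protein_id: str
    region: GeneRegion
    table: pd.DataFrame  # exposure summary-stat rows of the retained variants
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])


def select_cis_variants(
    exposure: SummaryStats,
    region: GeneRegion,
    outcome: SummaryStats,
    cfg: InstrumentConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Candidate instruments: cis, genome-wide significant, present in outcome.

    Returns the candidate rows (exposure coordinates/estimates) and
    per-stage provenance counts.  A region chromosome absent from the
    exposure yields an empty candidate list, not an error.
    """
    lo = region.start - cfg.cis_window_bp
    hi = region.end + cfg.cis_window_bp
    cis = exposure.region_subset(region.chrom, lo, hi)
    sig = cis.loc[cis["pvalue"] < cfg.p_threshold]  # strict inequality
    in_outcome = sig.loc[sig["variant_id"].isin(set(outcome.variant_ids))]
    provenance = {
        "n_exposure_variants": len(exposure),
        "n_cis": len(cis),
        "n_significant": len(sig),
        "absent_in_outcome": len(sig) - len(in_outcome),
        "n_candidates": len(in_outcome),
    }
    return in_outcome.copy(), provenance


def clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    cfg: InstrumentConfig,
    *,
    protein_id: str = "",
    region: GeneRegion | None = None,
    provenance: dict[str, int] | None = None,
) -> InstrumentSet:
    """Greedy p-ordered LD clumping within a distance window.

    Candidates missing from the LD panel are dropped with a warning
    (conservative: their independence cannot be verified).  Pairs separated
    by more than ``clump_window_bp`` are never pruned regardless of r^2.
    """
    provenance = dict(provenance or {})
    in_panel = candidates["variant_id"].isin(set(ld.variant_ids))
    n_missing = int((~in_panel).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} candidate(s) absent from the LD panel dropped "
            f"for {protein_id or 'protein'}", stacklevel=2)
    provenance["absent_in_ld_panel"] = n_missing
    pool = candidates.loc[in_panel].copy()

    # deterministic ordering: p ascending, then position, then variant_id
    order = np.lexsort((pool["variant_id"].to_numpy(),
                        pool["pos"].to_numpy(dtype=float),
                        pool["pvalue"].to_numpy(dtype=float)))
    pool = pool.iloc[order]

    kept_rows = []
    unclaimed = pool.to_dict("records")
    while unclaimed:
        index = unclaimed.pop(0)
        kept_rows.append(index)
        survivors = []
        for cand in unclaimed:
            dist = abs(int(cand["pos"]) - int(index["pos"]))
            r = ld.r_between(index["variant_id"], cand["variant_id"])
            if dist <= cfg.clump_window_bp and r * r >= cfg.clump_r2:
                continue  # pruned by the index variant
            survivors.append(cand)
        unclaimed = survivors

    table = (pd.DataFrame(kept_rows, columns=candidates.columns)
             if kept_rows else candidates.iloc[0:0].copy())
    provenance["n_instruments"] = len(table)
    if region is None:
        region = GeneRegion(gene_id=protein_id or "region", chrom="0", start=1, end=1)
    return InstrumentSet(protein_id=protein_id, region=region,
                         table=table.reset_index(drop=True), provenance=provenance)
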