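"""Allele harmonization between two studies' per-variant estimates.

Both sides of a two-sample MR analysis must report effects for the same
allele of each variant.  Four situations arise: the alleles already agree;
they are swapped (the outcome's effect allele is the exposure's other
allele), fixed by flipping the outcome beta and frequency; they agree only
after complementing (the studies reported opposite strands); or they are
irreconcilable.  Palindromic variants (A/T or C/G) are a special case —
allele labels cannot resolve strand, so orientation relies entirely on
allele-frequency concordance, and variants whose frequency is too close to
0.5 on either side are dropped as ambiguous.

Indels are never complemented and never treated as palindromic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .gwas_io import SummaryStats
from .instruments import InstrumentSet

__all__ = ["PalindromicPolicy", "HarmonizedPair", "harmonize_pair", "harmonize_set"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

KEPT = "kept"
FLIPPED = "flipped_outcome"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


@dataclass(frozen=True)
class PalindromicPolicy:
    """How to orient A/T and C/G variants.

    Frequencies inside [ambiguous_low, ambiguous_high] on either side make
    the variant unresolvable; both frequencies must be present and outside
    the window for frequency-based orientation.
    """

    ambiguous_low: float = 0.42
    ambiguous_high: float = 0.58


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome estimates aligned to one effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action: str = KEPT

    @property
    def dropped(self) -> bool:
        return self.action.startswith("dropped")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _complement(a1) == a2


def _eaf(value) -> float | None:
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value


def harmonize_pair(exp: Mapping, out: Mapping,
                   policy: PalindromicPolicy = PalindromicPolicy()) -> HarmonizedPair:
    """Align one outcome record to the exposure's effect allele.

    ``exp`` and ``out`` are mappings with keys variant_id, effect_allele,
    other_allele, beta, se, and optionally eaf.  The returned pair always
    reports the exposure's allele orientation; the action field records what
    was done (or why the variant was dropped).
    """
    if exp["variant_id"] != out["variant_id"]:
        raise ValueError("harmonize_pair requires matching variant_id")
    e1, e2 = str(exp["effect_allele"]).upper(), str(exp["other_allele"]).upper()
    o1, o2 = str(out["effect_allele"]).upper(), str(out["other_allele"]).upper()
    eaf_exp, eaf_out = _eaf(exp.get("eaf")), _eaf(out.get("eaf"))
    base = dict(
        variant_id=exp["variant_id"], effect_allele=e1, other_allele=e2,
        beta_exp=float(exp["beta"]), se_exp=float(exp["se"]),
        beta_out=float(out["beta"]), se_out=float(out["se"]),
        eaf_exp=eaf_exp, eaf_out=eaf_out,
    )
    is_indel = len(e1) > 1 or len(e2) > 1

    if not is_indel and _is_palindromic(e1, e2):
        # labels cannot resolve strand; orient purely by frequency
        if {o1, o2} != {e1, e2}:
            return HarmonizedPair(**base, action=DROPPED_MISMATCH)
        if eaf_exp is None or eaf_out is None:
            return HarmonizedPair(**base, action=DROPPED_PALINDROMIC)
        lo, hi = policy.ambiguous_low, policy.ambiguous_high
        if lo <= eaf_exp <= hi or lo <= eaf_out <= hi:
            return HarmonizedPair(**base, action=DROPPED_PALINDROMIC)
        if (eaf_exp - 0.5) * (eaf_out - 0.5) > 0:
            return HarmonizedPair(**base, action=KEPT)
        base["beta_out"] = -base["beta_out"]
        base["eaf_out"] = 1.0 - eaf_out
        return HarmonizedPair(**base, action=FLIPPED)

    for flip_strand in (False, True) if not is_indel else (False,):
        c1, c2 = (_complement(o1), _complement(o2)) if flip_strand else (o1, o2)
        if (c1, c2) == (e1, e2):
            return HarmonizedPair(**base, action=KEPT)
        if (c1, c2) == (e2, e1):
            base["beta_out"] = -base["beta_out"]
            if eaf_out is not None:
                base["eaf_out"] = 1.0 - eaf_out
            return HarmonizedPair(**base, action=FLIPPED)
    return HarmonizedPair(**base, action=DROPPED_MISMATCH)


def harmonize_set(
    instruments: InstrumentSet,
    outcome: SummaryStats,
    policy: PalindromicPolicy = PalindromicPolicy(),
) -> tuple[list[HarmonizedPair], dict[str, int]]:
    """Harmonize every instrument against the outcome study.

    Returns all pairs (kept and dropped, for the audit log) and a count of
    each action.  Instruments absent from the outcome are counted as
    ``absent_in_outcome`` — upstream selection normally prevents this.
    """
    out_idx = outcome.indexed()
    pairs: list[HarmonizedPair] = []
    counts: dict[str, int] = {}
    for exp_row in instruments.table.to_dict("records"):
        vid = exp_row["variant_id"]
        if vid not in out_idx.index:
            counts["absent_in_outcome"] = counts.get("absent_in_outcome", 0) + 1
            continue
        pair = harmonize_pair(exp_row, out_idx.loc[vid].to_dict(), policy)
        counts[pair.action] = counts.get(pair.action, 0) + 1
        pairs.append(pair)
    return pairs, counts


def kept_pairs(pairs: list[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if not p.dropped]


def audit_frame(pairs: list[HarmonizedPair], protein_id: str = "",
                outcome_id: str = "") -> pd.DataFrame:
    """Harmonization audit rows for the report."""
    columns = ["protein", "outcome", "variant_id", "effect_allele",
               "other_allele", "beta_exp", "beta_out", "action"]
    return pd.DataFrame([
        {"protein": protein_id, "outcome": outcome_id, "variant_id": p.variant_id,
         "effect_allele": p.effect_allele, "other_allele": p.other_allele,
         "beta_exp": p.beta_exp, "beta_out": p.beta_out, "action": p.action}
        for p in pairs
    ], columns=columns)
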