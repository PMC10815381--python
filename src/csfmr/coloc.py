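"""Single-causal-variant Bayesian colocalization of two association signals.

For each variant the Wakefield approximate Bayes factor for association
versus the null is computed in closed form from the effect estimate, its
standard error, and a prior effect variance W:

    z = beta/se,  V = se^2,  r = W/(W+V)
    log-ABF = 0.5 * [log(1 - r) + r * z^2]

Under the assumption of at most one causal variant per trait, the five
hypotheses are H0 (no association), H1/H2 (only trait 1/2), H3 (both, at
distinct variants), and H4 (both, at one shared variant).  Each causal
configuration's unnormalized weight is its prior (per-SNP priors p1, p2,
p12) times the product of the relevant ABFs; summing configurations per
hypothesis and normalizing yields the posteriors PPH0..PPH4.  All sums run
in log space.  The H3 cross-term sum over ordered pairs (i, j), i != j, is
evaluated exactly as an off-diagonal log-sum-exp of the pairwise matrix
l1_i + l2_j, which keeps PPH3 identically zero for a single-SNP region and
avoids the catastrophic cancellation of the subtracted-product identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .gwas_io import SummaryStats

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_labf",
    "coloc_from_labf",
    "coloc_abf",
    "coloc_gate",
    "DEFAULT_W",
]

#: default prior effect variance for a standardized quantitative trait
#: (prior SD 0.15 per allele copy)
DEFAULT_W = 0.0225


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("need 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass
class ColocResult:
    """Hypothesis posteriors plus per-SNP shared-signal posteriors."""

    pp: np.ndarray  # PPH0..PPH4, sums to 1
    n_snps: int
    variant_ids: list[str]
    per_snp_h4: np.ndarray  # sums to 1
    lead_shared_variant: str

    @property
    def pph4(self) -> float:
        return float(self.pp[4])

    @property
    def pph3(self) -> float:
        return float(self.pp[3])

    def as_dict(self) -> dict[str, float]:
        return {f"pph{i}": float(self.pp[i]) for i in range(5)}


def wakefield_labf(beta, se, W: float):
    """Log approximate Bayes factor for association versus the null.

    Accepts scalars or arrays; W = 0 gives log-ABF = 0 (the prior puts all
    mass on a zero effect, so the data cannot discriminate).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if W < 0:
        raise ValueError("prior variance W must be >= 0")
    V = se**2
    r = W / (W + V)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def coloc_from_labf(
    l1: np.ndarray,
    l2: np.ndarray,
    priors: ColocPriors = ColocPriors(),
    variant_ids: list[str] | None = None,
) -> ColocResult:
    """Enumerate the five hypotheses from per-SNP log-ABFs of both traits."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("log-ABF vectors must be 1-D and aligned")
    n = l1.size
    if n == 0:
        raise ValueError("empty region")
    variant_ids = variant_ids or [f"snp{i}" for i in range(n)]

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    if n > 1:
        pairwise = l1[:, None] + l2[None, :]
        np.fill_diagonal(pairwise, -np.inf)
        lcross = logsumexp(pairwise)
    else:
        lcross = -np.inf

    log_h = np.array([
        0.0,
        np.log(priors.p1) + lsum1,
        np.log(priors.p2) + lsum2,
        (np.log(priors.p1) + np.log(priors.p2) + lcross) if n > 1 else -np.inf,
        np.log(priors.p12) + lsum12,
    ])
    pp = softmax(log_h)
    per_snp_h4 = softmax(l1 + l2)
    lead = variant_ids[int(np.argmax(per_snp_h4))]
    return ColocResult(pp=pp, n_snps=n, variant_ids=list(variant_ids),
                       per_snp_h4=per_snp_h4, lead_shared_variant=lead)


def coloc_abf(
    trait1: SummaryStats,
    trait2: SummaryStats,
    priors: ColocPriors = ColocPriors(),
    W1: float = DEFAULT_W,
    W2: float = DEFAULT_W,
) -> ColocResult:
    """Colocalize two traits over an identical ordered variant panel.

    The caller intersects and orders the panels (and harmonizes alleles if
    per-SNP reporting is to be allele-consistent; the posteriors themselves
    depend on beta only through z^2).
    """
    ids1 = list(trait1.variant_ids)
    ids2 = list(trait2.variant_ids)
    if ids1 != ids2:
        raise ValueError("traits must share an identical ordered variant panel")
    l1 = wakefield_labf(trait1.table["beta"].to_numpy(),
                        trait1.table["se"].to_numpy(), W1)
    l2 = wakefield_labf(trait2.table["beta"].to_numpy(),
                        trait2.table["se"].to_numpy(), W2)
    return coloc_from_labf(l1, l2, priors, ids1)


def coloc_gate(result: ColocResult, cutoff: float = 0.70) -> bool:
    """True when PPH4 meets the (inclusive) colocalization cutoff."""
    return result.pph4 >= cutoff
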