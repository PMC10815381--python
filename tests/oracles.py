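"""Independent brute-force oracles used to check the library implementations.

Everything here is written from the defining formulas with explicit loops,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats


def ivw_oracle(theta_j, se_j):
    """Weighted mean, Q, I^2 and random-effects SE by explicit summation."""
    w = [1.0 / s**2 for s in se_j]
    sw = sum(w)
    theta = sum(wi * ti for wi, ti in zip(w, theta_j)) / sw
    se_fixed = sw ** -0.5
    Q = sum(wi * (ti - theta) ** 2 for wi, ti in zip(w, theta_j))
    k = len(theta_j)
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    se = se_fixed * max(1.0, math.sqrt(Q / (k - 1)))
    return theta, se_fixed, se, Q, I2


def weighted_median_oracle(theta_j, w):
    """Weight-interpolated median by explicit cumulative-weight search."""
    pairs = sorted(zip(theta_j, w))
    total = sum(w)
    s = []
    running = 0.0
    for _, wi in pairs:
        s.append((running + wi / 2.0) / total)
        running += wi
    if s[0] >= 0.5:
        return pairs[0][0]
    if s[-1] <= 0.5:
        return pairs[-1][0]
    for i in range(len(s) - 1):
        if s[i] <= 0.5 <= s[i + 1]:
            t0, t1 = pairs[i][0], pairs[i + 1][0]
            return t0 + (t1 - t0) * (0.5 - s[i]) / (s[i + 1] - s[i])
    raise AssertionError("unreachable")


def bh_oracle(pvalues, alpha=0.05):
    """Literal Benjamini-Hochberg step-up plus monotone q-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    cutoff_rank = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank * alpha / m:
            cutoff_rank = rank
    significant = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= cutoff_rank:
            significant[idx] = True
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, pvalues[idx] * m / rank)
        q[idx] = running_min
    return significant, q


def clump_oracle(candidates, r2_of, clump_r2, window_bp):
    """Greedy smallest-p maximal selection, verified by exhaustive scan.

    ``candidates`` is a list of dicts with variant_id, pos, pvalue;
    ``r2_of(a, b)`` returns pairwise r^2.  Returns the retained variant_ids
    and asserts the defining properties of the selection on the way out.
    """
    pool = sorted(candidates,
                  key=lambda c: (c["pvalue"], c["pos"], c["variant_id"]))
    kept = []
    claimed = set()
    for cand in pool:
        if cand["variant_id"] in claimed:
            continue
        kept.append(cand)
        for other in pool:
            if other["variant_id"] in claimed or other is cand:
                continue
            close = abs(other["pos"] - cand["pos"]) <= window_bp
            if close and r2_of(cand["variant_id"], other["variant_id"]) >= clump_r2:
                claimed.add(other["variant_id"])
        claimed.add(cand["variant_id"])
    # exhaustive verification of the invariants
    kept_ids = [c["variant_id"] for c in kept]
    for a in kept:
        for b in kept:
            if a["variant_id"] >= b["variant_id"]:
                continue
            if abs(a["pos"] - b["pos"]) <= window_bp:
                assert r2_of(a["variant_id"], b["variant_id"]) < clump_r2
    return kept_ids


def coloc_enum_oracle(l1, l2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Exhaustive causal-configuration enumeration in linear space.

    Valid for moderate log-ABFs (exp must not overflow); the acceptance
    checks stay inside that range by construction.
    """
    abf1 = [math.exp(v) for v in l1]
    abf2 = [math.exp(v) for v in l2]
    n = len(abf1)
    w = [1.0, 0.0, 0.0, 0.0, 0.0]
    for i in range(n):
        w[1] += p1 * abf1[i]
    for j in range(n):
        w[2] += p2 * abf2[j]
    for i in range(n):
        for j in range(n):
            if i != j:
                w[3] += p1 * p2 * abf1[i] * abf2[j]
    for i in range(n):
        w[4] += p12 * abf1[i] * abf2[i]
    total = sum(w)
    return [x / total for x in w]


def labf_integration_oracle(beta, se, W):
    """Wakefield ABF by numerically integrating the normal-normal model.

    BF = integral N(beta_hat; b, V) N(b; 0, W) db / N(beta_hat; 0, V).
    """
    V = se**2
    num, _ = integrate.quad(
        lambda b: stats.norm.pdf(beta, loc=b, scale=math.sqrt(V))
        * stats.norm.pdf(b, loc=0.0, scale=math.sqrt(W)),
        -20 * math.sqrt(W), 20 * math.sqrt(W), limit=200)
    den = stats.norm.pdf(beta, loc=0.0, scale=math.sqrt(V))
    return math.log(num / den)


def tetrachoric_r(hap_a, hap_b, maf_a, maf_b):
    """Latent Gaussian correlation recovered from two binary haplotypes."""
    p11 = float(np.mean(hap_a * hap_b))
    ta, tb = stats.norm.ppf(maf_a), stats.norm.ppf(maf_b)

    def orthant(rho):
        cov = [[1.0, rho], [rho, 1.0]]
        return stats.multivariate_normal(mean=[0, 0], cov=cov).cdf([ta, tb])

    from scipy.optimize import brentq
    return brentq(lambda rho: orthant(rho) - p11, -0.999, 0.999, xtol=1e-4)


def odds_ratio_2x2(dosage, status):
    """Cross-product odds ratio of a collapsible 0/1 dosage table."""
    d = np.asarray(dosage)
    s = np.asarray(status)
    a = np.sum((d == 1) & (s == 1))
    b = np.sum((d == 1) & (s == 0))
    c = np.sum((d == 0) & (s == 1))
    e = np.sum((d == 0) & (s == 0))
    return (a * e) / (b * c)
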