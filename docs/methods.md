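# Methods

`csfmr` implements a proteome-wide *cis*-Mendelian-randomization (MR)
screen: it asks, for each protein in a panel, whether genetically
predicted protein levels affect an outcome trait, using only GWAS summary
statistics from two non-overlapping samples. This note documents the
statistical model behind each stage, the tunable parameters, what the
synthetic generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Causal model and estimands

The estimand is θ, the change in the outcome (SD units for quantitative
traits, mm³ for volumetric MRI traits, log-odds for binary traits) per
1 log-RFU increase in the protein level. A *cis* variant G with
per-allele effect β_X on the protein and β_Y on the outcome identifies θ
under the instrumental-variable assumptions (relevance, exchangeability,
exclusion restriction) as θ = β_Y / β_X.

## Instrument selection

Variants are *cis* when within 1 Mb of the gene start or end (closed
interval; GRCh37 coordinates, 1-based inclusive internally, BED converted
at the boundary). The significance filter is strict (p < 5×10⁻⁸), and
instruments must be present in the outcome GWAS — no proxy substitution.
Clumping is greedy: the smallest-p unclaimed variant becomes an index and
removes every unclaimed variant with r² ≥ 0.01 within 1 Mb of it. Pairs
farther apart than the clumping window are never pruned regardless of r².
Ties on p break by position then lexicographic variant ID so the result
is invariant to input row order; candidates absent from the LD panel are
dropped with a warning, since their independence cannot be verified.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
alleles are kept, swapped labels flip the outcome beta and frequency, and
strand flips are resolved by complementing before re-matching. For
palindromic variants (A/T, C/G) the labels carry no strand information,
so orientation uses allele-frequency concordance alone; if either
frequency is missing or falls inside [0.42, 0.58] (a common default in
two-sample MR tooling) the variant is dropped as ambiguous. Indels are
never complemented and never treated as palindromic. Harmonization is
idempotent, and relabelling the outcome's alleles before harmonization
never changes the aligned pair — both properties are tested.

## Estimators

* **Wald ratio** (1 instrument): θ̂ = β_Y/β_X, SE = se_Y/|β_X|
  (first-order delta method), two-sided normal p.
* **IVW, random effects** (≥ 2): θ̂ = Σw_jθ̂_j / Σw_j with w_j the
  inverse squared first-order ratio SE; Cochran's Q = Σw_j(θ̂_j − θ̂)²;
  I² = max(0, (Q − (k−1))/Q)·100; the fixed-effect SE (Σw_j)^(−1/2) is
  inflated by max(1, √(Q/(k−1))) (multiplicative over-dispersion, floored
  at 1 — with the 1–3 instruments typical of cis panels the floor almost
  always binds).
* **Weighted median** (≥ 3): ratio estimates ordered by magnitude;
  cumulative standardized weights s_j = (Σ_{i≤j}w_i − w_j/2)/Σw; θ̂ is the
  linear interpolation of the ordered estimates at s = 0.5. The SE is a
  parametric bootstrap (default 5000 seeded draws of β_X and β_Y from
  their reported sampling distributions). Consistent when valid
  instruments carry > 50% of the weight.
* **FDR**: Benjamini–Hochberg at 5% across the family of proteins with
  at least one harmonized instrument in the screen invocation.

## Colocalization

Under at most one causal variant per trait per region, each variant's
evidence is the Wakefield approximate Bayes factor,
log-ABF = ½[log(1−r) + r·z²] with r = W/(W+se²), z = β/se. Per-SNP
priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; prior effect SD 0.15 (W = 0.0225) per
trait for standardized quantitative traits, configurable per trait.
Posteriors for H0–H4 come from summing configuration weights in log
space. The H3 sum over ordered pairs (i, j), i ≠ j, is computed as an
exact off-diagonal log-sum-exp of the pairwise matrix rather than the
subtracted-product identity: regions here hold at most a few thousand
variants, so the O(n²) cost is negligible, the result is exact (PPH3 is
identically 0 for one SNP), and the cancellation guard the identity needs
becomes moot. Colocalization "passes" at PPH4 ≥ 0.70 (inclusive);
sub-threshold results are always written to an exploratory table. The
default coloc region is the instrument cis window (gene ± 1 Mb); a
narrower window is a configuration choice.

Note the five-hypothesis posteriors are *not* invariant to a uniform
rescaling of all Bayes factors (H0's weight is fixed while H1/H2 scale
linearly and H3/H4 quadratically); the per-SNP shared-signal posterior
vector is, and that invariance is what the test suite asserts.

## Screen orchestration

Per protein: selection → clumping → harmonization → MR (Wald for 1
instrument, IVW otherwise; weighted median when ≥ 3) → BH-FDR across the
panel → colocalization for FDR-significant proteins → secondary-outcome
MR for colocalizing proteins, with the unit tag propagated verbatim.
Proteins with zero surviving instruments are reported with a reason and
excluded from the FDR family. "Consistent" weighted-median evidence — a
prerequisite for carrying a ≥3-instrument protein to colocalization — is
operationalized as same sign as the primary estimate with p < 0.05; the
criterion is recorded per protein because the notion is not otherwise
pinned down. Identical configuration and seed reproduce every output
file byte-for-byte.

## Synthetic data generator

Haplotypes are a one-parameter AR(1) Gaussian copula: latent standard
normals with adjacent correlation `ld_rho` thresholded at the quantile of
each variant's MAF; two haplotypes sum to a dosage. Pairwise LD decays as
ρ^|i−j| on the latent scale (tetrachorically attenuated on the dosage
scale), which is all that clumping and colocalization consume. The
exposure X is standardized with a configured share `var_explained_cis` of
its variance from the causal *cis* variant(s); the outcome follows the
scenario (`shared`, `distinct`, `null_protein_effect`, `null_assoc`).
Exposure and outcome samples are always independent draws — the screen's
two-sample, no-overlap design. Marginal (per-SNP) OLS mirrors deposited
GWAS estimates; binary phenotypes come from a logistic model whose
intercept is solved numerically to hit a target prevalence.

Defaults are the emulated study's conditions: exposure n = 835, effect
unit SD per log-RFU, demonstration θ = 0.23, MAF 0.3, 10 kb variant
spacing. Not emulated: realistic human LD maps, imputation uncertainty,
relatedness, population stratification, assay artefacts (e.g. missense
variants perturbing aptamer binding). Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the stated
model, not that real-data results are free of those biases.

## Calibration experiments and problem sizes

`csfmr.experiments` runs the validation studies reported by
`scripts/acceptance.py`; sizes were chosen so the whole set completes in
a few minutes on one CPU while keeping Monte-Carlo error small relative
to the asserted tolerances:

* **IVW recovery** — 200 replicates, shared scenario, θ = 0.3, three
  causal variants (total cis variance 0.1) spaced 20 AR(1) steps apart,
  n_outcome = 20 000. The full selection pipeline runs each replicate.
  The first-order ratio SE omits the θ²·se_X² term; its relative size is
  θ²(1−v)·n_outcome/n_exposure, ≈ 2 at the 835-sample exposure scale —
  enough to visibly undercover. CI calibration is therefore assessed with
  n_exposure = 20 000 (omitted term ≈ 9%), where the first-order
  approximation is valid; screens elsewhere keep the 835 default.
* **Coloc discrimination** — 100 replicates per scenario, ld_rho = 0.9,
  distinct causal variants 12 steps apart (|r| ≈ 0.28).
* **Screen calibration/power** — 100 replicates each: a 20-protein
  all-null panel (zero-discovery rate) and a 10-protein panel with two
  θ = 0.3 effects (recovery through both gates), m = 20 variants per
  region.
* **PheWAS calibration** — 100 null logistic fits at n = 5000,
  Kolmogorov–Smirnov uniformity of p.

## Numerical choices and degenerate inputs

p-values are floored at the smallest positive normal float (input p = 0
is replaced with a warning). Monomorphic variants get β = 0, SE = ∞ and
are dropped by read-side validation. LD matrices are symmetrized by
averaging when asymmetry is within 1e-6 and rejected beyond. Logistic
fits flag separation at |log-OR| > 15 or IRLS non-convergence within 100
iterations and leave such rows out of the FDR family. All confidence
intervals use the normal critical value 1.959964.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-signal
decomposition, masking, or conditional analysis). No MR-Egger or
mode-based estimators, no Steiger filtering, no proxy-variant lookup.
The LD model is exchangeable-AR(1), not a real recombination landscape.
The weighted-median bootstrap ignores between-study correlation (none
exists in the two-sample design). The first-order Wald SE undercovers
when the exposure GWAS is small relative to the outcome GWAS and θ is
non-negligible, as quantified above.
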