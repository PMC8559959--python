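# Methods

## Model and estimator

The flexible conditional FDR targets `Pr(H0 | P ≤ p, Q ≤ q)` for a principal
GWAS trait with two-sided p-values `p` and a continuous per-SNP covariate
`q`. The working assumptions are the standard cFDR ones: `P | H0 ~ U(0, 1)`,
`P ⊥ Q | H0`, `Pr(H0) ≈ 1` (conservative in the GWAS regime), and a positive
stochastic monotone relationship between `p` and `q` (small `q` enriched for
small `p`; the orientation is checked and, if clearly reversed, the
covariate's sign is flipped). The estimator is

```
cfdr(p, q) = p · Pr(Q ≤ q | H0) / Pr(P ≤ p, Q ≤ q).
```

p-values are mapped to absolute Z-scores `z = −Φ⁻¹(p/2)`; all densities live
on the `(|Z|, Q)` plane.

**Joint density.** A bivariate KDE with a normalised product Gaussian kernel,
fitted to an (approximately) LD-independent subset of SNPs so that the
normal-reference bandwidth rule — `1.06·min(sd, IQR/1.34)·n^(−1/5)` per axis
— applies. Because `|Z| ≥ 0`, each point is mirrored across zero and the
mirrored mass folded back (reflection technique), which removes the boundary
bias at `z = 0`. The density is evaluated on a rectangular grid (default
501×501; the Z axis spans `[0, max(1.1·max|z|, 10)]`, the covariate axis is
10% wider than the observed range, split 5% per side) and renormalised to
unit trapezoidal mass.

**Tail integrals.** `Pr(P ≤ p, Q ≤ q)` is the joint tail
`T(z, y) = Pr(|Z| ≥ z, Q ≤ y)`. Inside the pipeline T is computed from the
closed-form Gaussian integrals of each kernel rather than by cumulative
quadrature of the gridded density: with a grid step comparable to the
bandwidth, the trapezoid rule carries an `O((h/σ)²)` wobble (≈1.5% at a
201-point grid) that is larger than the genuine decline of the estimator
along `z` near the origin and corrupts contour placement. A grid-based
trapezoidal `joint_tail_table` is kept for diagnostics; the two agree to a
few parts in a thousand.

**Null covariate law.** `Pr(H0 | Z = z)` is an Efron-style local fdr: the
mirrored Z-scores are histogrammed (120 equal-width bins) and the counts
fitted by Poisson regression on a natural cubic spline (7 df). The null is
the theoretical N(0, 1) — exact here, because under `P | H0 ~ U(0, 1)` the
mirrored null |Z| sample is standard normal — and the null proportion is the
zero-assumption estimate `π0 = min(1, f(0)/φ(0))`. IRLS can diverge when the
outer histogram bins are empty; the fit falls back to direct maximisation of
the (strictly convex) Poisson likelihood. The null covariate density is then

```
f0(y) ∝ Σ_k a_k φ((y − q_k)/σ_q),   a_k = ∫ fdr(x) K_σp(x; z_k) dx,
```

i.e. each kernel weighted by its own null mass — the same per-kernel
closed-form treatment as T, so numerator and denominator of the estimator
agree node for node, including at the support edges where grid quadrature
would return an exact zero while kernel tails do not.

**From cFDR to v-values.** Rejecting whenever the raw estimate is below α is
not monotone in `p`, so each point's level is the running minimum of the
estimated surface along `z` up to the point itself — exactly the repair "if
any larger p′ on the same covariate row would be rejected, reject this point
too". This also neutralises the estimator's blow-up beyond the fitted data's
Z range, where Gaussian kernel tails decay faster than the null. The
L-region of a level is `{cfdr ≤ level}`; its rightmost p-boundary per
covariate row, `p_L(y)`, is found by binary search on the (monotone) running
minimum and linear interpolation *in p* between the bracketing nodes, and

```
v = ∫ p_L(y) f0(y) dy
```

because `P | H0` is uniform. Levels are deduplicated before curve
construction (SNPs sharing a level share an L-curve). For reporting, the
surface is also stored clamped to (0, 1]. v-values are approximately uniform
under the null and are passed to Benjamini–Hochberg.

## Sparse-data adaptations

**Left-censoring.** Covariate values left of the first "well-populated" cell
are moved onto that cell's edge. Population is counted in cells one
covariate-bandwidth wide: a cell much thinner than a kernel says nothing
about whether the KDE is locally supported, and at the ~10⁴-SNP scale of the
simulation studies display-grid cells would absorb entire mixture
components. The count threshold (`gridp`) defaults to 50. In practice a few
per mill to a few percent of values are censored.

**Spline correction.** Where `(p, q)` is jointly sparse a v-value can come
out far smaller than its p-value. A natural cubic regression spline with 5
interior knots (at the 1/6…5/6 quantiles of `q`) is fitted to
`log10(v/p)` against `q`; points more than `dist_thr` (default 0.5, log10
units) *below* the spline are mapped back onto it, `v → p·10^s(q)`. The
correction is one-sided by default: only deviations that inflate
significance are corrected, since deflated v-values are merely conservative,
and correcting them re-introduces anti-conservative mass under the null
(a `side="both"` flag restores unsigned correction).

**Sign alignment.** The Pearson correlation of `(p, q)` over the fitting
subset decides the covariate orientation; the sign is flipped only when the
estimate is below −2/√n. A dead band matters because a covariate independent
of `p` produces a correlation straddling zero, and a noise-driven flip can
move a heavy covariate tail onto the censored side.

## Iteration

The v-values of one iteration serve as the p-values of the next, each
iteration leveraging a fresh covariate. Repeatedly conditioning on
covariates that capture the same genomic feature inflates significance —
the pipeline warns when successive covariate columns have |Pearson r| > 0.3
— and the simulation harness's scenario E exists to demonstrate this
failure mode.

## Synthetic studies

The generator emulates a chromosome-scale case-control GWAS:

- **LD:** 24 independent blocks with within-block AR(1) correlation
  `ρ^|i−j|` (default ρ = 0.9), 420 SNPs per block (~10,080 SNPs), 400 bp
  between adjacent SNPs (matching ~80k SNPs over a ~35 Mb chromosome).
  AR(1) gives closed-form `r² = ρ^(2|i−j|)`, hence exact truth sets.
- **Signals:** 2–4 causal SNPs per block, log-OR effects `β ~ N(0, 0.2²)`
  (the standard fine-mapping prior). Expected Z-scores propagate through LD
  as `Σγ` with `γ = ncp_scale·β`, and observed Z-scores are multivariate
  normal around that mean with covariance Σ (sampled via the AR(1)
  recursion). `ncp_scale` defaults to 25 ≈ 1/se(log OR) for 5,000 cases and
  5,000 controls at a representative MAF of 0.2, which puts per-replicate
  power at stringent thresholds in a realistic GWAS regime.
- **Covariates (scenarios A–E):** A iid U(0,1); B p-values of a second
  simulated GWAS sharing causal variants in exactly 4 of the 24 blocks;
  C iid 0.5·N(−2, 0.5²) + 0.5·N(3, 2²), independent of the study;
  D mixtures whose component weights differ between "functional" SNPs
  (causal ± 10 kb) and the rest, with (μ1, μ2, w) drawn per realisation from
  μ1 ∈ {2.5, 3, 4}, μ2 ∈ {−1.5, −2, −3}, w ∈ {0.6, …, 0.95}; E functional
  ~ N(−2, 0.5²), others ~ N(3, 2²), identical across realisations.
- **Scoring:** truth sets from closed-form r² (associated: r² ≥ 0.8 with a
  causal; not-associated: r² ≤ 0.01 with all causals). Sensitivity and
  specificity use FDR ≤ 5×10⁻⁶ (roughly genome-wide significance);
  the FDR proxy uses a raised 0.05 threshold so control is measurable with
  ~100 replicates.
- **Independent subset:** greedy pruning at r² < 0.1 (every 11th SNP within
  a block), standing in for LDAK/PLINK pruning of real genotypes.

**What the generator does not emulate.** Real LD has long-range, irregular
correlation within blocks; AR(1) correlation dies within ~40 SNPs. Two
consequences worth knowing. First, related-trait p-values (scenario B) are
less informative here (cor(p, q) ≈ 0.02) than in a haplotype-based study,
while the functional covariate (D) is more informative (≈0.12, because the
fixed 10 kb windows around a fixed causal count cover a much larger share of
a 10k-SNP study than of an 80k-SNP chromosome). Sensitivity gains track
measured informativeness, so at this scale D gains more than B — the
opposite ordering to a haplotype-based study. Second, the distance between
the functional-window edge (25 SNPs) and the not-associated boundary
(22 SNPs at ρ = 0.9) is thin, so scenario E's FDR inflation, while clearly
present, flows through a narrower channel than with real LD. MAF structure,
genotyping error and imputation noise are not modelled; passing tests say
nothing about those.

## Numerical choices and problem sizes

- Library default grid 501×501; the replicate-level simulation studies use
  201×201, where the v-values agree with the fine grid to well within the
  Monte-Carlo noise of 100 replicates.
- Denominator floor 10⁻¹²: grid nodes with smaller joint tail inherit the
  nearest valid value toward smaller z (prevents spikes in empty corners).
- v-values floored at 10⁻³⁰⁰ and capped at 1.
- Test suite and acceptance script problem sizes: 10,080 SNPs per study;
  100 replicates per scenario in `scripts/acceptance.py`, 15–25 in the
  statistical test suite.
- Degenerate inputs: p = 1 is allowed (z = 0), p = 0 rejected (infinite Z);
  fewer than 10 fitting points, zero-variance covariates, and all-missing
  MAF are errors; fewer than 7 distinct covariate values skip the spline
  correction with a warning.

## Calibration at small m

Under the global null the v-values are asymptotically uniform, and BH on
them makes no false discoveries in practice. The Kolmogorov–Smirnov
distance of v from uniform shrinks with study size (mean over replicates:
≈0.049 at m = 2,500; ≈0.039 at m = 5,000; ≈0.026 at m = 20,000; the pure
sampling floor is 0.86/√m). The residual at small m comes from the
conditional covariate profile of the joint tail being estimated from few
effective tail points — a finite-sample property of the kernel estimator,
not of the contour construction, and it is concentrated in the
non-significant region (large p). FDR control at conventional thresholds is
unaffected (see the simulation studies).

## Known limitations

- Discrete or binary covariates are out of scope; the KDE assumes a
  continuous `q`.
- A single covariate orientation is assumed: covariates whose *both*
  extremes are enriched for signal cannot be exploited.
- The v-value of a SNP more extreme than anything in the KDE fitting subset
  is conservative: its level freezes at the running minimum near the data
  edge, preserving discovery but not the ranking among such SNPs.
- Iterating over strongly correlated covariates inflates significance by
  design of the method; the pipeline warns but does not stop.
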