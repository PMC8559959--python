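# flexcfdr

Covariate-informed FDR control for GWAS summary statistics: a flexible
conditional false discovery rate (cFDR) that leverages a continuous auxiliary
covariate — functional genomic scores, ChIP-seq fold changes, p-values from a
related trait — alongside the p-values of a principal trait, and returns
**v-values** that behave like p-values and feed directly into
Benjamini–Hochberg.

## Who this is for

GWAS analysts who have per-SNP auxiliary data from an arbitrary continuous
distribution and want to boost discovery without giving up FDR control.
Unlike grouping/weighting schemes, no binning or thresholding of the
covariate is required, and the method can be applied iteratively to stack
several covariates.

## The method

For each SNP with two-sided p-value `p` (absolute Z-score `z_p`) and
covariate `q`, the conditional FDR is estimated as

```
cfdr(p, q) = p · Pr(Q ≤ q | H0) / Pr(P ≤ p, Q ≤ q)
```

- the joint probability comes from a bivariate kernel density estimate of
  `(|Z|, Q)` with a product Gaussian kernel, fitted on an LD-independent
  subset of SNPs and mirrored across `|Z| = 0` (Silverman's reflection) to
  remove boundary bias;
- `Pr(Q ≤ q | H0)` is obtained by weighting that density with an Efron-style
  local false discovery rate `Pr(H0 | Z = z)` (Poisson regression of mirrored
  Z-score histogram counts on a natural cubic spline, theoretical N(0,1)
  null) and integrating out Z;
- each observed pair is mapped to its **L-region**
  `{(p', q') : cfdr(p', q') ≤ cfdr(p, q)}`, and the v-value is the
  probability that a fresh null pair (P uniform, Q from its null law,
  independent) falls inside it:

```
v(p, q) = ∫ p_L(q') f0(q') dq'
```

where `p_L(q')` is the rightmost p-boundary of the region in each covariate
row. Under the null v-values are approximately uniform, so `BH(v)` controls
the FDR. Sparse-data adaptations: left-censoring of the covariate's thin
left tail and a spline correction that pulls back artefactually inflated
v-values.

## Worked example

Simulate a 10,080-SNP study (24 LD blocks, AR(1) ρ = 0.9) with a bimodal
mixture-normal covariate, run one iteration, and score it against the
built-in truth labels:

```
flexcfdr simulate --output sim.tsv --truth-output truth.tsv --scenario D --seed 7
flexcfdr run --input sim.tsv --output out.tsv --q-cols q1 --indep-col indep --seed 7
flexcfdr evaluate --results out.tsv --truth truth.tsv --fdr-col fdr_iter1
```

which prints (numbers from this exact command sequence):

```
wrote 10080 SNPs to sim.tsv
wrote 10080 rows to out.tsv
 sensitivity  specificity  fdr_proxy  n_discoveries  sens_spec_threshold  fdr_threshold
    0.213333          1.0   0.021569            510             0.000005           0.05
```

Read: 21.3% of truly associated SNPs (r² ≥ 0.8 with a causal variant) are
discovered at the stringent FDR threshold 5×10⁻⁶; of the 510 discoveries at
the raised threshold FDR ≤ 0.05, 2.2% are truly not-associated (r² ≤ 0.01
with every causal variant) — within the nominal 5% — and specificity is ~1.

The same pipeline is available in-process:

```python
from flexcfdr import flexible_cfdr
res = flexible_cfdr(p, q, indep_mask)   # res.v, res.level, res.censored, ...
```

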