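# epichron

Chronological aging trends and breakpoint detection in age-structured genomic
count data.

Bulk ATAC-seq and RNA-seq studies of aging profile a cohort of donors whose
ages span the adult lifespan, producing a feature × sample count matrix
(chromatin-accessibility peaks or genes) plus per-sample metadata (age, sex,
batch, library size). Two questions drive the analysis this package
implements:

1. **Which features trend with chronological age**, rather than fluctuate like
   stationary noise — and what trajectory shapes (closing with age, opening
   early, opening late, sex-opposed) do they share?
2. **At which ages does change happen abruptly?** Gradual drift punctuated by
   short "breakpoint" periods of rapid remodeling is a hallmark of immune
   aging; locating those periods requires comparing the epigenomic state of
   donors just younger vs. just older than every candidate age.

`epichron` provides the full chain as a library with a thin CLI:

- **qc** — peak filtering (max raw count > 20 in ≥ 1 sample, max CPM ≤ 500,
  blacklist exclusion), discovery of *benchmark peaks* (|log₂FC| between age
  groups in the bottom quartile, maximum normalized count in the top decile,
  called in ≥ 90 % of samples) and flagging of samples that call < 92.5 % of
  them.
- **normalize** — TMM scaling factors (doubly trimmed, precision-weighted
  mean of M-values; matches edgeR to ~1e-12 on test data), CPM, per-feature
  negative-binomial GLMs with moderated dispersions and likelihood-ratio
  tests, BH FDR, model-adjusted values (log₂ CPM minus nuisance-model fit)
  and residual-PCA surrogate covariates.
- **trajectory** — per-(sex, age) averaged series, stepwise-AIC ARIMA(p, D, q)
  selection with KPSS differencing (D ≤ 2); a feature carries a significant
  chronological trend iff **D > 0 and p + q > 0**; fitted trajectories are
  z-scored and clustered by best-of-n-restarts k-means, with an
  enrichment-guided choice of k over the 2–15 grid and collapse of clusters
  with identical enrichment signatures.
- **breakpoints** — per cluster: PCA to 3 components, one-way MANOVA (Pillai
  trace) comparing donors in [t−w, t) vs. (t, t+w] at every integer age t for
  window spans w = 10…20 years; each −log₁₀ p curve is LOESS-smoothed under
  bandwidths 0.25…0.75 (step 0.05), the 11 smoothed p-values per age are
  combined by Fisher's method (χ², df = 22), the combined curve is smoothed
  again, and local maxima passing a significance and a 25 %-of-global-max
  prominence screen are grouped across window spans by a 1-D Gaussian
  mixture (BIC) into breakpoint intervals (median age + range).
- **annotate** — chromHMM-style conflict resolution (priority order plus the
  proximal/distal promoter-vs-enhancer rule at 1 kb), six pooled meta-states,
  cell/lineage specificity, nearest-TSS assignment within 100 kb, and
  hypergeometric gene-set enrichment with BH adjustment.
- **synthetic** — a negative-binomial cohort generator with planted trend
  clusters, breakpoints, batch shifts, library-size variation and corrupted
  samples, so every stage can be validated against known ground truth.

## Worked example

```python
import pandas as pd
from epichron import synthetic as syn, normalize, breakpoints as bp
from epichron.cohorts import breakpoint_benchmark_spec, BREAKPOINT_TRUTH

counts, samples, truth = syn.simulate_cohort(breakpoint_benchmark_spec(seed=1))
adj = normalize.model_adjusted_values(counts, pd.DataFrame(index=counts.columns))

cols = samples.index[samples["sex"] == "F"]
ages = samples.loc[cols, "age"].to_numpy()
members = truth.index[truth["cluster"] == "down_0"]   # closes rapidly near 40
ivs = bp.detect_breakpoints(adj.loc[members, cols], ages, bp.ScanConfig(seed=1))
for iv in ivs:
    print(f"breakpoint median {iv.median_age:.1f}  "
          f"range [{iv.age_min:.0f}, {iv.age_max:.0f}]  p={iv.combined_p:.2e}")
```

Output:

```
breakpoint median 39.0  range [38, 39]  p=8.47e-89
```

The cluster was simulated with a rapid loss of accessibility centered at age
40; the detector reports one interval whose median age (39) falls within a
year of the truth, pooled from the maxima found at each window span, with the
smallest Fisher-combined p-value among the supporting spans.

The same chain runs from the shell:

```bash
epichron simulate --seed 1 --outdir out/
epichron run-all --config config.yaml
```

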