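# skewlap

Skew-Laplace fitting and critical-sample-size (N_crit) goodness-of-fit
assessment for flow-cytometry scatter and microbial cell-size distributions.

Forward-scatter (FS) and side-scatter (SS) histograms of axenic microbial
cultures, and to a lesser degree electronically sized cell diameters, are
well described by the **skew-Laplace (asymmetric Laplace) distribution**

```
f(x; mu, alpha, beta) = (alpha*beta/(alpha+beta)) * exp(-alpha*(mu - x))   x <= mu
                      = (alpha*beta/(alpha+beta)) * exp(-beta*(x - mu))    x >  mu
```

with location `mu` and left/right tail rates `alpha, beta > 0`: on a
natural-log vertical axis the density is two straight lines with slopes
`+alpha` and `-beta` meeting at `mu`. The family maximises differential
entropy among laws with fixed `E[X - mu]` and `E[|X - mu|]`, and its three
parameters summarise a whole scatter histogram for rapid comparison between
strains, growth phases and sorting gates. `skewlap` is aimed at
microbiologists and cytometrists who want that summary plus an honest
verdict on whether the model actually fits.

The package provides:

* exact closed-form math (pdf, cdf, quantile, moments, entropy, sampling,
  log-linear representation) plus a shifted-gamma comparison density;
* the **global maximum-likelihood fit** on linear or natural-log scale
  ("log-skew-Laplace" for strictly positive sizes), via an order-statistic
  profile scan with closed-form inner solutions — exact, O(n log n);
* the **N_crit statistic**: events are binned into 40 equal-count intervals
  and `N_crit = chi2_{k-m-1;0.95} / sum_i (r_i - p_i)^2/p_i` estimates the
  sample size at which the observed lack of fit would become detectable at
  the 5% level, classified as excellent (>900), satisfactory (500-900],
  acceptable (250-500] or unacceptable (<=250);
* q-q and log-frequency diagnostic surfaces and plots;
* seeded synthetic generators (cytometer-like skew-Laplace channels,
  log-skew-Laplace cell sizes, an aquatic-community mixture that no single
  skew-Laplace fits, optional ADC quantization) with named presets;
* readers for FCS 3.0/3.1 and CSV/TSV event files, tidy CSV/JSON reports,
  and a `skewlap` command-line interface (`fit`, `batch`, `simulate`,
  `report`).

## Worked example

Simulate a strongly right-tailed side-scatter sample (cocci at 6 h of batch
growth, `mu=424, alpha=0.134, beta=0.009` on the channel scale), then fit
and score it:

```python
from skewlap import analyze_sample, generate, preset

values, prov = generate(preset("saureus_ss_6h", n=50_000, seed=1))
report = analyze_sample(values, "saureus_batch_6h", "SS")
p = report.best_fit.params
print(f"best scale : {report.best_scale} ({report.marker})")
print(f"mu = {p.mu:.2f}  alpha = {p.alpha:.4f}  beta = {p.beta:.4f}")
g = report.best_gof
print(f"N_crit = {g.n_crit:.0f}  (D = {g.discrepancy:.2e}, chi2_95[df={g.df}] = {g.chi2_crit:.3f})")
print(f"fit class = {g.fit_class}")
```

prints

```
best scale : linear (*)
mu = 423.93  alpha = 0.1340  beta = 0.0090
N_crit = 78247  (D = 6.52e-04, chi2_95[df=36] = 50.998)
fit class = excellent
```

The fit recovers the generating triple almost exactly; `alpha/beta ≈ 15`
quantifies the long right tail (high-granulosity cells). Both scales are
always attempted and the larger N_crit wins, marked `*` (skew-Laplace) or
`**` (log-skew-Laplace) in reports. On real data the binned discrepancy `D`
picks up model error as well as sampling noise, so N_crit values in the
hundreds-to-thousands are typical of good instrument fits, while the
`aquatic` mixture preset — a trimodal community size spectrum — lands firmly
in the unacceptable class on both scales.

The same run from the shell:

```sh
skewlap simulate saureus_ss_6h --n 50000 --seed 1 --out ss.csv
skewlap fit ss.csv --out results/ --plots
```

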