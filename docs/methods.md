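# Methods

## The model

The skew-Laplace (asymmetric Laplace) distribution glues two exponential
tails at a location `mu`:

```
f(x) = C * exp(-alpha*(mu - x))   for x <= mu
f(x) = C * exp(-beta*(x - mu))    for x >  mu,      C = alpha*beta/(alpha+beta)
```

with tail rates `alpha, beta > 0` in inverse data units. Mean and variance
are `mu - 1/alpha + 1/beta` and `1/alpha^2 + 1/beta^2`; when `alpha = beta`
the law is symmetric and `mu` is the mean. Its differential entropy is
`1 - ln C` nats, the maximum among continuous laws with given first signed
and absolute moments about `mu` — the theoretical motivation for using it on
scatter and size histograms, whose log-frequency plots are empirically close
to two straight lines (slopes `+alpha` and `-beta`).

Tail rates are stored as positive numbers throughout; the negative values
sometimes quoted for the right tail are the slope `-beta` of the right
log-frequency branch, not a parameter sign.

For strictly positive measurements (cell diameters in microns) the
**log-skew-Laplace** variant models `ln X` as skew-Laplace; fitting applies
the same estimator to the natural log of the data and reports parameters on
the log scale.

A shifted-gamma density `(m - m0)^gamma * exp(-beta*m) / U` (minimum viable
size `m0`) is included as the classical maximum-entropy biomass model. Its
skewness is `2/sqrt(gamma+1)` — always positive — which is why it cannot
describe the negatively skewed scatter histograms the skew-Laplace handles.
(It is implemented over `scipy.stats.gamma` with shape `gamma+1`, location
`m0`, scale `1/beta`.)

## Maximum-likelihood estimation

The log-likelihood is

```
l(mu, alpha, beta) = n ln C - alpha * sum_{x<=mu}(mu - x) - beta * sum_{x>mu}(x - mu).
```

For fixed `mu`, with `A = mean (mu - x)+` and `B = mean (x - mu)+`, the
inner maximum is closed form: `alpha = 1/(A + sqrt(AB))`,
`beta = 1/(B + sqrt(AB))`, and the profiled log-likelihood reduces to
`-n * (1 + 2 ln(sqrt(A) + sqrt(B)))`. Between consecutive order statistics
`A` and `B` are affine in `mu`, so `sqrt(A) + sqrt(B)` is concave on each
segment and minimised at a segment endpoint: the global MLE of `mu` lies at
an observed value. The fit therefore scans all distinct sample values with
prefix sums — an exact global optimum in O(n log n), no iterative optimiser
and no starting values. The test suite verifies equality with an exhaustive
brute-force maximization (numeric 2-D inner optimisation at every candidate
mode) on small samples.

Conventions and degenerate inputs:

* ties broken toward the smallest candidate mode attaining the maximum;
  events exactly at `mu` belong to the left branch (`x <= mu`), so heavily
  quantized channel data are handled exactly;
* minimum sample size 40 events (one per standardized interval); smaller
  inputs raise rather than silently fit;
* all-identical samples, and samples whose every candidate mode has data on
  one side only, raise as degenerate; if the likelihood is maximised only in
  the one-sided limit (at the sample extremes, where a tail rate diverges)
  the best interior candidate is returned with `converged=False`;
* the estimator is exactly equivariant: shifting data shifts `mu`, scaling
  by `s` scales `mu` and divides both rates by `s`.

## Goodness of fit: N_crit

Events are binned into `k = 40` intervals, as count-homogeneous as possible:
interior edges at the `i/k` empirical quantiles, outer bins open-ended so
every fitted bin probability `p_i` (CDF increments at the edges) is positive
and sums to one. The discrepancy `D = sum_i (r_i - p_i)^2 / p_i` against the
sample proportions `r_i` gives

```
N_crit = chi2_{k-m-1; 0.95} / D,       m = 3 estimated parameters,
```

interpretable as the sample size at which this lack of fit would be
rejected at the 5% level: larger is better, D = 0 gives +inf. Classes:
excellent (> 900), satisfactory (500, 900], acceptable (250, 500],
unacceptable [0, 250] — boundaries belong to the lower class. The
thresholds are a working convention, not a derived quantity, and are
overridable in the pipeline and CLI.

Numerical choices: the chi-square 0.95 quantile is computed in double
precision via the regularized incomplete-gamma inverse (`scipy.stats.chi2`);
duplicate quantile edges from tied data are merged, the realized `k` is
used in `df = k - m - 1`, and the merge is flagged; an equal-width binning
dialect is available for instrument-channel-style histograms. Degrees of
freedom are fixed at `k - m - 1`; with 40 intervals and 3 parameters the
choice within `[k-m-1, k-1]` hardly moves the 0.95 quantile.

Diagnostics: q-q surfaces pair the sorted sample with model quantiles at
plotting positions `(j - 0.5)/n`; log-frequency surfaces plot
`ln(proportion/width)` at interior bin midpoints against the two fitted
lines (empty bins skipped and flagged).

## Synthetic data

The generators emulate the statistical structure of the instruments'
event-level output, not their optics or electronics:

* **Scatter presets** (`*_fs_*`, `*_ss_*`): skew-Laplace draws on the
  channel scale at fitted triples for three morphologically distinct
  organisms (rods, cocci, endospore-formers) at 6/20/36 h of batch growth —
  locations in the hundreds of channels, rates 0.006–0.17 per channel.
* **Cell-size presets** (`*_multisizer_*`): log-skew-Laplace draws whose
  natural log is skew-Laplace at the published triple (micron scale,
  rates ~2–19 per log-micron).
* **`aquatic`**: a three-component Gaussian mixture on log size (weights
  0.5/0.3/0.2, means −0.6/0.3/1.4 ln-µm, sds 0.15/0.20/0.25, component
  separation ≥ 2 sds), exponentiated to positive sizes — a fixture
  convention for a multimodal community spectrum that no single skew-Laplace
  fits, not an estimate from any real lake or coastal dataset.
* Optional **quantization** maps draws onto an evenly spaced integer channel
  grid with clipping (default 10-bit, 0–1023), mimicking ADC output; with
  ≥ 1024 channels it moves the recovered rates by well under 2%.

Defaults `n = 50,000` events and an explicit per-spec seed; there is no
global random state, and sampling uses inverse-CDF on 53-bit dyadic uniforms
so identical specs are bit-identical across platforms.

What passing tests show — and do not show — about real data: the generators
draw *from the model family itself* (or from a deliberately non-Laplace
mixture), so recovery and classification results validate the estimator,
the N_crit arithmetic and the class dichotomy, not the biological claim
that any particular instrument's output is skew-Laplace. Real cytometer
data add effects the fixtures omit: doublets and debris, saturated end
channels, log-amplifier transfer curves, correlated FS/SS. Input values are
analysed as-is; whether they are raw or amplifier-linearized channels is
the user's responsibility to know.

## Pipeline and reporting

Per sample the pipeline fits the linear scale always and the log scale
whenever all events are strictly positive (otherwise the skip is recorded),
computes N_crit for each, and reports the scale with the larger N_crit,
marked `*` (skew-Laplace) or `**` (log-skew-Laplace). Reports are a tidy
CSV (one row per sample × channel) plus a full-detail JSON; `+inf` N_crit
serializes as the string `"inf"`. File inputs are FCS 3.0/3.1 (a minimal
built-in list-mode reader: single TEXT segment, float or uniform-width
integer data) or delimited text with one named/first numeric column.

## Problem sizes

Simulation-based tests use 50,000–200,000 events (seconds on one CPU);
oracle-equivalence tests use n ≤ 200 where exhaustive numeric maximization
is practical; the acceptance script uses 100,000 events per target.

## Known limitations

* No standard errors or confidence intervals for the fitted parameters.
* No mixture, censored or weighted likelihoods; no multivariate FS×SS model;
  the four-parameter hyperbolic family is deliberately out of scope.
* N_crit is a descriptive rescaling of the chi-square statistic, not a
  p-value; its class thresholds are conventional.
* The FCS reader covers the common list-mode subset only (no bit-packed
  integers, multi-dataset files, or analysis segments).
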