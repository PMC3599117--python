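# Methods

## Problem and pipeline

Public repositories hold expression data measured on thousands of different
microarray designs. Matrices from two chips cannot be compared directly:
they use manufacturer-specific probe identifiers, different recorded scales
(linear, log2, log10), different scanner analog-digital-converter depths,
and — even after those are reconciled — systematic non-biological
differences between platforms (batch effects) that typically dwarf the
biology.

`crossarray` integrates such datasets in seven steps, the first two
requiring user knowledge of the data:

1. **Load** each per-platform matrix as a feature x sample table
   (`datamodel_io`). Annotation arrives as a plain two-column probe ->
   common-identifier map rather than a live annotation database; this keeps
   the identical mapping semantics while removing any network dependency.
2. **Harmonize** scale and precision (`harmonize`). All data go to log2.
   Bit depths are reconciled by multiplying log2 values by the ratio of
   target to source bits, implemented literally as `x / source * target`
   (e.g. 20-bit data: `x / 20 * 16`), which makes the operation exactly
   invertible and bitwise reproducible. When the depth is unknown it is
   detected as the smallest allowed depth (12/14/16/20) whose range
   `0 .. 2^b - 1` covers the maximum observed linear intensity — a
   documented stand-in rule for scanner metadata that is often missing.
3. **Annotate** probes with common identifiers (gene symbols by default);
   unmapped probes are dropped and counted. A probe mapping to two
   identifiers is an error, not a fan-out: canonical annotation gives one
   identifier per probe, and fan-out would inflate overlap statistics.
4. **Collapse** redundant probes per identifier: median (default), mean, or
   Tukey median polish (overall + column effects of the probe x sample
   block; single-probe groups pass through). Median of an even-sized group
   is the arithmetic midpoint. Missing values are excluded per cell.
5. **Intersect**: keep only identifiers present on every platform, sorted
   lexicographically for deterministic output.
6. **Merge** columns in input order; every sample carries its batch label;
   per-batch original/collapsed feature counts are kept as provenance, and
   the coverage report prints `merged / collapsed` as a percentage rounded
   to one decimal.
7. **Remove batch effects** by one of seven methods, or return the merged
   matrix unadjusted.

## The empirical Bayes correction (default)

Per gene g, sample j in batch i:

    Y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * epsilon_ijg,
    epsilon_ijg ~ N(0, 1)

`alpha_g` is the grand mean, `X beta_g` optional covariate effects
(supervised mode), `gamma_ig` an additive and `delta_ig` a multiplicative
batch effect. The fit:

1. Least squares with batch indicators constrained to a batch-size-weighted
   zero sum, plus one-hot covariates (first level dropped). A rank-deficient
   design (batch confounded with a covariate) is an error.
2. Pooled variance `sigma2_g` = mean squared residual (denominator N).
3. Standardize `Z = (Y - alpha - X beta) / sigma`.
4. Per batch: `gamma_hat_ig` = gene mean of Z, `delta2_hat_ig` = gene
   variance of Z with the 1/n denominator. The 1/n choice (rather than
   1/(n-1)) follows the original formulation of the method and gives the
   exact identity property: two identical batches yield
   `gamma_hat = 0`, `delta2_hat = 1` and an adjustment that returns the
   input unchanged.
5. Hyperparameters by the method of moments across genes: normal prior
   moments `gamma_bar_i`, `tau2_i` for the location effects; inverse-gamma
   parameters `lambda_i = m^2/s^2 + 2`, `theta_i = m(lambda_i - 1)` from the
   mean m and variance s^2 of `delta2_hat`. Degenerate spreads
   (`tau2 = 0` or `s^2 = 0`, as with duplicated batches) disable shrinkage
   of the corresponding parameter instead of producing an infinite prior.
6. Parametric fixed-point iteration for the shrunken `gamma_star`,
   `delta2_star`; convergence when the maximum absolute parameter change
   falls below 1e-4, at most 200 iterations (non-convergence is an error
   naming the worst gene; in practice 3–6 iterations suffice).
7. Adjust: `Y* = sigma_g (Z - gamma_star) / sqrt(delta2_star) + alpha_g +
   X beta_g`.

Only the parametric prior variant is implemented; it is deterministic and
testable against a step-by-step reference evaluation, which the test suite
contains as an independently coded oracle.

What the shrunken parameters estimate: `gamma_star_ig` targets the
*identifiable* location effect — the batch effect centered by the
size-weighted across-batch mean, in units of `sigma_g` — and
`delta2_star_ig` targets the batch variance *relative to the pooled
variance*. Recovery metrics in the tests and the acceptance script compare
against exactly these estimands (de-standardized by `sigma_g` for gamma);
comparing raw uncentered effects would bound the attainable correlation at
`1/sqrt(2)` for two batches regardless of data quality.

## The six alternatives

* **MC** (mean centering): per gene, every batch is shifted onto the gene's
  grand mean.
* **QN** (quantile normalization): each column's rank-k value becomes the
  across-column mean of the k-th order statistics; tied cells receive the
  mean of their tied rank-values.
* **GQ** (gene quantile normalization): per gene, a value's within-batch
  quantile rank `(rank - 0.5)/n` (average ranks for ties; 0.5 for singleton
  batches) is mapped through the gene's pooled empirical quantile function.
  The pooled quantile uses the inverted-CDF convention, so a single batch
  maps exactly onto its own order statistics. The cited method is named but
  not specified in the source literature; this concrete rule is ours.
* **MRS** (median rank scores): the reference batch (largest; ties broken
  lexicographically) defines a per-rank median profile; every non-reference
  sample's rank-k value is replaced by profile[k].
* **QD** (quantile discretization): per sample, values fall into q
  equal-frequency bins (default q = 8), bin = `ceil(q * rank/n)` with
  average ranks for ties; an all-constant sample is degenerate and assigned
  bin 1.
* **NorDi** (normal discretization): per sample, iterated two-sided Grubbs
  tests (alpha = 0.05) drop extreme outliers; the retained values' mean m
  and standard deviation s set thresholds `m ± z(1 - alpha) s`
  (alpha = 0.05), labelling each original value -1/0/+1. The defaults are
  declared substitutes for the cited method's unpublished ones.

QD and NorDi emit integer codes; re-adjusting their output with a
continuous method is refused, since mixing discrete codes with
location/scale corrections is undefined.

## QC

Euclidean sample-sample distances; UPGMA (average linkage) clustering with
a deterministic tie-break (the pair containing the lexicographically
smallest member ID merges first) and Newick export whose branch lengths
derive from merge heights; PCA of the per-gene mean-centered matrix
(centering only, no scaling — standard expression-PCA practice), with each
component's sign fixed so its largest-magnitude loading is positive.
UPGMA and median polish are implemented in-package because no installed
library exposes the deterministic tie-break or the polish summary; scipy's
average linkage serves as an independent oracle in the tests on tie-free
inputs.

## Synthetic studies

The generator emulates a three-study stem-cell comparison: groups
fibroblast / ESC / iPSC measured on three platforms, two recording linear
16-bit intensities and one log2 20-bit values, with per-platform probe
designs (1–3 probes per gene), incomplete gene coverage and partially
unannotated probes. Defaults (chosen once as realistic study conditions):

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | genes in the universe |
| groups | 3 | biology groups, 4 samples each per platform |
| de_fraction / effect_size | 0.10 / 2.0 | genes shifted per group, log2 units |
| baseline | U(4, 12) | log2 expression on the 16-bit scale |
| sd_gamma | 1.0 | additive batch effect sd (strong: batch >> biology) |
| delta2 | InvGamma(3, 2) | multiplicative batch effect (mean 1) |
| noise_sd | 0.5 | residual sd multiplying delta |
| probe_offset_sd | 0.2 | per-probe constant offset |
| fraction present / unmapped | 0.85 / 0.05 | platform coverage, map gaps |

Batch effects are injected exactly under the EB model, so parameter
recovery is well-posed; a `batch_effect_model: lognormal` switch draws
centered shifted-lognormal location effects to probe prior
misspecification. All randomness flows through one `numpy` generator seeded
from the config: identical seeds give bit-identical studies.

What the simulation does *not* emulate: scanner image artifacts, probe
sequence and GC effects, intensity-dependent (nonlinear) platform
differences, correlated gene modules, and annotation errors beyond simple
missingness. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on any particular real
study.

`evaluate_correction` scores a before/after pair by adjusted Rand index of
UPGMA cuts against batch and biology labels, silhouette with respect to
batch, and the mean per-gene batch F statistic.

## Numerical and design choices

* Tables are UTF-8 tab-delimited; missing values are the literal `NA`;
  identifiers are case-sensitive. Reading uses a correctly rounded string to
  float conversion so write/read round trips are bit-exact.
* Feature order is lexicographic and sample order is input order everywhere,
  making CLI outputs byte-identical across reruns.
* The interactive sample-info step is replaced by write-template-and-exit
  plus `--assume-edited`, a scriptable equivalent of prompting the user.
* Problem sizes in the test suite and acceptance script (2000-gene studies,
  2 x 20-sample recovery harness) are desk-scale study conditions under
  which every contract is measurable in seconds.

## Known limitations

* Only the parametric EB prior family is available.
* Harmonization assumes the provided scale/precision hints are correct;
  empirical detection sees only the dynamic range, so e.g. heavily
  background-subtracted data can be assigned a too-small depth.
* GQ/QD/NorDi concrete rules and defaults are this package's documented
  fixings of methods the literature names without full specification.
* Median polish uses at most 10 sweeps with an absolute-residual
  convergence check (tolerance 1e-6 relative), adequate for the small
  probe groups it is applied to.
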