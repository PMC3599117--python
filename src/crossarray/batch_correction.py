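"""Cross-platform batch-effect removal.

Seven methods operate on a merged multi-batch expression matrix:

* ``EB``    — empirical Bayes location/scale adjustment (default).  Per gene
  g, sample j of batch i the model is ``Y_ijg = alpha_g + X beta_g +
  gamma_ig + delta_ig * epsilon_ijg``: additive batch effects ``gamma`` and
  multiplicative effects ``delta`` are estimated on standardized data,
  shrunk toward parametric priors (normal for gamma, inverse-gamma for
  delta^2) fitted across genes by the method of moments, and removed.
  With covariates in the design (supervised mode) biology encoded by the
  covariates is protected during adjustment.
* ``MC``    — per-gene mean centering of every batch onto the grand mean.
* ``QN``    — classic full quantile normalization over all samples.
* ``GQ``    — gene quantile normalization: per gene, within-batch quantile
  ranks are mapped through the gene's pooled empirical quantile function.
* ``MRS``   — median rank scores: every non-reference sample's rank-k value
  is replaced by the reference batch's rank-k median.
* ``QD``    — quantile discretization into q equal-frequency bins per sample.
* ``NorDi`` — per-sample normal discretization into {-1, 0, +1} after
  iterative Grubbs outlier removal.
* ``NONE``  — return the merged data unadjusted.

QD and NorDi output integer codes; re-adjusting discretized data with a
continuous method is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import MergedDataset, SampleInfoTable
from .exceptions import NumericalError, ValidationError

__all__ = [
    "CORRECTION_METHODS",
    "EBParams",
    "remove_batch_effects",
    "combat_eb",
    "mean_center",
    "quantile_normalize",
    "gene_quantile_normalize",
    "median_rank_scores",
    "quantile_discretize",
    "nordi",
]

CORRECTION_METHODS = ("EB", "MC", "QN", "GQ", "MRS", "QD", "NorDi", "NONE")

_CONTINUOUS_METHODS = {"EB", "MC", "QN", "GQ", "MRS"}


# ---------------------------------------------------------------------------
# empirical Bayes (ComBat-style)
# ---------------------------------------------------------------------------


@dataclass
class EBParams:
    """Fitted empirical Bayes model parameters.

    Arrays indexed by gene (rows of the input); per-batch quantities are
    DataFrames with one column per batch.  ``gamma_hat``/``delta2_hat`` are
    the raw per-batch estimates on standardized data, ``gamma_star``/
    ``delta2_star`` their shrunken counterparts; ``gamma_bar``/``tau2`` are
    the normal prior moments and ``lambda_``/``theta`` the inverse-gamma
    prior parameters, one per batch.
    """

    batches: list[str]
    alpha: pd.Series
    beta: pd.DataFrame
    sigma2: pd.Series
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series
    tau2: pd.Series
    lambda_: pd.Series
    theta: pd.Series
    n_iterations: dict[str, int] = field(default_factory=dict)


def _batch_design(batch_of_sample: pd.Series) -> tuple[list[str], np.ndarray]:
    batches: list[str] = []
    for b in batch_of_sample:
        if b not in batches:
            batches.append(b)
    X = np.zeros((len(batch_of_sample), len(batches)))
    for j, b in enumerate(batch_of_sample):
        X[j, batches.index(b)] = 1.0
    return batches, X


def _covariate_design(design_covariates: pd.DataFrame | None) -> np.ndarray | None:
    """One-hot encode covariate columns, dropping each first level."""
    if design_covariates is None or design_covariates.shape[1] == 0:
        return None
    cols = []
    for name in design_covariates.columns:
        levels = list(pd.unique(design_covariates[name].astype(str)))
        for lev in levels[1:]:
            cols.append((design_covariates[name].astype(str) == lev).to_numpy(float))
    if not cols:
        return None
    return np.column_stack(cols)


def _moments_invgamma(d2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma parameters from per-gene delta2_hat."""
    m = float(np.mean(d2))
    s2 = float(np.var(d2, ddof=1)) if d2.size > 1 else 0.0
    if s2 <= 0:
        return np.inf, np.inf  # degenerate prior -> no shrinkage
    lam = (2.0 * s2 + m * m) / s2
    theta = (m * s2 + m ** 3) / s2
    return lam, theta


def combat_eb(
    values: pd.DataFrame,
    batch_of_sample: pd.Series,
    design_covariates: pd.DataFrame | None = None,
    conv_tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[pd.DataFrame, EBParams]:
    """Parametric empirical Bayes batch adjustment of a gene x sample matrix.

    Fits the per-gene linear model (batch indicators constrained to a
    size-weighted zero sum, plus optional one-hot covariates), standardizes,
    estimates per-batch location/scale effects, shrinks them toward
    moment-matched priors via the parametric fixed-point iteration, and
    returns the adjusted matrix together with all fitted parameters.
    """
    if values.isna().to_numpy().any():
        raise ValidationError("EB adjustment requires a complete matrix (no missing values)")
    batch_of_sample = pd.Series(batch_of_sample, index=values.columns)
    batches, Xb = _batch_design(batch_of_sample)
    if len(batches) < 2:
        raise ValidationError("EB adjustment needs at least two batches")
    n_per_batch = Xb.sum(axis=0)
    if (n_per_batch < 2).any():
        small = [b for b, n in zip(batches, n_per_batch) if n < 2]
        raise ValidationError(
            f"every batch needs >= 2 samples for EB; too small: {', '.join(small)}"
        )
    Xc = _covariate_design(design_covariates)
    design = Xb if Xc is None else np.hstack([Xb, Xc])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("batch confounded with covariate: design matrix is rank deficient")

    Y = values.to_numpy(dtype=float)  # genes x samples
    G, N = Y.shape
    I = len(batches)

    # (1) least-squares fit; batch effects sum to zero weighted by batch size
    B, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # (I+C) x G
    w = n_per_batch / N
    alpha = w @ B[:I]  # grand mean per gene
    stand_mean = np.tile(alpha, (N, 1)).T
    beta = B[I:]
    if Xc is not None:
        stand_mean = stand_mean + (Xc @ beta).T

    # (2) pooled residual variance (denominator N)
    resid = Y - (design @ B).T
    sigma2 = np.mean(resid ** 2, axis=1)
    if np.any(sigma2 <= 0):
        raise NumericalError("zero pooled variance: some genes are constant across all samples")
    sigma = np.sqrt(sigma2)

    # (3) standardize
    Z = (Y - stand_mean) / sigma[:, None]

    gamma_hat = np.empty((G, I))
    delta2_hat = np.empty((G, I))
    gamma_star = np.empty((G, I))
    delta2_star = np.empty((G, I))
    gamma_bar = np.empty(I)
    tau2 = np.empty(I)
    lambda_ = np.empty(I)
    theta = np.empty(I)
    n_iterations: dict[str, int] = {}

    for i, b in enumerate(batches):
        cols = Xb[:, i] == 1.0
        Zi = Z[:, cols]
        ni = Zi.shape[1]
        # (4) per-batch estimates; delta2_hat uses the 1/n denominator so
        # that identical batches give delta2_hat == 1 exactly
        g_hat = Zi.mean(axis=1)
        d2_hat = np.mean((Zi - g_hat[:, None]) ** 2, axis=1)
        # (5) hyperparameters by the method of moments
        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1)) if G > 1 else 0.0
        lam, th = _moments_invgamma(d2_hat)
        # (6) parametric fixed-point iteration
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        if t2 <= 0 and not np.isfinite(lam):
            n_iterations[b] = 0  # both priors degenerate: no shrinkage
        else:
            converged = False
            for it in range(1, max_iter + 1):
                if t2 > 0:
                    g_new = (ni * t2 * g_hat + d2_star * g_bar) / (ni * t2 + d2_star)
                else:
                    g_new = np.full(G, g_bar)
                if np.isfinite(lam):
                    sum2 = ni * (d2_hat + (g_hat - g_new) ** 2)
                    d2_new = (th + 0.5 * sum2) / (ni / 2.0 + lam - 1.0)
                else:
                    d2_new = d2_hat
                change = max(
                    float(np.max(np.abs(g_new - g_star))),
                    float(np.max(np.abs(d2_new - d2_star))),
                )
                g_star, d2_star = g_new, d2_new
                if change < conv_tol:
                    converged = True
                    n_iterations[b] = it
                    break
            if not converged:
                worst = int(np.argmax(np.abs(g_star - g_hat)))
                raise NumericalError(
                    f"EB fixed-point iteration did not converge within {max_iter} "
                    f"iterations for batch {b!r} (worst gene: {values.index[worst]!r})"
                )
        if np.any(d2_star <= 0):
            raise NumericalError(f"non-positive shrunken variance in batch {b!r}")
        gamma_hat[:, i] = g_hat
        delta2_hat[:, i] = d2_hat
        gamma_star[:, i] = g_star
        delta2_star[:, i] = d2_star
        gamma_bar[i] = g_bar
        tau2[i] = t2
        lambda_[i] = lam
        theta[i] = th

    # (7) adjust
    adjusted = Z.copy()
    for i in range(I):
        cols = Xb[:, i] == 1.0
        adjusted[:, cols] = (adjusted[:, cols] - gamma_star[:, [i]]) / np.sqrt(
            delta2_star[:, [i]]
        )
    adjusted = adjusted * sigma[:, None] + stand_mean

    genes = values.index
    params = EBParams(
        batches=batches,
        alpha=pd.Series(alpha, index=genes),
        beta=pd.DataFrame(beta.T, index=genes),
        sigma2=pd.Series(sigma2, index=genes),
        gamma_hat=pd.DataFrame(gamma_hat, index=genes, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=genes, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=genes, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2=pd.Series(tau2, index=batches),
        lambda_=pd.Series(lambda_, index=batches),
        theta=pd.Series(theta, index=batches),
        n_iterations=n_iterations,
    )
    return pd.DataFrame(adjusted, index=genes, columns=values.columns), params


# ---------------------------------------------------------------------------
# simpler corrections
# ---------------------------------------------------------------------------


def mean_center(values: pd.DataFrame, batch_of_sample: pd.Series) -> pd.DataFrame:
    """Per gene, shift every batch onto the gene's grand mean over all samples."""
    batch_of_sample = pd.Series(batch_of_sample, index=values.columns)
    batches = pd.unique(batch_of_sample)
    if len(batches) < 2:
        raise ValidationError("mean centering needs at least two batches")
    Y = values.to_numpy(dtype=float)
    grand = Y.mean(axis=1)
    out = Y.copy()
    for b in batches:
        cols = (batch_of_sample == b).to_numpy()
        out[:, cols] += (grand - Y[:, cols].mean(axis=1))[:, None]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic full quantile normalization over all sample columns jointly.

    Each column's rank-k value is replaced by the mean over columns of the
    k-th order statistics; tied cells receive the mean of their tied
    rank-values.
    """
    if values.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least two samples")
    Y = values.to_numpy(dtype=float)
    G, N = Y.shape
    ref = np.sort(Y, axis=0).mean(axis=1)  # per-rank mean over columns
    out = np.empty_like(Y)
    for j in range(N):
        col = Y[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(G)
        assigned[order] = ref
        # average assigned values within tie groups
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def gene_quantile_normalize(
    values: pd.DataFrame, batch_of_sample: pd.Series
) -> pd.DataFrame:
    """Per gene, map within-batch quantile ranks through the gene's pooled
    empirical quantile function.

    The within-batch quantile of a value is (rank - 0.5)/n with average ranks
    for ties; the pooled quantile function uses the inverted-CDF convention,
    so with a single batch each gene's values map back onto its own order
    statistics.
    """
    batch_of_sample = pd.Series(batch_of_sample, index=values.columns)
    batches = pd.unique(batch_of_sample)
    Y = values.to_numpy(dtype=float)
    out = np.empty_like(Y)
    masks = [(batch_of_sample == b).to_numpy() for b in batches]
    for g in range(Y.shape[0]):
        pooled = Y[g]
        for mask in masks:
            x = Y[g, mask]
            n = x.size
            if n == 1:
                p = np.array([0.5])
            else:
                p = (stats.rankdata(x, method="average") - 0.5) / n
            out[g, mask] = np.quantile(pooled, p, method="inverted_cdf")
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def median_rank_scores(
    values: pd.DataFrame, batch_of_sample: pd.Series, reference_batch: str | None = None
) -> pd.DataFrame:
    """Replace every non-reference sample's rank-k value by the reference
    batch's rank-k median.

    The reference profile is the per-rank median over the reference batch's
    sorted sample columns.  ``reference_batch`` defaults to the batch with
    the most samples (ties broken by lexicographic batch name).
    """
    batch_of_sample = pd.Series(batch_of_sample, index=values.columns)
    batches = list(pd.unique(batch_of_sample))
    if reference_batch is None:
        sizes = batch_of_sample.value_counts()
        top = sizes.max()
        reference_batch = sorted(b for b in batches if sizes[b] == top)[0]
    if reference_batch not in batches:
        raise ValidationError(
            f"reference batch {reference_batch!r} not present; have: {', '.join(batches)}"
        )
    Y = values.to_numpy(dtype=float)
    ref_cols = (batch_of_sample == reference_batch).to_numpy()
    profile = np.median(np.sort(Y[:, ref_cols], axis=0), axis=1)
    out = Y.copy()
    for j in range(Y.shape[1]):
        if ref_cols[j]:
            continue
        order = np.argsort(Y[:, j], kind="stable")
        out[order, j] = profile
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_discretize(values: pd.DataFrame, q: int = 8) -> pd.DataFrame:
    """Bin each sample's values into q equal-frequency bins (codes 1..q).

    The bin of a value is ceil(q * rank/n) with average ranks for ties; an
    all-constant sample is degenerate and falls entirely into bin 1.
    """
    if q < 2:
        raise ValidationError("quantile discretization needs q >= 2 bins")
    G = values.shape[0]
    if q > G:
        raise ValidationError(f"q={q} exceeds the number of features ({G})")
    Y = values.to_numpy(dtype=float)
    out = np.empty_like(Y)
    for j in range(Y.shape[1]):
        col = Y[:, j]
        if np.unique(col).size == 1:
            out[:, j] = 1.0
            continue
        frac = stats.rankdata(col, method="average") / G
        out[:, j] = np.clip(np.ceil(q * frac), 1, q)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _grubbs_retained(x: np.ndarray, alpha: float) -> np.ndarray:
    """Iteratively drop the most extreme value while the two-sided Grubbs
    test rejects at level alpha; returns the retained values."""
    x = np.array(x, dtype=float)
    while x.size >= 3:
        m = x.mean()
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - m)
        k = int(np.argmax(dev))
        g = dev[k] / s
        n = x.size
        t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t * t / (n - 2 + t * t))
        if g > crit:
            x = np.delete(x, k)
        else:
            break
    return x


def nordi(
    values: pd.DataFrame,
    alpha_outlier: float = 0.05,
    alpha_disc: float = 0.05,
) -> pd.DataFrame:
    """Per-sample normal discretization into {-1, 0, +1}.

    Per sample: remove outliers by iterated two-sided Grubbs tests at
    ``alpha_outlier``, estimate mean m and standard deviation s of the
    retained values, and label every original value +1 (over-expressed) if it
    exceeds m + z(1-alpha_disc) s, -1 (under-expressed) below the mirror
    threshold, else 0.
    """
    for name, a in (("alpha_outlier", alpha_outlier), ("alpha_disc", alpha_disc)):
        if not 0.0 < a < 0.5:
            raise ValidationError(f"{name} must lie in (0, 0.5), got {a}")
    if values.shape[0] < 3:
        raise ValidationError("NorDi needs at least 3 values per sample")
    z = stats.norm.ppf(1.0 - alpha_disc)
    Y = values.to_numpy(dtype=float)
    out = np.zeros_like(Y)
    for j in range(Y.shape[1]):
        col = Y[:, j]
        retained = _grubbs_retained(col, alpha_outlier)
        m = retained.mean()
        s = retained.std(ddof=1)
        out[:, j] = np.where(col > m + z * s, 1.0, np.where(col < m - z * s, -1.0, 0.0))
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def remove_batch_effects(
    merged: MergedDataset,
    method: str = "EB",
    covariate_columns: Sequence[str] = (),
    reference_batch: str | None = None,
    qd_bins: int = 8,
    nordi_alpha_outlier: float = 0.05,
    nordi_alpha_disc: float = 0.05,
) -> MergedDataset:
    """Dispatch batch-effect removal on a merged dataset.

    ``method`` is one of EB, MC, QN, GQ, MRS, QD, NorDi or NONE
    (case-insensitive; "none" returns the data unadjusted).  EB with
    ``covariate_columns`` naming sample_info columns runs in supervised mode;
    without covariates only the batch contribution enters the design.
    """
    canonical = {m.upper(): m for m in CORRECTION_METHODS}
    key = str(method).upper()
    if key not in canonical:
        raise ValidationError(
            f"unknown batch-effect method {method!r}; valid: {', '.join(CORRECTION_METHODS)}"
        )
    method = canonical[key]
    if method == "NONE":
        return merged.with_values(merged.values.copy())
    if merged.discretized and method in _CONTINUOUS_METHODS:
        raise ValidationError(
            f"refusing {method} on discretized data: continuous re-adjustment of "
            "QD/NorDi output is undefined"
        )
    if method != "EB" and covariate_columns:
        raise ValidationError(f"covariates are only supported in EB supervised mode, not {method}")

    if method == "EB":
        covs = None
        if covariate_columns:
            if merged.sample_info is None:
                raise ValidationError("supervised EB requires a sample_info table")
            info = merged.sample_info.subset(merged.sample_ids)
            missing = [c for c in covariate_columns if c not in info.table.columns]
            if missing:
                raise ValidationError(
                    f"covariate columns missing from sample_info: {', '.join(missing)}"
                )
            covs = info.table[list(covariate_columns)].copy()
            covs.index = merged.sample_ids
        adjusted, _ = combat_eb(merged.values, merged.batch_of_sample, covs)
        return merged.with_values(adjusted)
    if method == "MC":
        return merged.with_values(mean_center(merged.values, merged.batch_of_sample))
    if method == "QN":
        return merged.with_values(quantile_normalize(merged.values))
    if method == "GQ":
        if len(merged.batches) < 2:
            raise ValidationError("GQ needs at least two batches")
        return merged.with_values(
            gene_quantile_normalize(merged.values, merged.batch_of_sample)
        )
    if method == "MRS":
        return merged.with_values(
            median_rank_scores(merged.values, merged.batch_of_sample, reference_batch)
        )
    if method == "QD":
        return merged.with_values(
            quantile_discretize(merged.values, qd_bins), discretized=True
        )
    # NorDi
    return merged.with_values(
        nordi(merged.values, nordi_alpha_outlier, nordi_alpha_disc), discretized=True
    )
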