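"""Negative-binomial differential expression over a three-point time course.

Samples are taken at 0 h (dark control), 6 h and 10 h after the inducing
light stimulus; biological replicates from different strains and experiments
are pooled per time point.  Three pairwise contrasts are evaluated
(0-6 h, 6-10 h, 0-10 h) and each transcript is classified by the contrast
where its maximal significant change occurred.

The test is a negative-binomial Wald test built from first principles:

* per-sample size factors by the median-of-ratios method;
* per-transcript dispersion alpha (variance = mu + alpha * mu^2) by a
  method-of-moments estimate pooled across within-group replicates, shrunk
  toward a mean-dispersion trend alpha(mu) = a0 + a1 / mu fitted across
  transcripts;
* group means as size-factor-weighted averages, log2 fold change of the
  two group means, a delta-method standard error, and a two-sided p-value
  from the normal approximation of the Wald statistic.

Calibration (type-I error at the nominal level) and effect recovery are the
design goals; numerical identity with any particular external tool is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTRASTS: tuple[tuple[int, int], ...] = ((0, 6), (6, 10), (0, 10))

DISPERSION_FLOOR = 1e-8


def contrast_label(contrast: tuple[int, int]) -> str:
    return f"{contrast[0]}-{contrast[1]}h"


@dataclass
class DEParams:
    """Knobs of the differential-expression stage.

    alpha is applied to raw p-values by default; Benjamini-Hochberg
    adjustment is available but off, since the significance rule this
    pipeline mirrors is stated on plain p-values.
    """

    alpha: float = 0.025
    adjust: str = "none"  # or "BH"
    min_total_count: int = 10
    dispersion_shrinkage: float = 0.8
    pseudo_mean: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")
        if not 0 <= self.dispersion_shrinkage <= 1:
            raise ValueError("dispersion_shrinkage must be in [0, 1]")


@dataclass
class CountMatrix:
    """Integer read counts (transcripts x samples) plus the sample sheet."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # sample_id, experiment, strain, timepoint_h

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        sheet = self.samples.set_index("sample_id")
        missing = set(self.counts.columns) - set(sheet.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        tp = sheet.loc[list(self.counts.columns), "timepoint_h"]
        bad = set(tp.unique()) - {0, 6, 10}
        if bad:
            raise ValueError(
                f"time points must be in {{0, 6, 10}} (map raw sampling times "
                f"via the sample sheet); got {sorted(bad)}"
            )
        vc = tp.value_counts()
        if (vc < 2).any():
            raise ValueError("every time point needs >= 2 pooled replicates")

    @property
    def timepoints(self) -> pd.Series:
        """timepoint_h per count column, in column order."""
        sheet = self.samples.set_index("sample_id")
        return sheet.loc[list(self.counts.columns), "timepoint_h"]

    def columns_at(self, timepoint: int) -> list[str]:
        tp = self.timepoints
        return [c for c in self.counts.columns if tp[c] == timepoint]


# ---------------------------------------------------------------------------
# normalisation and dispersion


def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j: factor_j = median over reference transcripts i of
    counts_ij / geomean_i, where the reference set is the transcripts with
    nonzero counts in every sample.  If no such transcript exists the
    factors fall back to total-count scaling (with a warning).
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        ref = mat[all_nonzero]
        log_geomean = np.log(ref).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(ref) - log_geomean, axis=0))
    else:
        logger.warning(
            "no transcript has nonzero counts in all samples; "
            "falling back to total-count size factors"
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _genewise_dispersion(
    norm: np.ndarray, groups: Sequence[np.ndarray], inv_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments dispersion pooled across within-group replicates.

    ``norm`` are size-factor-normalised counts; Var(k/s) = mu/s + alpha*mu^2,
    so the excess of the within-group variance over mu * mean(1/s) estimates
    alpha * mu^2.  Returns (alpha_hat, base_mean)."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    dof = 0
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        shot = m * inv_s[cols].mean()  # Poisson (counting) part of the variance
        w = len(cols) - 1
        num += w * (v - shot)
        den += w * m**2
        dof += w
    if dof == 0:
        raise ValueError("dispersion estimation needs >= 2 replicates in a group")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return alpha, norm.mean(axis=1)


def _fit_trend(alpha: np.ndarray, mean: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iteratively trimmed least squares.

    Only transcripts with informative gene-wise estimates (above the floor,
    mean > 1) enter the fit; extreme residuals are trimmed once to keep the
    trend robust to outlying genes."""
    keep = (alpha > DISPERSION_FLOOR * 10) & (mean > 1)
    if keep.sum() < 10:
        return float(np.median(alpha)), 0.0
    x = 1.0 / mean[keep]
    y = alpha[keep]
    for _ in range(2):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        mad = np.median(np.abs(resid)) + 1e-12
        inliers = np.abs(resid) < 5 * mad
        if inliers.all() or inliers.sum() < 10:
            break
        x, y = x[inliers], y[inliers]
    a0 = max(float(coef[0]), DISPERSION_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersion(
    cm: CountMatrix,
    factors: Optional[pd.Series] = None,
    shrinkage: float = 0.8,
) -> pd.DataFrame:
    """Per-transcript NB dispersion with mean-trend shrinkage.

    Returns a frame with columns ``genewise``, ``trend``, ``dispersion``
    (the shrunk value used for testing) and ``base_mean``.  All-zero
    transcripts receive NaN dispersion and are flagged untestable downstream.
    """
    if factors is None:
        factors = size_factors(cm)
    mat = cm.counts.to_numpy(dtype=float)
    s = factors.to_numpy()
    norm = mat / s
    tp = cm.timepoints.to_numpy()
    groups = [np.flatnonzero(tp == t) for t in (0, 6, 10)]
    genewise, base_mean = _genewise_dispersion(norm, groups, 1.0 / s)
    a0, a1 = _fit_trend(genewise, base_mean)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(base_mean, 1e-12)
    trend = np.minimum(trend, 10.0)  # cap: absurd trend values at mean ~ 0
    disp = (1 - shrinkage) * genewise + shrinkage * trend
    disp = np.maximum(disp, DISPERSION_FLOOR)
    all_zero = mat.sum(axis=1) == 0
    disp[all_zero] = np.nan
    return pd.DataFrame(
        {
            "genewise": genewise,
            "trend": trend,
            "dispersion": disp,
            "base_mean": base_mean,
        },
        index=cm.counts.index,
    )


# ---------------------------------------------------------------------------
# Wald test and classification


def nb_wald_test(
    cm: CountMatrix,
    contrast: tuple[int, int],
    factors: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
    params: Optional[DEParams] = None,
) -> pd.DataFrame:
    """NB Wald test of timepoint B vs timepoint A for one contrast.

    Group means are estimated as mu_g = sum_j k_ij / sum_j s_j over the
    group's samples; log2FC = log2((mu_B + c) / (mu_A + c)) with pseudo-mean
    c; the delta-method variance of log(mu_g) is
    (sum_j s_j mu + alpha sum_j s_j^2 mu^2) / (S_g mu)^2.  Untestable
    transcripts (total count below the filter, or an all-zero group pair)
    get NaN statistics and are excluded from significance calls.
    """
    params = params or DEParams()
    if factors is None:
        factors = size_factors(cm)
    if dispersions is None:
        dispersions = estimate_dispersion(
            cm, factors, shrinkage=params.dispersion_shrinkage
        )["dispersion"]
    t_a, t_b = contrast
    cols_a = cm.columns_at(t_a)
    cols_b = cm.columns_at(t_b)
    if not cols_a or not cols_b:
        raise ValueError(f"contrast {contrast}: both time points need samples")

    k = cm.counts.to_numpy(dtype=float)
    s = factors.to_numpy()
    col_idx = {c: i for i, c in enumerate(cm.counts.columns)}
    ia = np.array([col_idx[c] for c in cols_a])
    ib = np.array([col_idx[c] for c in cols_b])
    alpha_d = np.asarray(dispersions, dtype=float)

    c = params.pseudo_mean

    def group_stats(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        S = s[idx].sum()
        mu = k[:, idx].sum(axis=1) / S
        mu_safe = np.maximum(mu, 1e-8)
        # delta-method Var(log(mu_hat + c)) under Var(k) = mu + alpha mu^2;
        # the + c matches the pseudo-mean used in the fold change, keeping
        # the Wald statistic self-consistent (and calibrated) at low counts
        var_mu = (
            S * mu_safe + np.nan_to_num(alpha_d) * (s[idx] ** 2).sum() * mu_safe**2
        ) / S**2
        var_log = var_mu / (mu_safe + c) ** 2
        return mu, var_log

    mu_a, var_a = group_stats(ia)
    mu_b, var_b = group_stats(ib)

    log2fc = np.log2(mu_b + c) - np.log2(mu_a + c)
    se = np.sqrt(var_a + var_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    pval = 2 * stats.norm.sf(np.abs(z))

    total = cm.counts.to_numpy().sum(axis=1)
    untestable = (
        (total < params.min_total_count)
        | np.isnan(alpha_d)
        | ((mu_a <= 0) & (mu_b <= 0))
    )
    log2fc = np.where(untestable, np.nan, log2fc)
    se = np.where(untestable, np.nan, se)
    pval = np.where(untestable, np.nan, pval)

    out = pd.DataFrame(
        {
            "contrast": contrast_label(contrast),
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pval,
            "testable": ~untestable,
        },
        index=cm.counts.index,
    )
    out.index.name = "transcript_id"
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaN-aware)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def run_contrasts(
    cm: CountMatrix, params: Optional[DEParams] = None
) -> pd.DataFrame:
    """All three time-interval contrasts, long format, shared normalisation."""
    params = params or DEParams()
    factors = size_factors(cm)
    disp = estimate_dispersion(cm, factors, shrinkage=params.dispersion_shrinkage)
    frames = [
        nb_wald_test(cm, contrast, factors, disp["dispersion"], params)
        for contrast in CONTRASTS
    ]
    res = pd.concat(frames)
    res.attrs["size_factors"] = factors
    res.attrs["dispersions"] = disp
    return res


def max_interval_assignment(
    results: pd.DataFrame, params: Optional[DEParams] = None
) -> pd.DataFrame:
    """Per-transcript maximal significant change across the three contrasts.

    Among the contrasts with p below alpha (optionally BH-adjusted), the one
    with the largest |log2FC| is chosen; ties are broken in the fixed order
    0-6 h, 6-10 h, 0-10 h.  Transcripts with no significant contrast are not
    in the returned table — the DE set is exactly the table's index.
    """
    params = params or DEParams()
    labels = [contrast_label(c) for c in CONTRASTS]
    flat = results.reset_index()
    wide_p = flat.pivot(index="transcript_id", columns="contrast", values="pvalue")[
        labels
    ]
    wide_fc = flat.pivot(index="transcript_id", columns="contrast", values="log2fc")[
        labels
    ]
    pmat = wide_p.to_numpy()
    if params.adjust == "BH":
        pmat = np.column_stack([_bh_adjust(pmat[:, j]) for j in range(pmat.shape[1])])
    fc = wide_fc.to_numpy()
    sig = pmat < params.alpha  # NaN compares False
    absfc = np.where(sig, np.abs(fc), -np.inf)
    any_sig = sig.any(axis=1)
    best = np.argmax(absfc, axis=1)  # first index wins ties -> contrast order

    rows = np.flatnonzero(any_sig)
    chosen_fc = fc[rows, best[rows]]
    out = pd.DataFrame(
        {
            "best_contrast": [labels[j] for j in best[rows]],
            "log2fc": chosen_fc,
            "direction": np.where(chosen_fc >= 0, "up", "down"),
            "pvalue": pmat[rows, best[rows]],
            "x_fold": [fold_change(x) for x in chosen_fc],
        },
        index=wide_p.index[rows],
    )
    out.index.name = "transcript_id"
    return out


def fold_change(log2fc: float) -> float:
    """Convert a log2 fold change to an x-fold value.

    Returns 2**|log2fc| rounded to an integer when >= 10 and to one decimal
    below, the convention used when quoting fold changes in prose.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2 fold change must be finite")
    x = 2.0 ** abs(float(log2fc))
    return float(round(x)) if x >= 10 else round(x, 1)


# ---------------------------------------------------------------------------
# sample QC


def pca_samples(
    cm: CountMatrix, n_top_variable: int = 500
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log-transformed normalised counts.

    Counts are divided by size factors, log2(x+1)-transformed, restricted to
    the ``n_top_variable`` most variable transcripts and feature-centred;
    samples are projected on the first two principal components.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive, so coordinates are fully deterministic.
    """
    if cm.counts.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    factors = size_factors(cm)
    x = np.log2(cm.counts.to_numpy(dtype=float) / factors.to_numpy() + 1.0)
    n_top = min(n_top_variable, x.shape[0])
    var = x.var(axis=1)
    top = np.argsort(var)[::-1][:n_top]
    xt = x[top].T  # samples x transcripts
    xt = xt - xt.mean(axis=0)
    u, sv, vt = np.linalg.svd(xt, full_matrices=False)
    for comp in range(min(2, vt.shape[0])):
        lead = np.argmax(np.abs(vt[comp]))
        if vt[comp, lead] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    coords = u[:, :2] * sv[:2]
    total_var = (sv**2) / max(xt.shape[0] - 1, 1)
    var_frac = total_var[:2] / total_var.sum() if total_var.sum() > 0 else np.zeros(2)
    frame = pd.DataFrame(
        coords, index=cm.counts.columns, columns=["PC1", "PC2"]
    )
    frame.index.name = "sample_id"
    return frame, var_frac
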