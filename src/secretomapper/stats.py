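"""Reproducibility correlations and differential-abundance statistics.

Three tests, all pairwise two-group contrasts on an imputed log2 table:

* :func:`moderated_pairwise_da` — protein-wise linear models with
  empirical-Bayes variance moderation.  Per-protein residual variances are
  shrunk toward a prior estimated by moment-matching the distribution of
  log sample variances (digamma/trigamma inversion, the scheme of Smyth 2004
  used by limma's ``squeezeVar``), buying extra degrees of freedom at small
  replicate numbers.  Significance: Bonferroni-corrected p < alpha AND
  |log2 fold change| >= a floor (default 2, which guards against imputation
  artifacts).

* :func:`s0_permutation_test` — SAM-lineage volcano statistic: a pooled
  two-sample t with a fudge constant ``s0`` added to the standard-error
  denominator, damping significance of small fold changes.  The cutoff on
  the modified |t| is calibrated so that the permutation-estimated FDR
  (mean permuted exceedance count over observed count, pi0 = 1) stays below
  alpha; the significance boundary is the familiar hyperbolic curve.

* :func:`plain_two_sample_t` — classical pooled-variance two-sample t.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .types import IntensityTable, ParameterSet

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_matrix",
    "moderated_pairwise_da",
    "s0_permutation_test",
    "plain_two_sample_t",
    "exclusive_proteins",
    "fit_variance_prior",
]


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_matrix(table: IntensityTable, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation between all sample pairs on a log2 table.

    Pairwise-complete: each pair of samples is correlated over the proteins
    present in both.  Pairs sharing fewer than ``min_shared`` proteins get a
    missing entry with a warning.  On a fully imputed table this coincides
    with the complete-observation correlation.
    """
    if table.scale == "raw":
        raise ValueError("correlations are computed on a log table")
    corr = table.data.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    n_missing = int(corr.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%d sample pairs share fewer than %d proteins; "
                       "entries set to missing", n_missing // 2, min_shared)
    return corr


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def _two_group_arrays(table: IntensityTable, group_a: str, group_b: str):
    a = table.group_data(group_a).to_numpy(dtype=float)
    b = table.group_data(group_b).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 replicates")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("differential abundance requires an imputed table "
                         "(no missing values)")
    return a, b


def _pooled_stats(a: np.ndarray, b: np.ndarray):
    """Difference of means, pooled variance, residual df, SE scale factor."""
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    c = math.sqrt(1.0 / na + 1.0 / nb)
    return diff, s2, df, c


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior (Smyth moment matching)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < tol:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Under the hierarchical model s2_g | sigma_g^2 ~ sigma_g^2 chi2_df / df and
    1/sigma_g^2 ~ chi2_d0 / (d0 s0^2), the log sample variances follow a
    shifted log-F distribution; matching the empirical mean and variance of
    log s2 via digamma/trigamma yields (d0, s0^2).  Returns
    ``(prior_df, prior_var)``; ``prior_df`` may be ``inf`` when the observed
    spread of variances is no wider than chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # spread of sample variances explained by chi-square sampling alone:
        # degenerate prior concentrated at the mean variance
        return math.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def moderated_pairwise_da(
    table: IntensityTable,
    group_a: str,
    group_b: str,
    params: ParameterSet | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test of ``group_a`` vs ``group_b``.

    Returns one row per protein with columns ``log2_fold_change`` (A minus B),
    ``t_stat``, ``p_value``, ``p_adjusted`` (Bonferroni), ``significant``
    (p_adjusted < alpha and |log2FC| >= da_log2fc_min) and ``method``.
    The fitted prior is exposed as ``result.attrs["prior_df"]`` and
    ``result.attrs["prior_var"]``.

    ``prior_df`` overrides the fitted prior degrees of freedom (0 disables
    shrinkage entirely, recovering the classical pooled t).  With fewer than
    10 proteins the prior cannot be estimated stably and shrinkage is
    disabled automatically.
    """
    params = params or ParameterSet()
    a, b = _two_group_arrays(table, group_a, group_b)
    diff, s2, df, c = _pooled_stats(a, b)

    n = len(diff)
    frac_zero = float((s2 <= 0).mean()) if n else 0.0
    if frac_zero > 0.9:
        raise ValueError(
            f"{frac_zero:.0%} of proteins have zero residual variance; "
            "input looks degenerate (constant replicates)"
        )

    if prior_df is not None:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df) if d0 > 0 else (0.0, float("nan"))
    elif n < 10:
        d0, s0_sq = 0.0, float("nan")
    else:
        d0, s0_sq = fit_variance_prior(s2, df)

    if d0 == 0:
        s2_post = s2
        df_total = float(df)
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    # the effective df cannot exceed the pooled residual df of the dataset
    df_total = min(df_total, float(df * n)) if n else df_total

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (np.sqrt(s2_post) * c)
    t = np.where(np.isfinite(t), t, 0.0)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p_adj = np.minimum(p * n, 1.0)
    significant = (p_adj < params.alpha) & (np.abs(diff) >= params.da_log2fc_min)

    result = pd.DataFrame(
        {
            "log2_fold_change": diff,
            "t_stat": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": significant,
            "method": "moderated_bonferroni",
        },
        index=table.data.index,
    )
    result.attrs["prior_df"] = d0
    result.attrs["prior_var"] = s0_sq
    result.attrs["residual_df"] = df
    return result


# ---------------------------------------------------------------------------
# SAM-style s0 statistic with permutation FDR
# ---------------------------------------------------------------------------

def _s0_stats(pooled: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray,
              s0: float, c: float, df: int) -> np.ndarray:
    a = pooled[:, cols_a]
    b = pooled[:, cols_b]
    diff = a.mean(axis=1) - b.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    se = np.sqrt((ssa + ssb) / df) * c
    return diff / (se + s0)


def s0_permutation_test(
    table: IntensityTable,
    group_a: str,
    group_b: str,
    s0: float = 0.1,
    alpha: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style modified t with permutation-calibrated FDR cutoff.

    The modified statistic is ``t = (meanA - meanB) / (SE_pooled + s0)``.
    Group labels are permuted ``n_perm`` times; for each candidate cutoff
    (the observed |t| values) the FDR is estimated as the mean number of
    permuted statistics exceeding the cutoff divided by the observed count
    (pi0 fixed at 1).  The smallest cutoff with estimated FDR <= alpha is
    chosen, maximising the number of calls.  Deterministic given ``seed``.

    Returns a per-protein frame (``log2_fold_change``, ``t_stat``,
    ``p_value`` = pooled permutation p, ``p_adjusted`` = estimated FDR at
    each protein's own |t|, ``significant``, ``method``) with the chosen
    cutoff in ``attrs["t_cutoff"]`` and the hyperbolic significance boundary
    (log2FC vs -log10 p coordinates) in ``attrs["threshold_curve"]``.
    """
    a, b = _two_group_arrays(table, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    c = math.sqrt(1.0 / na + 1.0 / nb)
    pooled = np.concatenate([a, b], axis=1)
    n_total = na + nb
    cols_a_obs = np.arange(na)
    cols_b_obs = np.arange(na, n_total)
    t_obs = _s0_stats(pooled, cols_a_obs, cols_b_obs, s0, c, df)

    n_distinct = math.comb(n_total, na)
    rng = np.random.Generator(np.random.PCG64(seed))
    if n_distinct < 20:
        logger.warning(
            "only %d distinct label assignments; using exhaustive enumeration",
            n_distinct,
        )
        assignments = [
            np.array(combo) for combo in itertools.combinations(range(n_total), na)
        ]
    else:
        assignments = []
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            assignments.append(perm[:na])

    all_idx = np.arange(n_total)
    t_perm = np.empty((len(assignments), len(t_obs)))
    for k, cols_a in enumerate(assignments):
        mask = np.zeros(n_total, dtype=bool)
        mask[cols_a] = True
        t_perm[k] = _s0_stats(pooled, all_idx[mask], all_idx[~mask], s0, c, df)

    abs_obs = np.abs(t_obs)
    abs_perm_sorted = np.sort(np.abs(t_perm).ravel())
    n_perm_used = len(assignments)

    # estimated FDR at cutoff = each observed |t| value
    order = np.argsort(-abs_obs)  # descending
    cutoffs = abs_obs[order]
    obs_count = np.arange(1, len(cutoffs) + 1, dtype=float)
    perm_exceed = (
        len(abs_perm_sorted)
        - np.searchsorted(abs_perm_sorted, cutoffs, side="left")
    ) / n_perm_used
    fdr_at = perm_exceed / obs_count
    # enforce monotone non-increasing FDR in the cutoff (step-down)
    fdr_monotone = np.minimum.accumulate(fdr_at[::-1])[::-1]

    passing = np.flatnonzero(fdr_monotone <= alpha)
    if passing.size:
        k_max = passing.max()  # smallest cutoff still meeting alpha
        t_cutoff = float(cutoffs[k_max])
        significant_sorted = np.zeros(len(cutoffs), dtype=bool)
        significant_sorted[: k_max + 1] = True
    else:
        t_cutoff = math.inf
        significant_sorted = np.zeros(len(cutoffs), dtype=bool)

    significant = np.zeros(len(t_obs), dtype=bool)
    significant[order] = significant_sorted
    fdr_per_protein = np.ones(len(t_obs))
    fdr_per_protein[order] = np.minimum(fdr_monotone, 1.0)

    # pooled permutation p-value per protein
    p_perm = (
        len(abs_perm_sorted)
        - np.searchsorted(abs_perm_sorted, abs_obs, side="left")
        + 1.0
    ) / (len(abs_perm_sorted) + 1.0)

    diff = a.mean(axis=1) - b.mean(axis=1)
    result = pd.DataFrame(
        {
            "log2_fold_change": diff,
            "t_stat": t_obs,
            "p_value": p_perm,
            "p_adjusted": np.maximum(p_perm, fdr_per_protein),
            "significant": significant,
            "method": "s0_permutation",
        },
        index=table.data.index,
    )
    result.attrs["t_cutoff"] = t_cutoff
    result.attrs["n_permutations"] = n_perm_used
    result.attrs["threshold_curve"] = _threshold_curve(t_cutoff, s0, df)
    return result


def _threshold_curve(t_cutoff: float, s0: float, df: int,
                     fc_max: float = 8.0, n_points: int = 200) -> pd.DataFrame:
    """Volcano-space hyperbola: points where the modified |t| equals the cutoff.

    A point with fold change x sits on the boundary when its classical t is
    ``x / (x / cutoff - s0)``; defined for |x| > cutoff * s0.
    """
    if not math.isfinite(t_cutoff):
        return pd.DataFrame(columns=["log2_fold_change", "neg_log10_p"])
    x_min = t_cutoff * s0
    xs = np.linspace(x_min * 1.001, max(fc_max, x_min * 2), n_points)
    t_classical = xs / (xs / t_cutoff - s0)
    p = 2.0 * sps.t.sf(t_classical, df)
    branch = pd.DataFrame(
        {"log2_fold_change": xs, "neg_log10_p": -np.log10(np.clip(p, 1e-300, 1))}
    )
    mirrored = branch.copy()
    mirrored["log2_fold_change"] = -mirrored["log2_fold_change"]
    return pd.concat([mirrored.iloc[::-1], branch], ignore_index=True)


# ---------------------------------------------------------------------------
# classical t
# ---------------------------------------------------------------------------

def plain_two_sample_t(
    table: IntensityTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Classical two-sample t-test (pooled variance by default) per protein."""
    a, b = _two_group_arrays(table, group_a, group_b)
    t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    diff = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {
            "log2_fold_change": diff,
            "t_stat": t,
            "p_value": p,
            "p_adjusted": p,
            "significant": p < alpha,
            "method": "plain_t",
        },
        index=table.data.index,
    )


def exclusive_proteins(
    table: IntensityTable,
    group_a: str,
    group_b: str,
    min_detected: int = 1,
) -> dict[str, list[str]]:
    """Proteins quantified in only one of the two conditions.

    Such proteins cannot be assigned a fold change or p-value and are
    reported separately rather than entering the tests.
    """
    counts_a = table.detected[table.design.columns_for(group_a)].sum(axis=1)
    counts_b = table.detected[table.design.columns_for(group_b)].sum(axis=1)
    only_a = table.data.index[(counts_a >= min_detected) & (counts_b == 0)]
    only_b = table.data.index[(counts_b >= min_detected) & (counts_a == 0)]
    return {group_a: list(only_a), group_b: list(only_b)}
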