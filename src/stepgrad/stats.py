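"""ROI-wise group statistics and tau-connectivity association.

Group differences in (summed) normalized stepwise connectivity are tested
ROI by ROI with ordinary least squares adjusted for age, sex and APOE-e4
carrier status. Family-wise error across the ROI map is controlled by a
permutation maxT procedure with Freedman-Lane residual permutation (the
covariates stay attached to their subjects; only residuals from the
covariate-only model are permuted), which is valid in the presence of
confounders where naive label permutation is not.

The OLS path is a closed-form vectorized implementation because it must
run inside the permutation loop; tests cross-check it against statsmodels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import CohortTable, canonical_group

DEFAULT_COVARIATES = ("age", "sex", "apoe4")


def _check_full_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a column implicated in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad or names}"
        )


def _ols_focal_t(X: np.ndarray, Y: np.ndarray, focal: int):
    """t-statistics of one coefficient, fitted jointly across all responses.

    Y is (n_subjects, n_responses); returns (coef, t, p, df).
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[focal, focal])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[focal] / np.where(se > 0, se, 1.0), np.inf)
    pval = 2.0 * sps.t.sf(np.abs(t), df)
    return beta[focal], t, pval, df


def _contrast_design(
    cohort: CohortTable, contrast, covariates=DEFAULT_COVARIATES
):
    """Subjects of the two contrast groups and their design matrix.

    Columns: intercept, group indicator (second contrast group = 1), then
    the requested covariates.
    """
    group_a, group_b = (canonical_group(g) for g in contrast)
    subs = [s for s in cohort.subjects if s.group in (group_a, group_b)]
    if sum(s.group == group_a for s in subs) < 2 or sum(
        s.group == group_b for s in subs
    ) < 2:
        raise ValueError(f"need >= 2 subjects per group for contrast {contrast}")
    cov = cohort.covariate_frame(subs)
    cols = [np.ones(len(subs)), (cov["group"] == group_b).to_numpy(float)]
    names = ["intercept", f"group[{group_b}]"]
    for c in covariates:
        cols.append(cov[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return subs, X, names


def roi_group_regression(
    values: np.ndarray,
    cohort: CohortTable,
    contrast,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.01,
    roi_names=None,
) -> pd.DataFrame:
    """ROI-wise OLS of connectivity values on group, adjusted for covariates.

    ``values`` is (n_subjects_in_contrast, n_rois) ordered as the contrast
    subjects appear in the cohort. The reported t is the group coefficient's
    (contrast[1] relative to contrast[0]).
    """
    subs, X, _ = _contrast_design(cohort, contrast, covariates)
    Y = np.asarray(values, dtype=float)
    if Y.shape[0] != len(subs):
        raise ValueError(
            f"values has {Y.shape[0]} rows but contrast selects {len(subs)} subjects"
        )
    coef, t, p, _ = _ols_focal_t(X, Y, focal=1)
    n_roi = Y.shape[1]
    return pd.DataFrame(
        {
            "roi_id": np.arange(n_roi),
            "name": list(roi_names) if roi_names is not None else [""] * n_roi,
            "coef": coef,
            "t": t,
            "p": p,
            "p_adj": np.nan,
            "significant": False,
            "contrast": f"{canonical_group(contrast[1])} vs {canonical_group(contrast[0])}",
            "alpha": alpha,
        }
    )


def fwer_maxT(
    values: np.ndarray,
    cohort: CohortTable,
    contrast,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    covariates=DEFAULT_COVARIATES,
) -> np.ndarray:
    """Permutation maxT family-wise adjusted p-values for a group contrast.

    Freedman-Lane: residuals from the covariate-only (reduced) model are
    permuted and added back to the reduced-model fit, then the full-model
    group t is recomputed; the null is the distribution of the maximum |t|
    across ROIs. p_adj = (1 + #{perm maxima >= |t_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very low for FWER control", RuntimeWarning, stacklevel=2
        )
    subs, X, _ = _contrast_design(cohort, contrast, covariates)
    Y = np.asarray(values, dtype=float)
    n = len(subs)
    if n < 6:
        raise ValueError("groups too small to permute meaningfully")
    _, t_obs, _, _ = _ols_focal_t(X, Y, focal=1)
    Z = np.delete(X, 1, axis=1)  # reduced model: covariates only
    hz = Z @ np.linalg.pinv(Z)
    fitted = hz @ Y
    resid = Y - fitted
    rng = np.random.default_rng(rng_seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        _, t_star, _, _ = _ols_focal_t(X, y_star, focal=1)
        maxima[b] = np.abs(t_star).max()
    exceed = (maxima[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def roi_group_comparison(
    values: np.ndarray,
    cohort: CohortTable,
    contrast,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    covariates=DEFAULT_COVARIATES,
    roi_names=None,
) -> pd.DataFrame:
    """Group regression plus permutation FWER adjustment in one table."""
    res = roi_group_regression(
        values, cohort, contrast, covariates=covariates, alpha=alpha, roi_names=roi_names
    )
    res["p_adj"] = fwer_maxT(
        values,
        cohort,
        contrast,
        n_perm=n_perm,
        alpha=alpha,
        rng_seed=rng_seed,
        covariates=covariates,
    )
    res["significant"] = res["p_adj"] < alpha
    return res


def tau_association(
    cohort: CohortTable,
    sum_normalized: dict,
    analysis_group: str,
    reference_group: str = "A-CN",
    rois: np.ndarray | None = None,
    covariates=DEFAULT_COVARIATES,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """ROI-wise regression of baseline tau on the stepwise-connectivity shift.

    For each analysis-group subject s the predictor at ROI r is
    delta_s(r) = sum_normalized_s(r) - mean over the reference group of
    sum_normalized(r); tau_s(r) is regressed on delta_s(r) plus covariates.
    Subjects with missing tau are dropped (from the reference average too).
    ROIs where delta has zero variance are flagged and skipped (NaN).
    """
    analysis_group = canonical_group(analysis_group)
    reference_group = canonical_group(reference_group)
    ref = [s for s in cohort.group_subjects(reference_group) if s.has_tau]
    ana = [s for s in cohort.group_subjects(analysis_group) if s.has_tau]
    if not ref:
        raise ValueError(f"reference group {reference_group!r} has no tau subjects")
    if len(ana) < len(covariates) + 3:
        raise ValueError(f"too few tau subjects in {analysis_group!r}")
    # sum_normalized vectors are already restricted to `rois` when given
    n_map = next(iter(sum_normalized.values())).shape[0]
    roi_idx = np.arange(n_map) if rois is None else np.asarray(rois)
    if roi_idx.shape[0] != n_map:
        raise ValueError("rois length does not match sum_normalized map length")
    ref_mean = np.mean([sum_normalized[s.subject_id] for s in ref], axis=0)
    delta = np.array([sum_normalized[s.subject_id] - ref_mean for s in ana])
    tau = np.array([s.tau_suvr[roi_idx] for s in ana])
    cov = cohort.covariate_frame(ana)
    n = len(ana)
    Z = np.column_stack(
        [np.ones(n)] + [cov[c].to_numpy(float) for c in covariates]
    )
    _check_full_rank(Z, ["intercept", *covariates])
    n_roi = delta.shape[1]
    p_full = Z.shape[1] + 1
    slope = np.full(n_roi, np.nan)
    tstat = np.full(n_roi, np.nan)
    pval = np.full(n_roi, np.nan)
    zero_var = np.zeros(n_roi, dtype=bool)
    rng = np.random.default_rng(rng_seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    abs_t_star = np.zeros((n_roi, n_perm))
    hz = Z @ np.linalg.pinv(Z)
    for r in range(n_roi):
        x = delta[:, r]
        if np.ptp(x) == 0.0:
            zero_var[r] = True
            continue
        X = np.column_stack([Z, x])
        focal = X.shape[1] - 1
        xtx_inv = np.linalg.inv(X.T @ X)
        pinv = xtx_inv @ X.T
        y = tau[:, r]
        beta = pinv @ y
        res = y - X @ beta
        sigma2 = (res**2).sum() / (n - p_full)
        se = np.sqrt(sigma2 * xtx_inv[focal, focal])
        slope[r] = beta[focal]
        tstat[r] = beta[focal] / se if se > 0 else np.inf
        pval[r] = 2.0 * sps.t.sf(abs(tstat[r]), n - p_full)
        # Freedman-Lane null for this ROI under the shared permutations
        fitted = hz @ y
        resid_red = y - fitted
        y_star = fitted[:, None] + resid_red[perm_idx].T  # (n, n_perm)
        b_star = pinv @ y_star
        res_star = y_star - X @ b_star
        sig2_star = (res_star**2).sum(axis=0) / (n - p_full)
        se_star = np.sqrt(sig2_star * xtx_inv[focal, focal])
        with np.errstate(divide="ignore", invalid="ignore"):
            abs_t_star[r] = np.abs(
                np.where(se_star > 0, b_star[focal] / np.where(se_star > 0, se_star, 1.0), np.inf)
            )
    maxima = abs_t_star[~zero_var].max(axis=0) if (~zero_var).any() else np.zeros(n_perm)
    p_adj = np.full(n_roi, np.nan)
    ok = ~zero_var
    exceed = (maxima[:, None] >= np.abs(tstat[ok])[None, :]).sum(axis=0)
    p_adj[ok] = (1.0 + exceed) / (n_perm + 1.0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} ROI(s) with zero-variance connectivity shift skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "roi_id": roi_idx,
            "slope": slope,
            "t": tstat,
            "p": pval,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "zero_variance": zero_var,
            "group": analysis_group,
            "reference": reference_group,
        }
    )
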