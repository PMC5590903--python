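"""Negative-binomial differential expression between two environments.

A deliberately compact engine: median-of-ratios size factors,
method-of-moments dispersions pooled across design cells, per-gene NB
log-link GLM with fixed dispersion fit by IRLS, Wald tests on the
condition coefficient, and BH / BY step-up adjustment. No fold-change
shrinkage, independent filtering, or outlier replacement.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from plastex.datatypes import CountMatrix, PlastexError, SampleDesign

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ("gene_id", "base_mean", "lfc", "lfc_se", "wald_stat",
              "p_value", "p_adj")


def estimate_size_factors(
    counts: CountMatrix, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with any zero count are excluded from the reference set. With
    ``pseudo_reference=True`` the gene-wise geometric mean is instead
    taken over positive counts only, rescuing sparse matrices.
    """
    mat = counts.values.astype(float)
    if (mat.sum(axis=0) == 0).any():
        raise PlastexError("a sample has zero total counts")
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        n_pos = (mat > 0).sum(axis=1)
        eligible = n_pos > 0
        log_geo = np.nanmean(
            np.where(eligible[:, None], logs, np.nan), axis=1
        )
    else:
        eligible = (mat > 0).all(axis=1)
        if not eligible.any():
            raise PlastexError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        log_geo = np.full(mat.shape[0], np.nan)
        log_geo[eligible] = np.log(mat[eligible]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratios = np.log(mat) - log_geo[:, None]
    factors = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        col = log_ratios[eligible, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise PlastexError(f"sample {counts.sample_ids[j]!r} has no "
                               "reference-eligible counts")
        factors[j] = np.exp(np.median(col))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def estimate_dispersions(
    counts: CountMatrix,
    design: SampleDesign,
    size_factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
    trend_shrinkage: bool = False,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene.

    Normalized counts are pooled across design cells (group x
    condition): alpha_g = max((s2_g - mbar_g) / mbar_g**2, floor) using
    the within-cell pooled variance, so group and condition shifts do
    not inflate the estimate. Cells with a single sample contribute no
    degrees of freedom; a design with no replicated cell is an error.
    """
    design.check_matches(counts)
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    y = counts.values / sf[None, :]
    tbl = design.table.set_index("sample_id").loc[counts.sample_ids]
    cells = (tbl["group"] + "\x00" + tbl["condition"]).to_numpy()

    ss = np.zeros(counts.n_genes)
    df = 0
    n_used = 0
    mean_sum = np.zeros(counts.n_genes)
    for cell in np.unique(cells):
        idx = np.where(cells == cell)[0]
        if idx.size < 2:
            continue
        sub = y[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += idx.size - 1
        mean_sum += sub.sum(axis=1)
        n_used += idx.size
    if df == 0:
        raise PlastexError(
            "no design cell has replication; dispersion is not estimable"
        )
    s2 = ss / df
    mbar = mean_sum / n_used
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mbar) / mbar**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.maximum(alpha, floor)

    if trend_shrinkage:
        ok = (mbar > 0) & (alpha > floor)
        if ok.sum() >= 10:
            coeffs = np.polyfit(np.log(mbar[ok]), np.log(alpha[ok]), 1)
            fitted = np.exp(np.polyval(coeffs, np.log(np.maximum(mbar, 1e-8))))
            alpha = np.maximum(np.sqrt(alpha * fitted), floor)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def _model_matrix(design: SampleDesign, sample_ids) -> np.ndarray:
    """Intercept + group indicators (first level dropped) + condition."""
    groups = design.groups(sample_ids)
    levels = sorted(set(groups))
    cols = [np.ones(len(sample_ids))]
    for lvl in levels[1:]:
        cols.append(np.array([1.0 if g == lvl else 0.0 for g in groups]))
    cols.append(design.condition_indicator(sample_ids))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PlastexError("model matrix is rank-deficient")
    return X


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit of an NB log-link GLM with fixed dispersion.

    Returns (beta, standard errors, converged). Natural-log scale.
    """
    n, p = X.shape
    mu = y + 0.5
    eta = np.log(mu) - offset
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta + offset, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        xw = X * w[:, None]
        xtwx = X.T @ xw
        try:
            new_beta = np.linalg.solve(xtwx, xw.T @ z)
        except np.linalg.LinAlgError:
            break
        step = new_beta - beta
        beta = new_beta
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return beta, se, converged


def test_condition_effect(
    counts: CountMatrix,
    design: SampleDesign,
    size_factors: pd.Series,
    dispersions: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene Wald test of the environment effect (EH vs MA).

    Fits an NB log-link GLM (~ group + condition) per gene with the
    supplied fixed dispersion; the log2 fold change is the condition
    coefficient (EH relative to the MA reference). All-zero genes and
    non-converged fits get a missing p-value.
    """
    design.check_matches(counts)
    sample_ids = counts.sample_ids
    conditions = set(
        design.table.set_index("sample_id").loc[sample_ids, "condition"]
    )
    if len(conditions) < 2:
        raise PlastexError("design contains a single condition")
    X = _model_matrix(design, sample_ids)
    offset = np.log(size_factors.loc[sample_ids].to_numpy(dtype=float))
    alphas = dispersions.loc[counts.gene_ids].to_numpy(dtype=float)
    mat = counts.values.astype(float)
    norm = mat / np.exp(offset)[None, :]
    base_mean = norm.mean(axis=1)
    cond_idx = X.shape[1] - 1

    n_genes = counts.n_genes
    lfc = np.full(n_genes, np.nan)
    lfc_se = np.full(n_genes, np.nan)
    wald = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    n_failed = 0
    for g in range(n_genes):
        y = mat[g]
        if y.sum() == 0:
            continue
        beta, se, ok = _fit_nb_glm(
            y, X, offset, float(alphas[g]), max_iter=max_iter, tol=tol
        )
        lfc[g] = beta[cond_idx] / LN2
        if not ok or not np.isfinite(se[cond_idx]) or se[cond_idx] == 0:
            n_failed += 1
            continue
        lfc_se[g] = se[cond_idx] / LN2
        wald[g] = beta[cond_idx] / se[cond_idx]
        pval[g] = 2.0 * stats.norm.sf(abs(wald[g]))
    if n_failed:
        logger.warning("%d genes failed to converge; p set missing",
                       n_failed)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": base_mean,
            "lfc": lfc,
            "lfc_se": lfc_se,
            "wald_stat": wald,
            "p_value": pval,
            "p_adj": adjust_pvalues(pval, "BH"),
        }
    )


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Benjamini-Yekutieli step-up adjustment.

    Missing values are excluded from the number of tests and returned
    missing. BY multiplies the BH adjustment by c(m) = sum_{i<=m} 1/i.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    vals = p[finite]
    if ((vals < 0) | (vals > 1)).any():
        raise PlastexError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order]
    scale = m / np.arange(1, m + 1)
    adj = ranked * scale
    if method.upper() == "BY":
        adj *= np.sum(1.0 / np.arange(1, m + 1))
    elif method.upper() != "BH":
        raise PlastexError(f"unknown adjustment method {method!r}")
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[finite] = result
    return out


def significant_genes(de: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Gene ids with adjusted p below ``alpha`` (missing excluded)."""
    mask = de["p_adj"].notna() & (de["p_adj"] < alpha)
    return set(de.loc[mask, "gene_id"].astype(str))


def remove_flagged_genes(
    de_maize: pd.DataFrame,
    de_teosinte: pd.DataFrame,
    flag_set: set[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Drop flagged genes (e.g. development-stage markers) and count the
    removals among the significant calls of each table.

    Returns the two filtered tables and counts keyed ``maize_only``,
    ``teosinte_only``, ``both``, ``total``, tallied over genes that were
    significant at ``alpha`` in each table before removal.
    """
    flag_set = {str(g) for g in flag_set}
    sig_m = significant_genes(de_maize, alpha)
    sig_t = significant_genes(de_teosinte, alpha)
    removed_m = sig_m & flag_set
    removed_t = sig_t & flag_set
    both = removed_m & removed_t
    counts = {
        "maize_only": len(removed_m - both),
        "teosinte_only": len(removed_t - both),
        "both": len(both),
        "total": len(removed_m | removed_t),
    }
    if not flag_set:
        return de_maize, de_teosinte, counts
    keep_m = ~de_maize["gene_id"].astype(str).isin(flag_set)
    keep_t = ~de_teosinte["gene_id"].astype(str).isin(flag_set)
    if counts["total"]:
        warnings.warn(
            f"removed {counts['total']} flagged genes from significant "
            f"calls ({counts['maize_only']} maize-only, "
            f"{counts['teosinte_only']} teosinte-only, "
            f"{counts['both']} both)",
            stacklevel=2,
        )
    return (
        de_maize.loc[keep_m].reset_index(drop=True),
        de_teosinte.loc[keep_t].reset_index(drop=True),
        counts,
    )
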