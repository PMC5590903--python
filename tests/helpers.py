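"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from plastex.datatypes import CountMatrix, SampleDesign


def make_design(n_groups: int = 1, reps: int = 3, taxon: str = "maize",
                conditions=("EH", "MA")) -> SampleDesign:
    rows = []
    for g in range(n_groups):
        for cond in conditions:
            for r in range(reps):
                rows.append(
                    {
                        "sample_id": f"{taxon}_g{g}_{cond}_{r}",
                        "taxon": taxon,
                        "group": f"{taxon}_g{g}",
                        "condition": cond,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def nb_counts(mu: np.ndarray, alpha, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam)


def count_matrix(values: np.ndarray, sample_ids=None,
                 gene_ids=None) -> CountMatrix:
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    return CountMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    )


def de_table(gene_ids, p_adj, lfc=None) -> pd.DataFrame:
    gene_ids = list(gene_ids)
    p_adj = np.asarray(p_adj, dtype=float)
    if lfc is None:
        lfc = np.ones(len(gene_ids))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": np.full(len(gene_ids), 100.0),
            "lfc": np.asarray(lfc, dtype=float),
            "lfc_se": np.full(len(gene_ids), 0.1),
            "wald_stat": np.zeros(len(gene_ids)),
            "p_value": p_adj,
            "p_adj": p_adj,
        }
    )


def hetero_block_expression(
    block_sizes, n_noise, n_samples, rng, w_lo=0.75, w_hi=0.98
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted modules with heterogeneous membership strength plus
    unstructured noise genes; gene i in a block loads on the block's
    latent factor with weight w_i ~ U(w_lo, w_hi), so intramodular
    connectivity varies within a module. Returns (expression, labels)
    with label 0 for noise genes."""
    rows = []
    labels = []
    for b, size in enumerate(block_sizes):
        factor = rng.normal(0, 1, n_samples)
        for _ in range(size):
            w = rng.uniform(w_lo, w_hi)
            rows.append(
                w * factor + np.sqrt(1 - w * w) * rng.normal(0, 1, n_samples)
            )
            labels.append(b + 1)
    rows.extend(rng.normal(0, 1, (n_noise, n_samples)))
    labels.extend([0] * n_noise)
    n = len(rows)
    expr = pd.DataFrame(
        np.array(rows),
        index=[f"G{i + 1:04d}" for i in range(n)],
        columns=[f"S{j + 1}" for j in range(n_samples)],
    )
    return expr, pd.Series(labels, index=expr.index)


def block_expression(
    block_sizes, n_samples, within_cor=0.9, rng=None, noise_sd=1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted-partition expression: genes in a block share one latent
    factor with correlation ``within_cor``; blocks are independent.
    Returns (expression genes x samples, true block labels)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    labels = []
    w = np.sqrt(within_cor)
    for b, size in enumerate(block_sizes):
        factor = rng.normal(0, 1, n_samples)
        for _ in range(size):
            gene = w * factor + np.sqrt(1 - within_cor) * rng.normal(
                0, noise_sd, n_samples
            )
            rows.append(gene)
            labels.append(b + 1)
    n = len(rows)
    expr = pd.DataFrame(
        np.array(rows),
        index=[f"G{i + 1:04d}" for i in range(n)],
        columns=[f"S{j + 1}" for j in range(n_samples)],
    )
    return expr, np.array(labels)
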