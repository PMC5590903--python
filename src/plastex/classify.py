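"""Cross-taxon response categories and assimilation-candidate refinement."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from plastex.datatypes import PlastexError

logger = logging.getLogger(__name__)


def classify_genes(
    de_maize: pd.DataFrame,
    de_teosinte: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each gene a response category from the two DE tables.

    The gene universe is the intersection of genes with a non-missing
    adjusted p in both taxa. A gene is ``shared_*`` when significant in
    both (split by the sign product of the two fold changes),
    ``*_specific`` when significant in exactly one, else ``non_DE``.
    """
    if not 0 < alpha < 1:
        raise PlastexError("alpha must lie in (0, 1)")
    m = de_maize.set_index(de_maize["gene_id"].astype(str))
    t = de_teosinte.set_index(de_teosinte["gene_id"].astype(str))
    common = m.index.intersection(t.index)
    if common.empty:
        raise PlastexError("no genes shared between the two DE tables")
    m = m.loc[common]
    t = t.loc[common]
    testable = m["p_adj"].notna().to_numpy() & t["p_adj"].notna().to_numpy()
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("excluding %d genes with missing adjusted p", n_dropped)
    m = m.loc[testable]
    t = t.loc[testable]

    sig_m = (m["p_adj"] < alpha).to_numpy()
    sig_t = (t["p_adj"] < alpha).to_numpy()
    sign_prod = np.sign(m["lfc"].to_numpy()) * np.sign(t["lfc"].to_numpy())

    category = np.where(
        sig_m & sig_t,
        np.where(sign_prod < 0, "shared_opposite", "shared_same"),
        np.where(
            sig_m, "maize_specific",
            np.where(sig_t, "teosinte_specific", "non_DE"),
        ),
    )
    n_zero_sign = int((sig_m & sig_t & (sign_prod == 0)).sum())
    if n_zero_sign:
        warnings.warn(
            f"{n_zero_sign} shared genes with a zero fold change in one "
            "taxon assigned shared_same",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "gene_id": m.index.to_numpy(),
            "category": category,
            "lfc_maize": m["lfc"].to_numpy(),
            "lfc_teosinte": t["lfc"].to_numpy(),
            "p_adj_maize": m["p_adj"].to_numpy(),
            "p_adj_teosinte": t["p_adj"].to_numpy(),
            "alpha": alpha,
        }
    ).reset_index(drop=True)


def category_counts(categories: pd.DataFrame) -> dict[str, int]:
    counts = categories["category"].value_counts().to_dict()
    return {str(k): int(v) for k, v in counts.items()}


def genes_in_category(categories: pd.DataFrame, category: str) -> set[str]:
    mask = categories["category"] == category
    return set(categories.loc[mask, "gene_id"].astype(str))


def refine_assimilation_candidates(
    categories: pd.DataFrame,
    selection_set: set[str],
    fixed_regulatory_set: set[str],
) -> dict[str, object]:
    """Nested candidate lists: taxon-plastic genes that also show
    selection evidence, and of those the ones with a fixed regulatory
    difference. Returns sorted lists and their sizes."""
    teo = genes_in_category(categories, "teosinte_specific")
    selected = teo & {str(g) for g in selection_set}
    fixed = selected & {str(g) for g in fixed_regulatory_set}
    return {
        "teosinte_specific_selected": sorted(selected),
        "teosinte_specific_selected_fixed": sorted(fixed),
        "n_selected": len(selected),
        "n_selected_fixed": len(fixed),
    }
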