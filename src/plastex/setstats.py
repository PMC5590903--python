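"""Gene-set overlap statistics.

Monte-Carlo resampling of equal-sized random sets from the expressed
background (the primary procedure), an exact hypergeometric tail as the
analytic oracle, and Fisher-exact term enrichment with
Benjamini-Yekutieli correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from plastex.datatypes import PlastexError
from plastex.diffexpr import adjust_pvalues


def hypergeometric_overlap_p(
    k: int, K: int, n: int, N: int, tail: str = "upper"
) -> float:
    """Exact tail probability of Hypergeometric(N, K, n) at overlap k.

    ``upper`` gives P(X >= k), ``lower`` gives P(X <= k); summed in log
    space over the support.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise PlastexError("need 0 <= K, n <= N")
    if not (0 <= k <= min(n, K)):
        raise PlastexError("need 0 <= k <= min(n, K)")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if tail == "upper":
        support = np.arange(k, hi + 1)
    elif tail == "lower":
        support = np.arange(lo, k + 1)
    else:
        raise PlastexError(f"unknown tail {tail!r}")
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


@dataclass
class EnrichmentResult:
    """Observed overlap of a candidate set with an annotation set plus
    the Monte-Carlo null summary."""

    candidate_name: str
    annotation_name: str
    candidate_size: int
    annotation_size: int
    background_size: int
    observed_overlap: int
    n_resamples: int
    null_mean: float
    null_sd: float
    z_score: float
    p_enrich: float
    p_deplete: float
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def resample_enrichment(
    candidate_set: set[str],
    annotation_set: set[str],
    background: set[str],
    n_resamples: int = 10_000,
    seed: int = 0,
    candidate_name: str = "candidate",
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """Empirical overlap enrichment against equal-sized random sets.

    Draws ``n_resamples`` uniform subsets of the background of the
    candidate's size and compares their overlap with the annotation set
    to the observed one. Empirical p-values carry the +1 pseudocount, so
    the smallest reportable p is 1/(n_resamples+1).
    """
    if n_resamples < 100:
        raise PlastexError("n_resamples must be >= 100")
    background = {str(g) for g in background}
    if not background:
        raise PlastexError("empty background")
    candidate = {str(g) for g in candidate_set}
    if not candidate <= background:
        stray = len(candidate - background)
        warnings.warn(
            f"{stray} candidate genes outside background ignored",
            stacklevel=2,
        )
        candidate &= background
    if len(candidate) > len(background):
        raise PlastexError("candidate larger than background")
    annotation = {str(g) for g in annotation_set} & background

    bg = sorted(background)
    ann_mask = np.fromiter((g in annotation for g in bg), dtype=bool,
                           count=len(bg))
    n = len(candidate)
    k_obs = len(candidate & annotation)

    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples, dtype=np.int64)
    N = len(bg)
    for b in range(n_resamples):
        idx = rng.choice(N, size=n, replace=False)
        null[b] = int(ann_mask[idx].sum())
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_resamples > 1 else 0.0
    z = (k_obs - null_mean) / null_sd if null_sd > 0 else 0.0
    p_enrich = (1 + int((null >= k_obs).sum())) / (n_resamples + 1)
    p_deplete = (1 + int((null <= k_obs).sum())) / (n_resamples + 1)
    return EnrichmentResult(
        candidate_name=candidate_name,
        annotation_name=annotation_name,
        candidate_size=n,
        annotation_size=len(annotation),
        background_size=N,
        observed_overlap=k_obs,
        n_resamples=n_resamples,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=float(z),
        p_enrich=float(p_enrich),
        p_deplete=float(p_deplete),
        seed=seed,
    )


def term_enrichment(
    gene_set: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
    min_term_size: int = 5,
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment with BY adjustment.

    Genes without terms are dropped from both the set and the
    background. Terms annotating fewer than ``min_term_size`` background
    genes are skipped. The Fisher test is two-sided.
    """
    background = {str(g) for g in background}
    annotated = {g for g in background if term_map.get(g)}
    if not annotated:
        raise PlastexError("no background gene has a term annotation")
    genes = {str(g) for g in gene_set} & annotated

    term_members: dict[str, set[str]] = {}
    for g in annotated:
        for t in term_map[g]:
            term_members.setdefault(t, set()).add(g)

    rows = []
    n_set = len(genes)
    n_bg = len(annotated)
    for term in sorted(term_members):
        members = term_members[term]
        if len(members) < min_term_size:
            continue
        a = len(genes & members)
        b = n_set - a
        c = len(members) - a
        d = n_bg - n_set - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if np.isnan(odds):  # degenerate margin, e.g. term covers everything
            odds = 1.0
        rows.append(
            {
                "term": term,
                "set_in_term": a,
                "set_not_in_term": b,
                "background_in_term": len(members),
                "background_size": n_bg,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "set_in_term", "set_not_in_term",
                 "background_in_term", "background_size", "odds_ratio",
                 "p_value"],
    )
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["p_adj"] = adjust_pvalues(out["p_value"].to_numpy(), "BY")
    out["significant"] = out["p_adj"] <= alpha
    return out
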