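"""Weighted co-expression networks, modules, and preservation.

Pearson-correlation adjacencies raised to a soft power, topological
overlap, average-linkage module detection with eigengene merging, and
permutation Z statistics for cross-environment module preservation.

The tree cut here is a static quantile cut plus a minimum module size —
a documented simplification of the dynamic hybrid cut, so absolute
module counts are configuration-dependent and not comparison targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from plastex.datatypes import ConfigError, CountMatrix, PlastexError

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    beta: int = 6
    network_type: str = "unsigned"
    min_module_size: int = 30
    merge_cutoff: float = 0.25
    cut_height_quantile: float = 0.99
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ConfigError("beta must be >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise ConfigError(f"unknown network type {self.network_type!r}")
        if not 0 < self.merge_cutoff < 1:
            raise ConfigError("merge_cutoff must lie in (0, 1)")
        if not 0 < self.cut_height_quantile <= 1:
            raise ConfigError("cut_height_quantile must lie in (0, 1]")


@dataclass
class ModuleAssignment:
    """Gene -> module label (0 = unassigned) with module eigengenes."""

    labels: pd.Series
    eigengenes: pd.DataFrame  # samples x modules, columns "ME<k>"

    @property
    def module_sizes(self) -> dict[int, int]:
        counts = self.labels.value_counts().to_dict()
        return {int(k): int(v) for k, v in counts.items()}

    def genes_in(self, module: int) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    def modules(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)


@dataclass
class PreservationResult:
    module: int
    size: int
    z_density: float
    z_connectivity: float
    z_summary: float = field(init=False)
    preservation_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.z_summary = (self.z_density + self.z_connectivity) / 2.0
        self.preservation_class = classify_preservation(self.z_summary)


def classify_preservation(z_summary: float) -> str:
    """Band a preservation Z score: <2 none, 2..10 moderate, >10 high."""
    if z_summary < 2:
        return "none"
    if z_summary <= 10:
        return "moderate"
    return "high"


def filter_coexpression_genes(
    counts_maize: CountMatrix,
    counts_teosinte: CountMatrix,
    design_maize,
    design_teosinte,
) -> list[str]:
    """Genes expressed in every taxon x condition group.

    A gene is retained iff it has at least one nonzero count in each of
    the four (taxon, condition) groups; the returned ids follow the
    maize matrix order.
    """
    retained = None
    for counts, design in (
        (counts_maize, design_maize),
        (counts_teosinte, design_teosinte),
    ):
        design.check_matches(counts)
        tbl = design.table.set_index("sample_id").loc[counts.sample_ids]
        conds = set(tbl["condition"])
        if len(conds) < 2:
            raise PlastexError("a taxon is missing one of the conditions")
        expressed = pd.Series(True, index=counts.data.index)
        for cond in sorted(conds):
            cols = tbl.index[tbl["condition"] == cond]
            expressed &= (counts.data[cols] > 0).any(axis=1)
        genes = set(counts.data.index[expressed])
        retained = genes if retained is None else retained & genes
    return [g for g in counts_maize.gene_ids if g in retained]


def transform_counts(
    counts: CountMatrix, size_factors: pd.Series
) -> pd.DataFrame:
    """Variance-flattening transform: log2(count / s_j + 1).

    Strictly monotone per sample; zero counts map to 0.
    """
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    if (sf <= 0).any():
        raise PlastexError("size factors must be positive")
    return pd.DataFrame(
        np.log2(counts.values / sf[None, :] + 1.0),
        index=counts.data.index,
        columns=counts.data.columns,
    )


def _correlation(expr: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Gene-gene Pearson correlation; zero-variance genes dropped."""
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise PlastexError("all genes have constant expression")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance genes",
            stacklevel=3,
        )
    values = values[keep]
    genes = [g for g, k in zip(expr.index, keep) if k]
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    return corr, genes


def adjacency_from_expr(
    expr: pd.DataFrame, beta: int, network_type: str = "unsigned"
) -> pd.DataFrame:
    """Soft-power adjacency: |cor|^beta (unsigned) or ((1+cor)/2)^beta."""
    corr, genes = _correlation(expr)
    if network_type == "unsigned":
        adj = np.abs(corr) ** beta
    else:
        adj = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=genes, columns=genes)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with k_i the connectivity excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # with a zeroed diagonal, (a @ a)_ij = sum_{u != i,j} a_iu a_uj
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def build_tom(
    expr: pd.DataFrame, params: NetworkParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjacency and TOM for an expression matrix (genes x samples)."""
    if expr.shape[1] < 3:
        raise PlastexError("need at least 3 samples to build a network")
    adjacency = adjacency_from_expr(expr, params.beta, params.network_type)
    tom = tom_from_adjacency(adjacency.to_numpy())
    tom_df = pd.DataFrame(tom, index=adjacency.index,
                          columns=adjacency.columns)
    return adjacency, tom_df


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins connectivity, regresses log10 frequency on log10 mean bin
    connectivity, and returns (signed R^2, slope); the R^2 is negated
    when the slope is positive so only decaying degree distributions
    can pass a threshold.
    """
    k = np.asarray(k, dtype=float)
    if k.size < n_bins:
        raise PlastexError("fewer genes than connectivity bins")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    signed = -np.sign(slope) * r2 if slope != 0 else r2
    return float(signed), float(slope)


def pick_soft_power(
    expr: pd.DataFrame,
    candidate_betas=tuple(range(1, 21)),
    r2_threshold: float = 0.8,
    network_type: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power whose network reaches the scale-free
    fit threshold; falls back to the largest candidate with a warning."""
    candidates = sorted(set(int(b) for b in candidate_betas))
    if len(candidates) < 1:
        raise ConfigError("need at least one candidate power")
    corr, genes = _correlation(expr)
    if len(genes) < n_bins:
        raise PlastexError("fewer genes than connectivity bins")
    base = np.abs(corr) if network_type == "unsigned" else (1 + corr) / 2
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in candidates:
        k = (base**beta).sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"beta": beta, "r2": r2, "slope": slope,
                     "mean_k": float(k.mean())})
    fits = pd.DataFrame(rows)
    passing = fits.loc[fits["r2"] >= r2_threshold, "beta"]
    if passing.empty:
        warnings.warn(
            f"no candidate power reaches R^2 >= {r2_threshold}; using "
            f"the largest candidate {candidates[-1]}",
            stacklevel=2,
        )
        return candidates[-1], fits
    return int(passing.iloc[0]), fits


def _module_eigengene(expr: np.ndarray) -> np.ndarray:
    """First principal component over samples of gene-standardized
    module expression; unit norm, oriented with the module mean."""
    sd = expr.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    norm = np.linalg.norm(eig)
    return eig / norm if norm > 0 else eig


def detect_modules(
    tom_dissimilarity: pd.DataFrame,
    expr: pd.DataFrame,
    params: NetworkParams,
) -> ModuleAssignment:
    """Average-linkage clustering of the TOM dissimilarity with a static
    quantile cut, minimum module size, and iterative eigengene merging
    at ``params.merge_cutoff``. Deterministic given inputs."""
    genes = list(tom_dissimilarity.index)
    d = tom_dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise PlastexError("dissimilarity must be square and symmetric")
    if len(genes) < params.min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned",
                      stacklevel=2)
        labels = pd.Series(0, index=genes, dtype=int)
        return ModuleAssignment(
            labels=labels,
            eigengenes=pd.DataFrame(index=expr.columns),
        )
    condensed = squareform(np.clip(d, 0, None), checks=False)
    Z = linkage(condensed, method="average")
    cut = float(np.quantile(Z[:, 2], params.cut_height_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")

    expr_mat = expr.loc[genes].to_numpy(dtype=float)
    labels = np.zeros(len(genes), dtype=int)
    next_label = 1
    for cl in np.unique(raw):
        idx = np.where(raw == cl)[0]
        if idx.size >= params.min_module_size:
            labels[idx] = next_label
            next_label += 1

    def eigengenes_for(lbls: np.ndarray) -> dict[int, np.ndarray]:
        return {
            m: _module_eigengene(expr_mat[lbls == m])
            for m in np.unique(lbls)
            if m != 0
        }

    eigs = eigengenes_for(labels)
    # merge modules whose eigengene dissimilarity is below the cutoff
    while len(eigs) > 1:
        mods = sorted(eigs)
        E = np.vstack([eigs[m] for m in mods])
        cor = np.clip(np.corrcoef(E), -1, 1)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= params.merge_cutoff:
            break
        keep, drop = mods[i], mods[j]
        labels[labels == drop] = keep
        eigs = eigengenes_for(labels)

    # relabel by decreasing size, 1..k
    sizes = {m: int((labels == m).sum()) for m in np.unique(labels) if m != 0}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    remap = {old: new + 1 for new, old in enumerate(order)}
    final = np.array([remap.get(l, 0) for l in labels], dtype=int)
    eigs = {
        remap[m]: v for m, v in eigengenes_for(labels).items()
    }
    eig_df = pd.DataFrame(
        {f"ME{m}": eigs[m] for m in sorted(eigs)}, index=expr.columns
    )
    return ModuleAssignment(
        labels=pd.Series(final, index=genes, dtype=int),
        eigengenes=eig_df,
    )


def _density_and_connectivity(
    adj_ref: np.ndarray, adj_test: np.ndarray
) -> tuple[float, float]:
    m = adj_ref.shape[0]
    off = ~np.eye(m, dtype=bool)
    density = float(adj_test[off].mean())
    k_ref = adj_ref.sum(axis=1) - 1.0
    k_test = adj_test.sum(axis=1) - 1.0
    if np.std(k_ref) == 0 or np.std(k_test) == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_ref, k_test)[0, 1])
    return density, conn


def module_preservation(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    modules: ModuleAssignment,
    params: NetworkParams,
) -> list[PreservationResult]:
    """Permutation Z statistics for module preservation in a test
    environment.

    Per module: density = mean intramodular adjacency in the test
    network; connectivity = correlation of intramodular connectivity
    between reference and test. Both are standardized against
    ``params.n_permutations`` size-matched random gene sets.
    """
    genes = [g for g in expr_ref.index if g in set(expr_test.index)]
    if len(genes) != len(expr_ref.index):
        raise PlastexError("reference and test gene universes differ")
    expr_ref = expr_ref.loc[genes]
    expr_test = expr_test.loc[genes]
    gene_pos = {g: i for i, g in enumerate(genes)}
    ref_mat = expr_ref.to_numpy(dtype=float)
    test_mat = expr_test.to_numpy(dtype=float)

    def adj_subset(mat: np.ndarray, idx: np.ndarray) -> np.ndarray:
        sub = mat[idx]
        sd = sub.std(axis=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        cor = np.clip(z @ z.T / sub.shape[1], -1, 1)
        if params.network_type == "unsigned":
            a = np.abs(cor) ** params.beta
        else:
            a = ((1 + cor) / 2) ** params.beta
        np.fill_diagonal(a, 1.0)
        return a

    rng = np.random.default_rng(params.seed)
    results = []
    for module in modules.modules():
        members = modules.genes_in(module)
        if len(members) < 3:
            warnings.warn(f"module {module}: fewer than 3 genes, skipped",
                          stacklevel=2)
            continue
        idx = np.array([gene_pos[g] for g in members])
        obs_d, obs_c = _density_and_connectivity(
            adj_subset(ref_mat, idx), adj_subset(test_mat, idx)
        )
        null_d = np.empty(params.n_permutations)
        null_c = np.empty(params.n_permutations)
        for b in range(params.n_permutations):
            ridx = rng.choice(len(genes), size=idx.size, replace=False)
            null_d[b], null_c[b] = _density_and_connectivity(
                adj_subset(ref_mat, ridx), adj_subset(test_mat, ridx)
            )
        sd_d = null_d.std(ddof=1)
        sd_c = null_c.std(ddof=1)
        z_d = (obs_d - null_d.mean()) / sd_d if sd_d > 0 else 0.0
        z_c = (obs_c - null_c.mean()) / sd_c if sd_c > 0 else 0.0
        results.append(
            PreservationResult(
                module=module,
                size=len(members),
                z_density=float(z_d),
                z_connectivity=float(z_c),
            )
        )
    return results


def preservation_table(results: list[PreservationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "size": r.size,
                "z_density": r.z_density,
                "z_connectivity": r.z_connectivity,
                "z_summary": r.z_summary,
                "preservation_class": r.preservation_class,
            }
            for r in results
        ],
        columns=["module", "size", "z_density", "z_connectivity",
                 "z_summary", "preservation_class"],
    )


def hub_genes(
    adjacency: pd.DataFrame,
    modules: ModuleAssignment,
    top_n: int = 10,
) -> dict[int, list[str]]:
    """Per-module genes ranked by intramodular connectivity (adjacency
    row sums within the module, diagonal excluded); lexicographic ties."""
    out: dict[int, list[str]] = {}
    for module in modules.modules():
        members = modules.genes_in(module)
        sub = adjacency.loc[members, members].to_numpy(dtype=float)
        k = sub.sum(axis=1) - np.diag(sub)
        ranked = sorted(zip(members, k), key=lambda t: (-t[1], t[0]))
        out[module] = [g for g, _ in ranked[:top_n]]
    return out
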