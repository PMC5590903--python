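"""Seeded synthetic-data generator with planted ground truth.

Generates negative-binomial count matrices for two taxa under two
environments with group (population / inbred-line) covariates, gene
response categories planted at configurable proportions, annotation
gene sets with configurable category enrichment, a gene x term map, a
per-gene diversity table with a taxon-wide reduction, and a many-line
panel expression matrix with category-dependent variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plastex.datatypes import (
    CATEGORIES,
    ConfigError,
    CountMatrix,
    SampleDesign,
)

# default category proportions anchored to the printed real-data counts:
# 1,021 shared DE genes, 3,953 maize DE, 3,355 teosinte DE, out of the
# 29,611 genes expressed in both taxa in both environments; shared genes
# split 80/20 same/opposite direction (free parameter).
_SHARED = 1021 / 29611
DEFAULT_CATEGORY_PROPORTIONS: dict[str, float] = {
    "maize_specific": (3953 - 1021) / 29611,
    "teosinte_specific": (3355 - 1021) / 29611,
    "shared_same": 0.8 * _SHARED,
    "shared_opposite": 0.2 * _SHARED,
}


@dataclass
class TaxonDesign:
    """Design of one taxon's grow-out: groups x replicates x conditions."""

    taxon: str
    n_groups: int = 4
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("EH", "MA")
    #: (group index, condition, replicate index) triples to drop
    missing: tuple[tuple[int, str, int], ...] = ()

    def build(self) -> SampleDesign:
        rows = []
        for g in range(self.n_groups):
            group = f"{self.taxon}_g{g + 1}"
            for cond in self.conditions:
                for r in range(self.n_replicates):
                    if (g, cond, r) in set(self.missing):
                        continue
                    rows.append(
                        {
                            "sample_id": f"{group}_{cond}_r{r + 1}",
                            "taxon": self.taxon,
                            "group": group,
                            "condition": cond,
                        }
                    )
        if not rows:
            raise ConfigError(f"empty design for taxon {self.taxon!r}")
        design = SampleDesign(pd.DataFrame(rows))
        counts = design.table.groupby(["taxon", "condition"]).size()
        if (counts < 2).any() and not self.missing:
            raise ConfigError(
                f"taxon {self.taxon!r}: fewer than 2 samples in a condition"
            )
        return design


def default_design() -> tuple[TaxonDesign, TaxonDesign]:
    """4 teosinte populations x 3 plants (one MA sample missing) and
    4 maize inbreds x 2 replicates, each in both environments."""
    teosinte = TaxonDesign(
        taxon="teosinte", n_groups=4, n_replicates=3,
        missing=((3, "MA", 2),),
    )
    maize = TaxonDesign(taxon="maize", n_groups=4, n_replicates=2)
    return maize, teosinte


@dataclass
class SimConfig:
    """Configuration for one synthetic two-taxon experiment."""

    n_genes: int = 2000
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    #: mean / sd of |log2 fold change| for responsive genes
    lfc_mean: float = 1.5
    lfc_sd: float = 0.5
    #: natural-log-scale mean / sd of the per-gene baseline mean
    base_mean_log_mean: float = math.log(200.0)
    base_mean_log_sd: float = 1.0
    #: natural-log-scale mean / sd of the per-gene NB dispersion
    dispersion_log_mean: float = math.log(0.1)
    dispersion_log_sd: float = 0.5
    #: sd (log2 units) of gene x group offsets
    population_effect_sd: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)
    design: tuple[TaxonDesign, ...] = field(
        default_factory=lambda: tuple(default_design())
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown categories {sorted(unknown)}")
        props = {k: float(v) for k, v in self.category_proportions.items()}
        if any(v < 0 for v in props.values()):
            raise ConfigError("category proportions must be >= 0")
        if sum(props.values()) > 1 + 1e-12:
            raise ConfigError("category proportions sum to more than 1")
        for name in ("lfc_sd", "base_mean_log_sd", "dispersion_log_sd",
                     "population_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be 0 < lo <= hi")
        if not self.design:
            raise ConfigError("design must list at least one taxon")
        self.category_proportions = props


def _category_counts(cfg: SimConfig) -> dict[str, int]:
    counts = {
        cat: int(round(cfg.n_genes * cfg.category_proportions.get(cat, 0.0)))
        for cat in CATEGORIES
        if cat != "non_DE"
    }
    assigned = sum(counts.values())
    if assigned > cfg.n_genes:
        raise ConfigError("category proportions exceed n_genes after rounding")
    counts["non_DE"] = cfg.n_genes - assigned
    return counts


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = _category_counts(cfg)
    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    categories = np.concatenate(
        [np.repeat(cat, n) for cat, n in counts.items()]
    )
    rng.shuffle(categories)

    def draw_lfc(n: int) -> np.ndarray:
        mag = np.abs(rng.normal(cfg.lfc_mean, cfg.lfc_sd, n))
        sign = rng.choice([-1.0, 1.0], n)
        return mag * sign

    n = cfg.n_genes
    lfc_m = np.zeros(n)
    lfc_t = np.zeros(n)
    for cat in ("maize_specific", "shared_same", "shared_opposite"):
        mask = categories == cat
        lfc_m[mask] = draw_lfc(mask.sum())
    for cat in ("teosinte_specific",):
        mask = categories == cat
        lfc_t[mask] = draw_lfc(mask.sum())
    same = categories == "shared_same"
    lfc_t[same] = np.sign(lfc_m[same]) * np.abs(draw_lfc(same.sum()))
    opp = categories == "shared_opposite"
    lfc_t[opp] = -np.sign(lfc_m[opp]) * np.abs(draw_lfc(opp.sum()))

    base_mean = rng.lognormal(cfg.base_mean_log_mean, cfg.base_mean_log_sd, n)
    dispersion = rng.lognormal(
        cfg.dispersion_log_mean, cfg.dispersion_log_sd, n
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": categories,
            "lfc_maize": lfc_m,
            "lfc_teosinte": lfc_t,
            "base_mean": base_mean,
            "dispersion": dispersion,
        }
    )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               alpha: np.ndarray) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2 (gamma-Poisson mixture)."""
    alpha = np.broadcast_to(alpha, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-10
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    rest = ~tiny
    if rest.any():
        shape = 1.0 / alpha[rest]
        lam = rng.gamma(shape, alpha[rest] * mu[rest])
        out[rest] = rng.poisson(lam)
    return out


def simulate_experiment(
    config: SimConfig,
) -> tuple[dict[str, CountMatrix], dict[str, SampleDesign], pd.DataFrame]:
    """Simulate count matrices for every taxon in the design.

    Counts are NB with mean
    ``libsize_j * base_mean_g * 2**(x_j * lfc_{taxon,g} + popeffect)``
    where ``x_j`` is 1 in EH and 0 in MA, and per-gene dispersion from
    the configured log-normal. Fully reproducible from ``config.seed``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(
        1 + 2 * len(config.design)
    )
    rng_truth = np.random.default_rng(streams[0])
    truth = _draw_truth(config, rng_truth)

    counts: dict[str, CountMatrix] = {}
    designs: dict[str, SampleDesign] = {}
    for i, taxon_design in enumerate(config.design):
        design = taxon_design.build()
        taxon = taxon_design.taxon
        rng_pop = np.random.default_rng(streams[1 + 2 * i])
        rng_counts = np.random.default_rng(streams[2 + 2 * i])

        lfc_col = f"lfc_{taxon}"
        lfc = (
            truth[lfc_col].to_numpy()
            if lfc_col in truth.columns
            else np.zeros(len(truth))
        )
        groups = sorted(set(design.table["group"]))
        pop_eff = {
            g: rng_pop.normal(0.0, config.population_effect_sd, config.n_genes)
            for g in groups
        }
        lo, hi = config.library_size_range
        sample_ids = design.sample_ids
        libsizes = rng_counts.uniform(lo, hi, len(sample_ids))
        x = design.condition_indicator(sample_ids)
        sample_groups = design.groups(sample_ids)

        mat = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
        base = truth["base_mean"].to_numpy()
        alpha = truth["dispersion"].to_numpy()
        for j, sid in enumerate(sample_ids):
            log2_shift = x[j] * lfc + pop_eff[sample_groups[j]]
            mu = libsizes[j] * base * np.exp2(log2_shift)
            mat[:, j] = _nb_sample(rng_counts, mu, alpha)
        counts[taxon] = CountMatrix(
            pd.DataFrame(mat, index=truth["gene_id"], columns=sample_ids)
        )
        designs[taxon] = design
    return counts, designs, truth


def simulate_annotations(
    truth: pd.DataFrame,
    enrichment_spec: dict[str, tuple[int, dict[str, float]]],
    seed: int,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 200),
    diversity_reduction: dict[str, float] | None = None,
    diversity_log_sd: float = 0.6,
) -> tuple[dict[str, set[str]], dict[str, set[str]], pd.DataFrame]:
    """Annotation sets with category-weighted membership, a gene->term
    map, and a two-taxon per-gene diversity table.

    ``enrichment_spec`` maps set name -> (size, {category: odds}); an
    absent category has odds 1. Sets are drawn without replacement with
    inclusion keys proportional to the odds (exponential-key weighted
    sampling), so the realized membership odds ratio approximates the
    configured odds when set size is small relative to n_genes.

    ``diversity_reduction`` maps taxon -> multiplicative factor applied
    to the per-gene base diversity (default maize 0.7, teosinte 1.0);
    the ratio of taxon medians equals the ratio of the factors.
    """
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_sets = np.random.default_rng(streams[0])
    rng_terms = np.random.default_rng(streams[1])
    rng_div = np.random.default_rng(streams[2])

    genes = truth["gene_id"].to_numpy()
    categories = truth["category"].to_numpy()
    n = len(genes)

    sets: dict[str, set[str]] = {}
    for name, (size, odds) in enrichment_spec.items():
        if size > n:
            raise ConfigError(
                f"set {name!r}: requested size {size} exceeds {n} genes"
            )
        weights = np.array(
            [float(odds.get(cat, 1.0)) for cat in categories]
        )
        if (weights < 0).any():
            raise ConfigError(f"set {name!r}: negative odds")
        eligible = weights > 0
        if eligible.sum() < size:
            raise ConfigError(
                f"set {name!r}: only {int(eligible.sum())} eligible genes "
                f"for size {size}"
            )
        # exponential-key weighted sampling without replacement
        keys = np.full(n, np.inf)
        keys[eligible] = (
            rng_sets.exponential(size=int(eligible.sum()))
            / weights[eligible]
        )
        chosen = np.argpartition(keys, size - 1)[:size] if size else []
        sets[name] = {str(genes[i]) for i in chosen}

    term_map: dict[str, set[str]] = {}
    lo, hi = term_size_range
    for t in range(n_terms):
        term = f"TERM{t + 1:04d}"
        size = int(rng_terms.integers(lo, min(hi, n) + 1))
        members = rng_terms.choice(n, size=size, replace=False)
        for i in members:
            term_map.setdefault(str(genes[i]), set()).add(term)

    reductions = {"teosinte": 1.0, "maize": 0.7}
    if diversity_reduction:
        reductions.update(diversity_reduction)
    base = rng_div.lognormal(math.log(0.01), diversity_log_sd, n)
    div = pd.DataFrame({"gene_id": genes})
    for taxon, factor in reductions.items():
        noise = np.exp(rng_div.normal(0.0, 0.1, n))
        div[taxon] = base * factor * noise
    return sets, term_map, div


def simulate_panel(
    truth: pd.DataFrame,
    n_lines: int,
    variance_spec: dict[str, float],
    seed: int,
    base_log_mean: float = math.log(100.0),
    base_log_sd: float = 1.0,
    default_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Panel expression matrix (genes x lines), log-normal per gene with
    category-dependent log-scale sd. A gene in category ``c`` has
    ``CV = sqrt(exp(sigma_c**2) - 1)`` where ``sigma_c`` is
    ``variance_spec[c]`` (``default_log_sd`` when absent); sigma 0 gives
    a constant gene."""
    if n_lines < 2:
        raise ConfigError("n_lines must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = truth["gene_id"].to_numpy()
    categories = truth["category"].to_numpy()
    n = len(genes)
    sigma = np.array(
        [float(variance_spec.get(cat, default_log_sd)) for cat in categories]
    )
    if (sigma < 0).any():
        raise ConfigError("variance_spec sds must be >= 0")
    mean = rng.lognormal(base_log_mean, base_log_sd, n)
    z = rng.normal(0.0, 1.0, (n, n_lines))
    # mean-preserving log-normal: E[value] = mean, CV = sqrt(e^{s^2}-1)
    values = mean[:, None] * np.exp(
        sigma[:, None] * z - 0.5 * sigma[:, None] ** 2
    )
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=[f"line{j + 1}" for j in range(n_lines)])
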