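"""End-to-end orchestration: simulate/load -> DE -> classify -> set
statistics -> co-expression -> variability, with one top-level seed and
a machine-readable JSON report."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from plastex import __version__, io
from plastex.classify import (
    category_counts,
    classify_genes,
    genes_in_category,
    refine_assimilation_candidates,
)
from plastex.coexpression import (
    NetworkParams,
    build_tom,
    detect_modules,
    filter_coexpression_genes,
    hub_genes,
    module_preservation,
    preservation_table,
    transform_counts,
)
from plastex.datatypes import ConfigError
from plastex.diffexpr import (
    estimate_dispersions,
    estimate_size_factors,
    remove_flagged_genes,
    significant_genes,
    test_condition_effect,
)
from plastex.setstats import resample_enrichment, term_enrichment
from plastex.synthetic import (
    SimConfig,
    simulate_annotations,
    simulate_experiment,
    simulate_panel,
)
from plastex.variability import compare_categories, gene_cv

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("de", "classify", "enrich", "coexpress", "variability")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    alpha_fdr: float = 0.05
    n_resamples: int = 10_000
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in DEFAULT_STAGES}
    )
    simulate: dict | None = None
    inputs: dict | None = None
    annotations: dict | None = None
    panel: dict | None = None
    network: dict = field(default_factory=dict)
    #: cap on genes entering the network stage (top variance)
    coexpress_max_genes: int = 400

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs a 'simulate' or 'inputs' block")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.out_dir = Path(self.out_dir)
        stages = {s: True for s in DEFAULT_STAGES}
        stages.update({k: bool(v) for k, v in (self.stages or {}).items()})
        unknown = set(stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        self.stages = stages

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "seed", "out_dir", "alpha_fdr", "n_resamples", "stages",
            "simulate", "inputs", "annotations", "panel", "network",
            "coexpress_max_genes",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ("simulate", "annotations", "panel", "enrich", "coexpress")
    return {n: int(s) for n, s in
            zip(names, rng.integers(0, 2**31 - 1, size=len(names)))}


class PipelineError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Writes every intermediate table under ``config.out_dir`` and returns
    the run report (also written as ``report.json``). The report is a
    pure function of config + seed.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "alpha_fdr": config.alpha_fdr,
        "parameters": {
            "n_resamples": config.n_resamples,
            "network": dict(config.network),
            "coexpress_max_genes": config.coexpress_max_genes,
        },
        "stages_run": [],
        "input_fingerprints": {},
        "warnings": [],
    }
    timings: dict[str, float] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage
            raise PipelineError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        report["stages_run"].append(name)
        logger.info("stage %s done in %.2fs", name, timings[name])

    state: dict = {}

    def stage_data():
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs["seed"] = seeds["simulate"]
            sim = SimConfig(**sim_kwargs)
            counts, designs, truth = simulate_experiment(sim)
            state["counts"] = counts
            state["designs"] = designs
            state["truth"] = truth
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            for taxon in counts:
                io.write_count_table(counts[taxon],
                                     out / f"counts_{taxon}.tsv")
                io.write_design_table(designs[taxon],
                                      out / f"design_{taxon}.tsv")
            ann_spec = {
                name: (int(block["size"]), dict(block.get("odds", {})))
                for name, block in (config.annotations or {}).items()
            } or {
                "selection": (max(2, len(truth) // 20),
                              {"teosinte_specific": 3.0}),
                "fixed_regulatory": (max(1, len(truth) // 60),
                                     {"teosinte_specific": 2.0}),
            }
            sets, term_map, diversity = simulate_annotations(
                truth, ann_spec, seed=seeds["annotations"]
            )
            state["gene_sets"] = sets
            state["term_map"] = term_map
            state["diversity"] = diversity.set_index("gene_id")
            for name, genes in sets.items():
                io.write_gene_set(genes, out / f"set_{name}.txt")
            io.write_term_map(term_map, out / "term_map.tsv")
            diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
            panel_spec = dict(config.panel or {})
            state["panel"] = simulate_panel(
                truth,
                n_lines=int(panel_spec.get("n_lines", 200)),
                variance_spec=dict(
                    panel_spec.get(
                        "variance_spec",
                        {"teosinte_specific": 0.3, "maize_specific": 0.4,
                         "non_DE": 0.5},
                    )
                ),
                seed=seeds["panel"],
            )
            io.write_expression_table(state["panel"], out / "panel.tsv")
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()}
            for key, p in paths.items():
                if p.exists():
                    report["input_fingerprints"][key] = _sha256(p)
            state["counts"] = {}
            state["designs"] = {}
            for taxon in ("maize", "teosinte"):
                ckey, dkey = f"{taxon}_counts", f"{taxon}_design"
                if ckey in paths:
                    state["counts"][taxon] = io.read_count_table(paths[ckey])
                    state["designs"][taxon] = io.read_design_table(
                        paths[dkey]
                    )
                if f"de_{taxon}" in paths:
                    state.setdefault("de", {})[taxon] = io.read_de_table(
                        paths[f"de_{taxon}"]
                    )
            if "flag_genes" in paths:
                state["flag_genes"] = io.read_gene_set(paths["flag_genes"])
            sets = {}
            for key in ("selection", "fixed_regulatory"):
                if key in paths:
                    sets[key] = io.read_gene_set(paths[key])
            state["gene_sets"] = sets
            if "term_map" in paths:
                state["term_map"] = io.read_term_map(paths["term_map"])
            if "panel" in paths:
                state["panel"] = io.read_expression_table(paths["panel"])
            if "diversity" in paths:
                state["diversity"] = io.read_expression_table(
                    paths["diversity"]
                )

    def stage_de():
        if "de" not in state:  # otherwise precomputed tables were supplied
            state["de"] = {}
            state["size_factors"] = {}
            for taxon, counts in state["counts"].items():
                design = state["designs"][taxon]
                sf = estimate_size_factors(counts)
                disp = estimate_dispersions(counts, design, sf)
                de = test_condition_effect(counts, design, sf, disp)
                state["de"][taxon] = de
                state["size_factors"][taxon] = sf
                io.write_de_table(de, out / f"de_{taxon}.tsv")
        report["de"] = {
            taxon: {
                "n_significant": len(significant_genes(de, config.alpha_fdr)),
                "n_tested": int(de["p_adj"].notna().sum()),
            }
            for taxon, de in state["de"].items()
        }
        flag = state.get("flag_genes")
        if flag and {"maize", "teosinte"} <= set(state["de"]):
            m, t, removed = remove_flagged_genes(
                state["de"]["maize"], state["de"]["teosinte"], flag,
                alpha=config.alpha_fdr,
            )
            state["de"]["maize"], state["de"]["teosinte"] = m, t
            report["de"]["flagged_removed"] = removed

    def stage_classify():
        cats = classify_genes(
            state["de"]["maize"], state["de"]["teosinte"],
            alpha=config.alpha_fdr,
        )
        state["categories"] = cats
        cats.to_csv(out / "categories.tsv", sep="\t", index=False)
        report["classification"] = {
            "counts": category_counts(cats),
            "universe_size": int(len(cats)),
        }
        sets = state.get("gene_sets", {})
        if "selection" in sets:
            refined = refine_assimilation_candidates(
                cats,
                sets["selection"],
                sets.get("fixed_regulatory", set()),
            )
            report["classification"]["assimilation_candidates"] = {
                "n_selected": refined["n_selected"],
                "n_selected_fixed": refined["n_selected_fixed"],
            }
            io.write_gene_set(refined["teosinte_specific_selected"],
                              out / "assimilation_candidates.txt")

    def stage_enrich():
        cats = state["categories"]
        universe = set(cats["gene_id"].astype(str))
        sig_m = genes_in_category(cats, "maize_specific") | genes_in_category(
            cats, "shared_same") | genes_in_category(cats, "shared_opposite")
        sig_t = (
            genes_in_category(cats, "teosinte_specific")
            | genes_in_category(cats, "shared_same")
            | genes_in_category(cats, "shared_opposite")
        )
        results = []
        independence = resample_enrichment(
            sig_m, sig_t, universe,
            n_resamples=config.n_resamples,
            seed=seeds["enrich"],
            candidate_name="maize_DE",
            annotation_name="teosinte_DE",
        )
        results.append(independence.to_dict())
        for i, (name, genes) in enumerate(
            sorted(state.get("gene_sets", {}).items())
        ):
            for cat in ("teosinte_specific", "maize_specific"):
                res = resample_enrichment(
                    genes_in_category(cats, cat), genes, universe,
                    n_resamples=config.n_resamples,
                    seed=seeds["enrich"] + 1 + i,
                    candidate_name=cat,
                    annotation_name=name,
                )
                results.append(res.to_dict())
        enrich_df = pd.DataFrame(results)
        enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "overlap_independence_p": independence.p_enrich,
            "results": results,
        }
        if "term_map" in state:
            terms = term_enrichment(
                genes_in_category(cats, "teosinte_specific"),
                universe,
                state["term_map"],
                alpha=config.alpha_fdr,
            )
            terms.to_csv(out / "term_enrichment.tsv", sep="\t", index=False)
            report["enrichment"]["n_significant_terms"] = int(
                terms["significant"].sum()
            ) if not terms.empty else 0

    def stage_coexpress():
        counts = state["counts"]
        designs = state["designs"]
        if not {"maize", "teosinte"} <= set(counts):
            raise ConfigError("co-expression needs both taxa's counts")
        retained = filter_coexpression_genes(
            counts["maize"], counts["teosinte"],
            designs["maize"], designs["teosinte"],
        )
        report["coexpression"] = {"n_filtered_genes": len(retained)}
        net_kwargs = dict(config.network)
        net_kwargs.setdefault("seed", seeds["coexpress"])
        params = NetworkParams(**net_kwargs)
        preservation = {}
        modules_out = {}
        for taxon in ("maize", "teosinte"):
            cm = counts[taxon].subset_genes(retained)
            sf = state.get("size_factors", {}).get(taxon)
            if sf is None:
                sf = estimate_size_factors(cm, pseudo_reference=True)
            expr = transform_counts(cm, sf)
            # cap network size at the most variable retained genes
            if expr.shape[0] > config.coexpress_max_genes:
                top = (
                    expr.var(axis=1)
                    .sort_values(ascending=False)
                    .index[: config.coexpress_max_genes]
                )
                expr = expr.loc[[g for g in expr.index if g in set(top)]]
            tbl = designs[taxon].table.set_index("sample_id")
            eh = [s for s in expr.columns if tbl.loc[s, "condition"] == "EH"]
            ma = [s for s in expr.columns if tbl.loc[s, "condition"] == "MA"]
            adjacency, tom = build_tom(expr[eh], params)
            dissim = 1.0 - tom
            modules = detect_modules(dissim, expr[eh].loc[tom.index], params)
            modules.labels.rename("module").to_csv(
                out / f"modules_{taxon}.tsv", sep="\t",
                index_label="gene_id",
            )
            pres = module_preservation(
                expr.loc[tom.index][eh], expr.loc[tom.index][ma],
                modules, params,
            )
            preservation_table(pres).to_csv(
                out / f"preservation_{taxon}.tsv", sep="\t", index=False
            )
            hubs = hub_genes(adjacency, modules, top_n=5)
            modules_out[taxon] = {
                "n_modules": len(modules.modules()),
                "module_sizes": {
                    str(k): v for k, v in modules.module_sizes.items()
                },
                "hub_genes": {str(k): v for k, v in hubs.items()},
            }
            preservation[taxon] = {
                str(r.module): {
                    "z_summary": r.z_summary,
                    "class": r.preservation_class,
                }
                for r in pres
            }
        report["coexpression"]["modules"] = modules_out
        report["coexpression"]["preservation"] = preservation

    def stage_variability():
        cats = state["categories"]
        pairs = [
            ("non_DE", "maize_specific"),
            ("non_DE", "teosinte_specific"),
            ("maize_specific", "teosinte_specific"),
        ]
        report["variability"] = {}
        if "panel" in state:
            cv = gene_cv(state["panel"])
            cv.rename("cv").to_csv(out / "gene_cv.tsv", sep="\t",
                                   index_label="gene_id")
            res = compare_categories(cv, cats, pairs=pairs,
                                     statistic_name="cv")
            res["comparisons"].to_csv(out / "cv_comparisons.tsv", sep="\t",
                                      index=False)
            report["variability"]["cv"] = {
                "summary": res["summary"].to_dict(orient="records"),
                "comparisons": res["comparisons"].to_dict(orient="records"),
            }
        if "diversity" in state:
            div = state["diversity"]
            for taxon in div.columns:
                res = compare_categories(
                    div[taxon], cats, pairs=pairs,
                    statistic_name=f"diversity_{taxon}",
                )
                res["comparisons"].to_csv(
                    out / f"diversity_comparisons_{taxon}.tsv", sep="\t",
                    index=False,
                )
                report["variability"][f"diversity_{taxon}"] = {
                    "summary": res["summary"].to_dict(orient="records"),
                    "comparisons": res["comparisons"].to_dict(
                        orient="records"
                    ),
                }

    run_stage("data", stage_data)
    if config.stages.get("de"):
        run_stage("de", stage_de)
    if config.stages.get("classify"):
        run_stage("classify", stage_classify)
    if config.stages.get("enrich"):
        run_stage("enrich", stage_enrich)
    if config.stages.get("coexpress"):
        run_stage("coexpress", stage_coexpress)
    if config.stages.get("variability"):
        run_stage("variability", stage_variability)

    report["timings_s"] = {}  # kept out of the determinism contract
    io.write_json_report(report, out / "report.json")
    report["timings_s"] = timings
    return report
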