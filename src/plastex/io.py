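"""Readers and writers for every tabular artifact.

All text formats are delimited (TSV written by default, CSV accepted on
read with automatic sniffing). Gene identifiers are treated as opaque
strings; an opt-in flag strips transcript-version suffixes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from plastex.datatypes import (
    CountMatrix,
    GeneSetCollection,
    ParseError,
    SampleDesign,
)

# case-insensitive column aliases for DE-result tables exported by the
# usual count-model tools; extensible at call sites
DE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene_id", "gene", "geneid", "id", "row", "unnamed: 0", ""),
    "base_mean": ("base_mean", "basemean", "mean_expression", "meanexpr",
                  "mean"),
    "lfc": ("lfc", "log2foldchange", "log2fc", "logfc", "log2_fold_change"),
    "lfc_se": ("lfc_se", "lfcse", "se"),
    "wald_stat": ("wald_stat", "stat", "wald", "z"),
    "p_value": ("p_value", "pvalue", "pval", "p"),
    "p_adj": ("p_adj", "padj", "fdr", "qvalue", "adj_p", "adjusted_pvalue",
              "q_value"),
}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _strip_versions(ids: pd.Index) -> pd.Index:
    return pd.Index([str(g).split(".")[0] for g in ids], name=ids.name)


def read_count_table(
    path,
    gene_column: str | None = None,
    sep: str | None = None,
    normalize_ids: bool = False,
) -> CountMatrix:
    """Read a delimited gene x sample count table.

    The gene-id column is either ``gene_column``, a column recognisably
    named (gene/gene_id/id, case-insensitive), or the first column.
    Values within 1e-9 of an integer are rounded; anything else is a
    :class:`ParseError`.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene column plus counts")
    if gene_column is None:
        lowered = {str(c).strip().lower(): c for c in df.columns}
        for cand in ("gene_id", "gene", "geneid", "id", "unnamed: 0"):
            if cand in lowered:
                gene_column = lowered[cand]
                break
        else:
            gene_column = df.columns[0]
    elif gene_column not in df.columns:
        raise ParseError(f"{path}: no column {gene_column!r}")
    df = df.set_index(gene_column)
    df.index = df.index.astype(str)
    if normalize_ids:
        df.index = _strip_versions(df.index)
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric sample columns {non_numeric}")
    try:
        return CountMatrix(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_count_table(counts: CountMatrix, path, sep: str = "\t") -> None:
    counts.data.to_csv(path, sep=sep, index_label="gene_id")


def read_design_table(path, sep: str | None = None) -> SampleDesign:
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    return SampleDesign(pd.read_csv(path, sep=sep, dtype=str))


def write_design_table(design: SampleDesign, path, sep: str = "\t") -> None:
    design.table.to_csv(path, sep=sep, index=False)


def read_de_table(
    path,
    sep: str | None = None,
    extra_aliases: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Read a DE-result table, mapping known column aliases onto the
    canonical schema (gene_id, base_mean, lfc, lfc_se, wald_stat,
    p_value, p_adj). Unknown columns are preserved as-is; missing
    optional columns are filled with NaN. gene_id and p_adj are
    required (possibly via the row index)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    aliases = {k: tuple(v) for k, v in DE_COLUMN_ALIASES.items()}
    if extra_aliases:
        for key, names in extra_aliases.items():
            aliases[key] = tuple(names) + aliases.get(key, ())
    rename: dict[str, str] = {}
    taken: set[str] = set()
    for canonical, names in aliases.items():
        for col in df.columns:
            if col in taken:
                continue
            if str(col).strip().lower() in names:
                rename[col] = canonical
                taken.add(col)
                break
    df = df.rename(columns=rename)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: no recognizable gene-id column")
    if "p_adj" not in df.columns:
        raise ParseError(f"{path}: no recognizable adjusted-p column")
    df["gene_id"] = df["gene_id"].astype(str)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    for col in ("base_mean", "lfc", "lfc_se", "wald_stat", "p_value",
                "p_adj"):
        if col not in df.columns:
            df[col] = np.nan
        else:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    ordered = ["gene_id", "base_mean", "lfc", "lfc_se", "wald_stat",
               "p_value", "p_adj"]
    rest = [c for c in df.columns if c not in ordered]
    return df[ordered + rest]


def write_de_table(de: pd.DataFrame, path, sep: str = "\t") -> None:
    de.to_csv(path, sep=sep, index=False)


def read_gene_set(path) -> set[str]:
    """One gene id per line; duplicates collapse; empty file warns."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token:
                ids.add(token.split("\t")[0].split(",")[0])
    if not ids:
        warnings.warn(f"{path}: empty gene-set file", stacklevel=2)
    return ids


def read_gene_sets(
    paths=None,
    membership_path=None,
    background: set[str] | None = None,
    sep: str | None = None,
) -> GeneSetCollection:
    """Build a collection from one-set-per-file paths and/or a
    two-column (gene, set-name) membership file."""
    sets: dict[str, set[str]] = {}
    if paths:
        for p in paths:
            p = Path(p)
            sets[p.stem] = read_gene_set(p)
    if membership_path is not None:
        membership_path = Path(membership_path)
        if sep is None:
            sep = _sniff_sep(membership_path)
        df = pd.read_csv(membership_path, sep=sep, dtype=str)
        if df.shape[1] < 2:
            raise ParseError(
                f"{membership_path}: membership file needs two columns"
            )
        gene_col, set_col = df.columns[:2]
        for name, grp in df.groupby(set_col):
            sets.setdefault(str(name), set()).update(
                grp[gene_col].astype(str)
            )
    return GeneSetCollection(sets=sets, background=background or set())


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted({str(g) for g in genes}):
            fh.write(f"{g}\n")


def write_gene_sets(collection: GeneSetCollection, path,
                    sep: str = "\t") -> None:
    """Two-column (gene, set) membership file."""
    rows = [
        (g, name)
        for name in collection.names()
        for g in sorted(collection[name])
    ]
    pd.DataFrame(rows, columns=["gene_id", "set_name"]).to_csv(
        path, sep=sep, index=False
    )


def read_term_map(path, sep: str | None = None) -> dict[str, set[str]]:
    """Two-column (gene, term) file -> gene -> set of terms."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: term map needs two columns")
    gene_col, term_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        out.setdefault(str(gene), set()).add(str(term))
    return out


def write_term_map(term_map: dict[str, set[str]], path,
                   sep: str = "\t") -> None:
    rows = [(g, t) for g in sorted(term_map) for t in sorted(term_map[g])]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(
        path, sep=sep, index=False
    )


def read_expression_table(path, gene_column: str | None = None,
                          sep: str | None = None) -> pd.DataFrame:
    """Continuous gene x column matrix (panel expression, diversity)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if gene_column is None:
        gene_column = df.columns[0]
    df = df.set_index(gene_column)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.apply(pd.to_numeric, errors="coerce")


def write_expression_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="gene_id")


def write_json_report(report: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, set):
            return sorted(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
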