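"""Readers and writers for the tab-delimited interchange formats.

All files are UTF-8, tab-delimited.  Expression matrices carry genes in
rows and samples in columns; Ct tables are long-format with one row per
well; "NA" or an empty field marks an undetermined well.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_FIELDS,
    DEFAULT_CT_RANGE,
    CtTable,
    DataValidationError,
    ExpressionMatrix,
    FoldChangeTable,
    StabilityRanking,
    WrsTable,
)

log = logging.getLogger(__name__)

_NA_VALUES = ["NA", "na", "NaN", ""]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation sheet (columns: sample + the four fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise DataValidationError(f"{path}: annotation sheet lacks a 'sample' column")
    missing = [c for c in ANNOTATION_FIELDS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: annotation sheet lacks column(s): {', '.join(missing)}"
        )
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise DataValidationError(f"{path}: duplicate sample id(s): {', '.join(dupes)}")
    return df.set_index("sample")


def read_family_map(path: str | Path) -> pd.Series:
    """Read a gene -> family map (two columns: gene, family)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "family"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: family map lacks a {col!r} column")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise DataValidationError(f"{path}: gene(s) mapped twice: {', '.join(dupes)}")
    return df.set_index("gene")["family"]


def read_expression_matrix(
    path: str | Path,
    annotation_path: str | Path,
    family_path: str | Path,
    dataset_id: str | None = None,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read one expression dataset.

    With ``log2=True`` the stored values are taken to be log2 intensities
    and are exponentiated (base 2) to the linear scale before validation,
    since the coefficient of variation is defined on linear intensities.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty or df.columns.str.startswith("Unnamed").any():
        raise DataValidationError(
            f"{path}: malformed header; expected gene ids in the first column and "
            "sample ids in the remaining header fields"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].astype(str).unique().tolist()
        raise DataValidationError(f"{path}: duplicate gene id(s): {', '.join(dupes)}")
    values = df.astype(float)
    if log2:
        values = np.exp2(values)
        log.info("%s: exponentiated log2 intensities to linear scale", path.name)
    annotations = read_annotations(annotation_path)
    family_map = read_family_map(family_path)
    matrix = ExpressionMatrix(
        dataset_id=dataset_id if dataset_id is not None else path.stem,
        values=values,
        sample_annotations=annotations,
        family_map=family_map,
    )
    log.info(
        "%s: read %d genes x %d samples", path.name, len(matrix.genes), len(matrix.samples)
    )
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample")


def write_family_map(family_map: pd.Series, path: str | Path) -> None:
    family_map.rename("family").to_csv(path, sep="\t", index_label="gene")


def read_ct_table(
    path: str | Path,
    annotation_path: str | Path | None = None,
    ct_range: tuple[float, float] = DEFAULT_CT_RANGE,
) -> CtTable:
    """Read a long-format Ct table (columns: gene, sample, replicate, ct).

    "NA" or blank in the ct column marks an undetermined well; such rows
    are recorded as absent entries, not as errors.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "sample": str},
        na_values=_NA_VALUES, keep_default_na=False,
    )
    for col in ("gene", "sample", "replicate", "ct"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: Ct table lacks a {col!r} column")
    n_missing = int(df["ct"].isna().sum())
    if n_missing:
        log.info("%s: %d undetermined well(s) recorded as absent", Path(path).name, n_missing)
    present = df[df["ct"].notna()].reset_index(drop=True)
    annotations = read_annotations(annotation_path) if annotation_path else None
    table = CtTable(entries=present, sample_annotations=annotations, ct_range=ct_range)
    log.info("%s: read %d Ct entries", Path(path).name, len(table.entries))
    return table


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.entries.to_csv(path, sep="\t", index=False)


def read_wrs(path: str | Path) -> pd.DataFrame:
    """Read back a written WRS aggregate table (indexed by gene)."""
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_wrs(wrs: WrsTable, path: str | Path, rows_path: str | Path | None = None) -> None:
    """Write the per-gene WRS aggregate; optionally the per-dataset rows too."""
    wrs.aggregate.to_csv(path, sep="\t", index_label="gene")
    if rows_path is not None:
        wrs.rows.to_csv(rows_path, sep="\t", index=False)


def write_ranking(ranking: StabilityRanking, path: str | Path, top_k: int | None = None) -> None:
    """Write a stability ranking in the classic four-class table layout.

    Columns: class (Single / 2-gene / 3-gene / 4-gene), reference (members
    joined by "/"), mean ΔCt SD printed to 3 decimals, rank in class and
    rank in total.  With ``top_k`` set, only the best ``top_k`` sets of
    each class are written.
    """
    if ranking.table.empty:
        raise DataValidationError("refusing to write an empty stability ranking")
    class_names = {1: "Single", 2: "2-gene", 3: "3-gene", 4: "4-gene"}
    out = ranking.table.copy()
    if top_k is not None:
        out = (
            out.sort_values(["size", "mean_sd", "reference"])
            .groupby("size", group_keys=False)
            .head(top_k)
        )
    out = out.assign(**{"class": out["size"].map(lambda k: class_names.get(k, f"{k}-gene"))})
    out = out[["class", "reference", "mean_sd", "rank_in_class", "rank_in_total"]]
    out = out.rename(columns={"mean_sd": "mean_sd_dct"})
    out["mean_sd_dct"] = out["mean_sd_dct"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def write_fold_changes(fct: FoldChangeTable, path: str | Path) -> None:
    fct.rows.to_csv(path, sep="\t", index=False)


def read_fold_change_summary(path: str | Path) -> pd.Series:
    """Read a per-target log2 fold-change table (columns: target, log2fc)."""
    df = pd.read_csv(path, sep="\t", dtype={"target": str})
    for col in ("target", "log2fc"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: fold-change table lacks a {col!r} column")
    if df["target"].duplicated().any():
        dupes = df.loc[df["target"].duplicated(), "target"].tolist()
        raise DataValidationError(f"{path}: duplicate target(s): {', '.join(dupes)}")
    return df.set_index("target")["log2fc"].astype(float)


def write_fold_change_summary(log2fc: Mapping[str, float] | pd.Series, path: str | Path) -> None:
    pd.Series(dict(log2fc), name="log2fc").rename_axis("target").to_csv(path, sep="\t")


def write_concordance(results, path_prefix: str | Path) -> None:
    """Write per-set concordance points and a ranked summary.

    ``results`` is a sequence of ConcordanceResult, assumed already ranked
    ascending by residual variance.  Points go to ``<prefix>.<label>.tsv``
    (with "/" replaced by "+") and the summary to ``<prefix>.summary.tsv``.
    """
    prefix = str(path_prefix)
    summary_rows = []
    for rank, res in enumerate(results, start=1):
        safe = res.label.replace("/", "+")
        res.points.to_csv(f"{prefix}.{safe}.tsv", sep="\t", index=False)
        summary_rows.append(
            {"reference": res.label, "n_retained": res.n_retained, "rv": res.rv, "rank": rank}
        )
    pd.DataFrame(summary_rows).to_csv(f"{prefix}.summary.tsv", sep="\t", index=False)
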