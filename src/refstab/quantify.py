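"""Relative quantification of target genes by the ΔΔCt method.

For each target gene and sample, ΔCt = Ct_target - Ct_reference, where the
reference Ct is the arithmetic mean over the chosen reference set (the
geometric mean of linear expression).  ΔΔCt subtracts the mean ΔCt over the
calibrator samples, and fold change is 2^(-ΔΔCt) — the classic assumption
of a doubling per cycle, with no amplification-efficiency correction.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import CtTable, DataValidationError, FoldChangeTable, ReferenceSet
from .stability import collapse_replicates, combination_ct

log = logging.getLogger(__name__)

# the reference profile contract is shared with the stability stage
reference_profile = combination_ct


def resolve_calibrator(
    calibrator: str | Sequence[str],
    samples: Sequence[str],
    annotations: pd.DataFrame | None = None,
) -> tuple[str, ...]:
    """Turn a calibrator spec into a tuple of sample ids.

    Accepts a sample id, an explicit sequence of sample ids, or — when
    annotations are available — an annotation level such as "well-watered",
    which selects every sample carrying that level in any annotation field.
    """
    if not isinstance(calibrator, str):
        cal = tuple(str(c) for c in calibrator)
        unknown = [c for c in cal if c not in samples]
        if unknown:
            raise DataValidationError(f"unknown calibrator sample(s): {', '.join(unknown)}")
        if not cal:
            raise DataValidationError("empty calibrator")
        return cal
    if calibrator in samples:
        return (calibrator,)
    if annotations is not None:
        hits = annotations.loc[
            annotations.index.intersection(samples)            # only samples in the grid
        ]
        mask = (hits == calibrator).any(axis=1)
        if mask.any():
            return tuple(hits.index[mask])
    raise DataValidationError(
        f"calibrator {calibrator!r} matches no sample id or annotation level"
    )


def ddct_quantify(
    grid: pd.DataFrame,
    targets: Sequence[str],
    refset: ReferenceSet | Sequence[str],
    calibrator: str | Sequence[str],
    annotations: pd.DataFrame | None = None,
) -> FoldChangeTable:
    """Quantify ``targets`` relative to ``refset``, calibrated to ``calibrator``.

    A target whose calibrator ΔCt values are entirely missing is skipped
    with a log notice rather than poisoning the whole table.
    """
    refset = refset if isinstance(refset, ReferenceSet) else ReferenceSet(refset)
    cal_samples = resolve_calibrator(calibrator, list(grid.columns), annotations)
    ref = combination_ct(grid, refset)
    rows = []
    for target in targets:
        target = str(target)
        if target not in grid.index:
            raise DataValidationError(f"target gene {target!r} absent from Ct grid")
        dct = grid.loc[target] - ref
        cal_mean = dct.loc[list(cal_samples)].mean()
        if np.isnan(cal_mean):
            log.warning(
                "target %s: no calibrator ΔCt available (all wells missing); skipped", target
            )
            continue
        ddct = dct - cal_mean
        for sample in grid.columns:
            if np.isnan(ddct[sample]):
                continue
            rows.append(
                {
                    "target": target,
                    "sample": sample,
                    "dct": float(dct[sample]),
                    "ddct": float(ddct[sample]),
                    "log2fc": float(-ddct[sample]),
                    "fc": float(2.0 ** (-ddct[sample])),
                }
            )
    if not rows:
        raise DataValidationError("no target could be quantified")
    return FoldChangeTable(
        rows=pd.DataFrame(rows), reference=refset, calibrator=cal_samples
    )


def quantify_ct_table(
    ct: CtTable,
    targets: Sequence[str],
    refset: ReferenceSet | Sequence[str],
    calibrator: str | Sequence[str],
) -> FoldChangeTable:
    """Convenience wrapper: collapse replicates, then run ``ddct_quantify``."""
    grid = collapse_replicates(ct)
    return ddct_quantify(grid, targets, refset, calibrator, ct.sample_annotations)


def summarize_by_condition(
    fct: FoldChangeTable,
    annotations: pd.DataFrame,
    by: str = "water_status",
) -> pd.DataFrame:
    """Condition-level fold changes: mean per-sample log2 fold change +- SE.

    Returns one row per (target, condition) with columns ``log2fc`` (the
    mean over that condition's samples), ``se`` (standard error, NaN for a
    single sample) and ``n``.
    """
    if by not in annotations.columns:
        raise DataValidationError(f"annotation field {by!r} not present")
    rows = fct.rows.merge(
        annotations[[by]].rename(columns={by: "condition"}),
        left_on="sample",
        right_index=True,
        how="left",
    )
    if rows["condition"].isna().any():
        bad = rows.loc[rows["condition"].isna(), "sample"].unique().tolist()
        raise DataValidationError(f"sample(s) missing annotations: {', '.join(bad)}")
    out = (
        rows.groupby(["target", "condition"])["log2fc"]
        .agg(log2fc="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    return out


def condition_log2fc(
    fct: FoldChangeTable,
    annotations: pd.DataFrame,
    condition: str,
    by: str = "water_status",
) -> pd.Series:
    """Per-target mean log2 fold change for one condition level."""
    summary = summarize_by_condition(fct, annotations, by=by)
    sel = summary[summary["condition"] == condition]
    if sel.empty:
        raise DataValidationError(f"no sample with {by} == {condition!r}")
    return sel.set_index("target")["log2fc"]
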