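"""Cross-platform validation of reference choices by fold-change concordance.

Paired log2 fold changes — x from an array platform, y from qRT-PCR under a
given reference set — are scored by their residual variance (RV) around the
fixed identity line y = x:

    RV = sum_i (y_i - x_i)^2 / (n - 1)

with no fitted parameters: a reference set that reproduces the independent
platform's fold changes exactly has RV 0, and RV grows with normalization
error.  Outlying targets may be omitted before computing RV, either by a
residual-SD rule, by removing a fixed count of the largest residuals, or by
explicit target ids; whichever policy is used is applied identically to
every reference set under comparison.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ConcordanceResult, DataValidationError

log = logging.getLogger(__name__)

OUTLIER_METHODS = ("residual-sd", "fixed-count", "explicit", "none")


def residual_variance(x: Sequence[float], y: Sequence[float]) -> float:
    """Residual variance of paired points around the fixed line y = x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataValidationError(f"x and y differ in length ({x.size} vs {y.size})")
    if x.size < 3:
        raise DataValidationError(f"residual variance needs >= 3 points, got {x.size}")
    r = y - x
    return float(np.sum(r * r) / (r.size - 1))


def detect_outliers(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "residual-sd",
    param: float | int | Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Flag discordant points.

    * ``residual-sd``: flag points with |y - x| > param x SD of residuals
      (default param 2; single pass, no re-estimation after removal).
    * ``fixed-count``: flag the ``param`` points with the largest |y - x|
      (ties broken toward the earlier index for determinism).
    * ``explicit``: ``param`` is a collection of point ids to flag;
      requires ``ids``.
    * ``none``: keep everything.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if method not in OUTLIER_METHODS:
        raise DataValidationError(f"unknown outlier method {method!r}; use {OUTLIER_METHODS}")
    if method == "none":
        return np.zeros(n, dtype=bool)
    resid = np.abs(y - x)
    if method == "explicit":
        if ids is None:
            raise DataValidationError("explicit outlier method requires point ids")
        wanted = {str(p) for p in (param or [])}
        unknown = wanted - {str(i) for i in ids}
        if unknown:
            raise DataValidationError(f"unknown outlier id(s): {', '.join(sorted(unknown))}")
        return np.array([str(i) in wanted for i in ids], dtype=bool)
    if n < 4:
        raise DataValidationError(f"automatic outlier detection needs >= 4 points, got {n}")
    if method == "fixed-count":
        count = int(param if param is not None else 0)
        if count >= n:
            raise DataValidationError(f"cannot flag {count} outliers out of {n} points")
        mask = np.zeros(n, dtype=bool)
        if count > 0:
            # stable argsort so equal residuals resolve by original order
            order = np.argsort(-resid, kind="stable")
            mask[order[:count]] = True
        return mask
    # residual-sd
    k = float(param if param is not None else 2.0)
    sd = float(np.std(y - x, ddof=1))
    if sd == 0:
        return np.zeros(n, dtype=bool)
    return resid > k * sd


def score_concordance(
    label: str,
    qpcr_fc: Mapping[str, float] | pd.Series,
    array_fc: Mapping[str, float] | pd.Series,
    method: str = "residual-sd",
    param: float | int | Sequence[str] | None = None,
) -> ConcordanceResult:
    """Pair one reference set's qPCR fold changes with array fold changes.

    Targets present on only one platform are dropped with a log notice.
    RV is computed over the retained (non-outlier) points, of which at
    least 3 must remain.
    """
    q = pd.Series(dict(qpcr_fc), dtype=float)
    a = pd.Series(dict(array_fc), dtype=float)
    shared = sorted(q.index.intersection(a.index))
    dropped = sorted(set(q.index).symmetric_difference(a.index))
    if dropped:
        log.info("%s: dropping target(s) on one platform only: %s", label, ", ".join(dropped))
    if len(shared) < 3:
        raise DataValidationError(
            f"{label}: only {len(shared)} target(s) shared between platforms; need >= 3"
        )
    x = a.loc[shared].to_numpy()
    y = q.loc[shared].to_numpy()
    mask = detect_outliers(x, y, method=method, param=param, ids=shared)
    if (~mask).sum() < 3:
        raise DataValidationError(
            f"{label}: fewer than 3 targets retained after outlier removal"
        )
    rv = residual_variance(x[~mask], y[~mask])
    points = pd.DataFrame({"target": shared, "x": x, "y": y, "outlier": mask})
    return ConcordanceResult(label=label, points=points, rv=rv)


def compare_references(
    qpcr_fc: Mapping[str, Mapping[str, float] | pd.Series],
    array_fc: Mapping[str, float] | pd.Series,
    method: str = "residual-sd",
    param: float | int | Sequence[str] | None = None,
) -> tuple[list[ConcordanceResult], pd.DataFrame]:
    """Score every reference set against the same array fold changes.

    Returns the per-set results ordered ascending by RV (ties by label)
    and a summary frame with tie-averaged ranks.
    """
    if not qpcr_fc:
        raise DataValidationError("no reference sets to compare")
    results = [
        score_concordance(label, fc, array_fc, method=method, param=param)
        for label, fc in qpcr_fc.items()
    ]
    results.sort(key=lambda r: (r.rv, r.label))
    summary = pd.DataFrame(
        {
            "reference": [r.label for r in results],
            "n_retained": [r.n_retained for r in results],
            "rv": [r.rv for r in results],
        }
    )
    summary["rank"] = summary["rv"].rank(method="average")
    return results, summary
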