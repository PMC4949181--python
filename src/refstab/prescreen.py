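"""Candidate pre-screening by coefficient of variation and weighted rank score.

Stage 1 of the workflow: within each public expression dataset, every gene's
cross-sample coefficient of variation (CV) is computed on the linear scale
and ranked within its gene family (rank 1 = lowest CV = most stable).  Ranks
are then aggregated across datasets into a weighted rank score (WRS): each
rank becomes a within-family percentile score

    s = 1 - (rank - 1) / (N_family - 1)        (s = 1 if the family has one gene)

so the most stable isogene of a family scores 1 and the least stable scores
0, and scores are summed over datasets with per-dataset weights.  The
default weight of a dataset is its sample variety - the number of distinct
(genotype, stage, tissue, water status) annotation tuples it covers - so
that broad experiments count more than narrow ones.  Finally each gene's
WRS is expressed as a percentage of the best WRS in its family, putting the
top isogene of every family at 100 %.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import DataValidationError, ExpressionMatrix, WrsTable

log = logging.getLogger(__name__)


def compute_cv(values: np.ndarray | Sequence[float]) -> float:
    """Coefficient of variation of linear-scale intensities.

    cv = sample standard deviation (n-1 denominator) / mean.  Requires at
    least two finite values and a strictly positive mean.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DataValidationError(f"CV needs >= 2 finite values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise DataValidationError(f"CV undefined for non-positive mean ({mean})")
    return float(arr.std(ddof=1) / mean)


def rank_within_family(cvs: pd.Series, family_map: pd.Series) -> pd.Series:
    """Rank genes by CV within each family (1 = most stable, ties averaged).

    Genes without a family label are dropped; families are ranked
    independently, so ranks restart at 1 in every family.
    """
    cvs = cvs.dropna()
    genes = cvs.index.intersection(family_map.index)
    skipped = cvs.index.difference(family_map.index)
    if len(skipped):
        log.info("excluding %d gene(s) without family label from ranking", len(skipped))
    if genes.empty:
        return pd.Series(dtype=float, name="family_rank")
    df = pd.DataFrame({"cv": cvs.loc[genes], "family": family_map.loc[genes]})
    ranks = df.groupby("family")["cv"].rank(method="average", ascending=True)
    ranks.name = "family_rank"
    return ranks


def compute_wrs(
    ranks: pd.DataFrame,
    family_sizes: Mapping[tuple[str, str], int],
    weights: Mapping[str, float],
) -> WrsTable:
    """Aggregate within-family ranks across datasets into weighted rank scores.

    Parameters
    ----------
    ranks:
        One row per (gene, dataset) with columns ``gene``, ``dataset``,
        ``family``, ``cv``, ``family_rank``.
    family_sizes:
        (family, dataset) -> number of ranked genes of that family in that
        dataset (needed to turn a rank into a percentile score).
    weights:
        dataset -> positive sample-variety weight.

    A gene absent from a dataset contributes score 0 there, i.e. missing
    evidence never raises a gene's WRS.  Higher WRS means more stable.
    """
    for d, w in weights.items():
        if w <= 0:
            raise DataValidationError(f"weight for dataset {d!r} must be > 0, got {w}")
    rows = ranks.copy()
    scores = []
    for r in rows.itertuples(index=False):
        key = (r.family, r.dataset)
        if key not in family_sizes:
            raise DataValidationError(
                f"no family size recorded for family {r.family!r} in dataset {r.dataset!r}"
            )
        n = family_sizes[key]
        if not 1 <= r.family_rank <= n:
            raise DataValidationError(
                f"rank {r.family_rank} outside [1, {n}] for gene {r.gene!r} "
                f"in dataset {r.dataset!r}"
            )
        scores.append(1.0 if n == 1 else 1.0 - (r.family_rank - 1.0) / (n - 1.0))
    rows["score"] = scores
    rows["weight"] = rows["dataset"].map(dict(weights))
    if rows["weight"].isna().any():
        bad = rows.loc[rows["weight"].isna(), "dataset"].unique().tolist()
        raise DataValidationError(f"no weight supplied for dataset(s): {', '.join(bad)}")

    agg = (
        rows.assign(contribution=rows["score"] * rows["weight"])
        .groupby("gene")
        .agg(family=("family", "first"), wrs=("contribution", "sum"))
    )
    fam_max = agg.groupby("family")["wrs"].transform("max")
    # a family whose every member scores 0 everywhere is flat: call them all 100
    agg["wrs_pct"] = np.where(fam_max > 0, 100.0 * agg["wrs"] / fam_max, 100.0)
    agg = agg.sort_index()
    return WrsTable(rows=rows.drop(columns=["score", "weight"]), aggregate=agg)


def prescreen_expression(
    matrices: Sequence[ExpressionMatrix],
    weights: Mapping[str, float] | None = None,
    quotas: Mapping[str, int] | None = None,
) -> tuple[WrsTable, list[str] | None]:
    """Run the full pre-screen over one or more expression datasets.

    Computes per-dataset CVs, ranks them within families, aggregates into
    WRS (weighting each dataset by its annotation variety unless ``weights``
    overrides), and - when ``quotas`` is given - selects the per-family
    candidate lists.  Genes whose CV is undefined in a dataset (constant
    zero, single sample) are excluded from that dataset with a log notice.
    """
    if not matrices:
        raise DataValidationError("prescreen needs at least one expression matrix")
    ids = [m.dataset_id for m in matrices]
    if len(set(ids)) != len(ids):
        raise DataValidationError(f"duplicate dataset ids: {ids}")

    if weights is None:
        weights = {m.dataset_id: float(m.annotation_variety()) for m in matrices}
        log.info("dataset weights from annotation variety: %s", weights)

    rank_rows = []
    family_sizes: dict[tuple[str, str], int] = {}
    for m in matrices:
        cvs = {}
        for gene in m.genes:
            try:
                cvs[gene] = compute_cv(m.values.loc[gene].to_numpy())
            except DataValidationError as exc:
                log.info("dataset %s: excluding gene %s (%s)", m.dataset_id, gene, exc)
        cv_series = pd.Series(cvs, dtype=float)
        ranks = rank_within_family(cv_series, m.family_map)
        fams = m.family_map.loc[ranks.index]
        for fam, grp in ranks.groupby(fams):
            family_sizes[(fam, m.dataset_id)] = len(grp)
        for gene, rank in ranks.items():
            rank_rows.append(
                {
                    "gene": gene,
                    "dataset": m.dataset_id,
                    "family": m.family_map.loc[gene],
                    "cv": cv_series.loc[gene],
                    "family_rank": float(rank),
                }
            )
    if not rank_rows:
        raise DataValidationError("no gene could be ranked in any dataset")
    wrs = compute_wrs(pd.DataFrame(rank_rows), family_sizes, weights)
    candidates = select_candidates(wrs, quotas) if quotas is not None else None
    return wrs, candidates


def select_candidates(wrs: WrsTable, quotas: Mapping[str, int]) -> list[str]:
    """Pick the top-``quota`` genes of each family by WRS.

    Ties at a quota boundary are broken by lexicographic gene id and
    logged.  The returned list concatenates families in the order given by
    ``quotas``; genes are ordered by descending WRS within a family.
    """
    chosen: list[str] = []
    for family, quota in quotas.items():
        members = wrs.aggregate[wrs.aggregate["family"] == family]
        if quota > len(members):
            raise DataValidationError(
                f"quota {quota} exceeds family {family!r} size {len(members)}"
            )
        if quota == 0:
            continue
        # stable sort on a lexicographically pre-sorted frame: ties fall to gene id
        ordered = members.sort_index().sort_values("wrs", ascending=False, kind="mergesort")
        cut = ordered["wrs"].iloc[quota - 1]
        if (ordered["wrs"] == cut).sum() > (ordered["wrs"].iloc[:quota] == cut).sum():
            log.info(
                "family %s: tie at quota boundary (WRS=%.6g) broken lexicographically",
                family,
                cut,
            )
        chosen.extend(ordered.index[:quota].tolist())
    return chosen
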