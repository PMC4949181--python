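"""Expression-stability scoring of reference genes and gene combinations.

Implements the pairwise ΔCt approach: a candidate reference (a single gene
or the arithmetic-mean Ct of a 2-4-gene combination, i.e. the geometric
mean of linear expression) is scored by the standard deviation across
samples of its ΔCt against every other candidate gene, averaged over those
partners.  Because any per-sample loading offset adds the same constant to
every gene's Ct in that sample, it cancels exactly in every ΔCt: the score
measures genuine expression instability, not RNA input differences.

All 1..max_size subsets of the candidate list are enumerated and ranked by
their mean ΔCt SD, both within their size class and overall.  A single-pass
geNorm-style M value is provided as an independent comparator for single
genes.
"""

from __future__ import annotations

import itertools
import logging
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import CtTable, DataValidationError, ReferenceSet, StabilityRanking

log = logging.getLogger(__name__)

#: Refuse to enumerate more reference sets than this.
MAX_ENUMERATED_SETS = 50_000

#: Minimum number of shared samples for a pairwise SD to be defined.
MIN_SHARED_SAMPLES = 3


def collapse_replicates(ct: CtTable) -> pd.DataFrame:
    """Average technical replicates into a gene x sample Ct grid.

    Wells with no measured replicate appear as NaN; wells with a single
    replicate keep that value unchanged.
    """
    grid = ct.entries.pivot_table(index="gene", columns="sample", values="ct", aggfunc="mean")
    return grid.sort_index(axis=0).sort_index(axis=1)


def combination_ct(grid: pd.DataFrame, refset: ReferenceSet | Sequence[str]) -> pd.Series:
    """Per-sample pseudo-reference Ct of a gene combination.

    The arithmetic mean of the member Cts, equivalent to the geometric mean
    of their linear expression levels — the standard multi-reference
    aggregation.  A sample missing any member is missing in the result.
    """
    genes = list(refset.genes if isinstance(refset, ReferenceSet) else refset)
    if not genes:
        raise DataValidationError("empty reference set")
    absent = [g for g in genes if g not in grid.index]
    if absent:
        raise DataValidationError(f"gene(s) absent from Ct grid: {', '.join(absent)}")
    return grid.loc[genes].mean(axis=0, skipna=False)


def pairwise_dct_sd(
    profile_a: pd.Series,
    profile_b: pd.Series,
    names: tuple[str, str] | None = None,
) -> float:
    """Sample SD (n-1) of ΔCt = Ct_a - Ct_b over pairwise-complete samples."""
    a, b = profile_a.align(profile_b, join="inner")
    d = (a - b).dropna().to_numpy()
    if d.size < MIN_SHARED_SAMPLES:
        pair = f" for pair {names[0]!r} vs {names[1]!r}" if names else ""
        raise DataValidationError(
            f"only {d.size} shared sample(s){pair}; need >= {MIN_SHARED_SAMPLES}"
        )
    return float(np.std(d, ddof=1))


def mean_dct_sd(
    grid: pd.DataFrame,
    refset: ReferenceSet | Sequence[str],
    candidates: Sequence[str],
) -> float:
    """Mean ΔCt SD of a reference set against all non-member candidates.

    Partners exclude the set's own members: comparing a combination against
    one of its constituents would deflate the SD artificially.
    """
    genes = tuple(refset.genes if isinstance(refset, ReferenceSet) else refset)
    partners = [c for c in candidates if c not in genes]
    if len(candidates) < 2:
        raise DataValidationError("need >= 2 candidates to score stability")
    if not partners:
        raise DataValidationError(
            f"reference set {'/'.join(genes)} leaves no partner candidates"
        )
    pseudo = combination_ct(grid, genes)
    sds = [
        pairwise_dct_sd(pseudo, grid.loc[p], names=("/".join(genes), p)) for p in partners
    ]
    return float(np.mean(sds))


def _nan_pair_sd(delta: np.ndarray, what: str) -> float:
    ok = ~np.isnan(delta)
    n = int(ok.sum())
    if n < MIN_SHARED_SAMPLES:
        raise DataValidationError(
            f"only {n} shared sample(s) for {what}; need >= {MIN_SHARED_SAMPLES}"
        )
    return float(np.std(delta[ok], ddof=1))


def enumerate_and_rank(
    grid: pd.DataFrame,
    candidates: Sequence[str],
    max_size: int = 4,
) -> StabilityRanking:
    """Score every 1..max_size-gene subset of ``candidates`` and rank all.

    Ranks are ascending in mean ΔCt SD with ties averaged, assigned both
    within each size class and across all sets.  Rows are ordered by
    (size, score, label) so equal-score output is deterministic.
    """
    candidates = [str(c) for c in candidates]
    n = len(candidates)
    if len(set(candidates)) != n:
        raise DataValidationError("candidate list contains duplicates")
    if not 2 <= n <= 20:
        raise DataValidationError(f"need 2-20 candidates, got {n}")
    if not 1 <= max_size <= n - 1:
        raise DataValidationError(
            f"max_size must lie in [1, {n - 1}] so every set keeps a partner; got {max_size}"
        )
    total = sum(comb(n, k) for k in range(1, max_size + 1))
    if total > MAX_ENUMERATED_SETS:
        raise DataValidationError(
            f"{total} reference sets exceed the {MAX_ENUMERATED_SETS} guard; "
            "shorten the candidate list or lower max_size"
        )
    absent = [c for c in candidates if c not in grid.index]
    if absent:
        raise DataValidationError(f"candidate(s) absent from Ct grid: {', '.join(absent)}")

    X = grid.loc[candidates].to_numpy(dtype=float)
    has_nan = bool(np.isnan(X).any())
    rows = []
    for k in range(1, max_size + 1):
        for idx in itertools.combinations(range(n), k):
            members = np.asarray(idx)
            pseudo = X[members].mean(axis=0)
            partner_mask = np.ones(n, dtype=bool)
            partner_mask[members] = False
            deltas = pseudo[None, :] - X[partner_mask]
            label = "/".join(candidates[i] for i in idx)
            if has_nan:
                sds = [
                    _nan_pair_sd(deltas[j], f"set {label}")
                    for j in range(deltas.shape[0])
                ]
                score = float(np.mean(sds))
            else:
                score = float(np.mean(np.std(deltas, axis=1, ddof=1)))
            rows.append({"reference": label, "size": k, "mean_sd": score})

    table = pd.DataFrame(rows).sort_values(
        ["size", "mean_sd", "reference"], kind="mergesort", ignore_index=True
    )
    table["rank_in_total"] = rankdata(table["mean_sd"], method="average")
    table["rank_in_class"] = (
        table.groupby("size")["mean_sd"].rank(method="average").to_numpy()
    )
    log.info("ranked %d reference sets from %d candidates (max size %d)", total, n, max_size)
    return StabilityRanking(table=table)


def genorm_m(grid: pd.DataFrame, candidates: Sequence[str]) -> pd.Series:
    """Single-pass geNorm-style M value per candidate gene.

    M_j is the average, over all partner genes k != j, of the standard
    deviation across samples of the log2 expression ratio of j and k — on
    the Ct scale (efficiency 2), the SD of Ct_k - Ct_j.  Lower M = more
    stable.  No stepwise worst-gene elimination is performed.
    """
    candidates = [str(c) for c in candidates]
    if len(candidates) < 3:
        raise DataValidationError(f"geNorm M needs >= 3 candidates, got {len(candidates)}")
    absent = [c for c in candidates if c not in grid.index]
    if absent:
        raise DataValidationError(f"candidate(s) absent from Ct grid: {', '.join(absent)}")
    X = grid.loc[candidates].to_numpy(dtype=float)
    m_values = {}
    for j, gene in enumerate(candidates):
        sds = []
        for k in range(len(candidates)):
            if k == j:
                continue
            sds.append(_nan_pair_sd(X[k] - X[j], f"pair {candidates[k]} vs {gene}"))
        m_values[gene] = float(np.mean(sds))
    return pd.Series(m_values, name="M")
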