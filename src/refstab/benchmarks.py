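"""Self-contained benchmark routines over the synthetic study conditions.

Each routine simulates data with the package's own generators, runs the
corresponding pipeline stage, and measures a recovery, agreement or
calibration statistic.  They exist so the package's statistical operating
characteristics can be recomputed from scratch with one call - by the test
suite and by the reproduction script alike.

All routines are deterministic given ``base_seed``: run ``r`` uses seed
``base_seed + r``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import detect_outliers, residual_variance
from .prescreen import prescreen_expression
from .quantify import ddct_quantify
from .simulate import (
    ct_benchmark_config,
    heterogeneous_noise_config,
    simulate_ct_table,
    simulate_expression_matrix,
    simulate_validation_scenario,
)
from .stability import collapse_replicates, enumerate_and_rank, genorm_m

QUIET_GENE = "REF01"


def count_reference_sets(seed: int = 0, n_candidates: int = 10, max_size: int = 4) -> int:
    """Enumerate all 1..max_size-gene sets on a simulated candidate panel."""
    config = ct_benchmark_config(seed, n_genes=n_candidates)
    ct, _ = simulate_ct_table(config)
    grid = collapse_replicates(ct)
    ranking = enumerate_and_rank(grid, list(grid.index), max_size=max_size)
    return len(ranking.table)


def single_reference_recovery(n_runs: int = 100, base_seed: int = 0) -> float:
    """Fraction of runs in which the planted quiet gene tops the single ranking."""
    hits = 0
    for r in range(n_runs):
        config = ct_benchmark_config(base_seed + r)
        ct, _ = simulate_ct_table(config)
        grid = collapse_replicates(ct)
        ranking = enumerate_and_rank(grid, list(grid.index), max_size=1)
        hits += ranking.best(1)["reference"] == QUIET_GENE
    return hits / n_runs


def wrs_recovery(n_runs: int = 100, base_seed: int = 0, n_datasets: int = 3) -> float:
    """Fraction of runs in which WRS pre-screening on matched expression
    matrices puts the quiet gene at 100 % of its family maximum."""
    hits = 0
    for r in range(n_runs):
        config = ct_benchmark_config(base_seed + r)
        matrices = [simulate_expression_matrix(config, d)[0] for d in range(n_datasets)]
        wrs, _ = prescreen_expression(matrices)
        agg = wrs.aggregate
        hits += (
            agg.loc[QUIET_GENE, "wrs_pct"] == 100.0
            and agg["wrs"].idxmax() == QUIET_GENE
        )
    return hits / n_runs


def method_agreement(n_runs: int = 100, base_seed: int = 0) -> float:
    """Fraction of runs where the ΔCt-approach top single gene coincides with
    the lowest single-pass geNorm M gene, on heterogeneous-noise panels."""
    hits = 0
    for r in range(n_runs):
        config = heterogeneous_noise_config(base_seed + r)
        ct, _ = simulate_ct_table(config)
        grid = collapse_replicates(ct)
        ranking = enumerate_and_rank(grid, list(grid.index), max_size=1)
        m = genorm_m(grid, list(grid.index))
        hits += ranking.best(1)["reference"] == m.idxmin()
    return hits / n_runs


def combination_benefit(n_runs: int = 100, base_seed: int = 0) -> float:
    """Fraction of runs where the best mean ΔCt SD is non-increasing as the
    reference grows from 1 to 4 genes (independent-noise panels)."""
    hits = 0
    for r in range(n_runs):
        config = heterogeneous_noise_config(base_seed + r)
        ct, _ = simulate_ct_table(config)
        grid = collapse_replicates(ct)
        t = enumerate_and_rank(grid, list(grid.index), max_size=4).table
        mins = [t.loc[t["size"] == k, "mean_sd"].min() for k in (1, 2, 3, 4)]
        hits += all(mins[i + 1] <= mins[i] + 1e-12 for i in range(3))
    return hits / n_runs


def loading_invariance_gap(seed: int = 0, shift_sd: float = 3.0) -> float:
    """Largest change in any stability score, M value or ΔΔCt fold change
    when a per-sample constant vector is added to every gene's Ct.

    The ΔCt family of statistics is exactly invariant to such loading
    shifts; the returned gap is pure floating-point noise.
    """
    config = ct_benchmark_config(seed)
    ct, _ = simulate_ct_table(config)
    grid = collapse_replicates(ct)
    rng = np.random.default_rng([seed, 55])
    shift = rng.normal(0.0, shift_sd, size=grid.shape[1])
    shifted = grid + shift

    genes = list(grid.index)
    r0 = enumerate_and_rank(grid, genes, max_size=3).table.set_index("reference")
    r1 = enumerate_and_rank(shifted, genes, max_size=3).table.set_index("reference")
    gap = float((r0["mean_sd"] - r1["mean_sd"]).abs().max())

    gap = max(gap, float((genorm_m(grid, genes) - genorm_m(shifted, genes)).abs().max()))

    targets = genes[4:6]
    refset = genes[:2]
    cal = grid.columns[0]
    f0 = ddct_quantify(grid, targets, refset, cal).rows["fc"].to_numpy()
    f1 = ddct_quantify(shifted, targets, refset, cal).rows["fc"].to_numpy()
    gap = max(gap, float(np.abs(f0 - f1).max()))
    return gap


def rv_calibration(seed: int = 0, n: int = 1000, sigma: float = 0.7) -> dict[str, float]:
    """RV of the identity line (exactly 0) and RV/sigma^2 for y = x + N(0, sigma)."""
    rng = np.random.default_rng([seed, 66])
    x = rng.normal(0.0, 2.0, size=n)
    rv_exact = residual_variance(x, x)
    y = x + rng.normal(0.0, sigma, size=n)
    return {"rv_identity": rv_exact, "rv_ratio": residual_variance(x, y) / sigma**2, "n": n}


def outlier_recovery(n_runs: int = 100, base_seed: int = 0) -> float:
    """Fraction of planted-outlier scenarios (8 targets, 2 outliers shifted by
    4 log2 units over 0.3 noise) where fixed-count(2) flags exactly the pair."""
    hits = 0
    for r in range(n_runs):
        points, planted = simulate_validation_scenario(
            n_targets=8, sd_concordant=0.3, n_outliers=2, outlier_shift=4.0,
            seed=base_seed + r,
        )
        mask = detect_outliers(points["x"], points["y"], method="fixed-count", param=2)
        hits += set(points.loc[mask, "target"]) == set(planted)
    return hits / n_runs
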