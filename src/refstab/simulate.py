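"""Synthetic expression and qRT-PCR data with known stability ground truth.

The generator mirrors the statistical structure the ΔCt approach relies on.
On the Ct scale the model is additive Gaussian:

    Ct[g, s, r] = mu_g + lambda_s + beta_g * x_s + eps[g, s, r]

where ``lambda_s`` is a per-sample loading offset (RNA input / RT
efficiency) shared by every gene, ``x_s`` is a centered +-0.5 contrast for
the water-status condition of sample s, ``beta_g`` is a gene's condition
sensitivity (a true reference gene has beta 0), and ``eps`` is technical
noise.  Because ``lambda_s`` enters every gene identically it cancels
exactly in any ΔCt — the property that makes pairwise stability statistics
robust to differing mRNA content per sample.  Expression matrices use the
same linear predictor without the loading term, exponentiated to linear
intensities: ``2**(mu_g + beta_g * x_s + eps)``.

Condition sensitivities of unstable genes are drawn with random sign:
stress-responsive transcripts are induced and repressed in comparable
numbers, and a shared-sign bundle would make the condition effect a
common mode that pairwise differencing removes.

Truth objects (true per-gene dispersion, planted outlier identities) are
returned alongside the data and never written into the data files.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_FIELDS,
    CtTable,
    DataValidationError,
    ExpressionMatrix,
    SimulationConfig,
)

# stream tags keep the rng draws of the three generators independent
_EXPR_STREAM = 11
_CT_STREAM = 22
_VALID_STREAM = 33


def _design(config: SimulationConfig, dataset_id: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Deterministic balanced annotation design and condition contrast.

    Samples cycle through the cartesian product of the annotation levels
    with water status flipping fastest, so conditions stay balanced for any
    sample count.  x_s is -0.5 for the first water-status level (control)
    and +0.5 otherwise.
    """
    levels = [config.annotation_design[f] for f in ANNOTATION_FIELDS]
    cycle = itertools.cycle(itertools.product(*levels))
    rows = []
    for i in range(config.n_samples_per_dataset):
        combo = next(cycle)
        rows.append(dict(zip(ANNOTATION_FIELDS, combo)))
    samples = [f"{dataset_id}_s{i + 1:02d}" for i in range(config.n_samples_per_dataset)]
    ann = pd.DataFrame(rows, index=pd.Index(samples, name="sample"))
    control = config.annotation_design["water_status"][0]
    x = np.where(ann["water_status"].to_numpy() == control, -0.5, 0.5)
    return ann, x


def simulate_expression_matrix(
    config: SimulationConfig, dataset_index: int = 0
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one linear-scale expression dataset plus its dispersion truth.

    Returns the matrix and a truth frame with one row per gene: ``family``,
    ``true_log2_sd`` (the model SD of the gene's log2 intensity across the
    realized design) and ``true_family_rank`` (1 = least dispersed in its
    family).  The empirical within-family CV ordering converges to this
    ranking as samples accumulate.
    """
    if dataset_index < 0:
        raise DataValidationError("dataset_index must be >= 0")
    dataset_id = f"D{dataset_index + 1}"
    rng = np.random.default_rng([config.seed, _EXPR_STREAM, dataset_index])
    ann, x = _design(config, dataset_id)
    genes = config.genes
    mu = np.array([config.gene_params[g]["mu"] for g in genes])
    beta = np.array([config.gene_params[g]["beta"] for g in genes])
    sigma = np.array([config.gene_params[g]["sigma_eps"] for g in genes])

    eps = rng.normal(0.0, 1.0, size=(len(genes), len(x))) * sigma[:, None]
    log2_values = mu[:, None] + beta[:, None] * x[None, :] + eps
    values = pd.DataFrame(np.exp2(log2_values), index=genes, columns=ann.index)

    # model dispersion over the realized (finite) design, not the asymptote
    var_x = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
    truth = pd.DataFrame(
        {
            "family": [config.families[g] for g in genes],
            "true_log2_sd": np.sqrt(beta**2 * var_x + sigma**2),
        },
        index=pd.Index(genes, name="gene"),
    )
    truth["true_family_rank"] = truth.groupby("family")["true_log2_sd"].rank(method="average")

    matrix = ExpressionMatrix(
        dataset_id=dataset_id,
        values=values,
        sample_annotations=ann,
        family_map=pd.Series(config.families),
    )
    return matrix, truth


def simulate_ct_table(config: SimulationConfig) -> tuple[CtTable, pd.DataFrame]:
    """Draw a qRT-PCR Ct table plus the per-gene truth parameters.

    Wells are dropped independently with ``missing_rate`` (undetermined
    reactions); surviving replicate indices are renumbered consecutively
    from 1 per well group, as a plate export would list them.
    """
    rng = np.random.default_rng([config.seed, _CT_STREAM])
    ann, x = _design(config, "qpcr")
    genes = config.genes
    samples = list(ann.index)
    lam = rng.normal(0.0, config.lambda_sd, size=len(samples))

    rows = []
    for gi, gene in enumerate(genes):
        p = config.gene_params[gene]
        for si, sample in enumerate(samples):
            well_mean = p["mu"] + lam[si] + p["beta"] * x[si]
            kept = 0
            for _ in range(config.n_replicates):
                ct = well_mean + rng.normal(0.0, p["sigma_eps"])
                if rng.random() < config.missing_rate:
                    continue
                kept += 1
                rows.append({"gene": gene, "sample": sample, "replicate": kept, "ct": ct})
    truth = pd.DataFrame(
        {
            "family": [config.families[g] for g in genes],
            "mu": [config.gene_params[g]["mu"] for g in genes],
            "beta": [config.gene_params[g]["beta"] for g in genes],
            "sigma_eps": [config.gene_params[g]["sigma_eps"] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    table = CtTable(entries=pd.DataFrame(rows), sample_annotations=ann)
    return table, truth


def simulate_validation_scenario(
    n_targets: int,
    sd_concordant: float = 0.3,
    n_outliers: int = 0,
    outlier_shift: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Paired cross-platform log2 fold changes with planted outliers.

    Array fold changes x are drawn N(0, 2); concordant qPCR fold changes
    follow y = x + N(0, sd_concordant); each of ``n_outliers`` randomly
    chosen targets gets an extra +-``outlier_shift`` on y.  Returns the
    points frame (target, x, y) and the planted outlier target ids.
    """
    if n_outliers >= n_targets:
        raise DataValidationError("n_outliers must be < n_targets")
    if sd_concordant < 0 or n_targets < 1:
        raise DataValidationError("invalid validation scenario parameters")
    rng = np.random.default_rng([seed, _VALID_STREAM])
    targets = [f"T{i + 1:02d}" for i in range(n_targets)]
    x = rng.normal(0.0, 2.0, size=n_targets)
    y = x + rng.normal(0.0, sd_concordant, size=n_targets)
    planted = sorted(rng.choice(n_targets, size=n_outliers, replace=False).tolist())
    for i in planted:
        y[i] += outlier_shift * rng.choice([-1.0, 1.0])
    points = pd.DataFrame({"target": targets, "x": x, "y": y})
    return points, [targets[i] for i in planted]


def ct_benchmark_config(
    seed: int,
    n_genes: int = 10,
    n_samples: int = 12,
    n_replicates: int = 3,
    quiet_sigma: float = 0.05,
    noisy_sigma_range: tuple[float, float] = (1.0, 1.5),
    beta_range: tuple[float, float] = (0.5, 1.5),
    lambda_sd: float = 1.0,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """Benchmark layout: one quiet candidate among condition-sensitive ones.

    Gene ``REF01`` is a true reference (beta 0, per-well noise
    ``quiet_sigma``); the remaining genes carry condition sensitivities of
    magnitude uniform in ``beta_range`` with random sign, plus per-well
    noise uniform in ``noisy_sigma_range``.  That noise term lumps
    technical scatter with condition-independent biological variability, so
    the 1-1.5 cycle default puts unstable isogenes in the 1-2 cycle ΔCt-SD
    regime typical of poor reference genes, while a genuine reference shows
    only replicate-level scatter.  Baseline Cts are uniform in the typical
    18-28 cycle window.  All genes share one family so that family rank 1
    means best of the whole candidate panel.
    """
    rng = np.random.default_rng([seed, 77])
    genes = ["REF01"] + [f"GENE{i + 2:02d}" for i in range(n_genes - 1)]
    params: dict[str, dict[str, float]] = {}
    for i, g in enumerate(genes):
        mu = float(rng.uniform(18.0, 28.0))
        if i == 0:
            params[g] = {"mu": mu, "beta": 0.0, "sigma_eps": quiet_sigma}
        else:
            beta = float(rng.uniform(*beta_range)) * float(rng.choice([-1.0, 1.0]))
            sigma = float(rng.uniform(*noisy_sigma_range))
            params[g] = {"mu": mu, "beta": beta, "sigma_eps": sigma}
    return SimulationConfig(
        gene_params=params,
        families={g: "candidate" for g in genes},
        n_samples_per_dataset=n_samples,
        n_replicates=n_replicates,
        lambda_sd=lambda_sd,
        missing_rate=missing_rate,
        seed=seed,
    )


def heterogeneous_noise_config(
    seed: int,
    n_genes: int = 10,
    n_samples: int = 12,
    n_replicates: int = 3,
    sigma_range: tuple[float, float] = (0.4, 0.8),
    lambda_sd: float = 1.0,
) -> SimulationConfig:
    """Independent-noise layout: every gene condition-neutral (beta 0) with
    its own noise level drawn uniform in ``sigma_range``.

    With no condition axis, stability differences come purely from
    independent per-gene noise; averaging genes into combinations then
    reduces the pseudo-reference's variance, the regime in which adding
    reference genes is expected to help.
    """
    rng = np.random.default_rng([seed, 99])
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    params = {
        g: {
            "mu": float(rng.uniform(18.0, 28.0)),
            "beta": 0.0,
            "sigma_eps": float(rng.uniform(*sigma_range)),
        }
        for g in genes
    }
    return SimulationConfig(
        gene_params=params,
        families={g: "candidate" for g in genes},
        n_samples_per_dataset=n_samples,
        n_replicates=n_replicates,
        lambda_sd=lambda_sd,
        seed=seed,
    )


def screen_config(
    seed: int,
    families: dict[str, int] | None = None,
    n_datasets: int = 3,
    n_samples: int = 12,
    quiet_sigma: float = 0.05,
    noisy_sigma_range: tuple[float, float] = (0.4, 0.9),
    beta_range: tuple[float, float] = (0.5, 1.5),
) -> SimulationConfig:
    """Pre-screen layout: gene families with one stable isogene each.

    Default family sizes follow the classic reference families of the rice
    panel (7 GAPDH, 13 actin, 31 ubiquitin, 23 cyclophilin isogenes, 74
    genes in all).  The first isogene of each family is quiet (beta 0,
    small noise); the rest are condition-sensitive with random sign and
    heterogeneous noise.  ``mu`` is the baseline log2 intensity.
    """
    if families is None:
        families = {"GAPDH": 7, "actin": 13, "ubiquitin": 31, "cyclophilin": 23}
    rng = np.random.default_rng([seed, 88])
    params: dict[str, dict[str, float]] = {}
    fam_map: dict[str, str] = {}
    for fam, count in families.items():
        for i in range(count):
            gene = f"{fam}{i + 1:02d}"
            fam_map[gene] = fam
            mu = float(rng.uniform(6.0, 12.0))
            if i == 0:
                params[gene] = {"mu": mu, "beta": 0.0, "sigma_eps": quiet_sigma}
            else:
                beta = float(rng.uniform(*beta_range)) * float(rng.choice([-1.0, 1.0]))
                params[gene] = {
                    "mu": mu,
                    "beta": beta,
                    "sigma_eps": float(rng.uniform(*noisy_sigma_range)),
                }
    return SimulationConfig(
        gene_params=params,
        families=fam_map,
        n_datasets=n_datasets,
        n_samples_per_dataset=n_samples,
        seed=seed,
    )
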