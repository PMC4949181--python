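"""Core domain types for the reference-gene stability pipeline.

The pipeline moves through four kinds of evidence:

* linear-scale expression matrices (microarray-style) used to pre-screen
  candidate reference genes family by family,
* threshold-cycle (Ct) tables from qRT-PCR used to score single genes and
  multi-gene reference combinations by the dispersion of pairwise ΔCt,
* fold-change tables produced by ΔΔCt quantification against a chosen
  reference set, and
* paired cross-platform fold changes used to validate reference choices by
  their concordance with an independent measurement.

Each type validates its own invariants on construction so that downstream
numerics never have to re-check inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Required per-sample annotation fields, in canonical column order.
ANNOTATION_FIELDS = ("genotype", "stage", "tissue", "water_status")

#: Default plausible instrument range for threshold-cycle values (cycles).
DEFAULT_CT_RANGE = (5.0, 40.0)


class DataValidationError(ValueError):
    """Raised when an input violates a structural invariant.

    Messages carry enough row/column context to locate the offending cell
    in the source file.
    """


def _check_annotations(annotations: pd.DataFrame, samples: Iterable[str]) -> None:
    missing_cols = [c for c in ANNOTATION_FIELDS if c not in annotations.columns]
    if missing_cols:
        raise DataValidationError(
            f"sample annotations lack required column(s): {', '.join(missing_cols)}"
        )
    unknown = [s for s in samples if s not in annotations.index]
    if unknown:
        raise DataValidationError(
            f"sample(s) present in data but absent from annotations: {', '.join(map(str, unknown))}"
        )
    sub = annotations.loc[list(samples), list(ANNOTATION_FIELDS)]
    if sub.isna().any().any():
        bad = sub[sub.isna().any(axis=1)].index.tolist()
        raise DataValidationError(
            f"incomplete annotation tuple for sample(s): {', '.join(map(str, bad))}"
        )


@dataclass
class ExpressionMatrix:
    """Linear-scale expression intensities for one dataset.

    Parameters
    ----------
    dataset_id:
        Identifier of the source experiment (one microarray dataset).
    values:
        Genes x samples grid of non-negative, finite, linear-scale
        intensities.
    sample_annotations:
        One row per sample (indexed by sample id) with the columns
        ``genotype``, ``stage``, ``tissue`` and ``water_status``.
    family_map:
        Gene id -> family label (e.g. GAPDH, actin, ubiquitin,
        cyclophilin).  Genes absent from the map are tolerated but take no
        part in per-family ranking.
    """

    dataset_id: str
    values: pd.DataFrame
    sample_annotations: pd.DataFrame
    family_map: pd.Series

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataValidationError(
                f"dataset {self.dataset_id!r}: duplicate gene id(s): {', '.join(dupes)}"
            )
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise DataValidationError(
                f"dataset {self.dataset_id!r}: non-finite or negative intensity at "
                f"gene {self.values.index[g]!r}, sample {self.values.columns[s]!r} "
                f"(value {arr[g, s]!r})"
            )
        _check_annotations(self.sample_annotations, self.values.columns)
        self.family_map = self.family_map.astype(str)
        self.family_map.index = self.family_map.index.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def annotation_variety(self) -> int:
        """Number of distinct (genotype, stage, tissue, water_status) tuples.

        Used as the default per-dataset weight when aggregating within-family
        ranks into a weighted rank score: a dataset covering more distinct
        biological conditions carries more weight.
        """
        sub = self.sample_annotations.loc[self.samples, list(ANNOTATION_FIELDS)]
        return int(len(sub.drop_duplicates()))


@dataclass
class CtTable:
    """Long-format threshold-cycle observations.

    ``entries`` has one row per measured well with columns ``gene``,
    ``sample``, ``replicate`` (1-based technical replicate index) and
    ``ct`` (cycles).  Undetermined wells are simply absent: missingness is
    represented by absence, and each consumer decides its own handling
    policy.
    """

    entries: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None
    ct_range: tuple[float, float] = DEFAULT_CT_RANGE

    def __post_init__(self) -> None:
        required = ["gene", "sample", "replicate", "ct"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise DataValidationError(
                f"Ct table lacks required column(s): {', '.join(missing)}"
            )
        df = self.entries.loc[:, required].copy()
        df["gene"] = df["gene"].astype(str)
        df["sample"] = df["sample"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = df["ct"].astype(float)

        dup = df.duplicated(subset=["gene", "sample", "replicate"])
        if dup.any():
            r = df[dup].iloc[0]
            raise DataValidationError(
                f"duplicate Ct entry for gene {r['gene']!r}, sample {r['sample']!r}, "
                f"replicate {int(r['replicate'])}"
            )
        lo, hi = self.ct_range
        bad = ~np.isfinite(df["ct"].to_numpy()) | (df["ct"] < lo) | (df["ct"] > hi)
        if bad.any():
            r = df[bad].iloc[0]
            raise DataValidationError(
                f"Ct value {r['ct']} outside plausible range [{lo}, {hi}] at "
                f"gene {r['gene']!r}, sample {r['sample']!r}, replicate {int(r['replicate'])}"
            )
        # replicate indices must be 1..k per well group
        for (gene, sample), grp in df.groupby(["gene", "sample"], sort=False):
            reps = sorted(grp["replicate"])
            if reps != list(range(1, len(reps) + 1)):
                raise DataValidationError(
                    f"replicate indices for gene {gene!r}, sample {sample!r} are {reps}; "
                    "expected consecutive integers starting at 1"
                )
        if self.sample_annotations is not None:
            _check_annotations(self.sample_annotations, df["sample"].unique())
        self.entries = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.entries["sample"].unique())


@dataclass(frozen=True)
class ReferenceSet:
    """An ordered set of 1-4 distinct reference genes.

    The label joins members with "/" which is also the on-disk encoding of
    a combination.
    """

    genes: tuple[str, ...]

    def __init__(self, genes: Sequence[str]) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in genes))
        if not 1 <= len(self.genes) <= 4:
            raise DataValidationError(
                f"reference set must contain 1-4 genes, got {len(self.genes)}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataValidationError(f"duplicate gene in reference set: {self.genes}")

    @property
    def label(self) -> str:
        return "/".join(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class WrsTable:
    """Weighted-rank-score pre-screening results.

    ``rows`` holds the per-dataset evidence: one row per (gene, dataset)
    with columns ``gene``, ``dataset``, ``family``, ``cv`` and
    ``family_rank`` (1 = lowest CV in that family, ties averaged).

    ``aggregate`` is indexed by gene with columns ``family``, ``wrs`` and
    ``wrs_pct``; within each family the best gene has ``wrs_pct`` 100.
    """

    rows: pd.DataFrame
    aggregate: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene", "dataset", "family", "cv", "family_rank"):
            if col not in self.rows.columns:
                raise DataValidationError(f"WRS rows lack column {col!r}")
        for col in ("family", "wrs", "wrs_pct"):
            if col not in self.aggregate.columns:
                raise DataValidationError(f"WRS aggregate lacks column {col!r}")


@dataclass
class StabilityRanking:
    """Ranked stability scores for reference sets (the Table-1 structure).

    ``table`` has one row per evaluated reference set with columns
    ``reference`` (the "/"-joined label), ``size``, ``mean_sd`` (mean ΔCt
    standard deviation in cycles), ``rank_in_class`` (among sets of equal
    size) and ``rank_in_total`` (among all sets); ascending mean_sd, ties
    averaged.  Rows are ordered by (size, mean_sd, label).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("reference", "size", "mean_sd", "rank_in_class", "rank_in_total"):
            if col not in self.table.columns:
                raise DataValidationError(f"stability ranking lacks column {col!r}")

    def best(self, size: int | None = None) -> pd.Series:
        """Row with the smallest mean ΔCt SD, optionally within one class."""
        t = self.table if size is None else self.table[self.table["size"] == size]
        if t.empty:
            raise DataValidationError(f"no reference sets of size {size}")
        return t.loc[t["mean_sd"].idxmin()]


@dataclass
class FoldChangeTable:
    """Per-sample ΔΔCt quantification results for one reference set.

    ``rows``: one row per (target, sample) with columns ``target``,
    ``sample``, ``dct`` (Ct_target - Ct_reference), ``ddct`` (ΔCt minus the
    calibrator mean ΔCt), ``log2fc`` (= -ΔΔCt) and ``fc`` (= 2^log2fc).
    """

    rows: pd.DataFrame
    reference: ReferenceSet
    calibrator: tuple[str, ...]

    def __post_init__(self) -> None:
        for col in ("target", "sample", "dct", "ddct", "log2fc", "fc"):
            if col not in self.rows.columns:
                raise DataValidationError(f"fold-change table lacks column {col!r}")


@dataclass
class ConcordanceResult:
    """Cross-platform concordance of fold changes for one reference set.

    ``points`` has one row per target gene with columns ``target``, ``x``
    (array log2 fold change), ``y`` (qRT-PCR log2 fold change) and
    ``outlier`` (bool).  ``rv`` is the residual variance of the retained
    points around the identity line y = x, in squared log2-fold-change
    units; lower means better concordance.
    """

    label: str
    points: pd.DataFrame
    rv: float

    def __post_init__(self) -> None:
        for col in ("target", "x", "y", "outlier"):
            if col not in self.points.columns:
                raise DataValidationError(f"concordance points lack column {col!r}")
        if self.rv < 0:
            raise DataValidationError(f"residual variance must be >= 0, got {self.rv}")

    @property
    def n_retained(self) -> int:
        return int((~self.points["outlier"]).sum())


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic-data generator.

    The Ct-scale model is additive Gaussian:

        Ct[g, s, r] = mu_g + lambda_s + beta_g * x_s + eps[g, s, r]

    with per-sample loading offsets ``lambda_s ~ N(0, lambda_sd)``, a
    centered condition contrast ``x_s`` (+-0.5 for drought vs well-watered),
    gene-specific condition sensitivity ``beta_g`` and technical noise
    ``eps ~ N(0, sigma_eps_g)``.  On the expression side the same linear
    predictor (without lambda) lives on the log2 scale, so intensities are
    multiplicative: ``2**(mu_g + beta_g * x_s + eps)``.

    ``gene_params`` maps gene id -> dict with keys ``mu`` (baseline Ct in
    cycles, or baseline log2 intensity), ``beta`` and ``sigma_eps``;
    ``families`` maps gene id -> family label.
    """

    gene_params: dict[str, dict[str, float]]
    families: dict[str, str]
    n_datasets: int = 3
    n_samples_per_dataset: int = 12
    annotation_design: dict[str, list[str]] = field(
        default_factory=lambda: {
            "genotype": ["IR64", "WAB56-104"],
            "stage": ["seedling", "reproductive"],
            "tissue": ["root", "leaf"],
            "water_status": ["well-watered", "drought"],
        }
    )
    lambda_sd: float = 1.0
    n_replicates: int = 3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.n_samples_per_dataset < 1 or self.n_replicates < 1:
            raise DataValidationError("counts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise DataValidationError("missing_rate must lie in [0, 1)")
        if self.lambda_sd < 0:
            raise DataValidationError("lambda_sd must be >= 0")
        for gene, p in self.gene_params.items():
            for key in ("mu", "beta", "sigma_eps"):
                if key not in p:
                    raise DataValidationError(f"gene {gene!r} lacks parameter {key!r}")
            if p["sigma_eps"] < 0:
                raise DataValidationError(f"gene {gene!r}: sigma_eps must be >= 0")
        unknown = set(self.gene_params) - set(self.families)
        if unknown:
            raise DataValidationError(
                f"gene(s) without family label: {', '.join(sorted(unknown))}"
            )
        for fld in ANNOTATION_FIELDS:
            if fld not in self.annotation_design or not self.annotation_design[fld]:
                raise DataValidationError(f"annotation design lacks levels for {fld!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_params)
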