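"""Synthetic radiomics-like datasets and CSV I/O.

Radiomics feature tables are high-dimensional (often far more features than
samples), contain blocks of strongly correlated features derived from the
same image statistics, and occasionally carry sparse missing values from
numerical failures during feature extraction.  The generator here emulates
those properties with a block-equicorrelated Gaussian model so that every
downstream stage (preprocessing, feature selection, cross-validation,
evaluation) can be exercised without any external download.

The missing-value regime is deliberately capped below 1% per feature, which
is the regime where column-mean imputation is a reasonable, low-impact fix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DatasetSpec",
    "RadiomicsDataset",
    "generate_dataset",
    "inject_missing",
    "read_dataset",
    "write_dataset",
]

MAX_MISSING_RATE = 0.01


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_samples
        Number of samples N.
    n_features
        Number of features d.  ``n_samples / n_features`` is the
        samples-per-feature ratio; values well below 1 mark the
        high-dimensional regime.
    prevalence
        Fraction of positive outcomes, in (0, 1).  The positive count is
        assigned exactly as ``round(N * prevalence)`` and then shuffled, so
        class counts are deterministic.
    n_informative
        Number of features carrying true signal.  They occupy the first
        ``n_informative`` columns.  Zero yields a null dataset with no
        feature-outcome association.
    effect_size
        Standardized mean shift of each informative feature in the positive
        class (features have unit variance, so this is in SD units).
    block_size
        Features per correlated block.  Features within a block share a
        latent factor; blocks are mutually independent.
    within_block_correlation
        Pairwise correlation of features inside a block, in [0, 1).
    missing_rate
        Per-cell missing probability, at most 0.01.
    seed
        RNG seed; identical spec + seed reproduces the dataset bitwise.
    """

    n_samples: int
    n_features: int
    prevalence: float = 0.5
    n_informative: int = 0
    effect_size: float = 1.0
    block_size: int = 1
    within_block_correlation: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be positive, got {self.n_features}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(
                f"prevalence must lie strictly in (0, 1), got {self.prevalence}"
            )
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative must be in [0, n_features], got {self.n_informative}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be non-negative, got {self.effect_size}")
        if not 1 <= self.block_size <= self.n_features:
            raise ValueError(
                f"block_size must be in [1, n_features], got {self.block_size}"
            )
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError(
                "within_block_correlation must lie in [0, 1), got "
                f"{self.within_block_correlation}"
            )
        if not 0.0 <= self.missing_rate <= MAX_MISSING_RATE:
            raise ValueError(
                f"missing_rate must lie in [0, {MAX_MISSING_RATE}], got "
                f"{self.missing_rate}"
            )


@dataclass
class RadiomicsDataset:
    """A tabular dataset: numeric feature matrix plus binary outcome.

    ``features`` may contain NaN before preprocessing (the missing marker).
    ``informative_mask``, when set, flags planted-signal columns of the
    synthetic generator; real data loaded from CSV leaves it ``None``.
    """

    features: np.ndarray
    outcome: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    informative_mask: np.ndarray | None = field(default=None, repr=False)
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if self.outcome.shape != (n,):
            raise ValueError("outcome length must match the number of samples")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must contain only 0/1 values")
        if len(self.feature_names) != d or len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique and match n_features")
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match n_samples")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def samples_per_feature(self) -> float:
        """Dimensionality ratio N/d; below 1 means high-dimensional."""
        return self.n_samples / self.n_features

    def copy(self) -> "RadiomicsDataset":
        return RadiomicsDataset(
            features=self.features.copy(),
            outcome=self.outcome.copy(),
            feature_names=list(self.feature_names),
            sample_ids=list(self.sample_ids),
            informative_mask=(
                None if self.informative_mask is None else self.informative_mask.copy()
            ),
            name=self.name,
        )


def generate_dataset(spec: DatasetSpec) -> RadiomicsDataset:
    """Draw one synthetic dataset from ``spec``.

    Features come from a block-equicorrelated standard normal: each block of
    ``block_size`` consecutive columns shares a latent factor, giving every
    within-block pair correlation ``within_block_correlation`` while keeping
    unit variances and zero means.  The outcome has exactly
    ``round(N * prevalence)`` positives.  The first ``n_informative`` columns
    get their mean shifted by ``effect_size`` in the positive class; all
    other columns are independent of the outcome.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    rho = spec.within_block_correlation

    n_pos = int(round(n * spec.prevalence))
    n_pos = min(max(n_pos, 1), n - 1)  # both classes always present
    outcome = np.zeros(n, dtype=int)
    outcome[:n_pos] = 1
    rng.shuffle(outcome)

    n_blocks = math.ceil(d / spec.block_size)
    if rho > 0.0:
        # x_ij = sqrt(rho) * z_block(j) + sqrt(1-rho) * eps_ij keeps unit
        # variance and gives corr rho for any two features in one block.
        latent = rng.standard_normal((n, n_blocks))
        noise = rng.standard_normal((n, d))
        block_of = np.repeat(np.arange(n_blocks), spec.block_size)[:d]
        features = math.sqrt(rho) * latent[:, block_of] + math.sqrt(1.0 - rho) * noise
    else:
        features = rng.standard_normal((n, d))

    if spec.n_informative > 0 and spec.effect_size > 0:
        features[outcome == 1, : spec.n_informative] += spec.effect_size

    if spec.missing_rate > 0:
        mask = _missing_mask(rng, n, d, spec.missing_rate)
        features[mask] = np.nan

    mask_info = np.zeros(d, dtype=bool)
    mask_info[: spec.n_informative] = True
    return RadiomicsDataset(
        features=features,
        outcome=outcome,
        feature_names=[f"feat_{j:04d}" for j in range(d)],
        sample_ids=[f"sample_{i:04d}" for i in range(n)],
        informative_mask=mask_info,
        name=f"synth_N{n}_d{d}_seed{spec.seed}",
    )


def _missing_mask(
    rng: np.random.Generator, n: int, d: int, rate: float
) -> np.ndarray:
    mask = rng.random((n, d)) < rate
    # never blank out an entire column
    full = np.flatnonzero(mask.all(axis=0))
    for j in full:
        mask[rng.integers(n), j] = False
    return mask


def inject_missing(
    dataset: RadiomicsDataset, missing_rate: float, seed: int
) -> RadiomicsDataset:
    """Return a copy with cells independently blanked at ``missing_rate``.

    The outcome is never touched and no column may become entirely missing.
    Rates above 1% are rejected: that is outside the sparse-missingness
    regime this pipeline (column-mean imputation) is meant for.
    """
    if not 0.0 <= missing_rate <= MAX_MISSING_RATE:
        raise ValueError(
            f"missing_rate must lie in [0, {MAX_MISSING_RATE}], got {missing_rate}"
        )
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples to inject missing values")
    out = dataset.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = _missing_mask(rng, out.n_samples, out.n_features, missing_rate)
    out.features[mask] = np.nan
    return out


def write_dataset(
    dataset: RadiomicsDataset, path, outcome_column: str = "Target"
) -> None:
    """Write a dataset as UTF-8 CSV: one header row, sample ids in the first
    column, features as numeric columns, the outcome in ``outcome_column``.
    Missing cells are written empty."""
    df = pd.DataFrame(
        dataset.features, columns=dataset.feature_names, index=dataset.sample_ids
    )
    df.insert(0, outcome_column, dataset.outcome)
    df.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_dataset(
    path,
    outcome_column: str = "Target",
    name: str | None = None,
    remap_outcome: bool = False,
) -> RadiomicsDataset:
    """Read a dataset from CSV.

    The outcome column must contain exactly the values {0, 1}; with
    ``remap_outcome=True`` any two distinct values are coerced to {0, 1} by
    sorted order.  Empty cells become missing markers.  Non-numeric feature
    cells are reported with their row and column.
    """
    df = pd.read_csv(path, index_col=0)
    if outcome_column not in df.columns:
        raise ValueError(f"outcome column {outcome_column!r} not found in {path}")
    outcome_raw = df[outcome_column]
    if outcome_raw.isna().any():
        raise ValueError(f"outcome column {outcome_column!r} contains missing values")
    values = sorted(pd.unique(outcome_raw))
    if remap_outcome:
        if len(values) != 2:
            raise ValueError(
                f"outcome remap needs exactly 2 distinct values, found {values}"
            )
        outcome = (outcome_raw == values[1]).astype(int).to_numpy()
    else:
        if set(values) != {0, 1}:
            raise ValueError(
                f"outcome column must contain exactly {{0, 1}}, found {values}"
            )
        outcome = outcome_raw.astype(int).to_numpy()

    feat = df.drop(columns=[outcome_column])
    matrix = np.empty(feat.shape, dtype=float)
    for j, col in enumerate(feat.columns):
        try:
            matrix[:, j] = pd.to_numeric(feat[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(feat[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & feat[col].notna())[0])
            raise ValueError(
                f"non-numeric feature cell at row {feat.index[row]!r}, "
                f"column {col!r}: {feat[col].iloc[row]!r}"
            ) from None
    return RadiomicsDataset(
        features=matrix,
        outcome=outcome,
        feature_names=list(feat.columns),
        sample_ids=[str(s) for s in feat.index],
        name=name or str(path),
    )
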