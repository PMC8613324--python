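"""Column-mean imputation and z-score normalization.

Both steps are applied once to the whole dataset, *before* any
cross-validation.  That is a deliberate design of the study pipeline this
package implements: preprocessing done fold-wise would itself move the
estimates and occlude the quantity being measured — the optimism bias caused
by selecting features on data that includes the validation folds.  Neither
step uses the outcome, so its own leakage contribution is small; the
estimates of that bias are therefore to be read as a lower bound.  A
fold-nested preprocessing variant is intentionally not offered here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import RadiomicsDataset

__all__ = ["PreprocessReport", "impute_mean", "zscore", "preprocess"]


@dataclass
class PreprocessReport:
    """Book-keeping of one preprocessing step.

    ``column_scales`` are strictly positive: constant columns are mapped to
    all zeros (scale kept at 1) and listed in ``constant_columns`` instead of
    being dropped, so feature indices stay aligned across schemes.
    """

    column_means: np.ndarray | None = None
    column_centers: np.ndarray | None = None
    column_scales: np.ndarray | None = None
    n_imputed_cells: int = 0
    constant_columns: list[int] = field(default_factory=list)


def impute_mean(dataset: RadiomicsDataset) -> tuple[RadiomicsDataset, PreprocessReport]:
    """Replace every missing cell by the mean of its column's observed values.

    Non-missing cells are untouched.  A fully missing column is an error:
    there is no support to estimate its mean from.
    """
    X = dataset.features
    missing = np.isnan(X)
    fully_missing = np.flatnonzero(missing.all(axis=0))
    if fully_missing.size:
        names = [dataset.feature_names[j] for j in fully_missing]
        raise ValueError(f"cannot impute fully missing column(s): {names}")
    out = dataset.copy()
    report = PreprocessReport(n_imputed_cells=int(missing.sum()))
    if report.n_imputed_cells:
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=0)
        rows, cols = np.nonzero(missing)
        out.features[rows, cols] = means[cols]
        report.column_means = means
    else:
        report.column_means = X.mean(axis=0)
    return out, report


def zscore(dataset: RadiomicsDataset) -> tuple[RadiomicsDataset, PreprocessReport]:
    """Standardize each column to mean 0 and population SD 1.

    The population convention (divide by N) matches common ML scalers.
    Constant columns become all zeros and are flagged in the report;
    downstream scorers treat them as minimally relevant.
    """
    X = dataset.features
    if np.isnan(X).any():
        raise ValueError("missing values present: impute before normalizing")
    centers = X.mean(axis=0)
    scales = X.std(axis=0)  # population SD (ddof=0)
    constant = np.flatnonzero(scales == 0.0)
    safe = scales.copy()
    safe[constant] = 1.0
    out = dataset.copy()
    out.features = (X - centers) / safe
    report = PreprocessReport(
        column_centers=centers,
        column_scales=safe,
        constant_columns=constant.tolist(),
    )
    return out, report


def preprocess(dataset: RadiomicsDataset) -> tuple[RadiomicsDataset, PreprocessReport]:
    """Impute column means, then z-score normalize; the pipeline contract."""
    imputed, rep_i = impute_mean(dataset)
    scaled, rep_z = zscore(imputed)
    rep_z.column_means = rep_i.column_means
    rep_z.n_imputed_cells = rep_i.n_imputed_cells
    return scaled, rep_z
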