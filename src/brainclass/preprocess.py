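"""Feature-table preprocessing: TICV normalization, covariate residualization,
standardization, and PCA with a cumulative-variance retention rule.

Conventions fixed package-wide: sample statistics use the n-1 denominator,
and PCA is by default fitted to standardized columns (correlation PCA), since
the raw measures mix units (mm, mm^2, mm^3, dimensionless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MEASURES
from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "Standardization",
    "PCAModel",
    "ticv_normalize",
    "residualize_covariates",
    "standardize",
    "apply_standardization",
    "fit_pca",
    "project",
]


@dataclass(frozen=True)
class Standardization:
    """Column means/scales of a fitted standardization, reusable on new data."""

    means: np.ndarray
    scales: np.ndarray
    zero_variance: np.ndarray  # flagged columns left centered with scale 1


@dataclass(eq=False)
class PCAModel:
    """Principal components of a (optionally pre-standardized) matrix.

    ``loadings`` columns are orthonormal eigenvectors of the sample
    covariance matrix; ``eigenvalues`` are sorted descending; ``k`` is the
    smallest count whose cumulative explained-variance fraction reaches the
    retention threshold.
    """

    means: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_fractions: np.ndarray
    k: int
    variance_threshold: float

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]


def ticv_normalize(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Divide the selected measures row-wise by each subject's TICV.

    Default divides all five measures (the literal protocol); pass
    ``measures=("area", "volume")`` for the physically scaled subset.
    """
    if not table.index.equals(cohort.index):
        raise InvalidInputError("feature table and cohort index subjects differently")
    if np.any(cohort["ticv"].to_numpy() <= 0):
        raise InvalidInputError("ticv must be positive for all subjects")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ConfigurationError(f"unknown measures: {sorted(unknown)}")
    out = table.copy()
    cols = [c for c in table.columns if c.split("__")[1] in measures]
    out[cols] = out[cols].div(cohort["ticv"], axis=0)
    return out


def _site_design(site: np.ndarray) -> np.ndarray:
    """Indicator columns for all but the first site level."""
    levels = np.unique(site)
    return np.column_stack([(site == s).astype(float) for s in levels[1:]]) if len(
        levels
    ) > 1 else np.zeros((len(site), 0))


def residualize_covariates(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "site"),
) -> pd.DataFrame:
    """Replace each feature by its OLS residual on intercept + covariates.

    Site enters as S-1 indicator columns; redundant (rank-deficient) design
    columns are dropped with a warning.  Residuals have zero mean per feature.
    """
    if not table.index.equals(cohort.index):
        raise InvalidInputError("feature table and cohort index subjects differently")
    n = len(cohort)
    cols = [np.ones(n)]
    if "age" in covariates:
        cols.append(cohort["age"].to_numpy(dtype=float))
    if "site" in covariates:
        sd = _site_design(cohort["site"].to_numpy())
        cols.extend(sd.T)
    design = np.column_stack(cols)
    # drop columns that do not increase rank (e.g., single-site indicator)
    keep: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"dropping {design.shape[1] - len(keep)} redundant design column(s)",
            stacklevel=2,
        )
    design = design[:, keep]
    if n <= design.shape[1]:
        raise InvalidInputError("need more subjects than regression parameters")
    x = table.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    return pd.DataFrame(resid, index=table.index, columns=table.columns)


def standardize(
    matrix: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, Standardization]:
    """Center columns to mean 0 and scale to unit sample SD (n-1 denominator).

    Zero-variance columns are left centered with scale 1 and flagged.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidInputError("standardize needs a 2-D matrix with >= 2 rows")
    means = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    scales = np.where(zero, 1.0, sd)
    return (x - means) / scales, Standardization(means, scales, zero)


def apply_standardization(matrix: np.ndarray, stz: Standardization) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != stz.means.shape[0]:
        raise InvalidInputError("column count does not match the standardization")
    return (x - stz.means) / stz.scales


def fit_pca(
    matrix: np.ndarray | pd.DataFrame, variance_threshold: float = 0.95
) -> PCAModel:
    """Eigendecompose the sample covariance; retain components per threshold.

    Centering is applied internally.  Retained count k is the smallest
    integer whose cumulative explained-variance fraction is >= threshold.
    """
    if not 0 < variance_threshold <= 1:
        raise ConfigurationError("variance_threshold must be in (0, 1]")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidInputError("fit_pca needs at least 2 rows")
    n, d = x.shape
    means = x.mean(axis=0)
    xc = x - means
    cov = (xc.T @ xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eig = eigvals[order]
    loadings = eigvecs[:, order]
    if eig.min() < -1e-8:
        raise InvalidInputError("covariance eigenvalue below the numerical floor")
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    fractions = eig / total if total > 0 else np.full(d, 1.0 / d)
    cum = np.cumsum(fractions)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    return PCAModel(
        means=means,
        loadings=loadings,
        eigenvalues=eig,
        explained_fractions=fractions,
        k=min(k, d),
        variance_threshold=variance_threshold,
    )


def project(
    model: PCAModel, matrix: np.ndarray | pd.DataFrame, k: int | None = None
) -> np.ndarray:
    """Scores of ``matrix`` on the retained loading vectors (n x k)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise InvalidInputError("column count does not match the PCA model")
    k = model.k if k is None else k
    return (x - model.means) @ model.loadings[:, :k]
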