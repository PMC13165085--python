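"""Per-plant PCA score spaces and day-1-baseline Mahalanobis monitoring.

Each plant gets its own PCA, fitted on its centered, preprocessed spectra
stacked over all acquisition days.  The first day's score cloud defines a
baseline: its centroid mu_ref and sample covariance Sigma_ref.  For every
pixel on every later day the squared Mahalanobis divergence

    MD^2 = (mu_t - mu_ref)^T Sigma_ref^{-1} (mu_t - mu_ref)

measures how far that pixel's score vector mu_t has moved from the
baseline condition.  A per-day two-sample rank test (Mann-Whitney U) of
the day-t MD^2 distribution against the day-1 MD^2 distribution yields a
p-value per day; the plant's change day is the earliest day with p below
alpha, defaulting to the last trial day when no day is significant.

For the day-1 comparison sample, MD^2 is computed leave-one-out (each
baseline pixel scored against the baseline refitted without it).
In-sample MD^2 of points that themselves defined the baseline is biased
low relative to new points, which would inflate the false-alarm rate of
the rank test; the leave-one-out values are exchangeable with day-t
values under no change, so the test is calibrated.  The plain in-sample
definition is kept in :func:`mahalanobis_md2` (it satisfies the exact
identity sum MD^2 = (n-1) k over the baseline points).

Wavelength importance is read off the first principal component: bands
whose absolute PC1 loading exceeds a quantile threshold are merged into
contiguous ranges and ranked by their peak loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import mannwhitneyu

from .tables import spectra_matrix

__all__ = [
    "PlantPCAModel",
    "BaselineReference",
    "ChangeReport",
    "ImportanceRange",
    "fit_plant_pca",
    "build_baseline",
    "mahalanobis_md2",
    "leave_one_out_md2",
    "detect_change_day",
    "wavelength_importance",
    "monitor_plant",
    "monitor_trial",
]


@dataclass
class PlantPCAModel:
    """Loadings/scores/explained variance of one plant's PCA."""

    loadings: np.ndarray  # (bands, k), orthonormal columns
    scores: np.ndarray  # (n, k)
    explained_variance_fraction: np.ndarray  # (k,)
    k: int
    wavelengths: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.loadings


@dataclass
class BaselineReference:
    """Day-1 score centroid and (regularized) covariance."""

    centroid: np.ndarray  # (k,)
    covariance: np.ndarray  # (k, k) symmetric positive-definite
    n_baseline: int
    _chol: tuple = field(default=None, repr=False)

    def _factor(self):
        if self._chol is None:
            self._chol = cho_factor(self.covariance)
        return self._chol


@dataclass
class ChangeReport:
    """Per-plant monitoring outcome."""

    plant_id: str
    md2_by_pixel_by_day: dict[int, np.ndarray]
    pvalue_by_day: dict[int, float]
    change_day: int
    defaulted: bool
    group: str = ""
    model: PlantPCAModel | None = None


@dataclass(frozen=True)
class ImportanceRange:
    """Contiguous wavelength range of high absolute PC1 loading."""

    wl_min: float
    wl_max: float
    peak_wavelength: float
    peak_loading: float

    def contains(self, wavelength: float) -> bool:
        return self.wl_min <= wavelength <= self.wl_max


def fit_plant_pca(
    matrix: np.ndarray,
    k: int | str = 3,
    wavelengths: np.ndarray | None = None,
) -> PlantPCAModel:
    """PCA of a centered spectra-by-bands matrix via SVD.

    ``k`` is the retained-component count, or ``"var95"`` for the
    smallest k explaining >= 95% of variance.  Sign convention: each
    loading's largest-magnitude element is positive, so results are
    deterministic.  Raises if the centered matrix has rank below k.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D spectra x bands matrix")
    colmeans = X.mean(axis=0)
    if np.max(np.abs(colmeans)) > 1e-6 * max(1.0, np.max(np.abs(X))):
        raise ValueError("matrix must be column-centered before PCA")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = np.sum(s**2)
    if total == 0:
        raise ValueError("matrix has no variance")
    frac = s**2 / total
    rank = int(np.sum(s > s[0] * 1e-10))
    if k == "var95":
        k_use = int(np.searchsorted(np.cumsum(frac), 0.95) + 1)
        k_use = min(k_use, rank)
    else:
        k_use = int(k)
        if rank < k_use:
            raise ValueError(f"matrix rank {rank} < requested components {k_use}")
    if X.shape[0] <= k_use:
        raise ValueError("need more spectra than retained components")
    loadings = Vt[:k_use].T.copy()
    for j in range(k_use):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = X @ loadings
    return PlantPCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=frac[:k_use],
        k=k_use,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def build_baseline(
    model: PlantPCAModel,
    day1_indices: np.ndarray,
    condition_limit: float = 1e8,
    ridge_eps: float = 1e-6,
) -> BaselineReference:
    """Day-1 centroid and sample covariance (n-1 denominator) in score space.

    The covariance diagonal is ridge-regularized by ``ridge_eps x trace/k``
    only when its condition number exceeds ``condition_limit``.  Degenerate
    (zero-variance) baselines raise.
    """
    idx = np.asarray(day1_indices)
    S = model.scores[idx]
    k = model.k
    if S.shape[0] < k + 2:
        raise ValueError(f"need >= {k + 2} baseline rows, got {S.shape[0]}")
    centroid = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1).reshape(k, k)
    tr = np.trace(cov)
    if tr <= 0:
        raise ValueError("baseline scores are degenerate (zero covariance)")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > condition_limit:
        cov = cov + ridge_eps * tr / k * np.eye(k)
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals[0] <= 0:
            raise ValueError("baseline covariance singular even after regularization")
    return BaselineReference(centroid=centroid, covariance=cov, n_baseline=S.shape[0])


def mahalanobis_md2(score, baseline: BaselineReference) -> float | np.ndarray:
    """Squared Mahalanobis divergence of score vector(s) from the baseline.

    Computed with a Cholesky solve, never an explicit inverse.  Accepts a
    single k-vector or an (n x k) matrix (one value per row).
    """
    d = np.atleast_2d(np.asarray(score, dtype=float)) - baseline.centroid
    if d.shape[1] != baseline.centroid.size:
        raise ValueError("score dimension does not match baseline")
    sol = cho_solve(baseline._factor(), d.T)
    md2 = np.einsum("ij,ji->i", d, sol)
    md2 = np.maximum(md2, 0.0)
    return float(md2[0]) if np.asarray(score).ndim == 1 else md2


def leave_one_out_md2(model: PlantPCAModel, day1_indices: np.ndarray) -> np.ndarray:
    """MD^2 of each baseline pixel against the baseline refitted without it."""
    idx = np.asarray(day1_indices)
    out = np.empty(idx.size)
    for i in range(idx.size):
        rest = np.delete(idx, i)
        ref = build_baseline(model, rest)
        out[i] = mahalanobis_md2(model.scores[idx[i]], ref)
    return out


def detect_change_day(
    md2_by_day: dict[int, np.ndarray],
    alpha: float = 0.01,
    plant_id: str = "",
    group: str = "",
    model: PlantPCAModel | None = None,
) -> ChangeReport:
    """Assign the earliest day whose MD^2 distribution departs from day 1.

    For each day after the first, a two-sided Mann-Whitney U test compares
    that day's per-pixel MD^2 values with the first day's.  The change day
    is the earliest day with p < alpha; if none is significant the plant
    is assigned the last trial day with ``defaulted=True``.  No
    multiple-testing correction is applied across days (earliest-crossing
    rule); the resulting family-wise false-alarm rate is quantified in the
    test suite instead.
    """
    days = list(md2_by_day)
    if len(days) < 2:
        raise ValueError("need at least two days to monitor change")
    for d, v in md2_by_day.items():
        if np.asarray(v).size < 2:
            raise ValueError(f"day {d} has fewer than 2 MD^2 values")
    ref = np.asarray(md2_by_day[days[0]], dtype=float)
    pvals: dict[int, float] = {}
    change_day, defaulted = days[-1], True
    for d in days[1:]:
        stat = mannwhitneyu(
            np.asarray(md2_by_day[d], dtype=float), ref, alternative="two-sided"
        )
        pvals[d] = float(stat.pvalue)
    for d in days[1:]:
        if pvals[d] < alpha:
            change_day, defaulted = d, False
            break
    return ChangeReport(
        plant_id=plant_id,
        md2_by_pixel_by_day={d: np.asarray(v, float) for d, v in md2_by_day.items()},
        pvalue_by_day=pvals,
        change_day=change_day,
        defaulted=defaulted,
        group=group,
        model=model,
    )


def wavelength_importance(
    model: PlantPCAModel,
    wavelengths: np.ndarray | None = None,
    quantile: float = 0.80,
    gap_tolerance: int = 2,
) -> list[ImportanceRange]:
    """Rank contiguous wavelength ranges by absolute PC1 loading.

    Bands whose |loading| strictly exceeds the given quantile of the
    loading magnitudes are grouped into runs; runs separated by at most
    ``gap_tolerance`` bands are merged.  Ranges are returned sorted by
    their peak |loading|, largest first.
    """
    wl = model.wavelengths if wavelengths is None else np.asarray(wavelengths, float)
    if wl is None:
        raise ValueError("model carries no wavelength grid; pass one explicitly")
    a = np.abs(model.loadings[:, 0])
    thr = np.quantile(a, quantile)
    above = np.nonzero(a > thr)[0]
    if above.size == 0:
        return []
    runs: list[list[int]] = [[int(above[0]), int(above[0])]]
    for i in above[1:]:
        if i - runs[-1][1] <= gap_tolerance + 1:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    out = []
    for lo, hi in runs:
        seg = a[lo : hi + 1]
        peak = lo + int(np.argmax(seg))
        out.append(
            ImportanceRange(
                wl_min=float(wl[lo]),
                wl_max=float(wl[hi]),
                peak_wavelength=float(wl[peak]),
                peak_loading=float(a[peak]),
            )
        )
    return sorted(out, key=lambda r: -r.peak_loading)


def monitor_plant(
    plant_table: pd.DataFrame,
    k: int | str = 3,
    alpha: float = 0.01,
) -> ChangeReport:
    """Full divergence monitoring for one plant's preprocessed table.

    Fits the plant's PCA on its day-stacked matrix, builds the day-1
    baseline, computes per-pixel MD^2 (leave-one-out for day 1 itself),
    and assigns the change day.
    """
    days = list(dict.fromkeys(plant_table["day"]))
    X, wl = spectra_matrix(plant_table)
    model = fit_plant_pca(X, k=k, wavelengths=wl)
    day_arr = plant_table["day"].to_numpy()
    day1_idx = np.nonzero(day_arr == days[0])[0]
    baseline = build_baseline(model, day1_idx)
    md2_by_day: dict[int, np.ndarray] = {
        days[0]: leave_one_out_md2(model, day1_idx)
    }
    for d in days[1:]:
        idx = np.nonzero(day_arr == d)[0]
        md2_by_day[d] = mahalanobis_md2(model.scores[idx], baseline)
    plant_id = str(plant_table["plant_id"].iloc[0])
    group = str(plant_table["group"].iloc[0]) if "group" in plant_table else ""
    return detect_change_day(md2_by_day, alpha=alpha, plant_id=plant_id,
                             group=group, model=model)


def monitor_trial(
    table: pd.DataFrame,
    k: int | str = 3,
    alpha: float = 0.01,
) -> list[ChangeReport]:
    """Run :func:`monitor_plant` for every plant in a preprocessed table."""
    return [
        monitor_plant(sub, k=k, alpha=alpha)
        for _, sub in table.groupby("plant_id", sort=False)
    ]
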