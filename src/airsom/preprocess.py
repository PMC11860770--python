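"""Reading, alignment, imputation and scaling of multisite hourly pollutant panels.

The canonical panel layout is one row per (site, hour) pair with five pollutant
columns in fixed order: benzene, toluene, PM10, NO, NO2.  All downstream stages
(SOM training, BMU tables, outlier timelines) index into rows sorted by
``(site, timestamp)``; that ordering is established here and never changed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VARIABLES",
    "PanelDataset",
    "ScalingModel",
    "PanelFormatError",
    "EmptyPanelError",
    "EmptyIntersectionError",
    "read_hourly_panel",
    "intersect_complete_timestamps",
    "impute_iterative_pca",
    "autoscale",
    "inverse_autoscale",
    "preprocess_panel",
    "write_scaling",
    "read_scaling",
]

#: Fixed variable order used throughout the pipeline.
VARIABLES = ("Ben", "Tol", "PM10", "NO", "NO2")

#: Default mapping canonical variable name -> CSV column header.
DEFAULT_COLUMN_MAP = {"Ben": "ben", "Tol": "tol", "PM10": "pm10", "NO": "no", "NO2": "no2"}

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


class PanelFormatError(ValueError):
    """Raised when an input file violates the panel CSV contract."""


class EmptyPanelError(ValueError):
    """Raised when an input contains no data rows."""


class EmptyIntersectionError(ValueError):
    """Raised when no timestamp survives the completeness intersection."""


@dataclass
class PanelDataset:
    """Hourly site-labelled sample matrix.

    Parameters
    ----------
    timestamps : ndarray of datetime64
        One entry per row, naive local time truncated to the hour.
    sites : ndarray of str
        Site identifier per row (e.g. ``"A1"``).
    X : ndarray of float, shape (n_rows, n_variables)
        Concentrations in native units; ``NaN`` marks a missing value.
    variable_names : tuple of str
        Fixed-order pollutant names, default :data:`VARIABLES`.

    Rows are expected to be sorted by ``(site, timestamp)``; use
    :meth:`sorted_copy` or the constructors in this module to guarantee it.
    """

    timestamps: np.ndarray
    sites: np.ndarray
    X: np.ndarray
    variable_names: tuple = field(default=VARIABLES)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.sites = np.asarray(self.sites, dtype=str)
        self.X = np.asarray(self.X, dtype=float)
        self.variable_names = tuple(self.variable_names)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.variable_names):
            raise PanelFormatError(
                f"X must be 2-D with {len(self.variable_names)} columns, got shape {self.X.shape}"
            )
        n = self.X.shape[0]
        if len(self.timestamps) != n or len(self.sites) != n:
            raise PanelFormatError("timestamps, sites and X must have equal row counts")
        pairs = pd.MultiIndex.from_arrays([self.sites, self.timestamps])
        if pairs.has_duplicates:
            dup = pairs[pairs.duplicated()][0]
            raise PanelFormatError(f"duplicated (site, timestamp) pair: {dup}")
        with np.errstate(invalid="ignore"):
            if np.any(self.X < 0):
                raise PanelFormatError("concentrations must be >= 0 or missing (NaN)")

    # -- basic views ------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def site_ids(self) -> tuple:
        return tuple(sorted(set(self.sites.tolist())))

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def sorted_copy(self) -> "PanelDataset":
        """Return a copy with rows sorted by (site, timestamp)."""
        order = np.lexsort((self.timestamps, self.sites))
        return PanelDataset(
            self.timestamps[order], self.sites[order], self.X[order].copy(), self.variable_names
        )

    def take(self, mask_or_index) -> "PanelDataset":
        idx = np.asarray(mask_or_index)
        return PanelDataset(
            self.timestamps[idx], self.sites[idx], self.X[idx].copy(), self.variable_names
        )

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "datetime": pd.DatetimeIndex(self.timestamps).strftime(TIMESTAMP_FORMAT),
                "site": self.sites,
            }
        )
        for j, name in enumerate(self.variable_names):
            df[DEFAULT_COLUMN_MAP.get(name, name.lower())] = self.X[:, j]
        return df

    def to_csv(self, path) -> None:
        """Write the panel in the canonical dialect (empty cell = missing)."""
        self.to_frame().to_csv(path, index=False, na_rep="")


def read_hourly_panel(
    path,
    variable_map: dict | None = None,
    timestamp_col: str = "datetime",
    site_col: str = "site",
) -> PanelDataset:
    """Read an hourly pollutant CSV into a :class:`PanelDataset`.

    Unparseable numeric cells (``"n/a"``, empty, ...) and negative values
    become missing marks.  Rows come back sorted by ``(site, timestamp)``.

    Raises
    ------
    PanelFormatError
        If a mandatory column is absent or a (site, timestamp) pair repeats.
    EmptyPanelError
        If the file has a header but no data rows.
    """
    variable_map = dict(variable_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(path)
    for col in [timestamp_col, site_col, *variable_map.values()]:
        if col not in df.columns:
            raise PanelFormatError(f"missing mandatory column: {col!r}")
    if len(df) == 0:
        raise EmptyPanelError(f"no data rows in {path}")
    timestamps = pd.to_datetime(df[timestamp_col]).to_numpy(dtype="datetime64[s]")
    sites = df[site_col].astype(str).to_numpy()
    X = np.column_stack(
        [pd.to_numeric(df[variable_map[v]], errors="coerce").to_numpy(float) for v in variable_map]
    )
    n_neg = int(np.sum(X < 0))
    if n_neg:
        warnings.warn(f"{n_neg} negative concentration(s) set to missing", RuntimeWarning)
        X[X < 0] = np.nan
    return PanelDataset(timestamps, sites, X, tuple(variable_map)).sorted_copy()


def intersect_complete_timestamps(panel: PanelDataset, max_na_per_row: int = 1) -> PanelDataset:
    """Keep only timestamps at which *every* site has an acceptable row.

    A row is acceptable when it has at most ``max_na_per_row`` missing values.
    ``max_na_per_row=0`` is the strict reading (drop every row touching a
    missing value); the default ``1`` lets sparse single-pollutant gaps
    survive so they can be imputed afterwards.

    After the call every site has exactly one row per retained timestamp, so
    ``n_rows == n_sites * n_common_timestamps``.
    """
    if panel.n_sites < 1:
        raise EmptyPanelError("panel has no sites")
    ok = np.isnan(panel.X).sum(axis=1) <= int(max_na_per_row)
    tab = (
        pd.DataFrame({"ts": panel.timestamps, "site": panel.sites, "ok": ok})
        .pivot(index="ts", columns="site", values="ok")
        .reindex(columns=list(panel.site_ids))
    )
    kept = tab.eq(True).all(axis=1)  # absent row (NaN) counts as not acceptable
    kept_ts = tab.index[kept].to_numpy(dtype="datetime64[s]")
    if kept_ts.size == 0:
        raise EmptyIntersectionError(
            "no timestamp is complete at every site; consider relaxing max_na_per_row"
        )
    mask = np.isin(panel.timestamps, kept_ts)
    return panel.take(mask).sorted_copy()


def impute_iterative_pca(
    X: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Fill missing cells by iterated PCA reconstruction.

    Missing entries are initialised with column means, then repeatedly
    overwritten with their rank-``n_components`` PCA reconstruction until the
    relative change of the imputed cells drops below ``tol``.  Observed
    entries are returned bit-for-bit unchanged.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 1 <= n_components < m:
        raise ValueError(f"n_components must be in [1, {m - 1}], got {n_components}")
    mask = np.isnan(X)
    if not mask.any():
        return X.copy()
    observed_per_col = (~mask).sum(axis=0)
    if np.any(observed_per_col == 0):
        bad = int(np.argmin(observed_per_col))
        raise ValueError(f"column {bad} is entirely missing; cannot impute")
    if np.any(observed_per_col < n_components + 1):
        bad = int(np.argmin(observed_per_col))
        raise ValueError(
            f"column {bad} has fewer than n_components+1={n_components + 1} observed values"
        )

    col_means = np.nanmean(X, axis=0)
    work = np.where(mask, col_means, X)
    converged = False
    for _ in range(int(max_iter)):
        mu = work.mean(axis=0)
        centered = work - mu
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        basis = vt[:n_components]
        recon = mu + centered @ basis.T @ basis
        old = work[mask]
        new = recon[mask]
        work[mask] = new
        denom = max(float(np.linalg.norm(old)), 1e-12)
        if float(np.linalg.norm(new - old)) / denom < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"iterative PCA imputation did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    out = X.copy()
    out[mask] = work[mask]
    return out


@dataclass(frozen=True)
class ScalingModel:
    """Per-variable autoscaling parameters (mean and sample sd, ddof=1)."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if np.any(self.sds <= 0):
            raise ValueError("all standard deviations must be strictly positive")

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        self._check(X)
        return (X - self.means) / self.sds

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        self._check(Xs)
        return Xs * self.sds + self.means

    def _check(self, X):
        if X.ndim != 2 or X.shape[1] != self.means.shape[0]:
            raise ValueError(
                f"expected {self.means.shape[0]} columns, got matrix of shape {X.shape}"
            )


def autoscale(X: np.ndarray, variable_names=None):
    """Autoscale columns to mean 0 / sample sd 1 (denominator n-1).

    Returns ``(scaled, ScalingModel)``.  Raises on missing values and on
    constant columns, naming the offending variable.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("autoscale requires a complete matrix; impute first")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        j = int(np.argmin(sds))
        name = variable_names[j] if variable_names is not None else f"column {j}"
        raise ValueError(f"constant variable cannot be autoscaled: {name}")
    model = ScalingModel(means, sds)
    return model.forward(X), model


def inverse_autoscale(Xs: np.ndarray, model: ScalingModel) -> np.ndarray:
    """Map autoscaled values back to concentration scale (``x = xs*sd + mean``)."""
    return model.inverse(Xs)


def preprocess_panel(
    panel: PanelDataset,
    max_na_per_row: int = 1,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PanelDataset:
    """Two-stage cleaning: completeness intersection, then PCA imputation.

    Residual missing values (allowed through by ``max_na_per_row > 0``) are
    imputed on the concentration scale; imputed cells are clipped at zero to
    preserve the nonnegativity invariant of the panel.
    """
    clean = intersect_complete_timestamps(panel, max_na_per_row=max_na_per_row)
    if np.isnan(clean.X).any():
        filled = impute_iterative_pca(
            clean.X, n_components=n_components, tol=tol, max_iter=max_iter
        )
        mask = np.isnan(clean.X)
        filled[mask] = np.clip(filled[mask], 0.0, None)
        clean = replace(clean, X=filled)
    return clean


def write_scaling(model: ScalingModel, path, variable_names=VARIABLES) -> None:
    """Write a ScalingModel as key-value text (variable, mean, sd)."""
    with open(path, "w") as fh:
        fh.write("variable\tmean\tsd\n")
        for name, mu, sd in zip(variable_names, model.means, model.sds):
            fh.write(f"{name}\t{float(mu)!r}\t{float(sd)!r}\n")


def read_scaling(path):
    """Read a ScalingModel written by :func:`write_scaling`.

    Returns ``(model, variable_names)``.
    """
    df = pd.read_csv(path, sep="\t")
    return ScalingModel(df["mean"].to_numpy(), df["sd"].to_numpy()), tuple(df["variable"])
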