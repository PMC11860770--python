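"""Batch self-organizing map on a hexagonal grid.

Covers map sizing (Vesanto-style heuristic), PCA linear initialisation,
batch training with a Gaussian neighbourhood, BMU assignment, the three
quality metrics used for model selection (quantization error, topographic
error, distribution-matching error), the neighbour-distance (U-matrix) map
and quantization-error outlier flagging.

Conventions fixed here and relied on elsewhere:

* node ids are row-major: ``node = row * xdim + col``;
* hex layout is "even-q" offset: planar x = col * sqrt(3)/2, planar
  y = row + 0.5 * (col % 2), so every adjacent pair is at planar distance 1;
* BMU ties break to the lowest node index.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import ks_2samp

from .preprocess import VARIABLES

__all__ = [
    "GridSpec",
    "Codebook",
    "SomParams",
    "QualityMetrics",
    "SomModel",
    "BmuAssignment",
    "heuristic_map_size",
    "linear_init",
    "train_batch_som",
    "assign_bmu",
    "quality_metrics",
    "u_matrix",
    "detect_qe_outliers",
    "select_best_model",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_SQ3_2 = np.sqrt(3.0) / 2.0


def _hex_coords(xdim: int, ydim: int) -> np.ndarray:
    rows, cols = np.divmod(np.arange(xdim * ydim), xdim)
    x = cols * _SQ3_2
    y = rows + 0.5 * (cols % 2)
    return np.column_stack([x, y]).astype(float)


@dataclass(eq=False)
class GridSpec:
    """Hexagonal SOM grid: ``xdim`` columns by ``ydim`` rows."""

    xdim: int
    ydim: int
    topology: str = "hexagonal"
    node_coords: np.ndarray = None

    def __post_init__(self):
        if self.topology != "hexagonal":
            raise ValueError("only hexagonal topology is supported")
        if self.xdim < 1 or self.ydim < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.node_coords is None:
            self.node_coords = _hex_coords(self.xdim, self.ydim)

    @property
    def n_nodes(self) -> int:
        return self.xdim * self.ydim

    def planar_distances(self) -> np.ndarray:
        """Pairwise planar distances between node positions."""
        return cdist(self.node_coords, self.node_coords)

    def adjacency(self) -> np.ndarray:
        """Boolean hex-adjacency matrix (planar distance == 1)."""
        d = self.planar_distances()
        adj = np.abs(d - 1.0) < 1e-9
        np.fill_diagonal(adj, False)
        return adj


@dataclass(eq=False)
class Codebook:
    """Node prototype matrix, one row per grid node."""

    M: np.ndarray
    variable_names: tuple = VARIABLES
    scale: str = "autoscaled"  # "autoscaled" | "concentration"

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.variable_names = tuple(self.variable_names)
        if not np.all(np.isfinite(self.M)):
            raise ValueError("codebook must be finite everywhere")


@dataclass(frozen=True)
class SomParams:
    """Training schedule: rough phase shrinks sigma linearly to 1 over the
    first half of the epochs, fine phase keeps sigma = 1."""

    epochs: int = 100
    radius_start: float | None = None  # default max(xdim, ydim) / 4
    radius_end: float = 1.0
    seed: int = 0

    def schedule(self, grid: GridSpec) -> np.ndarray:
        sigma0 = self.radius_start
        if sigma0 is None:
            sigma0 = max(grid.xdim, grid.ydim) / 4.0
        sigma0 = max(float(sigma0), float(self.radius_end))
        if sigma0 < self.radius_end or self.radius_end < 1.0:
            raise ValueError("need radius_start >= radius_end >= 1")
        rough = int(np.ceil(self.epochs / 2))
        if rough > 1:
            ramp = np.linspace(sigma0, self.radius_end, rough)
        else:
            ramp = np.full(rough, self.radius_end)
        fine = np.full(self.epochs - rough, self.radius_end)
        return np.concatenate([ramp, fine])


@dataclass(frozen=True)
class QualityMetrics:
    qe: float  # overall quantization error (mean sample-to-BMU distance)
    te: float  # fraction of samples with non-adjacent first/second BMUs
    dme: float  # mean per-variable KS distance, data vs BMU-mapped codebook


@dataclass(eq=False)
class SomModel:
    grid: GridSpec
    codebook: Codebook
    params: SomParams
    quality: QualityMetrics | None = None


@dataclass(eq=False)
class BmuAssignment:
    """Per-sample best matching unit, runner-up and quantization error."""

    bmu_index: np.ndarray
    second_bmu: np.ndarray
    qe_sample: np.ndarray


def heuristic_map_size(n_samples: int, eig_ratio: float) -> GridSpec:
    """Vesanto-style grid sizing.

    ``munits = 5 * sqrt(n_samples)``; the side ratio is ``sqrt(eig_ratio)``
    (ratio of the two largest data-covariance eigenvalues), with
    ``xdim = round(sqrt(munits * sqrt(eig_ratio)))`` and
    ``ydim = round(munits / xdim)``.  Rounding is half-away-from-zero.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples to size a map")
    if eig_ratio < 1:
        raise ValueError("eig_ratio must be >= 1 (largest eigenvalue first)")
    munits = 5.0 * np.sqrt(n_samples)
    xdim = int(np.floor(np.sqrt(munits * np.sqrt(eig_ratio)) + 0.5))
    xdim = max(xdim, 1)
    ydim = max(int(np.floor(munits / xdim + 0.5)), 1)
    return GridSpec(xdim=xdim, ydim=ydim)


def data_eig_ratio(X: np.ndarray) -> float:
    """Ratio of the two largest covariance eigenvalues of ``X`` (>= 1)."""
    X = np.asarray(X, dtype=float)
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if len(s) < 2 or s[1] <= 0:
        return 1.0
    return float((s[0] / s[1]) ** 2)


def linear_init(X: np.ndarray, grid: GridSpec, seed: int = 0) -> Codebook:
    """Initialise the codebook on the plane of the first two PCs.

    Node values are linear in the planar grid coordinates; the longer grid
    axis is aligned with the first principal component and spans +-2 sd of
    the PC scores.  ``seed`` is only used for the degenerate (rank-1)
    fallback direction.
    """
    X = np.asarray(X, dtype=float)
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("linear_init requires at least 2 distinct rows")
    mu = X.mean(axis=0)
    centered = X - mu
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    sd = svals / np.sqrt(max(X.shape[0] - 1, 1))
    v1 = vt[0]
    if len(sd) > 1 and sd[1] > 1e-12 * sd[0]:
        v2, s2 = vt[1], sd[1]
    else:
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(X.shape[1])
        raw -= raw @ v1 * v1
        norm = np.linalg.norm(raw)
        v2 = raw / norm if norm > 0 else v1
        s2 = 0.0
    coords = grid.node_coords
    u = np.zeros_like(coords)
    spans = coords.max(axis=0) - coords.min(axis=0)
    for a in range(2):
        if spans[a] > 0:
            mid = (coords[:, a].max() + coords[:, a].min()) / 2.0
            u[:, a] = (coords[:, a] - mid) / (spans[a] / 2.0)
    # longer planar axis follows PC1
    if spans[1] > spans[0]:
        u = u[:, ::-1]
    M = mu + 2.0 * sd[0] * np.outer(u[:, 0], v1) + 2.0 * s2 * np.outer(u[:, 1], v2)
    return Codebook(M, scale="autoscaled")


def _bmu_only(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    return cdist(X, M, metric="sqeuclidean").argmin(axis=1)


def train_batch_som(
    X: np.ndarray,
    grid: GridSpec,
    params: SomParams | None = None,
    variable_names=VARIABLES,
) -> SomModel:
    """Train a batch SOM with a Gaussian neighbourhood kernel.

    Each epoch assigns BMUs and replaces every prototype with the kernel-
    weighted mean of the samples, ``m_i = sum_j h(c(j), i) x_j / sum_j h``,
    with ``h(c, i) = exp(-d(c, i)^2 / (2 sigma^2))`` on planar node
    distances.  Nodes whose kernel mass underflows keep their previous
    value.  Fully deterministic given data, grid, params and seed.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("training data must be finite; impute first")
    params = params or SomParams()
    try:
        M = linear_init(X, grid, seed=params.seed).M.copy()
    except ValueError:  # collapsed data: every prototype starts at the one row
        M = np.tile(X[0], (grid.n_nodes, 1)).astype(float)
    D2 = grid.planar_distances() ** 2
    n_nodes, n_vars = grid.n_nodes, X.shape[1]
    for sigma in params.schedule(grid):
        bmu = _bmu_only(X, M)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        S = np.empty((n_nodes, n_vars))
        for j in range(n_vars):
            S[:, j] = np.bincount(bmu, weights=X[:, j], minlength=n_nodes)
        H = np.exp(-D2 / (2.0 * sigma**2))
        num = H @ S
        den = H @ counts
        ok = den > 1e-300
        if not ok.all():
            logger.warning("%d node(s) received no kernel mass; kept previous values", (~ok).sum())
        M[ok] = num[ok] / den[ok, None]
    codebook = Codebook(M, variable_names=variable_names, scale="autoscaled")
    model = SomModel(grid=grid, codebook=codebook, params=params)
    model.quality = quality_metrics(model, X)
    return model


def assign_bmu(codebook: Codebook | np.ndarray, X: np.ndarray) -> BmuAssignment:
    """Exact nearest-node assignment (Euclidean), ties to the lowest index."""
    M = codebook.M if isinstance(codebook, Codebook) else np.asarray(codebook, float)
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains NaN; impute before BMU assignment")
    if X.shape[1] != M.shape[1]:
        raise ValueError("column count mismatch between data and codebook")
    D = cdist(X, M)
    bmu = D.argmin(axis=1)
    rows = np.arange(X.shape[0])
    qe = D[rows, bmu].copy()
    D[rows, bmu] = np.inf
    second = D.argmin(axis=1)
    return BmuAssignment(bmu_index=bmu, second_bmu=second, qe_sample=qe)


def quality_metrics(model: SomModel, X: np.ndarray) -> QualityMetrics:
    """Quantization, topographic and distribution-matching errors on ``X``.

    The distribution-matching error is the mean over variables of the
    two-sample Kolmogorov-Smirnov distance between the data values and the
    BMU-mapped codebook values (codebook values weighted by BMU occupancy).
    """
    assignment = assign_bmu(model.codebook, X)
    qe = float(assignment.qe_sample.mean())
    adj = model.grid.adjacency()
    te = float(np.mean(~adj[assignment.bmu_index, assignment.second_bmu]))
    mapped = model.codebook.M[assignment.bmu_index]
    X = np.asarray(X, dtype=float)
    dme = float(
        np.mean([ks_2samp(X[:, j], mapped[:, j]).statistic for j in range(X.shape[1])])
    )
    return QualityMetrics(qe=qe, te=te, dme=dme)


def u_matrix(model: SomModel) -> np.ndarray:
    """Mean Euclidean codebook distance from each node to its hex neighbours."""
    adj = model.grid.adjacency()
    M = model.codebook.M
    D = cdist(M, M)
    out = np.empty(model.grid.n_nodes)
    for i in range(model.grid.n_nodes):
        out[i] = D[i, adj[i]].mean()
    return out


def detect_qe_outliers(assignment: BmuAssignment | np.ndarray, k: float = 1.5) -> np.ndarray:
    """Flag samples with ``qe > Q3 + k * IQR`` of the QE distribution."""
    qe = assignment.qe_sample if isinstance(assignment, BmuAssignment) else np.asarray(assignment)
    if qe.size < 4:
        raise ValueError("need at least 4 samples to define quartiles")
    q1, q3 = np.percentile(qe, [25, 75])
    return qe > q3 + k * (q3 - q1)


def select_best_model(models, qe_slack: float = 0.05) -> int:
    """Pick a model among candidates: lowest topographic error among those
    within ``qe_slack`` of the minimal quantization error; ties broken by
    distribution-matching error, then by candidate order."""
    quals = [m.quality for m in models]
    if any(q is None for q in quals):
        raise ValueError("all candidate models must carry quality metrics")
    qe_min = min(q.qe for q in quals)
    best, best_key = None, None
    for i, q in enumerate(quals):
        if q.qe > qe_min * (1.0 + qe_slack):
            continue
        key = (q.te, q.dme, i)
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best


# -- persistence ----------------------------------------------------------


def save_model(model: SomModel, directory) -> None:
    """Write codebook.csv plus a meta.json sidecar into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    grid = model.grid
    rows, cols = np.divmod(np.arange(grid.n_nodes), grid.xdim)
    df = pd.DataFrame({"node": np.arange(grid.n_nodes), "col": cols, "row": rows})
    for j, name in enumerate(model.codebook.variable_names):
        df[name] = model.codebook.M[:, j]
    df.to_csv(os.path.join(directory, "codebook.csv"), index=False)
    meta = {
        "xdim": grid.xdim,
        "ydim": grid.ydim,
        "topology": grid.topology,
        "scale": model.codebook.scale,
        "variable_names": list(model.codebook.variable_names),
        "params": {
            "epochs": model.params.epochs,
            "radius_start": model.params.radius_start,
            "radius_end": model.params.radius_end,
            "seed": model.params.seed,
        },
        "quality": None
        if model.quality is None
        else {"qe": model.quality.qe, "te": model.quality.te, "dme": model.quality.dme},
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(directory) -> SomModel:
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(os.path.join(directory, "codebook.csv"))
    grid = GridSpec(xdim=meta["xdim"], ydim=meta["ydim"], topology=meta["topology"])
    names = tuple(meta["variable_names"])
    M = df[list(names)].to_numpy(float)
    codebook = Codebook(M, variable_names=names, scale=meta["scale"])
    params = SomParams(**meta["params"])
    quality = QualityMetrics(**meta["quality"]) if meta["quality"] else None
    return SomModel(grid=grid, codebook=codebook, params=params, quality=quality)
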