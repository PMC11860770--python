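"""Uncertainty-weighted positive matrix factorization of the SOM codebook.

Minimises ``Q = sum_ij ((x_ij - (GF)_ij) / u_ij)^2`` over nonnegative
``G`` (node contributions) and ``F`` (factor profiles) with multiplicative
updates, from multiple random starts.  Includes the factor-count scan,
row-resampling bootstrap validation with correlation-based factor mapping,
species percentage fingerprints and per-factor top-node sets.

The codebook must be on the concentration scale (inverse-autoscaled) before
entering this module; :func:`concentration_codebook` performs that step and
clips residual negatives at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ScalingModel, inverse_autoscale
from .som import Codebook

__all__ = [
    "UncertaintyModel",
    "PmfSolution",
    "BootstrapReport",
    "FactorScan",
    "DEFAULT_RELATIVE_UNCERTAINTY",
    "build_uncertainties",
    "concentration_codebook",
    "fit_pmf",
    "q_expected",
    "select_factor_count",
    "bootstrap_pmf",
    "species_percent_profile",
    "top_nodes_per_factor",
    "factor_cluster_crosstab",
    "match_factors",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12

#: Relative measurement uncertainty per pollutant (fractions).
DEFAULT_RELATIVE_UNCERTAINTY = {
    "Ben": 0.109,
    "Tol": 0.109,
    "PM10": 0.10,
    "NO": 0.062,
    "NO2": 0.062,
}


@dataclass(frozen=True)
class UncertaintyModel:
    """Per-variable relative uncertainty and absolute floor."""

    rel: np.ndarray
    floor: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rel", np.asarray(self.rel, dtype=float))
        object.__setattr__(self, "floor", np.asarray(self.floor, dtype=float))
        if np.any(self.rel <= 0):
            raise ValueError("relative uncertainties must be > 0")
        if np.any(self.floor < 0):
            raise ValueError("uncertainty floors must be >= 0")

    @classmethod
    def from_data(
        cls,
        X: np.ndarray,
        rel=None,
        variable_names=None,
        floor_fraction: float = 0.1,
    ) -> "UncertaintyModel":
        """Default model: tabulated relative uncertainties plus a floor of
        ``floor_fraction`` times each variable's 5th percentile (of positive
        values), so zeros never produce zero uncertainty."""
        X = np.asarray(X, dtype=float)
        m = X.shape[1]
        if rel is None:
            if variable_names is None:
                raise ValueError("need rel or variable_names")
            rel = np.array([DEFAULT_RELATIVE_UNCERTAINTY[v] for v in variable_names])
        rel = np.asarray(rel, dtype=float)
        floor = np.empty(m)
        for j in range(m):
            pos = X[:, j][X[:, j] > 0]
            p5 = np.percentile(pos, 5) if pos.size else 1.0
            floor[j] = max(floor_fraction * p5, 1e-6)
        return cls(rel=rel, floor=floor)


def build_uncertainties(X: np.ndarray, model: UncertaintyModel) -> np.ndarray:
    """``u_ij = max(rel_j * x_ij, floor_j)``, strictly positive everywhere."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError(
            "X has negative entries; PMF needs concentration-scale data "
            "(apply inverse_autoscale / concentration_codebook first)"
        )
    if X.shape[1] != model.rel.shape[0]:
        raise ValueError("dimension mismatch between X and uncertainty model")
    U = np.maximum(model.rel * X, model.floor)
    if np.any(U <= 0):
        raise ValueError("uncertainty matrix has zeros; use positive floors")
    return U


def concentration_codebook(codebook: Codebook, scaling: ScalingModel) -> Codebook:
    """Inverse-autoscale a codebook to concentration units, clipping any
    residual negative value at zero (count is logged)."""
    if codebook.scale == "concentration":
        return codebook
    M = inverse_autoscale(codebook.M, scaling)
    n_neg = int(np.sum(M < 0))
    if n_neg:
        logger.info("clipped %d negative codebook value(s) to 0 before PMF", n_neg)
        M = np.clip(M, 0.0, None)
    return Codebook(M, variable_names=codebook.variable_names, scale="concentration")


@dataclass(eq=False)
class PmfSolution:
    G: np.ndarray  # (n, k) nonnegative contributions
    F: np.ndarray  # (k, m) nonnegative profiles, rows unit-sum
    Q: float
    Q_expected: float  # NaN when the formula is nonpositive
    scaled_residuals: np.ndarray
    n_starts: int
    seed: int
    converged: bool
    q_trace: np.ndarray = field(default=None)  # Q per iteration of best run

    @property
    def k(self) -> int:
        return self.F.shape[0]

    @property
    def q_ratio(self) -> float:
        return float(self.Q / self.Q_expected) if np.isfinite(self.Q_expected) else np.nan


def q_expected(n_nodes: int, n_variables: int, k: int) -> int:
    """Degrees-of-freedom reference ``n*m - k*(n + m)``; errors when <= 0."""
    value = n_nodes * n_variables - k * (n_nodes + n_variables)
    if value <= 0:
        raise ValueError(
            f"Q_expected = {value} <= 0: k={k} overparameterizes a "
            f"{n_nodes}x{n_variables} matrix"
        )
    return int(value)


def _q_value(X, U, G, F) -> float:
    return float(np.sum(((X - G @ F) / U) ** 2))


def _run_updates(X, W, G, F, tol, max_iter, g_warmup: int = 0):
    """Weighted multiplicative updates; returns (G, F, q_trace, converged).

    ``g_warmup`` iterations update only G first, so that an informative F
    initialisation is not destroyed while G is still random.  Every step is
    a monotone (Q non-increasing) multiplicative update.
    """
    WX = W * X
    for _ in range(int(g_warmup)):
        GF = G @ F
        G = G * ((WX @ F.T) / np.maximum((W * GF) @ F.T, _EPS))
    q_prev = _q_value(X, 1.0 / np.sqrt(W), G, F)
    trace = [q_prev]
    converged = False
    for _ in range(int(max_iter)):
        GF = G @ F
        G = G * ((WX @ F.T) / np.maximum((W * GF) @ F.T, _EPS))
        GF = G @ F
        F = F * ((G.T @ WX) / np.maximum(G.T @ (W * GF), _EPS))
        q = _q_value(X, 1.0 / np.sqrt(W), G, F)
        trace.append(q)
        if q_prev > 0 and abs(q_prev - q) / q_prev < tol:
            converged = True
            break
        q_prev = q
    return G, F, np.asarray(trace), converged


def _extreme_rows(X: np.ndarray, k: int) -> np.ndarray:
    """Successive-projection pick of ``k`` extreme data rows (cone vertices)."""
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    R = X / np.maximum(norms, _EPS)
    residual = R.copy()
    idx = []
    for _ in range(k):
        i = int(np.argmax(np.linalg.norm(residual, axis=1)))
        idx.append(i)
        v = residual[i]
        nv = np.linalg.norm(v)
        if nv <= _EPS:
            break
        v = v / nv
        residual = residual - np.outer(residual @ v, v)
    while len(idx) < k:  # degenerate data: pad with repeats
        idx.append(idx[-1] if idx else 0)
    return np.asarray(idx)


def _normalize(G, F):
    """Scale F rows to unit sum (G columns absorb the magnitude)."""
    s = F.sum(axis=1)
    ok = s > 0
    F = F.copy()
    G = G.copy()
    F[ok] = F[ok] / s[ok, None]
    G[:, ok] = G[:, ok] * s[ok]
    return G, F


def fit_pmf(
    X: np.ndarray,
    U: np.ndarray,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
    g_warmup: int = 200,
) -> PmfSolution:
    """Fit nonnegative ``X ~ G F`` weighted by ``1/U^2``; keep the lowest-Q
    run among ``n_starts`` initialisations.

    The first start seeds the profiles with extreme data rows (successive
    projection), the remaining starts with randomly drawn data rows; G is
    warmed up before alternating so informative profile starts survive.
    When several starts tie on Q (which happens whenever ``k >= n_variables``
    makes the exact fit non-unique) the earliest — most anchored — start is
    kept.  ``Q`` is non-increasing across iterations within each run and
    everything is deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    if np.any(U <= 0):
        raise ValueError("U must be strictly positive")
    n, m = X.shape
    # k may exceed the variable count (overcomplete scan); it cannot exceed rows
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    W = 1.0 / U**2
    children = np.random.SeedSequence(seed).spawn(n_starts)
    best = None
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        if s == 0:
            F0 = np.maximum(X[_extreme_rows(X, k)], _EPS)
        else:
            F0 = np.maximum(X[rng.integers(0, n, size=k)], _EPS)
            F0 = F0 * rng.uniform(0.8, 1.2, size=F0.shape)
        G0 = rng.uniform(0.1, 1.0, size=(n, k))
        G0 *= X.mean() / max((G0 @ F0).mean(), _EPS)
        G, F, trace, converged = _run_updates(X, W, G0, F0, tol, max_iter, g_warmup=g_warmup)
        q = trace[-1]
        if best is None or q < best[2] * (1.0 - 1e-6):
            best = (G, F, q, trace, converged)
    G, F, q, trace, converged = best
    if not converged:
        logger.warning("best PMF run did not converge within %d iterations", max_iter)
    G, F = _normalize(G, F)
    try:
        qexp = float(q_expected(n, m, k))
    except ValueError:
        qexp = np.nan
    return PmfSolution(
        G=G,
        F=F,
        Q=_q_value(X, U, G, F),
        Q_expected=qexp,
        scaled_residuals=(X - G @ F) / U,
        n_starts=n_starts,
        seed=seed,
        converged=converged,
        q_trace=trace,
    )


@dataclass(eq=False)
class BootstrapReport:
    n_boot: int  # completed replicates
    n_skipped: int
    mapping_counts: np.ndarray  # per base factor
    unmapped: int
    iqr_coverage: np.ndarray  # per base factor, fraction of species in IQR

    @property
    def mapping_fraction(self) -> np.ndarray:
        return np.minimum(self.mapping_counts / max(self.n_boot, 1), 1.0)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def bootstrap_pmf(
    X: np.ndarray,
    U: np.ndarray,
    base: PmfSolution,
    n_boot: int = 100,
    r_threshold: float = 0.6,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 1000,
    coverage_tol: float = 0.01,
) -> BootstrapReport:
    """Row-resampling bootstrap with correlation-based factor mapping.

    Each replicate resamples nodes with replacement, refits from the base
    solution as initialisation, then maps every bootstrap factor to the base
    factor whose contributions (over the resampled rows) correlate best,
    provided ``r >= r_threshold``; otherwise the factor counts as unmapped.
    Also tallies, per base factor, the fraction of species whose base profile
    value falls inside the bootstrap interquartile range (widened by
    ``coverage_tol`` on the unit-sum profile scale, so that a degenerately
    tight bootstrap distribution does not reject equal-within-noise values).
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    k = base.k
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    mapping_counts = np.zeros(k, dtype=int)
    unmapped = 0
    n_skipped = 0
    mapped_profiles: list[list[np.ndarray]] = [[] for _ in range(k)]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, Ub = X[idx], U[idx]
        if np.any(np.ptp(Xb, axis=0) == 0):
            n_skipped += 1
            logger.info("skipping degenerate bootstrap resample (constant column)")
            continue
        W = 1.0 / Ub**2
        G0 = np.maximum(base.G[idx], _EPS)
        F0 = np.maximum(base.F, _EPS)
        Gb, Fb, _, _ = _run_updates(Xb, W, G0, F0, tol, max_iter)
        Gb, Fb = _normalize(Gb, Fb)
        Gbase = base.G[idx]
        for f in range(k):
            rs = np.array([_safe_corr(Gb[:, f], Gbase[:, j]) for j in range(k)])
            jbest = int(np.argmax(rs))
            if rs[jbest] >= r_threshold:
                mapping_counts[jbest] += 1
                mapped_profiles[jbest].append(Fb[f])
            else:
                unmapped += 1
    completed = n_boot - n_skipped
    coverage = np.full(k, np.nan)
    for j in range(k):
        if mapped_profiles[j]:
            P = np.stack(mapped_profiles[j])
            q25 = np.percentile(P, 25, axis=0) - coverage_tol
            q75 = np.percentile(P, 75, axis=0) + coverage_tol
            coverage[j] = float(np.mean((base.F[j] >= q25) & (base.F[j] <= q75)))
    return BootstrapReport(
        n_boot=completed,
        n_skipped=n_skipped,
        mapping_counts=mapping_counts,
        unmapped=unmapped,
        iqr_coverage=coverage,
    )


@dataclass(eq=False)
class FactorScan:
    table: pd.DataFrame
    chosen_k: int
    solutions: dict
    reports: dict


def select_factor_count(
    X: np.ndarray,
    U: np.ndarray,
    kmin: int,
    kmax: int,
    n_starts: int = 20,
    seed: int = 0,
    n_boot: int = 50,
    r_threshold: float = 0.6,
    stability_threshold: float = 0.8,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FactorScan:
    """Scan factor counts and choose the best-supported k.

    For every k in the range the scan records Q, ``Q/Q_expected`` where the
    degrees-of-freedom formula is positive (with as few variables as factors
    it is not, so the ratio alone cannot carry the decision), and bootstrap
    stability (worst per-factor mapping fraction).  The chosen k is the one
    with the largest *relative drop in Q* over the previous factor count —
    the point where adding a factor still buys a qualitative improvement in
    fit — restricted to candidates whose factors are all mapped in at least
    ``stability_threshold`` of the bootstrap replicates (ties to the
    smaller k; if no candidate is stable, all compete).  The full table is
    returned for audit.
    """
    if kmin > kmax:
        raise ValueError("kmin must be <= kmax")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    q_null = float(np.sum((X / U) ** 2))  # Q of the empty (k=0) model
    q_floor = 1e-10 * max(q_null, 1.0)
    # baseline fit below the scan so the first candidate also has a drop
    if kmin >= 2:
        base_sol = fit_pmf(X, U, kmin - 1, n_starts=n_starts, seed=seed, tol=tol,
                           max_iter=max_iter)
        q_prev = base_sol.Q
    else:
        q_prev = q_null
    rows = []
    solutions, reports = {}, {}
    for k in range(kmin, kmax + 1):
        sol = fit_pmf(X, U, k, n_starts=n_starts, seed=seed, tol=tol, max_iter=max_iter)
        rep = bootstrap_pmf(
            X, U, sol, n_boot=n_boot, r_threshold=r_threshold, seed=seed + 1000 + k
        )
        solutions[k], reports[k] = sol, rep
        min_map = float(rep.mapping_fraction.min())
        q_drop = float(np.log(max(q_prev, q_floor) / max(sol.Q, q_floor)))
        rows.append(
            {
                "k": k,
                "Q": sol.Q,
                "Q_expected": sol.Q_expected,
                "Q_ratio": sol.q_ratio,
                "q_drop": q_drop,
                "min_mapping": min_map,
                "unmapped": rep.unmapped,
                "stable": min_map >= stability_threshold,
            }
        )
        q_prev = sol.Q
    table = pd.DataFrame(rows)
    pool = table.loc[table["stable"]] if table["stable"].any() else table
    chosen = int(pool.loc[pool["q_drop"].idxmax(), "k"])  # idxmax ties -> first
    return FactorScan(table=table, chosen_k=chosen, solutions=solutions, reports=reports)


def species_percent_profile(solution: PmfSolution) -> np.ndarray:
    """Percent of each variable's attributed mass per factor (columns sum to
    100).  Variables with zero attributed mass come back as NaN."""
    g = solution.G.sum(axis=0)  # total contribution per factor
    mass = g[:, None] * solution.F  # (k, m) attributed mass
    total = mass.sum(axis=0)
    out = np.full_like(mass, np.nan)
    ok = total > 0
    out[:, ok] = 100.0 * mass[:, ok] / total[ok]
    return out


def top_nodes_per_factor(solution: PmfSolution, q: float = 0.9) -> list:
    """Per factor, the nodes whose normalized contribution share exceeds the
    ``q``-quantile of that factor's shares."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    G = solution.G
    totals = G.sum(axis=1)
    shares = np.divide(G, totals[:, None], out=np.zeros_like(G), where=totals[:, None] > 0)
    sets = []
    for f in range(solution.k):
        cut = np.quantile(shares[:, f], q)
        sets.append(np.flatnonzero(shares[:, f] > cut))
    return sets


def factor_cluster_crosstab(
    solution: PmfSolution, labels: np.ndarray, q: float = 0.9, normalize: bool = False
) -> pd.DataFrame:
    """Distribution of each factor's top-node set across clusters.

    Rows are factors, columns cluster ids; counts by default, row
    percentages with ``normalize=True``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != solution.G.shape[0]:
        raise ValueError("labels must be aligned to codebook node order")
    ids = sorted(np.unique(labels).tolist())
    sets = top_nodes_per_factor(solution, q=q)
    counts = np.zeros((solution.k, len(ids)), dtype=float)
    for f, nodes in enumerate(sets):
        for j, c in enumerate(ids):
            counts[f, j] = np.sum(labels[nodes] == c)
    df = pd.DataFrame(counts, index=[f"factor_{f + 1}" for f in range(solution.k)], columns=ids)
    if normalize:
        sums = df.sum(axis=1)
        df = df.div(sums.where(sums > 0, 1.0), axis=0) * 100.0
    return df


def match_factors(F_est: np.ndarray, F_ref: np.ndarray) -> np.ndarray:
    """Optimal row matching between two profile matrices by cosine
    similarity (Hungarian assignment).  Returns ``perm`` such that
    ``F_est[perm[i]]`` corresponds to ``F_ref[i]``."""
    from scipy.optimize import linear_sum_assignment

    def unit(A):
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        return A / np.maximum(norms, _EPS)

    sim = unit(F_ref) @ unit(F_est).T
    _, cols = linear_sum_assignment(-sim)
    return cols
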