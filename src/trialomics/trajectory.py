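"""Principal-curve pseudotime and GLM trajectory-association testing.

Cells are embedded in a low-dimensional space (e.g., batch-corrected
components of antibody-derived-tag profiles); a principal curve — a
smooth one-dimensional curve minimizing total squared orthogonal
distance to the points — is fit by the Hastie–Stuetzle alternation of
(i) smoothing each coordinate against the current arc-length parameter
with a cubic smoothing spline (penalty by generalized cross-validation)
and (ii) re-projecting every cell to its nearest point on the
discretized curve. No start or end cell needs to be nominated; the
orientation of the resulting pseudotime is arbitrary unless anchored.

Genes are then tested for association with pseudotime by a Gaussian
identity-link GLM (ordinary least squares) on the z-scored gene, with
processing vendor as a batch covariate; response-group or timepoint
dependence is tested through a pseudotime x group interaction.
Family-wise error is controlled by Bonferroni (adjusted-p cutoff 0.10)
combined with a coefficient-magnitude gate: |coef| > 1 for trajectory
association, |coef| > 0.25 for group/timepoint dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline


class TestMode(str, Enum):
    TRAJECTORY = "TRAJECTORY"
    GROUP = "GROUP"
    TIMEPOINT = "TIMEPOINT"


@dataclass
class TrajectoryTestConfig:
    adjusted_p_cutoff: float = 0.10
    coef_cutoff_trajectory: float = 1.0
    coef_cutoff_group: float = 0.25
    covariates: tuple[str, ...] = ("vendor",)
    interaction: bool = True  # test pseudotime x group interaction (vs group main effect)


@dataclass
class PseudotimeFit:
    pseudotime: np.ndarray  # per cell, scaled to [0, 1]
    curve_points: np.ndarray  # n_grid x d sample points of the fitted curve
    iterations: int
    converged: bool
    total_sq_distance: float
    distance_history: list[float] = field(default_factory=list)
    orientation_flipped: bool = False


@dataclass
class GeneTrajectoryTest:
    gene: str
    mode: TestMode
    coefficient: float
    raw_p: float
    adjusted_p: float
    significant: bool
    testable: bool = True
    std_error: float = float("nan")


def scale_center(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise standardization to mean 0, sd 1 (ddof 0); constant
    columns are dropped with a warning."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s)", stacklevel=2)
    Xk = X[:, keep]
    return (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)


def _project_to_polyline(X: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project each row of X onto the polyline with vertices P.

    Returns (arc-length position, squared distance) per point; the
    projection considers every segment, not just nearest vertices.
    """
    seg = P[1:] - P[:-1]  # (m-1, d)
    seg_len2 = (seg**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    cum = np.concatenate(([0.0], np.cumsum(seg_len)))
    # t[i, j]: position of point i along segment j, clipped to [0, 1]
    diff = X[:, None, :] - P[None, :-1, :]  # (n, m-1, d)
    t = np.clip((diff * seg[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = P[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(X.shape[0])
    lam = cum[best] + t[rows, best] * seg_len[best]
    return lam, d2[rows, best]


def _fit_spline(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """GCV smoothing spline with a fixed mild-penalty fallback when the
    GCV search is ill-conditioned."""
    try:
        return make_smoothing_spline(x, y, w=w)
    except (ValueError, np.linalg.LinAlgError):
        span = float(x[-1] - x[0])
        return make_smoothing_spline(x, y, w=w, lam=1e-3 * span**3)


def _smooth_coords(
    lam: np.ndarray, X: np.ndarray, n_grid: int, max_knots: int = 250
) -> np.ndarray:
    """Fit a GCV smoothing spline of each coordinate against lam and
    evaluate on an even grid over the lam range.

    Duplicate lam values are merged and, beyond `max_knots` distinct
    positions, the axis is aggregated into equal-count bins (weighted by
    bin occupancy) — this conditions the GCV problem and bounds cost.
    """
    order = np.argsort(lam, kind="mergesort")
    lam_s = lam[order]
    uniq, inv, counts = np.unique(lam_s, return_inverse=True, return_counts=True)
    if uniq.size > max_knots:
        edges = np.quantile(lam_s, np.linspace(0, 1, max_knots + 1))
        inv = np.clip(np.searchsorted(edges, lam_s, side="right") - 1, 0, max_knots - 1)
        counts = np.bincount(inv, minlength=max_knots)
        keep = counts > 0
        uniq = (np.bincount(inv, weights=lam_s, minlength=max_knots) / np.where(counts, counts, 1))[keep]
        counts_kept = counts[keep]
        remap = np.cumsum(keep) - 1
        inv = remap[inv]
        counts = counts_kept
    grid = np.linspace(lam.min(), lam.max(), n_grid)
    curve = np.empty((n_grid, X.shape[1]))
    for d in range(X.shape[1]):
        y = np.bincount(inv, weights=X[order, d]) / counts
        if uniq.size >= 4:
            spl = _fit_spline(uniq, y, counts.astype(float))
            curve[:, d] = spl(grid)
        else:  # too few distinct positions for a cubic spline: linear fit
            coef = np.polyfit(uniq, y, 1)
            curve[:, d] = np.polyval(coef, grid)
    return curve


def fit_principal_curve(
    embedding: np.ndarray | pd.DataFrame,
    max_iter: int = 1000,
    tol: float = 1e-4,
    n_grid: int = 200,
    anchor: np.ndarray | None = None,
) -> PseudotimeFit:
    """Hastie–Stuetzle principal curve; returns arc-length pseudotime
    scaled to [0, 1].

    Initialization is the projection onto the first principal component.
    Each iteration smooths coordinates against the current parameter
    (cubic smoothing spline, GCV penalty) and re-projects points onto
    the discretized curve; it stops when the relative change in total
    squared orthogonal distance falls below `tol`, when an iteration
    fails to improve it (the previous curve is kept), or at `max_iter`.
    The recorded distance history is therefore non-increasing.

    `anchor`: optional per-cell score expected to *decrease* along the
    curve start->end is not assumed; if given, pseudotime is flipped so
    the anchor correlates positively with it.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("embedding must be cells x d with d >= 2")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells")
    if not np.isfinite(X).all():
        raise ValueError("embedding contains non-finite values")
    mean_ = X.mean(axis=0)
    Xc = X - mean_
    if np.allclose(Xc, 0):
        raise ValueError("degenerate embedding (all points identical)")
    # work in the PCA basis: per-coordinate smoothing then depends on the
    # data only through rotation-invariant quantities, so a rigid rotation
    # of the embedding cannot change the fitted pseudotime
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    X = Xc @ Vt.T
    lam = X[:, 0]
    prev_dist = np.inf
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    history: list[float] = []
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        curve = _smooth_coords(lam, X, n_grid)
        new_lam, d2 = _project_to_polyline(X, curve)
        dist = float(d2.sum())
        if dist > prev_dist:  # smoothing step degraded the fit: keep previous
            converged = True
            iterations = it - 1
            break
        history.append(dist)
        best = (new_lam, curve, dist)
        if prev_dist - dist <= tol * max(prev_dist, 1e-300) and np.isfinite(prev_dist):
            converged = True
            lam = new_lam
            break
        lam, prev_dist = new_lam, dist
    assert best is not None
    lam, curve, dist = best
    curve = curve @ Vt + mean_  # back to input coordinates
    rng_ = lam.max() - lam.min()
    pseudotime = (lam - lam.min()) / rng_ if rng_ > 0 else np.zeros_like(lam)
    flipped = False
    if anchor is not None:
        r = np.corrcoef(np.asarray(anchor, dtype=float), pseudotime)[0, 1]
        if r < 0:
            pseudotime = 1.0 - pseudotime
            flipped = True
    return PseudotimeFit(
        pseudotime=pseudotime,
        curve_points=curve,
        iterations=iterations,
        converged=converged,
        total_sq_distance=dist,
        distance_history=history,
        orientation_flipped=flipped,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS with t-reference p-values: returns (coef, se, p)."""
    n, k = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise ValueError("collinear design matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - k
    sigma2 = (resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = coef / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    return coef, se, p


def _design(
    pseudotime: np.ndarray,
    meta: pd.DataFrame | None,
    cfg: TrajectoryTestConfig,
    mode: TestMode,
) -> tuple[np.ndarray, int, list[str]]:
    """Build the design matrix; returns (X, index of tested column, names)."""
    n = len(pseudotime)
    cols = [np.ones(n), pseudotime]
    names = ["intercept", "pseudotime"]
    if meta is not None:
        for cov in cfg.covariates:
            if cov in meta.columns:
                levels = sorted(meta[cov].astype(str).unique())
                for lv in levels[1:]:
                    cols.append((meta[cov].astype(str) == lv).to_numpy(float))
                    names.append(f"{cov}[{lv}]")
    test_idx = 1
    if mode is not TestMode.TRAJECTORY:
        col = "response" if mode is TestMode.GROUP else "timepoint"
        if meta is None or col not in meta.columns:
            raise ValueError(f"mode {mode.value} needs metadata column {col!r}")
        levels = sorted(meta[col].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"column {col!r} must have exactly 2 levels")
        g = (meta[col].astype(str) == levels[1]).to_numpy(float)
        cols.append(g)
        names.append(f"{col}[{levels[1]}]")
        if cfg.interaction:
            cols.append(g * pseudotime)
            names.append(f"pseudotime:{col}[{levels[1]}]")
        test_idx = len(cols) - 1
    return np.column_stack(cols), test_idx, names


def glm_trajectory_association(
    expression: np.ndarray | pd.Series,
    fit: PseudotimeFit | np.ndarray,
    meta: pd.DataFrame | None = None,
    cfg: TrajectoryTestConfig | None = None,
    mode: TestMode = TestMode.TRAJECTORY,
    gene: str = "",
    n_tests: int = 1,
) -> GeneTrajectoryTest:
    """Test one gene's association with the trajectory (or its group/
    timepoint dependence) by a Gaussian identity-link GLM.

    The gene is z-scored across cells before fitting, so the coefficient
    cutoffs apply on the standardized scale. The Bonferroni-adjusted p
    uses `n_tests` as the family size.
    """
    cfg = cfg or TrajectoryTestConfig()
    pt = fit.pseudotime if isinstance(fit, PseudotimeFit) else np.asarray(fit, float)
    y = np.asarray(expression, dtype=float)
    if y.shape != pt.shape:
        raise ValueError("expression length must equal number of cells")
    sd = y.std(ddof=1)  # sample sd, matching the usual scale() convention
    if sd == 0:
        return GeneTrajectoryTest(
            gene=gene, mode=mode, coefficient=np.nan, raw_p=np.nan,
            adjusted_p=np.nan, significant=False, testable=False,
        )
    z = (y - y.mean()) / sd
    X, test_idx, _ = _design(pt, meta, cfg, mode)
    coef, se, p = _ols(X, z)
    raw_p = float(p[test_idx])
    adj_p = min(1.0, n_tests * raw_p)
    cutoff = (
        cfg.coef_cutoff_trajectory if mode is TestMode.TRAJECTORY else cfg.coef_cutoff_group
    )
    sig = adj_p <= cfg.adjusted_p_cutoff and abs(coef[test_idx]) > cutoff
    return GeneTrajectoryTest(
        gene=gene,
        mode=mode,
        coefficient=float(coef[test_idx]),
        raw_p=raw_p,
        adjusted_p=adj_p,
        significant=bool(sig),
        std_error=float(se[test_idx]),
    )


def run_gene_tests(
    genes: pd.DataFrame,
    fit: PseudotimeFit,
    meta: pd.DataFrame | None = None,
    cfg: TrajectoryTestConfig | None = None,
    mode: TestMode = TestMode.TRAJECTORY,
) -> pd.DataFrame:
    """Run glm_trajectory_association for every column of a cells x genes
    frame; Bonferroni family size = number of testable genes."""
    cfg = cfg or TrajectoryTestConfig()
    m = int((genes.std(axis=0, ddof=0) > 0).sum())
    rows = []
    for gene in genes.columns:
        r = glm_trajectory_association(
            genes[gene].to_numpy(), fit, meta, cfg, mode, gene=str(gene), n_tests=max(m, 1)
        )
        rows.append(
            {
                "gene": r.gene,
                "mode": r.mode.value,
                "coefficient": r.coefficient,
                "p": r.raw_p,
                "p_adj": r.adjusted_p,
                "significant": r.significant,
                "testable": r.testable,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni: p_adj = min(1, m * p) with m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def density_trend(
    fit: PseudotimeFit,
    strata: pd.Series | np.ndarray,
    n_grid: int = 256,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Gaussian kernel density of pseudotime per stratum on a [0, 1] grid.

    Bandwidth by Silverman's rule; each curve is renormalized so its
    trapezoid integral over the grid is 1. Strata below `min_cells` are
    suppressed with a warning.
    """
    strata = pd.Series(np.asarray(strata), name="stratum")
    grid = np.linspace(0.0, 1.0, n_grid)
    out = {}
    for label, idx in strata.groupby(strata).groups.items():
        pt = fit.pseudotime[np.asarray(idx, dtype=int)]
        if pt.size < min_cells:
            warnings.warn(f"stratum {label!r}: fewer than {min_cells} cells; suppressed",
                          stacklevel=2)
            continue
        if pt.std() < 1e-9:  # point mass: narrow grid-resolvable peak at the location
            dens = stats.norm.pdf(grid, loc=pt[0], scale=2.0 / (n_grid - 1))
        else:
            kde = stats.gaussian_kde(pt, bw_method="silverman")
            dens = kde(grid)
        dens = dens / np.trapezoid(dens, grid)
        out[label] = dens
    df = pd.DataFrame(out, index=grid)
    df.index.name = "pseudotime"
    return df


def signature_along_trajectory(
    scores: np.ndarray | pd.Series, fit: PseudotimeFit, n_grid: int = 100
) -> pd.DataFrame:
    """Smoothing-spline fit of a per-cell signature score against
    pseudotime, evaluated on an even grid."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    grid = np.linspace(0.0, 1.0, n_grid)
    pt = fit.pseudotime
    if np.ptp(s) == 0 or np.ptp(pt) == 0:
        vals = np.full(n_grid, s.mean())
    else:
        curve = _smooth_coords(pt, s[:, None], n_grid)
        vals = curve[:, 0]
    return pd.DataFrame({"pseudotime": grid, "signature": vals})
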