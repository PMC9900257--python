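"""Position-wise pathogenicity-score profiles: heat-strip means and a
size-dependent smoothed curve with a 95% confidence band.

Every amino-acid position carries several score values (one per possible
missense substitution), so the profile is built two ways at once:

* a *heat-strip*: the arithmetic mean of the values at each position, with
  gaps where no data exist;
* a smoothed conditional-mean curve fitted over the duplicated
  (position, value) points.  With >= 1000 points a penalized cubic
  regression spline with shrinkage (smoothing parameter by GCV) is used;
  below that, loess (local quadratic regression, tricube weights,
  span 0.75).  The 95% band is fit +/- 1.96 pointwise standard errors.

Both smoothers are linear in the responses, so adding a constant to all
values shifts the curve and band by exactly that constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

GAM_POINT_THRESHOLD = 1000     # >= this many points switches loess -> spline
CI_MULTIPLIER = 1.96           # normal-approximation 95% band


class DegenerateProfileError(ValueError):
    """Too few points (or a single position) to fit a smoothed profile."""


@dataclass
class PositionScoreSet:
    """All (amino-acid position, score value) points of one score."""

    score_name: str
    points: list[tuple[int, float]]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p for p, _ in self.points], dtype=float)
        y = np.array([v for _, v in self.points], dtype=float)
        return x, y


@dataclass
class ScoreProfile:
    """Fitted profile of one score along the protein."""

    score_name: str
    heat_strip: np.ndarray        # per-position means, NaN where no data
    grid: np.ndarray              # integer evaluation positions
    fit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    smoother_used: str            # "loess" | "gam"

    @property
    def protein_length(self) -> int:
        return len(self.heat_strip)

    def to_rows(self) -> list[dict]:
        """Rows for the profile export table."""
        strip = {i + 1: v for i, v in enumerate(self.heat_strip)}
        return [
            {
                "position": int(g),
                "heat_mean": strip.get(int(g), np.nan),
                "fit": float(f), "ci_low": float(lo), "ci_high": float(hi),
                "smoother": self.smoother_used,
            }
            for g, f, lo, hi in zip(self.grid, self.fit, self.ci_low, self.ci_high)
        ]


def heat_strip(ps: PositionScoreSet, protein_length: int) -> np.ndarray:
    """Arithmetic mean of the score values at each amino-acid position.

    Positions with no data are NaN and render as gaps.
    """
    x, y = ps.arrays()
    if np.any((x < 1) | (x > protein_length)):
        raise ValueError("points outside [1, protein_length]")
    sums = np.zeros(protein_length)
    counts = np.zeros(protein_length)
    idx = x.astype(int) - 1
    np.add.at(sums, idx, y)
    np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        strip = sums / counts
    strip[counts == 0] = np.nan
    return strip


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0, 1)
    return (1 - u ** 3) ** 3


def _loess(x, y, grid, span=0.75, degree=2):
    """Local polynomial regression with tricube weights and pointwise SE.

    At each grid point the span-fraction nearest data points are fitted
    with a weighted degree-2 polynomial; the equivalent-kernel row gives
    fit = l.y and var = sigma^2 ||l||^2.  sigma^2 is estimated from the
    residuals at the data points with the trace of the smoother matrix as
    model degrees of freedom.
    """
    n = len(x)
    r = max(degree + 1, int(np.ceil(span * n)))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    def kernel_row(x0):
        d = np.abs(xs - x0)
        cut = np.partition(d, r - 1)[r - 1]
        mask = d <= cut
        xi, di = xs[mask], d[mask]
        dmax = di.max()
        w = np.ones_like(di) if dmax == 0 else _tricube(di / dmax)
        X = np.vander(xi - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        # l = e1' (X'WX)^-1 X'W, solved with a pseudo-inverse for stability
        A = X.T @ WX
        l_local = np.linalg.pinv(A)[0] @ WX.T
        row = np.zeros(n)
        row[mask] = l_local
        return row

    # effective df + residual variance from the fit at the data positions
    unique_x = np.unique(xs)
    trace = 0.0
    resid_fit = np.empty(n)
    for x0 in unique_x:
        row = kernel_row(x0)
        here = xs == x0
        trace += row[here].sum()
        resid_fit[here] = row @ ys
    rss = float(np.sum((ys - resid_fit) ** 2))
    dof = max(n - trace, 1.0)
    sigma2 = rss / dof

    fit = np.empty(len(grid))
    se = np.empty(len(grid))
    for i, g in enumerate(grid):
        row = kernel_row(g)
        fit[i] = row @ ys
        se[i] = np.sqrt(sigma2 * np.sum(row ** 2))
    return fit, se


def _penalized_spline(x, y, grid, k=10, shrinkage=1e-3):
    """Penalized cubic regression spline with shrinkage; GCV picks lambda.

    Cubic B-spline basis with ``k`` functions, second-difference penalty on
    the coefficients plus a small ridge so the penalty null space (the
    linear trend) can also shrink.  Pointwise SE from the Bayesian
    covariance sigma^2 (X'X + lambda*P)^-1.
    """
    n = len(x)
    lo, hi = float(x.min()), float(x.max())
    inner = np.linspace(lo, hi, k - 2)[1:-1]
    knots = np.concatenate([[lo] * 4, inner, [hi] * 4])
    X = BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()

    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D + shrinkage * np.eye(k)

    XtX = X.T @ X
    Xty = X.T @ y
    best = None
    for lam in np.logspace(-3, 7, 30):
        A = XtX + lam * P
        Ainv = np.linalg.inv(A)
        beta = Ainv @ Xty
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(Ainv @ XtX))
        gcv = n * rss / max(n - edf, 1e-8) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, Ainv, rss, edf)
    _, lam, beta, Ainv, rss, edf = best
    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * Ainv

    Xg = BSpline.design_matrix(
        np.clip(np.asarray(grid, float), lo, hi), knots, 3, extrapolate=True
    ).toarray()
    fit = Xg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
    return fit, se


def fit_profile(
    ps: PositionScoreSet,
    protein_length: int | None = None,
    gam_threshold: int = GAM_POINT_THRESHOLD,
    loess_span: float = 0.75,
    loess_degree: int = 2,
    spline_k: int = 10,
) -> ScoreProfile:
    """Fit the size-dependent smoothed profile plus heat-strip for one score.

    The smoother follows the data volume: ``n >= gam_threshold`` uses the
    shrinkage penalized-spline GAM, fewer points use loess.  The grid is
    every integer position in the data's span.

    Raises :class:`DegenerateProfileError` below 10 points or when all
    points sit at one position.
    """
    x, y = ps.arrays()
    n = len(x)
    if n < 10 or len(np.unique(x)) < 2:
        raise DegenerateProfileError(
            f"{ps.score_name}: need >= 10 points over >= 2 positions "
            f"(got n={n}, positions={len(np.unique(x))})")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite score values")

    length = int(protein_length if protein_length is not None else x.max())
    grid = np.arange(int(x.min()), int(x.max()) + 1, dtype=float)

    if n >= gam_threshold:
        fit, se = _penalized_spline(x, y, grid, k=spline_k)
        smoother = "gam"
    else:
        fit, se = _loess(x, y, grid, span=loess_span, degree=loess_degree)
        smoother = "loess"

    return ScoreProfile(
        score_name=ps.score_name,
        heat_strip=heat_strip(ps, length),
        grid=grid,
        fit=fit,
        ci_low=fit - CI_MULTIPLIER * se,
        ci_high=fit + CI_MULTIPLIER * se,
        smoother_used=smoother,
    )


def points_from_variants(variants, scores, score_name: str,
                         consequences=("missense",)) -> PositionScoreSet:
    """Join simulated variants with score records into profile points.

    Only the listed consequence classes contribute (missense by default:
    the scores model substitutions, and truncating classes would distort
    per-position means).
    """
    value_by_key = {}
    for rec in scores:
        v = rec.values.get(score_name)
        if v is not None:
            value_by_key[rec.key] = v
    pts = [
        (v.codon_index, value_by_key[v.key])
        for v in variants
        if v.consequence in consequences and v.key in value_by_key
    ]
    return PositionScoreSet(score_name=score_name, points=pts)
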