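"""REML linear mixed models with a relatedness random effect, and Wald inference.

Model: y = X beta + g + e, with g ~ N(0, sigma_g^2 K) for a genetic
relatedness matrix K and e ~ N(0, sigma_e^2 I). Fitting follows the
spectral approach: eigendecompose K once (K = U S U'), rotate y and X by
U', and profile the restricted likelihood over the heritability ratio
h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) on [0, 1 - 1e-6] by a grid scan
plus bounded scalar refinement, the boundary h2 = 0 included. At the
optimum the GLS estimate beta_hat = (X'V^-1X)^-1 X'V^-1 y and its
covariance (X'V^-1X)^-1 are returned.

Inference is Wald-type throughout: z = estimate / se against a standard
normal, 95% CIs as estimate +/- 1.959964 se, and Holm-Bonferroni step-down
adjustment for families of univariate tests.

For family cohorts K is block-diagonal; :class:`SpectralGRM` accepts the
per-family blocks and eigendecomposes them independently, so cohorts of
many thousands never materialize (or decompose) a dense n x n matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .relatedness import RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralGRM",
    "LMMFit",
    "ContrastResult",
    "GroupMeanResult",
    "fit_lmm",
    "wald_test",
    "group_means",
    "multivariable_fit",
    "holm_bonferroni",
]

Z95 = 1.959964
H2_UPPER = 1.0 - 1e-6
GRM_RIDGE = 1e-6


class SpectralGRM:
    """Eigendecomposition of a relatedness matrix, possibly block-diagonal.

    Stores eigenvalues ``s`` (length n, in row order induced by the blocks)
    and enough structure to rotate vectors/matrices by U' without ever
    forming a dense U when the matrix is block-diagonal by family.
    """

    def __init__(self, s: np.ndarray, blocks: list[tuple[np.ndarray, np.ndarray]], n: int):
        self.s = s
        self._blocks = blocks  # list of (row indices, U_block)
        self.n = n

    @classmethod
    def from_dense(cls, k: np.ndarray) -> "SpectralGRM":
        k = np.asarray(k, dtype=float)
        if np.max(np.abs(k - k.T)) > 1e-8:
            raise ValueError("relatedness matrix must be symmetric")
        s, u = np.linalg.eigh(k)
        s = _ridge_if_needed(s)
        return cls(s, [(np.arange(k.shape[0]), u)], k.shape[0])

    @classmethod
    def from_blocks(cls, blocks: list[tuple[np.ndarray, np.ndarray]], n: int) -> "SpectralGRM":
        s = np.zeros(n)
        decomposed = []
        pos = 0
        order = []
        for idx, blk in blocks:
            sb, ub = np.linalg.eigh(np.asarray(blk, dtype=float))
            s[pos : pos + len(idx)] = sb
            decomposed.append((np.asarray(idx, dtype=int), ub))
            order.append((pos, idx))
            pos += len(idx)
        if pos != n:
            raise ValueError("block indices do not cover all n rows")
        s = _ridge_if_needed(s)
        return cls(s, decomposed, n)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        """Return U' a, rows ordered block by block (matching ``self.s``)."""
        a = np.asarray(a, dtype=float)
        squeeze = a.ndim == 1
        if squeeze:
            a = a[:, None]
        out = np.empty_like(a)
        pos = 0
        for idx, u in self._blocks:
            out[pos : pos + len(idx)] = u.T @ a[idx]
            pos += len(idx)
        return out[:, 0] if squeeze else out


def _ridge_if_needed(s: np.ndarray) -> np.ndarray:
    smin = s.min()
    if smin < -1e-8:
        raise ValueError(f"relatedness matrix is not PSD (min eigenvalue {smin:.3g})")
    if smin < 0:
        logger.info("adding ridge %.1e to GRM eigenvalues (min was %.3g)", GRM_RIDGE, smin)
        s = s + GRM_RIDGE
    return s


@dataclass
class LMMFit:
    """Fitted mixed model: fixed effects, variance components, REML state."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    converged: bool
    boundary: bool
    n: int
    p: int
    xnames: list[str] = field(default_factory=list)


@dataclass
class ContrastResult:
    """One Wald contrast: estimate, normal-theory 95% CI, two-sided p."""

    estimate: float
    se: float
    ci95: tuple[float, float]
    p: float
    label: str = ""


@dataclass
class GroupMeanResult:
    """A group's model-based mean PRS with CI, and its Wald contrast vs reference."""

    label: str
    mean: float
    se: float
    ci95: tuple[float, float]
    diff_vs_ref: float
    se_diff: float
    p_vs_ref: float
    n: int


def _check_design(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _, rmat = np.linalg.qr(x)
        diag = np.abs(np.diag(rmat))
        tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [names[j] for j in range(x.shape[1]) if diag[j] <= tol] or names
        raise ValueError(f"design matrix is rank deficient; collinear columns involve {bad}")


def _reml_nll(h2: float, y_rot: np.ndarray, x_rot: np.ndarray, s: np.ndarray):
    """Profiled (over total variance) restricted negative log-likelihood at h2."""
    n, p = x_rot.shape
    d = h2 * s + (1.0 - h2)
    w = 1.0 / d
    xw = x_rot * w[:, None]
    xtwx = x_rot.T @ xw
    xtwy = xw.T @ y_rot
    try:
        c = np.linalg.cholesky(xtwx)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = np.linalg.solve(xtwx, xtwy)
    r = y_rot - x_rot @ beta
    rss = float(np.sum(w * r * r))
    sigma2 = max(rss / (n - p), 1e-300)
    logdet_xtwx = 2.0 * float(np.sum(np.log(np.diag(c))))
    nll = 0.5 * ((n - p) * np.log(sigma2) + float(np.sum(np.log(d))) + logdet_xtwx + (n - p))
    return nll, beta, sigma2, xtwx


def fit_lmm(
    y: np.ndarray,
    x: np.ndarray | pd.DataFrame,
    k: np.ndarray | RelatednessMatrix | SpectralGRM,
    h2_tol: float = 1e-8,
    n_grid: int = 129,
) -> LMMFit:
    """Fit y = X beta + g + e with g ~ N(0, sigma_g^2 K) by spectral REML.

    ``k`` may be a dense symmetric matrix, a :class:`RelatednessMatrix`, or a
    precomputed :class:`SpectralGRM` (reusable across fits on the same
    cohort). Ties in the profiled criterion resolve toward h2 = 0.
    """
    names = list(x.columns.astype(str)) if isinstance(x, pd.DataFrame) else [f"x{j}" for j in range(np.atleast_2d(x).shape[1])]
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if len(y) != n:
        raise ValueError("y and X disagree on n")
    if p >= n:
        raise ValueError("more fixed effects than observations")
    _check_design(x, names)
    if isinstance(k, RelatednessMatrix):
        k = k.values
    spec = k if isinstance(k, SpectralGRM) else SpectralGRM.from_dense(k)
    if spec.n != n:
        raise ValueError("K and y disagree on n")
    y_rot = spec.rotate(y)
    x_rot = spec.rotate(x)
    s = spec.s

    grid = np.linspace(0.0, H2_UPPER, n_grid)
    nlls = np.array([_reml_nll(h, y_rot, x_rot, s)[0] for h in grid])
    best = int(np.argmin(nlls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: _reml_nll(h, y_rot, x_rot, s)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": h2_tol},
        )
        h2_hat, nll_hat = float(res.x), float(res.fun)
    else:
        h2_hat, nll_hat = float(grid[best]), float(nlls[best])
    # boundary candidates, ties resolved toward h2 = 0
    for h_b in (0.0, H2_UPPER):
        nll_b = _reml_nll(h_b, y_rot, x_rot, s)[0]
        if nll_b <= nll_hat + 1e-10:
            h2_hat, nll_hat = h_b, min(nll_b, nll_hat)
            break
    nll, beta, sigma2, xtwx = _reml_nll(h2_hat, y_rot, x_rot, s)
    beta_cov = sigma2 * np.linalg.inv(xtwx)
    boundary = h2_hat in (0.0, H2_UPPER)
    if boundary:
        logger.info("REML solution at h2 boundary (h2=%.6g)", h2_hat)
    return LMMFit(
        beta=beta,
        beta_cov=(beta_cov + beta_cov.T) / 2.0,
        sigma_g2=h2_hat * sigma2,
        sigma_e2=(1.0 - h2_hat) * sigma2,
        h2=h2_hat,
        reml_loglik=-nll,
        converged=True,
        boundary=boundary,
        n=n,
        p=p,
        xnames=names,
    )


def wald_test(fit: LMMFit, contrast: np.ndarray, label: str = "") -> ContrastResult:
    """Wald test of c' beta: z = estimate/se against the standard normal."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.p,):
        raise ValueError(f"contrast length {c.shape} does not match p={fit.p}")
    est = float(c @ fit.beta)
    var = float(c @ fit.beta_cov @ c)
    if var <= 0:
        raise ValueError("zero-variance contrast")
    se = float(np.sqrt(var))
    if est == 0.0:
        p = 1.0
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(est) / se)))
        p = max(p, np.nextafter(0.0, 1.0))
    return ContrastResult(est, se, (est - Z95 * se, est + Z95 * se), p, label)


def group_means(
    y: np.ndarray,
    group_labels,
    k,
    reference: str = "no_headache",
    order: list[str] | None = None,
) -> list[GroupMeanResult]:
    """Model-based mean PRS per group with 95% CI and Wald p vs the reference.

    Fits one cell-means LMM (one-hot design, no intercept) so all group
    means share the variance components and the family random effect; the
    reference group's self-contrast is reported as difference 0 with p = 1.
    """
    labels = pd.Series(np.asarray(group_labels, dtype=object))
    if order is None:
        if isinstance(group_labels, pd.Series) and isinstance(group_labels.dtype, pd.CategoricalDtype):
            order = [g for g in group_labels.cat.categories if g in set(labels)]
        else:
            order = sorted(set(labels))
    counts = labels.value_counts()
    for g in order:
        if counts.get(g, 0) == 0:
            raise ValueError(f"empty group {g!r}")
    if reference not in order:
        raise ValueError(f"reference group {reference!r} not present")
    if len(order) < 2:
        raise ValueError("need at least two groups")
    x = pd.DataFrame({g: (labels == g).astype(float).to_numpy() for g in order})
    fit = fit_lmm(np.asarray(y, dtype=float), x, k)
    i_ref = order.index(reference)
    results = []
    for i, g in enumerate(order):
        e = np.zeros(len(order))
        e[i] = 1.0
        mean_res = wald_test(fit, e, label=g)
        if i == i_ref:
            diff, se_diff, p = 0.0, 0.0, 1.0
        else:
            c = e.copy()
            c[i_ref] = -1.0
            d = wald_test(fit, c, label=f"{g} - {reference}")
            diff, se_diff, p = d.estimate, d.se, d.p
        results.append(
            GroupMeanResult(g, mean_res.estimate, mean_res.se, mean_res.ci95, diff, se_diff, p, int(counts[g]))
        )
    return results


def multivariable_fit(y: np.ndarray, criteria_matrix: pd.DataFrame, k) -> list[ContrastResult]:
    """All criteria in one LMM; per-criterion partial effects adjusted for the rest.

    ``criteria_matrix`` holds dichotomous columns (e.g. A, B, C, D1, D2, or
    aura indicators); an intercept is added internally. Perfect collinearity
    raises an error naming the offending columns.
    """
    cm = pd.DataFrame(criteria_matrix).astype(float)
    x = pd.concat([pd.Series(1.0, index=cm.index, name="intercept"), cm], axis=1)
    fit = fit_lmm(np.asarray(y, dtype=float), x, k)
    out = []
    for j, col in enumerate(cm.columns, start=1):
        c = np.zeros(fit.p)
        c[j] = 1.0
        out.append(wald_test(fit, c, label=str(col)))
    return out


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
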