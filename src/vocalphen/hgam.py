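"""Hierarchical binomial smooth of daily vocal activity.

Model, per species x elevation stratum::

    k_sd ~ Binomial(n_sd, p_sd),   logit p_sd = a + f(day_sd) + b_site(s)

with ``f`` a low-rank penalized cubic spline of ordinal day (rank ``k_basis``,
default 7, curvature penalized via second-order coefficient differences —
the P-spline formulation of a low-rank smoother) and ``b_site`` Gaussian
site random intercepts, treated as a ridge-penalized coefficient block with
common precision.  Fitting is penalized IRLS; the smoothing parameter and
the site-effect standard deviation are chosen on a log-spaced grid by the
Laplace-approximate restricted likelihood (REML).

The population-level curve sets the site offset to zero (the median site)
— one curve per species-stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.special import expit, xlogy


@dataclass
class HGAMSpec:
    """Tunable structure of the hierarchical smooth."""

    k_basis: int = 7
    degree: int = 3
    smoothing_selection: str = "reml"
    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-2, 6, 9))
    sigma_grid: np.ndarray = field(default_factory=lambda: np.logspace(-1.3, 0.7, 5))
    max_iter: int = 200
    tol: float = 1e-9

    def __post_init__(self):
        if self.k_basis < 3:
            raise ValueError("k_basis must be >= 3")


@dataclass
class HGAMDesign:
    """Design bundle for one species x stratum cell."""

    species_code: str
    stratum: str
    days: np.ndarray
    k: np.ndarray                 # successes (labels)
    n: np.ndarray                 # trials (segments)
    X_smooth: np.ndarray          # centered basis, n_rows x (k_eff - 1)
    S: np.ndarray                 # curvature penalty in the constrained space
    knots: np.ndarray
    constraint: np.ndarray        # k_eff x (k_eff - 1) sum-to-zero transform
    degree: int
    site_ids: list[str]
    site_index: np.ndarray        # row -> position in site_ids
    day_range: tuple[float, float]

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


@dataclass
class HGAMFit:
    """Fitted hierarchical smooth and its diagnostics."""

    species_code: str
    stratum: str
    spec: HGAMSpec
    alpha: float                  # population intercept
    beta: np.ndarray              # constrained smooth coefficients
    site_ids: list[str]
    site_effects: np.ndarray      # logit-scale offsets, shrunk toward 0
    lambda_smooth: float
    sigma_site: float
    loglik: float
    reml: float
    deviance: float
    null_deviance: float
    converged: bool
    knots: np.ndarray
    constraint: np.ndarray
    degree: int
    day_range: tuple[float, float]

    @property
    def deviance_explained(self) -> float:
        return deviance_explained(self)

    def site_effect_map(self) -> dict[str, float]:
        return dict(zip(self.site_ids, self.site_effects))


@dataclass
class PhenoCurve:
    """Population-level predicted daily vocalization probability."""

    species_code: str
    stratum: str
    days: np.ndarray              # daily integer grid
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_code": self.species_code, "stratum": self.stratum,
             "day": self.days, "p_hat": self.p}
        )


def spline_knots(lo: float, hi: float, k_basis: int, degree: int = 3) -> np.ndarray:
    """Open uniform knot vector giving exactly ``k_basis`` B-spline functions."""
    n_interior = k_basis - degree - 1
    if n_interior < 0:
        raise ValueError(f"k_basis={k_basis} too small for degree {degree}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def spline_basis(days: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    x = np.clip(np.asarray(days, dtype=float), knots[degree], knots[-degree - 1])
    return BSpline.design_matrix(x, knots, degree).toarray()


def difference_penalty(k_basis: int, order: int = 2) -> np.ndarray:
    """Squared ``order``-th difference penalty; its null space holds coefficient
    vectors with zero curvature (constant and linear trends)."""
    D = np.diff(np.eye(k_basis), n=order, axis=0)
    return D.T @ D


def build_design(cell: pd.DataFrame, spec: HGAMSpec | None = None) -> HGAMDesign:
    """Assemble basis, penalty and random-effect blocks for one cell.

    The smooth basis is column-centered (sum-to-zero over the observed rows)
    for identifiability against the intercept, dropping one column; with
    fewer distinct days than ``k_basis`` the rank is reduced with a warning.
    """
    spec = spec or HGAMSpec()
    days = cell.day.to_numpy(dtype=float)
    uniq = np.unique(days)
    k_eff = spec.k_basis
    if len(uniq) < k_eff:
        k_eff = max(spec.degree + 1, len(uniq))
        warnings.warn(
            f"only {len(uniq)} distinct days; reducing basis rank to {k_eff}", stacklevel=2
        )
    lo, hi = float(uniq.min()), float(uniq.max())
    knots = spline_knots(lo, hi, k_eff, spec.degree)
    B = spline_basis(days, knots, spec.degree)

    # sum-to-zero constraint over observed rows: columns of Z span null(colsum)
    Z = null_space(B.sum(axis=0, keepdims=True))
    S_full = difference_penalty(k_eff)
    site_ids, site_index = np.unique(cell.site_id.to_numpy(), return_inverse=True)

    return HGAMDesign(
        species_code=str(cell.species_code.iloc[0]),
        stratum=str(cell.stratum.iloc[0]),
        days=days,
        k=cell.k_labels.to_numpy(dtype=float),
        n=cell.n_segments.to_numpy(dtype=float),
        X_smooth=B @ Z,
        S=Z.T @ S_full @ Z,
        knots=knots,
        constraint=Z,
        degree=spec.degree,
        site_ids=[str(s) for s in site_ids],
        site_index=site_index,
        day_range=(lo, hi),
    )


def binomial_deviance(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(2.0 * np.sum(xlogy(k, k / (n * p)) + xlogy(n - k, (n - k) / (n * (1 - p)))))


def _penalized_irls(X, k, n, P, theta0, max_iter, tol):
    """Newton/IRLS maximizing binomial loglik - 0.5 theta' P theta."""
    theta = theta0.copy()

    def pll(th):
        eta = X @ th
        return float(np.sum(k * eta - n * np.logaddexp(0.0, eta)) - 0.5 * th @ P @ th)

    current = pll(theta)
    converged = False
    for _ in range(max_iter):
        eta = X @ theta
        mu = expit(eta)
        w = np.maximum(n * mu * (1 - mu), 1e-12)
        grad = X.T @ (k - n * mu) - P @ theta
        H = X.T @ (w[:, None] * X) + P
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving keeps the penalized loglik non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            new = pll(cand)
            if new >= current - 1e-12:
                break
            scale *= 0.5
        theta, improved = cand, new - current
        current = new
        if abs(improved) < tol * (abs(current) + 1.0):
            converged = True
            break
    eta = X @ theta
    mu = expit(eta)
    w = np.maximum(n * mu * (1 - mu), 1e-12)
    H = X.T @ (w[:, None] * X) + P
    loglik = float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))
    return theta, H, loglik, current, converged


def fit_hgam(design: HGAMDesign, spec: HGAMSpec | None = None) -> HGAMFit:
    """Fit the penalized binomial smooth with REML-selected (lambda, sigma).

    Deterministic given the data and spec.  Non-convergence at the selected
    grid point flags the fit for downstream exclusion.
    """
    spec = spec or HGAMSpec()
    n_rows = len(design.days)
    p_smooth = design.X_smooth.shape[1]
    m = design.n_sites

    Z_site = np.zeros((n_rows, m))
    Z_site[np.arange(n_rows), design.site_index] = 1.0
    X = np.column_stack([np.ones(n_rows), design.X_smooth, Z_site])

    s_eigs = np.linalg.eigvalsh(design.S)
    s_pos = s_eigs[s_eigs > 1e-10 * max(s_eigs.max(), 1.0)]
    rank_S = len(s_pos)
    logdet_S_base = float(np.sum(np.log(s_pos)))

    pbar = (design.k.sum() + 0.5) / (design.n.sum() + 1.0)
    theta0 = np.zeros(1 + p_smooth + m)
    theta0[0] = np.log(pbar / (1 - pbar))

    best = None
    for sig in spec.sigma_grid:
        tau = 1.0 / sig**2
        theta_warm = theta0
        for lam in spec.lambda_grid:
            P = np.zeros((X.shape[1], X.shape[1]))
            P[1:1 + p_smooth, 1:1 + p_smooth] = lam * design.S
            P[1 + p_smooth:, 1 + p_smooth:] = tau * np.eye(m)
            theta, H, loglik, pen_ll, conv = _penalized_irls(
                X, design.k, design.n, P, theta_warm, spec.max_iter, spec.tol
            )
            theta_warm = theta
            sign, logdet_H = np.linalg.slogdet(H)
            if sign <= 0:
                continue
            logdet_P = rank_S * np.log(lam) + logdet_S_base + m * np.log(tau)
            reml = pen_ll + 0.5 * logdet_P - 0.5 * logdet_H
            if best is None or reml > best["reml"]:
                best = dict(reml=reml, lam=lam, sig=sig, theta=theta,
                            loglik=loglik, converged=conv)

    if best is None:
        raise RuntimeError("no smoothing-parameter candidate produced a valid fit")

    theta = best["theta"]
    alpha = float(theta[0])
    beta = theta[1:1 + p_smooth]
    b_site = theta[1 + p_smooth:]
    p_hat = expit(X @ theta)
    dev = binomial_deviance(design.k, design.n, p_hat)
    null_dev = binomial_deviance(
        design.k, design.n, np.full(n_rows, design.k.sum() / design.n.sum())
    )

    return HGAMFit(
        species_code=design.species_code,
        stratum=design.stratum,
        spec=spec,
        alpha=alpha,
        beta=beta,
        site_ids=design.site_ids,
        site_effects=b_site,
        lambda_smooth=float(best["lam"]),
        sigma_site=float(best["sig"]),
        loglik=best["loglik"],
        reml=float(best["reml"]),
        deviance=dev,
        null_deviance=null_dev,
        converged=bool(best["converged"]),
        knots=design.knots,
        constraint=design.constraint,
        degree=design.degree,
        day_range=design.day_range,
    )


def predict_curve(fit: HGAMFit, days: np.ndarray | None = None) -> PhenoCurve:
    """Evaluate the population-level curve (site offset 0) on a daily grid.

    Days outside the observed range are clipped to it with a warning — no
    phenometric is ever extracted from extrapolation.
    """
    lo, hi = fit.day_range
    if days is None:
        days = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    days = np.asarray(days)
    if days.min() < lo or days.max() > hi:
        warnings.warn("requested days outside the observed range; clipping", stacklevel=2)
        days = days[(days >= lo) & (days <= hi)]
    B = spline_basis(days.astype(float), fit.knots, fit.degree)
    eta = fit.alpha + B @ fit.constraint @ fit.beta
    return PhenoCurve(fit.species_code, fit.stratum, days, expit(eta))


def deviance_explained(fit: HGAMFit) -> float:
    """1 - D_model / D_null; defined as 0 when the null deviance is 0."""
    if fit.null_deviance <= 0:
        return 0.0
    return 1.0 - fit.deviance / fit.null_deviance
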