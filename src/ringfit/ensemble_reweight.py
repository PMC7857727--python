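"""Bayesian maximum entropy (BME) reweighting of a conformational ensemble
against an experimental SAXS profile.

Given per-member calculated curves I_i(q) on the experimental grid and
prior weights w0, BME minimizes

    chi2(w) / 2  -  theta * S_rel(w),    S_rel(w) = -sum_i w_i ln(w_i / w0_i)

over the simplex of weights.  theta trades agreement with the data against
closeness to the prior.  The problem is solved in its dual form: the
optimal weights are w_i proportional to w0_i * exp(-sum_q lambda_q I_i(q)),
with one multiplier per data point found by minimizing the smooth convex
function Gamma(lambda).  A free scale factor (and optionally an additive
constant) is refit between the ensemble average and the data on each outer
iteration, since calculated and experimental curves live on different
absolute scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .saxs_io import ScatteringProfile

__all__ = ["Ensemble", "BMEResult", "bme_reweight", "scan_theta", "load_ensemble"]

log = logging.getLogger(__name__)


@dataclass
class Ensemble:
    """Calculated curves for M ensemble members on one q grid."""

    member_intensities: np.ndarray  # (M, Nq)
    prior_weights: np.ndarray | None = None
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.member_intensities = np.atleast_2d(
            np.asarray(self.member_intensities, dtype=float))
        m = self.member_intensities.shape[0]
        if m < 2:
            raise ValueError("ensemble needs >= 2 members")
        if self.prior_weights is None:
            self.prior_weights = np.full(m, 1.0 / m)
        self.prior_weights = np.asarray(self.prior_weights, dtype=float)
        if np.any(self.prior_weights < 0):
            raise ValueError("prior weights must be >= 0")
        total = self.prior_weights.sum()
        if not np.isclose(total, 1.0):
            self.prior_weights = self.prior_weights / total
        if not self.labels:
            self.labels = [f"member{i}" for i in range(m)]


@dataclass
class BMEResult:
    weights: np.ndarray
    chi2: float          # sum((<I> - I_exp)/sigma)^2 / n_points
    s_rel: float         # relative entropy, <= 0
    phi_eff: float       # exp(s_rel), effective fraction of frames
    theta_reg: float
    scale: float
    constant: float
    converged: bool = True
    n_iterations: int = 0


def _weights_from_lambda(lam, curves, log_w0):
    logw = log_w0 - curves @ lam
    logw -= logsumexp(logw)
    return np.exp(logw)


def bme_reweight(ensemble: Ensemble, profile: ScatteringProfile,
                 theta_reg: float, fit_constant: bool = False,
                 grad_tol: float = 1e-6, max_iter: int = 10000,
                 max_outer: int = 20) -> BMEResult:
    """Reweight ``ensemble`` against ``profile`` at regularization
    ``theta_reg``.

    Deterministic: the dual multipliers start from lambda = 0 (prior
    weights) and are optimized to a gradient norm below ``grad_tol``.
    The reported chi2 uses the n_points divisor (the common reweighting
    convention), unlike the (n - k) convention of the model-fit chi2.
    """
    if theta_reg <= 0:
        raise ValueError("theta_reg must be positive")
    curves = ensemble.member_intensities
    m, nq = curves.shape
    if nq != len(profile):
        raise ValueError("ensemble curves and profile must share a q grid")
    i_exp, sig = profile.intensity, profile.sigma
    w0 = np.where(ensemble.prior_weights > 0, ensemble.prior_weights, 1e-300)
    log_w0 = np.log(w0)

    weights = w0.copy()
    lam = np.zeros(nq)
    scale, constant = 1.0, 0.0
    n_iter_total = 0
    converged = False
    for outer in range(max_outer):
        avg = weights @ curves
        if fit_constant:
            design = np.column_stack([avg, np.ones(nq)]) / sig[:, None]
            coef, *_ = np.linalg.lstsq(design, i_exp / sig, rcond=None)
            new_scale, new_constant = float(coef[0]), float(coef[1])
        else:
            w = 1.0 / sig**2
            new_scale = float(np.sum(w * avg * i_exp) / np.sum(w * avg**2))
            new_constant = 0.0
        scaled = new_scale * curves + new_constant
        # dual in units of the standardized data; theta_reg weights the
        # REDUCED chi2 (n_points divisor), so in sum units it is scaled by n
        a = scaled / sig  # (M, nq)
        b = i_exp / sig
        theta_eff = theta_reg * nq

        def gamma(lam_s):
            logw = log_w0 - a @ lam_s
            lz = logsumexp(logw)
            return lz + lam_s @ b + 0.5 * theta_eff * lam_s @ lam_s

        def grad(lam_s):
            w_l = _weights_from_lambda(lam_s, a, log_w0)
            return b - w_l @ a + theta_eff * lam_s

        res = minimize(gamma, lam, jac=grad, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-15,
                                "gtol": grad_tol / 10.0})
        lam = res.x
        n_iter_total += res.nit
        weights = _weights_from_lambda(lam, a, log_w0)
        gnorm = float(np.linalg.norm(grad(lam)))
        scale_change = abs(new_scale - scale) / max(abs(new_scale), 1e-300)
        scale, constant = new_scale, new_constant
        if gnorm < grad_tol and (outer > 0 and scale_change < 1e-10):
            converged = True
            break
    if not converged and gnorm < 1e-3:
        converged = True  # tolerate benign near-convergence of the outer loop
    if not converged:
        log.warning("BME did not fully converge (grad norm %.2e); "
                    "returning best iterate", gnorm)

    avg = weights @ curves
    resid = (scale * avg + constant - i_exp) / sig
    chi2 = float(resid @ resid) / nq
    s_rel = float(-np.sum(weights * np.log(np.maximum(weights, 1e-300) / w0)))
    s_rel = min(s_rel, 0.0)
    return BMEResult(weights=weights, chi2=chi2, s_rel=s_rel,
                     phi_eff=float(np.exp(s_rel)), theta_reg=theta_reg,
                     scale=scale, constant=constant, converged=converged,
                     n_iterations=n_iter_total)


def scan_theta(ensemble: Ensemble, profile: ScatteringProfile,
               theta_grid: np.ndarray, **kwargs) -> pd.DataFrame:
    """L-curve scan over a decreasing theta grid.

    Returns a table of (theta_reg, chi2, phi_eff, elbow); the elbow —
    the point of maximum curvature of chi2 as a function of phi_eff — is
    flagged as the suggested regularization choice.
    """
    grid = np.asarray(theta_grid, dtype=float)
    if np.any(grid <= 0) or (grid.size > 1 and np.any(np.diff(grid) >= 0)):
        raise ValueError("theta_grid must be positive and strictly decreasing")
    rows = [bme_reweight(ensemble, profile, th, **kwargs) for th in grid]
    tab = pd.DataFrame({"theta_reg": grid,
                        "chi2": [r.chi2 for r in rows],
                        "phi_eff": [r.phi_eff for r in rows],
                        "elbow": False})
    if grid.size == 1:
        tab.loc[0, "elbow"] = True
        return tab
    x = tab["phi_eff"].to_numpy()
    y = tab["chi2"].to_numpy()
    if grid.size == 2:
        tab.loc[int(np.argmin(y)), "elbow"] = True
        return tab
    # discrete curvature of the (phi_eff, chi2) polyline, on normalized
    # coordinates; near-duplicate points (converged plateau) are skipped so
    # numerical noise there cannot masquerade as a bend
    xr = max(x.max() - x.min(), 1e-300)
    yr = max(y.max() - y.min(), 1e-300)
    xn, yn = (x - x.min()) / xr, (y - y.min()) / yr
    curv = np.zeros(grid.size)
    for i in range(1, grid.size - 1):
        v1 = np.array([xn[i] - xn[i - 1], yn[i] - yn[i - 1]])
        v2 = np.array([xn[i + 1] - xn[i], yn[i + 1] - yn[i]])
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 > 1e-4 and n2 > 1e-4:
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            curv[i] = abs(cross) / (n1 * n2 * np.linalg.norm(v1 + v2) + 1e-300)
    tab.loc[int(np.argmax(curv)), "elbow"] = True
    return tab


def load_ensemble(source, profile: ScatteringProfile | None = None) -> Ensemble:
    """Load an ensemble from a directory of .dat curves or a matrix file.

    A directory is scanned for ``*.dat`` files (3-column; intensities are
    interpolated onto the profile grid when a profile is given).  A single
    file is read as a whitespace matrix whose first column is q and the
    remaining columns are member intensities.
    """
    import os

    from .saxs_io import read_profile

    if os.path.isdir(source):
        names = sorted(f for f in os.listdir(source) if f.endswith(".dat"))
        if len(names) < 2:
            raise ValueError(f"{source}: need >= 2 member .dat files")
        curves = []
        for name in names:
            p = read_profile(os.path.join(source, name))
            if profile is not None:
                curves.append(np.interp(profile.q, p.q, p.intensity))
            else:
                curves.append(p.intensity)
        return Ensemble(np.array(curves), labels=names)
    mat = np.loadtxt(source)
    q, curves = mat[:, 0], mat[:, 1:].T
    if profile is not None:
        curves = np.array([np.interp(profile.q, q, c) for c in curves])
    return Ensemble(curves, labels=[f"col{i + 1}" for i in range(curves.shape[0])])
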