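"""Regularized indirect Fourier transformation (IFT) to p(r), D_max scanning
and peak/shoulder detection.

The pair distance distribution p(r) is related to the 1D scattering curve by

    I(q) = 4 pi \int_0^{D_max} p(r) sin(q r) / (q r) dr.

The inversion is ill-posed; we expand p(r) on an equally spaced r grid with
both endpoints pinned to zero and solve the sigma-weighted linear system with
a second-derivative (Tikhonov) smoothness penalty.  The regularization weight
can be chosen automatically by generalized cross-validation (GCV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .saxs_io import ScatteringProfile

__all__ = ["PairDistribution", "Peak", "ift_pr", "scan_dmax", "find_peaks",
           "write_pr", "DEFAULT_Q_MAX"]

log = logging.getLogger(__name__)

#: default upper q bound for IFT and model fits [1/A]; data above this are
#: noise-dominated for the particle sizes this package targets.
DEFAULT_Q_MAX = 0.27


@dataclass
class PairDistribution:
    """p(r) on an equally spaced r grid from 0 to dmax (inclusive)."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg_real: float
    i0: float
    reg_alpha: float = 0.0
    fit_chi2: float = np.nan  # reduced chi2 of the regularized fit to I(q)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.size != self.p.size:
            raise ValueError("r and p must have equal length")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])


@dataclass
class Peak:
    position: float  # [A]
    height: float
    kind: str  # "peak" or "shoulder"


def _kernel(q: np.ndarray, r: np.ndarray, dr: float) -> np.ndarray:
    """Trapezoid-rule kernel K[i, j] = 4 pi dr sinc(q_i r_j)."""
    x = np.outer(q, r)
    return 4.0 * np.pi * dr * np.sinc(x / np.pi)


def _second_difference(m: int) -> np.ndarray:
    """Second-difference operator on m interior coefficients, with the
    pinned zero endpoints included implicitly."""
    d = np.zeros((m, m))
    for i in range(m):
        d[i, i] = -2.0
        if i > 0:
            d[i, i - 1] = 1.0
        if i < m - 1:
            d[i, i + 1] = 1.0
    return d


def ift_pr(profile: ScatteringProfile, dmax: float, n_r: int = 101,
           reg_alpha: float | str = "auto", q_max: float = DEFAULT_Q_MAX,
           ) -> PairDistribution:
    """Indirect Fourier transform of ``profile`` to p(r) on [0, dmax].

    Parameters
    ----------
    dmax : float
        Assumed maximum intramolecular distance [A].
    n_r : int
        Number of r grid points including the pinned endpoints.
    reg_alpha : float or "auto"
        Second-derivative smoothness weight; "auto" selects it by a GCV scan
        over a logarithmic grid.
    q_max : float
        Upper fit limit in q [1/A].
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    prof = profile.restrict(q_max=q_max)
    q, i_exp, sig = prof.q, prof.intensity, prof.sigma
    if dmax < np.pi / q[-1]:
        warnings.warn(
            f"dmax={dmax:.0f} A is below the resolution support pi/q_max="
            f"{np.pi / q[-1]:.0f} A of the fitted range")

    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    k_full = _kernel(q, r, dr)
    k_full[:, 0] *= 0.5  # trapezoid end weights (both pinned to zero anyway)
    k_full[:, -1] *= 0.5
    a = k_full[:, 1:-1] / sig[:, None]  # interior coefficients only
    b = i_exp / sig
    m = n_r - 2
    d2 = _second_difference(m)
    g = d2.T @ d2
    ata = a.T @ a
    atb = a.T @ b

    # alpha is scanned in units of the natural scale tr(A^T A)/tr(G)
    alpha_scale = np.trace(ata) / np.trace(g)

    def solve(alpha_eff: float):
        mmat = ata + alpha_eff * g
        try:
            p_in = np.linalg.solve(mmat, atb)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular IFT system at reg_alpha={alpha_eff:g}; "
                "raise reg_alpha") from err
        return p_in, mmat

    if reg_alpha == "auto":
        best = None
        n = q.size
        for la in np.logspace(-6, 2, 33):
            alpha_eff = la * alpha_scale
            p_in, mmat = solve(alpha_eff)
            resid = a @ p_in - b
            # tr(H) = tr(A M^-1 A^T) = tr(M^-1 A^T A)
            tr_h = float(np.trace(np.linalg.solve(mmat, ata)))
            gcv = n * float(resid @ resid) / (n - tr_h) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, la, p_in)
        _, la, p_in = best
        alpha_used = la
    else:
        alpha_used = float(reg_alpha)
        p_in, _ = solve(alpha_used * alpha_scale)

    p = np.zeros(n_r)
    p[1:-1] = p_in
    resid = a @ p_in - b
    chi2 = float(resid @ resid) / max(q.size - 1, 1)

    integral = np.trapezoid(p, r)
    i0 = 4.0 * np.pi * integral
    r2 = np.trapezoid(p * r**2, r)
    rg_real = float(np.sqrt(r2 / (2.0 * integral))) if integral > 0 else np.nan
    return PairDistribution(r=r, p=p, dmax=float(dmax), rg_real=rg_real,
                            i0=float(i0), reg_alpha=alpha_used, fit_chi2=chi2)


def scan_dmax(profile: ScatteringProfile, dmax_grid: np.ndarray,
              chi2_window: float = 0.05, **ift_kwargs) -> pd.DataFrame:
    """Scan candidate D_max values and select by the chi2-plateau rule.

    Runs :func:`ift_pr` per grid value and selects the smallest dmax whose
    fit chi2 is within ``chi2_window`` (default 5%) of the plateau minimum
    and whose p(r) has no forced negative dip at the tail.  Returns a table
    with columns (dmax, chi2, smoothness, selected).
    """
    grid = np.asarray(dmax_grid, dtype=float)
    if grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("dmax_grid must be increasing")
    rows = []
    prs = []
    for dm in grid:
        pr = ift_pr(profile, dm, **ift_kwargs)
        prs.append(pr)
        smooth = float(np.sum(np.diff(pr.p, 2) ** 2)) / max(np.max(np.abs(pr.p)), 1e-300) ** 2
        rows.append({"dmax": dm, "chi2": pr.fit_chi2, "smoothness": smooth,
                     "selected": False})
    tab = pd.DataFrame(rows)
    if grid.size == 1:
        tab.loc[0, "selected"] = True
        return tab

    chi2 = tab["chi2"].to_numpy()
    chi_min = chi2.min()
    # the plateau window is the larger of a 5% band and one standard
    # deviation of a reduced chi2 (sqrt(2/n)), so that noise-driven drift of
    # the plateau does not push the selection to ever-larger dmax
    q_max = ift_kwargs.get("q_max", DEFAULT_Q_MAX)
    n_fit = len(profile.restrict(q_max=q_max))
    plateau_ok = chi2 <= chi_min + np.maximum(chi2_window * chi_min,
                                              np.sqrt(2.0 / max(n_fit, 2)))
    # plateau must actually flatten: reject if chi2 is still falling fast at
    # the top of the grid and that is the only place the minimum lives
    still_falling = (int(np.argmin(chi2)) == grid.size - 1
                     and chi2[-1] < (1.0 - chi2_window) * chi2[-2])
    # a dip deeper than half of max(p) in the outer 15% of the r range is a
    # truncation artifact (dmax too small forces p strongly negative there);
    # shallower negative excursions are ordinary ringing of the regularized
    # solution near its support edge, pronounced for noisy data
    tail_ok = np.empty(grid.size, dtype=bool)
    for i, pr in enumerate(prs):
        tail = pr.p[pr.r >= 0.85 * pr.dmax]
        tail_ok[i] = tail.min() >= -0.5 * np.max(np.abs(pr.p))
    candidates = np.flatnonzero(plateau_ok & tail_ok)
    # the global minimum is trivially a 5% candidate; only distrust it when
    # it sits at the top of the grid with chi2 still falling fast
    if candidates.size and candidates[0] < grid.size - 1:
        still_falling = False
    if still_falling or candidates.size == 0:
        warnings.warn("no chi2 plateau found in dmax scan; selection left unset")
        return tab
    tab.loc[candidates[0], "selected"] = True
    return tab


def _quadratic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (clamped at edges)."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dx = x[1] - x[0]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def find_peaks(pr: PairDistribution, min_prominence: float = 0.02,
               include_shoulders: bool = False) -> list[Peak]:
    """Detect local maxima (and optionally shoulders) of p(r).

    Maxima with prominence >= ``min_prominence`` * max(p) are classified as
    peaks; positions are refined by quadratic interpolation of the three
    points around each extremum.  Shoulders are inflection plateaus: zero
    crossings of the second derivative without a sign change of the first.
    """
    p = pr.p
    pmax = float(np.max(p))
    if pmax <= 0:
        return []
    idx, _ = _scipy_find_peaks(p, prominence=min_prominence * pmax)
    peaks = [Peak(*_quadratic_vertex(pr.r, p, i), kind="peak") for i in idx]
    if include_shoulders:
        d1 = np.gradient(p, pr.r)
        d2 = np.gradient(d1, pr.r)
        # smooth the curvature a little before looking for zero crossings
        kern = np.ones(5) / 5.0
        d2s = np.convolve(d2, kern, mode="same")
        sign = np.sign(d2s)
        for i in np.flatnonzero(np.diff(sign) != 0):
            if i < 2 or i > p.size - 3:
                continue
            if np.sign(d1[i - 1]) == np.sign(d1[i + 1]) != 0 and p[i] > 0.02 * pmax:
                near_peak = any(abs(pr.r[i] - pk.position) < 3 * pr.dr for pk in peaks)
                if not near_peak:
                    peaks.append(Peak(float(pr.r[i]), float(p[i]), kind="shoulder"))
    peaks.sort(key=lambda pk: pk.position)
    return peaks


def write_pr(path, profile: ScatteringProfile, pr: PairDistribution) -> None:
    """GNOM-style two-block text output: the fit block (q, I_exp, sigma,
    I_reg) followed by the p(r) block (r, p)."""
    prof = profile.restrict(q_max=np.inf)
    k = _kernel(prof.q, pr.r, pr.dr)
    k[:, 0] *= 0.5
    k[:, -1] *= 0.5
    i_reg = k @ pr.p
    with open(path, "w") as fh:
        fh.write(f"# ringfit p(r): dmax={pr.dmax:.2f} A  Rg={pr.rg_real:.2f} A "
                 f"I0={pr.i0:.4e}  reg_alpha={pr.reg_alpha:g}\n")
        fh.write("# q I_exp sigma I_reg\n")
        for row in zip(prof.q, prof.intensity, prof.sigma, i_reg):
            fh.write(" ".join(f"{v:.6e}" for v in row) + "\n")
        fh.write("\n# r p(r)\n")
        for r, p in zip(pr.r, pr.p):
            fh.write(f"{r:.4f} {p:.6e}\n")
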