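"""Principal-axis analysis, the alpha-angle orientation statistic, model
D_max and the direct model p(r).

The alpha angle quantifies how the ligand-binding face at each vertex of a
flat cyclic oligomer is oriented relative to the oligomer plane: it is the
angle between a per-protomer "eye vector" (defined by two named anchor
beads) and the smallest principal axis of the whole assembly.  With the
flip convention (negate the axis when the protomer-average is below 90
degrees) the mean always lies in [90, 180]: 180 means all binding faces
point the same way out of the plane, 90 means they lie in the plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .pair_distribution import PairDistribution
from .scattering_calc import BeadModel

__all__ = ["PrincipalAxes", "AlphaResult", "principal_axes", "alpha_angle",
           "model_dmax", "model_pr"]


@dataclass
class PrincipalAxes:
    """Eigen-decomposition of the unweighted gyration tensor.

    eigenvalues are sorted ascending [A^2]; axes[i] is the unit eigenvector
    for eigenvalues[i], so axes[0] is the smallest principal axis (the
    thinnest direction of a flat particle).  The set is right-handed and
    each axis sign is canonicalized so its largest-magnitude component is
    positive.
    """

    eigenvalues: np.ndarray
    axes: np.ndarray  # rows are unit vectors
    degenerate: bool = False


@dataclass
class AlphaResult:
    per_protomer_alpha: np.ndarray  # [degrees]
    mean_alpha: float
    flipped: bool


def principal_axes(model: BeadModel) -> PrincipalAxes:
    """Principal axes of the unweighted gyration tensor about the centroid."""
    x = model.coordinates - model.coordinates.mean(axis=0)
    if model.n_beads < 3:
        raise ValueError("principal axes need >= 3 beads")
    gyr = x.T @ x / model.n_beads
    evals, evecs = np.linalg.eigh(gyr)  # ascending
    axes = evecs.T.copy()
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    # restore right-handedness after sign canonicalization
    if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
        axes[2] = -axes[2]
    degenerate = False
    scale = max(float(evals[-1]), 1e-300)
    if evals[0] / scale < 1e-8 or (evals[1] - evals[0]) / scale < 1e-8:
        degenerate = True
        warnings.warn("degenerate/collinear bead set: principal axes ill-defined")
    elif evals[1] > 0 and (evals[1] - evals[0]) < 0.01 * evals[1]:
        degenerate = True
        warnings.warn("smallest two gyration eigenvalues within 1%: "
                      "the thin axis (and alpha) is ill-defined")
    return PrincipalAxes(eigenvalues=evals, axes=axes, degenerate=degenerate)


def alpha_angle(model: BeadModel, anchor_from: str = "S345",
                anchor_to: str = "A402") -> AlphaResult:
    """Mean angle between per-protomer eye vectors and the smallest
    principal axis of the whole model.

    Anchors are addressed by their base name; each protomer k must carry
    ``{name}/{k}`` entries in ``model.anchors``.  If the protomer average is
    below 90 degrees the axis is negated and the result flagged flipped.
    """
    protomers = np.unique(model.protomer_id)
    vecs = []
    for k in protomers:
        a, b = f"{anchor_from}/{k}", f"{anchor_to}/{k}"
        for name in (a, b):
            if name not in model.anchors:
                raise KeyError(f"anchor {name!r} missing from protomer {k}")
        v = model.anchor_xyz(b) - model.anchor_xyz(a)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"zero-length eye vector in protomer {k}")
        vecs.append(v / norm)
    axis = principal_axes(model).axes[0]

    def mean_alpha(ax):
        cosv = np.clip(np.asarray(vecs) @ ax, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosv))
        return ang, float(np.mean(ang))

    ang, mean = mean_alpha(axis)
    flipped = False
    if mean < 90.0:
        ang, mean = mean_alpha(-axis)
        flipped = True
    return AlphaResult(per_protomer_alpha=ang, mean_alpha=mean, flipped=flipped)


def model_dmax(model: BeadModel) -> float:
    """Maximum pairwise bead distance [A] (exact)."""
    if model.n_beads < 2:
        raise ValueError("model_dmax needs >= 2 beads")
    return float(pdist(model.coordinates).max())


def model_pr(model: BeadModel, bin_width: float = 1.0) -> PairDistribution:
    """Direct weight-product pair distance histogram of a bead model.

    Each unordered pair i < j contributes 2 * w_i * w_j (both orderings), so
    the integral of p over r equals (sum w)^2 - sum w^2.  The histogram is
    zero-padded at both ends; this is the model-space oracle for the IFT.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = pdist(model.coordinates)
    n = model.n_beads
    iu = np.triu_indices(n, k=1)
    w = model.weight
    wprod = 2.0 * w[iu[0]] * w[iu[1]]
    # one spare bin beyond the support so resampling never clips tail mass
    n_bins = max(int(np.ceil(d.max() / bin_width)), 1) + 2
    hist, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width),
                               weights=wprod)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # density at bin centers, linearly resampled onto an equally spaced node
    # grid r_j = j * bin_width with zero-pinned endpoints
    r = bin_width * np.arange(n_bins + 2)
    p = np.interp(r, centers, hist / bin_width, left=0.0, right=0.0)
    p[0] = p[-1] = 0.0
    integral = np.trapezoid(p, r)
    i0 = float(np.sum(w) ** 2 - np.sum(w**2))
    rg = float(np.sqrt(np.trapezoid(p * r**2, r) / (2.0 * integral))) if integral > 0 else np.nan
    return PairDistribution(r=r, p=p, dmax=float(d.max()), rg_real=rg, i0=i0,
                            reg_alpha=0.0)
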