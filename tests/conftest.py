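"""Shared fixtures: analytic oracles and small synthetic systems.

All fixtures are generated programmatically; the sphere form factor and the
closed-form sphere distance distribution serve as independent analytic
oracles for the Guinier, Debye and IFT code paths.
"""

import numpy as np
import pytest

from ringfit.saxs_io import ScatteringProfile


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized intensity of a homogeneous sphere, I(0) = 1."""
    x = q * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form distance distribution of a homogeneous sphere (arbitrary
    normalization): p(r) ~ r^2 (1 - 3u/4 + u^3/16), u = r/R, for r <= 2R."""
    u = r / radius
    p = r**2 * (1.0 - 0.75 * u + u**3 / 16.0)
    p[r > 2.0 * radius] = 0.0
    return p


def make_sphere_profile(radius: float, q_max: float = 0.4, n_q: int = 1200,
                        sigma: float = 1e-6) -> ScatteringProfile:
    q = np.linspace(0.002, q_max, n_q)
    return ScatteringProfile(q, sphere_form_factor(q, radius),
                             np.full(n_q, sigma), label=f"sphere R={radius}")


def make_two_point_profile(d: float, q_max: float = 0.3,
                           n_q: int = 600) -> ScatteringProfile:
    q = np.linspace(0.002, q_max, n_q)
    intensity = 2.0 * (1.0 + np.sinc(q * d / np.pi))
    return ScatteringProfile(q, intensity, np.full(n_q, 1e-6),
                             label=f"two-point d={d}")


@pytest.fixture(scope="session")
def sphere50_profile():
    return make_sphere_profile(50.0)


@pytest.fixture(scope="session")
def two_point100_profile():
    return make_two_point_profile(100.0)


@pytest.fixture(scope="session")
def small_fp3():
    """Reduced-bead trimer truth used by the refinement tests."""
    from ringfit.synthetic import make_oligomer, preset
    return make_oligomer(preset("fp3", beads_per_eye=40, beads_per_arm_cluster=8))


def eye_separation(model) -> float:
    """Neighbor eye-eye centroid distance of a realized model (body 0 is
    the eye in generator assemblies)."""
    centers = []
    for p in np.unique(model.protomer_id):
        m = (model.protomer_id == p) & (model.body_id == 0)
        centers.append(model.coordinates[m].mean(axis=0))
    centers = np.asarray(centers)
    n = centers.shape[0]
    if n < 2:
        raise ValueError("need >= 2 protomers")
    return float(np.linalg.norm(centers[0] - centers[1 % n]))
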