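"""Synthetic "eye + arm" cyclic oligomer models with known geometry, and
simulated noisy SAXS profiles.

The generator emulates the architecture of head-to-tail oligomers such as
properdin: each of the n vertices is a compact, slightly flattened
ellipsoidal "eye" cluster (~40 A across) carrying the binding-site anchor
pair, and consecutive vertices are joined by an arm of three compact
sub-clusters (the three-domain connecting segment) tracing the arc between
them.  The per-protomer eye vector is tilted by a designed angle
``alpha_true`` to the +z symmetry axis, so every analysis stage can be
checked against known truth values.

Bead positions are filled with a deterministic low-discrepancy (Halton)
sequence: a noise-free pipeline is therefore bit-reproducible, and only
the profile noise consumes the random stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .rigid_body import AssemblySpec, Placement, Restraint, RigidBodySpec, apply_cn
from .saxs_io import ScatteringProfile
from .scattering_calc import BeadModel, debye_intensity

__all__ = ["SyntheticSpec", "SyntheticTruth", "make_oligomer",
           "simulate_profile", "reference_restraints", "PRESETS", "preset"]


@dataclass
class SyntheticSpec:
    """Design parameters of a synthetic cyclic oligomer.

    n : oligomer order (1-8).
    eye_sep : neighbor eye-eye centroid distance [A].
    eye_extent : eye cluster diameter [A].
    arm_clusters : number of compact sub-clusters per connecting arm.
    beads_per_eye / beads_per_arm_cluster : fill density (one bead is
        roughly one residue at the defaults).
    alpha_true : designed tilt of the eye vector to +z [degrees, 90-180].
    out_of_plane : z bowing of the arm midpoints [A].
    noise_level : relative sigma at low q for simulated profiles.
    """

    n: int = 2
    eye_sep: float = 165.0
    eye_extent: float = 40.0
    arm_clusters: int = 3
    beads_per_eye: int = 160
    # the eye carries ~71% of the protomer mass (5 of 7 domains in the real
    # protein); 3 x 22 arm beads against 160 eye beads preserves that ratio
    beads_per_arm_cluster: int = 22
    alpha_true: float = 150.0
    out_of_plane: float = 0.0
    noise_level: float = 0.01
    seed: int = 0
    arm_bulge: float | None = None  # in-plane bowing of arm midpoints [A];
    # None -> 40 for dimers (antiparallel arms ~80 A apart), 0 for n >= 3
    # (arms stay on the circle through the eyes)

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 8:
            raise ValueError("n must be in 1..8")
        if self.eye_sep <= self.eye_extent:
            raise ValueError("eye_sep must exceed eye_extent")
        if not 90.0 <= self.alpha_true <= 180.0:
            raise ValueError("alpha_true must be in [90, 180] degrees")


@dataclass
class SyntheticTruth:
    """Realized model plus the designed ground-truth values."""

    model: BeadModel
    assembly: AssemblySpec
    spec: SyntheticSpec
    eye_centers: np.ndarray  # (n, 3)
    anchor_from: str = "S345"
    anchor_to: str = "A402"


#: presets mirroring the dimer/trimer/tetramer study conditions
PRESETS = {
    "fp2": SyntheticSpec(n=2, eye_sep=165.0, alpha_true=150.0),
    "fp3": SyntheticSpec(n=3, eye_sep=180.0, alpha_true=128.0),
    "fp4": SyntheticSpec(n=4, eye_sep=195.0, alpha_true=109.0),
}


def preset(name: str, **overrides) -> SyntheticSpec:
    """A copy of a named preset with optional field overrides."""
    import dataclasses
    return dataclasses.replace(PRESETS[name], **overrides)


def _halton_ellipsoid(n_beads: int, semi_axes: np.ndarray) -> np.ndarray:
    """Deterministic quasi-random fill of an axis-aligned ellipsoid."""
    sampler = qmc.Halton(d=3, scramble=False, seed=0)
    pts = []
    while len(pts) < n_beads:
        cand = 2.0 * sampler.random(4 * n_beads) - 1.0
        inside = np.sum(cand**2, axis=1) <= 1.0
        pts.extend(cand[inside])
    pts = np.asarray(pts[:n_beads])
    return pts * semi_axes


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _eye_body(spec: SyntheticSpec, u: np.ndarray, e2: np.ndarray,
              to_prev: np.ndarray) -> RigidBodySpec:
    """The eye rigid body in its own frame (centered at the eye centroid).

    u is the unit eye vector (tilted at alpha_true to +z), e2 the in-plane
    direction toward the next vertex; the ellipsoid is flattened along
    e3 = u x e2 so the eye plane contains the eye vector.
    """
    e3 = _unit(np.cross(u, e2))
    frame = np.column_stack([u, e2, e3])
    a = spec.eye_extent / 2.0
    semi = np.array([a, 0.75 * a, 0.3 * a])
    local = _halton_ellipsoid(spec.beads_per_eye, semi) @ frame.T
    anchors_xyz = {
        "S345": np.zeros(3),
        "A402": a * u,
        "eye_out": 0.75 * a * e2,
        "eye_in": 0.75 * a * _unit(to_prev - (to_prev @ u) * u),
        "C132": 0.6 * a * e2 + 0.5 * a * u,
    }
    coords = np.vstack([local] + [anchors_xyz[k] for k in anchors_xyz])
    anchors = {name: spec.beads_per_eye + i for i, name in enumerate(anchors_xyz)}
    return RigidBodySpec("eye", coords, anchors=anchors)


def _arm_cluster_body(name: str, n_beads: int, long_semi: float,
                      tangent: np.ndarray, perp: np.ndarray,
                      extra: dict | None = None) -> RigidBodySpec:
    """A prolate arm sub-cluster with its long axis along the path tangent."""
    e1 = _unit(tangent)
    e2 = _unit(perp - (perp @ e1) * e1)
    e3 = np.cross(e1, e2)
    frame = np.column_stack([e1, e2, e3])
    semi = np.array([long_semi, 8.0, 8.0])
    local = _halton_ellipsoid(n_beads, semi) @ frame.T
    anchors_xyz = {f"{name}_n": -long_semi * e1, f"{name}_c": long_semi * e1}
    if extra:
        anchors_xyz.update(extra)
    coords = np.vstack([local] + [anchors_xyz[k] for k in anchors_xyz])
    anchors = {a: n_beads + i for i, a in enumerate(anchors_xyz)}
    return RigidBodySpec(name, coords, anchors=anchors)


def make_oligomer(spec: SyntheticSpec) -> SyntheticTruth:
    """Build the truth assembly for ``spec`` and realize it with C_n."""
    n = spec.n
    alpha = np.radians(spec.alpha_true)
    if spec.arm_bulge is None:
        import dataclasses
        spec = dataclasses.replace(spec, arm_bulge=40.0 if n == 2 else 0.0)
    if n >= 2:
        ring_r = spec.eye_sep / (2.0 * np.sin(np.pi / n))
        v0 = np.array([ring_r, 0.0, 0.0])
        v_next = ring_r * np.array([np.cos(2 * np.pi / n), np.sin(2 * np.pi / n), 0.0])
        v_prev = ring_r * np.array([np.cos(2 * np.pi / n), -np.sin(2 * np.pi / n), 0.0])
        chord = v_next - v0
        radial = _unit(v0)
    else:
        v0 = np.zeros(3)
        v_next = v0
        v_prev = v0
        chord = np.array([0.0, spec.eye_sep, 0.0])  # nominal direction only
        radial = np.array([1.0, 0.0, 0.0])

    # eye vector: in-plane component along the outward radial, tilted to +z
    u = np.sin(alpha) * radial + np.cos(alpha) * np.array([0.0, 0.0, 1.0])
    e2 = _unit(chord - (chord @ u) * u)
    to_prev = (v_prev - v0) if n >= 2 else -chord
    eye = _eye_body(spec, u, e2, to_prev)
    bodies = [(eye, Placement(np.eye(3), v0))]

    if spec.arm_clusters > 0:

        zhat = np.array([0.0, 0.0, 1.0])

        def path(f: float) -> np.ndarray:
            bow = np.sin(np.pi * f)
            if n >= 3:
                # straight peripheral edge between vertices (trimers and
                # tetramers are polygons with near-straight connections);
                # arm_bulge bows the edge midpoint outward if nonzero
                mid_out = _unit(0.5 * (v0 + v_next))
                return (v0 + f * (v_next - v0) + spec.arm_bulge * bow * mid_out
                        + spec.out_of_plane * bow * zhat)
            if n == 2:
                # curved dimer: the two arms bow out antiparallel, separated
                # by about 2 * arm_bulge across the central opening
                chat = _unit(v_next - v0)
                perp = np.cross(zhat, chat)
                return (v0 + f * (v_next - v0) + spec.arm_bulge * bow * perp
                        + spec.out_of_plane * bow * zhat)
            # monomer: the arm loops back to its own eye (pretzel); eye_sep
            # sets the loop circumference (~2 * eye_sep of arm contour)
            loop_r = spec.eye_sep / np.pi
            center = v0 + loop_r * radial
            phi = np.pi * (1.0 - 2.0 * f)
            return (center + loop_r * (np.cos(phi) * radial
                                       + np.sin(phi) * np.array([0, 1.0, 0]))
                    + spec.out_of_plane * bow * zhat)

        # feasibility: the arm must be able to span the arc between eyes
        ff = np.linspace(0.0, 1.0, 64)
        arc = float(np.sum(np.linalg.norm(np.diff([path(f) for f in ff], axis=0),
                                          axis=1)))
        needed = arc - spec.eye_extent
        capacity = (spec.arm_clusters + 1) * 55.0
        if needed > capacity:
            raise ValueError(
                f"infeasible geometry: arm must span {needed:.0f} A but the "
                f"{spec.arm_clusters}-cluster arm capacity is {capacity:.0f} A")

        fracs = (np.arange(spec.arm_clusters) + 1.0) / (spec.arm_clusters + 1.0)
        seg = np.linalg.norm(path(fracs[0]) - path(0.0))
        # 0.40 leaves clearance between consecutive clusters even on bowed
        # paths where the tangents rotate; the truth model must be clash-free
        long_semi = min(0.40 * seg, 27.5)
        for j, f in enumerate(fracs, start=1):
            center = path(f)
            tangent = path(f + 0.01) - path(f - 0.01)
            extra = None
            if j == 1:
                # C170 sits off the cluster long axis (like the TSR2 cysteine
                # that disulfide-bonds back to the eye), so the tie to C132
                # constrains eye roll about the linker axis
                e1 = _unit(tangent)
                p = u - (u @ e1) * e1
                p = _unit(p) if np.linalg.norm(p) > 1e-9 else np.array([0, 0, 1.0])
                extra = {"C170": -0.5 * long_semi * e1 + 6.0 * p}
            body = _arm_cluster_body(f"arm{j}", spec.beads_per_arm_cluster,
                                     long_semi, tangent, np.array([0, 0, 1.0]),
                                     extra)
            bodies.append((body, Placement(np.eye(3), center)))

    assembly = AssemblySpec(bodies, symmetry_n=n)
    model = apply_cn(assembly)
    centers = np.array([v0 @ _rotz(2 * np.pi * k / n).T for k in range(n)]) \
        if n >= 2 else v0[None, :]
    return SyntheticTruth(model=model, assembly=assembly, spec=spec,
                          eye_centers=centers)


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def reference_restraints(truth: SyntheticTruth, tol_frac: float = 0.2,
                         k: float = 10.0) -> list[Restraint]:
    """Connectivity restraints for refining against a profile simulated from
    ``truth``: eye-arm and arm-arm linkers per protomer, the head-to-tail
    closure to the next protomer's eye, and the disulfide-analogue
    eye-arm1 tie (tolerance 1.5 A like a Cys-Cys pair).

    Targets are the truth model's own anchor distances, so the truth model
    scores zero restraint energy.
    """
    model = truth.model
    n = truth.spec.n
    m = truth.spec.arm_clusters
    pairs = []
    for prot in range(n):
        if m < 1:
            break
        pairs.append((f"eye_out/{prot}", f"arm1_n/{prot}", tol_frac))
        for j in range(1, m):
            pairs.append((f"arm{j}_c/{prot}", f"arm{j + 1}_n/{prot}", tol_frac))
        nxt = (prot + 1) % n
        pairs.append((f"arm{m}_c/{prot}", f"eye_in/{nxt}", tol_frac))
        pairs.append((f"C132/{prot}", f"C170/{prot}", None))  # disulfide-like
    out = []
    for a, b, tf in pairs:
        d = float(np.linalg.norm(model.anchor_xyz(a) - model.anchor_xyz(b)))
        d = max(d, 1.0)
        tol = 1.5 if tf is None else tf * d
        out.append(Restraint(a, b, target=d, tolerance=tol, k=k))
    return out


def simulate_profile(model: BeadModel, qmax: float = 0.30, n_q: int = 150,
                     noise_level: float = 0.01, seed: int = 0,
                     label: str = "synthetic") -> ScatteringProfile:
    """Simulate a noisy SAXS profile of ``model`` on a linear q grid.

    The uncertainty model mimics beamline data (small relative errors at
    low q, growing toward high q):

        sigma(q) = eff * I(0) * (0.001 + 0.02 (q/qmax)^2) + eff * 0.01 * I(q)

    with eff = noise_level, and intensities perturbed by Gaussian(0, sigma).
    With noise_level = 0 the curve is exact and sigma falls back to the
    same formula at eff = 0.01 (a deterministic floor).
    """
    if n_q < 50:
        raise ValueError("n_q must be >= 50")
    q = np.linspace(0.005, qmax, n_q)
    intensity = debye_intensity(model, q, method="auto")
    i0 = float(np.sum(model.weight)) ** 2
    eff = noise_level if noise_level > 0 else 0.01
    sigma = eff * i0 * (0.001 + 0.02 * (q / qmax) ** 2) + eff * 0.01 * np.abs(intensity)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, sigma)
    return ScatteringProfile(q, intensity, sigma, label=label)
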