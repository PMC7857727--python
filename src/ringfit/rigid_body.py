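"""Restrained rigid-body refinement of C_n-symmetric bead assemblies
against a SAXS profile, by Metropolis simulated annealing.

An assembly is one protomer — a list of rigid bodies with placements —
plus a symmetry order n; the realized model applies rotations by 2*pi*k/n
about the z axis (the symmetry axis is always z, with input models
pre-oriented by the caller).  The objective is

    chi2(fit of Debye curve to data) + w_r * restraint_energy
                                     + w_c * clash_energy

with flat-bottom quadratic distance restraints between named anchor beads
and a soft-sphere quadratic clash penalty between beads of different
bodies.  Note the objective is invariant under global rotation about z and
translation along z when n > 1 (scattering and restraints are isometry
invariant); this degeneracy is left in place.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .pair_distribution import DEFAULT_Q_MAX
from .saxs_io import ScatteringProfile
from .scattering_calc import BeadModel, DebyeEvaluator, FitResult, fit_profile

__all__ = ["RigidBodySpec", "Placement", "AssemblySpec", "Restraint",
           "RefineConfig", "RefinementResult", "BatchResult",
           "apply_cn", "penalty_energy", "refine", "run_batch",
           "read_restraints", "linker_restraint"]

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Unresolvable anchors or otherwise inconsistent refinement setup."""


@dataclass
class RigidBodySpec:
    """A rigid body: beads in the body frame plus named local anchors."""

    body_id: str
    coords: np.ndarray  # (m, 3), body frame
    weights: np.ndarray | None = None
    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] < 1:
            raise ValueError("rigid body needs >= 1 bead")
        if self.weights is None:
            self.weights = np.ones(self.coords.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        for name, idx in self.anchors.items():
            if not 0 <= idx < self.coords.shape[0]:
                raise ConfigurationError(f"anchor {name!r} index out of range")


@dataclass
class Placement:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper orthonormal (det = +1)")


@dataclass
class AssemblySpec:
    """One protomer (bodies + placements) and the symmetry order."""

    bodies: list  # of (RigidBodySpec, Placement)
    symmetry_n: int = 1

    def __post_init__(self) -> None:
        if self.symmetry_n < 1:
            raise ValueError("symmetry_n must be >= 1")

    def copy(self) -> "AssemblySpec":
        return AssemblySpec(
            [(spec, Placement(p.rotation.copy(), p.translation.copy()))
             for spec, p in self.bodies],
            self.symmetry_n)


@dataclass
class Restraint:
    """Flat-bottom quadratic distance restraint between protomer-qualified
    anchors: zero inside |d - target| <= tolerance, k*(excess)^2 outside."""

    anchor_a: str
    anchor_b: str
    target: float
    tolerance: float = 0.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.target <= 0 or self.tolerance < 0 or self.k <= 0:
            raise ValueError("require target > 0, tolerance >= 0, k > 0")

    def energy(self, d: float) -> float:
        excess = abs(d - self.target) - self.tolerance
        return self.k * excess**2 if excess > 0 else 0.0


def linker_restraint(anchor_a: str, anchor_b: str, gap_residues: int,
                     k: float = 10.0) -> Restraint:
    """Restraint for a flexible linker of ``gap_residues`` missing residues:
    target 3.8 A (the C-alpha virtual bond) per bond, tolerance 20%."""
    target = 3.8 * (gap_residues + 1)
    return Restraint(anchor_a, anchor_b, target=target, tolerance=0.2 * target, k=k)


def read_restraints(path) -> list[Restraint]:
    """Read a whitespace-delimited restraint table:
    anchor_a anchor_b target tolerance k (comment lines start with '#')."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            a, b, t, tol, k = parts[:5]
            out.append(Restraint(a, b, float(t), float(tol), float(k)))
    return out


def _rz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def apply_cn(assembly: AssemblySpec) -> BeadModel:
    """Realize the protomer and apply C_n rotations about z.

    Beads carry body and protomer labels; every body anchor ``name`` is
    replicated as ``name/k`` for protomer k.
    """
    coords_p = []
    weights_p = []
    body_p = []
    anchors_local = {}
    offset = 0
    for b_idx, (spec, place) in enumerate(assembly.bodies):
        xyz = spec.coords @ place.rotation.T + place.translation
        coords_p.append(xyz)
        weights_p.append(spec.weights)
        body_p.append(np.full(xyz.shape[0], b_idx, dtype=int))
        for name, idx in spec.anchors.items():
            if name in anchors_local:
                raise ConfigurationError(f"duplicate anchor name {name!r} in protomer")
            anchors_local[name] = offset + idx
        offset += xyz.shape[0]
    coords_p = np.vstack(coords_p)
    weights_p = np.concatenate(weights_p)
    body_p = np.concatenate(body_p)

    n = assembly.symmetry_n
    m = coords_p.shape[0]
    coords = np.vstack([coords_p @ _rz(2.0 * np.pi * k / n).T for k in range(n)])
    anchors = {f"{name}/{k}": k * m + idx
               for k in range(n) for name, idx in anchors_local.items()}
    return BeadModel(
        coordinates=coords,
        weight=np.tile(weights_p, n),
        body_id=np.tile(body_p, n),
        protomer_id=np.repeat(np.arange(n), m),
        anchors=anchors,
    )


def penalty_energy(model: BeadModel, restraints: list[Restraint],
                   clash_dist: float = 3.8, k_clash: float = 1.0):
    """Restraint and clash energies of a realized model.

    Returns (restraint_energy, clash_energy, per-restraint table) where the
    table rows are (anchor_a, anchor_b, distance, target, energy).
    """
    table = []
    e_rest = 0.0
    for rst in restraints:
        for name in (rst.anchor_a, rst.anchor_b):
            if name not in model.anchors:
                raise ConfigurationError(f"restraint anchor {name!r} not in model")
        d = float(np.linalg.norm(model.anchor_xyz(rst.anchor_a)
                                 - model.anchor_xyz(rst.anchor_b)))
        e = rst.energy(d)
        e_rest += e
        table.append((rst.anchor_a, rst.anchor_b, d, rst.target, e))

    d = pdist(model.coordinates)
    pair_key = model.body_id.astype(np.int64) * (model.protomer_id.max() + 1) \
        + model.protomer_id.astype(np.int64)
    iu = np.triu_indices(model.n_beads, k=1)
    inter = pair_key[iu[0]] != pair_key[iu[1]]
    close = inter & (d < clash_dist)
    e_clash = float(k_clash * np.sum((clash_dist - d[close]) ** 2))
    return e_rest, e_clash, table


@dataclass
class RefineConfig:
    """Annealing and scoring parameters.

    The start temperature is calibrated so the initial acceptance is about
    50% unless ``temp_init`` is given; the temperature cools geometrically
    by ``cool_factor`` every ``cool_every`` moves and the move sizes shrink
    with it.
    """

    max_moves: int = 20000
    sigma_trans: float = 5.0     # [A]
    sigma_rot: float = 10.0      # [degrees]
    cool_factor: float = 0.97
    cool_every: int = 100
    temp_init: float | None = None
    w_restraint: float = 1.0
    w_clash: float = 1.0
    clash_dist: float = 3.8
    k_clash: float = 1.0
    q_max: float = DEFAULT_Q_MAX
    fit_constant: bool = True
    bin_width: float = 0.5
    move_scale_floor: float = 0.1
    quench_moves: int = 2000  # greedy (T = 0) random polish after cooling
    polish_evals: int = 4000  # budget for the deterministic pattern search
    # greedy pre-relaxation of restraint + clash energy only (no scattering),
    # so annealing starts from a connected, clash-free configuration instead
    # of being dominated by huge linker violations
    pre_relax_moves: int = 3000
    big_rot_prob: float = 0.1   # fraction of rotation moves with uniform angle
    # fraction of moves that rotate the whole protomer rigidly about its
    # centroid by a uniform angle: hops between discrete mirror-like basins
    # (e.g. an arm bowed to the wrong side) that per-body moves cannot reach
    protomer_move_prob: float = 0.05


@dataclass
class RefinementResult:
    assembly: AssemblySpec
    model: BeadModel
    chi2: float
    restraint_energy: float
    clash_energy: float
    total_score: float
    trace: np.ndarray  # best score after each cooling block
    seed: int
    config: RefineConfig
    scale: float = 1.0
    constant: float = 0.0


class _Objective:
    """Scores an assembly against a profile.

    The scoring is equivalent to fit_profile(debye) + penalty_energy but
    avoids rebuilding BeadModel objects inside the annealing loop: bead
    bookkeeping (weights, body/protomer masks, anchor indices, symmetry
    rotations, the sinc matrix) is precomputed once from the start model,
    and each evaluation reduces to coordinate assembly, one pdist shared by
    the Debye histogram and the clash term, and vectorized restraints.
    """

    def __init__(self, profile: ScatteringProfile, restraints, config: RefineConfig,
                 start: AssemblySpec, d_max_hint: float):
        self.profile = profile.restrict(q_max=config.q_max)
        self.restraints = restraints
        self.config = config
        self.evaluator = DebyeEvaluator(self.profile.q, d_max_hint,
                                        bin_width=config.bin_width)
        template = apply_cn(start)
        self.n_beads = template.n_beads
        w = template.weight
        self.self_term = float(np.sum(w**2))
        iu = np.triu_indices(self.n_beads, k=1)
        self.wprod = w[iu[0]] * w[iu[1]]
        key = (template.body_id.astype(np.int64)
               * (int(template.protomer_id.max()) + 1)
               + template.protomer_id.astype(np.int64))
        self.inter_mask = key[iu[0]] != key[iu[1]]
        for rst in restraints:
            for name in (rst.anchor_a, rst.anchor_b):
                if name not in template.anchors:
                    raise ConfigurationError(
                        f"restraint anchor {name!r} not in model")
        self.r_ia = np.array([template.anchors[r.anchor_a] for r in restraints],
                             dtype=int)
        self.r_ib = np.array([template.anchors[r.anchor_b] for r in restraints],
                             dtype=int)
        self.r_target = np.array([r.target for r in restraints])
        self.r_tol = np.array([r.tolerance for r in restraints])
        self.r_k = np.array([r.k for r in restraints])
        n = start.symmetry_n
        self.rz = [_rz(2.0 * np.pi * k / n) for k in range(n)]

    def coordinates(self, assembly: AssemblySpec) -> np.ndarray:
        protomer = np.vstack([spec.coords @ place.rotation.T + place.translation
                              for spec, place in assembly.bodies])
        return np.vstack([protomer @ r.T for r in self.rz])

    def score(self, assembly: AssemblySpec):
        """(total, chi2, restraint_energy, clash_energy) without bead-model
        construction; used inside the annealing loop."""
        coords = self.coordinates(assembly)
        d = pdist(coords)
        if d.max() >= self.evaluator.d_max:
            return np.inf, np.inf, np.inf, np.inf
        calc = self.evaluator.intensity_from_dist(d, self.wprod, self.self_term)
        fit = fit_profile(calc, self.profile, fit_constant=self.config.fit_constant)
        if self.r_ia.size:
            dr = np.linalg.norm(coords[self.r_ia] - coords[self.r_ib], axis=1)
            excess = np.maximum(np.abs(dr - self.r_target) - self.r_tol, 0.0)
            e_rest = float(np.sum(self.r_k * excess**2))
        else:
            e_rest = 0.0
        close = self.inter_mask & (d < self.config.clash_dist)
        e_clash = float(self.config.k_clash
                        * np.sum((self.config.clash_dist - d[close]) ** 2))
        total = (fit.chi2 + self.config.w_restraint * e_rest
                 + self.config.w_clash * e_clash)
        return total, fit.chi2, e_rest, e_clash

    def __call__(self, assembly: AssemblySpec):
        model = apply_cn(assembly)
        try:
            calc = self.evaluator.intensity(model.coordinates, model.weight)
        except ValueError:
            # model drifted beyond the precomputed distance range: reject
            fit = FitResult(1.0, 0.0, np.inf, len(self.profile), np.array([]))
            return np.inf, fit, np.inf, np.inf, model
        fit = fit_profile(calc, self.profile, fit_constant=self.config.fit_constant)
        e_rest, e_clash, _ = penalty_energy(model, self.restraints,
                                            self.config.clash_dist,
                                            self.config.k_clash)
        total = (fit.chi2 + self.config.w_restraint * e_rest
                 + self.config.w_clash * e_clash)
        return total, fit, e_rest, e_clash, model


def _rotate_body(spec, place, rot):
    centroid = spec.coords.mean(axis=0) @ place.rotation.T + place.translation
    return Placement(rot @ place.rotation,
                     rot @ (place.translation - centroid) + centroid)


def _perturb_protomer(assembly: AssemblySpec, rng: np.random.Generator) -> AssemblySpec:
    """Concerted uniform-angle rotation of every body about the protomer
    centroid (a global basin-hopping move)."""
    new = assembly.copy()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, 180.0))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    centroid = np.mean([spec.coords.mean(axis=0) @ p.rotation.T + p.translation
                        for spec, p in new.bodies], axis=0)
    for i, (spec, place) in enumerate(new.bodies):
        new.bodies[i] = (spec, Placement(
            rot @ place.rotation,
            rot @ (place.translation - centroid) + centroid))
    return new


def _perturb(assembly: AssemblySpec, body_index: int, rng: np.random.Generator,
             sigma_trans: float, sigma_rot_deg: float,
             big_rot_prob: float = 0.0) -> AssemblySpec:
    """Copy of ``assembly`` with one body rotated about its centroid and/or
    translated by Gaussian perturbations.

    With probability ``big_rot_prob`` the rotation move draws its angle
    uniformly from (0, 180] degrees instead: domain orientations have
    restraint-compatible alternative basins (e.g. a body rolled about the
    axis through its two linker attachment points), and only large-angle
    proposals hop between them.
    """
    new = assembly.copy()
    spec, place = new.bodies[body_index]
    if rng.random() < 0.5:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        if big_rot_prob > 0 and rng.random() < big_rot_prob:
            angle = np.radians(rng.uniform(0.0, 180.0))
        else:
            angle = np.radians(rng.normal(0.0, sigma_rot_deg))
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        centroid = spec.coords.mean(axis=0) @ place.rotation.T + place.translation
        new_r = rot @ place.rotation
        new_t = rot @ (place.translation - centroid) + centroid
        new.bodies[body_index] = (spec, Placement(new_r, new_t))
    else:
        shift = rng.normal(0.0, sigma_trans, size=3)
        new.bodies[body_index] = (spec, Placement(place.rotation.copy(),
                                                  place.translation + shift))
    return new


def _dmax_hint(assembly: AssemblySpec, margin: float = 200.0) -> float:
    model = apply_cn(assembly)
    return float(pdist(model.coordinates).max()) + margin


def _compass_polish(objective: "_Objective", assembly: AssemblySpec, score: float,
                    max_evals: int = 4000, step_trans: float = 2.0,
                    step_rot_deg: float = 4.0, min_scale: float = 0.02):
    """Deterministic coordinate pattern search over per-body rigid motions.

    Cycles through +-x/y/z translations and +-rotations about the body
    centroid for every body, walking along any improving direction and
    halving the step when a full sweep yields no improvement.  Far more
    efficient at the final-convergence stage than random-walk moves.
    """
    current = assembly.copy()
    n_bodies = len(current.bodies)
    evals = 0
    scale = 1.0
    axes = np.eye(3)
    while scale > min_scale and evals < max_evals:
        improved = False
        for b in range(n_bodies):
            for kind in ("rot", "trans"):
                for ax in range(3):
                    for sign in (1.0, -1.0):
                        while evals < max_evals:
                            spec, place = current.bodies[b]
                            if kind == "trans":
                                newp = Placement(place.rotation.copy(),
                                                 place.translation
                                                 + sign * scale * step_trans * axes[ax])
                            else:
                                ang = np.radians(sign * scale * step_rot_deg)
                                rot = Rotation.from_rotvec(ang * axes[ax]).as_matrix()
                                newp = _rotate_body(spec, place, rot)
                            trial = current.copy()
                            trial.bodies[b] = (spec, newp)
                            s = objective.score(trial)[0]
                            evals += 1
                            if s < score:
                                current, score = trial, s
                                improved = True
                            else:
                                break
        if not improved:
            scale *= 0.5
    return current, score


def refine(start: AssemblySpec, restraints: list[Restraint],
           profile: ScatteringProfile, config: RefineConfig | None = None,
           seed: int = 0) -> RefinementResult:
    """Simulated-annealing refinement of body placements.

    Moves act on the protomer bodies; symmetry copies are regenerated each
    step.  Fully reproducible given ``seed``.
    """
    config = config or RefineConfig()
    rng = np.random.default_rng(seed)
    objective = _Objective(profile, restraints, config, start, _dmax_hint(start))

    current = start.copy()
    score, fit, e_rest, e_clash, model = objective(current)
    if not np.isfinite(score):
        for term, val in (("chi2", fit.chi2), ("restraint", e_rest), ("clash", e_clash)):
            if not np.isfinite(val):
                raise ValueError(f"non-finite {term} term at the start model")
        raise ValueError("non-finite objective at the start model")
    best = (score, current.copy())
    trace = [score]

    n_bodies = len(current.bodies)
    if config.max_moves <= 0:
        return RefinementResult(current, model, fit.chi2, e_rest, e_clash, score,
                                np.asarray(trace), seed, config, fit.scale, fit.constant)

    def penalty_only(assembly: AssemblySpec) -> float:
        coords = objective.coordinates(assembly)
        d = pdist(coords)
        e = 0.0
        if objective.r_ia.size:
            dr = np.linalg.norm(coords[objective.r_ia] - coords[objective.r_ib],
                                axis=1)
            excess = np.maximum(np.abs(dr - objective.r_target) - objective.r_tol,
                                0.0)
            e += float(np.sum(objective.r_k * excess**2))
        close = objective.inter_mask & (d < config.clash_dist)
        e += float(config.k_clash * np.sum((config.clash_dist - d[close]) ** 2))
        return e

    if config.pre_relax_moves > 0:
        e_pen = penalty_only(current)
        for _ in range(config.pre_relax_moves):
            if e_pen <= 0.0:
                break
            # small moves only: the penalty is blind to body roll, and large
            # rotations here would scramble orientations into wrong basins
            trial = _perturb(current, int(rng.integers(n_bodies)), rng,
                             config.sigma_trans, config.sigma_rot)
            e_trial = penalty_only(trial)
            if e_trial < e_pen:
                current, e_pen = trial, e_trial
        score = objective.score(current)[0]
        if score < best[0]:
            best = (score, current.copy())

    # calibrate T0 for ~50% initial acceptance from a sample of trial moves
    if config.temp_init is None:
        deltas = []
        for _ in range(32):
            trial = _perturb(current, int(rng.integers(n_bodies)), rng,
                             config.sigma_trans, config.sigma_rot)
            s_trial = objective.score(trial)[0]
            if s_trial > score:
                deltas.append(s_trial - score)
        t0 = float(np.median(deltas)) / np.log(2.0) if deltas else 1.0
        # cap the start temperature: on the steep chi2 landscapes of
        # low-noise profiles the 50%-acceptance rule yields temperatures
        # that turn the walk into basin roulette and forget good starts
        t0 = float(np.clip(t0, 1e-6, 50.0))
    else:
        t0 = config.temp_init

    temp = t0
    for move in range(config.max_moves):
        frac = max(config.move_scale_floor, np.sqrt(temp / t0))
        if rng.random() < config.protomer_move_prob and n_bodies > 1:
            trial = _perturb_protomer(current, rng)
        else:
            trial = _perturb(current, int(rng.integers(n_bodies)), rng,
                             config.sigma_trans * frac, config.sigma_rot * frac,
                             big_rot_prob=config.big_rot_prob if frac > 0.3 else 0.0)
        s_trial = objective.score(trial)[0]
        delta = s_trial - score
        if delta <= 0 or rng.random() < np.exp(-delta / temp):
            current, score = trial, s_trial
            if score < best[0]:
                best = (score, current.copy())
        if (move + 1) % config.cool_every == 0:
            temp *= config.cool_factor
            trace.append(best[0])

    # greedy quench from the best state: accept improvements only, with the
    # move scale decaying from move_scale_floor down to 0.02 for precision
    current, score = best[1].copy(), best[0]
    for j in range(config.quench_moves):
        decay = (0.02 / config.move_scale_floor) ** (j / max(config.quench_moves - 1, 1))
        qscale = config.move_scale_floor * decay
        trial = _perturb(current, int(rng.integers(n_bodies)), rng,
                         config.sigma_trans * qscale,
                         config.sigma_rot * qscale)
        s_trial = objective.score(trial)[0]
        if s_trial < score:
            current, score = trial, s_trial
    if score < best[0]:
        best = (score, current)

    if config.polish_evals > 0:
        polished, p_score = _compass_polish(objective, best[1], best[0],
                                            max_evals=config.polish_evals)
        if p_score < best[0]:
            best = (p_score, polished)
    trace.append(best[0])

    final = best[1]
    score, fit, e_rest, e_clash, model = objective(final)
    return RefinementResult(final, model, fit.chi2, e_rest, e_clash, score,
                            np.asarray(trace), seed, config, fit.scale, fit.constant)


@dataclass
class BatchResult:
    results: list
    kept: np.ndarray           # runs within the chi2 cutoff
    cluster_labels: np.ndarray  # label per kept run
    representative: int        # index into results
    cluster_sizes: dict


def _anchor_distance_vector(model: BeadModel) -> np.ndarray:
    names = sorted(model.anchors)
    xyz = np.array([model.anchor_xyz(n) for n in names])
    return pdist(xyz)


def randomized_start(start: AssemblySpec, rng: np.random.Generator,
                     max_rot_deg: float = 60.0, max_trans: float = 30.0,
                     clash_dist: float = 3.8, max_tries: int = 50) -> AssemblySpec:
    """Perturb every body by a uniform rotation <= max_rot_deg about its
    centroid and a uniform translation <= max_trans, rejecting clashing
    starts (up to ``max_tries`` attempts)."""
    for _ in range(max_tries):
        new = start.copy()
        for i, (spec, place) in enumerate(new.bodies):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.radians(rng.uniform(0.0, max_rot_deg))
            rot = Rotation.from_rotvec(angle * axis).as_matrix()
            centroid = spec.coords.mean(axis=0) @ place.rotation.T + place.translation
            shift = rng.uniform(-1.0, 1.0, size=3)
            while np.linalg.norm(shift) > 1.0:
                shift = rng.uniform(-1.0, 1.0, size=3)
            new.bodies[i] = (spec, Placement(
                rot @ place.rotation,
                rot @ (place.translation - centroid) + centroid + max_trans * shift))
        _, e_clash, _ = penalty_energy(apply_cn(new), [], clash_dist=clash_dist)
        if e_clash == 0.0:
            return new
    return new  # accept the last attempt rather than fail


def run_batch(start: AssemblySpec, restraints: list[Restraint],
              profile: ScatteringProfile, n_runs: int = 10, seed: int = 0,
              config: RefineConfig | None = None, cluster_cutoff: float = 10.0,
              randomize_starts: bool = True) -> BatchResult:
    """Independent refinements from randomized starts, clustered by the RMSD
    of their anchor-anchor distance vectors (single linkage).

    All runs are clustered; runs with chi2 above twice the best run's chi2
    are excluded from the statistics, and the representative is the medoid
    of the largest cluster among the remaining runs (ties broken by lower
    chi2) -- mirroring the practice of pooling many stochastic refinements
    and discarding those trapped in poorly fitting local minima.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or RefineConfig()
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    results = []
    for i in range(n_runs):
        rng = np.random.default_rng(seeds[i])
        a0 = randomized_start(start, rng, clash_dist=config.clash_dist) \
            if randomize_starts else start
        run_seed = int(seeds[i].generate_state(1)[0] % (2**31))
        results.append(refine(a0, restraints, profile, config, seed=run_seed))

    chi2s = np.array([r.chi2 for r in results])
    kept = np.flatnonzero(chi2s <= 2.0 * chi2s.min())
    if n_runs == 1:
        return BatchResult(results, kept, np.array([1]), 0, {1: 1})

    # all runs are clustered geometrically; the chi2 outlier filter applies
    # to the statistics and to the choice of representative
    vecs = np.array([_anchor_distance_vector(r.model) for r in results])
    rmsd = squareform(np.sqrt(np.mean((vecs[:, None, :] - vecs[None, :, :]) ** 2,
                                      axis=2)), checks=False)
    labels = fcluster(linkage(rmsd, method="single"), t=cluster_cutoff,
                      criterion="distance")
    sizes = {int(lab): int(np.sum(labels == lab)) for lab in np.unique(labels)}
    largest = max(sizes, key=lambda lab: (sizes[lab], -lab))
    members = np.flatnonzero(labels == largest)
    cand = [m for m in members if m in set(kept)] or list(members)
    dmat = squareform(rmsd)[np.ix_(members, members)]
    total = {m: dmat[i].sum() for i, m in enumerate(members)}
    representative = int(min(cand, key=lambda m: (total[m], chi2s[m])))
    return BatchResult(results, kept, labels, representative, sizes)
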