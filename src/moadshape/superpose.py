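"""Rigid-body ("solid-body") maximization of Gaussian overlap volume.

The query shape is moved over a fixed reference shape with a deterministic
step-halving pattern search over the 6 rigid degrees of freedom.  Start
poses come from three families:

* ``com``      — identity rotation, centers of mass superimposed;
* ``random``   — query COM dropped on a randomly chosen reference atom
                 center with a uniform random rotation (seeded);
* ``inertial`` — principal axes of the two shapes' second-moment tensors
                 aligned, in all 4 proper sign-flip combinations.

The optimizer only ever accepts uphill moves, so the final overlap is
never below the starting overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .gaussian_shape import GaussianShape, _cross_overlap
from .transforms import RigidTransform

__all__ = [
    "RigidTransform",
    "ConvergenceSettings",
    "SuperpositionResult",
    "com_align",
    "generate_starts",
    "optimize_overlap",
]


@dataclass(frozen=True)
class ConvergenceSettings:
    """Pattern-search controls.

    ``tol`` is the relative overlap improvement below which a sweep counts
    as converged; translation/rotation steps start at ``trans_step`` (A) and
    ``rot_step`` (rad) and halve down to 1/64 of their initial size before
    the search gives up on finding an uphill move.
    """

    tol: float = 1e-6
    max_iter: int = 200
    trans_step: float = 0.5
    rot_step: float = 0.25
    min_trans_step: float = 0.5 / 64
    min_rot_step: float = 0.25 / 64


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    overlap: float
    tanimoto: float
    start_family: str
    start_index: int
    iterations: int
    converged: bool


def com_align(query: GaussianShape, reference: GaussianShape) -> RigidTransform:
    """Identity rotation, translating the query centroid onto the reference centroid."""
    return RigidTransform(translation=reference.centroid - query.centroid)


def _principal_axes(shape: GaussianShape) -> np.ndarray:
    """Right-handed frame of principal axes, columns ordered by decreasing moment."""
    centered = shape.centers - shape.centroid
    moments = centered.T @ centered / max(len(centered), 1)
    eigval, eigvec = np.linalg.eigh(moments)
    frame = eigvec[:, ::-1]  # descending eigenvalue order
    if np.linalg.det(frame) < 0:
        frame = frame.copy()
        frame[:, 2] *= -1.0
    return frame

# the four proper (det = +1) axis sign flips
_PROPER_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def generate_starts(
    query: GaussianShape,
    reference: GaussianShape,
    mode: str,
    n: int = 8,
    seed: int = 0,
) -> List[RigidTransform]:
    """Start poses for the local optimizer.

    ``random`` draws ``n`` poses (reference atom chosen uniformly, rotation
    uniform on SO(3)), reproducible per seed.  ``inertial`` returns exactly
    4 poses aligning the principal axes with every proper sign combination,
    centers of mass superimposed.
    """
    if mode == "random":
        if n < 1:
            raise ValueError("random mode needs n >= 1")
        rng = np.random.default_rng(seed)
        starts = []
        for _ in range(n):
            target = reference.centers[rng.integers(reference.n_atoms)]
            quat = rng.normal(size=4)
            rotation = Rotation.from_quat(quat / np.linalg.norm(quat))
            translation = target - rotation.apply(query.centroid)
            starts.append(RigidTransform.from_rotation(rotation, translation))
        return starts
    if mode == "inertial":
        frame_q = _principal_axes(query)
        frame_r = _principal_axes(reference)
        starts = []
        for flip in _PROPER_FLIPS:
            rot = Rotation.from_matrix(frame_r @ flip @ frame_q.T)
            translation = reference.centroid - rot.apply(query.centroid)
            starts.append(RigidTransform.from_rotation(rot, translation))
        return starts
    raise ValueError(f"unknown start mode {mode!r} (expected 'random' or 'inertial')")


def optimize_overlap(
    query: GaussianShape,
    reference: GaussianShape,
    start: RigidTransform,
    settings: Optional[ConvergenceSettings] = None,
    start_family: str = "com",
    start_index: int = 0,
) -> SuperpositionResult:
    """Locally maximize overlap_volume(reference, moved query) from ``start``.

    One iteration probes 12 candidate moves (+-step along each translation
    axis; +-step rotations about each axis through the moving query's
    centroid) and accepts the best uphill one.  When no probe improves, the
    steps are halved down to their minimum before declaring convergence, so
    a pose is only accepted as converged when it is a local optimum at the
    finest step resolution (or the sweep gain drops below ``tol``).
    """
    s = settings or ConvergenceSettings()
    qc = query.centers
    qcom = query.centroid

    def objective(matrix: np.ndarray, translation: np.ndarray) -> float:
        moved = qc @ matrix.T + translation
        return _cross_overlap(
            reference.centers, reference.alphas, moved, query.alphas,
            reference.prefactor, query.prefactor,
        )

    matrix = start.matrix
    translation = start.translation.copy()
    current = objective(matrix, translation)
    if not np.isfinite(current):
        raise ArithmeticError(
            f"non-finite overlap at start (family={start_family!r}, index={start_index})"
        )

    axes = np.eye(3)
    step_t, step_r = s.trans_step, s.rot_step
    iterations = 0
    converged = False
    for iterations in range(1, s.max_iter + 1):
        best_val = current
        best_pose = None
        while True:
            center = matrix @ qcom + translation
            for k in range(3):
                for sign in (1.0, -1.0):
                    cand_t = translation + sign * step_t * axes[k]
                    val = objective(matrix, cand_t)
                    if val > best_val:
                        best_val, best_pose = val, (matrix, cand_t)
                    d_rot = Rotation.from_rotvec(sign * step_r * axes[k]).as_matrix()
                    cand_m = d_rot @ matrix
                    cand_t2 = d_rot @ (translation - center) + center
                    val = objective(cand_m, cand_t2)
                    if val > best_val:
                        best_val, best_pose = val, (cand_m, cand_t2)
            if best_pose is not None:
                break
            if step_t <= s.min_trans_step and step_r <= s.min_rot_step:
                break
            step_t = max(step_t / 2.0, s.min_trans_step)
            step_r = max(step_r / 2.0, s.min_rot_step)
        if best_pose is None:
            converged = True
            break
        if not np.isfinite(best_val):
            raise ArithmeticError(
                f"non-finite overlap during ascent (family={start_family!r}, "
                f"index={start_index}, iteration={iterations})"
            )
        gain = (best_val - current) / max(abs(current), 1e-300)
        matrix, translation = best_pose
        current = best_val
        if gain < s.tol:
            converged = True
            break

    transform = RigidTransform.from_matrix(matrix, translation)
    tanimoto = current / (query.self_overlap + reference.self_overlap - current)
    return SuperpositionResult(
        transform=transform,
        overlap=current,
        tanimoto=tanimoto,
        start_family=start_family,
        start_index=start_index,
        iterations=iterations,
        converged=converged,
    )
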