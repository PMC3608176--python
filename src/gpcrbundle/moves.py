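"""Rigid-body helix move set and the greedy acceptance rule.

Each transmembrane helix is treated as a rigid body: a move translates it,
spins it about its own axis, or re-sets its tilt against the membrane
normal, leaving all intra-helix geometry untouched.  Proposals are accepted
only on a strict energy decrease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import perpendicular_vector, rotation_about_axis, rotate_points, unit
from .structure import BackboneStructure, HelixSegment, MembraneFrame

logger = logging.getLogger(__name__)


@dataclass
class MoveRanges:
    """Sampling ranges of the three move types.

    translate_max: per-axis uniform translation bound (Å).
    spin_max: uniform spin bound about the helix axis (degrees).
    tilt_mean / tilt_sd: Gaussian for the target helix tilt against the
    membrane normal (degrees).
    """

    translate_max: float = 5.0
    spin_max: float = 180.0
    tilt_mean: float = 30.0
    tilt_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("translate_max", "spin_max", "tilt_mean", "tilt_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sample_translation(ranges: MoveRanges, rng: np.random.Generator) -> np.ndarray:
    """Independent uniform draws on [-translate_max, +translate_max] per axis."""
    return rng.uniform(-ranges.translate_max, ranges.translate_max, size=3)


def sample_spin(ranges: MoveRanges, rng: np.random.Generator) -> float:
    """Uniform spin angle on [-spin_max, +spin_max] degrees."""
    return float(rng.uniform(-ranges.spin_max, ranges.spin_max))


def sample_tilt(ranges: MoveRanges, rng: np.random.Generator) -> float:
    """Target tilt angle (degrees) drawn from Normal(tilt_mean, tilt_sd^2).

    Folded at zero: a tilt is an unsigned angle between two directions.
    """
    return float(abs(rng.normal(ranges.tilt_mean, ranges.tilt_sd)))


def translate_helix(
    s: BackboneStructure, helix_range: tuple[int, int], delta: np.ndarray
) -> BackboneStructure:
    """Shift all atoms of the residues in ``helix_range`` by ``delta``."""
    lo, hi = helix_range
    if lo < 1 or hi > s.n_residues or lo > hi:
        raise ValueError(f"helix range ({lo},{hi}) out of bounds for n={s.n_residues}")
    out = s.copy()
    out.coords[lo - 1 : hi] += np.asarray(delta, dtype=float)
    return out


def _rotate_segment(
    s: BackboneStructure,
    helix_range: tuple[int, int],
    rot: np.ndarray,
    center: np.ndarray,
) -> BackboneStructure:
    lo, hi = helix_range
    out = s.copy()
    seg = out.coords[lo - 1 : hi]
    out.coords[lo - 1 : hi] = rotate_points(seg, rot, center)
    return out


def spin_helix(
    s: BackboneStructure,
    helix: HelixSegment,
    angle_deg: float,
    max_angle: float = 180.0,
) -> BackboneStructure:
    """Rotate the helix about its own axis through its centroid.

    The axis direction and centroid are preserved; only the azimuthal
    placement of the atoms around the axis changes.
    """
    if abs(angle_deg) > max_angle + 1e-9:
        raise ValueError(f"spin angle {angle_deg} outside [-{max_angle}, {max_angle}]")
    rot = rotation_about_axis(helix.axis, angle_deg)
    return _rotate_segment(s, helix.range, rot, helix.centroid)


def tilt_helix(
    s: BackboneStructure,
    helix: HelixSegment,
    frame: MembraneFrame,
    rng: np.random.Generator,
    ranges: MoveRanges,
) -> tuple[BackboneStructure, float]:
    """Re-set the helix tilt against the membrane normal to a sampled angle.

    The target tilt is drawn from the configured Gaussian.  The helix is
    rotated about an axis through its centroid perpendicular to both its
    current axis and the membrane normal, so the post-move angle between
    helix axis and normal equals the sampled tilt.  The helix axis is first
    sign-aligned with the normal (tilt is measured in [0, 90] territory for
    either chain direction).
    """
    target = sample_tilt(ranges, rng)
    axis = helix.axis if np.dot(helix.axis, frame.normal) >= 0 else -helix.axis
    cos_cur = np.clip(np.dot(axis, frame.normal), -1.0, 1.0)
    current = float(np.degrees(np.arccos(cos_cur)))
    cross = np.cross(frame.normal, axis)
    if np.linalg.norm(cross) < 1e-9:
        # axis coincides with the normal: the tilt direction is undefined,
        # choose it deterministically from the stream
        rot_axis = perpendicular_vector(frame.normal, rng)
    else:
        rot_axis = unit(cross)
    rot = rotation_about_axis(rot_axis, target - current)
    return _rotate_segment(s, helix.range, rot, helix.centroid), target


def greedy_accept(
    current_energy: float, proposed_energy: float, tol: float = 1e-9
) -> bool:
    """Strict greedy rule: accept iff proposed < current; ties rejected.

    ``tol`` guards the tie rejection against floating-point noise: moves
    that leave the energy unchanged analytically (for example a spin that
    no energy term can see) must not be accepted on round-off.  A
    non-finite proposal is rejected and flagged in the log.
    """
    if not np.isfinite(proposed_energy):
        logger.warning("rejecting proposal with non-finite energy %r", proposed_energy)
        return False
    if not np.isfinite(current_energy):
        logger.warning("current energy non-finite (%r); rejecting proposal", current_energy)
        return False
    return proposed_energy < current_energy - tol
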