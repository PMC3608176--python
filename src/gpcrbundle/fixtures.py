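"""Synthetic seven-helix bundles for testing and calibration.

The generators emulate the conserved GPCR architecture — seven ideal
alpha-helices packed on a ring, alternating up/down, connected by short
closed loops, embedded in a membrane slab normal to z.  They provide:

* an ideal bundle whose energy-minimum neighbourhood is known by
  construction,
* controlled rigid-body perturbations with recorded ground truth, and
* complementary template sets (each template near-native on a different
  subset of helices) exercising the multi-template crossing machinery.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import rotation_about_axis, unit
from .loops import (
    ANGLE_N_CA_C,
    BOND_CA_C,
    BOND_N_CA,
    LoopRefineConfig,
    ccd_close,
    close_all_loops,
    connectivity_gap,
    extend_chain,
    place_carbonyl_o,
)
from .packing import PackingParams, calibrate_area_bounds
from .structure import BackboneStructure, MembraneFrame, Topology, fit_helix_axis

PHI_HELIX = -57.0
PSI_HELIX = -47.0


@dataclass
class BundleSpec:
    """Geometry of the synthetic bundle family."""

    n_helices: int = 7
    helix_length: int = 25
    loop_length: int = 6
    ring_radius: float = 12.0
    rise_per_residue: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices != 7:
            raise ValueError("the bundle topology requires exactly 7 helices")
        for name in ("helix_length", "loop_length", "ring_radius", "rise_per_residue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HelixPerturbation:
    """Recorded ground-truth rigid transform applied to one helix.

    Atoms move as x -> R (x - center) + center + translation.
    """

    helix_index: int
    rotation: np.ndarray
    center: np.ndarray
    translation: np.ndarray


def _build_ideal_helix(length: int) -> np.ndarray:
    """(length, 4, 3) ideal alpha-helix backbone starting at the origin."""
    coords = np.zeros((length, 4, 3))
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    # C0 in the xy-plane making the ideal N-CA-C angle
    d = unit(n0 - ca0)
    rot = Rotation.from_rotvec(np.array([0.0, 0.0, 1.0]) * ang).as_matrix()
    coords[0, 0], coords[0, 1] = n0, ca0
    coords[0, 2] = ca0 + BOND_CA_C * (rot @ d)
    coords[0, 3] = place_carbonyl_o(coords[0, 0], coords[0, 1], coords[0, 2], PSI_HELIX)
    if length > 1:
        coords[1:] = extend_chain(
            coords[0, :3], [(PHI_HELIX, PSI_HELIX)] * (length - 1), psi_prev=PSI_HELIX
        )
    return coords


def _orient_helix(
    helix: np.ndarray, target_axis: np.ndarray, target_centroid: np.ndarray
) -> np.ndarray:
    """Rigidly place a helix so its CA principal axis matches target_axis."""
    cas = helix[:, 1, :]
    centroid = cas.mean(axis=0)
    centered = cas - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors([target_axis], [axis])
    rmat = rot.as_matrix()
    return (helix - centroid) @ rmat.T + target_centroid


def make_ideal_bundle(
    spec: BundleSpec | None = None,
) -> tuple[BackboneStructure, Topology, MembraneFrame]:
    """Ideal 7-TM bundle: helices on a ring, antiparallel, loops closed.

    Helix k sits at ring angle 2*pi*k/7 with axis +z for odd-numbered
    helices (1-based) and -z for even ones, CA centroid in the z=0
    midplane.  Loops are grown with extended dihedrals and closed by CCD;
    construction retries a loop with jittered dihedrals until its junction
    gap is below 0.05 Å.
    """
    if spec is None:
        spec = BundleSpec()
    rng = np.random.default_rng(spec.seed)
    L, ll = spec.helix_length, spec.loop_length
    n = 7 * L + 6 * ll
    coords = np.zeros((n, 4, 3))
    template = _build_ideal_helix(L)

    tm_ranges = []
    loop_ranges = []
    pos = 1
    helix_slices = []
    for k in range(7):
        tm_ranges.append((pos, pos + L - 1))
        helix_slices.append((pos - 1, pos + L - 1))
        pos += L
        if k < 6:
            loop_ranges.append((pos, pos + ll - 1))
            pos += ll

    for k in range(7):
        theta = 2.0 * np.pi * k / 7.0
        center = np.array(
            [spec.ring_radius * np.cos(theta), spec.ring_radius * np.sin(theta), 0.0]
        )
        axis = np.array([0.0, 0.0, 1.0 if k % 2 == 0 else -1.0])
        lo, hi = helix_slices[k]
        coords[lo:hi] = _orient_helix(template, axis, center)

    topology = Topology(tm_ranges=tm_ranges, loop_ranges=loop_ranges)
    # grow initial loop conformations from each helix end
    base_phipsi = [(-120.0, 120.0)] * ll
    for j, (lo, hi) in enumerate(loop_ranges):
        prev = coords[lo - 2, :3]
        coords[lo - 1 : hi] = extend_chain(prev, base_phipsi)

    s = BackboneStructure(
        residue_ids=np.arange(1, n + 1), coords=coords, chain_id="A"
    )
    cfg = LoopRefineConfig(max_outer_cycles=40, max_inner_cycles=10, closure_tolerance=0.02)
    for j, (lo, hi) in enumerate(loop_ranges):
        best_gap = np.inf
        best = None
        for _attempt in range(10):
            closed, gap, ok = ccd_close(s, (lo, hi), cfg)
            if gap < best_gap:
                best_gap, best = gap, closed
            if ok:
                break
            jitter = rng.uniform(-60.0, 60.0, size=(ll, 2))
            phipsi = [
                (base_phipsi[i][0] + jitter[i, 0], base_phipsi[i][1] + jitter[i, 1])
                for i in range(ll)
            ]
            s.coords[lo - 1 : hi] = extend_chain(s.coords[lo - 2, :3], phipsi)
        s = best
        if best_gap > 0.05:
            raise RuntimeError(
                f"loop {j + 1} failed to close during construction (gap {best_gap:.3f} Å)"
            )

    mid_z = float(s.ca[topology.tm_indices()][:, 2].mean())
    frame = MembraneFrame(
        normal=np.array([0.0, 0.0, 1.0]), midplane_point=np.array([0.0, 0.0, mid_z])
    )
    return s, topology, frame


def _perturb_helices(
    s: BackboneStructure,
    topology: Topology,
    frame: MembraneFrame,
    bounds: dict[int, tuple[float, float, float]],
    rng: np.random.Generator,
    loop_config: LoopRefineConfig | None = None,
) -> tuple[BackboneStructure, list[HelixPerturbation]]:
    """Apply per-helix uniform rigid perturbations, then re-close loops.

    ``bounds[h] = (max_translation, max_spin_deg, max_tilt_deg)`` for
    1-based helix index h.
    """
    out = s.copy()
    records = []
    for h in range(1, 8):
        mt, ms, mtl = bounds.get(h, (0.0, 0.0, 0.0))
        seg = fit_helix_axis(out, topology.tm_ranges[h - 1], index=h)
        spin = rng.uniform(-ms, ms) if ms > 0 else 0.0
        tilt = rng.uniform(-mtl, mtl) if mtl > 0 else 0.0
        delta = rng.uniform(-mt, mt, size=3) if mt > 0 else np.zeros(3)
        r_spin = rotation_about_axis(seg.axis, spin)
        cross = np.cross(frame.normal, seg.axis)
        if np.linalg.norm(cross) < 1e-9:
            tilt_axis = unit(np.cross(frame.normal, np.array([1.0, 0.3, 0.2])))
        else:
            tilt_axis = unit(cross)
        r_tilt = rotation_about_axis(tilt_axis, tilt)
        rot = r_tilt @ r_spin
        lo, hi = topology.tm_ranges[h - 1]
        seg_coords = out.coords[lo - 1 : hi]
        out.coords[lo - 1 : hi] = (seg_coords - seg.centroid) @ rot.T + seg.centroid + delta
        records.append(
            HelixPerturbation(
                helix_index=h, rotation=rot, center=seg.centroid, translation=delta
            )
        )
    out = close_all_loops(out, topology, loop_config)
    return out, records


def perturb_bundle(
    s: BackboneStructure,
    topology: Topology,
    frame: MembraneFrame,
    max_translation: float,
    max_spin: float,
    max_tilt: float,
    rng: np.random.Generator,
    loop_config: LoopRefineConfig | None = None,
) -> tuple[BackboneStructure, list[HelixPerturbation]]:
    """Independent random rigid perturbation of every helix, loops re-closed."""
    bounds = {h: (max_translation, max_spin, max_tilt) for h in range(1, 8)}
    return _perturb_helices(s, topology, frame, bounds, rng, loop_config)


def apply_perturbations(
    s: BackboneStructure,
    topology: Topology,
    records: list[HelixPerturbation],
    loop_config: LoopRefineConfig | None = None,
) -> BackboneStructure:
    """Replay recorded helix perturbations on a structure, then close loops."""
    out = s.copy()
    for rec in records:
        lo, hi = topology.tm_ranges[rec.helix_index - 1]
        seg = out.coords[lo - 1 : hi]
        out.coords[lo - 1 : hi] = (
            (seg - rec.center) @ rec.rotation.T + rec.center + rec.translation
        )
    return close_all_loops(out, topology, loop_config)


LIGHT_NOISE = (0.3, 5.0, 2.0)
HEAVY_SPIN = 60.0
HEAVY_TILT = 15.0


def make_complementary_templates(
    s: BackboneStructure,
    topology: Topology,
    frame: MembraneFrame,
    split: list[list[int]],
    noise_high: float,
    rng: np.random.Generator,
    loop_config: LoopRefineConfig | None = None,
) -> list[BackboneStructure]:
    """Templates that are individually wrong somewhere, jointly correct.

    ``split`` partitions helices 1..7; template k keeps the helices of
    subset k near-native (light noise) and heavily perturbs the rest
    (``noise_high`` Å translations plus large spin/tilt).
    """
    flat = sorted(h for subset in split for h in subset)
    if flat != list(range(1, 8)):
        raise ValueError(f"split must partition helices 1..7, got {split}")
    templates = []
    for subset in split:
        bounds = {
            h: (LIGHT_NOISE if h in subset else (noise_high, HEAVY_SPIN, HEAVY_TILT))
            for h in range(1, 8)
        }
        t, _ = _perturb_helices(s, topology, frame, bounds, rng, loop_config)
        templates.append(t)
    return templates


@lru_cache(maxsize=8)
def _cached_family_bounds(
    helix_length: int, loop_length: int, ring_radius: float, rise: float
) -> tuple[float, float]:
    refs = []
    for factor in (0.875, 1.125):
        spec = BundleSpec(
            helix_length=helix_length,
            loop_length=loop_length,
            ring_radius=ring_radius * factor,
            rise_per_residue=rise,
        )
        refs.append(make_ideal_bundle(spec))
    params = calibrate_area_bounds([(s, t, f) for s, t, f in refs], weight=1.0)
    return params.s_min, params.s_max


def default_packing_params(
    spec: BundleSpec | None = None, weight: float = 100.0
) -> PackingParams:
    """Area band calibrated from the synthetic ideal-bundle family.

    References are ideal bundles at ring radii 12.5% below and above the
    spec's radius, bracketing realistic bundle tightness; results are
    cached per family geometry.
    """
    if spec is None:
        spec = BundleSpec()
    s_min, s_max = _cached_family_bounds(
        spec.helix_length, spec.loop_length, spec.ring_radius, spec.rise_per_residue
    )
    return PackingParams(s_min=s_min, s_max=s_max, weight=weight)


@lru_cache(maxsize=16)
def _helix_half_span(length: int) -> float:
    """Half-extent of the built ideal helix along its own axis (Å).

    Measured from the actual phi/psi construction rather than assumed from
    a nominal rise: ideal (-57, -47) geometry gives ~1.56 Å per residue.
    """
    helix = _build_ideal_helix(length)
    cas = helix[:, 1, :]
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid, full_matrices=False)
    proj = (cas - centroid) @ vt[0]
    return float((proj.max() - proj.min()) / 2.0)


def default_membrane_params(spec: BundleSpec | None = None, **overrides):
    """Surrogate membrane parameters scaled to a bundle family's geometry.

    The contact wells follow the ring chords (2 r sin(k pi/7)), the
    anchoring height follows the measured helix half-span, and the slab
    hugs the helix extent.  With the default spec this reproduces the
    class defaults.
    """
    from .packing import MembraneScoreParams

    if spec is None:
        spec = BundleSpec()
    half_span = _helix_half_span(spec.helix_length)
    params = dict(
        d_contact=round(2 * spec.ring_radius * np.sin(np.pi / 7), 1),
        d_contact2=round(2 * spec.ring_radius * np.sin(2 * np.pi / 7), 1),
        z_anchor=round(half_span, 1),
        half_thickness=round(half_span + 0.5, 1),
    )
    params.update(overrides)
    return MembraneScoreParams(**params)


def default_energy_model(
    s: BackboneStructure,
    topology: Topology,
    frame: MembraneFrame | None = None,
    spec: BundleSpec | None = None,
):
    """Energy model with family-calibrated area band and membrane params."""
    from .packing import EnergyModel

    return EnergyModel(
        topology=topology,
        packing=default_packing_params(spec),
        frame=frame,
        membrane=default_membrane_params(spec),
    )


def bundle_gaps(s: BackboneStructure, topology: Topology) -> list[float]:
    """Junction gaps at every helix-loop junction of the chain."""
    gaps = []
    for lo, hi in topology.loop_ranges:
        if lo > 1:
            gaps.append(connectivity_gap(s, lo - 1))
        if hi < s.n_residues:
            gaps.append(connectivity_gap(s, hi))
    return gaps
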