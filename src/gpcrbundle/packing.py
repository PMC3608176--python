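"""Bundle-packing energy over membrane-plane projection geometry.

The seven helix axes are intersected with the membrane midplane; the seven
intersection points, together with their centroid O, define a closed fan of
seven triangles (O, p_i, p_{i+1}) following the TM1..TM7 sequence order
with wraparound.  The summed triangle area S measures how tightly the
bundle is packed, and the packing term is a piecewise quadratic penalty

    E' = ((S - S_min)/S_min)^2   if S < S_min   (too tight)
       = 0                       if S_min <= S <= S_max
       = ((S - S_max)/S_max)^2   if S > S_max   (too loose)

where [S_min, S_max] is the area band observed in a reference set of known
bundles.  E' supplements a coarse surrogate membrane score — spherocylinder
helix-helix sterics, a membrane-slab depth term, helix-packing contact
wells and interface anchoring — standing in for a full membrane energy
function, which is outside the scope of this package.  Every surrogate
term is deliberately invariant under a spin of a helix about its own axis:
a backbone-only score has no physical basis for ranking spin phase, and a
term that couples to it only through noise would let the greedy search
randomise helix phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import (
    BackboneStructure,
    HelixSegment,
    MembraneFrame,
    Topology,
    derive_membrane_frame,
    fit_all_helices,
)


def _segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> float:
    """Minimum distance between 3-D line segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    c = float(d1 @ r)
    b = float(d1 @ d2)
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-12 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


@dataclass
class PackingParams:
    """Area band [s_min, s_max] in Å² and the weight of E' in the total."""

    s_min: float
    s_max: float
    weight: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.s_min < self.s_max):
            raise ValueError(
                f"invalid area bounds: require 0 < s_min < s_max, got "
                f"({self.s_min}, {self.s_max})"
            )
        if self.weight < 0:
            raise ValueError("packing weight must be >= 0")


@dataclass
class MembraneScoreParams:
    """Parameters of the surrogate membrane score.

    d_clash / clash_model: steric model.  The default "cylinder" model
    treats each helix as a rigid spherocylinder along its fitted axis and
    penalises pairs of helices whose axis segments approach below
    d_clash_cyl; it is exactly invariant under a spin of a helix about
    its own axis, which a backbone-only score cannot meaningfully rank
    anyway.  The "ca" model is a CA-CA soft sphere at d_clash over
    residue pairs at least min_sequence_separation apart in sequence
    (restricted to TM residues when clash_region="tm" — loop positions
    are stale while helices move and are restored geometrically by
    closure, so they should not steer helix placement).
    half_thickness: membrane slab half-width (Å); TM-residue CAs farther
    than this from the midplane are penalised quadratically.
    d_contact / d_contact2 / contact_slack: helix-packing contact wells
    (Å) on first- and second-neighbour centroid separations around the
    seven-ring (TM1-TM2, ..., TM7-TM1 and TM1-TM3, ...).  Separations
    outside d ± slack are penalised quadratically.  Together the two
    shells encode the conserved near-regular packing geometry of the
    7-TM ring — the coarse stand-in for the attractive environment/pair
    terms of a full membrane potential, without which a repulsion-only
    score would let the ring drift apart, buckle or pucker.  The defaults
    describe a tightly packed ring of circumradius ~12 Å; calibrate them
    from reference bundles for other families.
    z_anchor / anchor_slack / anchor_weight: interface anchoring (Å).
    The two ends of each helix (axis-projected, hence spin-invariant) are
    pulled to |z| = z_anchor — the membrane interfaces, emulating the
    aromatic-belt anchoring of real TM helices; deviations beyond the
    slack are penalised quadratically.  This is what makes over-tilted or
    vertically slipped helices expensive for a backbone-only score.
    """

    clash_model: str = "cylinder"
    d_clash: float = 4.0
    d_clash_cyl: float = 9.0
    half_thickness: float = 19.2
    d_contact: float = 10.4
    d_contact2: float = 18.8
    contact_slack: float = 0.5
    z_anchor: float = 18.7
    anchor_slack: float = 0.75
    clash_weight: float = 1.0
    depth_weight: float = 1.0
    cohesion_weight: float = 1.0
    anchor_weight: float = 8.0
    min_sequence_separation: int = 4
    clash_region: str = "tm"


@dataclass
class PackingGeometry:
    """Midplane projection geometry: points p1..p7, center O, areas S1..S7."""

    intersections: np.ndarray
    center: np.ndarray
    areas: np.ndarray
    total_area: float


@dataclass
class EnergyReport:
    """Energy breakdown: total = surrogate_membrane + weight * E'."""

    total: float
    surrogate_membrane: float
    packing: float
    total_area: float = float("nan")


def membrane_intersections(
    helices: list[HelixSegment], frame: MembraneFrame
) -> np.ndarray:
    """Intersect each helix axis line with the membrane midplane.

    The line through the helix centroid along its axis meets the plane at
    centroid + t*axis with t = ((midplane_point - centroid)·normal)/(axis·normal).
    """
    pts = []
    for h in helices:
        denom = float(np.dot(h.axis, frame.normal))
        if abs(denom) <= 1e-6:
            raise ValueError(
                f"degenerate intersection: helix {h.index} axis parallel to membrane plane"
            )
        t = float(np.dot(frame.midplane_point - h.centroid, frame.normal)) / denom
        pts.append(h.centroid + t * h.axis)
    return np.asarray(pts)


def packing_areas(points: np.ndarray) -> PackingGeometry:
    """Triangle-fan areas of the seven midplane intersection points.

    O is the centroid of the points; S_i is the area of the triangle
    (O, p_i, p_{i+1}) with p_8 = p_1 (adjacency in TM sequence order).
    Coincident points yield zero areas rather than an error: the packing
    term penalises the degenerate bundle.
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (7, 3):
        raise ValueError(f"expected 7 midplane points, got shape {points.shape}")
    center = points.mean(axis=0)
    v = points - center
    v_next = np.roll(v, -1, axis=0)
    areas = 0.5 * np.linalg.norm(np.cross(v, v_next), axis=1)
    return PackingGeometry(
        intersections=points,
        center=center,
        areas=areas,
        total_area=float(areas.sum()),
    )


def packing_energy_term(S: float, params: PackingParams) -> float:
    """Piecewise quadratic penalty on the total projected area S (Å²)."""
    if S < 0:
        raise ValueError(f"total area must be non-negative, got {S}")
    if S < params.s_min:
        return ((S - params.s_min) / params.s_min) ** 2
    if S > params.s_max:
        return ((S - params.s_max) / params.s_max) ** 2
    return 0.0


class BundleAxes:
    """Per-helix axis geometry of a pose, computed in one pass.

    axes/centroids are (7, 3); seg_lo/seg_hi are the axis segment end
    points clipped to the CA extent of each helix (spin-invariant).
    """

    __slots__ = ("axes", "centroids", "seg_lo", "seg_hi", "projections")

    def __init__(self, ca: np.ndarray, topology: Topology):
        lengths = {b - a for a, b in topology.tm_ranges}
        blocks = [ca[a - 1 : b] for a, b in topology.tm_ranges]
        if len(lengths) == 1:
            stack = np.stack(blocks)  # (7, L, 3)
            centroids = stack.mean(axis=1)
            centered = stack - centroids[:, None, :]
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axes = vt[:, 0, :]
            proj = np.einsum("hlk,hk->hl", centered, axes)
        else:
            centroids, axes, proj = [], [], []
            for cas in blocks:
                c = cas.mean(axis=0)
                _, _, vt = np.linalg.svd(cas - c, full_matrices=False)
                centroids.append(c)
                axes.append(vt[0])
                proj.append((cas - c) @ vt[0])
            centroids = np.array(centroids)
            axes = np.array(axes)
        # orient N -> C
        flip = np.array(
            [1.0 if p[-1] >= p[0] else -1.0 for p in proj]
        )
        axes = axes * flip[:, None]
        proj = [p * f for p, f in zip(proj, flip)]
        self.axes = axes
        self.centroids = centroids
        self.projections = proj
        lo = np.array([p.min() for p in proj])
        hi = np.array([p.max() for p in proj])
        self.seg_lo = centroids + lo[:, None] * axes
        self.seg_hi = centroids + hi[:, None] * axes

    def helix_segments(self, topology: Topology) -> list[HelixSegment]:
        return [
            HelixSegment(
                index=i + 1,
                range=topology.tm_ranges[i],
                axis=self.axes[i] / np.linalg.norm(self.axes[i]),
                centroid=self.centroids[i],
            )
            for i in range(len(topology.tm_ranges))
        ]


def surrogate_membrane_score(
    s: BackboneStructure,
    topology: Topology,
    frame: MembraneFrame,
    params: MembraneScoreParams | None = None,
    bundle_axes: BundleAxes | None = None,
) -> float:
    """Coarse membrane score: sterics + depth + packing wells + anchoring.

    clash (cylinder model) = sum over helix pairs of
    max(0, d_clash_cyl - segment distance)^2 on the fitted axis segments
    (CA soft spheres in the "ca" model); depth = sum over axis-projected
    TM-residue positions of max(0, |z| - half_thickness)^2 with z the
    signed distance from the midplane along the normal; cohesion = contact
    wells on first- and second-neighbour helix centroid separations;
    anchor = interface anchoring of the axis segment ends.  Deterministic
    for fixed input.
    """
    if params is None:
        params = MembraneScoreParams()
    ca = s.ca
    n = len(ca)
    geom = bundle_axes if bundle_axes is not None else BundleAxes(ca, topology)
    if params.clash_model == "cylinder":
        clash = 0.0
        for i in range(7):
            for j in range(i + 1, 7):
                dist = _segment_distance(
                    geom.seg_lo[i], geom.seg_hi[i], geom.seg_lo[j], geom.seg_hi[j]
                )
                clash += max(0.0, params.d_clash_cyl - dist) ** 2
    elif params.clash_model == "ca":
        d = squareform(pdist(ca))
        ii, jj = np.triu_indices(n, k=params.min_sequence_separation)
        if params.clash_region == "tm":
            tm_mask = np.zeros(n, dtype=bool)
            tm_mask[topology.tm_indices()] = True
            keep = tm_mask[ii] & tm_mask[jj]
            ii, jj = ii[keep], jj[keep]
        elif params.clash_region != "all":
            raise ValueError(
                f"clash_region must be 'tm' or 'all', got {params.clash_region!r}"
            )
        overlap = np.maximum(0.0, params.d_clash - d[ii, jj])
        clash = float(np.sum(overlap**2))
    else:
        raise ValueError(
            f"clash_model must be 'cylinder' or 'ca', got {params.clash_model!r}"
        )
    # depth over axis-projected residue positions (spin-invariant): the
    # helix body must stay inside the membrane slab
    depth = 0.0
    cz = (geom.centroids - frame.midplane_point) @ frame.normal
    az = geom.axes @ frame.normal
    for k, proj in enumerate(geom.projections):
        z = cz[k] + proj * az[k]
        excess = np.maximum(0.0, np.abs(z) - params.half_thickness)
        depth += float(np.sum(excess**2))
    centroids = geom.centroids
    cohesion = 0.0
    for shell, target in ((1, params.d_contact), (2, params.d_contact2)):
        sep = np.linalg.norm(centroids - np.roll(centroids, -shell, axis=0), axis=1)
        stretch = np.maximum(0.0, np.abs(sep - target) - params.contact_slack)
        cohesion += float(np.sum(stretch**2))
    ends = np.concatenate([geom.seg_lo, geom.seg_hi])
    z_ends = np.abs((ends - frame.midplane_point) @ frame.normal)
    off = np.maximum(0.0, np.abs(z_ends - params.z_anchor) - params.anchor_slack)
    anchor = float(np.sum(off**2))
    return (
        params.clash_weight * clash
        + params.depth_weight * depth
        + params.cohesion_weight * cohesion
        + params.anchor_weight * anchor
    )


def total_energy(
    s: BackboneStructure,
    topology: Topology,
    frame: MembraneFrame | None,
    params: PackingParams,
    membrane_params: MembraneScoreParams | None = None,
) -> EnergyReport:
    """Full pose energy: surrogate membrane score plus weighted E'."""
    if frame is None:
        frame = derive_membrane_frame(s, topology)
    axes = BundleAxes(s.ca, topology)
    helices = axes.helix_segments(topology)
    geom = packing_areas(membrane_intersections(helices, frame))
    e_prime = packing_energy_term(geom.total_area, params)
    surrogate = surrogate_membrane_score(
        s, topology, frame, membrane_params, bundle_axes=axes
    )
    packing = params.weight * e_prime
    return EnergyReport(
        total=surrogate + packing,
        surrogate_membrane=surrogate,
        packing=packing,
        total_area=geom.total_area,
    )


def bundle_total_area(
    s: BackboneStructure, topology: Topology, frame: MembraneFrame | None = None
) -> float:
    """Total projected triangle area S of a pose (Å²)."""
    if frame is None:
        frame = derive_membrane_frame(s, topology)
    helices = fit_all_helices(s, topology)
    return packing_areas(membrane_intersections(helices, frame)).total_area


def calibrate_area_bounds(
    reference_bundles: list[tuple[BackboneStructure, Topology, MembraneFrame | None]],
    weight: float = 100.0,
) -> PackingParams:
    """Set [s_min, s_max] to the min/max total area over reference bundles."""
    if len(reference_bundles) < 2:
        raise ValueError("calibration requires at least 2 reference bundles")
    areas = [bundle_total_area(s, topo, frame) for s, topo, frame in reference_bundles]
    s_min, s_max = min(areas), max(areas)
    if not s_min < s_max:
        raise ValueError(f"degenerate bounds (s_min = s_max = {s_min})")
    return PackingParams(s_min=s_min, s_max=s_max, weight=weight)


@dataclass
class EnergyModel:
    """Bound evaluation context: topology, membrane frame and parameters.

    With ``frame=None`` the membrane frame is re-derived from the pose on
    every evaluation, so the score stays invariant under rigid motions of
    the whole bundle.
    """

    topology: Topology
    packing: PackingParams
    frame: MembraneFrame | None = None
    membrane: MembraneScoreParams = field(default_factory=MembraneScoreParams)

    def evaluate(self, s: BackboneStructure) -> EnergyReport:
        return total_energy(s, self.topology, self.frame, self.packing, self.membrane)
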