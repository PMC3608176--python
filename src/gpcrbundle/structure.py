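"""Backbone structure model: PDB I/O, topology, helix axes, superposition.

A pose is the full-chain backbone (N, CA, C, O per residue).  Helices are
treated as rigid bodies elsewhere in the package; here we only provide the
representation, geometry read-outs (helix axis, membrane frame) and the
CA-based superposition/RMSD evaluation used to score models against a
native structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates for a single chain.

    ``residue_ids`` are normalised to contiguous ``1..n`` on construction
    from a file; the author numbering is kept in ``original_ids`` and used
    again on output.  ``coords`` has shape (n, 4, 3) ordered N, CA, C, O.
    """

    residue_ids: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"
    original_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.residue_ids)
        if n == 0:
            raise ValueError("no residues")
        if self.coords.shape != (n, 4, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} residues x 4 atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        diffs = np.diff(self.residue_ids)
        if np.any(diffs <= 0):
            raise ValueError("residue_ids must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def ca(self) -> np.ndarray:
        """(n, 3) alpha-carbon coordinates."""
        return self.coords[:, 1, :]

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(
            residue_ids=self.residue_ids.copy(),
            coords=self.coords.copy(),
            chain_id=self.chain_id,
            original_ids=None if self.original_ids is None else self.original_ids.copy(),
        )

    def slice_coords(self, rng: tuple[int, int]) -> np.ndarray:
        """Coordinates of the 1-based inclusive residue range as a view."""
        lo, hi = rng
        return self.coords[lo - 1 : hi]


@dataclass
class Topology:
    """Partition of the chain into 7 TM helix ranges and loop ranges.

    Ranges are 1-based inclusive ``(start, end)`` tuples.  Loop ranges cover
    everything the helices do not: the N-terminal tail (if any), the six
    inter-helix loops, and the C-terminal tail (if any).
    """

    tm_ranges: list[tuple[int, int]]
    loop_ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tm_ranges = [(int(a), int(b)) for a, b in self.tm_ranges]
        self.loop_ranges = [(int(a), int(b)) for a, b in self.loop_ranges]
        if len(self.tm_ranges) != 7:
            raise ValueError(f"expected 7 TM ranges, got {len(self.tm_ranges)}")
        for i, (a, b) in enumerate(self.tm_ranges, start=1):
            if b - a + 1 < 5:
                raise ValueError(f"TM{i} range ({a},{b}) shorter than 5 residues")
        allr = sorted(self.tm_ranges + self.loop_ranges)
        for (a1, b1), (a2, b2) in zip(allr, allr[1:]):
            if a2 <= b1:
                raise ValueError("topology ranges overlap")

    @property
    def n_residues(self) -> int:
        return max(b for _, b in self.tm_ranges + self.loop_ranges)

    def validate_coverage(self, n: int) -> None:
        """Check that TM and loop ranges jointly cover residues 1..n."""
        covered = np.zeros(n, dtype=bool)
        for a, b in self.tm_ranges + self.loop_ranges:
            if a < 1 or b > n:
                raise ValueError(f"range ({a},{b}) outside chain 1..{n}")
            covered[a - 1 : b] = True
        if not covered.all():
            missing = np.flatnonzero(~covered) + 1
            raise ValueError(f"residues not covered by topology: {missing[:5].tolist()}...")

    def tm_indices(self) -> np.ndarray:
        """0-based residue indices of the union of the 7 helix ranges."""
        return np.concatenate(
            [np.arange(a - 1, b) for a, b in self.tm_ranges]
        )

    def loop_indices(self) -> np.ndarray:
        if not self.loop_ranges:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(a - 1, b) for a, b in self.loop_ranges])

    def loop_kind(self, loop_index: int) -> str:
        """Classify a loop as 'nterm', 'cterm' or 'internal'."""
        a, b = self.loop_ranges[loop_index]
        first_tm = min(s for s, _ in self.tm_ranges)
        last_tm = max(e for _, e in self.tm_ranges)
        if b < first_tm:
            return "nterm"
        if a > last_tm:
            return "cterm"
        return "internal"

    def to_dict(self) -> dict:
        return {
            "tm_ranges": [list(r) for r in self.tm_ranges],
            "loop_ranges": [list(r) for r in self.loop_ranges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            tm_ranges=[tuple(r) for r in d["tm_ranges"]],
            loop_ranges=[tuple(r) for r in d.get("loop_ranges", [])],
        )


@dataclass
class HelixSegment:
    """A fitted helix: 1..7 index, residue range, unit axis (N→C), centroid."""

    index: int
    range: tuple[int, int]
    axis: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("helix axis must be unit length")


@dataclass
class MembraneFrame:
    """Membrane midplane: a point on the plane and the unit normal."""

    normal: np.ndarray
    midplane_point: np.ndarray

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.midplane_point = np.asarray(self.midplane_point, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be unit length")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def read_pdb_backbone(path: str | Path, chain: str = "A") -> BackboneStructure:
    """Read the N/CA/C/O backbone of one chain from a PDB file.

    Residues with insertion codes are rejected (determinism); for altloc
    duplicates the first location is kept.  A residue missing any of the
    four backbone atoms is an error.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ValueError(f"chain not found: {chain!r}")
    ids = []
    coords = []
    for res in ch:
        if res.het_flag == "H":
            continue
        if res.seqid.icode not in ("", " ", "\x00"):
            raise ValueError(
                f"insertion codes are not supported (residue {res.seqid.num}{res.seqid.icode})"
            )
        pos = {}
        for atom in res:
            if atom.name in BACKBONE_ATOMS and atom.name not in pos:
                pos[atom.name] = [atom.pos.x, atom.pos.y, atom.pos.z]
        missing = [a for a in BACKBONE_ATOMS if a not in pos]
        if missing:
            raise ValueError(
                f"incomplete residue {res.seqid.num}: missing {','.join(missing)}"
            )
        ids.append(res.seqid.num)
        coords.append([pos[a] for a in BACKBONE_ATOMS])
    if not ids:
        raise ValueError(f"chain {chain!r} contains no complete backbone residues")
    original = np.asarray(ids, dtype=int)
    n = len(ids)
    return BackboneStructure(
        residue_ids=np.arange(1, n + 1),
        coords=np.asarray(coords, dtype=float),
        chain_id=chain,
        original_ids=original,
    )


def write_pdb_backbone(s: BackboneStructure, path: str | Path) -> None:
    """Write standard ATOM records (N, CA, C, O per residue) to ``path``."""
    s.validate()
    st = gemmi.Structure()
    st.name = "gpcrbundle"
    model = gemmi.Model("1")
    ch = gemmi.Chain(s.chain_id)
    out_ids = s.original_ids if s.original_ids is not None else s.residue_ids
    for i in range(s.n_residues):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(out_ids[i]), " ")
        for j, name in enumerate(BACKBONE_ATOMS):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            x, y, z = s.coords[i, j]
            atom.pos = gemmi.Position(round(x, 3), round(y, 3), round(z, 3))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def fit_helix_axis(
    s: BackboneStructure, rng: tuple[int, int], index: int = 0
) -> HelixSegment:
    """Fit a helix axis as the dominant principal direction of its CAs.

    The sign is fixed so the axis points from the N- toward the C-terminal
    end of the segment.
    """
    lo, hi = rng
    if hi - lo + 1 < 5:
        raise ValueError(f"degenerate helix: range ({lo},{hi}) shorter than 5 residues")
    cas = s.ca[lo - 1 : hi]
    centroid = cas.mean(axis=0)
    centered = cas - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)
    return HelixSegment(index=index, range=(lo, hi), axis=axis, centroid=centroid)


def fit_all_helices(s: BackboneStructure, topology: Topology) -> list[HelixSegment]:
    return [
        fit_helix_axis(s, rng, index=i + 1) for i, rng in enumerate(topology.tm_ranges)
    ]


def derive_membrane_frame(s: BackboneStructure, topology: Topology) -> MembraneFrame:
    """Default membrane frame when none is supplied.

    Normal = mean of the 7 helix axis directions after sign-alignment to the
    first axis; midplane through the centroid of all TM CAs.
    """
    helices = fit_all_helices(s, topology)
    ref = helices[0].axis
    axes = np.array([h.axis if np.dot(h.axis, ref) >= 0 else -h.axis for h in helices])
    normal = axes.mean(axis=0)
    normal = normal / np.linalg.norm(normal)
    midpoint = s.ca[topology.tm_indices()].mean(axis=0)
    return MembraneFrame(normal=normal, midplane_point=midpoint)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimising
    ||R·mobile + t − reference|| together with the post-fit RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points of dimension 3")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    fitted = mobile @ rmat.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd)


def region_rmsd(
    model: BackboneStructure,
    native: BackboneStructure,
    region: str,
    topology: Topology,
) -> float:
    """CA RMSD after superposition restricted to a region.

    ``region`` is one of ``"TM"`` (union of the 7 helices), ``"FL"``
    (full length) or ``"loops"`` (union of loop ranges).  CA-only by
    convention throughout the package.
    """
    if model.n_residues != native.n_residues:
        raise ValueError(
            f"topology mismatch: model has {model.n_residues} residues, "
            f"native has {native.n_residues}"
        )
    topology.validate_coverage(model.n_residues)
    if region == "TM":
        idx = topology.tm_indices()
    elif region == "FL":
        idx = np.arange(model.n_residues)
    elif region == "loops":
        idx = topology.loop_indices()
        if idx.size == 0:
            raise ValueError("topology has no loop ranges")
    else:
        raise ValueError(f"unknown region {region!r} (expected TM, FL or loops)")
    return kabsch_superpose(model.ca[idx], native.ca[idx]).rmsd
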