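"""Binding-patch classification of docked poses.

Ketoreductases of type II polyketide synthases present two entrances to
the substrate channel: a "front patch" of arginines (R38, R65, R93 in
ActKR numbering) that binds the phosphate of the phosphopantetheine arm,
and a "back patch" of positive/amidic residues (Q149, R220, N260).
Docked poses are assigned to a patch by the distance from a pose
reference point (the phosphorus atom when present, else the heavy-atom
centroid) to the patch centroid; poses far from both patches, or
equidistant, are labelled "other". This replaces visual assessment in a
molecular viewer with a reproducible rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Pose, PoseSet, Structure

logger = logging.getLogger("ksbind")

DEFAULT_PATCH_THRESHOLD_A = 8.0
_TIE_TOLERANCE_A = 1e-6

#: Patch residue lists in crystal-structure (ActKR) numbering.
FRONT_PATCH_RESIDUES = [("A", 38), ("A", 65), ("A", 93)]
BACK_PATCH_RESIDUES = [("A", 149), ("A", 220), ("A", 260)]
#: Catalytic residues at the channel centre; diagnostics only.
ACTIVE_SITE_RESIDUES = [("A", 114), ("A", 144), ("A", 157), ("A", 161)]


@dataclass
class PatchDefinition:
    """A named residue cluster defining one binding patch."""

    name: str
    residues: list[tuple[str, int]]  # (chain_id, residue_number)
    centroid_rule: str = "all-heavy-atoms"  # or "side-chain-heavy-atoms"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a patch needs at least one residue")
        if self.centroid_rule not in ("all-heavy-atoms", "side-chain-heavy-atoms"):
            raise ValueError(f"unknown centroid_rule {self.centroid_rule!r}")


@dataclass(frozen=True)
class PoseAssignment:
    pose_id: str
    label: str  # front | back | other
    distance_to_front_A: float
    distance_to_back_A: float


@dataclass
class MotifTable:
    """Counts and one-decimal percentages of poses per binding motif."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_poses: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_poses:
            raise ValueError("counts must sum to n_poses")


_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def patch_centroid(receptor: Structure, patch: PatchDefinition) -> np.ndarray:
    """Unweighted mean position of the patch residues' heavy atoms."""
    positions: list[np.ndarray] = []
    for chain_id, resnum in patch.residues:
        atoms = [
            a for a in receptor.atoms
            if a.chain_id == chain_id and a.residue_number == resnum and a.is_heavy
        ]
        if patch.centroid_rule == "side-chain-heavy-atoms":
            side = [a for a in atoms if a.name.strip() not in _BACKBONE_NAMES]
            atoms = side or atoms  # glycine has no side chain; fall back
        if not atoms:
            raise ValueError(f"residue {chain_id}:{resnum} not found in receptor")
        positions.extend(a.position for a in atoms)
    return np.mean(np.stack(positions), axis=0)


def pose_reference_point(
    pose_coordinates: np.ndarray,
    rule: str = "phosphorus-atom",
    elements: list[str] | None = None,
) -> np.ndarray:
    """Reference point of a pose: its (first) P atom or heavy-atom centroid.

    The phosphorus default reflects the role of the phosphate group as
    the anchor of the observed patch interaction. When phosphorus is
    requested but absent, the centroid is used and a warning logged.
    """
    coords = np.asarray(pose_coordinates, dtype=float)
    if rule == "phosphorus-atom":
        if elements:
            p_idx = [i for i, e in enumerate(elements) if e.upper() == "P"]
            if p_idx:
                return coords[p_idx[0]]
        logger.warning("no phosphorus atom in pose; falling back to heavy-atom centroid")
        rule = "heavy-atom-centroid"
    if rule == "heavy-atom-centroid":
        if elements:
            heavy = [i for i, e in enumerate(elements) if e.upper() not in ("H", "D", "T")]
            coords = coords[heavy] if heavy else coords
        return coords.mean(axis=0)
    raise ValueError(f"unknown pose reference rule {rule!r}")


def classify_pose(
    pose: Pose,
    receptor: Structure,
    front: PatchDefinition,
    back: PatchDefinition,
    threshold_A: float = DEFAULT_PATCH_THRESHOLD_A,
    reference_rule: str = "phosphorus-atom",
    ligand_elements: list[str] | None = None,
    _centroids: tuple[np.ndarray, np.ndarray] | None = None,
) -> PoseAssignment:
    """Label a pose front/back/other by reference-point-to-centroid distance.

    The nearest patch wins if its distance is within ``threshold_A``;
    ties within 1e-6 A and distant poses are labelled "other".
    """
    if _centroids is None:
        c_front = patch_centroid(receptor, front)
        c_back = patch_centroid(receptor, back)
    else:
        c_front, c_back = _centroids
    ref = pose_reference_point(pose.coordinates, reference_rule, ligand_elements)
    d_front = float(np.linalg.norm(ref - c_front))
    d_back = float(np.linalg.norm(ref - c_back))
    if abs(d_front - d_back) < _TIE_TOLERANCE_A:
        label = "other"
    elif d_front < d_back and d_front <= threshold_A:
        label = "front"
    elif d_back < d_front and d_back <= threshold_A:
        label = "back"
    else:
        label = "other"
    return PoseAssignment(
        pose_id=pose.pose_id, label=label,
        distance_to_front_A=d_front, distance_to_back_A=d_back,
    )


def classify_pose_set(
    pose_set: PoseSet,
    front: PatchDefinition,
    back: PatchDefinition,
    threshold_A: float = DEFAULT_PATCH_THRESHOLD_A,
    reference_rule: str = "phosphorus-atom",
) -> list[PoseAssignment]:
    """Classify every pose in a set against the two patches."""
    centroids = (
        patch_centroid(pose_set.receptor, front),
        patch_centroid(pose_set.receptor, back),
    )
    elements = (
        [a.element for a in pose_set.ligand_template.atoms]
        if pose_set.ligand_template is not None else None
    )
    return [
        classify_pose(
            p, pose_set.receptor, front, back, threshold_A,
            reference_rule, elements, _centroids=centroids,
        )
        for p in pose_set.poses
    ]


def tabulate_assignments(assignments: list[PoseAssignment]) -> MotifTable:
    """Counts and one-decimal percentages per motif label."""
    if not assignments:
        raise ValueError("cannot tabulate an empty assignment list")
    counts = {"front": 0, "back": 0, "other": 0}
    for a in assignments:
        counts[a.label] += 1
    n = len(assignments)
    percentages = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return MotifTable(counts=counts, percentages=percentages, n_poses=n)
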