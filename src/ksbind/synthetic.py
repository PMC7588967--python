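"""Synthetic fixtures with the statistical structure the analysis assumes.

Everything downstream (stability scoring, exit detection, patch
classification, energy decomposition, grouped statistics) can be
exercised without MD engines, docking runs or external coordinates:

- toy receptor-ligand complexes on a jittered lattice, built so that at
  least one heavy-atom cross pair starts within the 7 A native cutoff;
- bound trajectories (rigid receptor, ligand jittering isotropically
  about its initial pose) and unbinding trajectories (ligand drifts out
  along a fixed random direction after a switch frame);
- per-frame energy tables drawn from a bivariate normal over
  (dG_vdw, dG_ele) with controllable component-total correlations,
  back-filled into raw VDWAALS/EEL/EPB/ENPOLAR terms so the table
  round-trips through parsing and decomposition;
- docking pose clouds centred on patch centroids, with the front/back/
  other composition apportioned exactly from the requested weights.

Defaults mirror the study conditions: 200 frames at 1 ns, triplicate
replicates, and a 1.0% / 98.0% / 1.0% front/back/other pose composition.
All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Atom, EnergySeries, Pose, PoseSet, Structure, Trajectory

#: Fixed back-fill splits turning component draws into raw MM-PBSA terms.
#: dG_vdw splits 9:1 into VDWAALS:ENPOLAR; dG_ele back-fills as
#: EEL = -dG_ele, EPB = 2*dG_ele (sign-opposing, as in typical charged
#: receptor-ligand systems where polar solvation opposes Coulomb).
VDW_SPLIT = (0.9, 0.1)      # VDWAALS, ENPOLAR coefficients of dG_vdw
ELE_SPLIT = (-1.0, 2.0)     # EEL, EPB coefficients of dG_ele


@dataclass
class SyntheticSpec:
    """Generator settings; defaults are the emulated study conditions."""

    seed: int = 0
    n_frames: int = 200                 # 200 snapshots at 1 ns = 200 ns
    frame_interval_ns: float = 1.0
    n_replicates: int = 3
    jitter_sigma_A: float = 0.3         # bound-state positional noise per atom
    exit_frame: int | None = None       # None = stays bound
    drift_rate_A_per_frame: float = 1.0
    energy_means: tuple = (-40.5, -30.0, 60.0, -4.5)  # VDWAALS, EEL, EPB, ENPOLAR
    energy_sds: tuple = (9.0, 2.0, 4.0, 1.0)
    target_corr_vdw_total: float | None = None
    target_corr_ele_total: float | None = None
    pose_sigma_A: float = 1.5           # within-motif docking-cluster spread
    pose_weights: tuple = (0.01, 0.98, 0.01)  # front, back, other
    n_poses: int = 200

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.energy_sds):
            raise ValueError("energy sds must be >= 0")
        if abs(sum(self.pose_weights) - 1.0) > 1e-9:
            raise ValueError("pose_weights must sum to 1")
        for c in (self.target_corr_vdw_total, self.target_corr_ele_total):
            if c is not None and not -1 < c < 1:
                raise ValueError("target correlations must lie in (-1, 1)")


@dataclass
class ToyComplex:
    """A receptor and ligand pair plus their merged topology."""

    receptor: Structure
    ligand: Structure

    @property
    def topology(self) -> Structure:
        return Structure(atoms=list(self.receptor.atoms) + list(self.ligand.atoms))

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.arange(len(self.receptor))

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.arange(len(self.receptor), len(self.receptor) + len(self.ligand))

    @property
    def coordinates(self) -> np.ndarray:
        return np.vstack([self.receptor.coordinates, self.ligand.coordinates])


def make_toy_complex(
    n_receptor_atoms: int,
    n_ligand_atoms: int,
    seed: int = 0,
    include_phosphorus: bool = False,
) -> ToyComplex:
    """Build a deterministic toy complex with >= 1 native cross pair.

    Receptor heavy atoms sit on a jittered cubic lattice (3 A spacing);
    the ligand is a short chain whose first atom is placed 4 A outside
    the receptor surface, guaranteeing a cross pair inside the 7 A
    cutoff. ``include_phosphorus`` makes the first ligand atom a P (for
    patch-classifier reference-point tests).
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)

    side = int(np.ceil(n_receptor_atoms ** (1 / 3)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:n_receptor_atoms] * 3.0
    grid += rng.normal(0.0, 0.15, grid.shape)

    receptor_atoms = [
        Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
             residue_number=i + 1, chain_id="A", position=grid[i])
        for i in range(n_receptor_atoms)
    ]

    anchor = grid[np.argmax(grid[:, 0])]
    lig_coords = np.array(
        [anchor + np.array([4.0 + 1.5 * i, 0.0, 0.0]) for i in range(n_ligand_atoms)]
    )
    lig_coords += rng.normal(0.0, 0.1, lig_coords.shape)
    ligand_atoms = []
    for i in range(n_ligand_atoms):
        element = "P" if (include_phosphorus and i == 0) else "C"
        name = "P1" if element == "P" else f"C{i + 1}"
        ligand_atoms.append(
            Atom(serial=n_receptor_atoms + i + 1, name=name, element=element,
                 residue_name="LIG", residue_number=1, chain_id="B",
                 position=lig_coords[i])
        )
    return ToyComplex(
        receptor=Structure(atoms=receptor_atoms),
        ligand=Structure(atoms=ligand_atoms),
    )


def _ligand_frames(complex_: ToyComplex, spec: SyntheticSpec, drift_vector=None):
    rng = np.random.default_rng(spec.seed)
    base = complex_.coordinates
    lig = complex_.ligand_indices
    if drift_vector is None and spec.exit_frame is not None:
        v = rng.normal(size=3)
        drift_vector = v / np.linalg.norm(v)
    frames = [base.copy()]  # frame 0 is the initial pose exactly
    for i in range(1, spec.n_frames):
        frame = base.copy()
        frame[lig] += rng.normal(0.0, spec.jitter_sigma_A, (len(lig), 3))
        if spec.exit_frame is not None and i >= spec.exit_frame:
            frame[lig] += spec.drift_rate_A_per_frame * (i - spec.exit_frame) * drift_vector
        frames.append(frame)
    return frames


def simulate_bound_trajectory(complex_: ToyComplex, spec: SyntheticSpec) -> Trajectory:
    """Rigid receptor, ligand jittering about its initial pose.

    Frame 0 equals the initial coordinates exactly; every later frame
    redraws an isotropic Gaussian displacement per ligand atom.
    """
    if spec.exit_frame is not None:
        raise ValueError("bound trajectory requires exit_frame = None")
    if spec.jitter_sigma_A < 0:
        raise ValueError("jitter_sigma_A must be >= 0")
    return Trajectory(
        topology=complex_.topology,
        frames=_ligand_frames(complex_, spec),
        frame_interval_ns=spec.frame_interval_ns,
    )


def simulate_unbinding_trajectory(complex_: ToyComplex, spec: SyntheticSpec) -> Trajectory:
    """Bound until ``exit_frame``; then the ligand drifts out linearly.

    After the switch frame the ligand centre is additionally translated
    by drift_rate * (frame - exit_frame) along a fixed random unit
    vector, emulating a ligand that leaves the binding pocket.
    """
    if spec.exit_frame is None or not 0 <= spec.exit_frame < spec.n_frames:
        raise ValueError("unbinding trajectory requires 0 <= exit_frame < n_frames")
    if spec.drift_rate_A_per_frame <= 0:
        raise ValueError("drift_rate_A_per_frame must be > 0")
    return Trajectory(
        topology=complex_.topology,
        frames=_ligand_frames(complex_, spec),
        frame_interval_ns=spec.frame_interval_ns,
    )


def _component_moments(spec: SyntheticSpec) -> tuple[float, float, float, float]:
    mv, me, mpb, mnp = spec.energy_means
    sv, se, spb, snp = spec.energy_sds
    # Components are the primitive draw; raw-term sds map through the
    # fixed split coefficients (|0.9| + |0.1| = 1 for vdw; |-1| + |2| = 3 for ele).
    mu_vdw = mv + mnp
    mu_ele = me + mpb
    sigma_vdw = sv + snp
    sigma_ele = (se + spb) / 3.0
    return mu_vdw, mu_ele, sigma_vdw, sigma_ele


def _implied_corrs(rho: float, sv: float, se: float) -> tuple[float, float]:
    st = np.sqrt(sv**2 + se**2 + 2 * rho * sv * se)
    return (sv + rho * se) / st, (se + rho * sv) / st


def _solve_rho(spec: SyntheticSpec, sv: float, se: float) -> float:
    tv, te = spec.target_corr_vdw_total, spec.target_corr_ele_total
    if tv is None and te is None:
        return 0.0

    def loss(rho: float) -> float:
        cv, ce = _implied_corrs(rho, sv, se)
        err = 0.0
        if tv is not None:
            err += (cv - tv) ** 2
        if te is not None:
            err += (ce - te) ** 2
        return err

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(loss, bounds=(-0.999, 0.999), method="bounded")
    rho = float(res.x)
    if np.sqrt(res.fun) > 0.1:
        det = (sv * se) ** 2 * (1 - rho**2)
        raise ValueError(
            "infeasible correlation targets "
            f"(corr_vdw_total={tv}, corr_ele_total={te}); best achievable "
            f"residual {np.sqrt(res.fun):.3f}, covariance determinant {det:.4g}"
        )
    return rho


def simulate_energy_table(spec: SyntheticSpec) -> EnergySeries:
    """Draw a per-frame energy table with controlled component correlations.

    (dG_vdw, dG_ele) are drawn from a bivariate normal whose single free
    correlation parameter is fitted so the implied correlations of each
    component with their sum match the targets (unconstrained components
    are independent). Raw terms are back-filled through the fixed splits
    so read -> decompose reproduces the drawn sums exactly.
    """
    mu_v, mu_e, s_v, s_e = _component_moments(spec)
    rho = _solve_rho(spec, s_v, s_e)
    cov = np.array([[s_v**2, rho * s_v * s_e], [rho * s_v * s_e, s_e**2]])
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal([mu_v, mu_e], cov, size=spec.n_frames)
    vdw, ele = draws[:, 0], draws[:, 1]
    table = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "VDWAALS": VDW_SPLIT[0] * vdw,
            "EEL": ELE_SPLIT[0] * ele,
            "EPB": ELE_SPLIT[1] * ele,
            "ENPOLAR": VDW_SPLIT[1] * vdw,
        }
    )
    return EnergySeries(table=table)


def _largest_remainder_counts(weights, n: int) -> np.ndarray:
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def make_patch_receptor(separation_A: float = 24.0, seed: int = 0):
    """A minimal receptor carrying front- and back-patch residues.

    Front-patch residues (R38/R65/R93) cluster around the origin and
    back-patch residues (Q149/R220/N260) around (separation, 0, 0);
    returns (receptor, front PatchDefinition, back PatchDefinition).
    """
    from .patches import PatchDefinition

    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1

    def add_residue(resname, resnum, centre):
        nonlocal serial
        offsets = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]], dtype=float)
        names = ["N", "CA", "C", "CB"]
        for name, off in zip(names, offsets):
            atoms.append(
                Atom(serial=serial, name=name, element=name[0], residue_name=resname,
                     residue_number=resnum, chain_id="A",
                     position=np.asarray(centre, dtype=float) + off
                     + rng.normal(0, 0.05, 3))
            )
            serial += 1

    front_spec = [("ARG", 38), ("ARG", 65), ("ARG", 93)]
    back_spec = [("GLN", 149), ("ARG", 220), ("ASN", 260)]
    for i, (resname, resnum) in enumerate(front_spec):
        add_residue(resname, resnum, np.array([0.0, 3.0 * i, 0.0]))
    for i, (resname, resnum) in enumerate(back_spec):
        add_residue(resname, resnum, np.array([separation_A, 3.0 * i, 0.0]))

    receptor = Structure(atoms=atoms)
    front = PatchDefinition(name="front", residues=[("A", n) for _, n in front_spec])
    back = PatchDefinition(name="back", residues=[("A", n) for _, n in back_spec])
    return receptor, front, back


def simulate_pose_set(
    receptor: Structure,
    front_centroid: np.ndarray,
    back_centroid: np.ndarray,
    spec: SyntheticSpec,
) -> PoseSet:
    """Generate a docking pose cloud around the patch centroids.

    The front/back/other composition is apportioned from ``pose_weights``
    by largest remainder (so the generated composition equals the
    weights exactly at any seed), then the pose order is shuffled. Patch
    poses scatter isotropically (sigma = ``pose_sigma_A``) about their
    centroid; "other" poses land uniformly in a shell 15-30 A from both
    centroids. Each pose is a two-atom fragment with its phosphorus at
    the reference point. Scores decrease with pose rank.
    """
    front_centroid = np.asarray(front_centroid, dtype=float)
    back_centroid = np.asarray(back_centroid, dtype=float)
    sep = np.linalg.norm(front_centroid - back_centroid)
    if sep < 4 * spec.pose_sigma_A:
        raise ValueError(
            f"patch centroids {sep:.1f} A apart violate the separability guard "
            f"(need >= {4 * spec.pose_sigma_A:.1f} A)"
        )
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder_counts(spec.pose_weights, spec.n_poses)
    labels = np.repeat(["front", "back", "other"], counts)
    rng.shuffle(labels)

    midpoint = (front_centroid + back_centroid) / 2.0
    refs = []
    for label in labels:
        if label == "front":
            refs.append(rng.normal(front_centroid, spec.pose_sigma_A))
        elif label == "back":
            refs.append(rng.normal(back_centroid, spec.pose_sigma_A))
        else:
            for _ in range(10000):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                point = midpoint + direction * rng.uniform(15.0, 30.0 + sep / 2)
                df = np.linalg.norm(point - front_centroid)
                db = np.linalg.norm(point - back_centroid)
                if 15.0 <= df <= 30.0 and 15.0 <= db <= 30.0:
                    refs.append(point)
                    break
            else:
                raise RuntimeError("could not place an 'other' pose in the 15-30 A shell")

    template = Structure(
        atoms=[
            Atom(serial=1, name="P1", element="P", residue_name="FRG",
                 residue_number=1, chain_id="L", position=np.zeros(3)),
            Atom(serial=2, name="C1", element="C", residue_name="FRG",
                 residue_number=1, chain_id="L", position=np.array([1.6, 0.0, 0.0])),
        ]
    )
    poses = [
        Pose(
            pose_id=str(i),
            coordinates=np.vstack([ref, ref + np.array([1.6, 0.0, 0.0])]),
            score=-5.0 - 0.01 * i,
        )
        for i, ref in enumerate(refs)
    ]
    return PoseSet(receptor=receptor, poses=poses, ligand_template=template)
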