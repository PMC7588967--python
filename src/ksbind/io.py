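"""Structure, trajectory, pose-set and energy-table I/O.

The canonical on-disk dialects are plain text: multi-model PDB for
structures, trajectories (one MODEL per frame) and docking pose sets,
and delimited tables (CSV/TSV) for per-frame MM-PBSA energy terms.
Binary trajectory formats are accepted as an optional pass-through when
``mdtraj`` is importable.

Coordinates are Angstrom throughout; energies are kcal/mol as emitted by
MM-PBSA-style post-processors (no unit conversion is performed).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ksbind")

#: Residue names treated as protein by the "protein" selection keyword.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER
    THR TRP TYR VAL HID HIE HIP CYX ASH GLH LYN MSE SEC PYL""".split()
)

#: Required energy-table columns (canonical upper-case spelling).
ENERGY_TERMS = ("VDWAALS", "EEL", "EPB", "ENPOLAR")


class ParseError(ValueError):
    """Raised when an input file violates its dialect contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus a position in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int  # 1-based, as printed in the source PDB
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        object.__setattr__(self, "position", pos)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D", "T")


@dataclass
class Structure:
    """An ordered collection of atoms with free-form metadata."""

    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Angstrom."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in self.atoms])


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a fixed topology.

    One frame corresponds to one structural snapshot; the default
    ``frame_interval_ns`` of 1 matches snapshots extracted every 1 ns.
    """

    topology: Structure
    frames: list[np.ndarray]  # each (n_atoms, 3), Angstrom
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be > 0")
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i}: expected {n} atom coordinates, got {f.shape[0]}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns


@dataclass(frozen=True)
class Pose:
    """One docked placement of the ligand: coordinates plus optional score."""

    pose_id: str
    coordinates: np.ndarray  # (n_atoms, 3)
    score: float | None = None


@dataclass
class PoseSet:
    """A receptor plus an ordered set of docked ligand poses.

    When scores are present, poses must already be ordered by
    non-increasing score (docking output convention: best first).
    """

    receptor: Structure
    poses: list[Pose]
    ligand_template: Structure | None = None  # atom identities shared by all poses

    def __post_init__(self) -> None:
        ids = [p.pose_id for p in self.poses]
        if len(set(ids)) != len(ids):
            raise ValueError("pose_ids must be unique")
        scores = [p.score for p in self.poses]
        if any(s is not None for s in scores):
            if any(s is None for s in scores):
                raise ParseError("scores must be present for all poses or none")
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ParseError("poses with scores must be ordered by non-increasing score")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class EnergySeries:
    """Per-frame MM-PBSA energy terms (kcal/mol)."""

    table: pd.DataFrame  # columns: frame + ENERGY_TERMS

    def __post_init__(self) -> None:
        missing = [c for c in ENERGY_TERMS if c not in self.table.columns]
        if missing:
            raise ValueError(f"energy series missing terms: {missing}")
        if "frame" not in self.table.columns:
            self.table = self.table.copy()
            self.table.insert(0, "frame", np.arange(len(self.table)))
        frames = self.table["frame"].to_numpy()
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        vals = self.table[list(ENERGY_TERMS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("all energy terms must be finite in every record")

    def __len__(self) -> int:
        return len(self.table)

    def term(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Atom selection mini-grammar
# ---------------------------------------------------------------------------

def _parse_int_list(text: str) -> set[int]:
    out: set[int] = set()
    for piece in text.replace(" ", "").split(","):
        if not piece:
            continue
        if "-" in piece[1:]:  # allow negative lower bound edge case
            lo, hi = piece.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(piece))
    return out


def make_selection(expr):
    """Compile a selection into a predicate ``Atom -> bool``.

    Accepts a callable unchanged, or a string of clauses joined by
    ``and``: ``all``, ``protein``, ``not protein``, ``resname A[,B...]``,
    ``chain A[,B...]``, ``resid 38,65,90-93``.
    """
    if callable(expr):
        return expr
    clauses = [c.strip() for c in re.split(r"\band\b", expr) if c.strip()]
    if not clauses:
        raise ValueError("empty selection expression")
    preds = []
    for clause in clauses:
        tokens = clause.split(None, 1)
        head = tokens[0].lower()
        arg = tokens[1] if len(tokens) > 1 else ""
        if head == "all":
            preds.append(lambda a: True)
        elif head == "protein":
            preds.append(lambda a: a.residue_name.upper() in PROTEIN_RESIDUES)
        elif head == "not" and arg.strip().lower() == "protein":
            preds.append(lambda a: a.residue_name.upper() not in PROTEIN_RESIDUES)
        elif head == "resname":
            names = {n.upper() for n in arg.replace(",", " ").split()}
            preds.append(lambda a, names=names: a.residue_name.upper() in names)
        elif head == "chain":
            chains = {c for c in arg.replace(",", " ").split()}
            preds.append(lambda a, chains=chains: a.chain_id in chains)
        elif head == "resid":
            ids = _parse_int_list(arg)
            preds.append(lambda a, ids=ids: a.residue_number in ids)
        else:
            raise ValueError(f"unknown selection clause: {clause!r}")
    return lambda a: all(p(a) for p in preds)


# ---------------------------------------------------------------------------
# PDB reading (Bio.PDB) and writing (fixed-column records)
# ---------------------------------------------------------------------------

def _biopdb_models(path: Path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ParseError(f"{path}: malformed PDB record ({exc})") from exc
    return list(structure)


def _model_to_structure(model, metadata: Mapping | None = None) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                element = (atom.element or "").strip()
                if not element:
                    # Bio.PDB normally infers this; keep a last-resort rule:
                    # first alphabetic character of the atom name.
                    stripped = atom.get_name().strip()
                    element = next((c for c in stripped if c.isalpha()), "C").upper()
                atoms.append(
                    Atom(
                        serial=atom.serial_number,
                        name=atom.get_name(),
                        element=element.upper(),
                        residue_name=residue.get_resname().strip(),
                        residue_number=residue.id[1],
                        chain_id=chain.id if chain.id.strip() else "A",
                        position=np.array(atom.coord, dtype=float),
                    )
                )
    return Structure(atoms=atoms, metadata=dict(metadata or {}))


def read_structure(path, model_index: int = 0) -> Structure:
    """Read one model of a (possibly multi-model) PDB file.

    ``model_index`` is 0-based over the MODEL blocks in file order;
    residue numbering is preserved exactly as printed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    models = _biopdb_models(path)
    if not models:
        raise ParseError(f"{path}: no models found")
    if not 0 <= model_index < len(models):
        raise IndexError(
            f"{path}: model_index {model_index} out of range (file has {len(models)} models)"
        )
    return _model_to_structure(models[model_index], metadata={"source": str(path)})


def read_trajectory(topology_path, frames_path, frame_interval_ns: float = 1.0) -> Trajectory:
    """Read a trajectory: a topology PDB plus a frames file.

    The required dialect for frames is multi-model PDB (one MODEL per
    snapshot). Other extensions are passed through ``mdtraj`` when it is
    available. Every frame must carry exactly as many atoms as the
    topology; a mismatch is reported with the offending frame number.
    """
    topology = read_structure(topology_path)
    frames_path = Path(frames_path)
    if not frames_path.exists():
        raise FileNotFoundError(frames_path)

    if frames_path.suffix.lower() in (".pdb", ".ent", ".pdb1"):
        models = _biopdb_models(frames_path)
        if not models:
            raise ParseError(f"{frames_path}: no models found")
        frames = []
        for i, model in enumerate(models):
            coords = _model_to_structure(model).coordinates
            if coords.shape[0] != len(topology):
                raise ParseError(
                    f"{frames_path}: frame {i + 1} has {coords.shape[0]} atoms, "
                    f"topology has {len(topology)}"
                )
            frames.append(coords)
    else:  # binary pass-through
        import mdtraj

        traj = mdtraj.load(str(frames_path), top=str(topology_path))
        if traj.n_atoms != len(topology):
            raise ParseError(
                f"{frames_path}: frame 1 has {traj.n_atoms} atoms, "
                f"topology has {len(topology)}"
            )
        frames = [np.asarray(xyz, dtype=float) * 10.0 for xyz in traj.xyz]  # nm -> A

    return Trajectory(topology=topology, frames=frames, frame_interval_ns=frame_interval_ns)


_SCORE_RE = re.compile(r"^REMARK\s+(?:VINA\s+RESULT:|SCORE[:=]?)\s*(-?\d+(?:\.\d+)?)", re.I)


def read_pose_set(receptor_path, poses_path) -> PoseSet:
    """Read a docking pose set: receptor PDB plus multi-model ligand PDB.

    An optional per-model score is parsed from ``REMARK VINA RESULT:`` or
    ``REMARK SCORE`` lines inside each MODEL block.
    """
    receptor = read_structure(receptor_path)
    poses_path = Path(poses_path)
    models = _biopdb_models(poses_path)
    if not models:
        raise ParseError(f"{poses_path}: pose file contains zero models")

    # Per-model scores: light scan, because Bio.PDB drops REMARK records.
    scores: list[float | None] = []
    current: float | None = None
    in_model = False
    with open(poses_path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                in_model, current = True, None
            elif line.startswith("ENDMDL"):
                scores.append(current)
                in_model = False
            elif in_model:
                m = _SCORE_RE.match(line)
                if m:
                    current = float(m.group(1))
    if len(scores) != len(models):  # single-model file without MODEL/ENDMDL
        scores = [None] * len(models)

    template = _model_to_structure(models[0])
    poses = [
        Pose(pose_id=str(i), coordinates=_model_to_structure(m).coordinates, score=s)
        for i, (m, s) in enumerate(zip(models, scores))
    ]
    return PoseSet(receptor=receptor, poses=poses, ligand_template=template)


def _format_atom_line(atom: Atom, serial: int) -> str:
    name = atom.name
    # PDB v3.3 name justification: element symbols of one character start
    # in column 14 unless the name is 4 characters long.
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.position
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
        f"{atom.chain_id[:1]:1s}{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2.2s}\n"
    )


def _write_model(fh, structure: Structure, coordinates: np.ndarray | None = None) -> None:
    coords = structure.coordinates if coordinates is None else np.asarray(coordinates)
    for atom, pos in zip(structure.atoms, coords):
        moved = Atom(
            serial=atom.serial, name=atom.name, element=atom.element,
            residue_name=atom.residue_name, residue_number=atom.residue_number,
            chain_id=atom.chain_id, position=pos,
        )
        fh.write(_format_atom_line(moved, moved.serial))


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as a single-model PDB file."""
    with open(path, "w") as fh:
        _write_model(fh, structure)
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB file (one MODEL per frame)."""
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"MODEL     {i + 1:>4d}\n")
            _write_model(fh, traj.topology, frame)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_pose_set(pose_set: PoseSet, path) -> None:
    """Write pose-set ligand coordinates as a multi-model PDB with scores."""
    template = pose_set.ligand_template
    if template is None:
        raise ValueError("pose set has no ligand template to write")
    with open(path, "w") as fh:
        for i, pose in enumerate(pose_set.poses):
            fh.write(f"MODEL     {i + 1:>4d}\n")
            if pose.score is not None:
                fh.write(f"REMARK SCORE {pose.score:.4f}\n")
            _write_model(fh, template, pose.coordinates)
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Energy tables and result tables
# ---------------------------------------------------------------------------

def read_energy_table(path) -> EnergySeries:
    """Read a per-frame MM-PBSA energy table from delimited text.

    The header must contain VDWAALS, EEL, EPB and ENPOLAR
    (case-insensitive); extra columns are ignored and derived totals are
    never trusted from input. An explicit ``Frame`` column provides the
    frame index; otherwise row order (from 0) is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    lookup = {c.strip().upper(): c for c in df.columns}
    missing = [t for t in ENERGY_TERMS if t not in lookup]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame()
    if "FRAME" in lookup:
        out["frame"] = pd.to_numeric(df[lookup["FRAME"]], errors="raise").astype(int)
    for term in ENERGY_TERMS:
        col = df[lookup[term]]
        try:
            out[term] = pd.to_numeric(col, errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            bad = col[pd.to_numeric(col, errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise ParseError(
                f"{path}: non-numeric value in column {lookup[term]!r}, data row {row}"
            ) from exc
    return EnergySeries(table=out)


def write_table(rows: Iterable[Mapping] | pd.DataFrame, path) -> None:
    """Write records as a UTF-8 CSV with a deterministic column order."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
        if rows:
            df = df[list(rows[0].keys())]  # first-record key order, stable
    df.to_csv(path, index=False, encoding="utf-8")
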