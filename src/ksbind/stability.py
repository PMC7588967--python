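"""Framewise native-contact stability score (SS) for receptor-ligand MD.

The native pair set is defined on the reference frame (by default the
first frame of the trajectory): all receptor-ligand heavy-atom pairs
within 7 A. In any frame, SS is the fraction of those native pairs whose
distance is still within the cutoff, so SS of the reference frame is 1
by construction, SS near 1 indicates the ligand holds its initial pose,
and SS near 0 indicates it has left the binding site.

Distance comparisons use a closed boundary (<= cutoff) on both the
reference and subsequent frames. Only receptor x ligand cross pairs are
counted: the score measures the stability of the intermolecular
interface, and intra-molecular pairs would dilute that signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Structure, Trajectory, make_selection

logger = logging.getLogger("ksbind")

DEFAULT_CUTOFF_A = 7.0  # Angstrom, native-contact distance cutoff

#: Intra-ligand nearest-neighbour distance above which we suspect an
#: un-imaged (wrapped) molecule and warn.
_WRAP_GUARD_A = 3.0


class NoNativeContactsError(ValueError):
    """Raised when SS is requested for an empty native pair set."""


@dataclass
class NativePairSet:
    """Receptor-ligand heavy-atom pairs within the cutoff at the reference frame."""

    pairs: np.ndarray  # (n_pairs, 2) of (receptor_atom_index, ligand_atom_index)
    cutoff_A: float = DEFAULT_CUTOFF_A
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class StabilitySeries:
    """Per-frame SS values in [0, 1] with timing metadata."""

    values: np.ndarray
    frame_interval_ns: float = 1.0
    n_native_pairs: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("SS values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def times_ns(self, start_frame: int = 0) -> np.ndarray:
        return (start_frame + np.arange(len(self.values))) * self.frame_interval_ns


def select_heavy_atoms(structure: Structure, selection="all") -> np.ndarray:
    """Indices (topology order) of non-hydrogen atoms matching a selection.

    ``selection`` is a predicate string (see :func:`ksbind.io.make_selection`)
    or a callable. Hydrogen and its isotopes (D, T) are excluded.
    """
    pred = make_selection(selection)
    idx = [i for i, a in enumerate(structure.atoms) if pred(a) and a.is_heavy]
    if not idx:
        raise ValueError(f"selection {selection!r} matches no heavy atoms")
    return np.array(idx, dtype=int)


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    delta = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.linalg.norm(delta, axis=1)


def native_pairs(
    traj: Trajectory,
    receptor_atoms: np.ndarray,
    ligand_atoms: np.ndarray,
    cutoff_A: float = DEFAULT_CUTOFF_A,
    reference_frame: int = 0,
) -> NativePairSet:
    """Enumerate receptor-ligand atom pairs within ``cutoff_A`` at the reference frame.

    The boundary is closed: a pair at exactly the cutoff distance is
    native. An empty result is returned with a warning (SS is undefined
    downstream until contacts exist).
    """
    receptor_atoms = np.asarray(receptor_atoms, dtype=int)
    ligand_atoms = np.asarray(ligand_atoms, dtype=int)
    if np.intersect1d(receptor_atoms, ligand_atoms).size:
        raise ValueError("receptor and ligand atom selections must be disjoint")
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    ref = traj.frames[reference_frame]
    diff = ref[receptor_atoms][:, None, :] - ref[ligand_atoms][None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    ri, li = np.nonzero(dist <= cutoff_A)
    pairs = np.column_stack([receptor_atoms[ri], ligand_atoms[li]])
    if len(pairs) == 0:
        logger.warning(
            "no receptor-ligand heavy-atom pairs within %.2f A at frame %d",
            cutoff_A, reference_frame,
        )
    return NativePairSet(pairs=pairs, cutoff_A=cutoff_A, reference_frame=reference_frame)


def _check_ligand_imaging(traj: Trajectory, ligand_atoms: np.ndarray) -> None:
    # Wrapping guard: in an imaged, whole molecule every atom has a
    # neighbour within normal bond length; a nearest-neighbour distance
    # above 3 A suggests the ligand is split across the periodic box.
    if len(ligand_atoms) < 2:
        return
    coords = traj.frames[0][ligand_atoms]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    worst = dist.min(axis=1).max()
    if worst > _WRAP_GUARD_A:
        logger.warning(
            "ligand nearest-neighbour distance %.2f A exceeds %.1f A; "
            "molecule may be wrapped across the periodic box", worst, _WRAP_GUARD_A,
        )


def stability_series(traj: Trajectory, pairs: NativePairSet) -> StabilitySeries:
    """Per-frame SS: the surviving fraction of the native pair set.

    SS(frame) = |{native pairs with distance <= cutoff in frame}| / |native pairs|.
    The reference frame scores exactly 1.
    """
    if len(pairs) == 0:
        raise NoNativeContactsError("no native contacts; SS undefined")
    ligand_atoms = np.unique(pairs.pairs[:, 1])
    _check_ligand_imaging(traj, ligand_atoms)
    n = len(pairs)
    values = np.array(
        [np.count_nonzero(_pair_distances(f, pairs.pairs) <= pairs.cutoff_A) / n
         for f in traj.frames]
    )
    return StabilitySeries(
        values=values,
        frame_interval_ns=traj.frame_interval_ns,
        n_native_pairs=n,
    )


def production_window(series: StabilitySeries, start_fraction: float = 0.5) -> StabilitySeries:
    """Equilibrated suffix of the series, starting at floor(start_fraction * n).

    The default of 0.5 extracts the last 100 ns of a 200-frame / 200-ns
    trajectory, the window used for all grouped statistics.
    """
    if not 0 <= start_fraction < 1:
        raise ValueError("start_fraction must lie in [0, 1)")
    n = len(series)
    if n < 2:
        raise ValueError("series must have at least 2 frames to extract a window")
    start = int(np.floor(start_fraction * n))
    return StabilitySeries(
        values=series.values[start:],
        frame_interval_ns=series.frame_interval_ns,
        n_native_pairs=series.n_native_pairs,
    )


def mean_ss(series: StabilitySeries) -> float:
    """Arithmetic mean SS of a series (the replicate-selection statistic)."""
    if len(series) == 0:
        raise ValueError("cannot average an empty series")
    return float(np.mean(series.values))


def detect_exit(
    series: StabilitySeries,
    exit_threshold: float = 0.1,
    sustain_frames: int = 10,
) -> int | None:
    """First frame where SS stays below ``exit_threshold`` for ``sustain_frames``.

    Operationalizes "the ligand exited the binding pocket": a transient
    dip shorter than the sustain window does not count. Returns None if
    no qualifying window exists (including a terminal dip shorter than
    the window).
    """
    if sustain_frames < 1:
        raise ValueError("sustain_frames must be >= 1")
    if len(series) == 0:
        raise ValueError("cannot scan an empty series")
    below = series.values < exit_threshold
    if len(below) < sustain_frames:
        return None
    run = np.convolve(below.astype(int), np.ones(sustain_frames, dtype=int), "valid")
    hits = np.nonzero(run == sustain_frames)[0]
    return int(hits[0]) if hits.size else None
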