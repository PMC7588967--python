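"""Binding free-energy decomposition and framewise correlation analysis.

Per-frame MM-PBSA output is decomposed into a non-electrostatic
component dG_vdw = VDWAALS + ENPOLAR (packing / hydrophobic effects plus
nonpolar solvation), an electrostatic component dG_ele = EEL + EPB
(Coulombic plus polar solvation), and their sum dG_total. The components
are then compared framewise by Pearson correlation to ask which one
drives the total.

A desk-scale Lennard-Jones + Coulomb calculator provides the molecular-
mechanics cross terms for synthetic structures. It is a truncated-pair
calculator (10 A cutoff, no switching, vacuum dielectric); the solvation
terms (EPB, ENPOLAR) are always parsed from tables, never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ENERGY_TERMS, EnergySeries
from .stability import StabilitySeries, mean_ss, production_window

logger = logging.getLogger("ksbind")

#: Coulomb constant in kcal*A/(mol*e^2), Amber convention.
COULOMB_KCAL = 332.0637
DEFAULT_NB_CUTOFF_A = 10.0
_CLASH_DISTANCE_A = 0.1


@dataclass
class DecomposedEnergySeries:
    """Per-frame dG_vdw / dG_ele / dG_total (kcal/mol)."""

    table: pd.DataFrame  # frame, dG_vdw, dG_ele, dG_total
    provenance: str = "parsed"  # parsed | computed

    def component(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def summary(self) -> pd.DataFrame:
        comps = ["dG_vdw", "dG_ele", "dG_total"]
        return pd.DataFrame(
            {
                "component": comps,
                "mean": [self.table[c].mean() for c in comps],
                "sd": [self.table[c].std(ddof=1) for c in comps],
            }
        )


@dataclass
class NonbondedParams:
    """Per-atom nonbonded parameters (Amber-style LJ rmin/2 + epsilon)."""

    partial_charge: np.ndarray  # elementary charges
    lj_epsilon: np.ndarray      # kcal/mol, >= 0
    lj_rmin_half: np.ndarray    # Angstrom

    def __post_init__(self) -> None:
        self.partial_charge = np.asarray(self.partial_charge, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        for arr, name in (
            (self.partial_charge, "partial_charge"),
            (self.lj_epsilon, "lj_epsilon"),
            (self.lj_rmin_half, "lj_rmin_half"),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "NonbondedParams":
        """Load params from a CSV with columns serial, charge, epsilon, rmin_half."""
        df = pd.read_csv(path).sort_values("serial")
        return cls(
            partial_charge=df["charge"].to_numpy(),
            lj_epsilon=df["epsilon"].to_numpy(),
            lj_rmin_half=df["rmin_half"].to_numpy(),
        )


def decompose(series: EnergySeries) -> DecomposedEnergySeries:
    """Sum raw MM-PBSA terms into dG_vdw, dG_ele and dG_total per frame.

    Any TOTAL column present in the input is ignored; the total is always
    recomputed as dG_vdw + dG_ele.
    """
    for term in ENERGY_TERMS:
        if term not in series.table.columns:
            raise ValueError(f"energy series is missing term {term}")
    t = series.table
    out = pd.DataFrame({"frame": t["frame"]})
    out["dG_vdw"] = t["VDWAALS"] + t["ENPOLAR"]
    out["dG_ele"] = t["EEL"] + t["EPB"]
    out["dG_total"] = out["dG_vdw"] + out["dG_ele"]
    return DecomposedEnergySeries(table=out, provenance="parsed")


def framewise_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r between two per-frame series with its two-sided p-value.

    The p-value comes from the t-distribution with n - 2 degrees of
    freedom. Series of fewer than 3 frames or zero variance are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 frames for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate series: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_report(decomp: DecomposedEnergySeries) -> pd.DataFrame:
    """Correlate dG_total with each component framewise."""
    rows = []
    for comp in ("dG_vdw", "dG_ele"):
        r, p = framewise_correlation(decomp.component("dG_total"), decomp.component(comp))
        rows.append({"pair": f"dG_total~{comp}", "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows)


def select_representative_replicate(
    replicates: list[StabilitySeries],
    start_fraction: float = 0.5,
) -> int:
    """Index of the replicate with the highest mean SS over the production window.

    This is the replicate whose energies feed the t-test analysis. Exact
    ties go to the lowest index, with a log message.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    lengths = {len(r) for r in replicates}
    if len(lengths) != 1:
        raise ValueError("replicate series must all have the same length")
    means = [mean_ss(production_window(r, start_fraction)) for r in replicates]
    best = int(np.argmax(means))
    if means.count(max(means)) > 1:
        logger.warning("replicate mean-SS tie at %.6f; choosing lowest index %d", means[best], best)
    return best


def lj_coulomb_interaction(
    coordinates: np.ndarray,
    receptor_atoms: np.ndarray,
    ligand_atoms: np.ndarray,
    params: NonbondedParams,
    cutoff_A: float = DEFAULT_NB_CUTOFF_A,
) -> tuple[float, float]:
    """Truncated receptor-ligand LJ and Coulomb cross energies (kcal/mol).

    For each cross pair with r <= cutoff:
      vdw += eps_ij * ((rmin_ij / r)**12 - 2 * (rmin_ij / r)**6)
      ele += k * q_i * q_j / r            (k = 332.0637, dielectric 1)
    with Lorentz-Berthelot combining: eps_ij = sqrt(eps_i * eps_j),
    rmin_ij = rmin_half_i + rmin_half_j. Hard truncation, no switching.
    """
    coords = np.asarray(coordinates, dtype=float)
    ri = np.asarray(receptor_atoms, dtype=int)
    li = np.asarray(ligand_atoms, dtype=int)
    needed = max(ri.max(initial=-1), li.max(initial=-1)) + 1
    if len(params.partial_charge) < needed:
        raise ValueError("params do not cover all selected atoms")
    diff = coords[ri][:, None, :] - coords[li][None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    if np.any(r < _CLASH_DISTANCE_A):
        raise ValueError(f"atomic clash: pair distance below {_CLASH_DISTANCE_A} A")
    mask = r <= cutoff_A
    if not mask.any():
        return 0.0, 0.0
    eps = np.sqrt(np.outer(params.lj_epsilon[ri], params.lj_epsilon[li]))
    rmin = params.lj_rmin_half[ri][:, None] + params.lj_rmin_half[li][None, :]
    with np.errstate(divide="ignore"):
        ratio6 = np.where(mask, (rmin / r) ** 6, 0.0)
    vdw = float(np.sum(np.where(mask, eps * (ratio6**2 - 2.0 * ratio6), 0.0)))
    qq = np.outer(params.partial_charge[ri], params.partial_charge[li])
    ele = float(np.sum(np.where(mask, COULOMB_KCAL * qq / r, 0.0)))
    return vdw, ele


def lj_coulomb_series(
    traj,
    receptor_atoms: np.ndarray,
    ligand_atoms: np.ndarray,
    params: NonbondedParams,
    cutoff_A: float = DEFAULT_NB_CUTOFF_A,
) -> pd.DataFrame:
    """Evaluate the cross-term calculator on every frame of a trajectory."""
    rows = []
    for i, frame in enumerate(traj.frames):
        vdw, ele = lj_coulomb_interaction(frame, receptor_atoms, ligand_atoms, params, cutoff_A)
        rows.append({"frame": i, "vdw": vdw, "ele": ele})
    return pd.DataFrame(rows)
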