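"""Grouped statistical comparisons of stability scores and energies.

Production-window values (SS per frame, or per-frame binding energies)
are compared between cells of a labelled dataset with Welch's
unequal-variance two-sided t-test, and p-values are mapped onto the
significance-star scheme used in the figures:

    ns  p > 0.05        *   p <= 0.05       **  p <= 0.01
    *** p <= 0.001      **** p <= 0.0001    (boundaries inclusive)

Framewise values within one trajectory are autocorrelated; treating
frames as observations mirrors the source convention, and an optional
block-averaging pre-step is available to reduce the effective sample
size honestly. No multiple-testing correction is applied by default;
Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ksbind")

STAR_LEVELS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)

_LIGAND_RE = re.compile(r"^(m-)?(tet|oct)(-(p|pp))?$")


@dataclass(frozen=True)
class LigandCode:
    """Parsed ligand nomenclature: [m-]{tet|oct}[-{p|pp}]."""

    mimic: bool          # isoxazole mimic vs natural poly-beta-ketone
    body: str            # "tet" (8 C) or "oct" (16 C)
    arm: str | None      # "p" pantetheine, "pp" phosphopantetheine, None = bare

    @property
    def phosphorylated(self) -> bool:
        return self.arm == "pp"


def parse_ligand_code(code: str) -> LigandCode:
    """Parse a ligand label such as ``m-oct-pp`` or ``tet-p``.

    Prefix ``m`` marks an isoxazole mimic; body ``tet``/``oct`` gives the
    ketide length; suffix ``p``/``pp`` distinguishes pantetheine from
    phosphopantetheine (absent suffix = polyketide moiety only).
    """
    m = _LIGAND_RE.match(code.strip().lower())
    if not m:
        raise ValueError(f"unknown ligand code {code!r}")
    return LigandCode(mimic=m.group(1) is not None, body=m.group(2), arm=m.group(4))


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float
    stars: str
    direction: int  # sign of mean_a - mean_b
    context: str = ""  # e.g. the ligand or KR the comparison is stratified by


def welch_t_test(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; Welch (unequal variance) by default.

    Returns (t statistic, Welch-Satterthwaite df, two-sided p). Two
    constant samples with equal means give (0, n_a + n_b - 2, 1) by
    convention; constant samples with different means are degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate input: zero variance with different means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def significance_stars(p_value: float) -> str:
    """Map a p-value onto the figure star scheme (inclusive boundaries)."""
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    for bound, stars in STAR_LEVELS:
        if p_value <= bound:
            return stars
    return "ns"


def block_average(values: np.ndarray, block_size: int) -> np.ndarray:
    """Average consecutive blocks to blunt framewise autocorrelation.

    A trailing partial block is dropped. block_size = 1 is the identity.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    values = np.asarray(values, dtype=float)
    n = (len(values) // block_size) * block_size
    if n == 0:
        return np.empty(0)
    return values[:n].reshape(-1, block_size).mean(axis=1)


def _compare_cells(
    name_a: str, values_a: np.ndarray,
    name_b: str, values_b: np.ndarray,
    context: str, equal_var: bool,
) -> ComparisonResult | None:
    if len(values_a) < 2 or len(values_b) < 2:
        logger.warning("skipping %s: cell %s or %s has < 2 values",
                       context, name_a, name_b)
        return None
    t, df, p = welch_t_test(values_a, values_b, equal_var=equal_var)
    mean_a, mean_b = float(np.mean(values_a)), float(np.mean(values_b))
    return ComparisonResult(
        group_a=name_a, group_b=name_b,
        n_a=len(values_a), n_b=len(values_b),
        mean_a=mean_a, mean_b=mean_b,
        t_stat=t, df=df, p_value=p,
        stars=significance_stars(p),
        direction=int(np.sign(mean_a - mean_b)),
        context=context,
    )


def grouped_comparison(
    dataset: pd.DataFrame,
    grouping: str,
    value_column: str = "value",
    equal_var: bool = False,
    block_size: int = 1,
    bh_correction: bool = False,
) -> list[ComparisonResult]:
    """Run the panel-style pairwise comparisons over a labelled dataset.

    ``dataset`` holds one production-window value per row with labels
    ``ligand``, ``kr_type``, ``binding_site`` (and optionally
    ``replicate``). Groupings:

    - ``by-binding-site``: per ligand, front vs back windows.
    - ``by-kr-type``: per ligand, every pair of KR types.
    - ``by-phosphorylation``: per KR type and ketide body, -p vs -pp.

    Cells with fewer than 2 values are skipped with a warning. Results
    are sorted deterministically by (context, group pair).
    """
    results: list[ComparisonResult] = []

    def cell(mask) -> np.ndarray:
        vals = dataset.loc[mask, value_column].to_numpy(dtype=float)
        return block_average(vals, block_size)

    if grouping == "by-binding-site":
        for ligand in sorted(dataset["ligand"].unique()):
            sub = dataset["ligand"] == ligand
            res = _compare_cells(
                "front", cell(sub & (dataset["binding_site"] == "front")),
                "back", cell(sub & (dataset["binding_site"] == "back")),
                context=ligand, equal_var=equal_var,
            )
            if res:
                results.append(res)
    elif grouping == "by-kr-type":
        for ligand in sorted(dataset["ligand"].unique()):
            sub = dataset["ligand"] == ligand
            kr_types = sorted(dataset.loc[sub, "kr_type"].unique())
            for kr_a, kr_b in itertools.combinations(kr_types, 2):
                res = _compare_cells(
                    kr_a, cell(sub & (dataset["kr_type"] == kr_a)),
                    kr_b, cell(sub & (dataset["kr_type"] == kr_b)),
                    context=ligand, equal_var=equal_var,
                )
                if res:
                    results.append(res)
    elif grouping == "by-phosphorylation":
        parsed = dataset["ligand"].map(parse_ligand_code)
        bodies = parsed.map(lambda c: c.body)
        arms = parsed.map(lambda c: c.arm)
        for kr in sorted(dataset["kr_type"].unique()):
            for body in sorted(bodies.unique()):
                sub = (dataset["kr_type"] == kr) & (bodies == body)
                res = _compare_cells(
                    f"{body}-p", cell(sub & (arms == "p")),
                    f"{body}-pp", cell(sub & (arms == "pp")),
                    context=kr, equal_var=equal_var,
                )
                if res:
                    results.append(res)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    results.sort(key=lambda r: (r.context, r.group_a, r.group_b))
    if bh_correction and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = m - rank
            prev = min(prev, results[idx].p_value * m / i)
            adj[idx] = prev
        results = [
            ComparisonResult(
                **{**r.__dict__, "p_value": float(adj[i]),
                   "stars": significance_stars(float(adj[i]))}
            )
            for i, r in enumerate(results)
        ]
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a tidy DataFrame for CSV output."""
    return pd.DataFrame([r.__dict__ for r in results])
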