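"""Lookup tables of accuracy bounds over parameter grids.

Regenerates, as delimited text, the reference tables a user would otherwise
look bounds up in: maximal AUC over a (PVE, prevalence) grid, maximal
sensitivity over specificity targets for chosen (PVE, prevalence) pairs,
and a bin-resolution convergence report.  Grid cells where (k, PVE) is not
attainable on the bin grid are flagged infeasible (NaN) rather than filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .auc_bound import max_auc
from .risk_model import DiseaseParams
from .roc_bound import max_roc_point

__all__ = ["BoundTable", "auc_table", "sens_table", "convergence_report"]

logger = logging.getLogger(__name__)


@dataclass
class BoundTable:
    """A labelled grid of bounds, serializable to CSV with metadata header."""

    row_labels: list
    col_labels: list
    values: np.ndarray
    statuses: np.ndarray
    metadata: dict = field(default_factory=dict)
    row_name: str = "pve"
    col_name: str = "k"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("bound values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.Index(self.row_labels, name=self.row_name)
        return pd.DataFrame(self.values, index=idx, columns=self.col_labels)

    def to_csv(self, path, percent: bool = False) -> None:
        """Write as CSV with a commented ``# key=value`` metadata header."""
        df = self.to_dataframe()
        if percent:
            df = df * 100.0
        with open(path, "w") as fh:
            for key, val in self.metadata.items():
                fh.write(f"# {key}={val}\n")
            fh.write(f"# units={'percent' if percent else 'proportion'}\n")
            df.to_csv(fh)


def _labels_ok(grid: Sequence[float], upper_open: bool = True) -> None:
    g = np.asarray(grid, dtype=float)
    if np.any(np.diff(g) <= 0):
        raise ValueError("grid labels must be strictly increasing")
    if np.any(g <= 0) or np.any(g > 1) or (upper_open and np.any(g >= 1)):
        raise ValueError("grid values out of range")


def _meta(b: int, kind: str) -> dict:
    from riskbounds import __version__

    return {
        "tool": f"riskbounds {__version__}",
        "table": kind,
        "bins": b,
        "generated": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def auc_table(
    pve_grid: Sequence[float], k_grid: Sequence[float], b: int = 100
) -> BoundTable:
    """Maximal AUC for every (PVE, prevalence) grid cell.

    Rows are PVE values, columns prevalences; infeasible cells are NaN with
    status recorded.  Deterministic for a given solver and ``b``.
    """
    _labels_ok(pve_grid, upper_open=False)  # pve = 1 (Mendelian) is allowed
    _labels_ok(k_grid)
    values = np.full((len(pve_grid), len(k_grid)), np.nan)
    statuses = np.empty(values.shape, dtype=object)
    for r, pve in enumerate(pve_grid):
        for c, k in enumerate(k_grid):
            res = max_auc(DiseaseParams(k=k, pve=pve), b=b)
            values[r, c] = res.max_auc
            statuses[r, c] = res.solver_status
            logger.debug("auc cell pve=%g k=%g: %s", pve, k, res.solver_status)
    n_bad = int((statuses != "optimal").sum())
    logger.info("auc_table: %d cells, %d not optimal", values.size, n_bad)
    return BoundTable(list(pve_grid), list(k_grid), values, statuses, _meta(b, "max_auc"))


def sens_table(
    pve_k_pairs: Sequence[tuple[float, float]],
    spec_grid: Sequence[float],
    b: int = 1000,
) -> BoundTable:
    """Maximal sensitivity per specificity, one row per (PVE, prevalence).

    Columns are specificity targets; row labels are ``(pve, k)`` pairs.
    """
    spec = np.asarray(spec_grid, dtype=float)
    if np.any(np.diff(spec) <= 0) or np.any(spec < 0) or np.any(spec > 1):
        raise ValueError("spec_grid must be strictly increasing within [0, 1]")
    values = np.full((len(pve_k_pairs), len(spec)), np.nan)
    statuses = np.empty(values.shape, dtype=object)
    for r, (pve, k) in enumerate(pve_k_pairs):
        params = DiseaseParams(k=k, pve=pve)
        for c, s in enumerate(spec):
            pt = max_roc_point(params, s, b=b)
            values[r, c] = pt.value
            statuses[r, c] = pt.solver_status
            logger.debug(
                "sens cell pve=%g k=%g spec=%g: %s", pve, k, s, pt.solver_status
            )
    n_bad = int((statuses != "optimal").sum())
    logger.info("sens_table: %d cells, %d not optimal", values.size, n_bad)
    tab = BoundTable(
        [f"pve={pve:g},k={k:g}" for pve, k in pve_k_pairs],
        list(spec),
        values,
        statuses,
        _meta(b, "max_sensitivity"),
        row_name="pve_k",
        col_name="specificity",
    )
    return tab


def convergence_report(
    pve_grid: Sequence[float],
    k_grid: Sequence[float],
    b_list: Sequence[int],
) -> pd.DataFrame:
    """Per-cell change in maximal AUC across bin counts.

    The last (largest) entry of ``b_list`` is the reference; for each other
    ``b`` the report gives ``|AUC(b) - AUC(b_ref)|`` per feasible-at-both
    cell, in long format, plus the grid maximum is available as
    ``df.groupby('b')['abs_diff'].max()``.
    """
    b_list = list(b_list)
    if b_list != sorted(b_list):
        raise ValueError("b_list must be sorted ascending")
    b_ref = b_list[-1]
    tables = {b: auc_table(pve_grid, k_grid, b=b) for b in b_list}
    rows = []
    for b in b_list[:-1]:
        diff = np.abs(tables[b].values - tables[b_ref].values)
        for r, pve in enumerate(pve_grid):
            for c, k in enumerate(k_grid):
                rows.append(
                    {
                        "b": b,
                        "b_ref": b_ref,
                        "pve": pve,
                        "k": k,
                        "auc_b": tables[b].values[r, c],
                        "auc_ref": tables[b_ref].values[r, c],
                        "abs_diff": diff[r, c],
                    }
                )
    return pd.DataFrame(rows)
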