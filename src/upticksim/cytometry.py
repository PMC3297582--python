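"""Single-cell two-reporter competence classification.

The pipeline starts from a per-cell intensity table (cell id, mean CFP
pixel intensity, mean YFP pixel intensity).  A competence threshold on the
comK-CFP reporter is calibrated from a late-timepoint population in which
truly competent cells are identified by a second, ComK-dependent reporter
(comG-YFP): the fraction of comG-high cells fixes the competent fraction,
and the threshold is the CFP value enclosing that same upper fraction of
an earlier population.  Cells above threshold are classified competent,
competent fractions are histogrammed against a YFP axis reporting Spo0A~P,
and the proportion of competent cells on either side of an
analyst-supplied YFP boundary is compared with a two-proportion z-test
(Fisher's exact test as a small-count cross-check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

REQUIRED_COLUMNS = ("cell_id", "cfp", "yfp")

#: default comG-YFP cutoff separating the competent cluster in a late
#: calibration population (a.u.)
DEFAULT_COMG_CUTOFF = 50.0


class CellTableError(ValueError):
    """Malformed per-cell intensity table."""


class DegenerateCalibrationError(ValueError):
    """Calibration population is all-competent or all-noncompetent."""


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the (cell_id, cfp, yfp) schema and intensity invariants."""
    for col in REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise CellTableError(f"cell table is missing column {col!r}")
    if len(cells) == 0:
        raise CellTableError("cell table is empty")
    for col in ("cfp", "yfp"):
        vals = cells[col]
        if vals.isna().any():
            raise CellTableError(f"column {col!r} contains missing values")
        if (vals < 0).any():
            raise CellTableError(f"column {col!r} contains negative intensities")
    return cells


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV cell table with header cell_id, cfp, yfp."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    return validate_cell_table(pd.read_csv(path, sep=sep))


def upper_quantile_threshold(values: np.ndarray, fraction: float) -> float:
    """Lower edge of the box enclosing the upper ``fraction`` of values.

    Nearest-rank convention: with values sorted ascending, the threshold is
    the ceil((1 - fraction) * n)-th value, so strictly more-than-threshold
    selects (at ties, at most) the upper ``fraction`` of cells.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise CellTableError("no values to take a quantile of")
    k = max(1, math.ceil((1.0 - fraction) * n))
    return float(values[k - 1])


def calibrate_threshold(
    calib_late: pd.DataFrame,
    comg_cutoff: float = DEFAULT_COMG_CUTOFF,
    early: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Calibrate the competent fraction and the comK-CFP threshold.

    Parameters
    ----------
    calib_late
        Late-timepoint cell table whose ``yfp`` channel reports comG
        expression; cells with yfp > comg_cutoff form the competent
        cluster.
    comg_cutoff
        comG-YFP value separating that cluster (a.u.).
    early
        Earlier cell table whose ``cfp`` distribution the calibrated
        fraction is transferred onto.  The returned threshold is the lower
        edge of the box enclosing the upper ``fraction`` of its CFP values.

    Returns
    -------
    (fraction, threshold)
        The competent fraction at the late time and the CFP threshold
        (a.u.) derived from the early population.
    """
    validate_cell_table(calib_late)
    if early is None:
        raise CellTableError("an early cell table is required for the threshold")
    validate_cell_table(early)
    fraction = float((calib_late["yfp"] > comg_cutoff).mean())
    if fraction <= 0.0 or fraction >= 1.0:
        raise DegenerateCalibrationError(
            f"competent fraction at the late time is {fraction:.3f}; the "
            f"comG cutoff {comg_cutoff} does not separate two populations"
        )
    threshold = upper_quantile_threshold(early["cfp"].to_numpy(), fraction)
    return fraction, threshold


def classify_competent(
    cells: pd.DataFrame, threshold: float
) -> tuple[np.ndarray, float]:
    """Label cells with cfp strictly above threshold as competent.

    Returns the boolean label array and the competent fraction.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    validate_cell_table(cells)
    labels = cells["cfp"].to_numpy() > threshold
    return labels, float(labels.mean())


def binned_competence_fraction(
    cells: pd.DataFrame, labels: np.ndarray, yfp_bin_edges: np.ndarray
) -> pd.DataFrame:
    """Percent competent per YFP bin, normalised within each bin.

    Returns a frame with bin edges and centres, total and competent counts,
    ``percent_competent`` (NaN for empty bins) and an ``empty`` flag --
    empty bins are flagged, not reported as 0%.
    """
    validate_cell_table(cells)
    edges = np.asarray(yfp_bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("yfp_bin_edges must be strictly increasing")
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(cells):
        raise ValueError("labels length must match the cell table")
    yfp = cells["yfp"].to_numpy()
    total, _ = np.histogram(yfp, bins=edges)
    comp, _ = np.histogram(yfp[labels], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(total > 0, 100.0 * comp / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "yfp_low": edges[:-1],
            "yfp_high": edges[1:],
            "yfp_center": 0.5 * (edges[:-1] + edges[1:]),
            "n_total": total,
            "n_competent": comp,
            "percent_competent": percent,
            "empty": total == 0,
        }
    )


@dataclass(frozen=True)
class ContingencyTable:
    """Competent-vs-total counts on either side of a YFP boundary."""

    n_comp_above: int
    n_total_above: int
    n_comp_below: int
    n_total_below: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_comp_above <= self.n_total_above):
            raise ValueError("need 0 <= n_comp_above <= n_total_above")
        if not (0 <= self.n_comp_below <= self.n_total_below):
            raise ValueError("need 0 <= n_comp_below <= n_total_below")

    @classmethod
    def from_cells(
        cls, cells: pd.DataFrame, labels: np.ndarray, boundary: float
    ) -> "ContingencyTable":
        """Split a labelled cell table at a YFP boundary."""
        validate_cell_table(cells)
        labels = np.asarray(labels, dtype=bool)
        above = cells["yfp"].to_numpy() > boundary
        return cls(
            n_comp_above=int((labels & above).sum()),
            n_total_above=int(above.sum()),
            n_comp_below=int((labels & ~above).sum()),
            n_total_below=int((~above).sum()),
        )


@dataclass(frozen=True)
class ProportionTestResult:
    p_above: float        # percent competent above the boundary
    p_below: float        # percent competent below the boundary
    p_value: float        # two-sided p-value (z-test, or Fisher if sparse)
    z_statistic: float
    p_value_ztest: float
    p_value_fisher: float | None
    used_fisher: bool


def boundary_proportion_test(table: ContingencyTable) -> ProportionTestResult:
    """Two-sided test that the competent proportions differ across the
    boundary.

    Uses the pooled two-proportion z-test (the standard large-sample test
    for equality of two proportions).  When any contingency cell is below
    5, Fisher's exact test is computed as a cross-check and its p-value is
    reported as the headline ``p_value``.
    """
    if table.n_total_above == 0 or table.n_total_below == 0:
        raise ValueError("both boundary groups must contain cells")
    x1, n1 = table.n_comp_above, table.n_total_above
    x2, n2 = table.n_comp_below, table.n_total_below
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        z, p_z = 0.0, 1.0
    else:
        z = (p1 - p2) / se
        p_z = 2.0 * sps.norm.sf(abs(z))
    cells = (x1, n1 - x1, x2, n2 - x2)
    p_fisher = None
    if min(cells) < 5:
        _, p_fisher = sps.fisher_exact(
            [[x1, n1 - x1], [x2, n2 - x2]], alternative="two-sided"
        )
        p_fisher = float(p_fisher)
    used_fisher = p_fisher is not None
    return ProportionTestResult(
        p_above=100.0 * p1,
        p_below=100.0 * p2,
        p_value=p_fisher if used_fisher else p_z,
        z_statistic=z,
        p_value_ztest=p_z,
        p_value_fisher=p_fisher,
        used_fisher=used_fisher,
    )


def boundary_scan(
    cells: pd.DataFrame, labels: np.ndarray, candidates
) -> pd.DataFrame:
    """Proportion profile over candidate YFP boundaries.

    Helper for choosing the boundary by inspection: for each candidate it
    reports the competent percentage on each side and the test p-value.
    """
    rows = []
    for b in candidates:
        tab = ContingencyTable.from_cells(cells, labels, b)
        if tab.n_total_above == 0 or tab.n_total_below == 0:
            continue
        res = boundary_proportion_test(tab)
        rows.append(
            {
                "boundary": b,
                "pct_above": res.p_above,
                "pct_below": res.p_below,
                "p_value": res.p_value,
                "n_above": tab.n_total_above,
                "n_below": tab.n_total_below,
            }
        )
    return pd.DataFrame(rows)
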