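"""Grid-cell species assemblages and their trait summaries.

An assemblage is the set of species breeding in one equal-area grid cell.
Per cell this module derives nest-type counts, mean egg elongation for cup
and dome nesters (cavity nesters are too few and are excluded from the
elongation summaries), the proportion of dome-nesting species, and a
Chao2-based sampling-completeness index used to drop poorly surveyed cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec, assign_cell, project_lonlat

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "cell_ix", "cell_iy", "x", "y", "n_species", "n_cup", "n_dome",
    "n_cavity", "n_unknown", "mean_elong_cup", "mean_elong_dome",
    "prop_dome", "completeness", "retained",
]


@dataclass
class CompletenessResult:
    s_obs: int
    s_est: float
    q1: int
    q2: int
    index: float  # NaN when undefined (fewer than 2 sampling events)


def completeness_index(incidence_counts, n_events: int) -> CompletenessResult:
    """Chao2 sampling-completeness from incidence counts.

    ``incidence_counts`` holds, per observed species, the number of distinct
    sampling events in which it was recorded in the cell; ``n_events`` (m)
    is the number of sampling events in the cell.  The bias-corrected Chao2
    richness estimate is

        S_est = S_obs + ((m-1)/m) * Q1 (Q1 - 1) / (2 (Q2 + 1))

    with Q1/Q2 the species seen in exactly one/two events, and the index is
    S_obs / S_est.  With m < 2 the estimator is undefined (index NaN).
    """
    counts = np.asarray(list(incidence_counts), dtype=int)
    counts = counts[counts > 0]
    s_obs = int(counts.size)
    q1 = int(np.count_nonzero(counts == 1))
    q2 = int(np.count_nonzero(counts == 2))
    m = int(n_events)
    if m < 2 or s_obs == 0:
        return CompletenessResult(s_obs, float("nan"), q1, q2, float("nan"))
    s_est = s_obs + ((m - 1) / m) * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    return CompletenessResult(s_obs, float(s_est), q1, q2, s_obs / s_est)


def _grid_occurrences(occurrences: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Attach (cell_ix, cell_iy) to occurrence rows; drop off-grid points."""
    occ = occurrences
    if {"cell_ix", "cell_iy"}.issubset(occ.columns):
        out = occ.copy()
    else:
        if not {"lon", "lat"}.issubset(occ.columns):
            raise ValueError(
                "occurrences need either lon/lat or cell_ix/cell_iy columns"
            )
        x, y = project_lonlat(occ["lon"].to_numpy(), occ["lat"].to_numpy(),
                              grid.projection)
        ix, iy = assign_cell(x, y, grid)
        out = occ.copy()
        out["cell_ix"], out["cell_iy"] = ix, iy
    off = (out["cell_ix"] < 0) | (out["cell_iy"] < 0)
    if off.any():
        logger.info("dropping %d off-grid occurrence record(s)", int(off.sum()))
        out = out.loc[~off]
    return out


def build_assemblages(occurrences: pd.DataFrame, traits: pd.DataFrame,
                      grid: GridSpec,
                      dome_denominator: str = "all") -> pd.DataFrame:
    """Build per-cell assemblages with trait summaries.

    Occurrence rows may carry lon/lat (projected and gridded here) or
    pre-gridded cell_ix/cell_iy.  Duplicate (species, cell) records collapse
    to one — assemblages have set semantics.  Species without a trait record
    are counted as ``n_unknown`` and excluded from summaries.

    ``dome_denominator``: 'all' divides n_dome by all trait-classified
    species in the cell; 'cup_dome' divides by cup + dome only.
    """
    if dome_denominator not in ("all", "cup_dome"):
        raise ValueError("dome_denominator must be 'all' or 'cup_dome'")
    occ = _grid_occurrences(occurrences, grid)
    has_events = "event_id" in occ.columns and occ["event_id"].notna().any()
    cell_keys = ["cell_ix", "cell_iy"]

    # set semantics: one row per (species, cell)
    pairs = occ[cell_keys + ["species_id"]].drop_duplicates()
    pairs = pairs.merge(
        traits[["species_id", "nest_type", "elongation"]],
        on="species_id", how="left",
    )
    base = pairs.groupby(cell_keys).agg(n_species=("species_id", "size"))
    counts = (pairs.dropna(subset=["nest_type"])
              .groupby(cell_keys + ["nest_type"], observed=True)
              .size().unstack("nest_type", fill_value=0)
              .reindex(columns=["cup", "dome", "cavity"], fill_value=0))
    means = (pairs.dropna(subset=["nest_type"])
             .groupby(cell_keys + ["nest_type"], observed=True)["elongation"]
             .mean().unstack("nest_type")
             .reindex(columns=["cup", "dome"]))
    cells = base.join(counts, how="left").join(
        means.rename(columns={"cup": "mean_elong_cup",
                              "dome": "mean_elong_dome"}), how="left")
    for col in ("cup", "dome", "cavity"):
        cells[col] = cells[col].fillna(0).astype(int)
    cells = cells.rename(columns={"cup": "n_cup", "dome": "n_dome",
                                  "cavity": "n_cavity"})
    cells["n_unknown"] = (pairs["nest_type"].isna()
                          .groupby([pairs[k] for k in cell_keys]).sum()
                          .astype(int))
    denom = cells["n_cup"] + cells["n_dome"]
    if dome_denominator == "all":
        denom = denom + cells["n_cavity"]
    cells["prop_dome"] = np.where(denom > 0, cells["n_dome"] / denom, np.nan)

    if has_events:
        ev = occ.dropna(subset=["event_id"])
        m_events = ev.groupby(cell_keys)["event_id"].nunique()
        incidence = (ev.groupby(cell_keys + ["species_id"])["event_id"]
                     .nunique())
        comp = {}
        for key, inc in incidence.groupby(level=cell_keys):
            comp[key] = completeness_index(
                inc.to_numpy(), int(m_events.loc[key])
            ).index
        cells["completeness"] = pd.Series(comp)
    else:
        cells["completeness"] = np.nan

    cells = cells.reset_index()
    cx, cy = grid.centroid(cells["cell_ix"].to_numpy(),
                           cells["cell_iy"].to_numpy())
    cells["x"], cells["y"] = cx, cy
    cells["retained"] = True
    return (cells[CELL_COLUMNS]
            .sort_values(cell_keys, kind="mergesort")
            .reset_index(drop=True))


def filter_cells(cells: pd.DataFrame, min_per_type: int = 10,
                 ci_threshold: float = 0.7,
                 missing_completeness: str = "retain") -> pd.DataFrame:
    """Set the ``retained`` flag for analysis cells.

    A cell is retained iff it has at least ``min_per_type`` dome-nesting AND
    ``min_per_type`` cup-nesting species, and its completeness index clears
    ``ci_threshold``.  Cells lacking a completeness value are retained or
    dropped according to ``missing_completeness`` ('retain' / 'drop').
    """
    if missing_completeness not in ("retain", "drop"):
        raise ValueError("missing_completeness must be 'retain' or 'drop'")
    out = cells.copy()
    ok_counts = (out["n_dome"] >= min_per_type) & (out["n_cup"] >= min_per_type)
    comp = out["completeness"]
    ok_comp = comp >= ci_threshold
    if missing_completeness == "retain":
        ok_comp = ok_comp | comp.isna()
    out["retained"] = (ok_counts & ok_comp).to_numpy()
    return out


def quantile_threshold(values, q: float = 0.8) -> float:
    """Empirical quantile, linear interpolation between order statistics."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values for quantile")
    return float(np.quantile(vals, q))


def cells_to_raster(cells: pd.DataFrame, grid: GridSpec,
                    column: str) -> np.ndarray:
    """Paint a per-cell column onto the (ny, nx) grid (NaN where absent)."""
    out = np.full((grid.ny, grid.nx), np.nan)
    out[cells["cell_iy"].to_numpy(), cells["cell_ix"].to_numpy()] = (
        cells[column].to_numpy(dtype=float)
    )
    return out
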