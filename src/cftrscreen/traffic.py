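"""High-content siRNA traffic-screen scoring.

Image-level well summaries (median surface-reporter intensity per image)
are QC-filtered, collapsed to one value per well, and converted to a
Z-score against the median of the well's 5 x 5 plate neighbourhood —
a local reference that removes smooth spatial gradients (edge effects,
illumination) without touching isolated well-level siRNA effects.  The
scale is the plate-level robust SD (1.4826 x MAD) of the local
residuals.  Per-siRNA scores are medians across replicate wells and
experimental replicates; hits are siRNAs with Z > +1 (increase) or
Z < -1 (decrease), and a gene is called ambiguous when its siRNAs pass
in opposite directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MEASURE_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "replicate",
    "image_index",
    "n_cells",
    "median_traffic",
    "median_expression",
    "focus_metric",
    "sirna_id",
    "gene",
    "is_negative_control",
]


@dataclass
class QCResult:
    kept: pd.DataFrame
    rejected: pd.DataFrame  # with a "reject_reason" column
    reasons: dict[str, int]


def qc_filter(
    measures: pd.DataFrame,
    min_cells: int = 100,
    focus_threshold: float = 0.5,
    expression_threshold: float | None = None,
    neg_control_quantile: float = 0.10,
) -> QCResult:
    """Reject images with too few cells, poor focus or negligible expression.

    Rules, applied per image in order: ``n_cells < min_cells``;
    ``focus_metric < focus_threshold``; ``median_expression`` below the
    negligible-expression threshold.  When ``expression_threshold`` is
    None it defaults per plate/replicate to the ``neg_control_quantile``
    quantile of the negative-control wells' expression (absolute values
    can be supplied instead).
    """
    df = measures.copy()
    reason = pd.Series("", index=df.index, dtype=object)

    if expression_threshold is None:
        neg = df[df["is_negative_control"]]
        if len(neg) == 0:
            warnings.warn(
                "no negative-control wells; skipping expression QC", stacklevel=2
            )
            thresh = pd.Series(-np.inf, index=df.index)
        else:
            per_plate = neg.groupby(["plate_id", "replicate"])[
                "median_expression"
            ].quantile(neg_control_quantile)
            key = pd.MultiIndex.from_frame(df[["plate_id", "replicate"]])
            thresh = pd.Series(
                per_plate.reindex(key).to_numpy(), index=df.index
            ).fillna(-np.inf)
    else:
        thresh = pd.Series(expression_threshold, index=df.index)

    low_expr = df["median_expression"] < thresh
    out_of_focus = df["focus_metric"] < focus_threshold
    low_cells = df["n_cells"] < min_cells
    # first matching rule wins for the tally
    reason[low_expr] = "low_expression"
    reason[out_of_focus] = "out_of_focus"
    reason[low_cells] = "low_cells"

    bad = reason != ""
    rejected = df[bad].copy()
    rejected["reject_reason"] = reason[bad]
    reasons = rejected["reject_reason"].value_counts().to_dict()
    return QCResult(kept=df[~bad].copy(), rejected=rejected, reasons=reasons)


def well_summary(kept: pd.DataFrame) -> pd.DataFrame:
    """Median of the valid image medians per well (plate, replicate, row, col).

    Wells whose images were all rejected simply have no row here and are
    excluded downstream.
    """
    grouped = (
        kept.groupby(
            ["plate_id", "replicate", "row", "col", "sirna_id", "gene"],
            as_index=False,
        )
        .agg(well_traffic=("median_traffic", "median"), n_images=("median_traffic", "size"))
    )
    return grouped


def _window_median(grid: np.ndarray, half: int = 2) -> np.ndarray:
    """NaN-aware median of the (2*half+1)^2 window, truncated at edges."""
    n_rows, n_cols = grid.shape
    out = np.full_like(grid, np.nan)
    for r in range(n_rows):
        r0, r1 = max(0, r - half), min(n_rows, r + half + 1)
        for c in range(n_cols):
            c0, c1 = max(0, c - half), min(n_cols, c + half + 1)
            window = grid[r0:r1, c0:c1]
            if np.isfinite(window).any():
                out[r, c] = np.nanmedian(window)
    return out


def _mad(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return 0.0
    return float(np.median(np.abs(values - np.median(values))))


def neighborhood_zscore(
    wells: pd.DataFrame,
    scale: str = "plate_mad",
    include_center: bool = True,
) -> pd.DataFrame:
    """Per-well Z against the median of its 5 x 5 neighbourhood.

    For well w: center(w) = median of valid well summaries in the 5 x 5
    window around w (truncated at plate edges; the center well is part
    of its own window unless ``include_center=False``).  Scale options:

    - ``plate_mad`` (default): 1.4826 x MAD of (well - center) over all
      valid wells on the plate/replicate;
    - ``neighborhood_mad``: per-well 1.4826 x MAD of the window residuals;
    - ``neg_control_sd``: SD of negative-control well summaries.

    Z = (well - center) / scale, and Z = 0 wherever the scale is 0.
    Plates with fewer than 2 valid wells are skipped with a warning.
    """
    if scale not in ("plate_mad", "neighborhood_mad", "neg_control_sd"):
        raise ValueError(f"unknown scale estimator {scale!r}")
    results = []
    for (plate_id, rep), grp in wells.groupby(["plate_id", "replicate"]):
        if len(grp) < 2:
            warnings.warn(
                f"plate {plate_id}/{rep}: fewer than 2 valid wells, skipped",
                stacklevel=2,
            )
            continue
        n_rows = int(grp["row"].max())
        n_cols = int(grp["col"].max())
        grid = np.full((n_rows, n_cols), np.nan)
        grid[grp["row"] - 1, grp["col"] - 1] = grp["well_traffic"].to_numpy()
        center = (
            _window_median(grid) if include_center else _window_median_excl(grid)
        )
        resid = grid - center
        if scale == "plate_mad":
            s = 1.4826 * _mad(resid)
            s_grid = np.full_like(grid, s)
        elif scale == "neg_control_sd":
            neg = grp[grp["sirna_id"] == "siNeg1"]["well_traffic"].to_numpy()
            s = float(np.std(neg, ddof=1)) if len(neg) > 1 else 0.0
            s_grid = np.full_like(grid, s)
        else:
            s_grid = _window_mad(grid, center)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(s_grid > 0, resid / s_grid, 0.0)
        out = grp.copy()
        out["z_score"] = z[grp["row"] - 1, grp["col"] - 1]
        results.append(out)
    if not results:
        return wells.iloc[0:0].assign(z_score=pd.Series(dtype=float))
    return pd.concat(results, ignore_index=True)


def _window_median_excl(grid: np.ndarray, half: int = 2) -> np.ndarray:
    n_rows, n_cols = grid.shape
    out = np.full_like(grid, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            r0, r1 = max(0, r - half), min(n_rows, r + half + 1)
            c0, c1 = max(0, c - half), min(n_cols, c + half + 1)
            window = grid[r0:r1, c0:c1].copy()
            window[r - r0, c - c0] = np.nan
            if np.isfinite(window).any():
                out[r, c] = np.nanmedian(window)
    return out


def _window_mad(grid: np.ndarray, center: np.ndarray, half: int = 2) -> np.ndarray:
    resid = grid - center
    n_rows, n_cols = grid.shape
    out = np.full_like(grid, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            r0, r1 = max(0, r - half), min(n_rows, r + half + 1)
            c0, c1 = max(0, c - half), min(n_cols, c + half + 1)
            window = resid[r0:r1, c0:c1]
            if np.isfinite(window).any():
                out[r, c] = 1.4826 * _mad(window)
    return out


def aggregate_and_call(
    zscores: pd.DataFrame,
    z_threshold: float = 1.0,
    layout: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse well Z-scores to per-siRNA results and per-gene calls.

    The reported per-siRNA Z is the median across that siRNA's valid
    wells over all experimental replicates; ``n_valid_replicates``
    counts replicates contributing at least one valid well.  Direction:
    increase if Z > +z_threshold, decrease if Z < -z_threshold, else
    none.  Gene call: enhancer / inhibitor when at least one siRNA
    passes in a single direction, ambiguous when siRNAs pass in both
    directions, none otherwise.  When a ``layout`` (sirna_id, gene) frame
    is supplied, siRNAs with no valid wells are still reported, with
    n_valid_replicates = 0 and no call.
    """
    if layout is not None:
        all_sirnas = layout[["sirna_id", "gene"]].drop_duplicates()
    else:
        all_sirnas = zscores[["sirna_id", "gene"]].drop_duplicates()
    agg = (
        zscores.groupby(["sirna_id", "gene"])
        .agg(
            z_score=("z_score", "median"),
            n_valid_replicates=("replicate", "nunique"),
        )
        .reset_index()
    )
    sirna = all_sirnas.merge(agg, on=["sirna_id", "gene"], how="left")
    sirna["n_valid_replicates"] = sirna["n_valid_replicates"].fillna(0).astype(int)

    def _direction(row) -> str:
        if row["n_valid_replicates"] == 0 or not np.isfinite(row["z_score"]):
            return "none"
        if row["z_score"] > z_threshold:
            return "increase"
        if row["z_score"] < -z_threshold:
            return "decrease"
        return "none"

    sirna["direction"] = sirna.apply(_direction, axis=1)

    gene_rows = []
    for gene, grp in sirna.groupby("gene"):
        dirs = set(grp["direction"]) - {"none"}
        if dirs == {"increase", "decrease"}:
            call = "ambiguous"
        elif dirs == {"increase"}:
            call = "enhancer"
        elif dirs == {"decrease"}:
            call = "inhibitor"
        else:
            call = "none"
        gene_rows.append((gene, call, len(grp)))
    genes = pd.DataFrame(gene_rows, columns=["gene", "gene_call", "n_sirnas"])
    return sirna, genes
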