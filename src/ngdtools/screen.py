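"""Reporter-SGA overexpression screen scoring.

Colony-array plates (1536 format, four colonies per overexpression strain)
carry GFP and RFP fluorescence plus colony size.  Scoring: drop border strains
and size outliers (<1500 or >6000 px), aggregate replicate colonies per strain
(median by default; the mean is selectable), take log2(GFP/RFP), remove smooth
spatial artifacts with per-plate LOESS against column then row, and Z-score
each plate.  A strain is a hit when |Z| > 2.5 on an NGD reporter plate while
its OPT-reporter Z stays strictly inside (-2.5, 2.5) — the signature by which
the screen singled out CUE2 overexpression.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger("ngdtools")

SIZE_MIN = 1500
SIZE_MAX = 6000
Z_CUTOFF = 2.5


def filter_colonies(
    grid: pd.DataFrame,
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
    border_width: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove border positions and colony-size outliers.

    The size band is inclusive: exactly 1500 or 6000 px survives.  Border
    positions come from the ``is_border`` column when present; otherwise the
    outermost ``border_width`` (default 2) rows/columns are treated as border.
    """
    grid = grid.copy()
    if "is_border" in grid.columns and border_width is None:
        border = grid["is_border"].astype(bool)
    else:
        bw = 2 if border_width is None else border_width
        nr, nc = grid["row"].max() + 1, grid["col"].max() + 1
        border = (
            (grid["row"] < bw) | (grid["col"] < bw)
            | (grid["row"] >= nr - bw) | (grid["col"] >= nc - bw)
        )
    size_out = (grid["size_px"] < size_min) | (grid["size_px"] > size_max)
    kept = grid[~border & ~size_out]
    report = {
        "total": len(grid),
        "border": int(border.sum()),
        "size_outlier": int((size_out & ~border).sum()),
        "kept": len(kept),
    }
    if report["kept"] == 0:
        warnings.warn("no colonies survive filtering")
    return kept.reset_index(drop=True), report


def score_strains(
    filtered: pd.DataFrame, aggregator: str = "median"
) -> pd.DataFrame:
    """Per-strain replicate aggregation and log2(GFP/RFP).

    Returns one row per strain with n_colonies_used, aggregated intensities,
    the log ratio and the strain's mean plate position (the LOESS covariates).
    Strains with a nonpositive aggregated intensity are omitted with a log
    message.
    """
    if aggregator not in ("median", "mean"):
        raise ValueError("aggregator must be 'median' or 'mean'")
    agg = filtered.groupby("strain").agg(
        plate_id=("plate_id", "first"),
        n_colonies_used=("gfp", "size"),
        med_gfp=("gfp", aggregator),
        med_rfp=("rfp", aggregator),
        row=("row", "mean"),
        col=("col", "mean"),
    )
    bad = agg[(agg["med_gfp"] <= 0) | (agg["med_rfp"] <= 0)]
    if len(bad):
        logger.warning("omitting %d strain(s) with nonpositive intensity", len(bad))
        agg = agg.drop(bad.index)
    agg["log2_ratio"] = np.log2(agg["med_gfp"] / agg["med_rfp"])
    return agg.reset_index().rename(columns={"strain": "strain_id"})


def loess_normalize(
    scores: pd.DataFrame, span: float = 0.5, covariates: Sequence[str] = ("col", "row")
) -> pd.DataFrame:
    """Subtract per-plate LOESS fits of log2_ratio against spatial covariates.

    Sequential smoothing (column index, then row index) removes smooth plate
    artifacts.  Plates with fewer than 10 strains skip LOESS and are centered
    on their median instead, with a warning.
    """
    scores = scores.copy()
    resid = scores["log2_ratio"].to_numpy(dtype=float)
    if len(scores) < 10:
        warnings.warn("fewer than 10 strains; skipping LOESS, centering on median")
        scores["loess_adjusted"] = resid - np.median(resid)
        return scores
    for cov in covariates:
        fitted = lowess(
            resid, scores[cov].to_numpy(dtype=float), frac=span, return_sorted=False
        )
        resid = resid - fitted
    scores["loess_adjusted"] = resid
    return scores


def zscore_plate(scores: pd.DataFrame) -> pd.DataFrame:
    """Standardize LOESS-adjusted scores per plate (sample sd)."""
    scores = scores.copy()
    adj = scores["loess_adjusted"].to_numpy(dtype=float)
    sd = adj.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("plate standard deviation is zero; Z-scores undefined")
    scores["z"] = (adj - adj.mean()) / sd
    return scores


def score_plate(
    grid: pd.DataFrame,
    aggregator: str = "median",
    span: float = 0.5,
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
) -> pd.DataFrame:
    """filter -> aggregate -> LOESS -> Z for one plate."""
    filtered, _ = filter_colonies(grid, size_min, size_max)
    return zscore_plate(loess_normalize(score_strains(filtered, aggregator), span))


def call_hits(
    z_ngd: Mapping[str, float] | pd.DataFrame,
    z_opt: Mapping[str, float] | pd.DataFrame,
    cutoff: float = Z_CUTOFF,
) -> pd.DataFrame:
    """Dual-reporter hit table.

    Hit iff |Z_ngd| > cutoff (strict) and -cutoff < Z_opt < cutoff.  The
    direction column separates decreased-GFP (Cue2-like) from increased-GFP
    strains.  Strains missing from either plate are excluded and counted in
    the ``n_excluded`` attribute.
    """
    def as_map(z) -> dict[str, float]:
        if isinstance(z, pd.DataFrame):
            return dict(zip(z["strain_id"], z["z"]))
        return dict(z)

    zn, zo = as_map(z_ngd), as_map(z_opt)
    shared = sorted(set(zn) & set(zo))
    if not shared:
        raise ValueError("no strains shared between NGD and OPT plates")
    rows = []
    for strain in shared:
        a, b = zn[strain], zo[strain]
        hit = abs(a) > cutoff and -cutoff < b < cutoff
        rows.append(
            {
                "strain_id": strain,
                "z_ngd": a,
                "z_opt": b,
                "is_hit": hit,
                "direction": ("decreased" if a < 0 else "increased") if hit else "",
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_excluded"] = len(set(zn) ^ set(zo))
    return table


def candidate_overlaps(hit_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Pairwise and full-intersection cardinalities over reporter hit sets."""
    out = {label: len(s) for label, s in hit_sets.items()}
    for a, b in combinations(sorted(hit_sets), 2):
        out[f"{a}&{b}"] = len(hit_sets[a] & hit_sets[b])
    if len(hit_sets) > 2:
        inter = set.intersection(*hit_sets.values())
        out["&".join(sorted(hit_sets))] = len(inter)
    return out
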