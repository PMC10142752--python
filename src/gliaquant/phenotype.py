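"""High/low gating of per-cell marker intensities (MOI^high phenotyping).

Cells are pooled across all cases when fitting a cutoff, each cell is
flagged MOI^high (mean intensity strictly above the cutoff) or MOI^low per
marker, and MOI^high percentages are aggregated per case and region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .config import MARKERS

__all__ = ["Threshold", "ThresholdSet", "fit_threshold", "classify_moi", "percent_high"]


class ThresholdError(ValueError):
    pass


@dataclass
class Threshold:
    """One marker cutoff with provenance.

    provenance is "manual", "valley" (KDE minimum between the two largest
    log-intensity modes), "quantile", or "quantile_fallback" (valley
    requested but the density was unimodal/degenerate).
    """

    cutoff: float
    provenance: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ThresholdError("cutoff must be > 0")


class ThresholdSet(dict):
    """Mapping marker -> :class:`Threshold` with flat-file serialisation."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"marker": m, "cutoff": t.cutoff, "provenance": t.provenance}
                for m, t in self.items()
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThresholdSet":
        ts = cls()
        for _, row in df.iterrows():
            ts[row["marker"]] = Threshold(float(row["cutoff"]), str(row["provenance"]))
        return ts


def _valley_cutoff(log_x: np.ndarray) -> tuple[float | None, dict]:
    """KDE minimum between the two largest modes of the log-intensity
    density; None when fewer than two modes exist."""
    kde = gaussian_kde(log_x)
    grid = np.linspace(log_x.min(), log_x.max(), 512)
    dens = kde(grid)
    # a mode must be prominent (>= 2% of the tallest peak) to count; real
    # minority modes sit well above this, the micro-wiggles a KDE shows on
    # unimodal data well below
    peaks, _ = find_peaks(dens, prominence=0.02 * dens.max())
    if len(peaks) < 2:
        return None, {"n_modes": int(len(peaks))}
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(grid[top2])
    between = (grid > lo) & (grid < hi)
    if not between.any():
        return None, {"n_modes": int(len(peaks))}
    valley_idx = np.argmin(dens[between])
    valley = grid[between][valley_idx]
    diag = {
        "n_modes": int(len(peaks)),
        "mode_lo": float(np.exp(lo)),
        "mode_hi": float(np.exp(hi)),
        "valley_density": float(dens[between][valley_idx]),
        "peak_density": float(dens[peaks].max()),
    }
    return float(valley), diag


def fit_threshold(
    intensities: np.ndarray,
    method: str = "valley",
    manual_value: float | None = None,
    quantile: float = 0.9,
) -> Threshold:
    """Fit (or set) the high/low cutoff for one marker.

    valley: minimum of a Gaussian KDE of log-intensity between the two
    largest modes — appropriate for markers with a genuinely bimodal
    distribution (e.g. Iba1); falls back to the upper quantile with a
    warning when the density is unimodal. quantile: the stated upper
    quantile of the pooled intensities. manual: pass-through of a cutoff
    read off a density or XY scatter plot.
    """
    if method == "manual":
        if manual_value is None:
            raise ThresholdError("manual method requires manual_value")
        return Threshold(float(manual_value), "manual")
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 100:
        raise ThresholdError(f"fitted methods need >= 100 cells, got {x.size}")
    if method == "quantile":
        return Threshold(float(np.quantile(x, quantile)), "quantile")
    if method != "valley":
        raise ThresholdError(f"unknown method {method!r}")
    log_x = np.log(x)
    if np.ptp(log_x) < 1e-12:
        warnings.warn("degenerate (constant) intensities; falling back to quantile")
        return Threshold(float(np.quantile(x, quantile)), "quantile_fallback")
    valley, diag = _valley_cutoff(log_x)
    if valley is None:
        warnings.warn("unimodal intensity density; falling back to quantile cutoff")
        return Threshold(
            float(np.quantile(x, quantile)), "quantile_fallback", diag
        )
    return Threshold(float(np.exp(valley)), "valley", diag)


def fit_thresholds(
    cells: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
    method: str = "valley",
    manual_values: dict[str, float] | None = None,
) -> ThresholdSet:
    """Fit one cutoff per marker on cells pooled across all cases."""
    ts = ThresholdSet()
    for m in markers:
        if method == "manual":
            ts[m] = fit_threshold(None, "manual", manual_value=(manual_values or {})[m])
        else:
            ts[m] = fit_threshold(cells[m].to_numpy(), method)
    return ts


def classify_moi(cells: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Append per-marker boolean ``<marker>_high`` flags.

    A cell is MOI^high when its mean intensity is strictly above the cutoff
    (a cell exactly at the cutoff is low). Existing columns are untouched;
    the operation is idempotent.
    """
    out = cells.copy()
    for marker, thr in thresholds.items():
        if marker not in out.columns:
            raise ThresholdError(f"cell table lacks marker column {marker!r}")
        out[f"{marker}_high"] = out[marker].to_numpy() > thr.cutoff
    return out


def percent_high(
    cells: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
    by: tuple[str, ...] = ("case_id", "group", "region"),
) -> pd.DataFrame:
    """MOI^high percentages per case/region, long format.

    Returns columns (``by``..., marker, pct_high, n_cells); groups with zero
    cells never appear (warned). Percentages are 100 x high / total.
    """
    flag_cols = [f"{m}_high" for m in markers]
    missing = [c for c in flag_cols if c not in cells.columns]
    if missing:
        raise ThresholdError(f"missing MOI^high flags: {missing} — run classify_moi first")
    if cells.empty:
        warnings.warn("empty cell table: no percentages computed")
        return pd.DataFrame(columns=[*by, "marker", "pct_high", "n_cells"])
    rows = []
    for key, grp in cells.groupby(list(by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        for m in markers:
            rows.append(
                {
                    **dict(zip(by, key)),
                    "marker": m,
                    "pct_high": 100.0 * grp[f"{m}_high"].mean(),
                    "n_cells": len(grp),
                }
            )
    return pd.DataFrame(rows)
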