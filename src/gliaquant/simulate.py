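"""Ground-truthed synthetic cohorts: single-cell tables and tissue images.

The generator emulates the statistical structure the downstream analysis
assumes: per-cell marker mean intensities are log-normal with a low and a
high mode per marker; each cell carries a latent phenotype (a high/low
assignment over the five markers) drawn from group-specific mixture
fractions; disease severity co-scales the CD68-containing phenotype
fractions and the pTDP-43 aggregate burden per case. Image mode renders
somata as non-overlapping disks, astrocytes into the GFAP and L-ferritin
channels only, aggregates as small high-intensity blobs, optional
HLA-DR -> pTDP-43 bleed-through, and Gaussian background noise, and records
the planted truth for every quantity the pipeline later measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    MARKERS,
    PHENOTYPES,
    SEVERITY_SCALED_PHENOTYPES,
    ConfigError,
    GroupSpec,
    SimulationConfig,
)
from .quantify import ChannelImage, MultiplexImageSet

__all__ = [
    "SimulationTruth",
    "PlacementError",
    "generate_cell_table",
    "generate_image_set",
]

#: Channels rendered in image mode beyond the five measured markers.
EXTRA_CHANNELS = ("pTDP-43", "GFAP", "Hoechst")


class PlacementError(RuntimeError):
    """Requested somata cannot be packed into the ROI (overcrowded)."""


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated cohort.

    ``cells`` has one row per generated cell (cell_id, case_id, group,
    region, phenotype); ``cases`` one row per case with the true MOI^high
    fraction per marker (``true_<marker>_high_frac``), the true pTDP-43
    integrated intensity per ROI area (``true_ptdp_load``), the true GFAP
    area fraction, the true cell count and the drawn severity.
    """

    cells: pd.DataFrame
    cases: pd.DataFrame
    placements: dict[str, pd.DataFrame] = field(default_factory=dict)

    def true_fraction(self, case_id: str, marker: str) -> float:
        row = self.cases.loc[self.cases["case_id"] == case_id]
        return float(row[f"true_{marker}_high_frac"].iloc[0])


def _case_severity(rng: np.random.Generator, spec: GroupSpec) -> float:
    lo, hi = spec.severity_range
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _effective_fractions(spec: GroupSpec, severity: float) -> dict[str, float]:
    """Scale severity-coupled phenotype fractions, rebalancing into pan_low."""
    frac = dict(spec.phenotype_fractions)
    if all(math.isclose(severity, 1.0) for _ in (0,)) and spec.severity_range == (1.0, 1.0):
        return frac
    delta = 0.0
    for name in SEVERITY_SCALED_PHENOTYPES:
        if name in frac:
            scaled = frac[name] * severity
            delta += scaled - frac[name]
            frac[name] = scaled
    base = frac.get("pan_low", 0.0) - delta
    if base < -1e-9:
        raise ConfigError(
            "severity scaling exhausts the pan_low fraction; reduce severity_range"
        )
    frac["pan_low"] = max(base, 0.0)
    total = sum(frac.values())
    return {k: v / total for k, v in frac.items()}


def _draw_case_cells(
    rng: np.random.Generator,
    config: SimulationConfig,
    spec: GroupSpec,
    case_id: str,
    fractions: dict[str, float],
) -> pd.DataFrame:
    """Draw phenotypes and per-marker intensities for one case."""
    n = config.cells_per_case
    names = list(fractions)
    probs = np.asarray([fractions[p] for p in names], dtype=float)
    pheno_idx = rng.choice(len(names), size=n, p=probs)
    phenos = np.asarray(names, dtype=object)[pheno_idx]

    cols: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        mu = np.empty(n)
        sd = np.empty(n)
        for j, p in enumerate(names):
            m, s = config.marker_intensity_params[(p, marker)]
            sel = pheno_idx == j
            mu[sel] = m
            sd[sel] = s
        cols[marker] = rng.lognormal(mean=mu, sigma=sd)

    df = pd.DataFrame(cols)
    df.insert(0, "cell_id", [f"{case_id}:{i}" for i in range(n)])
    df["case_id"] = case_id
    df["group"] = spec.group_label
    df["region"] = spec.region_label
    df["phenotype"] = phenos
    return df


def _nominal_ptdp_load(config: SimulationConfig, spec: GroupSpec, severity: float) -> float:
    """Planted pTDP-43 integrated intensity per ROI area (intensity/um^2)
    implied by the configured aggregate burden, used in table-only mode."""
    if not spec.aggregates:
        return 0.0
    ip = config.image_params
    n_agg = int(round(ip.aggregate_count_per_case * severity))
    blob_px = _disk_offsets(ip.aggregate_radius_px)[0].size
    roi_w = ip.width_px - 2 * ip.roi_margin_px
    roi_h = ip.height_px - 2 * ip.roi_margin_px
    roi_um2 = roi_w * roi_h * ip.um_per_px**2
    return n_agg * blob_px * ip.aggregate_intensity / roi_um2


def generate_cell_table(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the per-cell marker-intensity table for a whole cohort.

    Returns a cell table (one row per cell: id, per-marker mean intensity,
    case/group/region labels) and the matching :class:`SimulationTruth`.
    Identical (config, seed) reproduces the table bit-for-bit.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    case_rows: list[dict] = []
    for spec in config.groups:
        for i in range(spec.n_cases):
            case_id = f"{spec.group_label}_{spec.region_label}_{i + 1:02d}"
            severity = _case_severity(rng, spec)
            fractions = _effective_fractions(spec, severity)
            df = _draw_case_cells(rng, config, spec, case_id, fractions)
            frames.append(df)
            row = {
                "case_id": case_id,
                "group": spec.group_label,
                "region": spec.region_label,
                "n_cells": len(df),
                "severity": severity,
                "true_ptdp_load": _nominal_ptdp_load(config, spec, severity),
                "true_gfap_fraction": float("nan"),
            }
            for marker in MARKERS:
                row[f"true_{marker}_high_frac"] = float(
                    np.mean([marker in PHENOTYPES[p] for p in df["phenotype"]])
                )
            case_rows.append(row)
    cells = pd.concat(frames, ignore_index=True)
    truth_cells = cells[["cell_id", "case_id", "group", "region", "phenotype"]].copy()
    cells = cells.drop(columns="phenotype")
    return cells, SimulationTruth(cells=truth_cells, cases=pd.DataFrame(case_rows))


# ---------------------------------------------------------------------------
# image rendering


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of the pixels inside a disk of the given radius."""
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dy**2 + dx**2 <= radius**2
    return dy[inside], dx[inside]


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radius: float,
    shape: tuple[int, int],
    margin: int,
    existing: list[tuple[float, float, float]],
    min_gap_px: float = 3.0,
    max_tries: int = 20_000,
) -> list[tuple[float, float]]:
    """Rejection-sample n non-overlapping disk centres inside the ROI.

    ``existing`` holds (y, x, radius) of disks already placed (any kind);
    a gap of ``min_gap_px`` between disk edges keeps the rendered objects
    8-disconnected so downstream object counts are exact.
    """
    h, w = shape
    lo_y, hi_y = margin + radius, h - margin - radius
    lo_x, hi_x = margin + radius, w - margin - radius
    if hi_y <= lo_y or hi_x <= lo_x:
        raise PlacementError("ROI too small for the requested disk radius")
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} disks of radius {radius:.1f}px without overlap"
            )
        y = rng.uniform(lo_y, hi_y)
        x = rng.uniform(lo_x, hi_x)
        ok = True
        for ey, ex, er in existing:
            if (y - ey) ** 2 + (x - ex) ** 2 < (radius + er + min_gap_px) ** 2:
                ok = False
                break
        if ok:
            placed.append((y, x))
            existing.append((y, x, radius))
    return placed


def _paint(
    img: np.ndarray, cy: float, cx: float, offs: tuple[np.ndarray, np.ndarray], value: float
) -> None:
    dy, dx = offs
    rr = np.clip(np.round(cy).astype(int) + dy, 0, img.shape[0] - 1)
    cc = np.clip(np.round(cx).astype(int) + dx, 0, img.shape[1] - 1)
    img[rr, cc] = value


def _render_case(
    rng: np.random.Generator,
    config: SimulationConfig,
    cells: pd.DataFrame,
    spec: GroupSpec,
    case_id: str,
    severity: float,
) -> tuple[MultiplexImageSet, pd.DataFrame, float, float]:
    """Render one case's channels; returns (image set, placements,
    true pTDP load per um^2, true GFAP area fraction)."""
    ip = config.image_params
    h, w = ip.height_px, ip.width_px
    soma_r = ip.soma_radius_px
    margin = ip.roi_margin_px

    roi = np.zeros((h, w), dtype=bool)
    roi[margin : h - margin, margin : w - margin] = True
    roi_area_px = int(roi.sum())
    soma_area = math.pi * soma_r**2
    if len(cells) * soma_area > 0.5 * roi_area_px:
        raise PlacementError(
            f"{len(cells)} somata of radius {soma_r:.1f}px exceed 50% of the ROI"
        )

    channels = {name: np.zeros((h, w)) for name in MARKERS + EXTRA_CHANNELS}
    existing: list[tuple[float, float, float]] = []

    soma_offs = _disk_offsets(soma_r)
    centres = _place_disks(rng, len(cells), soma_r, (h, w), margin, existing)
    nuc_offs = _disk_offsets(max(soma_r * 0.4, 1.5))
    rows = []
    for (cy, cx), (_, cell) in zip(centres, cells.iterrows()):
        for marker in MARKERS:
            _paint(channels[marker], cy, cx, soma_offs, float(cell[marker]))
        _paint(channels["Hoechst"], cy, cx, nuc_offs, 3000.0)
        rows.append({"cell_id": cell["cell_id"], "y": cy, "x": cx, "kind": "microglia"})

    # astrocytes: GFAP + L-ferritin only, disjoint from somata
    astro_r = ip.astrocyte_radius_um / ip.um_per_px
    astro_offs = _disk_offsets(astro_r)
    gfap_painted = np.zeros((h, w), dtype=bool)
    if ip.n_astrocytes > 0:
        for cy, cx in _place_disks(rng, ip.n_astrocytes, astro_r, (h, w), margin, existing):
            gfap_val = float(rng.lognormal(6.8, 0.2))
            lf_val = float(rng.lognormal(5.8, 0.2))
            _paint(channels["GFAP"], cy, cx, astro_offs, gfap_val)
            _paint(channels["L-ferritin"], cy, cx, astro_offs, lf_val)
            _paint(gfap_painted, cy, cx, astro_offs, True)
            rows.append({"cell_id": "", "y": cy, "x": cx, "kind": "astrocyte"})
    true_gfap_fraction = float((gfap_painted & roi).sum() / roi_area_px)

    # pTDP-43 aggregates, count scaled by severity, disjoint from all somata
    n_agg = (
        int(round(ip.aggregate_count_per_case * severity)) if spec.aggregates else 0
    )
    agg_offs = _disk_offsets(ip.aggregate_radius_px)
    if n_agg > 0:
        for cy, cx in _place_disks(rng, n_agg, ip.aggregate_radius_px, (h, w), margin, existing):
            _paint(channels["pTDP-43"], cy, cx, agg_offs, ip.aggregate_intensity)
            rows.append({"cell_id": "", "y": cy, "x": cx, "kind": "aggregate"})
    roi_um2 = roi_area_px * ip.um_per_px**2
    true_ptdp_load = float(channels["pTDP-43"][roi].sum() / roi_um2)

    # channel bleed-through: a fraction of the HLA-DR signal leaks into the
    # pTDP-43 channel (cross-reactive secondary), before background noise
    if ip.bleedthrough_coefficient > 0:
        channels["pTDP-43"] = (
            channels["pTDP-43"] + ip.bleedthrough_coefficient * channels["HLA-DR"]
        )

    for name, img in channels.items():
        if ip.noise_sd > 0:
            img = img + rng.normal(ip.background_mean, ip.noise_sd, size=img.shape)
        else:
            img = img + ip.background_mean
        channels[name] = np.clip(img, 0.0, None)

    imgset = MultiplexImageSet(
        channels={
            name: ChannelImage(arr, name, ip.um_per_px) for name, arr in channels.items()
        },
        roi=roi,
        case_id=case_id,
        group=spec.group_label,
        region=spec.region_label,
        um_per_px=ip.um_per_px,
    )
    return imgset, pd.DataFrame(rows), true_ptdp_load, true_gfap_fraction


def generate_image_set(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[MultiplexImageSet], SimulationTruth]:
    """Render one multi-channel tissue field per case for the whole cohort.

    Somata are rendered as disks carrying the cell's drawn marker
    intensities, so running the quantification pipeline on the output
    should recover the cell table that :func:`generate_cell_table` logic
    produced, up to imaging noise. Truth records per-case counts, MOI^high
    fractions, the painted pTDP-43 load and GFAP area fraction.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    image_sets: list[MultiplexImageSet] = []
    frames, case_rows, placements = [], [], {}
    for spec in config.groups:
        for i in range(spec.n_cases):
            case_id = f"{spec.group_label}_{spec.region_label}_{i + 1:02d}"
            severity = _case_severity(rng, spec)
            fractions = _effective_fractions(spec, severity)
            cells = _draw_case_cells(rng, config, spec, case_id, fractions)
            imgset, placed, ptdp_load, gfap_frac = _render_case(
                rng, config, cells, spec, case_id, severity
            )
            image_sets.append(imgset)
            frames.append(cells)
            placements[case_id] = placed
            row = {
                "case_id": case_id,
                "group": spec.group_label,
                "region": spec.region_label,
                "n_cells": len(cells),
                "severity": severity,
                "true_ptdp_load": ptdp_load,
                "true_gfap_fraction": gfap_frac,
            }
            for marker in MARKERS:
                row[f"true_{marker}_high_frac"] = float(
                    np.mean([marker in PHENOTYPES[p] for p in cells["phenotype"]])
                )
            case_rows.append(row)
    all_cells = pd.concat(frames, ignore_index=True)
    truth = SimulationTruth(
        cells=all_cells[["cell_id", "case_id", "group", "region", "phenotype"]].copy(),
        cases=pd.DataFrame(case_rows),
        placements=placements,
    )
    # the drawn per-cell intensities are part of the truth in image mode
    truth.cells = truth.cells.join(all_cells[list(MARKERS)])
    return image_sets, truth
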