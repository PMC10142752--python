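"""Configuration objects for the simulation and analysis pipeline.

The five microglial functional markers quantified per cell are fixed
package-wide: L-ferritin, HLA-DR, CD68, CD74 and Iba1. A *phenotype* is a
binary high/low assignment over these five markers (32 possibilities); the
named presets below cover the combinations that matter for the disease
contrast (e.g. the L-ferritin^high CD68^high population enriched in the
diseased motor cortex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

#: Canonical marker order used everywhere (cell-table columns, feature
#: matrices, threshold sets).
MARKERS: tuple[str, ...] = ("L-ferritin", "HLA-DR", "CD68", "CD74", "Iba1")

#: Markers whose binary masks form the microglial master mask (human arm).
MASTER_MASK_MARKERS: tuple[str, ...] = ("Iba1", "HLA-DR", "CD68", "CD74")

#: Named phenotype presets: phenotype name -> set of markers that are "high".
PHENOTYPES: dict[str, frozenset[str]] = {
    "pan_low": frozenset(),
    "iba1_high": frozenset({"Iba1"}),
    "hladr_cd74_high": frozenset({"HLA-DR", "CD74"}),
    "cd68_high": frozenset({"CD68"}),
    "lferritin_cd68_high": frozenset({"L-ferritin", "CD68"}),
}

#: Phenotypes whose abundance scales with per-case disease severity (they
#: contain CD68^high cells, the population that tracks pTDP-43 load).
SEVERITY_SCALED_PHENOTYPES: tuple[str, ...] = ("cd68_high", "lferritin_cd68_high")


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class ImageParams:
    """Geometry and rendering parameters for synthetic tissue fields.

    Defaults give a 1024x1024 px field at 0.5 um/px on a 16-bit-like
    intensity scale. ``soma_radius_um`` controls the rendered microglial
    soma disk; processes are deliberately not rendered.
    """

    width_px: int = 1024
    height_px: int = 1024
    um_per_px: float = 0.5
    soma_radius_um: float = 5.0
    min_cell_area_px: int = 20
    background_mean: float = 100.0
    noise_sd: float = 15.0
    n_astrocytes: int = 8
    astrocyte_radius_um: float = 7.0
    aggregate_count_per_case: int = 12
    aggregate_radius_px: int = 3
    aggregate_intensity: float = 5000.0
    bleedthrough_coefficient: float = 0.0
    roi_margin_px: int = 16

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be > 0")
        if not (0.0 <= self.bleedthrough_coefficient <= 1.0):
            raise ConfigError("bleedthrough_coefficient must lie in [0, 1]")
        if self.width_px < 8 or self.height_px < 8:
            raise ConfigError("image must be at least 8x8 px")
        if self.noise_sd < 0 or self.background_mean < 0:
            raise ConfigError("background_mean and noise_sd must be >= 0")

    @property
    def soma_radius_px(self) -> float:
        return self.soma_radius_um / self.um_per_px


@dataclass
class GroupSpec:
    """One case/region subgroup of the simulated cohort.

    ``severity_range`` draws a per-case severity multiplier s ~ U(lo, hi)
    that scales the CD68-containing phenotype fractions (mass taken from
    pan_low) and the pTDP-43 aggregate count, planting the within-group
    covariation between %CD68^high and aggregate load that the disease
    cortex exhibits. ``aggregates=False`` renders no pTDP-43 aggregates at
    all (control tissue lacks the pathology) while leaving the phenotype
    mixture untouched.
    """

    group_label: str  # "control" | "disease"
    region_label: str  # "motor_cortex" | "hippocampus" | timepoint tag
    n_cases: int
    phenotype_fractions: dict[str, float]
    severity_range: tuple[float, float] = (1.0, 1.0)
    aggregates: bool = True

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        total = sum(self.phenotype_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"phenotype fractions for {self.group_label}/{self.region_label} "
                f"sum to {total!r}, expected 1"
            )
        if any(f < 0 for f in self.phenotype_fractions.values()):
            raise ConfigError("phenotype fractions must be non-negative")
        unknown = set(self.phenotype_fractions) - set(PHENOTYPES)
        if unknown:
            raise ConfigError(f"unknown phenotypes: {sorted(unknown)}")
        lo, hi = self.severity_range
        if lo > hi or lo < 0:
            raise ConfigError("severity_range must satisfy 0 <= lo <= hi")


def make_intensity_params(
    marker_levels: dict[str, tuple[float, float, float]],
    phenotypes: dict[str, frozenset[str]] | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Expand per-marker (log_mean_low, log_mean_high, log_sd) levels into
    the per-(phenotype, marker) log-normal parameter map.

    A marker in a phenotype's high set gets the high log-mean, otherwise the
    low one; the log-sd is shared between modes.
    """
    phenotypes = PHENOTYPES if phenotypes is None else phenotypes
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for pheno, high_set in phenotypes.items():
        for marker in MARKERS:
            if marker not in marker_levels:
                raise ConfigError(f"marker_levels missing {marker}")
            lo, hi, sd = marker_levels[marker]
            if sd <= 0 or not all(map(math.isfinite, (lo, hi, sd))):
                raise ConfigError(f"invalid intensity levels for {marker}")
            params[(pheno, marker)] = (hi if marker in high_set else lo, sd)
    return params


#: Default per-marker log-normal levels: (log_mean_low, log_mean_high,
#: log_sd). Low and high modes are 1.2 natural-log units apart = 6 log-sd at
#: log-sd 0.2, i.e. comfortably bimodal, on an intensity scale where the low
#: mode (~245) sits well above the imaging background (~100).
DEFAULT_MARKER_LEVELS: dict[str, tuple[float, float, float]] = {
    marker: (5.5, 6.7, 0.2) for marker in MARKERS
}

#: Baseline (control) phenotype mixture: mostly surveillant pan-low
#: microglia with small high-expressing subsets.
CONTROL_FRACTIONS: dict[str, float] = {
    "pan_low": 0.70,
    "iba1_high": 0.10,
    "hladr_cd74_high": 0.10,
    "cd68_high": 0.05,
    "lferritin_cd68_high": 0.05,
}

#: Disease motor-cortex mixture: CD68^high and L-ferritin^high CD68^high
#: fractions elevated at the expense of pan-low cells.
DISEASE_FRACTIONS: dict[str, float] = {
    "pan_low": 0.40,
    "iba1_high": 0.10,
    "hladr_cd74_high": 0.15,
    "cd68_high": 0.20,
    "lferritin_cd68_high": 0.15,
}


@dataclass
class SimulationConfig:
    """Full description of a simulated cohort.

    ``marker_intensity_params`` maps (phenotype, marker) to the (log-mean,
    log-sd) of the log-normal its per-cell mean intensities are drawn from;
    build it with :func:`make_intensity_params` or pass a custom map.
    """

    groups: list[GroupSpec]
    cells_per_case: int = 500
    marker_intensity_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: make_intensity_params(DEFAULT_MARKER_LEVELS)
    )
    image_params: ImageParams = field(default_factory=ImageParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_case < 1:
            raise ConfigError("cells_per_case must be >= 1")
        if not self.groups:
            raise ConfigError("at least one group is required")
        for (pheno, marker), (mu, sd) in self.marker_intensity_params.items():
            if sd <= 0 or not (math.isfinite(mu) and math.isfinite(sd)):
                raise ConfigError(f"invalid intensity params for ({pheno}, {marker})")

    def phenotypes_used(self) -> list[str]:
        names: list[str] = []
        for g in self.groups:
            for p in g.phenotype_fractions:
                if p not in names:
                    names.append(p)
        return names


def default_cohort_config(
    n_cases: int = 10,
    cells_per_case: int = 500,
    regions: tuple[str, ...] = ("motor_cortex", "hippocampus"),
    seed: int = 0,
    image_params: ImageParams | None = None,
) -> SimulationConfig:
    """The default two-group cohort emulating the human study design.

    ``n_cases`` controls per group and per region; disease subgroups carry a
    per-case severity multiplier U(0.5, 1.5) that co-scales the CD68^high
    fractions and the pTDP-43 aggregate count; controls have severity 0
    (no aggregates).
    """
    groups = []
    for region in regions:
        groups.append(
            GroupSpec(
                "control",
                region,
                n_cases,
                dict(CONTROL_FRACTIONS),
                (1.0, 1.0),
                aggregates=False,
            )
        )
        # Hippocampal disease involvement is milder than motor cortex.
        frac = DISEASE_FRACTIONS if region == "motor_cortex" else {
            "pan_low": 0.60,
            "iba1_high": 0.10,
            "hladr_cd74_high": 0.12,
            "cd68_high": 0.10,
            "lferritin_cd68_high": 0.08,
        }
        groups.append(
            GroupSpec("disease", region, n_cases, dict(frac), (0.5, 1.5), aggregates=True)
        )
    return SimulationConfig(
        groups=groups,
        cells_per_case=cells_per_case,
        image_params=image_params or ImageParams(),
        seed=seed,
    )


@dataclass
class QuantConfig:
    """Parameters of the image-quantification stage.

    ``clip_thresholds`` supplies the per-channel "high immunoreactivity"
    cutoffs used by the threshold-clip masks (pTDP-43, GFAP, and the HLA-DR
    bleed-correction mask); there is no automatic default because these are
    per-marker, per-dataset choices. ``adaptive_offset`` is the intensity
    added to the local mean in the adaptive threshold.
    """

    adaptive_window_um: float = 25.0
    adaptive_offset: float = 50.0
    min_cell_area_px: int = 20
    clip_thresholds: dict[str, float] = field(
        default_factory=lambda: {"pTDP-43": 1000.0, "GFAP": 400.0, "HLA-DR": 900.0}
    )
    master_markers: tuple[str, ...] = MASTER_MASK_MARKERS
    normalise_to: str = "roi"  # "roi" (default) or "mask" for tissue-wide intensity

    def __post_init__(self) -> None:
        if self.adaptive_window_um <= 0:
            raise ConfigError("adaptive_window_um must be > 0")
        if self.min_cell_area_px < 1:
            raise ConfigError("min_cell_area_px must be >= 1")
        if self.normalise_to not in ("roi", "mask"):
            raise ConfigError("normalise_to must be 'roi' or 'mask'")


@dataclass
class EmbeddingConfig:
    """t-SNE + kNN-Louvain parameters.

    The learning rate is tied to the early-exaggeration factor by the rule
    learning_rate = N_cells / EE_factor; the EE factor applies during the
    first ``ee_iterations`` of ``max_iterations``. ``perplexity`` defaults
    to 250 and is reduced automatically (with a warning) to (N-1)/3 when the
    subsample is small.
    """

    n_per_group: int = 31_200
    perplexity: float = 250.0
    ee_factor: float = 12.0
    ee_iterations: int = 250
    max_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ee_factor <= 0:
            raise ConfigError("ee_factor must be > 0")
        if self.ee_iterations > self.max_iterations:
            raise ConfigError("ee_iterations must be <= max_iterations")
        if self.perplexity >= self.n_per_group:
            raise ConfigError("perplexity must be < n_per_group")

    def learning_rate(self, n_cells: int) -> float:
        return n_cells / self.ee_factor


def config_to_yaml(config: SimulationConfig) -> str:
    """Serialise a SimulationConfig to YAML (flat, human-editable)."""
    d = asdict(config)
    d["marker_intensity_params"] = {
        f"{p}/{m}": list(v) for (p, m), v in config.marker_intensity_params.items()
    }
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> SimulationConfig:
    d = yaml.safe_load(text)
    groups = [
        GroupSpec(
            g["group_label"],
            g["region_label"],
            g["n_cases"],
            g["phenotype_fractions"],
            tuple(g.get("severity_range", (1.0, 1.0))),
            g.get("aggregates", True),
        )
        for g in d["groups"]
    ]
    params = {
        tuple(k.split("/", 1)): tuple(v)
        for k, v in d["marker_intensity_params"].items()
    }
    return SimulationConfig(
        groups=groups,
        cells_per_case=d["cells_per_case"],
        marker_intensity_params=params,  # type: ignore[arg-type]
        image_params=ImageParams(**d["image_params"]),
        seed=d.get("seed", 0),
    )
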