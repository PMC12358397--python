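"""Obligate-parasite host constraint: the two-scenario comparison.

An obligate parasite can only occur where its host does.  The constraint is
implemented two ways at once, mirroring how a host-dependent range model is
built in practice:

1. the host's continuous suitability P_HA enters the parasite model as one
   more predictor (a spatially explicit constraint layer), and
2. after prediction, the conditional probability transfer zeroes the
   parasite suitability P_CD wherever P_HA falls below the effective
   parasitism threshold (0.4 by default, the medium-and-high host range).

The Natural Habitat Scenario (NHS) omits both steps; the Parasitic
Constraint Scenario (PCS) applies both.  Scenario divergence is summarized
per suitability class by the area difference rate,

    (area_PCS - area_NHS) / area_NHS * 100 %,

and by the shift between the two scenarios' suitable-area centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classification_change import (
    ClassificationScheme,
    binarize,
    centroid_shift,
    class_areas,
    classify_suitability,
    suitable_centroid,
)
from .evaluation import EvaluationReport, replicate_fit
from .grid_io import GridLayer, assert_coregistered, cell_area_layer
from .model_tuning import DEFAULT_FCS, DEFAULT_RMS, TuningResult, tune_grid
from .maxent_core import FeatureSpec
from .occurrences import OccurrenceSet

__all__ = [
    "ScenarioConfig",
    "ScenarioComparison",
    "build_pcs_predictors",
    "conditional_probability_transfer",
    "area_difference_rate",
    "run_two_scenarios",
]

logger = logging.getLogger(__name__)

HOST_LAYER_NAME = "P_HA"


@dataclass
class ScenarioConfig:
    scenario: str = "NHS"                      # "NHS" or "PCS"
    parasitism_threshold: float = 0.4
    host_layer: GridLayer | None = None        # required iff PCS

    def __post_init__(self) -> None:
        if self.scenario not in ("NHS", "PCS"):
            raise ValueError("scenario must be 'NHS' or 'PCS'")
        if not (0.0 < self.parasitism_threshold < 1.0):
            raise ValueError("parasitism threshold must lie in (0, 1)")
        if self.scenario == "PCS" and self.host_layer is None:
            raise ValueError("PCS requires a host suitability layer")


@dataclass
class ScenarioComparison:
    class_areas_nhs: dict[str, float]
    class_areas_pcs: dict[str, float]
    difference_rates: dict[str, float]
    centroid_nhs: tuple[float, float]
    centroid_pcs: tuple[float, float]
    centroid_shift_km: float
    suitability_nhs: GridLayer = field(repr=False)
    suitability_pcs: GridLayer = field(repr=False)
    report_nhs: EvaluationReport | None = None
    report_pcs: EvaluationReport | None = None
    report_host: EvaluationReport | None = None
    host_layer: GridLayer | None = field(default=None, repr=False)
    tuning_nhs: TuningResult | None = None
    tuning_pcs: TuningResult | None = None
    tuning_host: TuningResult | None = None

    def summary_text(self) -> str:
        lines = ["class\tarea_nhs_km2\tarea_pcs_km2\tdifference_rate_pct"]
        for cls in self.class_areas_nhs:
            rate = self.difference_rates.get(cls, float("nan"))
            lines.append(
                f"{cls}\t{self.class_areas_nhs[cls]:.2f}\t"
                f"{self.class_areas_pcs[cls]:.2f}\t{rate:.2f}"
            )
        lines.append(f"centroid_nhs\t{self.centroid_nhs[0]:.3f}\t{self.centroid_nhs[1]:.3f}")
        lines.append(f"centroid_pcs\t{self.centroid_pcs[0]:.3f}\t{self.centroid_pcs[1]:.3f}")
        lines.append(f"centroid_shift_km\t{self.centroid_shift_km:.1f}")
        return "\n".join(lines)


def build_pcs_predictors(env_layers: list[GridLayer], host_suitability: GridLayer) -> list[GridLayer]:
    """Environmental predictors plus the host suitability layer P_HA."""
    assert_coregistered(list(env_layers) + [host_suitability])
    host = host_suitability.copy_with(host_suitability.values, name=HOST_LAYER_NAME)
    return list(env_layers) + [host]


def conditional_probability_transfer(
    p_cd: GridLayer, p_ha: GridLayer, theta: float = 0.4
) -> GridLayer:
    """Zero the parasite suitability wherever host suitability < theta.

    Where P_HA >= theta the parasite value passes through unchanged; nodata
    in either input propagates.  Idempotent.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    assert_coregistered([p_cd, p_ha])
    out = np.where(p_ha.values >= theta, p_cd.values, 0.0)
    out[~(np.isfinite(p_cd.values) & np.isfinite(p_ha.values))] = np.nan
    return p_cd.copy_with(out, name=(p_cd.name + "_constrained").lstrip("_"))


def area_difference_rate(area_pcs: float, area_nhs: float) -> float:
    """((area_PCS - area_NHS) / area_NHS) * 100, in percent."""
    if area_nhs <= 0:
        raise ValueError("NHS area must be positive; rate undefined")
    return (area_pcs - area_nhs) / area_nhs * 100.0


def _resolve_model_settings(
    occ, env, fc, rm, fcs, rms, seed, n_background, hinge_knots, threshold_knots
):
    """Use fixed (fc, rm) when given, otherwise tune on the AICc grid."""
    if fc is not None and rm is not None:
        return FeatureSpec(fc, hinge_knots, threshold_knots), rm, None
    tuning = tune_grid(
        occ, env, fcs, rms, seed=seed, n_background=n_background,
        hinge_knots=hinge_knots, threshold_knots=threshold_knots, eval_split=False,
    )
    sel_fc, sel_rm = tuning.selected
    return FeatureSpec(sel_fc, hinge_knots, threshold_knots), sel_rm, tuning


def run_two_scenarios(
    parasite_occ: OccurrenceSet,
    env_layers: list[GridLayer],
    host: OccurrenceSet | GridLayer,
    theta: float = 0.4,
    fc: str | None = None,
    rm: float | None = None,
    host_fc: str | None = None,
    host_rm: float | None = None,
    fcs: tuple[str, ...] = DEFAULT_FCS,
    rms: tuple[float, ...] = DEFAULT_RMS,
    n_replicates: int = 10,
    seed: int | None = None,
    n_background: int = 10000,
    hinge_knots: int = 50,
    threshold_knots: int = 50,
    scheme: ClassificationScheme = ClassificationScheme(),
) -> ScenarioComparison:
    """Full NHS-vs-PCS comparison for one parasite.

    ``host`` may be an OccurrenceSet (a host model is tuned/fitted and its
    mean replicate suitability becomes P_HA) or a ready-made continuous
    suitability layer in [0, 1].  When ``fc``/``rm`` are omitted each model
    is tuned independently on the AICc grid.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    report_host = None
    tuning_host = None
    if isinstance(host, GridLayer):
        host_layer = host
    else:
        host_spec, host_rm_sel, tuning_host = _resolve_model_settings(
            host, env_layers, host_fc, host_rm, fcs, rms, int(seeds[0]),
            n_background, hinge_knots, threshold_knots,
        )
        report_host, host_layer = replicate_fit(
            host, env_layers, host_spec, host_rm_sel, n_replicates,
            seed=int(seeds[1]), n_background=n_background,
        )

    # Natural habitat scenario: environment only
    nhs_spec, nhs_rm, tuning_nhs = _resolve_model_settings(
        parasite_occ, env_layers, fc, rm, fcs, rms, int(seeds[2]),
        n_background, hinge_knots, threshold_knots,
    )
    report_nhs, p_nhs = replicate_fit(
        parasite_occ, env_layers, nhs_spec, nhs_rm, n_replicates,
        seed=int(seeds[3]), n_background=n_background,
    )

    # Parasitic constraint scenario: env + P_HA, then the transfer
    pcs_env = build_pcs_predictors(env_layers, host_layer)
    pcs_spec, pcs_rm, tuning_pcs = _resolve_model_settings(
        parasite_occ, pcs_env, fc, rm, fcs, rms, int(seeds[4]),
        n_background, hinge_knots, threshold_knots,
    )
    report_pcs, p_pcs_raw = replicate_fit(
        parasite_occ, pcs_env, pcs_spec, pcs_rm, n_replicates,
        seed=int(seeds[5]), n_background=n_background,
    )
    p_pcs = conditional_probability_transfer(p_pcs_raw, host_layer, theta)

    cell_areas = cell_area_layer(env_layers[0])
    areas_nhs = class_areas(classify_suitability(p_nhs, scheme), cell_areas, scheme)
    areas_pcs = class_areas(classify_suitability(p_pcs, scheme), cell_areas, scheme)
    rates = {}
    for cls in scheme.labels:
        if areas_nhs[cls] > 0:
            rates[cls] = area_difference_rate(areas_pcs[cls], areas_nhs[cls])
        else:
            rates[cls] = float("nan")
            logger.warning("NHS area for class %r is zero; rate undefined", cls)

    c_nhs = suitable_centroid(binarize(p_nhs, theta), cell_areas)
    c_pcs = suitable_centroid(binarize(p_pcs, theta), cell_areas)
    shift_km, _ = centroid_shift(c_nhs, c_pcs)

    return ScenarioComparison(
        class_areas_nhs=areas_nhs,
        class_areas_pcs=areas_pcs,
        difference_rates=rates,
        centroid_nhs=c_nhs,
        centroid_pcs=c_pcs,
        centroid_shift_km=shift_km,
        suitability_nhs=p_nhs,
        suitability_pcs=p_pcs,
        report_nhs=report_nhs,
        report_pcs=report_pcs,
        report_host=report_host,
        host_layer=host_layer,
        tuning_nhs=tuning_nhs,
        tuning_pcs=tuning_pcs,
        tuning_host=tuning_host,
    )
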