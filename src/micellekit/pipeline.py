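"""End-to-end orchestration of the aggregate-characterization stages, plus
scalar concentration utilities.

``run_isotropic_pipeline`` drives the dilute-phase workflow: per-frame
clustering -> unwrapping -> shape and Willard-Chandler surface metrics for
aggregates with aggregation number >= 5 -> reduction to system timeseries ->
MSER/ADF convergence report.  ``run_bilayer_pipeline`` drives the lamellar
workflow: per-frame surface -> leaflet split -> thickness and area per
headgroup pooled over t > t_min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import clustering, convergence, shape, surface
from .errors import (
    EmptyInputError,
    EmptySeriesError,
    MicelleKitError,
    NotABilayerError,
)
from .structures import Frame, Trajectory

logger = logging.getLogger(__name__)

#: Real molar mass of AOT (g/mol), used for concentration conversions.
AOT_MOLAR_MASS = 444.6


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ClusterConfig(BaseModel):
    """Clustering settings; r_cut=None derives (5/4)*sigma from the topology."""

    r_cut: float | None = Field(default=None, gt=0)
    min_aggregation_number: int = Field(default=5, ge=1)


class SurfaceConfig(BaseModel):
    bandwidth: float = Field(default=4.0, gt=0)
    spacing: float = Field(default=2.0, gt=0)
    iso_fraction: float = Field(default=1.0 / 3.0, gt=0, lt=1)
    truncation: float = Field(default=4.0, gt=0)
    mode: str = Field(default="supercell", pattern="^(supercell|minimum_image)$")

    def to_params(self) -> surface.WCParams:
        return surface.WCParams(
            bandwidth=self.bandwidth, spacing=self.spacing,
            iso_fraction=self.iso_fraction, truncation=self.truncation,
        )


class ConvergenceConfig(BaseModel):
    confidence: float = Field(default=0.99, gt=0, lt=1)
    sampling_interval_ns: float = Field(default=2.0, gt=0)
    bin_width_ns: float = Field(default=100.0, gt=0)
    n_boot: int = Field(default=1000, ge=1)


class RunConfig(BaseModel):
    """Resolved run configuration; echoed into the output directory."""

    seed: int = 0
    t_min_ns: float = 30.0
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    surface: SurfaceConfig = Field(default_factory=SurfaceConfig)
    convergence: ConvergenceConfig = Field(default_factory=ConvergenceConfig)


# ---------------------------------------------------------------------------
# isotropic (micelle/vesicle) pipeline
# ---------------------------------------------------------------------------

@dataclass
class IsotropicResult:
    """Outputs of the dilute-phase pipeline."""

    aggregates: pd.DataFrame        # every cluster incl. monomers
    properties: pd.DataFrame        # qualifying aggregates with shape+surface
    series: dict[str, convergence.PropertyTimeseries]
    report: dict
    counters: dict[str, int] = field(default_factory=dict)


def run_isotropic_pipeline(trajectory: Trajectory,
                           config: RunConfig | None = None,
                           compute_surfaces: bool = True) -> IsotropicResult:
    """Characterize every frame's aggregates and assess convergence.

    Aggregates below the minimum aggregation number enter the aggregate
    table (the clustering is a full partition) but are excluded from shape
    and surface metrics and from the reduced timeseries.  Percolating
    aggregates are flagged and skipped, counted in ``counters``.
    """
    if config is None:
        config = RunConfig()
    if len(trajectory) == 0:
        raise EmptyInputError("trajectory contains no frames")

    wc = config.surface.to_params()
    counters = {"percolating_skipped": 0, "surface_failures": 0, "frames": 0}
    agg_rows: list[pd.DataFrame] = []
    prop_rows: list[dict] = []

    for i_frame, frame in enumerate(trajectory):
        try:
            params = _cluster_params(frame, config.cluster)
            aggs = clustering.find_aggregates(frame, params)
        except MicelleKitError:
            logger.error("clustering failed at frame %d (t=%s ns)", i_frame, frame.time)
            raise
        counters["frames"] += 1
        agg_rows.append(clustering.aggregates_table(aggs, frame))

        for agg in aggs:
            if agg.n < params.min_aggregation_number:
                continue
            if agg.percolating:
                counters["percolating_skipped"] += 1
                continue
            desc = shape.describe_aggregate(agg, frame)
            row = {
                "time": frame.time, "aggregate_id": agg.aggregate_id,
                "N": agg.n,
                "normalized_N": clustering.normalized_aggregation_number(agg, frame),
                "r_g": desc.r_g, "a": desc.a, "b": desc.b, "c": desc.c,
                "e_ab": desc.e_ab, "e_ac": desc.e_ac,
                "ellipsoid_class": desc.ellipsoid_class,
            }
            if compute_surfaces:
                try:
                    mesh = surface.aggregate_surface(
                        agg.coordinates, frame.box, wc, mode=config.surface.mode
                    )
                    area, volume = surface.mesh_area_volume(mesh)
                    a_n, v_n, sav = surface.per_surfactant_metrics(area, volume, agg.n)
                    row.update({
                        "area": area, "volume": volume,
                        "area_per_surfactant": a_n,
                        "volume_per_surfactant": v_n,
                        "sa_to_volume": sav,
                        "outer_volume": float(np.nanmax(mesh.component_volume)),
                    })
                except MicelleKitError as exc:
                    counters["surface_failures"] += 1
                    logger.warning(
                        "surface failed for aggregate %d at frame %d: %s",
                        agg.aggregate_id, i_frame, exc,
                    )
            prop_rows.append(row)

    aggregates = pd.concat(agg_rows, ignore_index=True)
    properties = pd.DataFrame(prop_rows)
    series: dict[str, convergence.PropertyTimeseries] = {}
    report: dict = {}
    if not properties.empty:
        try:
            series = convergence.reduce_aggregate_properties(
                properties, min_n=config.cluster.min_aggregation_number
            )
            if all(s.n >= 4 for s in series.values()):
                report = convergence.convergence_report(
                    series, confidence=config.convergence.confidence
                )
        except EmptySeriesError:
            logger.info("no qualifying aggregates; convergence report skipped")
    return IsotropicResult(
        aggregates=aggregates, properties=properties, series=series,
        report=report, counters=counters,
    )


def _cluster_params(frame: Frame, cfg: ClusterConfig) -> clustering.ClusterParams:
    if cfg.r_cut is not None:
        return clustering.ClusterParams(
            r_cut=cfg.r_cut, min_aggregation_number=cfg.min_aggregation_number
        )
    return clustering.ClusterParams.for_frame(
        frame, min_aggregation_number=cfg.min_aggregation_number
    )


# ---------------------------------------------------------------------------
# bilayer pipeline
# ---------------------------------------------------------------------------

@dataclass
class BilayerResult:
    """Pooled bilayer geometry over the analysis window t > t_min."""

    per_frame: pd.DataFrame
    thickness_samples: np.ndarray
    mean_thickness: float
    mean_area_per_headgroup: float
    skipped_frames: int


def run_bilayer_pipeline(trajectory: Trajectory,
                         config: RunConfig | None = None) -> BilayerResult:
    """Thickness and area-per-headgroup distributions of a lamellar system.

    Frames at t <= t_min are discarded (pre-equilibration of the box area);
    frames whose surface does not split into two leaflets are skipped with a
    warning and counted.
    """
    if config is None:
        config = RunConfig()
    if len(trajectory) == 0:
        raise EmptyInputError("trajectory contains no frames")
    frames = [f for f in trajectory if f.time > config.t_min_ns]
    if not frames:
        raise EmptyInputError(
            f"no frames with t > {config.t_min_ns} ns in the trajectory"
        )

    wc = config.surface.to_params()
    rows: list[dict] = []
    pooled: list[np.ndarray] = []
    skipped = 0
    for i_frame, frame in enumerate(frames):
        surf_mols = frame.surfactant_molecules()
        bead_mask = np.isin(frame.mol_index, surf_mols)
        field_ = surface.gaussian_density_grid(
            frame.coordinates[bead_mask], frame.box, wc, mode=config.surface.mode
        )
        mesh = surface.willard_chandler_surface(field_, wc)
        try:
            upper, lower = surface.split_bilayer_leaflets(mesh)
        except NotABilayerError as exc:
            skipped += 1
            logger.warning("frame %d (t=%s ns) skipped: %s", i_frame, frame.time, exc)
            continue
        thick = surface.bilayer_thickness(upper, lower)
        aph = surface.area_per_headgroup(upper, lower, surf_mols.size)
        pooled.append(thick)
        rows.append({
            "time": frame.time,
            "thickness_mean": float(thick.mean()),
            "thickness_p5": float(np.percentile(thick, 5)),
            "thickness_p95": float(np.percentile(thick, 95)),
            "area_per_headgroup": aph,
            "n_surfactants": int(surf_mols.size),
        })
    if not rows:
        raise EmptyInputError("every frame was skipped; no bilayer detected")
    per_frame = pd.DataFrame(rows)
    samples = np.concatenate(pooled)
    return BilayerResult(
        per_frame=per_frame,
        thickness_samples=samples,
        mean_thickness=float(samples.mean()),
        mean_area_per_headgroup=float(per_frame["area_per_headgroup"].mean()),
        skipped_frames=skipped,
    )


# ---------------------------------------------------------------------------
# concentration utilities
# ---------------------------------------------------------------------------

def wtpercent_from_millimolar(c_mm: float, molar_mass: float = AOT_MOLAR_MASS,
                              solvent_density: float = 1.0) -> float:
    """Convert a molar concentration (mM) to weight percent.

    Solute mass per litre is c*M_r/10^6 kg; weight percent is solute mass
    over total (solute + solvent) mass.  The critical vesicle concentration
    of AOT, 7.5 mM, converts to ~0.33 wt %.
    """
    if c_mm < 0:
        raise ValueError("concentration must be non-negative")
    if molar_mass <= 0 or solvent_density <= 0:
        raise ValueError("molar mass and solvent density must be positive")
    solute_kg_per_l = c_mm * molar_mass / 1.0e6
    return 100.0 * solute_kg_per_l / (solute_kg_per_l + solvent_density)
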