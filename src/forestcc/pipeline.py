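"""End-to-end synthetic pipeline: scene -> four products -> change -> statistics.

This module wires the whole analysis together on a generated landscape: the
four sensor products are rendered from one ground truth, each is taken
through its own change recipe at the analysis resolution, and the change
maps are compared by agreement mapping, area accounting and provincial
correlation.  It backs the ``report`` CLI subcommand and the worked
examples; every stage is equally callable on real rasters through the
module APIs it composes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import accounting, concordance, mapchange, scaling, scenegen, trajfit
from .config import RunConfig
from .grid import AnnualCube, GridSpec


@dataclass
class PipelineResult:
    truth: scenegen.TruthScene
    grid: GridSpec
    change_maps: dict[str, np.ndarray]        # label maps per dataset
    delta_maps: dict[str, np.ndarray]         # signed percent, where fractional
    province_ids: np.ndarray
    province_land: pd.DataFrame
    province_tables: dict[str, pd.DataFrame]
    national: pd.DataFrame
    agreement: dict[str, dict[str, np.ndarray]]
    correlations: dict[str, pd.DataFrame]


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def run_synthetic_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Run the full four-dataset comparison on one synthetic landscape."""
    cfg = config or RunConfig()
    g = cfg.grid
    grid = GridSpec(
        rows=g.rows, cols=g.cols, pixel_size_m=g.pixel_size_m,
        origin_x=g.origin_x, origin_y=g.origin_y,
        year_start=g.year_start, year_end=g.year_end,
    )
    sc = cfg.scene
    truth = scenegen.make_truth(
        grid, sc.mix, _derive_seed(cfg.seed, 0),
        loss_magnitude=sc.loss_magnitude, gain_magnitude=sc.gain_magnitude,
        ramp_rate=sc.ramp_rate,
    )

    # --- render the four products -----------------------------------------
    nbr = scenegen.render_nbr(
        truth, sc.nbr_level_forest, sc.nbr_level_bare, sc.nbr_sigma,
        _derive_seed(cfg.seed, 1),
    )
    lc = scenegen.render_lc(
        truth, flip_prob=sc.lc_flip_prob, seed=_derive_seed(cfg.seed, 2)
    )
    vcf_fine = scenegen.render_vcf(
        truth, sc.vcf_refine_factor, sc.vcf_sigma_pct, _derive_seed(cfg.seed, 3)
    )
    gfc = scenegen.render_gfc(truth, sc.gfc_refine_factor, seed=_derive_seed(cfg.seed, 4))

    # --- change extraction, each product's own recipe ----------------------
    det = trajfit.DetectorParams(
        forest_threshold=cfg.detector.forest_threshold,
        change_threshold=cfg.detector.change_threshold,
        max_segments=cfg.detector.max_segments,
        despike_threshold=cfg.detector.despike_threshold,
        mse_improvement_min=cfg.detector.mse_improvement_min,
        mask_filters_gain=cfg.detector.mask_filters_gain,
    )
    # independent forest mask: forest at the start of the span (true baseline
    # cover >= 0.5), the role the land-cover product plays for the real data
    mask = truth.cover(grid.year_start) >= 0.5
    nbr_result = trajfit.detect_changes(nbr, det, mask)
    nbr_labels = nbr_result["label"]

    w = cfg.windows
    lc_t1 = mapchange.stable_class_map(lc, w.lc_t1)
    lc_t2 = mapchange.stable_class_map(lc, w.lc_t2)
    lc_labels = mapchange.categorical_change(
        lc_t1, lc_t2, mapchange.ForestDefinition("class_set",
                                                 class_codes=frozenset({scenegen.FOREST_CODE}))
    )

    vcf = AnnualCube(
        grid,
        np.stack([
            scaling.aggregate_average(vcf_fine.layer(y), sc.vcf_refine_factor)
            for y in grid.years
        ]),
    )
    vcf_delta = mapchange.fractional_change(
        mapchange.period_mean_cover(vcf, w.vcf_t1),
        mapchange.period_mean_cover(vcf, w.vcf_t2),
    )

    gfc_loss_fine = mapchange.accumulate_annual_loss(gfc["loss"])
    gfc_loss_pct = scaling.aggregate_fraction(gfc_loss_fine, sc.gfc_refine_factor)
    gfc_gain_pct = scaling.aggregate_fraction(gfc["gain"], sc.gfc_refine_factor)
    gfc_delta = gfc_gain_pct - gfc_loss_pct

    change_maps = {
        "nbr": nbr_labels,
        "lc": lc_labels,
        "vcf": mapchange.fractional_to_labels(vcf_delta),
        "gfc": mapchange.fractional_to_labels(gfc_delta),
    }
    delta_maps = {"vcf": vcf_delta, "gfc": gfc_delta}

    # --- provinces, accounting, agreement, correlation ---------------------
    province_ids, province_land = scenegen.render_provinces(
        grid, sc.province_rows, sc.province_cols
    )
    tables = {}
    for name, labels in change_maps.items():
        if name in delta_maps:
            tables[name] = accounting.provincial_aggregate(
                province_ids=province_ids, land_areas=province_land,
                grid=grid, delta_map=delta_maps[name],
            )
        else:
            tables[name] = accounting.provincial_aggregate(
                province_ids=province_ids, land_areas=province_land,
                grid=grid, label_map=labels,
            )

    national_rows = []
    total_land = float(province_land["land_area_km2"].sum())
    for name, tab in tables.items():
        tot = accounting.national_totals(tab)
        national_rows.append({
            "dataset": name, **tot,
            "loss_pct": accounting.coverage_percent(tot["loss_km2"], total_land),
            "gain_pct": accounting.coverage_percent(tot["gain_km2"], total_land),
            "net_pct": accounting.coverage_percent(tot["net_km2"], total_land),
        })
    national = pd.DataFrame(national_rows)

    agreement = {}
    for direction in ("loss", "gain"):
        binaries = []
        for name in change_maps:
            if name in delta_maps:
                binaries.append(concordance.to_binary_change(
                    delta_maps[name], direction, kind="fractional"))
            else:
                binaries.append(concordance.to_binary_change(
                    change_maps[name], direction))
        agreement[direction] = concordance.agreement_count(binaries)

    correlations = {}
    for metric in ("loss", "gain", "net"):
        r, sig = concordance.correlation_matrix(tables, metric=metric)
        correlations[metric] = r
        correlations[f"{metric}_significant"] = sig

    return PipelineResult(
        truth=truth, grid=grid,
        change_maps=change_maps, delta_maps=delta_maps,
        province_ids=province_ids, province_land=province_land,
        province_tables=tables, national=national,
        agreement=agreement, correlations=correlations,
    )
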