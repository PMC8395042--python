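"""End-to-end orchestration: from a raster series (real or synthetic) to
transition matrices, carbon summaries, level maps, process records, and the
clustered process-year matrix, all written as plain-text artifacts.

Every stage's computation lives in the sibling modules; this module only
sequences them, validates inputs, and fixes the output formats so that a run
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbon import (
    CarbonDensityTable,
    group_storage,
    level_map,
    sequestration,
    total_storage,
)
from .clustering import build_process_year_matrix, cluster_rows, export_heatmap, zscore_by_period
from .lulc import GROUPS, LULCSeries, read_lulc_raster, write_lulc_raster
from .processes import category_map, process_table, process_table_frame
from .synthetic import CoastScenario, generate_series
from .transitions import series_transition_matrices, write_matrix_csv


@dataclass
class RunConfig:
    """One pipeline run: either input rasters or a synthetic scenario."""

    rasters: list[str] | None = None
    scenario: CoastScenario | None = None
    density_csv: str | None = None  # None -> packaged coastal table
    out_dir: str = "results/run"
    seed: int = 0
    linkage: str = "complete"
    sample_sd: bool = False
    jenks_k: int = 4
    include_unclassified: bool = False

    def __post_init__(self) -> None:
        if (self.rasters is None) == (self.scenario is None):
            raise ValueError("give either raster paths or a scenario, not both")
        if self.rasters is not None and len(self.rasters) < 2:
            raise ValueError("need >= 2 raster dates")


def load_series(config: RunConfig) -> LULCSeries:
    if config.scenario is not None:
        scenario = config.scenario
        if scenario.seed != config.seed:
            from dataclasses import replace

            scenario = replace(scenario, seed=config.seed)
        return generate_series(scenario)
    return LULCSeries([read_lulc_raster(p) for p in config.rasters])


def validate_inputs(config: RunConfig) -> dict:
    """Report-only validation: congruence failures, unknown codes, and
    density-table pool/total inconsistencies. Never raises for data issues."""
    report: dict = {"raster_issues": [], "density_issues": [], "ok": True}
    table = CarbonDensityTable.from_csv(config.density_csv)
    for code in table.inconsistent_rows():
        pools = table.pools[code]
        report["density_issues"].append(
            {
                "code": code,
                "pool_sum": round(sum(pools), 6),
                "printed_total": table.totals[code],
            }
        )
    if config.rasters is not None:
        grids = []
        for p in config.rasters:
            try:
                grids.append(read_lulc_raster(p))
            except Exception as e:  # noqa: BLE001 - report, don't abort
                report["raster_issues"].append({"path": str(p), "error": str(e)})
        if grids:
            first = grids[0]
            for p, g in zip(config.rasters[1:], grids[1:]):
                if not first.congruent_with(g):
                    report["raster_issues"].append(
                        {"path": str(p), "error": "not congruent with first raster"}
                    )
                elif not np.array_equal(first.mask, g.mask):
                    report["raster_issues"].append(
                        {"path": str(p), "error": "nodata mask differs from first raster"}
                    )
    report["ok"] = not report["raster_issues"]
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the output bundle; returns a summary dict.

    Outputs under ``config.out_dir``:

    * ``transition_<a>_<b>.csv`` — per-period change matrices with marginals
    * ``carbon_summary.csv`` — storage per date (total, per group, Mg and
      10⁴ Mg) and per-period sequestration
    * ``level_map_<date>.asc`` + ``level_legend.json`` — carbon-level rasters
    * ``process_table.csv`` — per-chain carbon records
    * ``category_map.asc`` + ``category_legend.json``
    * ``process_year_matrix.csv``, ``heatmap.csv``, ``heatmap.json``
    * ``manifest.json`` — config echo, seed, version
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = CarbonDensityTable.from_csv(config.density_csv)
    stage = "load series"
    try:
        series = load_series(config)
        labels = series.date_labels

        stage = "transition matrices"
        matrices = series_transition_matrices(series)
        for m in matrices:
            write_matrix_csv(m, out / f"transition_{m.period[0]}_{m.period[1]}.csv")

        stage = "carbon accounting"
        rows = []
        for g in series:
            tot = total_storage(g, table)
            by_group = group_storage(g, table)
            rows.append(
                {
                    "date": g.date_label,
                    "total_Mg": tot,
                    "total_1e4Mg": tot / 1e4,
                    **{f"{grp} Mg": by_group[grp] for grp in GROUPS},
                }
            )
        summary = pd.DataFrame(rows)
        seqs = []
        for k in range(len(series) - 1):
            s = sequestration(series[k], series[k + 1], table)
            seqs.append(
                {
                    "period": f"{labels[k]}-{labels[k + 1]}",
                    "sequestration_Mg": s,
                    "sequestration_1e4Mg": s / 1e4,
                }
            )
        s_all = sequestration(series[0], series[-1], table)
        seqs.append(
            {
                "period": f"{labels[0]}-{labels[-1]}",
                "sequestration_Mg": s_all,
                "sequestration_1e4Mg": s_all / 1e4,
            }
        )
        with open(out / "carbon_summary.csv", "w") as fh:
            fh.write(summary.to_csv(index=False, float_format="%.4f"))
            fh.write(pd.DataFrame(seqs).to_csv(index=False, float_format="%.4f"))

        stage = "carbon level maps"
        legend = None
        for g in series:
            levels, legend = level_map(g, table, k=config.jenks_k)
            write_lulc_raster(
                g.with_cells(np.where(g.mask, levels, 0)), out / f"level_map_{g.date_label}.asc"
            )
        with open(out / "level_legend.json", "w") as fh:
            json.dump(legend, fh, indent=1)
            fh.write("\n")

        stage = "driving processes"
        records = process_table(
            series, table, include_unclassified=config.include_unclassified
        )
        frame = process_table_frame(records)
        frame.to_csv(out / "process_table.csv", index=False, float_format="%.4f")
        cats, cat_legend = category_map(series, table)
        write_lulc_raster(series[0].with_cells(cats), out / "category_map.asc")
        with open(out / "category_legend.json", "w") as fh:
            json.dump(cat_legend, fh, indent=1)
            fh.write("\n")

        stage = "process clustering"
        pym = build_process_year_matrix(
            series, table, include_unclassified=config.include_unclassified
        )
        pym.to_csv(out / "process_year_matrix.csv", index_label="chain", float_format="%.4f")
        cluster_summary = None
        if len(pym) >= 2:
            z = zscore_by_period(pym, sample_sd=config.sample_sd)
            result = cluster_rows(z, linkage=config.linkage)
            export_heatmap(result, out / "heatmap")
            cluster_summary = {
                "n_chains": len(pym),
                "leaf_order": result.ordered_labels,
            }

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "linkage": config.linkage,
            "sample_sd": config.sample_sd,
            "jenks_k": config.jenks_k,
            "rasters": config.rasters,
            "scenario": None
            if config.scenario is None
            else {
                "shape": list(config.scenario.shape),
                "cell_size": config.scenario.cell_size,
                "n_dates": config.scenario.n_dates,
                "rates": config.scenario.rates,
                "reclamation_targets": {
                    str(k): v for k, v in config.scenario.reclamation_targets.items()
                },
                "reclamation_reach": config.scenario.reclamation_reach,
            },
            "dates": list(labels),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    return {
        "out_dir": str(out),
        "dates": list(labels),
        "total_storage_Mg": {r["date"]: r["total_Mg"] for r in rows},
        "sequestration_Mg": {s["period"]: s["sequestration_Mg"] for s in seqs},
        "n_process_records": len(records),
        "clustering": cluster_summary,
    }
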