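#!/usr/bin/env python
"""Carbon storage and sequestration of the simulated series: total and
per-group storage at each date, per-period sequestration, and four-level
natural-breaks carbon maps."""

import argparse
import json
from pathlib import Path

import pandas as pd

from bluecarbon import (
    CarbonDensityTable,
    GROUPS,
    LULCSeries,
    group_storage,
    level_map,
    read_lulc_raster,
    sequestration,
    total_storage,
    write_lulc_raster,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
parser.add_argument("--out-dir", type=Path, default=Path("results/carbon"))
args = parser.parse_args()

series = LULCSeries([read_lulc_raster(p) for p in sorted(args.in_dir.glob("*.asc"))])
table = CarbonDensityTable.from_csv()
args.out_dir.mkdir(parents=True, exist_ok=True)

rows = []
for grid in series:
    tot = total_storage(grid, table)
    by_group = group_storage(grid, table)
    rows.append({"date": grid.date_label, "total_1e4Mg": tot / 1e4,
                 **{g: by_group[g] / 1e4 for g in GROUPS}})
    levels, legend = level_map(grid, table)
    write_lulc_raster(grid.with_cells(levels), args.out_dir / f"level_map_{grid.date_label}.asc")
storage = pd.DataFrame(rows)
storage.to_csv(args.out_dir / "storage_by_date.csv", index=False, float_format="%.4f")
with open(args.out_dir / "level_legend.json", "w") as fh:
    json.dump(legend, fh, indent=1)

print("storage by date (10⁴ Mg):")
print(storage.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
labels = series.date_labels
print("sequestration (10⁴ Mg):")
for a, b in [*zip(labels, labels[1:]), (labels[0], labels[-1])]:
    ga = series[labels.index(a)]
    gb = series[labels.index(b)]
    print(f"  {a}-{b}: {sequestration(ga, gb, table) / 1e4:+.4f}")
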