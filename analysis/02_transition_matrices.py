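#!/usr/bin/env python
"""Cross-tabulate the simulated series into per-period transition matrices
(km², with transfer-in/out marginals) and report the largest conversions."""

import argparse
from pathlib import Path

import numpy as np

from bluecarbon import (
    CODE_NAMES,
    LULCSeries,
    read_lulc_raster,
    write_matrix_csv,
)
from bluecarbon.transitions import series_transition_matrices

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
parser.add_argument("--out-dir", type=Path, default=Path("results/transitions"))
args = parser.parse_args()

paths = sorted(args.in_dir.glob("*.asc"))
series = LULCSeries([read_lulc_raster(p) for p in paths])
args.out_dir.mkdir(parents=True, exist_ok=True)

for m in series_transition_matrices(series):
    out = write_matrix_csv(m, args.out_dir / f"transition_{m.period[0]}_{m.period[1]}.csv")
    flat = [
        (m.areas[i, j], i + 1, j + 1)
        for i in range(10)
        for j in range(10)
        if i != j and m.areas[i, j] > 0
    ]
    flat.sort(reverse=True)
    print(f"{m.period[0]}->{m.period[1]}: changed area {m.changed_area_km2:.2f} km²")
    for area, i, j in flat[:3]:
        print(f"  {CODE_NAMES[i]} -> {CODE_NAMES[j]}: {area:.2f} km²")
    print(f"  wrote {out}")
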