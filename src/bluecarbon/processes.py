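"""Natural-human driving-process chains behind per-pixel LULC trajectories.

Every ordered pair of class codes maps to exactly one process step:

* Accretion (A): sediment deposition creates tidal flat/marsh from open
  water — 1-2, 1-3, 5-2, 5-3.
* Succession (S): natural advance toward the marsh/grassland climax —
  2-3, 2-4, 3-4.
* Regressive succession (Rs): marsh degrading back to tidal flat — 3-2.
* Erosion (E): flats/marsh/grassland lost to open water — 2-1, 3-1, 4-1.
* Reclamation (R): any water/wetland class (1-5) converted to an artificial
  or other land class (6-10).
* Restoration (Re): an artificial/other class (6-10) returned to a
  water/wetland class (1-5).
* Stable: no change.
* Unclassified: any remaining pair (e.g. 9-6, 2-5); the taxonomy above does
  not cover it, so such steps are reported separately rather than silently
  binned. ``extra_steps`` lets a user extend the mapping.

A pixel's chain is the ordered sequence of its non-Stable steps with
consecutive duplicates collapsed (so "Mono" means one distinct process, not
one interval), labelled e.g. "A-S" or "R-Re-R". Chains are Natural if every
step is A/S/Rs/E, Human if every step is R/Re, Natural-Human otherwise, and
fall into Mono+/Mono-/Multiple+/Multiple- by chain length and the sign of
the net carbon change.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .carbon import CarbonDensityTable, carbon_map
from .lulc import CODES, LULCGrid, LULCSeries

STEP_A = "A"
STEP_S = "S"
STEP_RS = "Rs"
STEP_E = "E"
STEP_R = "R"
STEP_RE = "Re"
STABLE = "Stable"
UNCLASSIFIED = "U"

NATURAL_STEPS = frozenset({STEP_A, STEP_S, STEP_RS, STEP_E})
HUMAN_STEPS = frozenset({STEP_R, STEP_RE})

_WETLAND_WATER = frozenset({1, 2, 3, 4, 5})
_ARTIFICIAL_OTHER = frozenset({6, 7, 8, 9, 10})

STEP_PAIRS: dict[str, frozenset[tuple[int, int]]] = {
    STEP_A: frozenset({(1, 2), (1, 3), (5, 2), (5, 3)}),
    STEP_S: frozenset({(2, 3), (2, 4), (3, 4)}),
    STEP_RS: frozenset({(3, 2)}),
    STEP_E: frozenset({(2, 1), (3, 1), (4, 1)}),
    STEP_R: frozenset((i, j) for i in _WETLAND_WATER for j in _ARTIFICIAL_OTHER),
    STEP_RE: frozenset((i, j) for i in _ARTIFICIAL_OTHER for j in _WETLAND_WATER),
}

_PAIR_TO_STEP: dict[tuple[int, int], str] = {}
for _step, _pairs in STEP_PAIRS.items():
    for _p in _pairs:
        _PAIR_TO_STEP[_p] = _step


def step_process(
    code_a: int, code_b: int, extra_steps: dict[tuple[int, int], str] | None = None
) -> str:
    """Classify one interval's transition into a process step.

    >>> step_process(1, 2)
    'A'
    >>> step_process(3, 7)
    'R'
    >>> step_process(9, 6)
    'U'
    """
    for c in (code_a, code_b):
        if c not in CODES:
            raise ValueError(f"invalid LULC code {c!r}: expected 1..10")
    if code_a == code_b:
        return STABLE
    if extra_steps and (code_a, code_b) in extra_steps:
        return extra_steps[(code_a, code_b)]
    return _PAIR_TO_STEP.get((code_a, code_b), UNCLASSIFIED)


def pixel_chain(
    codes, extra_steps: dict[tuple[int, int], str] | None = None
) -> str:
    """Chain label for one pixel's dated code sequence.

    Stable steps are dropped and consecutive duplicate steps collapse;
    an all-stable pixel is labelled "Stable".

    >>> pixel_chain([3, 7, 3, 9])
    'R-Re-R'
    >>> pixel_chain([1, 2, 2, 3])
    'A-S'
    """
    codes = list(codes)
    if len(codes) < 2:
        raise ValueError("a chain needs codes at >= 2 dates")
    steps: list[str] = []
    for a, b in zip(codes, codes[1:]):
        s = step_process(a, b, extra_steps)
        if s == STABLE:
            continue
        if steps and steps[-1] == s:
            continue
        steps.append(s)
    return "-".join(steps) if steps else STABLE


def chain_steps(label: str) -> list[str]:
    """Split a chain label back into its steps; "Stable" -> []."""
    return [] if label == STABLE else label.split("-")


def chain_attribute(chain: str) -> str:
    """Natural / Human / Natural-Human attribution of a chain."""
    steps = chain_steps(chain)
    if not steps:
        raise ValueError("Stable chain has no attribute")
    if UNCLASSIFIED in steps:
        raise ValueError(f"chain {chain!r} contains an unclassified step")
    if all(s in NATURAL_STEPS for s in steps):
        return "Natural"
    if all(s in HUMAN_STEPS for s in steps):
        return "Human"
    return "Natural-Human"


def chain_category(chain: str, total_dc: float) -> str:
    """Mono+/Mono-/Multiple+/Multiple- by chain length and sign of net
    carbon change; Stable for the empty chain, Neutral on an exact zero."""
    steps = chain_steps(chain)
    if not steps:
        return "Stable"
    if total_dc == 0:
        return "Neutral"
    kind = "Mono" if len(steps) == 1 else "Multiple"
    return kind + ("+" if total_dc > 0 else "−")


@dataclass(frozen=True)
class ProcessRecord:
    """Aggregate carbon change of all pixels sharing one chain."""

    chain: str
    total_dc: float  # Mg, end-minus-start
    area_ha: float
    category: str
    attribute: str
    n_pixels: int

    @property
    def magnitude(self) -> float:
        """Carbon change per unit area, Mg/ha."""
        return self.total_dc / self.area_ha


def _chain_labels(
    series: LULCSeries, extra_steps: dict[tuple[int, int], str] | None = None
) -> np.ndarray:
    """Chain label per pixel (object array; nodata pixels get "Stable")."""
    stack = series.codes_per_date()
    mask = series[0].mask
    labels = np.full(mask.shape, STABLE, dtype=object)
    # label cache keyed by the trajectory tuple: real series have few
    # distinct trajectories relative to pixels
    cache: dict[tuple[int, ...], str] = {}
    changed = np.zeros(mask.shape, dtype=bool)
    for k in range(len(series) - 1):
        changed |= stack[k] != stack[k + 1]
    changed &= mask
    for r, c in np.argwhere(changed):
        traj = tuple(int(v) for v in stack[:, r, c])
        lab = cache.get(traj)
        if lab is None:
            lab = pixel_chain(traj, extra_steps)
            cache[traj] = lab
        labels[r, c] = lab
    return labels


def process_table(
    series: LULCSeries,
    table: CarbonDensityTable,
    extra_steps: dict[tuple[int, int], str] | None = None,
    include_unclassified: bool = False,
) -> list[ProcessRecord]:
    """One record per distinct chain among changed pixels, sorted by
    total carbon change.

    ``total_dc`` is the summed per-pixel end-minus-start storage, ``area``
    the pixel count times the cell area in ha. Chains containing an
    unclassified step are excluded unless ``include_unclassified``; their
    attribute is then reported as "Unclassified".
    """
    labels = _chain_labels(series, extra_steps)
    dc = carbon_map(series[-1], table) - carbon_map(series[0], table)
    cell_ha = series[0].cell_area_ha
    totals: dict[str, float] = defaultdict(float)
    counts: dict[str, int] = defaultdict(int)
    for (r, c), lab in np.ndenumerate(labels):
        if lab == STABLE:
            continue
        totals[lab] += float(dc[r, c])
        counts[lab] += 1
    records = []
    for lab, total in totals.items():
        has_u = UNCLASSIFIED in chain_steps(lab)
        if has_u and not include_unclassified:
            continue
        records.append(
            ProcessRecord(
                chain=lab,
                total_dc=total,
                area_ha=counts[lab] * cell_ha,
                category=chain_category(lab, total),
                attribute="Unclassified" if has_u else chain_attribute(lab),
                n_pixels=counts[lab],
            )
        )
    return sorted(records, key=lambda rec: rec.total_dc)


def process_table_frame(records: list[ProcessRecord]) -> pd.DataFrame:
    """Records as a table with the published column layout."""
    return pd.DataFrame(
        {
            "Driving Process": [r.chain for r in records],
            "Total(Mg)": [r.total_dc for r in records],
            "Magnitude (Mg/ha)": [r.magnitude for r in records],
            "Categories": [r.category for r in records],
            "Attribute": [r.attribute for r in records],
        }
    )


CATEGORY_CODES = {
    "Stable": 0,
    "Mono+": 1,
    "Mono−": 2,
    "Multiple+": 3,
    "Multiple−": 4,
    "Neutral": 5,
    "Unclassified": 6,
}


def category_map(
    series: LULCSeries,
    table: CarbonDensityTable,
    extra_steps: dict[tuple[int, int], str] | None = None,
) -> tuple[np.ndarray, dict[int, str]]:
    """Per-pixel category raster (the spatial counterpart of the chain
    table): each changed pixel is Mono/Multiple by its own chain and +/- by
    the sign of its own carbon change. Returns the integer raster and the
    legend mapping code -> category name."""
    labels = _chain_labels(series, extra_steps)
    dc = carbon_map(series[-1], table) - carbon_map(series[0], table)
    out = np.zeros(labels.shape, dtype=np.int64)
    for (r, c), lab in np.ndenumerate(labels):
        if lab == STABLE:
            continue
        if UNCLASSIFIED in chain_steps(lab):
            out[r, c] = CATEGORY_CODES["Unclassified"]
        else:
            out[r, c] = CATEGORY_CODES[chain_category(lab, float(dc[r, c]))]
    legend = {v: k for k, v in CATEGORY_CODES.items()}
    return out, legend


def chain_raster(
    series: LULCSeries, extra_steps: dict[tuple[int, int], str] | None = None
) -> tuple[np.ndarray, dict[int, str]]:
    """Integer raster of chain labels plus its codebook (0 = Stable)."""
    labels = _chain_labels(series, extra_steps)
    uniq = sorted({lab for _, lab in np.ndenumerate(labels) if lab != STABLE})
    codebook = {0: STABLE, **{i + 1: lab for i, lab in enumerate(uniq)}}
    lab_to_code = {lab: i for i, lab in codebook.items()}
    out = np.zeros(labels.shape, dtype=np.int64)
    for (r, c), lab in np.ndenumerate(labels):
        out[r, c] = lab_to_code[lab]
    return out, codebook
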