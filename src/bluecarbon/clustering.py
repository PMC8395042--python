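"""Chains x dates carbon matrix, per-date z-scoring, and hierarchical
clustering of the chain rows (the clustered-heatmap analysis).

The matrix entry (chain, date) is the summed storage, at that date, of all
pixels that experienced the chain over the full series. Each date column is
z-scored across chains — population standard deviation by default, matching
the bare (X - mu)/sigma convention; a sample-sd switch is provided for
parity with common heatmap tooling. Rows are then clustered agglomeratively
under Euclidean distance.

The agglomeration is implemented directly (the row counts here are tens, not
thousands) so that tie-breaking is fully specified: when two pairs share the
minimal linkage distance, the lexicographically smallest pair of current
cluster indices merges first. scipy's linkage serves as an independent
cross-check in the test-suite, not as the implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .carbon import CarbonDensityTable, carbon_map
from .lulc import LULCSeries
from .processes import STABLE, UNCLASSIFIED, chain_steps, _chain_labels

LINKAGES = ("complete", "average", "single")


def build_process_year_matrix(
    series: LULCSeries,
    table: CarbonDensityTable,
    include_unclassified: bool = False,
) -> pd.DataFrame:
    """Accumulated carbon storage (Mg) of each chain's pixels at each date.

    Rows are chain labels, columns the series' date labels. Pixels that never
    change (chain "Stable") are excluded; chains bearing unclassified steps
    are excluded unless requested.
    """
    labels = _chain_labels(series)
    maps = [carbon_map(g, table) for g in series]
    sums: dict[str, np.ndarray] = {}
    for (r, c), lab in np.ndenumerate(labels):
        if lab == STABLE:
            continue
        if not include_unclassified and UNCLASSIFIED in chain_steps(lab):
            continue
        acc = sums.setdefault(lab, np.zeros(len(series)))
        for k, cm in enumerate(maps):
            acc[k] += float(cm[r, c])
    frame = pd.DataFrame.from_dict(sums, orient="index", columns=list(series.date_labels))
    return frame.sort_index()


def zscore_by_period(matrix: pd.DataFrame, sample_sd: bool = False) -> pd.DataFrame:
    """Z-score each date column across chains: (X - mu) / sigma.

    ``sample_sd=False`` divides by the population sd (n); ``True`` by the
    sample sd (n-1). A constant column (sigma 0) maps to all zeros.
    """
    if len(matrix) < 2:
        raise ValueError("z-scoring needs >= 2 rows")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("matrix contains non-finite values")
    ddof = 1 if sample_sd else 0
    mu = matrix.mean(axis=0)
    sigma = matrix.std(axis=0, ddof=ddof)
    out = matrix.sub(mu, axis=1)
    nonzero = sigma > 0
    out.loc[:, nonzero] = out.loc[:, nonzero].div(sigma[nonzero], axis=1)
    out.loc[:, ~nonzero] = 0.0
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative merge tree over the rows of a normalized matrix.

    ``merges`` lists (left, right, height, size) with scipy-style node ids:
    leaves are 0..n-1 in row order, merge m creates node n+m.
    """

    matrix: pd.DataFrame
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    linkage: str

    @property
    def ordered_labels(self) -> list[str]:
        return [self.matrix.index[i] for i in self.leaf_order]

    def linkage_matrix(self) -> np.ndarray:
        """The merge tree in scipy's (n-1, 4) linkage layout."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float)


def _linkage_distance(
    d: np.ndarray, members_a: list[int], members_b: list[int], linkage: str
) -> float:
    block = d[np.ix_(members_a, members_b)]
    if linkage == "complete":
        return float(block.max())
    if linkage == "average":
        return float(block.mean())
    if linkage == "single":
        return float(block.min())
    raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")


def cluster_rows(matrix: pd.DataFrame, linkage: str = "complete") -> ClusterResult:
    """Agglomerative clustering of matrix rows under Euclidean distance.

    At each step the pair of clusters with minimal linkage distance merges;
    exact ties go to the lexicographically smallest pair of active node ids.
    Leaf order comes from traversing the merge tree depth-first, lower node
    id first — deterministic across platforms.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    X = matrix.to_numpy(dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("clustering needs >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    # active cluster id -> leaf members; ids follow scipy numbering
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    children: dict[int, tuple[int, int]] = {}
    for step in range(n - 1):
        active = sorted(members)
        best: tuple[float, int, int] | None = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dist = _linkage_distance(d, members[a], members[b], linkage)
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best  # type: ignore[misc]
        new = n + step
        members[new] = members.pop(a) + members.pop(b)
        children[new] = (a, b)
        merges.append((a, b, dist, len(members[new])))
    leaf_order: list[int] = []

    def _walk(node: int) -> None:
        if node < n:
            leaf_order.append(node)
            return
        left, right = children[node]
        _walk(left)
        _walk(right)

    _walk(n + n - 2)
    return ClusterResult(matrix=matrix, merges=merges, leaf_order=leaf_order, linkage=linkage)


def export_heatmap(result: ClusterResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write the normalized matrix (rows in leaf order) as CSV and the
    dendrogram (children, heights) as JSON; returns the two paths.

    Any plotted heatmap is a veneer over these two files, so they are the
    canonical artifact.
    """
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    ordered = result.matrix.iloc[result.leaf_order]
    ordered.to_csv(csv_path, index_label="chain", float_format="%.9g")
    payload = {
        "linkage": result.linkage,
        "labels": list(result.matrix.index),
        "leaf_order": result.leaf_order,
        "merges": [
            {"left": l, "right": r, "height": h, "size": s}
            for l, r, h, s in result.merges
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return csv_path, json_path


def render_heatmap(result: ClusterResult, path: str | Path) -> Path:
    """Optional matplotlib rendering of the clustered matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = result.matrix.iloc[result.leaf_order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(ordered)), ordered.index)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns)
    fig.colorbar(im, ax=ax, label="z-scored storage")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
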