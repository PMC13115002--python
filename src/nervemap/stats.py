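"""Per-slice spatial statistics of the innervation map.

Four complementary metrics describe how nerve fibres are distributed
across a ring:

* Shannon entropy of the density histogram (heterogeneity of the
  distribution) over the fixed logarithmic density bins, natural log;
* global Moran's I on the density-map lattice (spatial autocorrelation:
  positive = clustered similar values, near 0 = random, negative =
  alternating), binary rook/queen contiguity weights;
* mean nearest-neighbour distance (NND) of fibre pixels (local packing;
  1 px is the lattice minimum, so values near 1 mean near-saturation);
* hotspot volume: total pixel area of windows whose density strictly
  exceeds a high-density threshold.

The apex -> base profile tabulates these per slice with per-region
mean and 95% Student-t confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial import cKDTree

from .density import DEFAULT_BIN_EDGES, DensityMap
from .fiber_detect import FiberMask

__all__ = [
    "SliceMetrics",
    "ProfileTable",
    "shannon_entropy",
    "morans_i",
    "mean_nnd",
    "hotspot_volume",
    "slice_metrics",
    "innervation_profile",
    "DEFAULT_HOTSPOT_THRESHOLD",
]

# lowest edge of the top logarithmic bin
DEFAULT_HOTSPOT_THRESHOLD = DEFAULT_BIN_EDGES[-1]


@dataclass
class SliceMetrics:
    slice_index: int  # 1 = apex
    entropy: float
    morans_i: float
    nnd_mean: float
    hotspot_volume_px: float


def _covered_values(dm: DensityMap) -> np.ndarray:
    """Density values of tissue-covered cells (all cells if no coverage
    information is attached)."""
    if dm.tissue_frac is not None:
        return dm.grid[dm.tissue_frac > 0]
    return dm.grid.ravel()


def shannon_entropy(dm: DensityMap, edges: np.ndarray | None = None) -> float:
    """H = -sum p_i ln p_i over the histogram of cell densities.

    Cells are assigned to the fixed logarithmic bins (inclusive lower
    edges); values below the first edge form their own background
    category, so near-empty cells still shape the histogram. Only
    tissue-covered cells are counted. Empty bins contribute 0.
    """
    edges = np.asarray(edges if edges is not None else DEFAULT_BIN_EDGES, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be a strictly increasing 1-D sequence")
    vals = _covered_values(dm)
    if vals.size == 0:
        raise ValueError("density map has no tissue-covered cells")
    idx = np.searchsorted(edges, vals, side="right") - 1  # -1 = background
    counts = np.bincount(idx + 1, minlength=len(edges) + 1).astype(np.float64)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


_SHIFTS_ROOK = ((0, 1), (1, 0))
_SHIFTS_QUEEN = ((0, 1), (1, 0), (1, 1), (1, -1))


def morans_i(values: np.ndarray, valid: np.ndarray | None = None, adjacency: str = "queen") -> float:
    """Global Moran's I on a lattice with binary contiguity weights.

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 for adjacent valid cells (rook: edge neighbours; queen:
    edge + diagonal) and W the total weight counting both directions.

    Raises on zero variance, fewer than 2 valid cells or no adjacent
    valid pair.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D grid")
    v = np.ones_like(x, dtype=bool) if valid is None else np.asarray(valid).astype(bool)
    if v.shape != x.shape:
        raise ValueError("valid mask shape differs from values")
    n = int(v.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    xbar = x[v].mean()
    denom = float(((x[v] - xbar) ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined on a constant grid")
    if adjacency == "rook":
        shifts = _SHIFTS_ROOK
    elif adjacency == "queen":
        shifts = _SHIFTS_QUEEN
    else:
        raise ValueError("adjacency must be 'rook' or 'queen'")
    z = np.where(v, x - xbar, 0.0)
    num = 0.0
    w_total = 0
    for dr, dc in shifts:
        a = slice(max(dr, 0), x.shape[0] + min(dr, 0))
        b = slice(max(-dr, 0), x.shape[0] + min(-dr, 0))
        c = slice(max(dc, 0), x.shape[1] + min(dc, 0))
        d = slice(max(-dc, 0), x.shape[1] + min(-dc, 0))
        pair_valid = v[a, c] & v[b, d]
        num += 2.0 * float((z[a, c] * z[b, d] * pair_valid).sum())
        w_total += 2 * int(pair_valid.sum())
    if w_total == 0:
        raise ValueError("no adjacent valid cell pairs")
    return (n / w_total) * num / denom


def mean_nnd(points_or_mask: FiberMask | np.ndarray) -> float:
    """Mean Euclidean distance from each point to its nearest other point.

    A fibre mask is treated as the set of its pixel centres (px units at
    the working downscale). Requires >= 2 points.
    """
    if isinstance(points_or_mask, FiberMask):
        pts = np.column_stack(np.nonzero(points_or_mask.mask)).astype(np.float64)
    else:
        arr = np.asarray(points_or_mask)
        if arr.ndim == 2 and arr.shape[1] == 2:
            pts = arr.astype(np.float64)
        elif arr.ndim == 2 and arr.dtype == bool:
            pts = np.column_stack(np.nonzero(arr)).astype(np.float64)
        else:
            raise ValueError("expected an (n, 2) point array or a boolean mask")
    if len(pts) < 2:
        raise ValueError("mean NND needs at least 2 points")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return float(dist[:, 1].mean())


def hotspot_volume(dm: DensityMap, threshold: float = DEFAULT_HOTSPOT_THRESHOLD) -> float:
    """Total pixel area (at the working downscale) of windows whose
    density strictly exceeds ``threshold``."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    hot = dm.grid > threshold
    return float(dm.cell_area[hot].sum())


def slice_metrics(
    slice_index: int,
    dm: DensityMap,
    fibers: FiberMask | None = None,
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    edges: np.ndarray | None = None,
    adjacency: str = "queen",
) -> SliceMetrics:
    """All four spatial metrics for one ring/slice level. NND is NaN when
    no fibre mask is supplied or fewer than 2 fibre pixels exist."""
    valid = dm.tissue_frac > 0 if dm.tissue_frac is not None else None
    nnd = float("nan")
    if fibers is not None and fibers.count >= 2:
        nnd = mean_nnd(fibers)
    return SliceMetrics(
        slice_index=slice_index,
        entropy=shannon_entropy(dm, edges),
        morans_i=morans_i(dm.grid, valid, adjacency),
        nnd_mean=nnd,
        hotspot_volume_px=hotspot_volume(dm, threshold),
    )


@dataclass
class ProfileTable:
    """Apex -> base innervation profile.

    slices : one row per slice (slice_index, entropy, morans_i, nnd_mean,
        hotspot_volume_px), ordered by slice_index.
    regions : per named region, mean and 95% t-CI for each metric; CI
        bounds are NaN for single-slice regions.
    """

    slices: pd.DataFrame
    regions: pd.DataFrame

    def to_csv(self, path: str) -> None:
        self.slices.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path: str) -> None:
        payload = {
            "slices": self.slices.to_dict(orient="records"),
            "regions": self.regions.to_dict(orient="records"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)


_METRICS = ("entropy", "morans_i", "nnd_mean", "hotspot_volume_px")


def innervation_profile(
    slices: list[tuple],
    region_spec: dict[str, tuple[int, int]] | None = None,
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    edges: np.ndarray | None = None,
    adjacency: str = "queen",
) -> ProfileTable:
    """Per-slice metrics plus per-region summaries.

    ``slices`` holds (slice_index, DensityMap) or (slice_index,
    DensityMap, FiberMask) tuples; ``region_spec`` maps region names to
    inclusive (lo, hi) slice-index ranges. Raises if a region references
    an absent slice.
    """
    if not slices:
        raise ValueError("need at least one slice")
    rows = []
    for entry in sorted(slices, key=lambda e: e[0]):
        idx, dm = entry[0], entry[1]
        fm = entry[2] if len(entry) > 2 else None
        m = slice_metrics(idx, dm, fm, threshold=threshold, edges=edges, adjacency=adjacency)
        rows.append(m.__dict__)
    df = pd.DataFrame(rows)
    present = set(df["slice_index"])

    region_rows = []
    for name, (lo, hi) in (region_spec or {}).items():
        wanted = set(range(lo, hi + 1))
        if not wanted <= present:
            raise ValueError(f"region {name!r} references absent slices {sorted(wanted - present)}")
        sub = df[df["slice_index"].between(lo, hi)]
        row: dict = {"region": name, "slice_lo": lo, "slice_hi": hi, "n_slices": len(sub)}
        for metric in _METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            mean = float(vals.mean()) if len(vals) else float("nan")
            if len(vals) >= 2:
                sem = vals.std(ddof=1) / np.sqrt(len(vals))
                tcrit = sstats.t.ppf(0.975, df=len(vals) - 1)
                lo_ci, hi_ci = mean - tcrit * sem, mean + tcrit * sem
            else:
                lo_ci = hi_ci = float("nan")
            row[f"{metric}_mean"] = mean
            row[f"{metric}_ci_lo"] = lo_ci
            row[f"{metric}_ci_hi"] = hi_ci
        region_rows.append(row)
    regions = pd.DataFrame(region_rows)
    return ProfileTable(slices=df, regions=regions)
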