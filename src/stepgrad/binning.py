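"""Binned summaries of ROI-level values in 2-D gradient space.

ROIs are placed at their (gradient 1, gradient 2) coordinates, min-max
scaled to [0, 1], and allocated to an n_bins x n_bins grid of equal-width
cells (default 15 per axis). A cell shows the mean of its member ROIs;
empty cells are missing (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BinnedGrid:
    """n_bins x n_bins cell values with ROI occupancy and optional mask."""

    values: np.ndarray  # (n_bins, n_bins), NaN where empty
    occupancy: np.ndarray  # (n_bins, n_bins) int counts
    n_bins: int
    mask: np.ndarray | None = None  # True where cell retained

    @property
    def n_placed(self) -> int:
        return int(self.occupancy.sum())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_bins):
            for j in range(self.n_bins):
                rows.append(
                    {
                        "bin_g1": i,
                        "bin_g2": j,
                        "value": self.values[i, j],
                        "occupancy": int(self.occupancy[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def assign_bins(scaled_coords: np.ndarray, n_bins: int = 15) -> np.ndarray:
    """Equal-width bin indices for coordinates in [0, 1].

    bin = floor(coordinate * n_bins); coordinate 1.0 falls in the last bin
    (the final bin is right-closed).
    """
    c = np.asarray(scaled_coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("scaled_coords must be n x 2")
    if c.min() < 0.0 or c.max() > 1.0:
        raise ValueError("coordinates must lie in [0, 1]; min-max scale first")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    idx = np.floor(c * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def grid_mean(values: np.ndarray, bins: np.ndarray, n_bins: int) -> BinnedGrid:
    """Mean of member ROI values per cell; empty cells are NaN."""
    v = np.asarray(values, dtype=float)
    b = np.asarray(bins, dtype=int)
    if v.shape[0] != b.shape[0]:
        raise ValueError("values and bin assignment differ in length")
    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(sums, (b[:, 0], b[:, 1]), v)
    np.add.at(counts, (b[:, 0], b[:, 1]), 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedGrid(values=means, occupancy=counts, n_bins=n_bins)


def grid_stat(
    tstats: np.ndarray,
    significant: np.ndarray,
    bins: np.ndarray,
    n_bins: int,
    retain: str = "any",
):
    """Mean t-statistic per cell, full and FWER-thresholded.

    The thresholded grid keeps only cells containing ROIs that survived
    family-wise error correction: with ``retain="any"`` (default, matching
    the reporting convention) a cell stays if at least one member ROI is
    significant; ``retain="all"`` is the strict variant.
    """
    if retain not in ("any", "all"):
        raise ValueError("retain must be 'any' or 'all'")
    sig = np.asarray(significant, dtype=bool)
    t = np.asarray(tstats, dtype=float)
    if sig.shape != t.shape:
        raise ValueError("tstats and significant differ in shape")
    full = grid_mean(t, bins, n_bins)
    b = np.asarray(bins, dtype=int)
    sig_count = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(sig_count, (b[:, 0], b[:, 1]), sig.astype(int))
    if retain == "any":
        mask = sig_count > 0
    else:
        mask = (sig_count == full.occupancy) & (full.occupancy > 0)
    thresholded = BinnedGrid(
        values=np.where(mask, full.values, np.nan),
        occupancy=full.occupancy,
        n_bins=n_bins,
        mask=mask,
    )
    return full, thresholded


def unsmoothed_records(
    values: np.ndarray, scaled_coords: np.ndarray, names=None
) -> pd.DataFrame:
    """Per-ROI scatter records (the n_bins = 0 'unsmoothed' mode)."""
    c = np.asarray(scaled_coords, dtype=float)
    v = np.asarray(values, dtype=float)
    df = pd.DataFrame({"g1": c[:, 0], "g2": c[:, 1], "value": v})
    if names is not None:
        df.insert(0, "name", list(names))
    return df


def bin_map(values, scaled_coords, n_bins: int = 15):
    """Convenience: bin a map, or emit scatter records when n_bins == 0."""
    if n_bins == 0:
        return unsmoothed_records(values, scaled_coords)
    return grid_mean(values, assign_bins(scaled_coords, n_bins), n_bins)


def grid_to_table(grid: BinnedGrid) -> pd.DataFrame:
    """Serialize a grid as long-format TSV-ready table; empty cells are NA."""
    return grid.to_dataframe()
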