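"""Convergence diagnostics for adaptive-bias (flat-histogram) sampling.

When an adaptive bias has converged, the negative bias approximates the
underlying free energy and the biased coordinate distribution should be
flat. Residual structure in the sampled histogram therefore measures the
free-energy error: dev_i = -RT ln(p_i / target_i). Two complementary
diagnostics are the imbalance of transitions between neighbouring bins
(equally probable in both directions at convergence) and, for
multi-walker runs, the number of walkers whose own distribution carries
appreciable density at each point of the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .units import RT_STANDARD_KJ_PER_MOL

logger = logging.getLogger(__name__)


@dataclass
class WalkerHistograms:
    """Per-walker visit counts on a shared grid.

    ``counts`` is (n_walkers, n_bins) for 1-D grids or
    (n_walkers, n1, n2) for 2-D; ``target`` is the intended sampling
    distribution on the same grid (uniform over the grid by default).
    """

    counts: np.ndarray
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim not in (2, 3):
            raise ValueError("counts must be (n_walkers, bins...) with 1-D or 2-D bins")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        grid_shape = self.counts.shape[1:]
        if self.target is None:
            self.target = np.full(grid_shape, 1.0 / np.prod(grid_shape))
        self.target = np.asarray(self.target, dtype=float)
        if self.target.shape != grid_shape:
            raise ValueError("target must match the grid shape")

    @property
    def n_walkers(self) -> int:
        return self.counts.shape[0]

    def total(self) -> np.ndarray:
        """Summed histogram over walkers."""
        return self.counts.sum(axis=0)


@dataclass
class ConvergenceReport:
    """Aggregated convergence diagnostics for one simulation."""

    deviation_kj_mol: np.ndarray
    equilibrated_min: bool
    equilibrated_mean: bool
    walker_overlap: np.ndarray | None = None
    imbalance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.where(np.isnan(a), None, a).tolist()

        return {
            "deviation_kj_mol": arr(self.deviation_kj_mol),
            "equilibrated_min": self.equilibrated_min,
            "equilibrated_mean": self.equilibrated_mean,
            "walker_overlap": arr(self.walker_overlap),
            "imbalance": arr(self.imbalance),
            "metadata": self.metadata,
        }


def flatness_deviation(
    histogram: np.ndarray,
    target: np.ndarray | None = None,
    *,
    rt: float = RT_STANDARD_KJ_PER_MOL,
) -> np.ndarray:
    """Per-bin free-energy deviation from the target distribution, kJ/mol.

    dev_i = -RT ln(p_i / target_i) with p the normalised histogram;
    positive where a bin is undersampled. Unvisited bins are NaN.
    """
    histogram = np.asarray(histogram, dtype=float)
    total = histogram.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    if target is None:
        target = np.full(histogram.shape, 1.0 / histogram.size)
    target = np.asarray(target, dtype=float)
    if target.shape != histogram.shape:
        raise ValueError("target shape must match histogram")
    if np.any(target <= 0):
        raise ValueError("target distribution must be strictly positive")
    target = target / target.sum()
    p = histogram / total
    dev = np.full(histogram.shape, np.nan)
    visited = histogram > 0
    dev[visited] = -rt * np.log(p[visited] / target[visited])
    return dev


def histogram_equilibrated(
    histogram: np.ndarray,
    target: np.ndarray | None = None,
    fraction: float = 0.8,
) -> tuple[bool, bool]:
    """Has the histogram reached the target distribution?

    Returns ``(strict, mean_based)``: the strict variant requires every
    visited bin's sampled share to reach ``fraction`` of its target
    share; the mean-based variant requires the mean ratio over visited
    bins to reach ``fraction``. Both are reported because the criterion
    "within 80% of the target distribution" admits either reading.
    """
    histogram = np.asarray(histogram, dtype=float)
    total = histogram.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    if target is None:
        target = np.full(histogram.shape, 1.0 / histogram.size)
    target = np.asarray(target, dtype=float) / np.asarray(target, dtype=float).sum()
    ratio = (histogram / total) / target
    visited = histogram > 0
    return bool(ratio[visited].min() >= fraction), bool(ratio[visited].mean() >= fraction)


def transition_imbalance(binned_series: np.ndarray, n_bins: int | None = None):
    """Directional imbalance of transitions between neighbouring bins.

    Parameters
    ----------
    binned_series : (n_frames,) int array or (n_frames, 2) for 2-D grids
        Bin index visited at each frame.
    n_bins : int or (int, int), optional
        Grid size; inferred from the series maximum when omitted.

    Returns
    -------
    counts : dict[(from_bin, to_bin) -> int]
        All observed frame-to-frame transitions (total = n_frames - 1).
    imbalance : dict[(bin_a, bin_b) -> float]
        For each 4-connected neighbouring pair with traffic,
        ``|n_ab - n_ba| / (n_ab + n_ba)`` in [0, 1]; symmetric keys with
        bin_a < bin_b.
    """
    series = np.asarray(binned_series)
    if series.ndim == 1:
        series = series[:, None]
    if series.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    keys = [tuple(int(x) for x in row) for row in series]
    counts: dict[tuple, int] = {}
    for a, b in zip(keys[:-1], keys[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    imbalance: dict[tuple, float] = {}
    seen = set()
    for (a, b) in counts:
        if a == b:
            continue
        if sum(abs(x - y) for x, y in zip(a, b)) != 1:
            continue  # not 4-connected neighbours (diagonal or long jump)
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        fwd = counts.get((key[0], key[1]), 0)
        bwd = counts.get((key[1], key[0]), 0)
        imbalance[key] = abs(fwd - bwd) / (fwd + bwd)
    return counts, imbalance


def walker_overlap(
    walkers: WalkerHistograms, threshold: float = 0.1
) -> np.ndarray:
    """Per-bin count of walkers carrying appreciable density.

    Each walker's histogram is normalised to a density; a walker counts
    at a bin when its density is strictly above ``threshold`` times the
    across-walker mean density there. Empty walkers are excluded with a
    warning. The result lies in [0, n_active_walkers] per bin.
    """
    if walkers.n_walkers < 2:
        raise ValueError("walker overlap requires at least 2 walkers")
    counts = walkers.counts.astype(float)
    totals = counts.reshape(walkers.n_walkers, -1).sum(axis=1)
    active = totals > 0
    if not active.all():
        logger.warning("excluding %d empty walker(s)", int((~active).sum()))
    counts = counts[active]
    totals = totals[active]
    density = counts / totals.reshape(-1, *([1] * (counts.ndim - 1)))
    mean_density = density.mean(axis=0)
    with np.errstate(invalid="ignore"):
        overlap = (density > threshold * mean_density).sum(axis=0)
    overlap[mean_density == 0] = 0
    return overlap


def convergence_report(
    walkers: WalkerHistograms,
    binned_series: np.ndarray | None = None,
    *,
    rt: float = RT_STANDARD_KJ_PER_MOL,
    equilibration_fraction: float = 0.8,
    overlap_threshold: float = 0.1,
) -> ConvergenceReport:
    """Full convergence report for a multi-walker run."""
    total = walkers.total()
    dev = flatness_deviation(total, walkers.target, rt=rt)
    eq_min, eq_mean = histogram_equilibrated(total, walkers.target, equilibration_fraction)
    overlap = walker_overlap(walkers, overlap_threshold) if walkers.n_walkers >= 2 else None
    imbalance = None
    if binned_series is not None:
        _, imbalance = transition_imbalance(binned_series)
    return ConvergenceReport(
        deviation_kj_mol=dev,
        equilibrated_min=eq_min,
        equilibrated_mean=eq_mean,
        walker_overlap=overlap,
        imbalance=None if imbalance is None else _imbalance_to_array(imbalance, total.shape),
        metadata={
            "rt": rt,
            "equilibration_fraction": equilibration_fraction,
            "overlap_threshold": overlap_threshold,
            "n_walkers": walkers.n_walkers,
        },
    )


def _imbalance_to_array(imbalance: dict, grid_shape: tuple) -> np.ndarray:
    """Max imbalance over the edges touching each bin (NaN where none)."""
    out = np.full(grid_shape, np.nan)
    for (a, b), v in imbalance.items():
        for node in (a, b):
            idx = node if len(grid_shape) > 1 else node[0]
            if np.isnan(out[idx]) or v > out[idx]:
                out[idx] = v
    return out
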