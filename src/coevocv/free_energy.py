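"""Free-energy surfaces from converged biased sampling.

The frame-wise estimate assigns each frame the free energy of the CV bin
it visits, U(bin) = -RT ln(n_bin / N), anchored so the lowest visited bin
sits at zero. Projection onto a new observable Y redistributes each
frame's share of its bin's Boltzmann mass — w_t = exp(-U_bin/RT)/n_bin —
into bins of Y and converts the accumulated mass back to an energy,
-RT ln(sum of member weights). Projecting onto the original CV with the
original binning therefore reproduces the input surface exactly, and the
total Boltzmann weight is conserved by construction.

Basins are watershed regions of local minima on the binned surface,
trimmed at concave shoulders (sign change of the discrete second
difference) and discarded when smaller than a minimum bin count.
Populations are Boltzmann weights of basin member bins. Functional state
labels (active vs resting) come from the mean RMSD of a basin's frames
to a reference structure after rigid-body superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .units import RT_STANDARD_KJ_PER_MOL

#: Default CV-space windows (nm) for the two refined collective variables.
DEFAULT_CV1_RANGE: tuple[float, float] = (0.4, 1.3)
DEFAULT_CV2_RANGE: tuple[float, float] = (0.3, 1.0)
DEFAULT_BINS_PER_AXIS: int = 50


def make_bins(low: float, high: float, n_bins: int = DEFAULT_BINS_PER_AXIS) -> np.ndarray:
    """Uniform bin edges over [low, high]."""
    if high <= low or n_bins < 1:
        raise ValueError("need high > low and n_bins >= 1")
    return np.linspace(low, high, n_bins + 1)


@dataclass
class FreeEnergySurface:
    """Binned free energies over a 1-D or 2-D collective-variable grid.

    ``energies`` is NaN on never-visited bins; ``mask`` is True on visited
    bins. Energies are anchored so the minimum over visited bins is 0.
    """

    edges: tuple[np.ndarray, ...]
    energies: np.ndarray
    counts: np.ndarray
    rt: float = RT_STANDARD_KJ_PER_MOL
    #: Detection-limit free energy (anchored scale): a never-visited bin
    #: is known to lie at or above this value. None when unknown.
    energy_cap: float | None = None

    def __post_init__(self) -> None:
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        if len(self.edges) not in (1, 2):
            raise ValueError("only 1-D and 2-D surfaces are supported")
        shape = tuple(e.size - 1 for e in self.edges)
        if self.energies.shape != shape or self.counts.shape != shape:
            raise ValueError("energies/counts shape must match the bin grid")

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def mask(self) -> np.ndarray:
        """True on visited bins."""
        return self.counts > 0

    def probabilities(self) -> np.ndarray:
        """Boltzmann probabilities over visited bins (sum to 1); 0 elsewhere."""
        p = np.zeros_like(self.energies, dtype=float)
        m = self.mask
        p[m] = np.exp(-self.energies[m] / self.rt)
        p /= p.sum()
        return p

    def bin_index(self, series: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, ...]:
        """Per-frame bin index along each axis."""
        series = _as_columns(series, self.ndim)
        idx = []
        for d, edges in enumerate(self.edges):
            x = series[:, d]
            out_of_range = (x < edges[0]) | (x > edges[-1])
            if out_of_range.any() and not clamp:
                raise ValueError(
                    f"{int(out_of_range.sum())} frames outside the bin range on axis {d}; "
                    "pass clamp=True to clip them to the edge bins"
                )
            i = np.searchsorted(edges, x, side="right") - 1
            idx.append(np.clip(i, 0, edges.size - 2))
        return tuple(idx)

    def frame_energies(self, series: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame (bin free energy, bin frame count) by lookup."""
        idx = self.bin_index(series, clamp=clamp)
        return self.energies[idx], self.counts[idx]


def _as_columns(series: np.ndarray, ndim: int) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if series.ndim != 2 or series.shape[1] != ndim:
        raise ValueError(f"series must be (n_frames, {ndim})")
    return series


def frame_free_energy(
    cv_series: np.ndarray,
    bin_edges: np.ndarray | tuple[np.ndarray, ...],
    *,
    rt: float = RT_STANDARD_KJ_PER_MOL,
    clamp: bool = False,
) -> FreeEnergySurface:
    """Histogram-based free-energy surface, U = -RT ln(count/total).

    ``cv_series`` is (n_frames,) for a 1-D surface or (n_frames, 2) for
    2-D; ``bin_edges`` one edge array per axis. Frames outside the bin
    range raise unless ``clamp`` clips them into the edge bins.
    """
    if isinstance(bin_edges, np.ndarray) or np.isscalar(bin_edges[0]):
        bin_edges = (np.asarray(bin_edges),)
    edges = tuple(np.asarray(e, dtype=float) for e in bin_edges)
    shape = tuple(e.size - 1 for e in edges)
    probe = FreeEnergySurface(
        edges=edges, energies=np.zeros(shape), counts=np.zeros(shape, dtype=int), rt=rt
    )
    series = _as_columns(cv_series, len(edges))
    if series.shape[0] < 1:
        raise ValueError("need at least one frame")
    idx = probe.bin_index(series, clamp=clamp)
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, idx, 1)
    energies = np.full(shape, np.nan)
    visited = counts > 0
    energies[visited] = -rt * np.log(counts[visited] / series.shape[0])
    anchor = energies[visited].min()
    energies[visited] -= anchor
    # an unvisited bin holds fewer than one frame
    cap = -rt * np.log(1.0 / series.shape[0]) - anchor
    return FreeEnergySurface(
        edges=edges, energies=energies, counts=counts, rt=rt, energy_cap=cap
    )


def project_fes(
    frame_energies: np.ndarray,
    observable_series: np.ndarray,
    bin_edges: np.ndarray | tuple[np.ndarray, ...],
    *,
    rt: float = RT_STANDARD_KJ_PER_MOL,
    source_bin_counts: np.ndarray | None = None,
    clamp: bool = False,
) -> FreeEnergySurface:
    """Project frame-wise free energies onto a new observable.

    Each frame contributes the Boltzmann weight exp(-U_t/RT), divided by
    ``source_bin_counts`` when given (the number of frames sharing the
    frame's source bin, i.e. the frame's share of its bin's mass — pass
    the counts returned by :meth:`FreeEnergySurface.frame_energies`).
    Per observable bin, the summed mass is converted back to an energy
    -RT ln(mass), masked where empty, and anchored to min 0.
    """
    frame_energies = np.asarray(frame_energies, dtype=float)
    weights = np.exp(-frame_energies / rt)
    if source_bin_counts is not None:
        weights = weights / np.asarray(source_bin_counts, dtype=float)
    if isinstance(bin_edges, np.ndarray) or np.isscalar(bin_edges[0]):
        bin_edges = (np.asarray(bin_edges),)
    edges = tuple(np.asarray(e, dtype=float) for e in bin_edges)
    shape = tuple(e.size - 1 for e in edges)
    probe = FreeEnergySurface(
        edges=edges, energies=np.zeros(shape), counts=np.zeros(shape, dtype=int), rt=rt
    )
    series = _as_columns(observable_series, len(edges))
    if series.shape[0] != weights.size:
        raise ValueError("frame energies and observable must align frame-wise")
    idx = probe.bin_index(series, clamp=clamp)
    mass = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    np.add.at(mass, idx, weights)
    np.add.at(counts, idx, 1)
    energies = np.full(shape, np.nan)
    visited = counts > 0
    energies[visited] = -rt * np.log(mass[visited] / mass[visited].sum())
    anchor = energies[visited].min()
    energies[visited] -= anchor
    # an unvisited bin holds less mass than the lightest single frame
    cap = -rt * np.log(weights.min() / mass[visited].sum()) - anchor
    return FreeEnergySurface(
        edges=edges, energies=energies, counts=counts, rt=rt, energy_cap=cap
    )


# ---------------------------------------------------------------------------
# basins


@dataclass
class Basin:
    """A metastable region of the surface."""

    basin_id: int
    minimum_bin: tuple[int, ...]
    member_bins: list[tuple[int, ...]]
    population: float | None = None
    state_label: str | None = None
    sub_label: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.member_bins)


@dataclass
class BasinSet:
    """Disjoint basins plus the per-bin label grid (-1 = unassigned)."""

    labels: np.ndarray
    basins: list[Basin] = field(default_factory=list)

    def __iter__(self):
        return iter(self.basins)

    def __len__(self) -> int:
        return len(self.basins)


def _neighbours(index: tuple[int, ...], shape: tuple[int, ...]):
    for axis in range(len(shape)):
        for step in (-1, 1):
            nb = list(index)
            nb[axis] += step
            if 0 <= nb[axis] < shape[axis]:
                yield tuple(nb)


def detect_basins(
    fes: FreeEnergySurface, min_bins: int = 3, trim_concave: bool = True
) -> BasinSet:
    """Partition visited bins into basins around local minima.

    Every visited bin descends to its lowest visited neighbour (ties
    broken towards the smaller flat index) until it reaches a fixpoint;
    bins sharing a fixpoint form one watershed basin. With
    ``trim_concave`` (default) bins whose discrete second difference is
    negative along every axis where it is defined — concave shoulders
    and barrier tops — are released from their basin, approximating an
    inflection-point border on the grid. Basins with fewer than
    ``min_bins`` member bins are discarded and their bins left
    unassigned. A surface without any strict minimum yields one basin
    covering all visited bins.
    """
    shape = fes.energies.shape
    mask = fes.mask
    visited = list(zip(*np.nonzero(mask)))
    labels = np.full(shape, -1, dtype=int)
    if not visited:
        return BasinSet(labels=labels, basins=[])

    flat = {idx: np.ravel_multi_index(idx, shape) for idx in visited}
    descend: dict[tuple[int, ...], tuple[int, ...]] = {}
    for idx in visited:
        best = idx
        for nb in _neighbours(idx, shape):
            if not mask[nb]:
                continue
            if (fes.energies[nb], flat[nb]) < (fes.energies[best], flat[best]):
                best = nb
        descend[idx] = best

    def root(idx):
        seen = []
        while descend[idx] != idx:
            seen.append(idx)
            idx = descend[idx]
        for s in seen:  # path compression
            descend[s] = idx
        return idx

    minima = sorted({root(idx) for idx in visited}, key=lambda i: flat[i])
    minimum_id = {m: k for k, m in enumerate(minima)}
    assignment: dict[tuple[int, ...], int] = {idx: minimum_id[root(idx)] for idx in visited}

    if trim_concave and len(minima) >= 1:
        for idx in visited:
            if idx in minimum_id:
                continue
            # Only border bins are candidates: trimming happens where a
            # basin meets the ridge (a different basin or unvisited
            # space). Interior bins keep their assignment even when
            # sampling noise makes their discrete curvature negative.
            on_border = any(
                (not mask[nb]) or root(nb) != root(idx)
                for nb in _neighbours(idx, shape)
            )
            if not on_border:
                continue
            curvatures = []
            for axis in range(len(shape)):
                lo = list(idx)
                hi = list(idx)
                lo[axis] -= 1
                hi[axis] += 1
                lo_t, hi_t = tuple(lo), tuple(hi)
                if (
                    0 <= lo[axis]
                    and hi[axis] < shape[axis]
                    and mask[lo_t]
                    and mask[hi_t]
                ):
                    curvatures.append(
                        fes.energies[lo_t] - 2 * fes.energies[idx] + fes.energies[hi_t]
                    )
            if curvatures and all(c < 0 for c in curvatures):
                assignment.pop(idx)

    members: dict[int, list[tuple[int, ...]]] = {}
    for idx, lab in assignment.items():
        members.setdefault(lab, []).append(idx)

    basins: list[Basin] = []
    for k, m in enumerate(minima):
        bins = sorted(members.get(minimum_id[m], []), key=lambda i: flat[i])
        if len(bins) < min_bins:
            continue
        basin = Basin(basin_id=len(basins), minimum_bin=m, member_bins=bins)
        basins.append(basin)
        for b in bins:
            labels[b] = basin.basin_id
    return BasinSet(labels=labels, basins=basins)


def basin_populations(fes: FreeEnergySurface, basins: BasinSet) -> np.ndarray:
    """Boltzmann population fraction of each basin.

    p_b = sum over b's bins of exp(-U/RT), normalised over all
    basin-assigned bins (unassigned bins carry no population). The
    fractions are also written onto the Basin objects.
    """
    masses = np.array(
        [
            sum(np.exp(-fes.energies[b] / fes.rt) for b in basin.member_bins)
            for basin in basins.basins
        ]
    )
    if masses.size == 0:
        return masses
    fractions = masses / masses.sum()
    for basin, p in zip(basins.basins, fractions):
        basin.population = float(p)
    return fractions


def assign_sub_labels(
    basins: BasinSet, fes: FreeEnergySurface, cv1_split: float | None = None,
    cv2_split: float | None = None,
) -> None:
    """Annotate 2-D basins by their quadrant in CV space.

    Upper-right is the resting-like corner (R), lower-left the primary
    active-like corner (A1), lower-right the secondary active corner
    (A2), upper-left intermediate (I). Split points default to the
    midpoint of each axis range.
    """
    if fes.ndim != 2:
        raise ValueError("sub-labels are defined on 2-D surfaces")
    c1 = cv1_split if cv1_split is not None else 0.5 * (fes.edges[0][0] + fes.edges[0][-1])
    c2 = cv2_split if cv2_split is not None else 0.5 * (fes.edges[1][0] + fes.edges[1][-1])
    centers1 = 0.5 * (fes.edges[0][:-1] + fes.edges[0][1:])
    centers2 = 0.5 * (fes.edges[1][:-1] + fes.edges[1][1:])
    for basin in basins:
        x = centers1[basin.minimum_bin[0]]
        y = centers2[basin.minimum_bin[1]]
        if x >= c1 and y >= c2:
            basin.sub_label = "R"
        elif x < c1 and y < c2:
            basin.sub_label = "A1"
        elif x >= c1 and y < c2:
            basin.sub_label = "A2"
        else:
            basin.sub_label = "I"


# ---------------------------------------------------------------------------
# functional-state classification


@dataclass
class StateClassification:
    """Active/resting call for one basin from RMSD to an active reference."""

    reference_id: str
    cutoff_angstrom: float
    per_frame_rmsd: np.ndarray
    mean_rmsd: float
    label: str

    @property
    def active(self) -> bool:
        return self.label == "active"


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix, translation, transformed mobile) minimising
    the RMSD between the point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    r = rot.as_matrix()
    moved = (mobile - cm) @ r.T + ct
    return r, ct - cm @ r.T, moved


def classify_basin_state(
    basin_frames: np.ndarray,
    reference: np.ndarray,
    *,
    align_indices: np.ndarray | None = None,
    rmsd_indices: np.ndarray | None = None,
    cutoff_angstrom: float = 3.0,
    reference_id: str = "",
) -> StateClassification:
    """Label a basin active or resting from RMSD to an active reference.

    Each frame (n_frames, n_atoms, 3, Angstrom) is superposed onto the
    reference on ``align_indices`` (default: all atoms, typically the
    shared C-alpha set), then the RMSD over ``rmsd_indices`` (default:
    all atoms; typically the TM6 helix selection) is computed. The basin
    is active iff the mean RMSD is strictly below the cutoff.
    """
    frames = np.asarray(basin_frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != reference.shape:
        raise ValueError("frames must be (n_frames, n_atoms, 3) matching the reference")
    n_atoms = reference.shape[0]
    align_indices = np.arange(n_atoms) if align_indices is None else np.asarray(align_indices)
    rmsd_indices = np.arange(n_atoms) if rmsd_indices is None else np.asarray(rmsd_indices)
    if align_indices.size == 0 or rmsd_indices.size == 0:
        raise ValueError("alignment and RMSD selections must be non-empty")
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    rmsds = np.empty(frames.shape[0])
    for t, frame in enumerate(frames):
        cm = frame[align_indices].mean(axis=0)
        ct = reference[align_indices].mean(axis=0)
        rot, _ = Rotation.align_vectors(reference[align_indices] - ct, frame[align_indices] - cm)
        moved = (frame - cm) @ rot.as_matrix().T + ct
        diff = moved[rmsd_indices] - reference[rmsd_indices]
        rmsds[t] = np.sqrt((diff**2).sum(axis=1).mean())
    mean = float(rmsds.mean())
    return StateClassification(
        reference_id=reference_id,
        cutoff_angstrom=cutoff_angstrom,
        per_frame_rmsd=rmsds,
        mean_rmsd=mean,
        label="active" if mean < cutoff_angstrom else "resting",
    )


# ---------------------------------------------------------------------------
# energetic coupling


def energetic_coupling(fes_1d: FreeEnergySurface) -> float:
    """Barrier-to-basin gap of a 1-D projection, in kJ/mol.

    With at least two local minima, returns the highest barrier
    separating any two of them minus the global minimum energy; a
    surface with fewer than two minima (monotonic, flat or single-well)
    couples nothing and returns 0. Never-visited bins between minima
    count as the surface's detection-limit energy (``energy_cap``) when
    known: an unsampled barrier is at least that high.
    """
    if fes_1d.ndim != 1:
        raise ValueError("energetic_coupling expects a 1-D surface")
    u = fes_1d.energies
    visited = np.flatnonzero(fes_1d.mask)
    if visited.size == 0:
        return 0.0
    # Strict local minima among visited bins (plateaus are not minima,
    # so a flat surface couples nothing).
    minima = []
    for k in visited:
        neighbour_vals = []
        if k - 1 >= 0 and fes_1d.mask[k - 1]:
            neighbour_vals.append(u[k - 1])
        if k + 1 < u.size and fes_1d.mask[k + 1]:
            neighbour_vals.append(u[k + 1])
        if neighbour_vals and all(u[k] < nv for nv in neighbour_vals):
            minima.append(k)
    if len(minima) < 2:
        return 0.0
    lo, hi = min(minima), max(minima)
    barrier = -np.inf
    for k in range(lo, hi + 1):
        if fes_1d.mask[k]:
            barrier = max(barrier, u[k])
        elif fes_1d.energy_cap is not None:
            barrier = max(barrier, fes_1d.energy_cap)
    global_min = min(u[k] for k in visited)
    return float(barrier - global_min)
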