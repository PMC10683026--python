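"""Ground-truth generators for every stage of the pipeline.

Each generator is a pure function of its seed and specification and
emits the same objects (and, via the I/O helpers, the same file formats)
the analysis modules consume: Gibbs-sampled alignments from a Potts
model with planted couplings, toy PDB structures realising a requested
contact pattern, Metropolis-sampled two-state distance trajectories with
analytically known Boltzmann populations, and multi-walker histograms
with controllable flatness defects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.special import softmax

from .cv_learning import DistanceTrajectory
from .error_analysis import WalkerHistograms
from .msa import Msa, Q
from .potts import PottsModel
from .units import RT_STANDARD_KJ_PER_MOL

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Potts ground truth and Gibbs sampling


def planted_potts_model(
    length: int,
    pairs: list[tuple[int, int]],
    *,
    strength: float = 1.0,
    q: int = Q,
    field_scale: float = 0.0,
    seed: int = 0,
) -> PottsModel:
    """A Potts model with identity-favouring couplings at chosen pairs.

    Each planted pair (i, j) receives w[i, j, a, a] = strength for the
    20 amino-acid states (the gap state stays uncoupled), so matching
    states at the two positions are exp(strength)-fold favoured. Fields
    are zero unless ``field_scale`` adds seeded normal noise.
    """
    if len(set(map(tuple, pairs))) != len(pairs):
        raise ValueError("planted pairs must be distinct")
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, field_scale, size=(length, q)) if field_scale else np.zeros((length, q))
    w = np.zeros((length, length, q, q))
    eye = np.eye(q)
    eye[q - 1, q - 1] = 0.0  # gap state uncoupled
    for i, j in pairs:
        if i == j or not (0 <= i < length and 0 <= j < length):
            raise ValueError(f"invalid planted pair {(i, j)}")
        w[i, j] += strength * eye
        w[j, i] += strength * eye
    return PottsModel(
        q=q, v=v, w=w, column_map=np.arange(length),
        training_log={"planted_pairs": sorted(tuple(sorted(p)) for p in pairs)},
    )


def gibbs_sample_msa(
    model: PottsModel,
    n_sequences: int,
    *,
    burn_in: int = 100,
    thin: int = 0,
    seed: int = 0,
) -> Msa:
    """Sample an MSA from a Potts model by single-site Gibbs sweeps.

    One independent chain per sequence is initialised uniformly at
    random and updated position-by-position for ``burn_in`` (+ ``thin``)
    full sweeps; the final states form the alignment. Deterministic for
    a given seed.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    L, q = model.length, model.q
    rng = np.random.default_rng(seed)
    states = rng.integers(0, q, size=(n_sequences, L))
    w2 = np.transpose(model.w, (1, 3, 0, 2)).reshape(L * q, L * q)
    # w2[(j,b),(i,a)] = w[i,j,a,b]: column block i gives position i's logits.
    x = np.zeros((n_sequences, L * q))
    rows = np.arange(n_sequences)
    for j in range(L):
        x[rows, j * q + states[:, j]] = 1.0
    for _ in range(burn_in + thin):
        for i in range(L):
            logits = x @ w2[:, i * q : (i + 1) * q] + model.v[i]
            probs = softmax(logits, axis=1)
            u = rng.random(n_sequences)
            new = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            x[rows, i * q + states[:, i]] = 0.0
            states[:, i] = new
            x[rows, i * q + new] = 1.0
    ids = [f"synth_{k}" for k in range(n_sequences)]
    return Msa(ids=ids, matrix=states.astype(np.int8))


# ---------------------------------------------------------------------------
# toy structures


@dataclass
class ToyStructureSpec:
    """A point-residue structure realising a contact pattern.

    Residues are free C-alpha sites (no chain-connectivity constraint);
    requested contacts sit at ``contact_distance_angstrom`` and all
    other pairs at least ``noncontact_min_angstrom`` apart.
    """

    n_residues: int
    contacts: list[tuple[int, int]] = field(default_factory=list)
    contact_distance_angstrom: float = 4.0
    noncontact_min_angstrom: float = 12.0
    sequence: str | None = None  # one-letter codes; all-ALA when omitted
    seed: int = 0


def _check_realizable(spec: ToyStructureSpec) -> None:
    # A chain of contacts bounds the distance of its endpoints; if that
    # bound undercuts the non-contact floor the pattern cannot embed.
    n = spec.n_residues
    inf = np.inf
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for i, j in spec.contacts:
        d[i, j] = d[j, i] = spec.contact_distance_angstrom
    for k in range(n):  # Floyd-Warshall on the contact graph
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    contact_set = {tuple(sorted(p)) for p in spec.contacts}
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in contact_set and d[i, j] < spec.noncontact_min_angstrom:
                raise ValueError(
                    f"pattern unrealizable: contact chain bounds d({i},{j}) by "
                    f"{d[i, j]:.1f} A < non-contact floor "
                    f"{spec.noncontact_min_angstrom:.1f} A"
                )


def make_toy_structure(spec: ToyStructureSpec, path: str | Path) -> np.ndarray:
    """Write a CA-only PDB realising the requested contact pattern.

    Coordinates are found by seeded penalty minimisation: contact pairs
    are pinned to the contact distance, every other pair is pushed
    beyond the non-contact floor. Returns the (n_residues, 3) coordinate
    array (Angstrom) that was written.
    """
    if spec.n_residues < 2:
        raise ValueError("need at least 2 residues")
    contact_set = {tuple(sorted(p)) for p in spec.contacts}
    for i, j in contact_set:
        if i == j or not (0 <= i < spec.n_residues and 0 <= j < spec.n_residues):
            raise ValueError(f"invalid contact {(i, j)}")
    _check_realizable(spec)
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    x0 = rng.normal(0.0, spec.noncontact_min_angstrom, size=(n, 3))
    iu, ju = np.triu_indices(n, k=1)
    is_contact = np.array([(i, j) in contact_set for i, j in zip(iu, ju)])
    floor = spec.noncontact_min_angstrom * 1.15  # margin over the floor

    def objective(flat: np.ndarray) -> float:
        coords = flat.reshape(n, 3)
        d = pdist(coords)
        err_c = d[is_contact] - spec.contact_distance_angstrom
        err_n = np.maximum(0.0, floor - d[~is_contact])
        return float((err_c**2).sum() + (err_n**2).sum())

    best = None
    for attempt in range(5):
        res = minimize(objective, x0.ravel(), method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-8:
            break
        x0 = rng.normal(0.0, spec.noncontact_min_angstrom, size=(n, 3))
    coords = best.x.reshape(n, 3)
    d = squareform(pdist(coords))
    for i, j in zip(iu, ju):
        if (i, j) in contact_set:
            ok = abs(d[i, j] - spec.contact_distance_angstrom) < 0.5
        else:
            ok = d[i, j] > spec.noncontact_min_angstrom
        if not ok:
            raise ValueError(
                f"could not realise the pattern: d({i},{j}) = {d[i, j]:.2f} A"
            )
    _write_ca_pdb(coords, path, sequence=spec.sequence)
    return coords


def _write_ca_pdb(coords: np.ndarray, path: str | Path, sequence: str | None = None) -> None:
    from Bio.Data.IUPACData import protein_letters_1to3

    if sequence is not None and len(sequence) != len(coords):
        raise ValueError("sequence length must match residue count")
    lines = []
    for k, (x, y, z) in enumerate(coords, start=1):
        res3 = (
            protein_letters_1to3[sequence[k - 1].upper()].upper()
            if sequence
            else "ALA"
        )
        lines.append(
            f"ATOM  {k:5d}  CA  {res3} A{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C  "
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# two-state trajectories


@dataclass
class TwoStateSpec:
    """A tilted double well on one latent coordinate, mapped to distances.

    U(x) = barrier * (x^2 - 1)^2 + delta_u * [x > 0]  (kJ/mol): two
    congruent wells at x = +/-1 separated by ``barrier``, the x > 0 well
    offset by exactly ``delta_u``, so the Boltzmann odds of the wells
    are exactly exp(delta_u / RT) (the step sits at the barrier top,
    where sampling is negligible anyway). Informative pair distances
    follow the latent coordinate
    affinely (base + slope * x plus bounded uniform noise); noise pairs
    fluctuate around their base independently of x. All distances are
    clipped at zero.
    """

    barrier_kj_mol: float = 10.0
    delta_u_kj_mol: float = 0.0
    rt: float = RT_STANDARD_KJ_PER_MOL
    n_informative: int = 2
    n_noise: int = 50
    base_nm: float = 0.85
    slope_nm: float = 0.25
    noise_nm: float = 0.03
    step: float = 0.35
    #: Fraction of proposals that are reflections x -> -x (+ local noise).
    #: The mixture proposal is symmetric, so detailed balance holds, while
    #: reflections land near the mirror well and decorrelate the chain
    #: across the barrier within a few steps.
    jump_fraction: float = 0.2
    burn_in: int = 1000


@dataclass
class TwoStateTrajectory:
    """Synthetic trajectory plus its exact ground truth."""

    trajectory: DistanceTrajectory
    latent: np.ndarray
    state_labels: np.ndarray  # True where x > 0 (upper well)
    true_populations: tuple[float, float]  # (x < 0, x > 0)
    informative_pairs: list[tuple[int, int]]
    spec: TwoStateSpec


def latent_potential(x: np.ndarray, spec: TwoStateSpec) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return spec.barrier_kj_mol * (x**2 - 1.0) ** 2 + spec.delta_u_kj_mol * (x > 0)


def boltzmann_populations(spec: TwoStateSpec) -> tuple[float, float]:
    """Exact (quadrature) Boltzmann weight of the x<0 and x>0 half-lines."""

    def weight(x):
        return np.exp(-latent_potential(x, spec) / spec.rt)

    left, _ = quad(weight, -6.0, 0.0, limit=200)
    right, _ = quad(weight, 0.0, 6.0, limit=200)
    z = left + right
    return left / z, right / z


def sample_two_state_trajectory(
    spec: TwoStateSpec, n_frames: int, *, seed: int = 0
) -> TwoStateTrajectory:
    """Metropolis-sample the latent double well and emit pair distances.

    The first ``spec.n_informative`` pairs track the latent coordinate
    (these are the planted discriminative contacts); the remaining
    ``spec.n_noise`` pairs are uninformative. Pair ids are consecutive
    integers (2k, 2k+1) so every pair touches distinct residues.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    x = -1.0 if spec.delta_u_kj_mol >= 0 else 1.0
    u_x = float(latent_potential(x, spec))
    total = spec.burn_in + n_frames
    reflect = rng.random(total) < spec.jump_fraction
    steps = rng.normal(0.0, spec.step, size=total)
    accept_u = rng.random(total)
    latent = np.empty(n_frames)
    accepted = 0
    for t in range(total):
        prop = (-x if reflect[t] else x) + steps[t]
        u_prop = float(latent_potential(prop, spec))
        if accept_u[t] < np.exp(-(u_prop - u_x) / spec.rt):
            x, u_x = prop, u_prop
            accepted += 1
        if t >= spec.burn_in:
            latent[t - spec.burn_in] = x
    rate = accepted / total
    if not 0.05 < rate < 0.95:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.2f} outside (0.05, 0.95); "
            f"adjust spec.step (currently {spec.step})",
            stacklevel=2,
        )

    n_pairs = spec.n_informative + spec.n_noise
    pairs = [(2 * k, 2 * k + 1) for k in range(n_pairs)]
    distances = np.empty((n_frames, n_pairs))
    for k in range(spec.n_informative):
        noise = rng.uniform(0.0, spec.noise_nm, size=n_frames)
        distances[:, k] = spec.base_nm + spec.slope_nm * latent + noise
    for k in range(spec.n_informative, n_pairs):
        base = spec.base_nm * rng.uniform(0.8, 1.2)
        distances[:, k] = base + rng.uniform(-spec.noise_nm, spec.noise_nm, size=n_frames)
    np.clip(distances, 0.0, None, out=distances)
    return TwoStateTrajectory(
        trajectory=DistanceTrajectory(
            times=np.arange(n_frames, dtype=float),
            pairs=pairs,
            distances=distances,
            label="two-state",
        ),
        latent=latent,
        state_labels=latent > 0,
        true_populations=boltzmann_populations(spec),
        informative_pairs=pairs[: spec.n_informative],
        spec=spec,
    )


# ---------------------------------------------------------------------------
# walker histograms


@dataclass
class WalkerHistogramSpec:
    """Multi-walker histograms with controllable flatness defects.

    ``half_density_bins`` receive half their flat share, the deficit
    redistributed evenly over the remaining bins so the planted bin's
    sampled-to-target ratio is exactly 1/2; ``dead_walker_bins`` zeroes
    chosen bins of one walker. Counts stay exact integers when
    ``base_counts * len(half_density_bins) / (2 * (n_bins - len))`` is
    integral (generators round otherwise, with a warning).
    """

    n_walkers: int = 4
    n_bins: int = 10
    base_counts: int = 900
    half_density_bins: tuple[int, ...] = ()
    dead_walker: int | None = None
    dead_walker_bins: tuple[int, ...] = ()


def make_walker_histograms(spec: WalkerHistogramSpec) -> WalkerHistograms:
    """Deterministic per-walker histograms for convergence diagnostics."""
    if spec.n_walkers < 2:
        raise ValueError("need at least 2 walkers")
    per_bin = np.full(spec.n_bins, float(spec.base_counts))
    half = list(spec.half_density_bins)
    if half:
        removed = 0.5 * spec.base_counts * len(half)
        per_bin[half] = 0.5 * spec.base_counts
        others = [b for b in range(spec.n_bins) if b not in half]
        per_bin[others] += removed / len(others)
    rounded = np.rint(per_bin)
    if not np.allclose(rounded, per_bin):
        warnings.warn("non-integral planted counts were rounded", stacklevel=2)
    counts = np.tile(rounded.astype(np.int64), (spec.n_walkers, 1))
    if spec.dead_walker is not None:
        counts[spec.dead_walker, list(spec.dead_walker_bins)] = 0
    return WalkerHistograms(counts=counts)
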