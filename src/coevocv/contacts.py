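"""Structural contact maps and coevolutionary false-positive detection.

High coevolution scores at residue pairs that are far apart in the
reference structure ("false positives" from the contact-prediction point
of view) are the central signal exploited here: such pairs are candidate
contacts of an alternative, unobserved conformational state. This module
computes minimum heavy-atom distance maps from a PDB structure, aligns
MSA columns to structure residues, extracts the non-contacting
high-score pairs, clusters them by coevolution strength (cluster count
by mean shift, assignment by K-means) and turns each cluster into one
pull coordinate: a weighted mean of the intracluster pair distances with
a per-contact force constant and a common target distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, MeanShift, estimate_bandwidth

from .potts import CoevolutionMap
from .units import angstrom_to_nm

logger = logging.getLogger(__name__)

#: Minimum heavy-atom distance defining a structural contact (Angstrom).
DEFAULT_CONTACT_CUTOFF_A: float = 5.5
#: Pairs closer in sequence than this are never counted as contacts.
DEFAULT_MIN_SEQ_SEPARATION: int = 5


@dataclass
class ContactMap:
    """Minimum inter-residue heavy-atom distances of one structure.

    ``residues`` carries (chain id, author residue number, one-letter
    code) in structure order; ``distances`` is the symmetric L x L
    matrix in Angstrom with NaN where a residue lacked heavy atoms.
    """

    residues: list[tuple[str, int, str]]
    distances: np.ndarray
    cutoff_angstrom: float = DEFAULT_CONTACT_CUTOFF_A
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        L = len(self.residues)
        if self.distances.shape != (L, L):
            raise ValueError("distance matrix must be L x L")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(code for _, _, code in self.residues)

    def is_contact(self, i: int, j: int) -> bool:
        """Contact iff distance <= cutoff and |i - j| >= min separation.

        Pairs with unknown distance (missing atoms) are never contacts.
        """
        if abs(i - j) < self.min_seq_separation:
            return False
        d = self.distances[i, j]
        return bool(np.isfinite(d) and d <= self.cutoff_angstrom)

    def contact_matrix(self) -> np.ndarray:
        L = self.n_residues
        out = np.zeros((L, L), dtype=bool)
        for i in range(L):
            for j in range(i + 1, L):
                out[i, j] = out[j, i] = self.is_contact(i, j)
        return out


def _heavy_atom_coords(residue) -> np.ndarray:
    coords = [a.coord for a in residue.get_atoms() if a.element != "H"]
    return np.array(coords, dtype=float)


def contact_map(
    structure_path: str | Path,
    *,
    chain: str | None = None,
    cutoff_angstrom: float = DEFAULT_CONTACT_CUTOFF_A,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION,
) -> ContactMap:
    """Build the minimum heavy-atom distance map of a PDB structure.

    Only the first model is used; for multi-chain files ``chain`` must
    select one chain. Residues without any heavy atom get NaN rows and
    are excluded from contacts.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(structure_path)).get_models())
    chains = list(model.get_chains())
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"chain {chain!r} not found")
    elif len(chains) > 1:
        raise ValueError(
            f"structure has chains {[c.id for c in chains]}; select one explicitly"
        )
    residues = [r for r in chains[0].get_residues() if is_aa(r, standard=False)]
    if len(residues) < 2:
        raise ValueError("structure must contain at least 2 amino-acid residues")
    ids: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []
    for r in residues:
        code = protein_letters_3to1.get(r.get_resname().upper().strip(), "X")
        ids.append((chains[0].id, int(r.id[1]), code))
        coords.append(_heavy_atom_coords(r))
    L = len(ids)
    distances = np.full((L, L), np.nan)
    np.fill_diagonal(distances, 0.0)
    for i in range(L):
        if coords[i].size == 0:
            logger.warning("residue %s has no heavy atoms; pair distances unknown", ids[i])
            continue
        for j in range(i + 1, L):
            if coords[j].size == 0:
                continue
            d = cdist(coords[i], coords[j]).min()
            distances[i, j] = distances[j, i] = d
    return ContactMap(
        residues=ids,
        distances=distances,
        cutoff_angstrom=cutoff_angstrom,
        min_seq_separation=min_seq_separation,
    )


def map_alignment_to_structure(
    msa, query_id: str, cmap: ContactMap, *, min_identity: float = 0.9
) -> dict[int, int]:
    """Map retained MSA columns to structure residue indices.

    The ungapped query sequence is pairwise-aligned (global, BLOSUM62)
    to the structure's one-letter sequence; each query position carries
    its MSA column, giving an injective retained-column -> structure
    residue-index map. Columns falling in structure gaps are omitted.
    Raises if the identity over the aligned span falls below
    ``min_identity``.
    """
    try:
        qi = msa.ids.index(query_id)
    except ValueError:
        raise ValueError(f"query {query_id!r} not present in the MSA") from None
    row = msa.matrix[qi]
    from .msa import ALPHABET, GAP_STATE

    query_cols = [c for c in range(msa.alignment_length) if row[c] != GAP_STATE]
    query_seq = "".join(ALPHABET[row[c]] for c in query_cols)
    struct_seq = cmap.sequence

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(query_seq, struct_seq)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_len = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for offset in range(qe - qs):
            qpos, spos = qs + offset, ss + offset
            aligned_len += 1
            if query_seq[qpos] == struct_seq[spos]:
                matches += 1
            mapping[query_cols[qpos]] = spos
    if aligned_len == 0 or matches / aligned_len < min_identity:
        raise ValueError(
            f"query/structure identity {matches}/{aligned_len} below the "
            f"{min_identity:.0%} floor; wrong query or structure?"
        )
    return mapping


@dataclass
class FalsePositivePairs:
    """High-coevolution pairs with no structural contact.

    ``pairs`` holds (residue_index_i, residue_index_j, apc_score,
    distance_angstrom) in structure indexing, sorted by descending
    score; ``clusters`` (after clustering) maps cluster id -> list of
    row indices into ``pairs``.
    """

    pairs: list[tuple[int, int, float, float]]
    selection: dict = field(default_factory=dict)
    clusters: dict[int, list[int]] | None = None

    def __post_init__(self) -> None:
        scores = [p[2] for p in self.pairs]
        if any(a < b for a, b in zip(scores[:-1], scores[1:])):
            raise ValueError("pairs must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.pairs)

    def scores(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])


def detect_false_positives(
    coevo: CoevolutionMap,
    cmap: ContactMap,
    column_to_residue: dict[int, int],
    *,
    top_n_pairs: int | None = None,
) -> FalsePositivePairs:
    """Coevolving pairs absent from the structural contact map.

    Among the ``top_n_pairs`` highest APC scores (default 2L, L the
    number of retained columns), keep those whose mapped residues are
    not in contact, sorted by descending score. Pairs whose columns lack
    a structure mapping, whose sequence separation falls below the
    contact map's minimum, or whose distance is unknown are skipped.
    """
    L = coevo.scores.shape[0]
    if top_n_pairs is None:
        top_n_pairs = 2 * L
    out: list[tuple[int, int, float, float]] = []
    for ci, cj, score in coevo.top_pairs(top_n_pairs):
        ri = column_to_residue.get(int(coevo.column_map[ci]))
        rj = column_to_residue.get(int(coevo.column_map[cj]))
        if ri is None or rj is None:
            continue
        if abs(ri - rj) < cmap.min_seq_separation:
            continue
        d = cmap.distances[ri, rj]
        if not np.isfinite(d):
            continue
        if not cmap.is_contact(ri, rj):
            out.append((min(ri, rj), max(ri, rj), score, float(d)))
    if not out:
        warnings.warn("no false-positive pairs found among the top scores", stacklevel=2)
    return FalsePositivePairs(
        pairs=out,
        selection={
            "top_n_pairs": top_n_pairs,
            "cutoff_angstrom": cmap.cutoff_angstrom,
            "min_seq_separation": cmap.min_seq_separation,
        },
    )


def cluster_false_positives(
    fps: FalsePositivePairs, *, seed: int = 0, n_clusters: int | None = None
) -> FalsePositivePairs:
    """Cluster the pairs by coevolution strength.

    The cluster count is chosen by mean shift on the 1-D score
    distribution (unless ``n_clusters`` overrides it) and the assignment
    is made by K-means with that k; both are deterministic given the
    seed. When fewer pairs than clusters exist, k is reduced with a
    warning.
    """
    if len(fps) == 0:
        raise ValueError("no pairs to cluster")
    scores = fps.scores().reshape(-1, 1)
    if n_clusters is None:
        if np.allclose(scores, scores[0]):
            n_clusters = 1
        else:
            bandwidth = estimate_bandwidth(scores, random_state=seed)
            if not bandwidth or bandwidth <= 0:
                bandwidth = None
            ms = MeanShift(bandwidth=bandwidth)
            ms.fit(scores)
            n_clusters = len(np.unique(ms.labels_))
    if n_clusters > len(fps):
        warnings.warn(
            f"requested {n_clusters} clusters for {len(fps)} pairs; reducing",
            stacklevel=2,
        )
        n_clusters = len(fps)
    if n_clusters == 1:
        labels = np.zeros(len(fps), dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        labels = km.fit_predict(scores)
    # Relabel clusters by descending mean score for stable identities.
    means = {lab: scores[labels == lab].mean() for lab in np.unique(labels)}
    order = sorted(means, key=lambda lab: -means[lab])
    remap = {old: new for new, old in enumerate(order)}
    clusters: dict[int, list[int]] = {remap[lab]: [] for lab in order}
    for row, lab in enumerate(labels):
        clusters[remap[lab]].append(row)
    return FalsePositivePairs(
        pairs=list(fps.pairs),
        selection={**fps.selection, "n_clusters": n_clusters, "seed": seed},
        clusters=clusters,
    )


@dataclass
class PullCoordinate:
    """One steering coordinate: a weighted mean of pair distances (nm)."""

    pairs: list[tuple[int, int]]
    weights: np.ndarray
    force_constant_kj_mol_nm2: float
    target_nm: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.pairs),):
            raise ValueError("one weight per pair required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    def value(self, pair_distances_nm: dict[tuple[int, int], float]) -> float:
        return float(
            sum(w * pair_distances_nm[p] for p, w in zip(self.pairs, self.weights))
        )


@dataclass
class PullCoordinateSet:
    """One pull coordinate per false-positive cluster."""

    coordinates: list[PullCoordinate]

    def __len__(self) -> int:
        return len(self.coordinates)


#: Per-contact umbrella force constant used when steering (kJ mol^-1 nm^-2).
DEFAULT_PULL_FORCE_CONSTANT: float = 200.0
#: Target value of each pull coordinate (nm).
DEFAULT_PULL_TARGET_NM: float = 0.2


def build_pull_coordinates(
    fps: FalsePositivePairs,
    *,
    force_constant: float = DEFAULT_PULL_FORCE_CONSTANT,
    target_nm: float = DEFAULT_PULL_TARGET_NM,
    score_weighted: bool = True,
) -> PullCoordinateSet:
    """One pull coordinate per cluster of false-positive pairs.

    Each coordinate is the weighted mean of the intracluster pair
    distances, weights proportional to the APC scores (renormalised per
    cluster; duplicate listings of a pair are merged so renormalisation
    makes the coordinate invariant to duplication). With
    ``score_weighted=False`` the plain intracluster mean is used.
    """
    if fps.clusters is None:
        raise ValueError("pairs must be clustered first")
    if force_constant <= 0 or target_nm <= 0:
        raise ValueError("force constant and target must be positive")
    coordinates = []
    for cluster_id in sorted(fps.clusters):
        rows = fps.clusters[cluster_id]
        merged: dict[tuple[int, int], float] = {}
        for r in rows:
            i, j, score, _ = fps.pairs[r]
            key = (i, j)
            weight = score if score_weighted else 1.0
            merged[key] = max(merged.get(key, 0.0), weight)
        pairs = sorted(merged)
        w = np.array([merged[p] for p in pairs], dtype=float)
        coordinates.append(
            PullCoordinate(
                pairs=pairs,
                weights=w / w.sum(),
                force_constant_kj_mol_nm2=force_constant,
                target_nm=target_nm,
            )
        )
    return PullCoordinateSet(coordinates=coordinates)


def pair_distances_nm(cmap: ContactMap) -> dict[tuple[int, int], float]:
    """All finite pair distances of a contact map, converted to nm."""
    out = {}
    L = cmap.n_residues
    for i in range(L):
        for j in range(i + 1, L):
            d = cmap.distances[i, j]
            if np.isfinite(d):
                out[(i, j)] = angstrom_to_nm(d)
    return out
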