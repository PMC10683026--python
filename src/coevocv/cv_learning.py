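"""Learning refined collective variables from two conformational ensembles.

Given per-frame minimum inter-residue distances for a set of coevolving
pairs (both "false positives", expected to form contacts in an alternative
state, and true positives, expected to break), a linear max-margin
classifier is trained to separate a reference ensemble from an explored
ensemble. A steep maximum-margin separator approximates the direction of
the highest intrinsic energy barrier, so the top-ranked coefficients
identify the distances that change most decisively between states. The
classifier's top pairs are split by coefficient sign into two collective
variables, each a positively weighted sum of distances, which guarantees
a monotonic response to increasing distances.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


@dataclass
class DistanceTrajectory:
    """Per-frame minimum inter-residue distances for a list of pairs.

    Attributes
    ----------
    times : (n_frames,) array
        Frame times (arbitrary units; frame index when unknown).
    pairs : list of (i, j)
        Residue identifier pairs, i < j, no duplicates.
    distances : (n_frames, n_pairs) array
        Minimum heavy-atom distances in nm.
    label : str
        Free-form source label (e.g. "reference", "explored").
    """

    times: np.ndarray
    pairs: list[Pair]
    distances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.pairs = [tuple(int(x) for x in p) for p in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in DistanceTrajectory")
        if self.distances.shape != (self.times.size, len(self.pairs)):
            raise ValueError("distances must be (n_frames, n_pairs)")
        if self.distances.size and (
            not np.all(np.isfinite(self.distances)) or self.distances.min() < 0
        ):
            raise ValueError("distances must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def column(self, pair: Pair) -> np.ndarray:
        return self.distances[:, self.pairs.index(tuple(pair))]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV (time + one column per pair, header ``d_i_j``)."""
        header = "time\t" + "\t".join(f"d_{i}_{j}" for i, j in self.pairs)
        np.savetxt(
            path,
            np.column_stack([self.times, self.distances]),
            delimiter="\t",
            header=header,
            comments="",
        )

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "DistanceTrajectory":
        with open(path) as handle:
            header = handle.readline().strip().split("\t")
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        pairs = []
        for name in header[1:]:
            _, i, j = name.split("_")
            pairs.append((int(i), int(j)))
        return cls(times=data[:, 0], pairs=pairs, distances=data[:, 1:], label=label)


def distance_features(
    coordinates: np.ndarray,
    atom_residues: np.ndarray,
    pairs: list[Pair],
    *,
    times: np.ndarray | None = None,
    label: str = "",
) -> DistanceTrajectory:
    """Minimum inter-residue heavy-atom distance per frame and pair.

    Parameters
    ----------
    coordinates : (n_frames, n_atoms, 3) array, nm
        Heavy-atom coordinates per frame.
    atom_residues : (n_atoms,) int array
        Residue identifier of each atom.
    pairs : list of (res_i, res_j)
        Residue pairs to track.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim != 3 or coordinates.shape[2] != 3:
        raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
    atom_residues = np.asarray(atom_residues)
    if not pairs:
        raise ValueError("empty pair list")
    atom_index: dict[int, np.ndarray] = {}
    for res in np.unique(atom_residues):
        atom_index[int(res)] = np.flatnonzero(atom_residues == res)
    missing = [p for p in pairs if int(p[0]) not in atom_index or int(p[1]) not in atom_index]
    if missing:
        raise ValueError(f"pairs reference residues absent from the topology: {missing}")
    n_frames = coordinates.shape[0]
    out = np.empty((n_frames, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        ai, aj = atom_index[int(i)], atom_index[int(j)]
        for t in range(n_frames):
            out[t, k] = cdist(coordinates[t, ai], coordinates[t, aj]).min()
    if times is None:
        times = np.arange(n_frames, dtype=float)
    return DistanceTrajectory(times=times, pairs=list(pairs), distances=out, label=label)


@dataclass
class LinearStateModel:
    """Linear max-margin separator between two ensembles.

    Coefficients live in standardised feature space; the fitted scaler
    (per-pair mean and standard deviation) is stored so the model can be
    applied to raw nm distances. Ranking is by decreasing ``|coefficient|``
    with (i, j)-lexicographic tie-breaking.
    """

    pairs: list[Pair]
    coefficients: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.pairs),):
            raise ValueError("one coefficient per pair required")

    def ranked_pairs(self) -> list[int]:
        """Indices of pairs sorted by |coefficient| desc, then pair id."""
        order = sorted(
            range(len(self.pairs)),
            key=lambda k: (-abs(self.coefficients[k]), self.pairs[k]),
        )
        return order

    def decision_function(self, distances: np.ndarray) -> np.ndarray:
        z = (np.asarray(distances) - self.scaler_mean) / self.scaler_scale
        return z @ self.coefficients + self.intercept


def train_state_classifier(
    ensemble_a: DistanceTrajectory,
    ensemble_b: DistanceTrajectory,
    *,
    regularization: float = 1.0,
    seed: int = 0,
) -> LinearStateModel:
    """Train a linear-kernel SVM separating ensemble A (label 0) from B (1).

    Features are z-scored before the fit; class imbalance between the
    ensembles is compensated with inverse-frequency class weights. The
    fit is deterministic for a given seed.
    """
    if ensemble_a.pairs != ensemble_b.pairs:
        raise ValueError("ensembles must share an identical pair list")
    if ensemble_a.n_frames < 2 or ensemble_b.n_frames < 2:
        raise ValueError("each ensemble needs at least 2 frames")
    x = np.vstack([ensemble_a.distances, ensemble_b.distances])
    y = np.concatenate([np.zeros(ensemble_a.n_frames), np.ones(ensemble_b.n_frames)])
    scaler = StandardScaler()
    z = scaler.fit_transform(x)
    svm = SVC(
        kernel="linear",
        C=regularization,
        class_weight="balanced",
        random_state=seed,
        tol=1e-7,  # tight enough that label-swap antisymmetry holds ~1e-6
    )
    svm.fit(z, y)
    coef = svm.coef_.ravel().copy()
    accuracy = float((svm.predict(z) == y).mean())
    return LinearStateModel(
        pairs=list(ensemble_a.pairs),
        coefficients=coef,
        intercept=float(svm.intercept_[0]),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        metadata={
            "regularization": regularization,
            "seed": seed,
            "n_frames": (ensemble_a.n_frames, ensemble_b.n_frames),
            "training_accuracy": accuracy,
            "labels": (ensemble_a.label, ensemble_b.label),
        },
    )


@dataclass
class CollectiveVariable:
    """A positively weighted sum of pair distances (weights sum to 1)."""

    pairs: list[Pair]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.pairs),):
            raise ValueError("one weight per pair required")
        if len(self.pairs) and (self.weights <= 0).any():
            raise ValueError("CV weights must be strictly positive")

    @property
    def empty(self) -> bool:
        return not self.pairs


@dataclass
class CollectiveVariablePair:
    """Two complementary CVs from the positive / negative coefficients.

    ``cv1`` collects the pairs whose distance grows towards the second
    ensemble (positive coefficients); ``cv2`` the shrinking ones
    (negative coefficients, weights taken as |coefficient|). Pair sets
    are disjoint by construction.
    """

    cv1: CollectiveVariable
    cv2: CollectiveVariable
    normalization: str = "sum_to_one"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "normalization": self.normalization,
            "cv1": {"pairs": self.cv1.pairs, "weights": self.cv1.weights.tolist()},
            "cv2": {"pairs": self.cv2.pairs, "weights": self.cv2.weights.tolist()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CollectiveVariablePair":
        payload = json.loads(Path(path).read_text())
        return cls(
            cv1=CollectiveVariable(
                pairs=[tuple(p) for p in payload["cv1"]["pairs"]],
                weights=np.array(payload["cv1"]["weights"]),
            ),
            cv2=CollectiveVariable(
                pairs=[tuple(p) for p in payload["cv2"]["pairs"]],
                weights=np.array(payload["cv2"]["weights"]),
            ),
            normalization=payload["normalization"],
        )


def make_cv_pair(model: LinearStateModel, top_k: int = 20) -> CollectiveVariablePair:
    """Build the two CVs from the classifier's ``top_k`` pairs by |coefficient|.

    Weights are |coefficient| renormalised to sum to one within each CV.
    If every selected coefficient shares one sign, the other CV is empty
    (single-CV mode) and a warning is emitted.
    """
    if not 1 <= top_k <= len(model.pairs):
        raise ValueError(f"top_k must lie in [1, {len(model.pairs)}]")
    chosen = model.ranked_pairs()[:top_k]
    pos = [k for k in chosen if model.coefficients[k] > 0]
    neg = [k for k in chosen if model.coefficients[k] < 0]

    def build(indices: list[int]) -> CollectiveVariable:
        if not indices:
            return CollectiveVariable(pairs=[], weights=np.empty(0))
        w = np.abs(model.coefficients[indices])
        return CollectiveVariable(
            pairs=[model.pairs[k] for k in indices], weights=w / w.sum()
        )

    cv1, cv2 = build(pos), build(neg)
    if cv1.empty or cv2.empty:
        warnings.warn(
            "all selected coefficients share one sign; returning a single CV",
            stacklevel=2,
        )
    return CollectiveVariablePair(cv1=cv1, cv2=cv2)


def evaluate_cv(trajectory: DistanceTrajectory, cv: CollectiveVariable) -> np.ndarray:
    """Per-frame CV value: the weighted sum of the constituent distances (nm).

    Monotone non-decreasing in every input distance since weights are
    positive.
    """
    if cv.empty:
        raise ValueError("cannot evaluate an empty CV")
    missing = [p for p in cv.pairs if tuple(p) not in trajectory.pairs]
    if missing:
        raise ValueError(f"trajectory lacks CV pairs: {missing}")
    cols = [trajectory.pairs.index(tuple(p)) for p in cv.pairs]
    return trajectory.distances[:, cols] @ cv.weights
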