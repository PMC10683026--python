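"""Flat-file serialisation of analysis products.

Everything is plain text: tab-separated tables for matrices and series,
JSON for structured manifests. Column indices in coevolution outputs are
1-based original-MSA columns; residue identifiers are carried verbatim.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import FalsePositivePairs
from .error_analysis import WalkerHistograms
from .free_energy import FreeEnergySurface
from .network import CouplingNetwork, PathwayReport
from .potts import CoevolutionMap


def write_coevolution_tsv(
    raw: CoevolutionMap, corrected: CoevolutionMap, path: str | Path
) -> None:
    """Pair list with raw and APC scores, 1-based original MSA columns."""
    if raw.scores.shape != corrected.scores.shape:
        raise ValueError("raw and corrected maps must share a shape")
    L = raw.scores.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    frame = pd.DataFrame(
        {
            "i": raw.column_map[iu] + 1,
            "j": raw.column_map[ju] + 1,
            "raw_score": raw.scores[iu, ju],
            "apc_score": corrected.scores[iu, ju],
        }
    ).sort_values("apc_score", ascending=False)
    frame.to_csv(path, sep="\t", index=False)


def write_score_matrix(coevo: CoevolutionMap, path: str | Path) -> None:
    np.savetxt(path, coevo.scores, delimiter="\t")


def write_false_positives_tsv(fps: FalsePositivePairs, path: str | Path) -> None:
    rows = []
    cluster_of = {}
    if fps.clusters is not None:
        for cid, members in fps.clusters.items():
            for m in members:
                cluster_of[m] = cid
    for row, (i, j, score, dist) in enumerate(fps.pairs):
        rows.append(
            {
                "residue_i": i,
                "residue_j": j,
                "apc_score": score,
                "distance_angstrom": dist,
                "cluster": cluster_of.get(row, -1),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fes(fes: FreeEnergySurface, path: str | Path) -> None:
    """Bin centers, free energy (kJ/mol) and counts as TSV + JSON sidecar."""
    path = Path(path)
    centers = [0.5 * (e[:-1] + e[1:]) for e in fes.edges]
    if fes.ndim == 1:
        frame = pd.DataFrame(
            {"center_1": centers[0], "free_energy_kj_mol": fes.energies, "count": fes.counts}
        )
    else:
        g1, g2 = np.meshgrid(centers[0], centers[1], indexing="ij")
        frame = pd.DataFrame(
            {
                "center_1": g1.ravel(),
                "center_2": g2.ravel(),
                "free_energy_kj_mol": fes.energies.ravel(),
                "count": fes.counts.ravel(),
            }
        )
    frame.to_csv(path, sep="\t", index=False)
    meta = {
        "rt_kj_mol": fes.rt,
        "edges": [e.tolist() for e in fes.edges],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_fes(path: str | Path) -> FreeEnergySurface:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    edges = tuple(np.array(e) for e in meta["edges"])
    shape = tuple(e.size - 1 for e in edges)
    frame = pd.read_csv(path, sep="\t")
    return FreeEnergySurface(
        edges=edges,
        energies=frame["free_energy_kj_mol"].to_numpy().reshape(shape),
        counts=frame["count"].to_numpy().reshape(shape),
        rt=meta["rt_kj_mol"],
    )


def write_network_tsv(network: CouplingNetwork, path: str | Path) -> None:
    rows = [
        {"res_i": u, "res_j": v, "coupling_kj_mol": d["coupling"], "cost": d["cost"]}
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pathway_json(report: PathwayReport, path: str | Path) -> None:
    payload = {
        "source": report.source,
        "cost_transform": report.cost_transform,
        "paths": {
            str(sink): None if p is None else {"path": list(p[0]), "cost": p[1]}
            for sink, p in report.paths.items()
        },
        "betweenness": {str(k): v for k, v in report.betweenness.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_walker_histograms(walkers: WalkerHistograms, path: str | Path) -> None:
    """One row per walker, 1-D grids only (2-D grids are flattened)."""
    counts = walkers.counts.reshape(walkers.n_walkers, -1)
    np.savetxt(path, counts, delimiter="\t", fmt="%d")


def read_walker_histograms(path: str | Path) -> WalkerHistograms:
    counts = np.loadtxt(path, delimiter="\t", dtype=np.int64, ndmin=2)
    return WalkerHistograms(counts=counts)
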