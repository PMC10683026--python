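import numpy as np
import pytest

from coevocv.contacts import (
    ContactMap,
    FalsePositivePairs,
    build_pull_coordinates,
    cluster_false_positives,
    contact_map,
    detect_false_positives,
    map_alignment_to_structure,
)
from coevocv.msa import encode_sequences
from coevocv.potts import CoevolutionMap
from coevocv.synthetic import ToyStructureSpec, make_toy_structure

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       4.000   0.500   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       5.400   0.500   0.300  1.00  0.00           C
ATOM      6  N   SER A   3       9.000   4.000   1.000  1.00  0.00           N
ATOM      7  CA  SER A   3      10.300   4.600   1.200  1.00  0.00           C
ATOM      8  OG  SER A   3      11.000   5.900   1.500  1.00  0.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


class TestContactMap:
    def test_distances_match_brute_force(self, three_residue_pdb):
        cmap = contact_map(three_residue_pdb, min_seq_separation=1)
        coords = {
            0: np.array([[0, 0, 0], [1.5, 0, 0], [2.0, 1.4, 0]]),
            1: np.array([[4.0, 0.5, 0], [5.4, 0.5, 0.3]]),
            2: np.array([[9.0, 4.0, 1.0], [10.3, 4.6, 1.2], [11.0, 5.9, 1.5]]),
        }
        for i in range(3):
            for j in range(3):
                expected = min(
                    np.linalg.norm(a - b) for a in coords[i] for b in coords[j]
                )
                assert cmap.distances[i, j] == pytest.approx(expected, abs=1e-3)

    def test_contact_under_cutoff(self, three_residue_pdb):
        cmap = contact_map(three_residue_pdb, cutoff_angstrom=5.5, min_seq_separation=1)
        assert cmap.is_contact(0, 1)  # min distance ~2.06 A
        assert not cmap.is_contact(0, 2)

    def test_sequence_separation_excludes_neighbours(self, three_residue_pdb):
        cmap = contact_map(three_residue_pdb, cutoff_angstrom=5.5, min_seq_separation=4)
        assert not cmap.is_contact(0, 1)

    def test_sequence_extraction(self, three_residue_pdb):
        assert contact_map(three_residue_pdb).sequence == "AGS"

    def test_too_few_residues(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(THREE_RESIDUE_PDB.split("ATOM      4")[0] + "END\n")
        with pytest.raises(ValueError):
            contact_map(p)


class TestMapAlignmentToStructure:
    def _structure(self, tmp_path, sequence, seed=0):
        spec = ToyStructureSpec(n_residues=len(sequence), sequence=sequence, seed=seed)
        path = tmp_path / "s.pdb"
        make_toy_structure(spec, path)
        return contact_map(path)

    def test_identity_map(self, tmp_path):
        seq = "ACDEFGHIKL"
        cmap = self._structure(tmp_path, seq)
        msa = encode_sequences(["query", "other"], [seq, "ACDEFGHIKW"])
        mapping = map_alignment_to_structure(msa, "query", cmap)
        assert mapping == {c: c for c in range(len(seq))}

    def test_truncated_n_terminus_shifts_map(self, tmp_path):
        seq = "ACDEFGHIKLMNPQ"
        cmap = self._structure(tmp_path, seq[5:])
        msa = encode_sequences(["query"], [seq])
        mapping = map_alignment_to_structure(msa, "query", cmap)
        assert all(c not in mapping for c in range(5))
        assert mapping == {c: c - 5 for c in range(5, len(seq))}

    def test_gapped_query_columns_carry_original_indices(self, tmp_path):
        cmap = self._structure(tmp_path, "ACDEF")
        msa = encode_sequences(["query", "o"], ["AC-DEF", "ACWDEF"])
        mapping = map_alignment_to_structure(msa, "query", cmap)
        assert mapping == {0: 0, 1: 1, 3: 2, 4: 3, 5: 4}

    def test_query_absent_raises(self, tmp_path):
        cmap = self._structure(tmp_path, "ACDEF")
        msa = encode_sequences(["a"], ["ACDEF"])
        with pytest.raises(ValueError, match="not present"):
            map_alignment_to_structure(msa, "nope", cmap)

    def test_low_identity_raises(self, tmp_path):
        cmap = self._structure(tmp_path, "ACDEFGHIKL")
        msa = encode_sequences(["query"], ["WWYYWWYYWW"])
        with pytest.raises(ValueError):
            map_alignment_to_structure(msa, "query", cmap)


def _toy_overlay(tmp_path, n=8, contacts=((0, 5),), seed=0):
    spec = ToyStructureSpec(n_residues=n, contacts=list(contacts), seed=seed)
    path = tmp_path / "toy.pdb"
    make_toy_structure(spec, path)
    cmap = contact_map(path, min_seq_separation=2)
    return cmap


class TestDetectFalsePositives:
    def test_planted_expectations(self, tmp_path):
        cmap = _toy_overlay(tmp_path, contacts=[(0, 5)])
        scores = np.zeros((8, 8))
        scores[0, 5] = scores[5, 0] = 0.9  # high score, in contact -> excluded
        scores[1, 6] = scores[6, 1] = 0.8  # high score, far apart -> included
        scores[2, 7] = scores[7, 2] = 0.7
        coevo = CoevolutionMap(scores=scores, column_map=np.arange(8),
                               apc_applied=True, reduction="frobenius")
        fps = detect_false_positives(coevo, cmap, {c: c for c in range(8)},
                                     top_n_pairs=3)
        found = {(p[0], p[1]) for p in fps.pairs}
        assert found == {(1, 6), (2, 7)}
        assert fps.pairs[0][2] == pytest.approx(0.8)

    def test_no_intersection_with_contacts(self, tmp_path):
        rng = np.random.default_rng(0)
        cmap = _toy_overlay(tmp_path, contacts=[(0, 4), (1, 6), (2, 5)], seed=1)
        s = rng.uniform(0, 1, (8, 8))
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 0)
        coevo = CoevolutionMap(scores=s, column_map=np.arange(8),
                               apc_applied=True, reduction="frobenius")
        fps = detect_false_positives(coevo, cmap, {c: c for c in range(8)})
        for i, j, _, _ in fps.pairs:
            assert not cmap.is_contact(i, j)

    def test_empty_result_warns(self, tmp_path):
        cmap = _toy_overlay(tmp_path, contacts=[(0, 5)])
        scores = np.zeros((8, 8))
        scores[0, 5] = scores[5, 0] = 1.0
        coevo = CoevolutionMap(scores=scores, column_map=np.arange(8),
                               apc_applied=True, reduction="frobenius")
        with pytest.warns(UserWarning):
            fps = detect_false_positives(coevo, cmap, {c: c for c in range(8)},
                                         top_n_pairs=1)
        assert len(fps) == 0


def _fps(scores):
    ordered = sorted(enumerate(scores), key=lambda kv: -kv[1])
    return FalsePositivePairs(
        pairs=[(2 * k, 2 * k + 1, s, 15.0) for k, s in ordered]
    )


class TestClusterFalsePositives:
    def test_three_separated_modes(self):
        scores = [0.1] * 5 + [0.5] * 5 + [0.9] * 5
        out = cluster_false_positives(_fps(scores), seed=0)
        assert out.selection["n_clusters"] == 3
        by_cluster = {
            cid: sorted(out.pairs[r][2] for r in rows)
            for cid, rows in out.clusters.items()
        }
        assert by_cluster[0] == [0.9] * 5  # clusters ordered by mean score
        assert by_cluster[1] == [0.5] * 5
        assert by_cluster[2] == [0.1] * 5

    def test_identical_scores_single_cluster(self):
        out = cluster_false_positives(_fps([0.4] * 6), seed=0)
        assert out.selection["n_clusters"] == 1

    def test_deterministic_given_seed(self):
        scores = list(np.random.default_rng(0).uniform(0, 1, 12))
        a = cluster_false_positives(_fps(scores), seed=5)
        b = cluster_false_positives(_fps(scores), seed=5)
        assert a.clusters == b.clusters

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(1)
        scores = list(rng.uniform(0, 1, 10))
        a = cluster_false_positives(_fps(scores), seed=0, n_clusters=3)
        b = cluster_false_positives(_fps(list(reversed(scores))), seed=0, n_clusters=3)

        def partition(fps):
            return {
                frozenset(fps.pairs[r][2] for r in rows)
                for rows in fps.clusters.values()
            }

        assert partition(a) == partition(b)

    def test_fewer_pairs_than_clusters(self):
        with pytest.warns(UserWarning, match="reducing"):
            out = cluster_false_positives(_fps([0.2, 0.8]), seed=0, n_clusters=5)
        assert out.selection["n_clusters"] == 2


class TestBuildPullCoordinates:
    def _clustered(self, pair_scores):
        fps = _fps([s for _, s in pair_scores])
        fps.clusters = {0: list(range(len(pair_scores)))}
        return fps

    def test_single_pair_coordinate_equals_distance(self):
        fps = self._clustered([((0, 1), 0.5)])
        pull = build_pull_coordinates(fps)
        coord = pull.coordinates[0]
        assert coord.value({coord.pairs[0]: 0.73}) == pytest.approx(0.73)

    def test_equal_scores_give_plain_mean(self):
        fps = self._clustered([((0, 1), 0.5), ((2, 3), 0.5)])
        pull = build_pull_coordinates(fps)
        coord = pull.coordinates[0]
        d = dict(zip(coord.pairs, [0.4, 0.8]))
        assert coord.value(d) == pytest.approx(0.6)

    def test_weights_sum_to_one(self):
        fps = self._clustered([((0, 1), 0.9), ((2, 3), 0.3), ((4, 5), 0.1)])
        pull = build_pull_coordinates(fps)
        assert pull.coordinates[0].weights.sum() == pytest.approx(1.0)

    def test_duplicate_pair_listing_invariant(self):
        base = FalsePositivePairs(
            pairs=[(0, 1, 0.8, 15.0), (2, 3, 0.4, 15.0)],
            clusters={0: [0, 1]},
        )
        dup = FalsePositivePairs(
            pairs=[(0, 1, 0.8, 15.0), (0, 1, 0.8, 15.0), (2, 3, 0.4, 15.0)],
            clusters={0: [0, 1, 2]},
        )
        d = {(0, 1): 0.5, (2, 3): 1.1}
        v1 = build_pull_coordinates(base).coordinates[0].value(d)
        v2 = build_pull_coordinates(dup).coordinates[0].value(d)
        assert v1 == pytest.approx(v2)

    def test_uniform_weight_mode(self):
        fps = self._clustered([((0, 1), 0.9), ((2, 3), 0.1)])
        pull = build_pull_coordinates(fps, score_weighted=False)
        coord = pull.coordinates[0]
        d = dict(zip(coord.pairs, [0.4, 0.8]))
        assert coord.value(d) == pytest.approx(0.6)

    def test_invalid_parameters(self):
        fps = self._clustered([((0, 1), 0.5)])
        with pytest.raises(ValueError):
            build_pull_coordinates(fps, force_constant=-1)
        with pytest.raises(ValueError):
            build_pull_coordinates(fps, target_nm=0.0)
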