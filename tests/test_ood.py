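"""Similarity computation, clustering, OOD split assembly, pruning."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdFingerprintGenerator

from plignet import (
    assemble_ood_split,
    complex_distance,
    prune_training_by_similarity,
    sequence_identity,
    single_linkage_cluster,
    tanimoto_similarity,
)
from plignet.complex_io import AtomRecord, ProteinStructure
from plignet.ood import distance_matrix
from plignet.synthetic import SyntheticSpec, generate_complex

from _oracles import canon_labels, threshold_components


def _mol(smiles):
    mol = Chem.MolFromSmiles(smiles)
    AllChem.Compute2DCoords(mol)
    return mol


def _protein(*seqs):
    atoms = [(AtomRecord("C", (0.0, 0.0, 0.0), 4, 1, 3, False, False),
              ("C", 4, 1, 3, False, False))]
    return ProteinStructure(atoms=atoms, chains=list(seqs))


class TestTanimoto:
    def test_identical_ligands(self):
        lig = generate_complex(SyntheticSpec(seed=1), 0).ligand
        assert tanimoto_similarity(lig, lig) == pytest.approx(1.0)

    def test_disjoint_fingerprints(self):
        assert tanimoto_similarity(_mol("CCCCC"), _mol("FP(F)F")) == 0.0

    def test_methane_vs_ethane_set_arithmetic_oracle(self):
        m1, m2 = _mol("C"), _mol("CC")
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        a = set(gen.GetFingerprint(m1).GetOnBits())
        b = set(gen.GetFingerprint(m2).GetOnBits())
        expected = len(a & b) / len(a | b)
        assert tanimoto_similarity(m1, m2) == pytest.approx(expected, abs=1e-12)


class TestSequenceIdentity:
    def test_identical_single_chain(self):
        p = _protein("ACDEFGHIKLMNPQRSTVWY")
        assert sequence_identity(p, p) == pytest.approx(100.0)

    def test_unrelated_chains_low_identity(self):
        p1 = _protein("AAAAAAAAAA")
        p2 = _protein("WWWWWWWWWW")
        assert sequence_identity(p1, p2) == pytest.approx(0.0, abs=1e-9)

    def test_multichain_takes_maximum_over_chain_pairs(self):
        p1 = _protein("AAAAAAAAAA", "ACDEFGHIKL")
        p2 = _protein("ACDEFGHIKL")
        # exhaustive chain-pair loop oracle
        from plignet.ood import _pairwise_identity

        expected = max(
            _pairwise_identity(a, b)
            for a in p1.chains for b in p2.chains
        )
        assert sequence_identity(p1, p2) == pytest.approx(expected)
        assert sequence_identity(p1, p2) == pytest.approx(100.0)

    def test_pluggable_provider(self):
        p1, p2 = _protein("AAAA"), _protein("AAAA")
        assert sequence_identity(p1, p2, provider=lambda a, b: 42.0) == 42.0


class TestComplexDistance:
    def test_maximal_similarity_gives_zero(self):
        assert complex_distance(1.0, 0.0) == 0.0
        assert complex_distance(0.0, 100.0) == 0.0

    def test_no_similarity_gives_one(self):
        assert complex_distance(0.0, 0.0) == 1.0

    def test_hand_substitution(self):
        assert complex_distance(0.7, 40.0) == pytest.approx(0.3)

    def test_self_distance_zero_in_matrix_form(self):
        rng = np.random.default_rng(0)
        ts = rng.uniform(0, 1, size=(5, 5))
        ts = (ts + ts.T) / 2
        np.fill_diagonal(ts, 1.0)
        s = rng.uniform(0, 100, size=(5, 5))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 100.0)
        d = distance_matrix(ts, s)
        assert np.all(np.diag(d) == 0.0)
        assert np.all((d >= 0) & (d <= 1))


class TestSingleLinkage:
    def test_all_far_apart_gives_singletons(self):
        d = np.ones((4, 4)) - np.eye(4)
        labels = single_linkage_cluster(d, threshold=0.5)
        assert len(set(labels.tolist())) == 4

    def test_chain_merges_transitively(self):
        d = np.array([
            [0.0, 0.3, 0.9],
            [0.3, 0.0, 0.3],
            [0.9, 0.3, 0.0],
        ])
        labels = single_linkage_cluster(d, threshold=0.5)
        assert len(set(labels.tolist())) == 1

    def test_boundary_is_strict(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        labels = single_linkage_cluster(d, threshold=0.5)
        assert labels[0] != labels[1]  # d == threshold does not merge

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_connected_components_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 1, size=(20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = canon_labels(single_linkage_cluster(d, 0.5))
        ref = canon_labels(threshold_components(d, 0.5))
        np.testing.assert_array_equal(ours, ref)

    def test_lowering_threshold_only_refines(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 1, size=(15, 15))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        coarse = single_linkage_cluster(d, 0.6)
        fine = single_linkage_cluster(d, 0.3)
        # every fine cluster sits inside one coarse cluster
        for lab in set(fine.tolist()):
            members = np.nonzero(fine == lab)[0]
            assert len(set(coarse[members].tolist())) == 1


def _toy_split_inputs():
    """Six complexes, hand-set similarities -> hand-derived assignment.

    Clusters (threshold 0.5): {0,1} via Ts=0.8; {2}; {3,4} via seq 80%;
    {5}.  Candidate test clusters {2} and {3,4}: the latter contains a
    1200 Da ligand and is excluded whole (reason MW); {2} survives all
    filters, and the remaining complexes are dissimilar to it, so they all
    train.
    """
    ids = [f"c{k}" for k in range(6)]
    ts = np.eye(6)
    ts[0, 1] = ts[1, 0] = 0.8
    s = np.zeros((6, 6))
    np.fill_diagonal(s, 100.0)
    s[3, 4] = s[4, 3] = 80.0
    props = {i: (300.0, 5) for i in ids}
    props["c3"] = (1200.0, 5)  # heavy ligand
    pocket = {"c0": "fam1", "c1": "fam1", "c2": "fam2", "c3": "fam3",
              "c4": "fam3", "c5": "fam4"}
    return ids, ts, s, props, pocket


class TestAssembleSplit:
    def test_hand_derived_toy_assignment(self):
        ids, ts, s, props, pocket = _toy_split_inputs()
        d = distance_matrix(ts, s)
        labels = single_linkage_cluster(d, 0.5)
        # clusters: {0,1}, {2}, {3,4}, {5}
        assert labels[0] == labels[1] and labels[3] == labels[4]
        result = assemble_ood_split(
            ids, labels, ts, s, props, pocket_labels=pocket,
            test_clusters=[labels[2], labels[3]],
        )
        assert result.test_ids == ["c2"]
        reasons = dict(result.excluded)
        assert reasons["c3"] == "MW" and reasons["c4"] == "MW"
        assert set(result.train_ids) == {"c0", "c1", "c5"}

    def test_similar_extension_complex_excluded_from_training(self):
        """A complex clustered elsewhere (e.g. an extension pool entry) but
        ligand-similar to a test complex is excluded with reason similarity."""
        ids, ts, s, props, pocket = _toy_split_inputs()
        ts = ts.copy()
        ts[2, 5] = ts[5, 2] = 0.6  # c5 similar to test ligand c2
        # hand labels: c5 kept as its own cluster (external extension pool)
        labels = np.array([0, 0, 1, 2, 2, 3])
        result = assemble_ood_split(
            ids, labels, ts, s, props, pocket_labels=pocket,
            test_clusters=[1],
        )
        assert result.test_ids == ["c2"]
        assert ("c5", "similarity") in result.excluded
        assert "c5" not in result.train_ids

    def test_heavy_ligand_excludes_whole_cluster(self):
        ids, ts, s, props, pocket = _toy_split_inputs()
        labels = single_linkage_cluster(distance_matrix(ts, s), 0.5)
        result = assemble_ood_split(
            ids, labels, ts, s, props, pocket_labels=pocket,
            test_clusters=[labels[3]],
        )
        assert "c3" not in result.test_ids and "c4" not in result.test_ids

    def test_pocket_overlap_drops_test_cluster(self):
        ids, ts, s, props, pocket = _toy_split_inputs()
        # give c2's family to a training complex -> test cluster dropped
        pocket = dict(pocket)
        pocket["c0"] = "fam2"
        labels = single_linkage_cluster(distance_matrix(ts, s), 0.5)
        result = assemble_ood_split(
            ids, labels, ts, s, props, pocket_labels=pocket,
            test_clusters=[labels[2]],
        )
        assert result.test_ids == []
        assert ("c2", "pocket") in result.excluded

    def test_missing_pocket_labels_warns(self):
        ids, ts, s, props, _ = _toy_split_inputs()
        labels = single_linkage_cluster(distance_matrix(ts, s), 0.5)
        with pytest.warns(UserWarning, match="SKIPPED"):
            assemble_ood_split(ids, labels, ts, s, props,
                               test_clusters=[labels[2]])

    def test_partition_covers_every_id_once(self):
        ids, ts, s, props, pocket = _toy_split_inputs()
        labels = single_linkage_cluster(distance_matrix(ts, s), 0.5)
        result = assemble_ood_split(
            ids, labels, ts, s, props, pocket_labels=pocket,
            test_clusters=[labels[2], labels[3]],
        )
        seen = (set(result.test_ids) | set(result.train_ids)
                | {cid for cid, _ in result.excluded})
        assert seen == set(ids)

    def test_no_similar_train_test_pair_post_hoc(self):
        ids, ts, s, props, pocket = _toy_split_inputs()
        labels = single_linkage_cluster(distance_matrix(ts, s), 0.5)
        result = assemble_ood_split(
            ids, labels, ts, s, props, pocket_labels=pocket,
            test_clusters=[labels[2]],
        )
        idx = {cid: k for k, cid in enumerate(ids)}
        for a in result.train_ids:
            for b in result.test_ids:
                assert ts[idx[a], idx[b]] < 0.5
                assert s[idx[a], idx[b]] < 50.0


class TestPruning:
    def _tanimoto_table(self):
        table = {
            ("t1", "q1"): 1.0, ("t1", "q2"): 0.2,
            ("t2", "q1"): 0.65, ("t2", "q2"): 0.3,
            ("t3", "q1"): 0.85, ("t3", "q2"): 0.95,
            ("t4", "q1"): 0.1, ("t4", "q2"): 0.05,
        }
        return lambda a, b: table[(a, b)]

    def test_identical_ligand_removed_at_0_9(self):
        kept, removed = prune_training_by_similarity(
            ["t1", "t4"], ["q1", "q2"], self._tanimoto_table(), 0.9
        )
        assert kept == ["t4"]
        assert removed[0][0] == "t1"

    def test_threshold_one_keeps_everything(self):
        kept, removed = prune_training_by_similarity(
            ["t1", "t2", "t3", "t4"], ["q1", "q2"], self._tanimoto_table(), 1.0
        )
        assert kept == ["t1", "t2", "t3", "t4"] and removed == []

    def test_nested_across_decreasing_thresholds(self):
        train = ["t1", "t2", "t3", "t4"]
        fn = self._tanimoto_table()
        kept_sets = [
            set(prune_training_by_similarity(train, ["q1", "q2"], fn, t)[0])
            for t in (0.9, 0.8, 0.7, 0.6)
        ]
        for bigger, smaller in zip(kept_sets, kept_sets[1:]):
            assert smaller <= bigger
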