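"""Partitioning: held-out, stratified halves, GED pairing, leader clustering."""

import numpy as np
import pytest

from fmx.chemio import FingerprintSpec, LabeledDataset, MoleculeRecord, fingerprint_many, tanimoto
from fmx.splits import (
    PURINE_CORE_SMARTS,
    assign_pairs_to_splits,
    build_cluster_dataset,
    graph_edit_distance,
    holdout_split,
    make_split_plan,
    pair_by_ged,
    stratified_split,
    substructure_filter,
)


def rec(smiles):
    return MoleculeRecord.from_smiles(smiles)


class TestHoldout:
    def test_stratified_counts(self, alkane_ether_dataset):
        heldout, remainder = holdout_split(alkane_ether_dataset, 0.10, seed=0)
        assert len(heldout) == 10 and heldout.n_active == 1
        assert len(remainder) == 90 and remainder.n_active == 9

    def test_partition_and_determinism(self, alkane_ether_dataset):
        h1, r1 = holdout_split(alkane_ether_dataset, 0.10, seed=4)
        h2, r2 = holdout_split(alkane_ether_dataset, 0.10, seed=4)
        assert h1.smiles == h2.smiles and r1.smiles == r2.smiles
        assert sorted(h1.smiles + r1.smiles) == sorted(alkane_ether_dataset.smiles)
        assert not set(h1.smiles) & set(r1.smiles)

    def test_different_seed_differs(self, alkane_ether_dataset):
        h1, _ = holdout_split(alkane_ether_dataset, 0.10, seed=0)
        h2, _ = holdout_split(alkane_ether_dataset, 0.10, seed=1)
        assert h1.smiles != h2.smiles

    def test_bad_fraction(self, alkane_ether_dataset):
        with pytest.raises(ValueError):
            holdout_split(alkane_ether_dataset, 1.5, seed=0)


class TestStratifiedSplit:
    def test_even_counts(self, alkane_ether_dataset):
        s1, s2 = stratified_split(alkane_ether_dataset, seed=0)
        assert s1.n_active == s2.n_active == 5
        assert abs(len(s1) - len(s2)) == 0

    def test_odd_counts_within_one(self):
        smiles = ["OC" + "C" * n for n in range(1, 10)] + ["C" * n for n in range(1, 91)]
        data = LabeledDataset([rec(s) for s in smiles], [1] * 9 + [0] * 90)
        s1, s2 = stratified_split(data, seed=3)
        assert sorted((s1.n_active, s2.n_active)) == [4, 5]
        assert abs((len(s1) - s1.n_active) - (len(s2) - s2.n_active)) <= 1

    def test_partition(self, alkane_ether_dataset):
        s1, s2 = stratified_split(alkane_ether_dataset, seed=9)
        assert sorted(s1.smiles + s2.smiles) == sorted(alkane_ether_dataset.smiles)

    def test_stratification_invariant(self, alkane_ether_dataset):
        s1, s2 = stratified_split(alkane_ether_dataset, seed=2)
        gap = abs(s1.active_fraction - s2.active_fraction)
        assert gap <= 1.0 / min(len(s1), len(s2))

    def test_plan_disjoint(self, alkane_ether_dataset):
        plan = make_split_plan(alkane_ether_dataset, 0.1, seed=0)
        parts = [set(plan.heldout.smiles), set(plan.split1.smiles), set(plan.split2.smiles)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_manifest_roundtrip(self, alkane_ether_dataset, tmp_path):
        from fmx.splits import SplitPlan

        plan = make_split_plan(alkane_ether_dataset, 0.1, seed=0)
        plan.save(tmp_path / "plan.csv")
        again = SplitPlan.load(tmp_path / "plan.csv")
        assert again.split1.smiles == plan.split1.smiles
        assert again.heldout.labels == plan.heldout.labels


class TestGEDPairing:
    def test_exact_ged_oracle_small_graphs(self):
        # exact values verifiable by hand on <= 7-node graphs:
        # benzene -> toluene: add one C and one bond (2 edits)
        assert graph_edit_distance(rec("c1ccccc1"), rec("Cc1ccccc1"), timeout=None) == 2
        # benzene -> cyclohexane: 6 bond-order substitutions
        assert graph_edit_distance(rec("c1ccccc1"), rec("C1CCCCC1"), timeout=None) == 6

    def test_greedy_matching_picks_min_ged_pair(self):
        data = LabeledDataset([rec(s) for s in ("c1ccccc1", "Cc1ccccc1", "C1CCCCC1")], [0, 0, 0])
        pairs, unpaired = pair_by_ged(data, max_ged=10)
        assert len(pairs) == 1
        assert {pairs[0].a.smiles, pairs[0].b.smiles} == {"c1ccccc1", "Cc1ccccc1"}
        assert [u.smiles for u in unpaired] == ["C1CCCCC1"]

    def test_duplicates_all_pair_at_zero(self):
        # k duplicated molecules -> k/2 pairs at GED 0, none unpaired
        records = [MoleculeRecord(id=str(i), smiles="CCO") for i in range(6)]
        data = LabeledDataset(records, [0] * 6)
        pairs, unpaired = pair_by_ged(data, max_ged=10)
        assert len(pairs) == 3 and not unpaired
        assert all(p.ged == 0 for p in pairs)

    def test_pairing_within_class_only(self):
        data = LabeledDataset(
            [rec(s) for s in ("CCO", "CCN", "CCC", "CCCC")], [1, 0, 1, 0]
        )
        pairs, _ = pair_by_ged(data, max_ged=10)
        smi = {r.smiles: l for r, l in data}
        for p in pairs:
            assert smi[p.a.smiles] == smi[p.b.smiles]

    def test_threshold_is_strict(self):
        data = LabeledDataset([rec("c1ccccc1"), rec("Cc1ccccc1")], [0, 0])
        pairs, unpaired = pair_by_ged(data, max_ged=2)  # GED == 2 is not < 2
        assert not pairs and len(unpaired) == 2

    def test_assign_pairs_counts_and_membership(self):
        records = [rec("C" * n) for n in range(1, 9)]
        data = LabeledDataset(records, [0] * 8)
        pairs, unpaired = pair_by_ged(data, max_ged=10)
        assert len(pairs) == 4
        labels = {r.smiles: 0 for r in records}
        s1, s2, ev = assign_pairs_to_splits(pairs, unpaired, seed=0, labels=labels)
        assert len(s1) == len(s2) == 4 and len(ev) == 0
        for p in pairs:
            assert (p.a.smiles in s1.smiles) != (p.b.smiles in s1.smiles)

    def test_assign_preserves_class_balance(self):
        smiles_a = ["OC" + "C" * n for n in range(1, 5)]
        smiles_i = ["C" * n for n in range(1, 7)]
        data = LabeledDataset(
            [rec(s) for s in smiles_a + smiles_i], [1] * 4 + [0] * 6
        )
        pairs, unpaired = pair_by_ged(data, max_ged=10)
        labels = {r.smiles: l for r, l in data}
        s1, s2, _ = assign_pairs_to_splits(pairs, unpaired, seed=1, labels=labels)
        assert s1.n_active == s2.n_active
        assert len(s1) - s1.n_active == len(s2) - s2.n_active


class TestClusterDataset:
    def test_all_identical_actives_single_cluster(self):
        actives = [MoleculeRecord(id=str(i), smiles="NS(=O)(=O)c1ccccc1") for i in range(5)]
        data = build_cluster_dataset(actives, [], n_clusters=6)
        assert len(data) == 5 and data.n_active == 5

    def test_two_separated_families(self):
        fam1 = [rec("NS(=O)(=O)c1ccccc1" + "C" * n) for n in range(3)]
        fam2 = [rec("OC(=O)CCCCCCCC" + "N" * 0 + "C" * n) for n in range(3)]
        spec = FingerprintSpec("morgan", 2, 2048)
        fps = fingerprint_many(fam1 + fam2, spec)
        # oracle: the pairwise-similarity matrix confirms the families are
        # farther apart than the clustering distance threshold
        cross = [tanimoto(a, b) for a in fps[:3] for b in fps[3:]]
        assert max(cross) < 0.4
        data = build_cluster_dataset(fam1 + fam2, [], distance_threshold=0.6, n_clusters=2)
        assert len(data) == 6  # both families survive as the 2 biggest clusters

    def test_close_inactives_included(self):
        actives = [rec("NS(=O)(=O)c1ccccc1")]
        near = rec("NS(=O)(=O)c1ccccc1C")  # analog, similar
        far = rec("CCCCCCCC")
        data = build_cluster_dataset(actives, [near, far], n_clusters=1)
        assert near.smiles in data.smiles and far.smiles not in data.smiles


class TestSubstructureFilter:
    def test_phenyl_keeps_benzene_drops_ethanol(self):
        data = LabeledDataset([rec("c1ccccc1"), rec("CCO")], [0, 0])
        kept = substructure_filter(data, "c1ccccc1")
        assert kept.smiles == ["c1ccccc1"]

    def test_caffeine_matches_purine_core(self):
        # oracle: caffeine's bicycle is an N-methylated purine skeleton
        data = LabeledDataset([rec("Cn1cnc2c1c(=O)n(C)c(=O)n2C")], [1])
        assert len(substructure_filter(data, PURINE_CORE_SMARTS)) == 1

    def test_invalid_smarts(self):
        data = LabeledDataset([rec("CCO")], [0])
        with pytest.raises(ValueError):
            substructure_filter(data, "not-a-smarts((")
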