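"""Graph-GA operators and evolution loop."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from fmx.chemio import MoleculeRecord, canonical_smiles
from fmx.graphga import GAConfig, Trajectory, TrajectoryStep, crossover, evolve, mutate


def rec(smiles):
    return MoleculeRecord.from_smiles(smiles)


def enumerate_recombinants(smiles_a, smiles_b):
    """Oracle: all products of cutting each parent at every single non-ring
    bond and joining one fragment from each side."""
    def cuts(smiles):
        mol = Chem.MolFromSmiles(smiles)
        out = []
        for bond in mol.GetBonds():
            if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
                continue
            em = Chem.RWMol(mol)
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            for i in (a, b):
                em.GetAtomWithIdx(i).SetAtomMapNum(1)
            em.RemoveBond(a, b)
            frags = Chem.GetMolFrags(em.GetMol(), asMols=True, sanitizeFrags=False)
            for frag in frags:
                marked = [at.GetIdx() for at in frag.GetAtoms() if at.GetAtomMapNum() == 1]
                if len(marked) == 1:
                    out.append((frag, marked[0]))
        return out

    products = set()
    for (fa, ia), (fb, ib) in itertools.product(cuts(smiles_a), cuts(smiles_b)):
        em = Chem.RWMol(Chem.CombineMols(fa, fb))
        em.AddBond(ia, fa.GetNumAtoms() + ib, Chem.BondType.SINGLE)
        for at in em.GetAtoms():
            at.SetAtomMapNum(0)
        try:
            m = em.GetMol()
            Chem.SanitizeMol(m)
            products.add(Chem.MolToSmiles(m))
        except Exception:
            pass
    return products


class TestCrossover:
    def test_children_within_oracle_enumeration(self):
        oracle = enumerate_recombinants("CCO", "CCN")
        rng = np.random.default_rng(0)
        children = {
            crossover(rec("CCO"), rec("CCN"), rng).smiles for _ in range(60)
        }
        assert children <= oracle
        assert {"CCO", "CCN"} & oracle  # self-recombinants are reachable

    def test_methane_has_no_cuttable_bond(self):
        rng = np.random.default_rng(0)
        assert crossover(rec("C"), rec("CCO"), rng) is None

    def test_children_always_valid(self):
        rng = np.random.default_rng(1)
        a, b = rec("CC(=O)Nc1ccc(O)cc1"), rec("NS(=O)(=O)c1ccccc1CC")
        for _ in range(30):
            child = crossover(a, b, rng)
            if child is not None:
                assert Chem.MolFromSmiles(child.smiles) is not None


class TestMutate:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        benzene = rec("c1ccccc1")
        for _ in range(20):
            assert mutate(benzene, rng, 0.0) is benzene

    def test_outputs_always_valid(self):
        rng = np.random.default_rng(2)
        benzene = rec("c1ccccc1")
        for _ in range(300):
            m = mutate(benzene, rng, 1.0)
            assert canonical_smiles(m.smiles) == m.smiles
            assert m.mol is not None

    def test_insertion_on_methane_grows_molecule(self):
        from fmx.graphga import _op_insert_atom

        rng = np.random.default_rng(3)
        # oracle: insertion on methane can only yield CC, CN or CO
        outcomes = set()
        for _ in range(30):
            result = _op_insert_atom(rec("C").mol, rng)
            assert result is not None
            outcomes.add(result.smiles)
        assert outcomes <= {"CC", "CN", "CO"}
        assert len(outcomes) >= 2


@pytest.fixture(scope="module")
def initial():
    return [rec(s) for s in ("CCO", "CCN", "CCC", "CCCC", "CC(C)C", "CCOC")]


class TestEvolve:
    def test_constant_scorer_flat(self, initial):
        scorer = lambda mols: np.full(len(mols), 0.5)
        traj = evolve(initial, scorer, GAConfig(population_size=6, n_generations=5, seed=0))
        assert np.allclose(traj.best_so_far(), 0.5)

    def test_elitism_nondecreasing(self, initial):
        scorer = lambda mols: np.array([len(m.smiles) % 7 / 7.0 for m in mols])
        for seed in range(5):
            traj = evolve(
                initial, scorer, GAConfig(population_size=6, n_generations=8, seed=seed)
            )
            best = traj.best_so_far()
            assert np.all(np.diff(best) >= 0)

    def test_planted_substructure_preserved_by_elitism(self, initial):
        pyridine = Chem.MolFromSmarts("c1ccncc1")
        scorer = lambda mols: np.array(
            [1.0 if m.mol.HasSubstructMatch(pyridine) else 0.0 for m in mols]
        )
        start = initial + [rec("c1ccncc1")]
        traj = evolve(start, scorer, GAConfig(population_size=7, n_generations=6, seed=1))
        assert traj.best_so_far()[-1] == 1.0

    def test_population_size_constant(self, initial):
        scorer = lambda mols: np.zeros(len(mols))
        traj = evolve(initial, scorer, GAConfig(population_size=6, n_generations=5, seed=2))
        assert all(len(s.members) == 6 for s in traj.steps)

    def test_deterministic_per_seed(self, initial):
        scorer = lambda mols: np.array([m.smiles.count("C") / 10 for m in mols])
        cfg = GAConfig(population_size=6, n_generations=6, seed=5)
        t1 = evolve(initial, scorer, cfg)
        t2 = evolve(initial, scorer, cfg)
        assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_control_scorers_recorded_not_selective(self, initial):
        opt = lambda mols: np.array([m.smiles.count("C") / 10 for m in mols])
        ctrl = lambda mols: np.full(len(mols), 0.123)
        cfg = GAConfig(population_size=6, n_generations=4, seed=0)
        with_ctrl = evolve(initial, opt, cfg, control_scorers={"mc": ctrl, "dc": ctrl})
        without = evolve(initial, opt, cfg)
        # observational controls: identical optimization trajectory
        assert np.array_equal(
            with_ctrl.to_dataframe()["s_opt"], without.to_dataframe()["s_opt"]
        )
        assert np.allclose(with_ctrl.steps[-1].s_mc, 0.123)

    def test_scorer_errors_discard_molecule(self, initial):
        def flaky(mols):
            for m in mols:
                if m.smiles == "CCO":
                    raise RuntimeError("refuse")
            return np.zeros(len(mols))

        traj = evolve(initial, flaky, GAConfig(population_size=5, n_generations=1, seed=0))
        assert all("CCO" != m.smiles for m in traj.steps[0].members)


class TestTrajectory:
    def test_strictly_increasing_generations_enforced(self):
        step = lambda g: TrajectoryStep(g, [rec("C")], np.array([0.1]))
        with pytest.raises(ValueError):
            Trajectory([step(0), step(0)])

    def test_roundtrip_dataframe(self, tmp_path):
        steps = [
            TrajectoryStep(0, [rec("C")], np.array([0.2]), np.array([0.3]), np.array([0.1])),
            TrajectoryStep(1, [rec("CC")], np.array([0.4]), np.array([0.5]), np.array([0.2])),
        ]
        traj = Trajectory(steps)
        frame = traj.to_dataframe()
        assert list(frame["generation"]) == [0, 1]
        assert np.allclose(traj.per_step_mean("opt"), [0.2, 0.4])
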