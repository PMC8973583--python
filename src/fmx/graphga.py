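"""A goal-directed genetic algorithm on molecular graphs.

The generator evolves a population of molecules toward higher values of a
scoring function via fragment crossover (cut each parent at a non-ring
single bond and recombine complementary fragments) and local graph mutations
(atom insertion/deletion/replacement, bond-order change, ring formation and
opening).  Selection is rank-proportional with elitism: after each
generation the top ``population_size`` of parents plus offspring survive, so
the best score never decreases.

Control scorers can be attached to record model-control and data-control
scores of every sampled generation; they never influence selection — the
controls are purely observational.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "Population", "Trajectory", "crossover", "mutate", "evolve"]

# A batch scorer maps a list of molecules to a parallel array of reals.
BatchScorer = Callable[[Sequence[MoleculeRecord]], np.ndarray]

_MUTATION_ATOMS = (6, 7, 8)  # C, N, O for insertions
_REPLACEMENT_ATOMS = (6, 7, 8, 9, 16, 17)  # C, N, O, F, S, Cl


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``n_generations`` defaults to 151 epochs; population size, offspring
    count and mutation rate follow the usual graph-GA conventions and are
    fully configurable.
    """

    population_size: int = 100
    n_generations: int = 151
    mutation_rate: float = 0.01
    offspring_per_generation: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be a probability")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")

    @property
    def n_offspring(self) -> int:
        return self.offspring_per_generation or self.population_size


@dataclass
class Population:
    members: list[MoleculeRecord]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.members) != len(self.scores):
            raise ValueError("members and scores must be parallel")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class TrajectoryStep:
    generation: int
    members: list[MoleculeRecord]
    s_opt: np.ndarray
    s_mc: np.ndarray | None = None
    s_dc: np.ndarray | None = None


@dataclass
class Trajectory:
    """Per-generation record of the sampled population and its scores."""

    steps: list[TrajectoryStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        gens = [s.generation for s in self.steps]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generation indices must be strictly increasing")

    @property
    def generations(self) -> np.ndarray:
        return np.asarray([s.generation for s in self.steps])

    def channel(self, name: str) -> list[np.ndarray]:
        """Per-step score vectors for channel 'opt', 'mc' or 'dc'."""
        return [getattr(s, f"s_{name}") for s in self.steps]

    def per_step_mean(self, name: str = "opt") -> np.ndarray:
        return np.asarray([np.mean(v) for v in self.channel(name)])

    def best_so_far(self) -> np.ndarray:
        return np.maximum.accumulate([np.max(s.s_opt) for s in self.steps])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for step in self.steps:
            for i, rec in enumerate(step.members):
                rows.append(
                    {
                        "generation": step.generation,
                        "smiles": rec.smiles,
                        "s_opt": step.s_opt[i],
                        "s_mc": step.s_mc[i] if step.s_mc is not None else np.nan,
                        "s_dc": step.s_dc[i] if step.s_dc is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Variation operators


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]


def _cut(mol: Chem.Mol, bond_idx: int) -> list[tuple[Chem.Mol, int]]:
    """Fragments after cutting one bond; each with its open attachment atom."""
    bond = mol.GetBondWithIdx(bond_idx)
    emol = Chem.RWMol(mol)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    for idx in (a, b):
        emol.GetAtomWithIdx(idx).SetIntProp("cut_point", 1)
    emol.RemoveBond(a, b)
    frags = Chem.GetMolFrags(emol.GetMol(), asMols=True, sanitizeFrags=False)
    out = []
    for frag in frags:
        cut_atoms = [at.GetIdx() for at in frag.GetAtoms() if at.HasProp("cut_point")]
        if len(cut_atoms) == 1:
            out.append((frag, cut_atoms[0]))
    return out


def _join(frag_a: tuple[Chem.Mol, int], frag_b: tuple[Chem.Mol, int]) -> MoleculeRecord | None:
    mol_a, at_a = frag_a
    mol_b, at_b = frag_b
    combined = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    combined.AddBond(at_a, mol_a.GetNumAtoms() + at_b, Chem.BondType.SINGLE)
    for atom in combined.GetAtoms():
        atom.ClearProp("cut_point") if atom.HasProp("cut_point") else None
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
        smiles = Chem.MolToSmiles(product)
        if Chem.MolFromSmiles(smiles) is None:
            return None
        return MoleculeRecord(id=smiles, smiles=smiles)
    except Exception:  # noqa: BLE001
        return None


def crossover(
    parent_a: MoleculeRecord,
    parent_b: MoleculeRecord,
    rng: np.random.Generator,
    max_attempts: int = 10,
) -> MoleculeRecord | None:
    """Cut each parent at a random non-ring single bond and recombine.

    Returns None if either parent has no cuttable bond or no valid
    recombination is found within ``max_attempts``.
    """
    bonds_a = _cuttable_bonds(parent_a.mol)
    bonds_b = _cuttable_bonds(parent_b.mol)
    if not bonds_a or not bonds_b:
        return None
    for _ in range(max_attempts):
        frags_a = _cut(parent_a.mol, int(rng.choice(bonds_a)))
        frags_b = _cut(parent_b.mol, int(rng.choice(bonds_b)))
        if not frags_a or not frags_b:
            continue
        fa = frags_a[int(rng.integers(len(frags_a)))]
        fb = frags_b[int(rng.integers(len(frags_b)))]
        child = _join(fa, fb)
        if child is not None and child.mol.GetNumHeavyAtoms() >= 1:
            return child
    return None


def _try_sanitize(emol: Chem.RWMol) -> MoleculeRecord | None:
    try:
        product = emol.GetMol()
        Chem.SanitizeMol(product)
        smiles = Chem.MolToSmiles(product)
        if not smiles or Chem.MolFromSmiles(smiles) is None:
            return None
        return MoleculeRecord(id=smiles, smiles=smiles)
    except Exception:  # noqa: BLE001
        return None


def _op_insert_atom(mol: Chem.Mol, rng: np.random.Generator) -> MoleculeRecord | None:
    candidates = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]
    if not candidates:
        return None
    emol = Chem.RWMol(mol)
    new_idx = emol.AddAtom(Chem.Atom(int(rng.choice(_MUTATION_ATOMS))))
    emol.AddBond(int(rng.choice(candidates)), new_idx, Chem.BondType.SINGLE)
    return _try_sanitize(emol)


def _op_delete_atom(mol: Chem.Mol, rng: np.random.Generator) -> MoleculeRecord | None:
    terminals = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() <= 1]
    if mol.GetNumAtoms() <= 1 or not terminals:
        return None
    emol = Chem.RWMol(mol)
    emol.RemoveAtom(int(rng.choice(terminals)))
    if emol.GetNumAtoms() == 0:
        return None
    return _try_sanitize(emol)


def _op_replace_atom(mol: Chem.Mol, rng: np.random.Generator) -> MoleculeRecord | None:
    idx = int(rng.integers(mol.GetNumAtoms()))
    emol = Chem.RWMol(mol)
    atom = emol.GetAtomWithIdx(idx)
    choices = [z for z in _REPLACEMENT_ATOMS if z != atom.GetAtomicNum()]
    atom.SetAtomicNum(int(rng.choice(choices)))
    atom.SetNoImplicit(False)
    atom.SetNumExplicitHs(0)
    return _try_sanitize(emol)


def _op_change_bond(mol: Chem.Mol, rng: np.random.Generator) -> MoleculeRecord | None:
    if mol.GetNumBonds() == 0:
        return None
    emol = Chem.RWMol(mol)
    bond = emol.GetBondWithIdx(int(rng.integers(mol.GetNumBonds())))
    if bond.GetIsAromatic():
        return None
    new_type = (
        Chem.BondType.DOUBLE if bond.GetBondType() == Chem.BondType.SINGLE else Chem.BondType.SINGLE
    )
    bond.SetBondType(new_type)
    return _try_sanitize(emol)


def _op_form_ring(mol: Chem.Mol, rng: np.random.Generator) -> MoleculeRecord | None:
    dmat = Chem.GetDistanceMatrix(mol)
    candidates = [
        (i, j)
        for i in range(mol.GetNumAtoms())
        for j in range(i + 1, mol.GetNumAtoms())
        if 3 <= dmat[i, j] <= 5
        and mol.GetAtomWithIdx(i).GetTotalNumHs() >= 1
        and mol.GetAtomWithIdx(j).GetTotalNumHs() >= 1
    ]
    if not candidates:
        return None
    i, j = candidates[int(rng.integers(len(candidates)))]
    emol = Chem.RWMol(mol)
    emol.AddBond(i, j, Chem.BondType.SINGLE)
    return _try_sanitize(emol)


def _op_open_ring(mol: Chem.Mol, rng: np.random.Generator) -> MoleculeRecord | None:
    ring_bonds = [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE and not b.GetIsAromatic()
    ]
    if not ring_bonds:
        return None
    bond = mol.GetBondWithIdx(int(rng.choice(ring_bonds)))
    emol = Chem.RWMol(mol)
    emol.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return _try_sanitize(emol)


_OPERATORS = (
    _op_insert_atom,
    _op_delete_atom,
    _op_replace_atom,
    _op_change_bond,
    _op_form_ring,
    _op_open_ring,
)


def mutate(
    record: MoleculeRecord,
    rng: np.random.Generator,
    mutation_rate: float = 0.01,
    max_attempts: int = 12,
) -> MoleculeRecord:
    """With probability ``mutation_rate``, apply one random graph operator.

    Falls back to the input molecule if no operator yields a valid structure
    within ``max_attempts`` draws.
    """
    if rng.random() >= mutation_rate:
        return record
    for _ in range(max_attempts):
        op = _OPERATORS[int(rng.integers(len(_OPERATORS)))]
        result = op(record.mol, rng)
        if result is not None:
            return result
    return record


# ---------------------------------------------------------------------------
# Evolution loop


def _rank_probabilities(scores: np.ndarray) -> np.ndarray:
    """Selection probability proportional to rank (best gets weight n)."""
    order = np.argsort(np.argsort(scores, kind="stable"), kind="stable")
    weights = order + 1.0
    return weights / weights.sum()


def _safe_score(scorer: BatchScorer, members: list[MoleculeRecord]):
    """Score a batch, discarding (with a log line) molecules the scorer rejects."""
    try:
        return members, np.asarray(scorer(members), dtype=float)
    except Exception:  # noqa: BLE001 - retry molecule-by-molecule
        kept, scores = [], []
        for rec in members:
            try:
                scores.append(float(scorer([rec])[0]))
                kept.append(rec)
            except Exception:  # noqa: BLE001
                logger.warning("scorer rejected %s; molecule discarded", rec.smiles)
        return kept, np.asarray(scores, dtype=float)


def evolve(
    initial: Sequence[MoleculeRecord],
    scorer: BatchScorer,
    config: GAConfig = GAConfig(),
    control_scorers: dict[str, BatchScorer] | None = None,
) -> Trajectory:
    """Run the GA and record every generation's population with its scores.

    Generation 0 is the scored starting population (truncated to the
    ``population_size`` best if larger).  Each later generation samples
    parents rank-proportionally with replacement, produces offspring through
    crossover followed by mutation, and keeps the top ``population_size`` of
    parents plus offspring.  Control scorers are evaluated on each recorded
    generation but never influence selection.  Fixed seed, fixed trajectory.
    """
    if not initial:
        raise ValueError("initial population must be non-empty")
    rng = np.random.default_rng(config.seed)
    control_scorers = control_scorers or {}

    members, scores = _safe_score(scorer, list(initial))
    if not members:
        raise ValueError("scorer rejected the entire starting population")
    if len(members) > config.population_size:
        top = np.argsort(-scores, kind="stable")[: config.population_size]
        top = np.sort(top)
        members = [members[i] for i in top]
        scores = scores[top]

    steps: list[TrajectoryStep] = []

    def record_step(gen: int, mem: list[MoleculeRecord], sc: np.ndarray) -> None:
        controls = {name: np.asarray(fn(mem), dtype=float) for name, fn in control_scorers.items()}
        steps.append(
            TrajectoryStep(
                generation=gen,
                members=list(mem),
                s_opt=sc.copy(),
                s_mc=controls.get("mc"),
                s_dc=controls.get("dc"),
            )
        )

    record_step(0, members, scores)

    for gen in range(1, config.n_generations + 1):
        probs = _rank_probabilities(scores)
        offspring: list[MoleculeRecord] = []
        for _ in range(config.n_offspring):
            ia, ib = rng.choice(len(members), size=2, p=probs)
            child = crossover(members[ia], members[ib], rng)
            if child is None:
                child = members[ia]
            child = mutate(child, rng, config.mutation_rate)
            offspring.append(child)
        off_members, off_scores = _safe_score(scorer, offspring)
        pool = members + off_members
        pool_scores = np.concatenate([scores, off_scores])
        order = np.argsort(-pool_scores, kind="stable")
        # prefer unique structures to avoid premature convergence to copies
        # of a single molecule; duplicates only fill remaining slots
        unique_idx, dup_idx, seen_smiles = [], [], set()
        for i in order:
            if pool[i].smiles in seen_smiles:
                dup_idx.append(i)
            else:
                seen_smiles.add(pool[i].smiles)
                unique_idx.append(i)
        keep = np.sort(np.asarray((unique_idx + dup_idx)[: config.population_size]))
        members = [pool[i] for i in keep]
        scores = pool_scores[keep]
        record_step(gen, members, scores)

    return Trajectory(steps)
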