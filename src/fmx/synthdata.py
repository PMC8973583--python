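"""Synthetic structure-activity datasets with a planted activity rule.

Molecules are assembled by attaching 1-3 substituents from a small
medicinal-chemistry library to a heterocyclic or aryl scaffold.  The true
label is 1 iff the assembled molecule carries the pharmacophore (by default
a sulfonamide group); the observed label is the true label flipped with a
configurable noise probability.  This planting gives exactly the structure
the divergence analysis assumes: classifiers can learn the rule from
fingerprint bits, but on small noisy samples independently seeded or
independently split forests memorize the noise differently and disagree on
high-scoring molecules, while larger, cleaner samples with stronger
regularization yield concordant forests.

Two presets encode those regimes:

* ``divergent`` — n=400, 20% label noise, stock forest (100 trees, leaves
  of 1): underspecified models that disagree at the top of the score range.
* ``concordant`` — n=800, 5% label noise, regularized forest (200 trees,
  min 3 samples per leaf): models that agree on the data distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import LabeledDataset, MoleculeRecord
from .triad import DEFAULT_FOREST, MODIFIED_FOREST, ClassifierSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SynthesisConfig",
    "SCAFFOLD_LIBRARY",
    "SUBSTITUENT_LIBRARY",
    "PHARMACOPHORE_SMARTS",
    "generate_library",
    "regime_preset",
]

# Scaffolds: small aromatic/heteroaromatic and saturated cores, several of
# them phenyl-bearing so that Topliss augmentation has rings to work on.
SCAFFOLD_LIBRARY: tuple[str, ...] = (
    "c1ccccc1",                # benzene
    "c1ccncc1",                # pyridine
    "c1ccc(-c2ccccc2)cc1",     # biphenyl
    "c1cncnc1",                # pyrimidine
    "c1ccsc1",                 # thiophene
    "c1ccoc1",                 # furan
    "c1cc[nH]c1",              # pyrrole
    "c1ccc(C2CCNCC2)cc1",      # 4-phenylpiperidine
    "c1ccc(-c2ccncc2)cc1",     # phenylpyridine
    "c1ccc(Cc2ccccc2)cc1",     # diphenylmethane
    "c1ccc(OCC2CC2)cc1",       # cyclopropylmethoxybenzene
    "C1CCNCC1",                # piperidine
    "C1CCOCC1",                # tetrahydropyran
    "c1ccc2[nH]ccc2c1",        # indole
    "c1ccc2ncccc2c1",          # quinoline
    "c1ccc(N2CCOCC2)cc1",      # phenylmorpholine
    "c1cnc2[nH]ccc2c1",        # azaindole
    "c1ccc(CNC2CC2)cc1",       # benzyl-cyclopropylamine
    "c1csc(-c2ccccc2)c1",      # phenylthiophene
    "C1CCC(c2ccccc2)CC1",      # phenylcyclohexane
)

# Substituents as SMILES fragments; atom 0 bonds to the scaffold.
SUBSTITUENT_LIBRARY: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C",
    "F", "Cl", "Br", "I",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "C#N", "C(F)(F)F", "[N+](=O)[O-]",
    "C(=O)O", "C(=O)N", "C(=O)C", "C(=O)OC",
    "S(N)(=O)=O",              # sulfonamide — the default pharmacophore
    "S(C)(=O)=O", "SC",
    "CO", "CN", "C=C", "C1CC1", "N1CCOCC1",
)

# Primary/secondary sulfonamide.
PHARMACOPHORE_SMARTS = "[SX4](=[OX1])(=[OX1])[NX3]"


@dataclass(frozen=True)
class SynthesisConfig:
    """Settings for one synthetic structure-activity dataset."""

    n_molecules: int = 500
    active_fraction_target: float = 0.15
    label_noise: float = 0.1
    scaffold_library: tuple[str, ...] = SCAFFOLD_LIBRARY
    substituent_library: tuple[str, ...] = SUBSTITUENT_LIBRARY
    pharmacophore: str = PHARMACOPHORE_SMARTS
    regime: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must be in [0, 0.5]")
        if not 0 < self.active_fraction_target < 1:
            raise ValueError("active_fraction_target must be in (0, 1)")
        if not self.scaffold_library or not self.substituent_library:
            raise ValueError("libraries must be non-empty")


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() >= 1 and a.GetFormalCharge() == 0
    ]


def _assemble(
    scaffold_smiles: str, substituents: list[str], positions: list[int]
) -> str | None:
    """Attach substituent fragments (atom 0) to scaffold atoms; canonical
    SMILES of the product or None if chemistry fails."""
    mol = Chem.RWMol(Chem.MolFromSmiles(scaffold_smiles))
    for sub, pos in zip(substituents, positions):
        frag = Chem.MolFromSmiles(sub)
        if frag is None:
            return None
        offset = mol.GetNumAtoms()
        mol.InsertMol(frag)
        mol.AddBond(pos, offset, Chem.BondType.SINGLE)
    try:
        product = mol.GetMol()
        Chem.SanitizeMol(product)
        return Chem.MolToSmiles(product)
    except Exception:  # noqa: BLE001
        return None


def generate_library(config: SynthesisConfig) -> LabeledDataset:
    """Assemble a deduplicated dataset matching the configured regime.

    The true label is the pharmacophore rule; the observed label is flipped
    with probability ``label_noise``.  Candidates are accepted against
    per-class quotas (true-label actives vs inactives) so the realized
    active fraction approaches the target.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    pattern = Chem.MolFromSmarts(config.pharmacophore)
    if pattern is None:
        raise ValueError(f"invalid pharmacophore SMARTS {config.pharmacophore!r}")

    n = config.n_molecules
    quota = {1: int(round(n * config.active_fraction_target))}
    quota[0] = n - quota[1]
    if min(quota.values()) == 0:
        raise ValueError("quotas leave an empty class; adjust n or target")

    records: list[MoleculeRecord] = []
    observed_labels: list[int] = []
    n_true_active = 0
    seen: set[str] = set()
    counts = {0: 0, 1: 0}
    max_attempts = 400 * n
    attempts = 0
    while len(records) < n and attempts < max_attempts:
        attempts += 1
        scaffold = config.scaffold_library[int(rng.integers(len(config.scaffold_library)))]
        base = Chem.MolFromSmiles(scaffold)
        points = _attachment_points(base)
        if not points:
            continue
        k = int(rng.integers(1, min(3, len(points)) + 1))
        positions = list(rng.choice(points, size=k, replace=False))
        subs = [
            config.substituent_library[int(rng.integers(len(config.substituent_library)))]
            for _ in range(k)
        ]
        flip = rng.random() < config.label_noise
        smiles = _assemble(scaffold, subs, [int(p) for p in positions])
        if smiles is None or smiles in seen:
            continue
        mol = Chem.MolFromSmiles(smiles)
        true_label = int(mol.HasSubstructMatch(pattern))
        observed = int(true_label ^ flip)
        # quotas are on observed labels so the realized active fraction
        # tracks the target even under label noise
        if counts[observed] >= quota[observed]:
            continue
        seen.add(smiles)
        counts[observed] += 1
        n_true_active += true_label
        records.append(MoleculeRecord(id=f"synth:{len(records)}", smiles=smiles, mol=mol))
        observed_labels.append(observed)
    if len(records) < n:
        raise RuntimeError(
            f"could only assemble {len(records)} unique molecules of {n} requested; "
            "enlarge the libraries or lower n_molecules"
        )
    data = LabeledDataset(records, observed_labels, name=f"synth-{config.regime}-seed{config.seed}")
    logger.info(
        "generated %d molecules (%d true actives, %d observed actives) in %d attempts",
        n, n_true_active, data.n_active, attempts,
    )
    return data


def regime_preset(regime: str, seed: int = 0) -> tuple[SynthesisConfig, ClassifierSpec]:
    """Dataset + classifier settings for the two study regimes."""
    if regime == "divergent":
        return (
            SynthesisConfig(
                n_molecules=400, active_fraction_target=0.15, label_noise=0.2,
                regime="divergent", seed=seed,
            ),
            DEFAULT_FOREST,
        )
    if regime == "concordant":
        return (
            SynthesisConfig(
                n_molecules=800, active_fraction_target=0.15, label_noise=0.05,
                regime="concordant", seed=seed,
            ),
            MODIFIED_FOREST,
        )
    raise ValueError(f"unknown regime {regime!r} (expected 'divergent' or 'concordant')")
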