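"""Analog enumeration on phenyl rings following the Topliss operational
scheme for aromatic substituents.

The scheme explores substituents around a phenyl ring of a lead molecule
(4-Cl, 3,4-Cl2, 4-OCH3, ...).  Ring positions are numbered 1-6 with position
1 at the attachment point of the ring to the rest of the molecule; each
pattern places one or two groups at free (H-bearing) positions.  Applied to
every phenyl ring of every molecule of a set, this yields medicinal-
chemistry-reasonable structural analogs used here to densify the score
distribution of a held-out set; analogs carry no activity labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ToplissScheme",
    "default_scheme",
    "PhenylSite",
    "find_phenyl_rings",
    "enumerate_analogs",
    "augment_set",
]

# Substituent groups as SMILES fragments; atom 0 bonds to the ring.
SUBSTITUENT_SMILES: dict[str, str] = {
    "Cl": "Cl",
    "F": "F",
    "Br": "Br",
    "CH3": "C",
    "OCH3": "OC",
    "C(CH3)3": "C(C)(C)C",
    "CF3": "C(F)(F)F",
    "NO2": "[N+](=O)[O-]",
    "N(CH3)2": "N(C)C",
}

# The classical aromatic-substituent operational tree.  Patterns map ring
# position (2-6, 1 = attachment) to a named group.
_DEFAULT_PATTERNS: tuple[tuple[str, dict[int, str]], ...] = (
    ("4-Cl", {4: "Cl"}),
    ("3,4-Cl2", {3: "Cl", 4: "Cl"}),
    ("4-CH3", {4: "CH3"}),
    ("4-OCH3", {4: "OCH3"}),
    ("4-C(CH3)3", {4: "C(CH3)3"}),
    ("3-CF3", {3: "CF3"}),
    ("3-CF3-4-Cl", {3: "CF3", 4: "Cl"}),
    ("3-Cl", {3: "Cl"}),
    ("3-CH3", {3: "CH3"}),
    ("2-Cl", {2: "Cl"}),
    ("4-F", {4: "F"}),
    ("4-Br", {4: "Br"}),
    ("4-NO2", {4: "NO2"}),
    ("4-N(CH3)2", {4: "N(CH3)2"}),
)


@dataclass(frozen=True)
class ToplissScheme:
    """Ordered list of named substitution patterns on a phenyl ring."""

    patterns: tuple[tuple[str, dict[int, str]], ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("scheme must contain at least one pattern")
        names = [name for name, _ in self.patterns]
        if len(set(names)) != len(names):
            raise ValueError("pattern names must be unique")
        for name, pattern in self.patterns:
            for pos, group in pattern.items():
                if pos not in (2, 3, 4, 5, 6):
                    raise ValueError(f"{name}: position {pos} outside 2-6")
                if group not in SUBSTITUENT_SMILES:
                    raise ValueError(f"{name}: unknown group {group!r}")

    def __len__(self) -> int:
        return len(self.patterns)


def default_scheme() -> ToplissScheme:
    return ToplissScheme(_DEFAULT_PATTERNS)


@dataclass
class PhenylSite:
    """A non-fused benzene ring: atom indices ordered by ring position 1-6.

    ``ring_atoms[0]`` is position 1 (the attachment point, or an arbitrary
    canonical-rank-determined atom for an unsubstituted ring);
    ``free_positions`` are the 1-based positions bearing at least one H.
    """

    ring_atoms: tuple[int, ...]
    free_positions: frozenset[int]


def find_phenyl_rings(mol: Chem.Mol) -> list[PhenylSite]:
    """Locate non-fused benzene rings with at least one free position.

    Fused aromatics (naphthalene etc.) are excluded.  Ring positions are
    numbered from the attachment atom (smallest canonical rank if several),
    walking toward the lower-ranked neighbor so numbering is deterministic.
    """
    ring_info = mol.GetRingInfo()
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    atom_ring_count = {}
    for ring in ring_info.AtomRings():
        for idx in ring:
            atom_ring_count[idx] = atom_ring_count.get(idx, 0) + 1
    sites = []
    for ring in ring_info.AtomRings():
        if len(ring) != 6:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() and a.GetAtomicNum() == 6 for a in atoms):
            continue
        if any(atom_ring_count[i] > 1 for i in ring):
            continue  # fused
        ring_set = set(ring)
        attachments = [
            i
            for i in ring
            if any(n.GetIdx() not in ring_set for n in mol.GetAtomWithIdx(i).GetNeighbors())
        ]
        start = min(attachments, key=lambda i: ranks[i]) if attachments else min(ring, key=lambda i: ranks[i])
        neighbors_in_ring = [
            n.GetIdx() for n in mol.GetAtomWithIdx(start).GetNeighbors() if n.GetIdx() in ring_set
        ]
        nxt = min(neighbors_in_ring, key=lambda i: ranks[i])
        ordered = [start, nxt]
        while len(ordered) < 6:
            current = mol.GetAtomWithIdx(ordered[-1])
            nxt = next(
                n.GetIdx()
                for n in current.GetNeighbors()
                if n.GetIdx() in ring_set and n.GetIdx() != ordered[-2]
            )
            ordered.append(nxt)
        free = frozenset(
            pos
            for pos, idx in enumerate(ordered, start=1)
            if pos > 1 and mol.GetAtomWithIdx(idx).GetTotalNumHs() >= 1
        )
        if free:
            sites.append(PhenylSite(tuple(ordered), free))
    return sites


def _apply_pattern(
    mol: Chem.Mol, site: PhenylSite, pattern: dict[int, str]
) -> str | None:
    """Substituted canonical SMILES, or None if the pattern is not applicable."""
    if not set(pattern) <= site.free_positions:
        return None
    combined = Chem.RWMol(mol)
    for pos, group in pattern.items():
        frag = Chem.MolFromSmiles(SUBSTITUENT_SMILES[group])
        offset = combined.GetNumAtoms()
        combined.InsertMol(frag)
        combined.AddBond(site.ring_atoms[pos - 1], offset, Chem.BondType.SINGLE)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
    except Exception:  # noqa: BLE001 - any RDKit sanitization failure
        return None
    return Chem.MolToSmiles(product)


def enumerate_analogs(
    record: MoleculeRecord, scheme: ToplissScheme | None = None
) -> list[MoleculeRecord]:
    """All scheme analogs over every phenyl ring of a molecule.

    Output is canonicalized, deduplicated, and never contains the parent.
    Patterns whose positions are occupied are skipped (count logged at debug
    level).
    """
    scheme = scheme or default_scheme()
    sites = find_phenyl_rings(record.mol)
    seen: set[str] = {record.smiles}
    analogs: list[MoleculeRecord] = []
    skipped = 0
    for site_no, site in enumerate(sites):
        for name, pattern in scheme.patterns:
            smiles = _apply_pattern(record.mol, site, pattern)
            if smiles is None:
                skipped += 1
                continue
            if smiles in seen:
                continue
            seen.add(smiles)
            analogs.append(
                MoleculeRecord(id=f"{record.id}|ring{site_no}|{name}", smiles=smiles)
            )
    if skipped:
        logger.debug("%s: %d inapplicable patterns skipped", record.id, skipped)
    return analogs


def augment_set(
    records: list[MoleculeRecord],
    scheme: ToplissScheme | None = None,
    target_fold: float = 10.0,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Union of the originals and their analogs, aimed at ``target_fold`` x.

    If full enumeration overshoots ``target_fold * len(records)``, analogs
    are subsampled per parent (round-robin over seeded-shuffled per-parent
    lists) to land within one |originals| of the target; if it falls short,
    everything is kept and the achieved fold is logged.
    """
    if target_fold < 1:
        raise ValueError("target_fold must be >= 1")
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)
    originals = {r.smiles for r in records}
    per_parent: list[list[MoleculeRecord]] = []
    seen: set[str] = set(originals)
    for rec in records:
        analogs = [a for a in enumerate_analogs(rec, scheme) if not (a.smiles in seen or seen.add(a.smiles))]
        per_parent.append(analogs)
    budget = int(round((target_fold - 1) * len(records)))
    total = sum(len(a) for a in per_parent)
    if total <= budget:
        chosen = [a for analogs in per_parent for a in analogs]
        fold = (len(records) + total) / len(records) if records else 1.0
        if fold < target_fold:
            logger.info("augmentation reached %.2f-fold (target %.1f)", fold, target_fold)
    else:
        for analogs in per_parent:
            rng.shuffle(analogs)
        chosen = []
        depth = 0
        while len(chosen) < budget:
            added = False
            for analogs in per_parent:
                if depth < len(analogs):
                    chosen.append(analogs[depth])
                    added = True
                    if len(chosen) >= budget:
                        break
            if not added:
                break
            depth += 1
    return list(records) + chosen
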