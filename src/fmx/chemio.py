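"""Molecule ingestion, canonicalization, fingerprints, descriptors and similarity.

Every other module works on :class:`MoleculeRecord` / :class:`LabeledDataset`
objects produced here.  The canonical-SMILES dialect is RDKit's default
(isomeric canonical SMILES); all deduplication, serialization and identity
checks in the package use that single dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit import DataStructs
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

# RDKit is chatty about unparsable SMILES; we log drop counts ourselves.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MoleculeRecord",
    "LabeledDataset",
    "FingerprintSpec",
    "DescriptorVector",
    "canonical_smiles",
    "read_dataset",
    "read_smiles_file",
    "write_dataset",
    "fingerprint",
    "fingerprint_many",
    "tanimoto",
    "physchem_descriptors",
    "PHYSCHEM_NAMES",
    "feature_matrix",
]


def canonical_smiles(smiles: str, largest_fragment: bool = False) -> str | None:
    """Return RDKit canonical SMILES, or None if the string does not parse.

    With ``largest_fragment=True`` only the fragment with the most heavy
    atoms is kept (counter-ions and solvents stripped); no further
    standardization is attempted.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if largest_fragment and "." in smiles:
        frags = Chem.GetMolFrags(mol, asMols=True)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


@dataclass
class MoleculeRecord:
    """A molecule with a stable id and its canonical SMILES."""

    id: str
    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @classmethod
    def from_smiles(
        cls, smiles: str, id: str | None = None, largest_fragment: bool = False
    ) -> "MoleculeRecord | None":
        can = canonical_smiles(smiles, largest_fragment=largest_fragment)
        if can is None:
            return None
        return cls(id=id if id is not None else can, smiles=can, mol=Chem.MolFromSmiles(can))

    def __post_init__(self) -> None:
        if self.mol is None:
            self.mol = Chem.MolFromSmiles(self.smiles)
            if self.mol is None:
                raise ValueError(f"invalid SMILES for record {self.id!r}: {self.smiles!r}")


@dataclass
class LabeledDataset:
    """A sample of molecules with binary activity labels.

    ``records`` and ``labels`` are parallel; labels are 0 (inactive) or
    1 (active).  This is the in-memory form of the CSV/SDF inputs and of
    everything the splitters produce.
    """

    records: list[MoleculeRecord]
    labels: list[int]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels must be parallel")
        bad = set(self.labels) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary, got extra values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[MoleculeRecord, int]]:
        return iter(zip(self.records, self.labels))

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def n_active(self) -> int:
        return int(sum(self.labels))

    @property
    def active_fraction(self) -> float:
        return self.n_active / len(self) if len(self) else float("nan")

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            name=name if name is not None else self.name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": self.smiles,
                "active": self.labels,
            }
        )


@dataclass(frozen=True)
class FingerprintSpec:
    """Folded fingerprint parameters.

    kind='morgan' gives ECFP-style circular fingerprints (``radius`` is the
    environment depth, so radius 2 ~ ECFP4); kind='atom_pair' gives folded
    atom-pair fingerprints and ignores ``radius``.
    """

    kind: str = "morgan"
    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.kind not in ("morgan", "atom_pair"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


_GENERATOR_CACHE: dict[FingerprintSpec, object] = {}


def _generator(spec: FingerprintSpec):
    gen = _GENERATOR_CACHE.get(spec)
    if gen is None:
        if spec.kind == "morgan":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius, fpSize=spec.n_bits)
        else:
            gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=spec.n_bits)
        _GENERATOR_CACHE[spec] = gen
    return gen


def fingerprint(record: MoleculeRecord, spec: FingerprintSpec = FingerprintSpec()):
    """Folded bit-vector fingerprint of exactly ``spec.n_bits`` bits."""
    return _generator(spec).GetFingerprint(record.mol)


def fingerprint_many(records: Sequence[MoleculeRecord], spec: FingerprintSpec = FingerprintSpec()):
    gen = _generator(spec)
    return [gen.GetFingerprint(r.mol) for r in records]


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| between two equal-length bit vectors.

    Two all-zero vectors are defined as identical (similarity 1.0); the
    degenerate case is logged because it usually signals an upstream problem.
    """
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(
            f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}"
        )
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        logger.warning("tanimoto of two empty fingerprints; returning 1.0 by convention")
        return 1.0
    return DataStructs.TanimotoSimilarity(a, b)


# Fixed, documented descriptor order.  The Murcko ratio is 0 for acyclic
# molecules (empty scaffold); min/max cycle sizes are 0 when there is no ring.
PHYSCHEM_NAMES: tuple[str, ...] = (
    "hbd",
    "hba",
    "ring_count",
    "rotatable_bonds",
    "tpsa",
    "clogp",
    "molar_refractivity",
    "mol_weight",
    "fraction_csp3",
    "murcko_ratio",
    "heavy_atoms",
    "max_cycle_size",
    "min_cycle_size",
    "min_formal_charge",
    "max_formal_charge",
    "total_formal_charge",
    "chiral_centers",
)


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: tuple[str, ...] = PHYSCHEM_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must be parallel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def physchem_descriptors(record: MoleculeRecord) -> DescriptorVector:
    """Physico-chemical descriptor vector (order given by PHYSCHEM_NAMES)."""
    mol = record.mol
    ring_info = mol.GetRingInfo()
    cycle_sizes = [len(r) for r in ring_info.AtomRings()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    n_heavy = mol.GetNumHeavyAtoms()
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    murcko_ratio = scaffold.GetNumHeavyAtoms() / n_heavy if n_heavy else 0.0
    chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))
    values = [
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumRings(mol),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        rdMolDescriptors.CalcTPSA(mol),
        Crippen.MolLogP(mol),
        Crippen.MolMR(mol),
        Descriptors.MolWt(mol),
        rdMolDescriptors.CalcFractionCSP3(mol),
        murcko_ratio,
        n_heavy,
        max(cycle_sizes) if cycle_sizes else 0,
        min(cycle_sizes) if cycle_sizes else 0,
        min(charges) if charges else 0,
        max(charges) if charges else 0,
        sum(charges),
        chiral,
    ]
    return DescriptorVector(np.asarray(values, dtype=float))


def feature_matrix(
    records: Sequence[MoleculeRecord], feature_spec: FingerprintSpec | str = FingerprintSpec()
) -> np.ndarray:
    """Dense feature matrix for a list of molecules.

    ``feature_spec`` is either a :class:`FingerprintSpec` or the string
    ``"physchem"`` for the descriptor set.
    """
    if isinstance(feature_spec, str):
        if feature_spec != "physchem":
            raise ValueError(f"unknown descriptor set {feature_spec!r}")
        return np.vstack([physchem_descriptors(r).values for r in records])
    fps = fingerprint_many(records, feature_spec)
    out = np.zeros((len(fps), feature_spec.n_bits), dtype=np.uint8)
    for i, fp in enumerate(fps):
        DataStructs.ConvertToNumpyArray(fp, out[i])
    return out


def _dedupe(records: list[MoleculeRecord], labels: list[int]) -> tuple[list, list]:
    seen: dict[str, int] = {}
    out_r, out_l = [], []
    conflicts = 0
    for rec, lab in zip(records, labels):
        if rec.smiles in seen:
            if labels[seen[rec.smiles]] != lab:
                conflicts += 1
            continue
        seen[rec.smiles] = len(out_r)
        out_r.append(rec)
        out_l.append(lab)
    if conflicts:
        logger.warning("%d duplicate molecules had conflicting labels; kept first", conflicts)
    return out_r, out_l


def read_dataset(
    path: str | Path,
    smiles_col: str = "smiles",
    label_col: str = "active",
    name: str | None = None,
    largest_fragment: bool = False,
) -> LabeledDataset:
    """Read a labeled molecule table from CSV or SDF.

    Unparsable SMILES are dropped (count logged); records are canonicalized
    and deduplicated on canonical SMILES, keeping the first occurrence.
    For SDF input, ``label_col`` names the property tag carrying the label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".sdf":
        rows = []
        for mol in Chem.SDMolSupplier(str(path)):
            if mol is None:
                rows.append((None, None))
                continue
            if not mol.HasProp(label_col):
                raise KeyError(f"SDF property {label_col!r} missing on a record")
            rows.append((Chem.MolToSmiles(mol), mol.GetProp(label_col)))
        frame = pd.DataFrame(rows, columns=[smiles_col, label_col])
    else:
        frame = pd.read_csv(path)
        for col in (smiles_col, label_col):
            if col not in frame.columns:
                raise KeyError(f"column {col!r} not found in {path}")

    records, labels, dropped = [], [], 0
    for i, row in frame.iterrows():
        smi = row[smiles_col]
        rec = MoleculeRecord.from_smiles(str(smi), id=f"{path.stem}:{i}", largest_fragment=largest_fragment) if smi is not None and not pd.isna(smi) else None
        if rec is None:
            dropped += 1
            continue
        try:
            lab = int(float(row[label_col]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"label {row[label_col]!r} not coercible to 0/1") from exc
        if lab not in (0, 1):
            raise ValueError(f"label {lab} not in {{0,1}}")
        records.append(rec)
        labels.append(lab)
    if dropped:
        logger.warning("dropped %d unparsable molecules while reading %s", dropped, path)
    records, labels = _dedupe(records, labels)
    if not records:
        raise ValueError(f"no valid molecules in {path}")
    return LabeledDataset(records, labels, name=name or path.stem)


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Read a plain SMILES list (one per line, optional second id column)."""
    records = []
    dropped = 0
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rec = MoleculeRecord.from_smiles(parts[0], id=parts[1] if len(parts) > 1 else f"line:{i}")
        if rec is None:
            dropped += 1
        else:
            records.append(rec)
    if dropped:
        logger.warning("dropped %d unparsable SMILES from %s", dropped, path)
    return records


def write_dataset(data: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as CSV with canonical SMILES."""
    data.to_dataframe().to_csv(path, index=False)
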