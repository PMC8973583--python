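"""Dataset partitioning: held-out split, stratified halves, graph-edit-distance
pairing, and leader-clustering dataset construction.

All operations are deterministic for a fixed seed and are exact partitions:
no molecule is lost or duplicated.  Split plans can be round-tripped through
CSV manifests for reproducibility.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.SimDivFilters.rdSimDivPickers import LeaderPicker

from .chemio import FingerprintSpec, LabeledDataset, MoleculeRecord, fingerprint_many

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "MoleculePair",
    "holdout_split",
    "stratified_split",
    "make_split_plan",
    "pair_by_ged",
    "assign_pairs_to_splits",
    "build_cluster_dataset",
    "substructure_filter",
    "mol_to_graph",
    "graph_edit_distance",
]


@dataclass
class SplitPlan:
    """Held-out set plus the two model-building halves.

    split1 trains the optimization and model-control classifiers, split2 the
    data-control classifier; heldout is used for diagnostics only.  The three
    parts are pairwise disjoint on canonical SMILES.
    """

    heldout: LabeledDataset
    split1: LabeledDataset
    split2: LabeledDataset
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(p.smiles) for p in (self.heldout, self.split1, self.split2)]
        for a, b in combinations(range(3), 2):
            overlap = sets[a] & sets[b]
            if overlap:
                raise ValueError(f"split parts share {len(overlap)} molecules")

    def to_manifest(self) -> pd.DataFrame:
        frames = []
        for tag, part in (("heldout", self.heldout), ("split1", self.split1), ("split2", self.split2)):
            frame = part.to_dataframe()
            frame["partition"] = tag
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def save(self, path: str | Path) -> None:
        self.to_manifest().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "SplitPlan":
        frame = pd.read_csv(path)
        parts = {}
        for tag in ("heldout", "split1", "split2"):
            sub = frame[frame["partition"] == tag]
            parts[tag] = LabeledDataset(
                [MoleculeRecord(id=str(i), smiles=s) for i, s in zip(sub["id"], sub["smiles"])],
                [int(a) for a in sub["active"]],
                name=tag,
            )
        return cls(seed=seed, **parts)


@dataclass
class MoleculePair:
    a: MoleculeRecord
    b: MoleculeRecord
    ged: float


def _stratified_take(data: LabeledDataset, n_take: int, rng: np.random.Generator):
    """Pick n_take indices stratified on label; returns (taken, rest)."""
    labels = np.asarray(data.labels)
    idx_active = np.flatnonzero(labels == 1)
    idx_inactive = np.flatnonzero(labels == 0)
    rng.shuffle(idx_active)
    rng.shuffle(idx_inactive)
    frac = n_take / len(data)
    k_active = int(round(frac * len(idx_active)))
    k_active = min(max(k_active, n_take - len(idx_inactive)), len(idx_active), n_take)
    k_inactive = n_take - k_active
    taken = np.concatenate([idx_active[:k_active], idx_inactive[:k_inactive]])
    rest = np.concatenate([idx_active[k_active:], idx_inactive[k_inactive:]])
    return np.sort(taken), np.sort(rest)


def holdout_split(
    data: LabeledDataset, fraction: float = 0.1, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified held-out split; returns (heldout, remainder).

    ``|heldout| = round(fraction * n)``, active fraction preserved as closely
    as integer counts allow.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_take = int(round(fraction * len(data)))
    rng = np.random.default_rng(seed)
    taken, rest = _stratified_take(data, n_take, rng)
    heldout = data.subset(taken, name=f"{data.name}:heldout")
    remainder = data.subset(rest, name=f"{data.name}:remainder")
    rem_labels = np.asarray(remainder.labels)
    if (rem_labels == 1).sum() < 2 or (rem_labels == 0).sum() < 2:
        raise ValueError("remainder would have fewer than 2 molecules of a class")
    return heldout, remainder


def stratified_split(
    data: LabeledDataset, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """50/50 partition with per-class counts equal within 1.

    For odd class counts the extra molecule's side is decided by the seed.
    """
    labels = np.asarray(data.labels)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 molecules of each class")
    rng = np.random.default_rng(seed)
    side1, side2 = [], []
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        half = len(idx) // 2
        if len(idx) % 2 == 1 and rng.random() < 0.5:
            half += 1
        side1.extend(idx[:half])
        side2.extend(idx[half:])
    return (
        data.subset(np.sort(side1), name=f"{data.name}:split1"),
        data.subset(np.sort(side2), name=f"{data.name}:split2"),
    )


def make_split_plan(
    data: LabeledDataset, holdout_fraction: float = 0.1, seed: int = 0
) -> SplitPlan:
    """Held-out split followed by the stratified split of the remainder."""
    heldout, remainder = holdout_split(data, holdout_fraction, seed)
    split1, split2 = stratified_split(remainder, seed + 1)
    return SplitPlan(heldout=heldout, split1=split1, split2=split2, seed=seed)


# ---------------------------------------------------------------------------
# Graph edit distance pairing


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    """Molecular graph with element node labels and bond-order edge labels."""
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=bond.GetBondTypeAsDouble()
        )
    return g


def _mcs_ged_upper_bound(a: Chem.Mol, b: Chem.Mol, timeout: float) -> float:
    """Upper bound on GED from the maximum common substructure.

    Editing each graph down to the (element- and bond-order-exact) MCS and
    back up costs one edit per extra atom and per extra bond, which bounds
    the true edit distance from above.
    """
    from rdkit.Chem import rdFMCS

    result = rdFMCS.FindMCS(
        [a, b],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        timeout=max(1, int(timeout)),
    )
    return float(
        (a.GetNumAtoms() - result.numAtoms)
        + (b.GetNumAtoms() - result.numAtoms)
        + (a.GetNumBonds() - result.numBonds)
        + (b.GetNumBonds() - result.numBonds)
    )


def graph_edit_distance(
    a: MoleculeRecord, b: MoleculeRecord, timeout: float | None = 10.0
) -> float:
    """Graph edit distance between two molecular graphs.

    Node substitution matches on element, edge substitution on bond order.
    With ``timeout=None`` the exact (exponential-time) search runs to
    completion; with a budget, the result is the best available upper bound:
    the minimum of the networkx best-found mapping within the budget and a
    maximum-common-substructure bound.
    """
    ged = nx.graph_edit_distance(
        mol_to_graph(a.mol),
        mol_to_graph(b.mol),
        node_match=lambda x, y: x["element"] == y["element"],
        edge_match=lambda x, y: x["order"] == y["order"],
        timeout=timeout,
    )
    if timeout is None:
        return float(ged)
    if ged is None:
        logger.warning("GED search found no mapping in budget for %s / %s", a.smiles, b.smiles)
        ged = float("inf")
    return min(float(ged), _mcs_ged_upper_bound(a.mol, b.mol, timeout))


def pair_by_ged(
    data: LabeledDataset,
    max_ged: float = 10,
    timeout: float = 10.0,
) -> tuple[list[MoleculePair], list[MoleculeRecord]]:
    """Greedily pair molecules within each label class by ascending GED.

    Candidate pairs are enumerated within class, prefiltered on heavy-atom
    count difference (> max_ged atoms cannot have GED < max_ged), sorted by
    (GED, canonical-SMILES pair) and accepted most-similar-first while both
    members are unused and GED < max_ged.  Left-over molecules are returned
    unpaired.
    """
    labels = np.asarray(data.labels)
    pairs: list[MoleculePair] = []
    unpaired: list[MoleculeRecord] = []
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        candidates = []
        for pos_i, pos_j in combinations(range(len(idx)), 2):
            ri, rj = data.records[idx[pos_i]], data.records[idx[pos_j]]
            if abs(ri.mol.GetNumAtoms() - rj.mol.GetNumAtoms()) > max_ged:
                continue
            ged = graph_edit_distance(ri, rj, timeout=timeout)
            if ged < max_ged:
                key = tuple(sorted((ri.smiles, rj.smiles)))
                candidates.append((ged, key, pos_i, pos_j))
        candidates.sort(key=lambda c: (c[0], c[1]))
        used: set[int] = set()
        for ged, _key, pos_i, pos_j in candidates:
            if pos_i in used or pos_j in used:
                continue
            used.update((pos_i, pos_j))
            pairs.append(MoleculePair(data.records[idx[pos_i]], data.records[idx[pos_j]], ged))
        unpaired.extend(data.records[idx[p]] for p in range(len(idx)) if p not in used)
    return pairs, unpaired


def assign_pairs_to_splits(
    pairs: list[MoleculePair],
    unpaired: list[MoleculeRecord],
    seed: int = 0,
    labels: dict[str, int] | None = None,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Send one member of each pair to each split; unpaired molecules become
    the evaluation set.

    ``labels`` maps canonical SMILES to activity; if omitted, labels default
    to 0 (the pairing stage already separated classes, so callers who care
    should pass the mapping).
    """
    if not pairs:
        raise ValueError("no pairs to assign")
    rng = np.random.default_rng(seed)

    def lab(rec: MoleculeRecord) -> int:
        return int(labels.get(rec.smiles, 0)) if labels else 0

    s1_r, s1_l, s2_r, s2_l = [], [], [], []
    for pair in pairs:
        first, second = (pair.a, pair.b) if rng.random() < 0.5 else (pair.b, pair.a)
        s1_r.append(first)
        s1_l.append(lab(first))
        s2_r.append(second)
        s2_l.append(lab(second))
    eval_set = LabeledDataset(list(unpaired), [lab(r) for r in unpaired], name="evaluation")
    return (
        LabeledDataset(s1_r, s1_l, name="split1"),
        LabeledDataset(s2_r, s2_l, name="split2"),
        eval_set,
    )


def build_cluster_dataset(
    actives: list[MoleculeRecord],
    inactives: list[MoleculeRecord],
    fp_spec: FingerprintSpec = FingerprintSpec(kind="morgan", radius=2, n_bits=2048),
    distance_threshold: float = 0.6,
    n_clusters: int = 6,
) -> LabeledDataset:
    """Leader-clustering dataset construction.

    Actives are clustered with diversity-picked leaders at the given Tanimoto
    *distance* threshold; every non-leader active joins its nearest leader
    within the threshold (actives further than the threshold from every
    leader form singleton clusters).  The ``n_clusters`` most populated
    clusters are kept, and every inactive whose similarity to any kept active
    exceeds ``1 - distance_threshold`` is added.
    """
    if not 0 < distance_threshold < 1:
        raise ValueError("distance_threshold must be in (0, 1)")
    fps_active = fingerprint_many(actives, fp_spec)
    picker = LeaderPicker()
    leader_idx = list(picker.LazyBitVectorPick(fps_active, len(fps_active), distance_threshold))
    clusters: dict[int, list[int]] = {i: [i] for i in leader_idx}
    leader_set = set(leader_idx)
    singletons: list[int] = []
    for i, fp in enumerate(fps_active):
        if i in leader_set:
            continue
        sims = DataStructs.BulkTanimotoSimilarity(fp, [fps_active[j] for j in leader_idx])
        best = int(np.argmax(sims))
        if 1.0 - sims[best] <= distance_threshold:
            clusters[leader_idx[best]].append(i)
        else:
            singletons.append(i)
    for i in singletons:
        clusters[i] = [i]
    ordered = sorted(clusters.values(), key=lambda members: (-len(members), members[0]))
    if len(ordered) < n_clusters:
        logger.warning(
            "only %d clusters available (requested %d); keeping all", len(ordered), n_clusters
        )
    kept = ordered[:n_clusters]
    kept_active_idx = sorted(i for cluster in kept for i in cluster)
    kept_fps = [fps_active[i] for i in kept_active_idx]

    records = [actives[i] for i in kept_active_idx]
    labels = [1] * len(records)
    sim_cut = 1.0 - distance_threshold
    fps_inactive = fingerprint_many(inactives, fp_spec)
    for rec, fp in zip(inactives, fps_inactive):
        sims = DataStructs.BulkTanimotoSimilarity(fp, kept_fps)
        if max(sims) > sim_cut:
            records.append(rec)
            labels.append(0)
    return LabeledDataset(records, labels, name="clustered")


# Purine skeleton with any-order ring bonds, so it matches both aromatic
# purines (adenine) and partially non-aromatic ones (xanthines like caffeine).
PURINE_CORE_SMARTS = "[#7]~1~[#6]~[#7]~[#6]~2~[#6]~1~[#7]~[#6]~[#7]~[#6]~2"


def substructure_filter(data: LabeledDataset, smarts: str) -> LabeledDataset:
    """Keep records matching a SMARTS pattern, preserving order."""
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    keep = [i for i, rec in enumerate(data.records) if rec.mol.HasSubstructMatch(pattern)]
    return data.subset(keep, name=f"{data.name}:filtered")
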