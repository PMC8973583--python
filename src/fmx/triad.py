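"""The three-classifier experiment: optimization, model-control and
data-control random forests.

C_opt and C_mc are trained on split1 with different random seeds; C_dc is
trained on split2.  All three share the same architecture and feature
representation, so any systematic gap between the scores they assign to the
same molecule reflects either seed-level (model-specific) or split-level
(data-specific) underspecification, not an architectural difference.

Scores are the fraction of trees voting "active" — quantized to k/n_trees —
which is the confidence score of a random-forest classifier.  A
``probability`` mode that averages per-tree leaf class frequencies instead
is available because libraries differ on this definition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .chemio import FingerprintSpec, LabeledDataset, MoleculeRecord, feature_matrix
from .splits import SplitPlan

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "DEFAULT_FOREST",
    "MODIFIED_FOREST",
    "ScoreTriad",
    "train_score_triad",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest architecture shared by the three classifiers.

    The default mirrors scikit-learn's stock classifier (100 trees, leaves
    down to single samples).  The ``modified`` preset (200 trees, at least 3
    samples per leaf) regularizes the forest so that independently trained
    copies agree better on high-scoring molecules.
    """

    n_trees: int = 100
    min_samples_leaf: int = 1
    feature_spec: FingerprintSpec | str = FingerprintSpec(kind="morgan", radius=2, n_bits=1024)
    score_mode: Literal["vote", "probability"] = "vote"

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_trees and min_samples_leaf must be >= 1")
        if self.score_mode not in ("vote", "probability"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")


DEFAULT_FOREST = ClassifierSpec()
MODIFIED_FOREST = ClassifierSpec(n_trees=200, min_samples_leaf=3)


def _fit_forest(data: LabeledDataset, spec: ClassifierSpec, seed: int) -> RandomForestClassifier:
    y = np.asarray(data.labels)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{data.name}: training split must contain both classes")
    X = feature_matrix(data.records, spec.feature_spec)
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        min_samples_leaf=spec.min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _forest_scores(
    forest: RandomForestClassifier, X: np.ndarray, mode: str
) -> np.ndarray:
    if X.shape[0] == 0:
        return np.zeros(0)
    if mode == "probability":
        return forest.predict_proba(X)[:, list(forest.classes_).index(1)]
    votes = np.stack([tree.predict(X) for tree in forest.estimators_])
    return (votes == 1).mean(axis=0)


@dataclass
class ScoreTriad:
    """Three fitted forests with their score functions S_opt, S_mc, S_dc."""

    c_opt: RandomForestClassifier
    c_mc: RandomForestClassifier
    c_dc: RandomForestClassifier
    spec: ClassifierSpec
    seeds: tuple[int, int, int]
    plan: SplitPlan | None = field(default=None, repr=False)

    def score(
        self, mols: Sequence[MoleculeRecord]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(s_opt, s_mc, s_dc) score vectors parallel to ``mols``."""
        X = feature_matrix(mols, self.spec.feature_spec) if len(mols) else np.zeros((0, 1))
        return tuple(
            _forest_scores(forest, X, self.spec.score_mode)
            for forest in (self.c_opt, self.c_mc, self.c_dc)
        )

    def scorer(self, channel: str = "opt"):
        """Batch scoring callable for one channel (for use as a GA reward)."""
        forest = {"opt": self.c_opt, "mc": self.c_mc, "dc": self.c_dc}[channel]

        def _score(mols: Sequence[MoleculeRecord]) -> np.ndarray:
            X = feature_matrix(mols, self.spec.feature_spec) if len(mols) else np.zeros((0, 1))
            return _forest_scores(forest, X, self.spec.score_mode)

        return _score

    def auc(self, eval_set: LabeledDataset) -> tuple[float, float, float]:
        """ROC-AUC of each score channel against the evaluation labels."""
        y = np.asarray(eval_set.labels)
        if len(np.unique(y)) < 2:
            raise ValueError("evaluation set must contain both classes")
        return tuple(float(roc_auc_score(y, s)) for s in self.score(eval_set.records))

    def save(self, path: str | Path) -> None:
        """Serialize the bundle (forests + spec + training manifest hash)."""
        manifest_hash = None
        if self.plan is not None:
            digest = hashlib.sha256(
                self.plan.to_manifest().to_csv(index=False).encode()
            ).hexdigest()
            manifest_hash = digest
        joblib.dump(
            {
                "forests": (self.c_opt, self.c_mc, self.c_dc),
                "spec": self.spec,
                "seeds": self.seeds,
                "manifest_sha256": manifest_hash,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScoreTriad":
        bundle = joblib.load(path)
        c_opt, c_mc, c_dc = bundle["forests"]
        return cls(c_opt=c_opt, c_mc=c_mc, c_dc=c_dc, spec=bundle["spec"], seeds=bundle["seeds"])


def train_score_triad(
    plan: SplitPlan,
    spec: ClassifierSpec = DEFAULT_FOREST,
    seed_opt: int = 0,
    seed_mc: int = 1,
    seed_dc: int = 2,
    allow_equal_seeds: bool = False,
) -> ScoreTriad:
    """Train C_opt and C_mc on split1 (different seeds) and C_dc on split2.

    The forests are fully deterministic given the seeds.  ``seed_opt`` must
    differ from ``seed_mc`` unless ``allow_equal_seeds`` is set, which is the
    degenerate control where S_mc collapses onto S_opt exactly.
    """
    if seed_opt == seed_mc and not allow_equal_seeds:
        raise ValueError(
            "seed_opt == seed_mc makes the model control identical to the "
            "optimization model; pass allow_equal_seeds=True if intended"
        )
    return ScoreTriad(
        c_opt=_fit_forest(plan.split1, spec, seed_opt),
        c_mc=_fit_forest(plan.split1, spec, seed_mc),
        c_dc=_fit_forest(plan.split2, spec, seed_dc),
        spec=spec,
        seeds=(seed_opt, seed_mc, seed_dc),
        plan=plan,
    )
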