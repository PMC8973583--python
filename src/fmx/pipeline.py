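"""End-to-end orchestration of the divergence experiment.

Two entry points, both presented as model-like objects:

* :class:`FailureModeExperiment` — the full experiment: held-out split,
  stratified split-1/2, triad training, Topliss augmentation of the
  held-out set, conditional score tables, MAD curves and bias report, then
  N goal-directed GA runs started from the held-out set with tolerance-band
  overlays and band-compliance fractions.  ``fit()`` returns a
  :class:`FailureModeResults` with a ``summary()`` table.
* :class:`DivergenceAudit` — the pre-generation check a practitioner runs
  before trusting a model for goal-directed generation: everything above
  except the generation runs, plus a pass/warn flag on the top-decile MAD.

A single master seed fans out to per-stage seeds through a documented
counter scheme, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chemio import LabeledDataset, read_dataset
from .diagnostics import (
    BiasReport,
    ConditionalScoreTable,
    MADCurve,
    ToleranceBand,
    TrajectorySummary,
    band_compliance,
    bias_similarity_report,
    conditional_score_table,
    mad_at_quantile,
    mad_curve,
    tolerance_band,
    trajectory_summary,
)
from .graphga import GAConfig, Trajectory, evolve
from .splits import SplitPlan, make_split_plan
from .synthdata import SynthesisConfig, generate_library, regime_preset
from .topliss import ToplissScheme, augment_set, default_scheme
from .triad import DEFAULT_FOREST, ClassifierSpec, ScoreTriad, train_score_triad

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "FailureModeExperiment",
    "FailureModeResults",
    "DivergenceAudit",
    "AuditResults",
    "PipelineStageError",
    "run_failure_mode_experiment",
    "run_divergence_audit",
    "stage_seed",
]

# Stage indices of the seed fan-out (master seed -> per-stage integer seed).
_STAGES = {
    "split": 0,
    "triad_opt": 1,
    "triad_mc": 2,
    "triad_dc": 3,
    "topliss": 4,
    "band": 5,
    "ga": 6,  # run r uses stage index 6 + r
}


def stage_seed(master_seed: int, stage: str, offset: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    index = _STAGES[stage] + offset
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; artifacts from earlier stages are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of the experiment, with study-condition defaults."""

    holdout_fraction: float = 0.1
    classifier: ClassifierSpec = DEFAULT_FOREST
    scheme: ToplissScheme = field(default_factory=default_scheme)
    target_fold: float = 10.0
    ga: GAConfig = GAConfig()
    n_runs: int = 10
    n_bins: int = 25
    n_draws: int = 10
    alpha: float = 0.95
    top_pct: float = 5.0
    mad_quantile: float = 0.9
    mad_warn_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _manifest(config: ExperimentConfig, data: LabeledDataset) -> dict:
    import sklearn
    import rdkit

    return {
        "fmx_version": __version__,
        "python": platform.python_version(),
        "sklearn": sklearn.__version__,
        "rdkit": rdkit.__version__,
        "dataset": data.name,
        "n_molecules": len(data),
        "n_active": data.n_active,
        "seed": config.seed,
        "stage_seeds": {k: stage_seed(config.seed, k) for k in _STAGES},
        "classifier": {
            "n_trees": config.classifier.n_trees,
            "min_samples_leaf": config.classifier.min_samples_leaf,
            "score_mode": config.classifier.score_mode,
        },
        "ga": asdict(config.ga),
        "n_runs": config.n_runs,
        "n_bins": config.n_bins,
        "n_draws": config.n_draws,
        "alpha": config.alpha,
    }


class _ExperimentBase:
    """Shared staging for the audit and the full experiment."""

    def __init__(self, data: LabeledDataset, config: ExperimentConfig | None = None):
        if data.n_active < 4 or (len(data) - data.n_active) < 4:
            raise ValueError("dataset too small or single-class for the triad experiment")
        self.data = data
        self.config = config or ExperimentConfig()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, smiles_col: str = "smiles", label_col: str = "active",
        config: ExperimentConfig | None = None, name: str = "dataframe",
    ):
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            frame.to_csv(fh.name, index=False)
            data = read_dataset(fh.name, smiles_col, label_col, name=name)
        return cls(data, config)

    @classmethod
    def from_csv(cls, path, smiles_col: str = "smiles", label_col: str = "active",
                 config: ExperimentConfig | None = None):
        return cls(read_dataset(path, smiles_col, label_col), config)

    @classmethod
    def from_synthetic(cls, regime: str, seed: int = 0, config: ExperimentConfig | None = None):
        """Build from a synthetic regime preset; the preset's classifier spec
        overrides the config's unless a config explicitly provided one."""
        synth_cfg, clf_spec = regime_preset(regime, seed=seed)
        data = generate_library(synth_cfg)
        if config is None:
            config = ExperimentConfig(classifier=clf_spec, seed=seed)
        return cls(data, config)

    # -- shared stages -----------------------------------------------------

    def _stage_splits(self) -> SplitPlan:
        cfg = self.config
        return make_split_plan(self.data, cfg.holdout_fraction, stage_seed(cfg.seed, "split"))

    def _stage_triad(self, plan: SplitPlan, seed_mc_equals_opt: bool = False) -> ScoreTriad:
        cfg = self.config
        s_opt = stage_seed(cfg.seed, "triad_opt")
        s_mc = s_opt if seed_mc_equals_opt else stage_seed(cfg.seed, "triad_mc")
        return train_score_triad(
            plan, cfg.classifier, seed_opt=s_opt, seed_mc=s_mc,
            seed_dc=stage_seed(cfg.seed, "triad_dc"), allow_equal_seeds=seed_mc_equals_opt,
        )

    def _stage_augment(self, plan: SplitPlan):
        cfg = self.config
        return augment_set(
            plan.heldout.records, cfg.scheme, cfg.target_fold, stage_seed(cfg.seed, "topliss")
        )


@dataclass
class AuditResults:
    """Pre-generation divergence audit: conditional diagnostics only."""

    data_name: str
    plan: SplitPlan
    triad: ScoreTriad
    augmented_n: int
    aucs: tuple[float, float, float]
    table_mc: ConditionalScoreTable
    table_dc: ConditionalScoreTable
    mad_curve_mc: MADCurve
    mad_curve_dc: MADCurve
    mad_top_mc: float
    mad_top_dc: float
    bias: BiasReport
    warn_threshold: float

    @property
    def flag(self) -> str:
        """'warn' when top-decile divergence exceeds the threshold on either
        control, else 'pass'."""
        worst = max(self.mad_top_mc, self.mad_top_dc)
        return "warn" if worst > self.warn_threshold else "pass"

    def summary(self) -> str:
        lines = [
            "Divergence audit" + " " * 24 + f"dataset: {self.data_name}",
            "=" * 64,
            f"molecules: {len(self.plan.heldout) + len(self.plan.split1) + len(self.plan.split2):>6}"
            f"    held-out: {len(self.plan.heldout)}    augmented held-out: {self.augmented_n}",
            f"ROC-AUC     S_opt {self.aucs[0]:.3f}   S_mc {self.aucs[1]:.3f}   S_dc {self.aucs[2]:.3f}",
            f"top-decile MAD    model-control {self.mad_top_mc:+.3f}   data-control {self.mad_top_dc:+.3f}",
            f"bias (median NN similarity gap split1-split2): {self.bias.median_gap:+.3f}",
            "-" * 64,
            f"flag: {self.flag.upper()}  (warn threshold on top-decile MAD: {self.warn_threshold})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "dataset": self.data_name,
            "auc_opt": self.aucs[0],
            "auc_mc": self.aucs[1],
            "auc_dc": self.aucs[2],
            "mad_top_decile_mc": self.mad_top_mc,
            "mad_top_decile_dc": self.mad_top_dc,
            "bias_median_gap": self.bias.median_gap,
            "flag": self.flag,
        }


class DivergenceAudit(_ExperimentBase):
    """The pre-generation check: does the triad already diverge on the data?

    ``fit()`` runs held-out split, triad training, Topliss augmentation and
    the conditional diagnostics; no molecules are generated.
    """

    def fit(self) -> AuditResults:
        cfg = self.config
        stage = "splits"
        try:
            plan = self._stage_splits()
            stage = "triad"
            triad = self._stage_triad(plan)
            stage = "augment"
            augmented = self._stage_augment(plan)
            stage = "diagnostics"
            s_opt, s_mc, s_dc = triad.score(augmented)
            table_mc = conditional_score_table(s_opt, s_mc, cfg.n_bins)
            table_dc = conditional_score_table(s_opt, s_dc, cfg.n_bins)
            h_opt, _h_mc, _h_dc = triad.score(plan.heldout.records)
            bias = bias_similarity_report(
                plan.heldout.records, h_opt, plan.split1, plan.split2, cfg.top_pct
            )
            return AuditResults(
                data_name=self.data.name,
                plan=plan,
                triad=triad,
                augmented_n=len(augmented),
                aucs=triad.auc(plan.heldout),
                table_mc=table_mc,
                table_dc=table_dc,
                mad_curve_mc=mad_curve(s_opt, s_mc),
                mad_curve_dc=mad_curve(s_opt, s_dc),
                mad_top_mc=mad_at_quantile(s_opt, s_mc, cfg.mad_quantile),
                mad_top_dc=mad_at_quantile(s_opt, s_dc, cfg.mad_quantile),
                bias=bias,
                warn_threshold=cfg.mad_warn_threshold,
            )
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc


@dataclass
class FailureModeResults:
    """Everything the full experiment computes.

    ``compliance_mc`` / ``compliance_dc`` are the fractions of timesteps at
    which the observed median control score stays at or above the lower
    tolerance bound; values near 1 mean the divergence seen during
    generation is explained by the data distribution itself.
    """

    audit: AuditResults
    trajectories: list[Trajectory]
    summary_table: TrajectorySummary
    band_mc: ToleranceBand
    band_dc: ToleranceBand
    compliance_mc: float
    compliance_dc: float
    trace_mc: np.ndarray
    trace_dc: np.ndarray
    manifest: dict

    def summary(self) -> str:
        a = self.audit
        final = self.summary_table.table
        last = final[final["generation"] == final["generation"].max()]
        row = {r["channel"]: r["median"] for _, r in last.iterrows()}
        lines = [
            a.summary(),
            "",
            "Goal-directed generation" + " " * 16 + f"runs: {len(self.trajectories)}",
            "=" * 64,
            f"final median scores   S_opt {row.get('opt', float('nan')):.3f}"
            f"   S_mc {row.get('mc', float('nan')):.3f}   S_dc {row.get('dc', float('nan')):.3f}",
            f"tolerance-band compliance   model-control {self.compliance_mc:.3f}"
            f"   data-control {self.compliance_dc:.3f}",
            f"(fraction of timesteps with median control >= lower {self.band_dc.alpha:.0%} bound)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = self.audit.to_dict()
        out.update(
            {
                "n_runs": len(self.trajectories),
                "band_compliance_mc": self.compliance_mc,
                "band_compliance_dc": self.compliance_dc,
            }
        )
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.audit.plan.save(out_dir / "splits.csv")
        for i, traj in enumerate(self.trajectories):
            traj.save(out_dir / f"trajectory_run{i}.csv")
        self.summary_table.table.to_csv(out_dir / "trajectory_summary.csv", index=False)
        self.band_mc.to_dataframe().to_csv(out_dir / "tolerance_band_mc.csv", index=False)
        self.band_dc.to_dataframe().to_csv(out_dir / "tolerance_band_dc.csv", index=False)
        self.audit.mad_curve_dc.to_dataframe().to_csv(out_dir / "mad_curve_dc.csv", index=False)
        self.audit.mad_curve_mc.to_dataframe().to_csv(out_dir / "mad_curve_mc.csv", index=False)
        self.audit.bias.to_dataframe().to_csv(out_dir / "bias_report.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


class FailureModeExperiment(_ExperimentBase):
    """The full control-score experiment on one dataset.

    ``fit()`` stages: held-out split -> stratified split-1/2 -> triad
    training -> Topliss augmentation -> conditional tables + MAD + bias
    report -> N GA runs seeded from the (un-augmented) held-out set with
    control tracking -> trajectory summary -> tolerance bands ->
    band compliance.
    """

    def fit(self, seed_mc_equals_opt: bool = False) -> FailureModeResults:
        cfg = self.config
        stage = "audit"
        try:
            audit = _AuditView(self, seed_mc_equals_opt).fit()
            triad = audit.triad
            stage = "generation"
            trajectories = []
            for run in range(cfg.n_runs):
                ga_cfg = GAConfig(
                    population_size=cfg.ga.population_size,
                    n_generations=cfg.ga.n_generations,
                    mutation_rate=cfg.ga.mutation_rate,
                    offspring_per_generation=cfg.ga.offspring_per_generation,
                    seed=stage_seed(cfg.seed, "ga", offset=run),
                )
                trajectories.append(
                    evolve(
                        audit.plan.heldout.records,
                        triad.scorer("opt"),
                        ga_cfg,
                        control_scorers={"mc": triad.scorer("mc"), "dc": triad.scorer("dc")},
                    )
                )
            stage = "summary"
            summary = trajectory_summary(trajectories)
            stage = "tolerance"
            band_seed = stage_seed(cfg.seed, "band")
            # P_t[S_opt] is the distribution of optimization scores sampled at
            # step t; with several runs that sample is the pooled population
            pooled = [
                np.concatenate([t.steps[i].s_opt for t in trajectories])
                for i in range(len(trajectories[0].steps))
            ]
            band_mc = tolerance_band(audit.table_mc, pooled, cfg.n_draws, cfg.alpha, band_seed)
            band_dc = tolerance_band(audit.table_dc, pooled, cfg.n_draws, cfg.alpha, band_seed + 1)
            comp_mc, trace_mc = band_compliance(summary, band_mc, "mc")
            comp_dc, trace_dc = band_compliance(summary, band_dc, "dc")
            return FailureModeResults(
                audit=audit,
                trajectories=trajectories,
                summary_table=summary,
                band_mc=band_mc,
                band_dc=band_dc,
                compliance_mc=comp_mc,
                compliance_dc=comp_dc,
                trace_mc=trace_mc,
                trace_dc=trace_dc,
                manifest=_manifest(cfg, self.data),
            )
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc


class _AuditView(DivergenceAudit):
    """Audit stage bound to an experiment, honoring the degenerate-seed flag."""

    def __init__(self, parent: _ExperimentBase, seed_mc_equals_opt: bool):
        super().__init__(parent.data, parent.config)
        self._degenerate = seed_mc_equals_opt

    def _stage_triad(self, plan: SplitPlan, seed_mc_equals_opt: bool = False) -> ScoreTriad:
        return super()._stage_triad(plan, seed_mc_equals_opt or self._degenerate)


def run_failure_mode_experiment(
    data: LabeledDataset, config: ExperimentConfig | None = None, out_dir: str | Path | None = None
) -> FailureModeResults:
    """Functional wrapper: fit the full experiment, optionally write artifacts."""
    results = FailureModeExperiment(data, config).fit()
    if out_dir is not None:
        results.save(out_dir)
    return results


def run_divergence_audit(
    data: LabeledDataset, config: ExperimentConfig | None = None
) -> AuditResults:
    """Functional wrapper for the pre-generation audit."""
    return DivergenceAudit(data, config).fit()
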