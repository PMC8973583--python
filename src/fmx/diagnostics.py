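"""Core diagnostics: conditional control-score tables, empirical tolerance
bands, MAD curves, trajectory envelopes and split-similarity bias reports.

The central question these statistics answer: when a generator drives the
optimization score S_opt upward, do the control scores S_mc / S_dc fall
below what the *original data distribution* would predict for molecules with
the same S_opt?  The conditional law P[S_ctrl | S_opt] is estimated by
binning a reference (held-out, usually analog-augmented) sample of the data
distribution on S_opt; tolerance bands propagate that law along a
generation trajectory; the MAD curve summarizes the conditional gap as a
function of an S_opt threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import DataStructs

from .chemio import FingerprintSpec, LabeledDataset, MoleculeRecord, fingerprint_many
from .graphga import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionalScoreTable",
    "conditional_score_table",
    "ToleranceBand",
    "tolerance_band",
    "MADCurve",
    "mad_curve",
    "mad_at_quantile",
    "TrajectorySummary",
    "trajectory_summary",
    "band_compliance",
    "BiasReport",
    "bias_similarity_report",
]


@dataclass
class ConditionalScoreTable:
    """Binned empirical estimate of P[S_ctrl | S_opt].

    The score range [0, 1] (the codomain of tree-vote ratios) is divided
    into ``n_bins`` equal parts; bin i holds the control scores of the
    reference molecules whose optimization score falls in bin i (last bin
    right-closed).
    """

    n_bins: int
    bin_edges: np.ndarray
    samples: list[np.ndarray]

    @property
    def counts(self) -> np.ndarray:
        return np.asarray([len(s) for s in self.samples])

    @property
    def empty_bins(self) -> np.ndarray:
        return np.flatnonzero(self.counts == 0)

    def bin_of(self, s_opt: np.ndarray) -> np.ndarray:
        idx = np.floor(np.asarray(s_opt) * self.n_bins).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def nearest_occupied(self, bin_idx: int) -> int:
        occupied = np.flatnonzero(self.counts > 0)
        return int(occupied[np.argmin(np.abs(occupied - bin_idx))])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, sample in enumerate(self.samples):
            for value in sample:
                rows.append({"bin": i, "bin_left": self.bin_edges[i], "s_ctrl": value})
        return pd.DataFrame(rows)


def conditional_score_table(
    s_opt: np.ndarray, s_ctrl: np.ndarray, n_bins: int = 25
) -> ConditionalScoreTable:
    """Bin reference control scores by the optimization score of the same
    molecule, over ``n_bins`` equal-width bins of [0, 1]."""
    s_opt = np.asarray(s_opt, dtype=float)
    s_ctrl = np.asarray(s_ctrl, dtype=float)
    if s_opt.size == 0:
        raise ValueError("empty reference sample")
    if s_opt.shape != s_ctrl.shape:
        raise ValueError("score vectors must be parallel")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if s_opt.min() < 0 or s_opt.max() > 1 or s_ctrl.min() < 0 or s_ctrl.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.floor(s_opt * n_bins).astype(int), 0, n_bins - 1)
    samples = [s_ctrl[idx == i] for i in range(n_bins)]
    table = ConditionalScoreTable(n_bins=n_bins, bin_edges=edges, samples=samples)
    if len(table.empty_bins):
        logger.debug("conditional table has %d empty bins", len(table.empty_bins))
    return table


@dataclass
class ToleranceBand:
    """Per-timestep empirical tolerance interval for expected control scores.

    At each timestep the interval is expected to contain ``alpha`` of the
    population of control scores implied by the conditional law and the
    observed S_opt distribution.
    """

    generations: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    n_draws: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound above upper bound")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": self.generations, "lower": self.lower, "upper": self.upper}
        )


def tolerance_band(
    table: ConditionalScoreTable,
    trajectory: Trajectory | Sequence[np.ndarray],
    n_draws: int = 10,
    alpha: float = 0.95,
    seed: int = 0,
    min_bin_count: int = 5,
) -> ToleranceBand:
    """Empirical tolerance band for control scores along a trajectory.

    For every sampled molecule at timestep t, ``n_draws`` control scores are
    drawn with replacement from the empirical conditional sample of the bin
    its S_opt falls in; the band is the ((1-alpha)/2, (1+alpha)/2) quantile
    pair of the pooled draws.

    Tail quantiles cannot be estimated from one or two observations, so a
    bin holding fewer than ``min_bin_count`` reference samples borrows from
    its nearest occupied neighbours (by bin distance, lower side first on
    ties) until that occupancy is reached; an empty bin is the limiting
    case of the same rule.  Borrow events are logged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.all(table.counts == 0):
        raise ValueError("conditional table is empty")
    if isinstance(trajectory, Trajectory):
        generations = trajectory.generations
        per_step = trajectory.channel("opt")
    else:
        per_step = [np.asarray(v, dtype=float) for v in trajectory]
        generations = np.arange(len(per_step))

    widened = 0
    pooled_samples: dict[int, np.ndarray] = {}
    for b in range(table.n_bins):
        if len(table.samples[b]) >= min_bin_count:
            pooled_samples[b] = table.samples[b]
            continue
        order = sorted(range(table.n_bins), key=lambda j: (abs(j - b), j))
        parts, count = [], 0
        for j in order:
            if len(table.samples[j]):
                parts.append(table.samples[j])
                count += len(table.samples[j])
            if count >= min_bin_count:
                break
        pooled_samples[b] = np.concatenate(parts)
        widened += 1

    rng = np.random.default_rng(seed)
    lower, upper = [], []
    for s_opt in per_step:
        bins = table.bin_of(s_opt)
        draws = [
            rng.choice(pooled_samples[int(b)], size=n_draws, replace=True) for b in bins
        ]
        pooled = np.concatenate(draws)
        lower.append(np.quantile(pooled, (1 - alpha) / 2))
        upper.append(np.quantile(pooled, (1 + alpha) / 2))
    if widened:
        logger.info(
            "tolerance_band: %d bins below %d samples borrowed from neighbours",
            widened, min_bin_count,
        )
    return ToleranceBand(
        generations=np.asarray(generations),
        lower=np.asarray(lower),
        upper=np.asarray(upper),
        alpha=alpha,
        n_draws=n_draws,
    )


@dataclass
class MADCurve:
    """Mean difference between S_opt and a control score, as a function of
    an S_opt threshold x: mad(x) = mean(S_opt - S_ctrl | S_opt > x).

    The curve stops at x_max, the largest observed S_opt, beyond which no
    molecule supports the mean.
    """

    thresholds: np.ndarray
    values: np.ndarray
    x_max: float
    absolute: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "mad": self.values})


def mad_curve(
    s_opt: np.ndarray,
    s_ctrl: np.ndarray,
    thresholds: np.ndarray | None = None,
    absolute: bool = False,
) -> MADCurve:
    """MAD of control vs optimization scores above each threshold.

    Signed by default (positive when the control lags the optimization
    score); ``absolute=True`` averages |S_opt - S_ctrl| instead.  Thresholds
    with no supporting molecule are omitted.
    """
    s_opt = np.asarray(s_opt, dtype=float)
    s_ctrl = np.asarray(s_ctrl, dtype=float)
    if s_opt.shape != s_ctrl.shape or s_opt.size == 0:
        raise ValueError("score vectors must be parallel and non-empty")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 51)
    thresholds = np.asarray(thresholds, dtype=float)
    diff = np.abs(s_opt - s_ctrl) if absolute else s_opt - s_ctrl
    x_max = float(s_opt.max())
    kept_x, kept_v = [], []
    for x in thresholds:
        mask = s_opt > x
        if not mask.any():
            continue
        kept_x.append(x)
        kept_v.append(float(diff[mask].mean()))
    return MADCurve(
        thresholds=np.asarray(kept_x), values=np.asarray(kept_v), x_max=x_max, absolute=absolute
    )


def mad_at_quantile(
    s_opt: np.ndarray, s_ctrl: np.ndarray, quantile: float = 0.9, absolute: bool = False
) -> float:
    """MAD over molecules whose S_opt is at or above the given quantile.

    The top decile (quantile 0.9) is the working summary of conditional
    divergence used by the audit.
    """
    s_opt = np.asarray(s_opt, dtype=float)
    s_ctrl = np.asarray(s_ctrl, dtype=float)
    cut = np.quantile(s_opt, quantile)
    mask = s_opt >= cut
    diff = np.abs(s_opt - s_ctrl) if absolute else s_opt - s_ctrl
    return float(diff[mask].mean())


@dataclass
class TrajectorySummary:
    """Across-run envelope of per-run per-timestep mean scores.

    For each run the mean score of the sampled population at each timestep
    is taken; the summary is the median, interquartile range and central 95%
    envelope of those means across runs, per channel.
    """

    generations: np.ndarray
    table: pd.DataFrame  # columns: channel, generation, median, q25, q75, q025, q975

    def channel(self, name: str) -> pd.DataFrame:
        return self.table[self.table["channel"] == name].reset_index(drop=True)


def trajectory_summary(runs: Sequence[Trajectory]) -> TrajectorySummary:
    """Median / IQR / 95% envelope of per-run mean scores at each timestep."""
    if not runs:
        raise ValueError("need at least one run")
    grids = [tuple(r.generations.tolist()) for r in runs]
    if len(set(grids)) != 1:
        raise ValueError("runs must share the same timestep grid")
    generations = runs[0].generations
    channels = [name for name in ("opt", "mc", "dc") if runs[0].steps[0].__getattribute__(f"s_{name}") is not None]
    rows = []
    for name in channels:
        means = np.vstack([r.per_step_mean(name) for r in runs])  # runs x steps
        rows.append(
            pd.DataFrame(
                {
                    "channel": name,
                    "generation": generations,
                    "median": np.median(means, axis=0),
                    "q25": np.quantile(means, 0.25, axis=0),
                    "q75": np.quantile(means, 0.75, axis=0),
                    "q025": np.quantile(means, 0.025, axis=0),
                    "q975": np.quantile(means, 0.975, axis=0),
                }
            )
        )
    return TrajectorySummary(generations=generations, table=pd.concat(rows, ignore_index=True))


def band_compliance(
    summary: TrajectorySummary | np.ndarray, band: ToleranceBand, channel: str = "dc"
) -> tuple[float, np.ndarray]:
    """Fraction of timesteps where the observed median control score stays
    at or above the band's lower bound (plus the per-timestep trace)."""
    if isinstance(summary, TrajectorySummary):
        observed = summary.channel(channel)["median"].to_numpy()
    else:
        observed = np.asarray(summary, dtype=float)
    if observed.shape != band.lower.shape:
        raise ValueError("observed series and band are on different grids")
    trace = observed >= band.lower
    return float(trace.mean()), trace


@dataclass
class BiasReport:
    """Nearest-neighbor similarity of top-scored held-out molecules to the
    two training splits.

    A markedly higher similarity to split1 than split2 among the molecules
    C_opt scores highest means the apparent 'bias toward split1' predates
    any generation run.
    """

    smiles: list[str]
    s_opt: np.ndarray
    sim_split1: np.ndarray
    sim_split2: np.ndarray

    @property
    def quantiles(self) -> pd.DataFrame:
        qs = [0.05, 0.25, 0.5, 0.75, 0.95]
        return pd.DataFrame(
            {
                "quantile": qs,
                "sim_split1": np.quantile(self.sim_split1, qs),
                "sim_split2": np.quantile(self.sim_split2, qs),
            }
        )

    @property
    def median_gap(self) -> float:
        return float(np.median(self.sim_split1) - np.median(self.sim_split2))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": self.smiles,
                "s_opt": self.s_opt,
                "sim_split1": self.sim_split1,
                "sim_split2": self.sim_split2,
            }
        )


def _nn_similarities(query_fps, ref_fps) -> np.ndarray:
    return np.asarray(
        [max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps)) for fp in query_fps]
    )


def bias_similarity_report(
    heldout: Sequence[MoleculeRecord],
    s_opt: np.ndarray,
    split1: LabeledDataset | Sequence[MoleculeRecord],
    split2: LabeledDataset | Sequence[MoleculeRecord],
    top_pct: float = 5.0,
    fp_spec: FingerprintSpec = FingerprintSpec(kind="morgan", radius=2, n_bits=1024),
) -> BiasReport:
    """Nearest-neighbor Tanimoto similarity of the top-``top_pct``-percent
    scored held-out molecules to each training split."""
    if not 0 < top_pct < 100:
        raise ValueError("top_pct must be in (0, 100)")
    records1 = split1.records if isinstance(split1, LabeledDataset) else list(split1)
    records2 = split2.records if isinstance(split2, LabeledDataset) else list(split2)
    if not records1 or not records2:
        raise ValueError("splits must be non-empty")
    s_opt = np.asarray(s_opt, dtype=float)
    n_select = max(1, int(np.ceil(len(heldout) * top_pct / 100.0)))
    order = np.argsort(-s_opt, kind="stable")[:n_select]
    selected = [heldout[i] for i in order]
    query_fps = fingerprint_many(selected, fp_spec)
    sims1 = _nn_similarities(query_fps, fingerprint_many(records1, fp_spec))
    sims2 = _nn_similarities(query_fps, fingerprint_many(records2, fp_spec))
    return BiasReport(
        smiles=[r.smiles for r in selected],
        s_opt=s_opt[order],
        sim_split1=sims1,
        sim_split2=sims2,
    )


# ---------------------------------------------------------------------------
# Plotting helpers (thin, optional)


def plot_mad_curve(curve: MADCurve, ax=None, **kwargs):
    """Plot a MAD curve; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.thresholds, curve.values, **kwargs)
    ax.set_xlabel("optimization score threshold x")
    ax.set_ylabel("MAD(S_opt - S_ctrl | S_opt > x)")
    return ax


def plot_trajectory_with_band(
    summary: TrajectorySummary, band: ToleranceBand, channel: str = "dc", ax=None
):
    """Overlay the observed control-score envelope on the tolerance band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    obs = summary.channel(channel)
    ax.fill_between(band.generations, band.lower, band.upper, alpha=0.2, label="tolerance band")
    ax.fill_between(obs["generation"], obs["q25"], obs["q75"], alpha=0.3, label=f"{channel} IQR")
    ax.plot(obs["generation"], obs["median"], lw=2, label=f"median S_{channel}")
    opt = summary.channel("opt")
    ax.plot(opt["generation"], opt["median"], lw=1, ls="--", label="median S_opt")
    ax.set_xlabel("generation")
    ax.set_ylabel("score")
    ax.legend()
    return ax
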