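"""Window-length and cluster sweeps, demographics, and reports.

The full experiment is: generate or load a cohort; re-reference and
band-limit each recording; then, for every window length from 5 to
12 s, epoch the recordings, extract the 722-column feature table and
run cross-validation for each of the six classification problems.
The cluster sweep repeats the 12 s analysis on each anatomical
electrode cluster. Demographic statistics (Welch ANOVA on age, which
tolerates unequal group variances, and a tie-corrected Kruskal–Wallis
test with mean ranks on MMSE) mirror how such cohorts are reported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import PROBLEMS, MetricSet, build_dataset, run_cv
from .cohort import SubjectRecord
from .features import EstimatorParams, extract_features
from .montage import CLUSTERS
from .preprocess import apply_bandlimit, common_average_reference, segment

logger = logging.getLogger(__name__)

__all__ = [
    "DemographicsResult",
    "SweepResult",
    "kruskal_wallis",
    "welch_anova",
    "demographics",
    "preprocess_cohort",
    "cohort_features",
    "window_sweep",
    "cluster_sweep",
    "report",
]

WINDOWS: Tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 12)


# ---------------------------------------------------------------------------
# demographic statistics


@dataclass
class DemographicsResult:
    """Welch ANOVA (age) and Kruskal–Wallis (MMSE) cohort statistics."""

    welch_F: float
    welch_df: Tuple[float, float]
    welch_p: float
    kw_H: float
    kw_p: float
    mean_ranks: Dict[str, float]


def kruskal_wallis(groups: Dict[str, Sequence[float]]):
    """Tie-corrected Kruskal–Wallis H with per-group mean ranks.

    Returns ``(H, p, mean_ranks)``. Mean ranks use midranks for ties;
    the tie correction divides H by 1 - sum(t^3 - t)/(N^3 - N). With
    every value identical H = 0 and p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    values = [np.asarray(groups[g], dtype=np.float64) for g in names]
    if any(v.size == 0 for v in values):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: Dict[str, float] = {}
    h = 0.0
    start = 0
    for g, v in zip(names, values):
        r = ranks[start:start + v.size]
        mean_ranks[g] = float(r.mean())
        h += v.size * (r.mean() - (n_total + 1) / 2) ** 2
        start += v.size
    h *= 12.0 / (n_total * (n_total + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((tie_counts ** 3 - tie_counts).sum()
                 / (n_total ** 3 - n_total))
    if tie == 0.0:  # all values identical
        return 0.0, 1.0, mean_ranks
    h /= tie
    p = float(stats.chi2.sf(h, df=len(names) - 1))
    return float(h), p, mean_ranks


def welch_anova(groups: Dict[str, Sequence[float]]):
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, (df_between, df_within), p)`` with the Welch–
    Satterthwaite fractional denominator df. Groups need >= 2 values
    and nonzero variance.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(groups[g]) for g in names], dtype=np.float64)
    if (ns < 2).any():
        raise ValueError("every group needs at least two values")
    means = np.array([np.mean(groups[g]) for g in names])
    variances = np.array([np.var(groups[g], ddof=1) for g in names])
    if (variances == 0).any():
        raise ValueError("zero within-group variance")
    w = ns / variances
    w_total = w.sum()
    grand = (w * means).sum() / w_total
    between = (w * (means - grand) ** 2).sum() / (k - 1)
    hc = ((1 - w / w_total) ** 2 / (ns - 1)).sum()
    f_stat = between / (1 + 2 * (k - 2) * hc / (k ** 2 - 1))
    df2 = (k ** 2 - 1) / (3 * hc)
    p = float(stats.f.sf(f_stat, k - 1, df2))
    return float(f_stat), (float(k - 1), float(df2)), p


def demographics(subjects: Sequence[SubjectRecord]) -> DemographicsResult:
    """Cohort demographics: Welch ANOVA on age, Kruskal–Wallis on MMSE."""
    by_group: Dict[str, List[SubjectRecord]] = {}
    for s in subjects:
        by_group.setdefault(s.group, []).append(s)
    ages = {g: [s.age for s in ss] for g, ss in by_group.items()}
    mmse = {g: [s.mmse for s in ss] for g, ss in by_group.items()}
    f_stat, df, p_w = welch_anova(ages)
    h, p_kw, ranks = kruskal_wallis(mmse)
    return DemographicsResult(
        welch_F=f_stat, welch_df=df, welch_p=p_w,
        kw_H=h, kw_p=p_kw, mean_ranks=ranks,
    )


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepResult:
    """Metric grids of the window and cluster sweeps."""

    window_grid: Dict[Tuple[str, int], MetricSet] = field(default_factory=dict)
    cluster_grid: Dict[Tuple[str, str], MetricSet] = field(default_factory=dict)
    config: Dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "window_grid": {f"{p}|{w}": m.to_dict()
                            for (p, w), m in self.window_grid.items()},
            "cluster_grid": {f"{p}|{c}": m.to_dict()
                             for (p, c), m in self.cluster_grid.items()},
            "config": self.config,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepResult":
        wg = {}
        for key, m in d["window_grid"].items():
            p, w = key.rsplit("|", 1)
            wg[(p, int(w))] = MetricSet.from_dict(m)
        cg = {}
        for key, m in d["cluster_grid"].items():
            p, c = key.rsplit("|", 1)
            cg[(p, c)] = MetricSet.from_dict(m)
        return cls(window_grid=wg, cluster_grid=cg, config=d["config"],
                   seed=d["seed"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, SweepResult):
            return NotImplemented
        return (self.window_grid == other.window_grid
                and self.cluster_grid == other.cluster_grid
                and self.config == other.config
                and self.seed == other.seed)


def preprocess_cohort(subjects: Sequence[SubjectRecord]) -> List[SubjectRecord]:
    """Re-reference and band-limit every recording (kept out of the
    sweep loops so filtering runs once per subject)."""
    out = []
    for s in subjects:
        rec = apply_bandlimit(common_average_reference(s.recording))
        out.append(dataclasses.replace(s, recording=rec))
    return out


def cohort_features(subjects: Sequence[SubjectRecord], window_s: int,
                    params: EstimatorParams | None = None,
                    preprocessed: bool = False) -> pd.DataFrame:
    """Epoch a cohort at one window length and extract the feature table."""
    subs = subjects if preprocessed else preprocess_cohort(subjects)
    epochs = [e for s in subs for e in segment(s.recording, window_s)]
    return extract_features(epochs, params)


def window_sweep(subjects: Sequence[SubjectRecord],
                 windows: Sequence[int] = WINDOWS,
                 problems: Sequence[str] = tuple(PROBLEMS),
                 seed: int = 0, folds: int = 10,
                 params: EstimatorParams | None = None) -> SweepResult:
    """Full pipeline per window length: one MetricSet per (problem, window)."""
    pre = preprocess_cohort(subjects)
    result = SweepResult(seed=seed, config={
        "windows": list(windows), "problems": list(problems), "folds": folds})
    for w in windows:
        feats = cohort_features(pre, w, params, preprocessed=True)
        for p in problems:
            X, y = build_dataset(feats, p, "whole")
            result.window_grid[(p, int(w))] = run_cv(
                X, y, folds=folds, seed=seed)
            logger.info("window %s s, %s: acc=%.2f%%", w, p,
                        result.window_grid[(p, int(w))].accuracy)
    return result


def cluster_sweep(subjects: Sequence[SubjectRecord], window_s: int = 12,
                  problems: Sequence[str] = tuple(PROBLEMS),
                  clusters: Sequence[str] = tuple(CLUSTERS),
                  seed: int = 0, folds: int = 10,
                  params: EstimatorParams | None = None) -> SweepResult:
    """Region-wise analysis at one window length (12 s by default)."""
    feats = cohort_features(subjects, window_s, params)
    result = SweepResult(seed=seed, config={
        "window_s": window_s, "problems": list(problems),
        "clusters": list(clusters), "folds": folds})
    for p in problems:
        for c in clusters:
            X, y = build_dataset(feats, p, c)
            result.cluster_grid[(p, c)] = run_cv(X, y, folds=folds, seed=seed)
            logger.info("cluster %s, %s: acc=%.2f%%", c, p,
                        result.cluster_grid[(p, c)].accuracy)
    return result


# ---------------------------------------------------------------------------
# reporting


def report(sweep: SweepResult, demo: DemographicsResult | None = None,
           out_dir=".", plot: bool = False) -> Dict[str, Path]:
    """Write the result tables: accuracy per (problem x window) CSV,
    metrics per (problem x cluster) CSV, and a JSON bundle.

    Missing grid cells are reported as empty cells, never an error.
    Returns the paths written. ``plot=True`` additionally draws an
    accuracy-versus-window line chart (requires matplotlib).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    problems = sweep.config.get("problems", sorted(
        {p for p, _ in sweep.window_grid} | {p for p, _ in sweep.cluster_grid}))
    if sweep.window_grid:
        windows = sorted({w for _, w in sweep.window_grid})
        table = pd.DataFrame(index=problems, columns=windows, dtype=float)
        for (p, w), m in sweep.window_grid.items():
            table.loc[p, w] = m.accuracy
        path = out / "accuracy_by_window.csv"
        table.to_csv(path, index_label="problem")
        paths["accuracy_by_window"] = path
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(7, 4))
            for p in table.index:
                ax.plot(table.columns, table.loc[p], marker="o", label=p)
            ax.set_xlabel("window length (s)")
            ax.set_ylabel("accuracy (%)")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig_path = out / "accuracy_by_window.png"
            fig.savefig(fig_path, dpi=120)
            plt.close(fig)
            paths["figure"] = fig_path

    if sweep.cluster_grid:
        rows = []
        for (p, c), m in sweep.cluster_grid.items():
            rows.append({"cluster": c, "problem": p, "accuracy": m.accuracy,
                         "precision": m.precision, "f1": m.f1,
                         "kappa": m.kappa, "n_epochs": m.n_epochs})
        path = out / "metrics_by_cluster.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths["metrics_by_cluster"] = path

    bundle = {"sweep": sweep.to_dict()}
    if demo is not None:
        bundle["demographics"] = dataclasses.asdict(demo)
    path = out / "results.json"
    path.write_text(json.dumps(bundle, indent=2))
    paths["json"] = path
    return paths
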