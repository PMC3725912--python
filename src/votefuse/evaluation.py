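"""Confusion-matrix metrics, the size x time parameter sweep, and the
positive-ratio scatter / corner contribution analysis.

The sweep re-runs the full integration fit/predict cycle on a grid of
(sampling size, sampling time N) cells — the default grid is sizes 40..80 in
steps of 2 (21 values) by N = 25..1500 in steps of 25 (60 values), 1,260
cells — and reports accuracy / sensitivity / specificity for three arms per
cell: genotype-only (majority of the K-pool), cytokine-only (majority of the
N-pool, ties negative) and integrated (majority of all K+N votes).  The same
fitted pools serve all three arms of a cell; integrated vote counts are by
construction the sum of the two single-attribute counts.  Summaries are the
per-arm mean and SD over all cells, including unstable small-size cells.

The scatter plots each test sample at (r_g, r_c), the fraction of each pool
voting positive; the fused decision boundary is the diagonal
K*r_g + N*r_c = (K+N)/2.  With cutoff q (default 0.9) the corners are:
I both ratios <= 1-q (confidently negative), II r_g >= q only
(genotype-driven), III r_c >= q only (cytokine-driven), IV both >= q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .integration import PredictionSummary, fit_integration, predict_integration
from .io_model import CASE, CONTROL, LabeledCohort, RunConfig, ValidationError

DEFAULT_GRID = (40, 80, 2, 25, 1500, 25)


@dataclass
class MetricTriple:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass
class SweepResult:
    """Tidy per-cell metrics plus the per-arm mean +/- SD summary."""

    cells: pd.DataFrame  # sampling_size, sampling_time, arm, metrics
    summary: pd.DataFrame  # per arm: mean/sd of accuracy/sensitivity/specificity


def confusion_metrics(calls, truth) -> MetricTriple:
    """Accuracy / sensitivity / specificity with case as the positive class."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.size == 0:
        raise ValidationError("empty input to confusion_metrics")
    if calls.shape != truth.shape:
        raise ValidationError("calls and truth differ in length")
    tp = int(((calls == CASE) & (truth == CASE)).sum())
    fn = int(((calls == CONTROL) & (truth == CASE)).sum())
    tn = int(((calls == CONTROL) & (truth == CONTROL)).sum())
    fp = int(((calls == CASE) & (truth == CONTROL)).sum())
    acc = (tp + tn) / (tp + fn + tn + fp)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    if np.isnan(sens) or np.isnan(spec):
        import warnings

        warnings.warn("sensitivity/specificity undefined (single-class truth)")
    return MetricTriple(acc, sens, spec, tp, fn, tn, fp)


def grid_values(grid=DEFAULT_GRID) -> tuple[list[int], list[int]]:
    s0, s1, ss, t0, t1, ts = grid
    return list(range(s0, s1 + 1, ss)), list(range(t0, t1 + 1, ts))


def evaluate_cell(
    training: LabeledCohort,
    test: LabeledCohort,
    geno_train: pd.DataFrame,
    geno_test: pd.DataFrame,
    cyto_train: pd.DataFrame,
    cyto_test: pd.DataFrame,
    size: int,
    n_time: int,
    classifier: str,
    rng: np.random.Generator,
    seed: int = 0,
) -> list[dict]:
    """One grid cell: fit the ensemble once, report all three arms.

    The same fitted pools serve the genotype-only, cytokine-only and
    integrated arms, so the integrated vote counts are exactly the sum of
    the two single-attribute counts.
    """
    config = RunConfig(
        sampling_size=size, sampling_time=n_time, classifier=classifier, seed=seed
    )
    try:
        model = fit_integration(training, geno_train, cyto_train, config, rng)
        summary = predict_integration(model, geno_test, cyto_test)
    except Exception as exc:
        raise ValidationError(
            f"sweep cell (size={size}, N={n_time}) failed: {exc}"
        ) from exc
    truth = test.labels
    arms = {
        "genotype": summary.genotype_only_calls(),
        "cytokine": summary.cytokine_only_calls(),
        "integrated": summary.final_calls,
    }
    rows = []
    for arm, calls in arms.items():
        m = confusion_metrics(calls.reindex(truth.index), truth)
        rows.append(
            {"sampling_size": size, "sampling_time": n_time, "arm": arm,
             "accuracy": m.accuracy, "sensitivity": m.sensitivity,
             "specificity": m.specificity, "tp": m.tp, "fn": m.fn,
             "tn": m.tn, "fp": m.fp}
        )
    return rows


def cell_seeds(grid, master_seed: int) -> dict[tuple[int, int], np.random.SeedSequence]:
    """Deterministic child seed per (size, N) cell of the grid."""
    sizes, times = grid_values(grid)
    seqs = np.random.SeedSequence(master_seed).spawn(len(sizes) * len(times))
    return {
        (size, n_time): seqs[i * len(times) + j]
        for i, size in enumerate(sizes)
        for j, n_time in enumerate(times)
    }


def run_sweep(
    training: LabeledCohort,
    test: LabeledCohort,
    geno_train: pd.DataFrame,
    geno_test: pd.DataFrame,
    cyto_train: pd.DataFrame,
    cyto_test: pd.DataFrame,
    grid=DEFAULT_GRID,
    classifier: str = "svm_rbf",
    master_seed: int = 0,
    progress: Optional[callable] = None,
) -> SweepResult:
    """Fit and evaluate one integration model per (size, N) grid cell.

    Each cell gets an independent child seed spawned deterministically from
    the master seed, so cells can be computed in any order (or in parallel)
    with identical results.
    """
    seeds = cell_seeds(grid, master_seed)
    rows = []
    for (size, n_time), seq in seeds.items():
        rows.extend(
            evaluate_cell(
                training, test, geno_train, geno_test, cyto_train, cyto_test,
                size, n_time, classifier, np.random.default_rng(seq), master_seed,
            )
        )
        if progress is not None:
            progress(size, n_time)
    cells = pd.DataFrame(rows)
    summary = summarize_sweep(cells)
    return SweepResult(cells, summary)


def summarize_sweep(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean and SD of the three metrics over all grid cells."""
    g = cells.groupby("arm")[["accuracy", "sensitivity", "specificity"]]
    mean, sd = g.mean(), g.std(ddof=1).fillna(0.0)
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd")
    return out.loc[[a for a in ("genotype", "cytokine", "integrated") if a in out.index]]


# ---------------------------------------------------------------------------
# positive-ratio scatter and corner analysis
# ---------------------------------------------------------------------------

def scatter_and_corners(
    summary: PredictionSummary,
    truth: pd.Series,
    cutoff: float = 0.9,
) -> pd.DataFrame:
    """Per-sample (r_g, r_c) points with corner assignments.

    Corner II flags genotype-driven predictions, III cytokine-driven; IV/I
    are confident positives/negatives on both attributes.  cutoff must be in
    (0.5, 1) so the four corner bands cannot overlap.
    """
    if not 0.5 < cutoff < 1:
        raise ValidationError(f"cutoff must be in (0.5,1); got {cutoff}")
    t = summary.table
    lo, hi = 1 - cutoff, cutoff
    r_g, r_c = t["r_g"], t["r_c"]
    corner = np.select(
        [
            (r_g <= lo) & (r_c <= lo),
            (r_g >= hi) & (r_c <= lo),
            (r_g <= lo) & (r_c >= hi),
            (r_g >= hi) & (r_c >= hi),
        ],
        ["I", "II", "III", "IV"],
        default="none",
    )
    return pd.DataFrame(
        {"r_g": r_g, "r_c": r_c, "true_label": truth.reindex(t.index),
         "final_call": t["final_call"], "corner": corner},
        index=t.index,
    )


def corner_counts(points: pd.DataFrame) -> pd.DataFrame:
    """Per-corner counts and within-label fractions by true label."""
    rows = []
    for label in (CASE, CONTROL):
        sub = points[points["true_label"] == label]
        for corner in ("I", "II", "III", "IV", "none"):
            n = int((sub["corner"] == corner).sum())
            rows.append(
                {"true_label": label, "corner": corner, "count": n,
                 "fraction": n / len(sub) if len(sub) else float("nan")}
            )
    return pd.DataFrame(rows)


def decision_boundary_check(summary: PredictionSummary) -> pd.Series:
    """Verify final_call == [K*r_g + N*r_c > (K+N)/2] for every sample."""
    t = summary.table
    k, n = summary.k, summary.n
    lhs = k * t["r_g"] + n * t["r_c"]
    expected = np.where(lhs > (k + n) / 2, CASE, CONTROL)
    return pd.Series(t["final_call"].to_numpy() == expected, index=t.index)


def plot_scatter(points: pd.DataFrame, k: int, n: int, path=None):
    """Render the ratio scatter with the diagonal fused-decision boundary.

    Styling is not contractual; requires matplotlib (optional extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, marker in ((CASE, "o"), (CONTROL, "^")):
        sub = points[points["true_label"] == label]
        ax.scatter(sub["r_g"], sub["r_c"], marker=marker, label=label, alpha=0.7)
    # K*x + N*y = (K+N)/2
    xs = np.linspace(0, 1, 50)
    ys = ((k + n) / 2 - k * xs) / n
    ax.plot(xs, ys, "k--", lw=1)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("positive ratio, genotype pool (r_g)")
    ax.set_ylabel("positive ratio, cytokine pool (r_c)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
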