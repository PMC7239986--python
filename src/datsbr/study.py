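"""Normal-database-size resampling study.

For each database size n in a grid (default 5, 10, ..., 50), a large number
of normal databases (default 10,000) is drawn uniformly without replacement
from the cohort's normal group.  Each database defines a z-score transform;
the *entire* cohort -- database members included -- is classified at the
fixed cutoff, and accuracy, sensitivity and specificity are recorded.  Per
size, the mean and 5th percentile of each performance measure over the
repeats summarize expected performance and its downside variability.  The
benchmark uses the whole normal group as database; relative accuracy loss
is ``100 * (benchmark - accuracy) / benchmark`` (%), and the "maximum" loss
is that formula evaluated at the 5th percentile of accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .zscores import ClassifierConfig, NormalDbFit, fit_normal_db

__all__ = [
    "StudyGrid",
    "PerformanceTriple",
    "StudySummary",
    "performance",
    "relative_loss",
    "percentile_5",
    "effective_sample_size",
    "run_study",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "size", "acc_mean", "acc_p5", "acc_sd", "sens_mean", "sens_p5",
    "spec_mean", "spec_p5", "mean_loss_pct", "max_loss_pct",
)


@dataclass(frozen=True)
class StudyGrid:
    """Database sizes, repeats per size, and the root RNG seed."""

    sizes: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
    repeats: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if not sizes:
            raise ValueError("grid needs at least one size")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"sizes must be strictly increasing, got {sizes}")
        if sizes[0] < 2:
            raise ValueError(f"smallest size must be >= 2, got {sizes[0]}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")


@dataclass(frozen=True)
class PerformanceTriple:
    """Accuracy, sensitivity and specificity of one classification run."""

    accuracy: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class StudySummary:
    """Per-size summaries plus the full-normal-group benchmark."""

    per_size: pd.DataFrame
    benchmark: PerformanceTriple
    method: str
    n_normal: int
    n_disease: int
    repeats: int
    seed: int

    def loc(self, size: int) -> pd.Series:
        row = self.per_size[self.per_size["size"] == size]
        if row.empty:
            raise KeyError(f"size {size} not in study grid {list(self.per_size['size'])}")
        return row.iloc[0]


def performance(calls, truth) -> PerformanceTriple:
    """Accuracy, sensitivity, specificity of binary calls against truth.

    ``calls`` are boolean (True = positive / neurodegenerative); ``truth``
    is boolean (True = disease) or the string labels "normal"/"disease".
    Both groups must be represented, otherwise a rate is undefined.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth)
    if truth.dtype.kind in "US":
        truth = truth == "disease"
    truth = truth.astype(bool)
    if calls.shape != truth.shape or calls.size == 0:
        raise ValueError("calls and truth must be equal-length and non-empty")
    n_dis = int(truth.sum())
    n_norm = truth.size - n_dis
    if n_dis == 0 or n_norm == 0:
        raise ValueError(
            "both groups must be represented "
            f"(n_disease={n_dis}, n_normal={n_norm}); a rate is undefined"
        )
    sens = float(calls[truth].mean())
    spec = float((~calls[~truth]).mean())
    acc = float((calls == truth).mean())
    return PerformanceTriple(acc, sens, spec)


def relative_loss(benchmark_acc: float, acc: float) -> float:
    """Relative accuracy loss (%) against the benchmark.

    ``100 * (benchmark_acc - acc) / benchmark_acc``; negative when a
    sampled database beats the benchmark (passed through unclipped).
    """
    if benchmark_acc <= 0:
        raise ValueError(f"benchmark accuracy must be > 0, got {benchmark_acc}")
    return 100.0 * (benchmark_acc - acc) / benchmark_acc


def percentile_5(values, interpolation: str = "linear") -> float:
    """5th percentile under the package-wide interpolation rule."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty list is undefined")
    return float(np.percentile(values, 5.0, method=interpolation))


def effective_sample_size(n1: int, n2: int) -> float:
    """Effective equal-group sample size 2*n1*n2 / (n1 + n2).

    The power of a two-sample comparison between groups of sizes (n1, n2)
    approximately equals that of equal groups of this size; for a single
    subject against a database of n it reduces to 2n/(n+1) < 2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError(f"group sizes must be >= 1, got ({n1}, {n2})")
    return 2.0 * n1 * n2 / (n1 + n2)


def _classify_against_databases(
    test_x: np.ndarray,
    db_x: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    """Positive calls for each (repeat, subject) given per-repeat databases.

    ``db_x``: (repeats, size) array of (Ln-)SBR database draws.
    Returns a boolean (repeats, n_test) array.
    """
    mu = db_x.mean(axis=1)
    sigma = db_x.std(axis=1, ddof=1)
    if np.any(sigma == 0):
        raise ValueError(
            "a sampled normal database has zero variance (all values "
            "identical); z-scores are undefined"
        )
    z = (test_x[None, :] - mu[:, None]) / sigma[:, None]
    return z < cutoff


def run_study(
    cohort: CohortTable,
    grid: StudyGrid = StudyGrid(),
    cfg: ClassifierConfig = ClassifierConfig(),
    method: str = "hv",
    exclude_db_from_test: bool = False,
    interpolation: str = "linear",
) -> StudySummary:
    """Run the full normal-database-size experiment on one cohort.

    Databases are drawn independently across repeats and sizes from
    per-size RNG substreams spawned off ``grid.seed``, so the study is
    reproducible and a database of one size is unrelated to any other
    size's draws.  By default database members stay in the test set (the
    whole cohort is always classified); ``exclude_db_from_test=True``
    removes each repeat's database members from its own performance
    computation for sensitivity analyses.
    """
    sbr = cohort.sbr(method)
    is_normal = cohort.is_normal()
    truth = ~is_normal  # True = disease
    n_normal = int(is_normal.sum())
    n_disease = int(truth.sum())
    if n_normal == 0 or n_disease == 0:
        raise ValueError("cohort must contain both a normal and a disease group")
    if grid.sizes[-1] > n_normal:
        raise ValueError(
            f"largest database size {grid.sizes[-1]} exceeds the normal-group "
            f"size {n_normal}"
        )

    use_ln = cfg.use_ln
    if use_ln and np.any(sbr <= 0):
        raise ValueError("SBR values must be strictly positive for the Ln transform")
    test_x = np.log(sbr) if use_ln else sbr
    normal_x = test_x[is_normal]

    # Benchmark: the whole normal group as database.
    bench_fit = fit_normal_db(sbr[is_normal], use_ln=use_ln)
    bench_calls = ((test_x - bench_fit.mu) / bench_fit.sigma) < cfg.cutoff
    benchmark = performance(bench_calls, truth)
    if benchmark.accuracy <= 0:
        raise ValueError("benchmark accuracy is 0; relative losses undefined")

    children = np.random.SeedSequence(grid.seed).spawn(len(grid.sizes))
    rows = []
    for size, child in zip(grid.sizes, children, strict=True):
        rng = np.random.default_rng(child)
        # repeats x size indices, each row a uniform draw without replacement
        u = rng.random((grid.repeats, n_normal))
        idx = np.argpartition(u, size - 1, axis=1)[:, :size]
        calls = _classify_against_databases(test_x, normal_x[idx], cfg.cutoff)

        if exclude_db_from_test:
            normal_positions = np.flatnonzero(is_normal)
            in_db = np.zeros((grid.repeats, len(cohort)), dtype=bool)
            np.put_along_axis(in_db, normal_positions[idx], True, axis=1)
            keep = ~in_db
        else:
            keep = np.ones((grid.repeats, len(cohort)), dtype=bool)

        correct = calls == truth[None, :]
        acc = _masked_row_mean(correct, keep)
        sens = _masked_row_mean(calls[:, truth], keep[:, truth])
        spec = _masked_row_mean(~calls[:, ~truth], keep[:, ~truth])

        acc_mean, acc_p5 = float(acc.mean()), percentile_5(acc, interpolation)
        row = {
            "size": size,
            "acc_mean": acc_mean,
            "acc_p5": acc_p5,
            "acc_sd": float(acc.std(ddof=1)) if grid.repeats > 1 else 0.0,
            "sens_mean": float(sens.mean()),
            "sens_p5": percentile_5(sens, interpolation),
            "spec_mean": float(spec.mean()),
            "spec_p5": percentile_5(spec, interpolation),
            "mean_loss_pct": relative_loss(benchmark.accuracy, acc_mean),
            "max_loss_pct": relative_loss(benchmark.accuracy, acc_p5),
        }
        for stem in ("acc", "sens", "spec"):
            if row[f"{stem}_p5"] > row[f"{stem}_mean"] + 1e-12:
                warnings.warn(
                    f"5th percentile of {stem} exceeds its mean at size {size}; "
                    "distribution over repeats is pathological",
                    RuntimeWarning,
                    stacklevel=2,
                )
        rows.append(row)
        logger.info(
            "size %d: mean accuracy %.4f (5th pct %.4f) over %d repeats",
            size, acc_mean, acc_p5, grid.repeats,
        )

    per_size = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    return StudySummary(
        per_size=per_size,
        benchmark=benchmark,
        method=method,
        n_normal=n_normal,
        n_disease=n_disease,
        repeats=grid.repeats,
        seed=grid.seed,
    )


def _masked_row_mean(values: np.ndarray, keep: np.ndarray) -> np.ndarray:
    counts = keep.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("a repeat has an empty test set after exclusion")
    return (values & keep).sum(axis=1) / counts
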