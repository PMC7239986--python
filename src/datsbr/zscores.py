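"""Normal-database z-scoring and fixed-cutoff classification.

A "normal database" is a set of SBR values from subjects without
nigrostriatal deficit.  Its mean and standard deviation define the z-score
transform ``z = (x - mu) / sigma`` applied to every test subject, and a
scan is called neurodegenerative when its putaminal z-score falls below a
fixed cutoff (default -2.5).  Because normal SBR distributions are
right-skewed, values are Ln-transformed before z-scoring by default, which
both symmetrizes the database and stabilizes the SD estimate against
high-value outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NormalDbFit",
    "ClassifierConfig",
    "fit_normal_db",
    "zscore",
    "classify",
    "sample_skewness",
]


@dataclass(frozen=True)
class NormalDbFit:
    """Mean and sample SD (n-1 denominator) of (Ln-)SBR over one database."""

    n: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"database must hold >= 2 values, got n={self.n}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Fixed-cutoff z-score classifier settings."""

    cutoff: float = -2.5
    use_ln: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError(f"cutoff must be finite, got {self.cutoff}")


def _maybe_ln(values: np.ndarray, use_ln: bool, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if use_ln:
        if np.any(values <= 0):
            raise ValueError(
                f"{what} must be strictly positive for the Ln transform; "
                f"got minimum {values.min()}"
            )
        return np.log(values)
    return values


def fit_normal_db(sbr_values, use_ln: bool = True) -> NormalDbFit:
    """Fit mean and sample SD of the (Ln-)SBR over a normal database.

    Rejects databases with fewer than two values, non-positive values under
    the Ln transform, and zero variance (all values identical), each with a
    distinct message.
    """
    values = np.asarray(sbr_values, dtype=float)
    if values.size < 2:
        raise ValueError(
            f"normal database needs at least 2 values, got {values.size}"
        )
    x = _maybe_ln(values, use_ln, "normal-database SBR values")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        raise ValueError(
            "normal database has zero variance (all values identical); "
            "z-scores are undefined"
        )
    return NormalDbFit(n=values.size, mu=float(np.mean(x)), sigma=sigma)


def zscore(sbr, fit: NormalDbFit, use_ln: bool = True):
    """z-score of one or many SBR values against a database fit."""
    x = _maybe_ln(np.asarray(sbr, dtype=float), use_ln, "SBR")
    z = (x - fit.mu) / fit.sigma
    return float(z) if np.isscalar(sbr) or np.ndim(sbr) == 0 else z

def classify(z, cutoff: float = -2.5):
    """Call a scan neurodegenerative-positive iff its z-score is strictly
    below the cutoff; a z-score exactly at the cutoff is negative."""
    z = np.asarray(z, dtype=float)
    out = z < cutoff
    return bool(out) if out.ndim == 0 else out


def sample_skewness(values, bias_corrected: bool = True) -> float:
    """Adjusted Fisher-Pearson standardized third moment (G1 by default).

    With ``bias_corrected=False`` the plain moment estimator g1 is
    returned.  Needs at least three values and nonzero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"skewness needs >= 3 values, got {values.size}")
    if np.std(values) == 0:
        raise ValueError("skewness is undefined for a zero-variance sample")
    return float(stats.skew(values, bias=not bias_corrected))
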