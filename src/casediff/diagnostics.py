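"""Genomic-inflation and Q-Q diagnostics for association P values or z scores.

The genomic inflation factor lambda is the ratio of the median association
chi-square to the median of the chi-square(1) distribution (0.4549...); its
lambda_1000 rescaling expresses the inflation an equivalently confounded study
of 1000 cases and 1000 comparison subjects would show, making studies of
different size comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

#: Median of the chi-square distribution with 1 df.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


def _to_chi2(values, kind: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateInputError("empty input vector")
    if kind == "p":
        if np.any((v <= 0) | (v > 1)):
            raise ValidationError("P values must lie in (0, 1]")
        return stats.chi2.isf(v, 1)
    if kind == "z":
        if not np.all(np.isfinite(v)):
            raise ValidationError("z scores must be finite")
        return v * v
    if kind == "chi2":
        return v
    raise ValueError(f"unknown kind {kind!r}")


def lambda_gc(values, kind: str = "p") -> float:
    """Genomic inflation factor: median chi-square over 0.4549364.

    ``kind`` selects the input scale: two-sided P values (``"p"``, quantile
    transformed), z scores (``"z"``, squared) or chi-squares (``"chi2"``).
    """
    chi2 = _to_chi2(values, kind)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def lambda_1000(lam: float, n1: int, n2: int) -> float:
    """Rescale an inflation factor to an equivalent 1000-vs-1000 study.

    ``lambda_1000 = 1 + (lambda - 1) * (1/n1 + 1/n2) / (2/1000)``; for the
    case-case statistic n1 is the TRS case count and n2 the non-TRS case count.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("group sizes must be positive")
    return 1.0 + (lam - 1.0) * (1.0 / n1 + 1.0 / n2) / (2.0 / 1000.0)


def qq_table(p) -> pd.DataFrame:
    """Expected vs observed -log10 P for a Q-Q plot, sorted most-significant first.

    Expected quantiles use the (rank - 0.5)/n rule.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DegenerateInputError("empty input vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("P values must lie in (0, 1]")
    obs = -np.log10(np.sort(p))
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"EXPECTED": exp, "OBSERVED": obs})


@dataclass
class InflationReport:
    """Summary of distributional inflation for one association scan."""

    lambda_gc: float
    lambda_1000: float
    n_snvs: int
    median_chi2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "LAMBDA_GC": self.lambda_gc, "LAMBDA_1000": self.lambda_1000,
            "N_SNVS": self.n_snvs, "MEDIAN_CHI2": self.median_chi2,
        }])


def inflation_report(values, n1: int, n2: int, kind: str = "p") -> InflationReport:
    """Compute lambda and lambda_1000 for one scan in a single call."""
    chi2 = _to_chi2(values, kind)
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    return InflationReport(
        lambda_gc=lam,
        lambda_1000=lambda_1000(lam, n1, n2),
        n_snvs=int(chi2.size),
        median_chi2=float(np.median(chi2)),
    )
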