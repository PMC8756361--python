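"""Case-case difference ("interaction") statistic between two case-control GWASs.

For each SNV shared by a TRS-vs-controls GWAS (study 1) and a
non-TRS-vs-controls GWAS (study 2), the difference of log odds ratios

    d = log(OR1) - log(OR2),    SE(d) = sqrt(SE1^2 + SE2^2)

is a fixed-effect moderator test of whether the allele's association differs
between the two case definitions.  ``z = d / SE(d)`` is standard normal under
the null of equal effects when the two studies use independent control sets;
positive z means a stronger association in study 1 (the TRS study).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import ValidationError
from .sumstats import Harmonized

logger = logging.getLogger("casediff.interaction")

#: Smallest reported two-sided P (never exactly 0).
P_FLOOR = np.finfo(float).tiny


def interaction_test(beta1, se1, beta2, se2):
    """Difference of two independent log odds ratios.

    Accepts scalars or aligned arrays.  Returns ``(d, se_d, z, p)`` with
    ``d = beta1 - beta2``, ``se_d = sqrt(se1^2 + se2^2)``, ``z = d/se_d`` and
    two-sided normal ``p = 2*(1 - Phi(|z|))``, floored at the smallest
    positive float.
    """
    beta1, se1, beta2, se2 = (np.asarray(v, dtype=float) for v in (beta1, se1, beta2, se2))
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValidationError("standard errors must be positive")
    d = beta1 - beta2
    se_d = np.hypot(se1, se2)
    z = d / se_d
    p = np.maximum(2.0 * ndtr(-np.abs(z)), P_FLOOR)
    if d.ndim == 0:
        return float(d), float(se_d), float(z), float(p)
    return d, se_d, z, p


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering (1..22 before X, Y, MT)."""
    order = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return chrom.astype(str).map(lambda c: order.get(c, 26))


def run_interaction_gwas(harmonized: Harmonized) -> pd.DataFrame:
    """Per-SNV difference statistics over the retained harmonized rows.

    Study 1 is the TRS GWAS and study 2 the non-TRS GWAS, so positive ``Z``
    reflects a stronger association in TRS.  Output is sorted by
    (chromosome, position); excluded rows are absent.
    """
    t = harmonized.retained
    if t.empty:
        logger.warning("run_interaction_gwas: no retained SNVs; returning empty table")
        cols = ["SNP", "CHR", "BP", "A1", "A2", "EAF1", "EAF2",
                "N_CAS1", "N_CON1", "N_CAS2", "N_CON2", "D", "SE", "Z", "P"]
        return pd.DataFrame(columns=cols)
    d, se_d, z, p = interaction_test(
        t["BETA1"].to_numpy(), t["SE1"].to_numpy(),
        t["BETA2"].to_numpy(), t["SE2"].to_numpy())
    out = pd.DataFrame({
        "SNP": t["SNP"], "CHR": t["CHR"], "BP": t["BP"],
        "A1": t["A1"], "A2": t["A2"],
        "EAF1": t["EAF1"], "EAF2": t["EAF2"],
        "N_CAS1": t["N_CAS1"], "N_CON1": t["N_CON1"],
        "N_CAS2": t["N_CAS2"], "N_CON2": t["N_CON2"],
        "D": d, "SE": se_d, "Z": z, "P": p,
    })
    out = out.sort_values(
        ["BP"], kind="mergesort").sort_values(
        "CHR", key=_chrom_sort_key, kind="mergesort").reset_index(drop=True)
    return out


def interaction_to_sumstats(result: pd.DataFrame) -> pd.DataFrame:
    """Re-express the interaction table as a canonical sumstats frame.

    ``BETA := D``; the case-case convention labels TRS cases as "cases"
    (``N_CAS := N_CAS1``) and non-TRS cases as the comparison group
    (``N_CON := N_CAS2``); ``EAF`` is the TRS-study frequency.  The result
    feeds the LD-score-regression and PRS stages unchanged.
    """
    return pd.DataFrame({
        "SNP": result["SNP"], "CHR": result["CHR"], "BP": result["BP"],
        "A1": result["A1"], "A2": result["A2"], "EAF": result["EAF1"],
        "BETA": result["D"], "SE": result["SE"], "P": result["P"],
        "N_CAS": result["N_CAS1"], "N_CON": result["N_CAS2"],
    })
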