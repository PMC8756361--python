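"""Case-control association from dosages via the allelic 2x2 test.

Each SNV's effect-allele counts in cases and controls form a 2x2 table; the
log odds ratio with Woolf's standard error ``sqrt(1/a + 1/b + 1/c + 1/d)`` is
asymptotically equivalent to a covariate-free logistic Wald test and orders
of magnitude faster at simulation scale.  The Haldane-Anscombe +0.5
correction is applied to all four cells whenever any cell is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .cohort import GenotypeCohort
from .errors import ValidationError

logger = logging.getLogger("casediff.gwas")


@dataclass
class AssocResult:
    """Single-SNV allelic association summary."""

    snv_id: str
    beta: float
    se: float
    p: float
    counts: tuple  # (case_effect, case_other, control_effect, control_other)


def _tables_from_dosages(case_dosages: np.ndarray, control_dosages: np.ndarray):
    """Vectorised allele-count tables; dosage columns are SNVs."""
    a = case_dosages.sum(axis=0, dtype=float)
    b = 2.0 * case_dosages.shape[0] - a
    c = control_dosages.sum(axis=0, dtype=float)
    d = 2.0 * control_dosages.shape[0] - c
    return a, b, c, d


def _woolf(a, b, c, d):
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (np.where(zero, v + 0.5, v) for v in (a, b, c, d))
    beta = np.log(a * d / (b * c))
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    p = 2.0 * ndtr(-np.abs(beta / se))
    return beta, se, p


def assoc_2x2(case_dosages, control_dosages) -> AssocResult:
    """Allelic 2x2 association for one SNV.

    Dosages are effect-allele counts in {0,1,2}.
    """
    case_dosages = np.asarray(case_dosages, dtype=float)
    control_dosages = np.asarray(control_dosages, dtype=float)
    if case_dosages.size == 0 or control_dosages.size == 0:
        raise ValidationError("both groups must be non-empty")
    a, b, c, d = _tables_from_dosages(case_dosages[:, None], control_dosages[:, None])
    counts = (int(a[0]), int(b[0]), int(c[0]), int(d[0]))
    beta, se, p = _woolf(a, b, c, d)
    return AssocResult(snv_id="", beta=float(beta[0]), se=float(se[0]),
                       p=float(p[0]), counts=counts)


def run_gwas(cohort: GenotypeCohort, case_label: str, control_label: str) -> pd.DataFrame:
    """Canonical sumstats table for ``case_label`` vs ``control_label``.

    Effect-allele frequency (EAF) is reported from the control group;
    monomorphic SNVs (no copy of either allele across both groups) are
    dropped with a logged count.
    """
    labels = set(cohort.samples["LABEL"])
    for lab in (case_label, control_label):
        if lab not in labels:
            raise ValidationError(f"label {lab!r} not present in cohort")
    cases = cohort.subset(case_label).dosages.astype(float)
    controls = cohort.subset(control_label).dosages.astype(float)
    a, b, c, d = _tables_from_dosages(cases, controls)
    poly = (a + c > 0) & (b + d > 0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("run_gwas: dropping %d monomorphic SNVs", n_mono)
    beta, se, p = _woolf(a[poly], b[poly], c[poly], d[poly])
    snvs = cohort.snvs[poly].reset_index(drop=True)
    eaf = c[poly] / (c[poly] + d[poly])
    return pd.DataFrame({
        "SNP": snvs["SNP"], "CHR": snvs["CHR"].astype(str), "BP": snvs["BP"].astype(int),
        "A1": snvs["A1"], "A2": snvs["A2"],
        "EAF": eaf, "BETA": beta, "SE": se, "P": np.maximum(p, np.finfo(float).tiny),
        "N_CAS": cases.shape[0], "N_CON": controls.shape[0],
    })
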