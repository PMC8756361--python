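"""GWAS summary-statistics I/O and two-study allele harmonization.

The canonical in-memory representation is a :class:`pandas.DataFrame` with the
columns ``SNP, CHR, BP, A1, A2, EAF, BETA, SE, P, N_CAS, N_CON`` where ``A1``
is the effect allele and ``BETA`` is the log odds ratio (natural log).  Files
carrying an ``OR`` column are converted on read.

Harmonization aligns study 2 to study 1's effect-allele frame through the
standard lattice of actions — identity, allele swap (negate beta, eaf -> 1-eaf),
strand flip (complement both alleles) and swap+flip — and applies the
pre-imputation-style quality filter that drops SNVs whose allele-frequency
difference between the two studies exceeds a threshold (default 20%).
Palindromic SNVs (A/T, C/G) whose minor-allele frequency is close to 0.5 in
both studies are strand-ambiguous and are excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HarmonizeError, ValidationError

logger = logging.getLogger("casediff.sumstats")

#: Canonical column order of a summary-statistics table.
COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N_CAS", "N_CON"]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Harmonization actions, in resolution order.
ACTIONS = ("identity", "swap", "flip", "swap_flip")
#: Exclusion reasons.
REASONS = ("none", "allele_mismatch", "palindromic_ambiguous", "maf_diff")


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def read_sumstats(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read and validate a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path : str or file-like
        File with a header row.  Lines starting with ``#`` are ignored
        (provenance headers).
    dialect : dict, optional
        Mapping from the file's column names to the canonical names, e.g.
        ``{"rsid": "SNP", "log_or": "BETA"}``.  Unmapped canonical names must
        already be present in the file.

    Returns
    -------
    pandas.DataFrame
        Validated table in canonical column order; an ``OR`` column is
        converted to ``BETA = ln(OR)``.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype={"CHR": str})
    if dialect:
        df = df.rename(columns=dialect)
    if "CHR" in df.columns:
        df["CHR"] = df["CHR"].astype(str)
    return validate_sumstats(df, source=str(path))


def validate_sumstats(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a raw table against the summary-statistic invariants.

    Raises :class:`~casediff.errors.ValidationError` with row-level
    diagnostics on the first class of violation found.
    """
    df = df.copy()
    if "BETA" not in df.columns and "OR" in df.columns:
        orv = pd.to_numeric(df["OR"], errors="coerce")
        bad = df.index[~(orv > 0)].tolist()
        if bad:
            raise ValidationError(f"{source}: non-positive or malformed OR at rows {bad[:10]}")
        df["BETA"] = np.log(orv)
        df = df.drop(columns=["OR"])
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing mandatory column(s) {missing}")

    df["CHR"] = df["CHR"].astype(str)
    for col in ("BP", "N_CAS", "N_CON"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("EAF", "BETA", "SE", "P"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    checks = [
        ("malformed effect allele", ~df["A1"].astype(str).isin(_BASES)),
        ("malformed other allele", ~df["A2"].astype(str).isin(_BASES)),
        ("identical alleles", df["A1"].astype(str) == df["A2"].astype(str)),
        ("EAF outside [0,1]", ~df["EAF"].between(0.0, 1.0)),
        ("non-positive SE", ~(df["SE"] > 0)),
        ("P outside (0,1]", ~((df["P"] > 0) & (df["P"] <= 1))),
        ("non-finite BETA", ~np.isfinite(df["BETA"])),
        ("non-positive case count", ~(df["N_CAS"] > 0)),
        ("non-positive control count", ~(df["N_CON"] > 0)),
    ]
    for what, mask in checks:
        if mask.any():
            rows = df.index[mask].tolist()
            raise ValidationError(f"{source}: {what} at rows {rows[:10]}"
                                  + ("..." if len(rows) > 10 else ""))
    dup = df["SNP"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{source}: duplicated snv_id(s) {df.loc[dup, 'SNP'].unique()[:5].tolist()}")
    df["BP"] = df["BP"].astype(int)
    df["N_CAS"] = df["N_CAS"].astype(int)
    df["N_CON"] = df["N_CON"].astype(int)
    return df[COLUMNS].reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path, provenance: list[str] | None = None) -> None:
    """Write a validated table as tab-delimited text.

    The output round-trips exactly through :func:`read_sumstats` (floats use
    shortest-repr formatting; a ``-0.0`` beta is normalized to ``0.0``).
    Optional provenance lines are written as leading ``#`` comments.
    """
    out = df[COLUMNS].copy()
    for col in ("EAF", "BETA", "SE", "P"):
        out[col] = out[col] + 0.0  # normalize -0.0
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


@dataclass
class Harmonized:
    """SNV-aligned pair of studies with per-row harmonization bookkeeping.

    ``table`` carries, per SNV: study-1 fields (suffix 1), study-2 fields
    aligned to study 1's effect allele (suffix 2), the ``ACTION`` applied,
    ``MAF_DIFF`` (|EAF1 - aligned EAF2|), and the exclusion flag/reason.
    """

    table: pd.DataFrame
    maf_diff_threshold: float = 0.20
    counts: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[~self.table["EXCLUDED"]].reset_index(drop=True)

    @property
    def n_retained(self) -> int:
        return int((~self.table["EXCLUDED"]).sum())

    def exclusion_report(self) -> pd.DataFrame:
        """TSV-ready table of excluded SNVs with reasons."""
        ex = self.table[self.table["EXCLUDED"]]
        return ex[["SNP", "CHR", "BP", "ACTION", "MAF_DIFF", "REASON"]].reset_index(drop=True)


def harmonize(study1: pd.DataFrame, study2: pd.DataFrame,
              maf_diff_threshold: float = 0.20) -> Harmonized:
    """Align study 2 to study 1's effect-allele frame on the shared SNVs.

    Rows that cannot be reconciled by identity/swap/flip/swap+flip are
    excluded (``allele_mismatch``); palindromic SNVs with MAF in [0.4, 0.5]
    in both studies are excluded (``palindromic_ambiguous``); rows with
    post-alignment frequency difference above ``maf_diff_threshold`` are
    excluded (``maf_diff``).  Exclusion counts are logged.
    """
    m = study1.merge(study2, on="SNP", suffixes=("1", "2"))
    if m.empty:
        raise HarmonizeError("no SNVs shared between the two studies")

    a1, a2 = m["A11"].astype(str), m["A21"].astype(str)
    b1, b2 = m["A12"].astype(str), m["A22"].astype(str)
    b1c, b2c = _complement(b1), _complement(b2)

    is_identity = (b1 == a1) & (b2 == a2)
    is_swap = (b1 == a2) & (b2 == a1)
    is_flip = (b1c == a1) & (b2c == a2)
    is_swap_flip = (b1c == a2) & (b2c == a1)

    action = np.select(
        [is_identity, is_swap, is_flip, is_swap_flip],
        ["identity", "swap", "flip", "swap_flip"],
        default="mismatch",
    )
    needs_negation = np.isin(action, ("swap", "swap_flip"))

    eaf2 = m["EAF2"].to_numpy(float)
    beta2 = m["BETA2"].to_numpy(float)
    eaf2_aligned = np.where(needs_negation, 1.0 - eaf2, eaf2)
    beta2_aligned = np.where(needs_negation, -beta2, beta2)

    eaf1 = m["EAF1"].to_numpy(float)
    maf_diff = np.abs(eaf1 - eaf2_aligned)

    palindromic = a2 == a1.map(_COMPLEMENT)
    maf1 = np.minimum(eaf1, 1.0 - eaf1)
    maf2 = np.minimum(eaf2_aligned, 1.0 - eaf2_aligned)
    ambiguous = palindromic.to_numpy() & (maf1 >= 0.4) & (maf2 >= 0.4)

    reason = np.where(action == "mismatch", "allele_mismatch",
                      np.where(ambiguous, "palindromic_ambiguous",
                               np.where(maf_diff > maf_diff_threshold, "maf_diff", "none")))

    tbl = pd.DataFrame({
        "SNP": m["SNP"],
        "CHR": m["CHR1"].astype(str), "BP": m["BP1"].astype(int),
        "A1": a1, "A2": a2,
        "EAF1": eaf1, "BETA1": m["BETA1"].to_numpy(float),
        "SE1": m["SE1"].to_numpy(float), "P1": m["P1"].to_numpy(float),
        "N_CAS1": m["N_CAS1"].astype(int), "N_CON1": m["N_CON1"].astype(int),
        "EAF2": eaf2_aligned, "BETA2": beta2_aligned,
        "SE2": m["SE2"].to_numpy(float), "P2": m["P2"].to_numpy(float),
        "N_CAS2": m["N_CAS2"].astype(int), "N_CON2": m["N_CON2"].astype(int),
        "ACTION": np.where(action == "mismatch", "identity", action),
        "MAF_DIFF": maf_diff,
        "EXCLUDED": reason != "none",
        "REASON": reason,
    })
    counts = {r: int((reason == r).sum()) for r in REASONS if r != "none"}
    counts["retained"] = int((reason == "none").sum())
    logger.info("harmonize: %d shared SNVs, retained %d, excluded %s",
                len(tbl), counts["retained"],
                {k: v for k, v in counts.items() if k != "retained"})
    return Harmonized(table=tbl, maf_diff_threshold=maf_diff_threshold, counts=counts)
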