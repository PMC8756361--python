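"""Genotyped cohort container shared by the GWAS, PRS and simulation stages.

A cohort is a dosage matrix (individuals x SNVs, effect-allele counts in
{0,1,2}; missing values allowed as NaN in float matrices), a sample sheet
(id, phenotype label, sex, optional covariates) and per-SNV metadata.
Phenotype labels are ``control``, ``case_nonTRS`` and ``case_TRS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LABELS = ("control", "case_nonTRS", "case_TRS")

SNV_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "MAF", "BLOCK"]


@dataclass
class GenotypeCohort:
    """Individuals x SNVs dosages with phenotype labels and covariates.

    ``samples`` must carry columns ``IID``, ``LABEL`` and ``SEX``; ``snvs``
    carries ``SNP, CHR, BP, A1, A2, MAF, BLOCK``.  ``meta`` holds free-form
    simulation provenance (e.g. the per-seed effect vectors used to build
    liabilities, realized prevalence).
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    snvs: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValidationError("sample sheet length does not match dosage rows")
        if len(self.snvs) != m:
            raise ValidationError("snv table length does not match dosage columns")
        if self.samples["IID"].duplicated().any():
            raise ValidationError("duplicated individual ids")
        bad = set(self.samples["LABEL"].unique()) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown phenotype label(s) {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.dosages.shape[1]

    def subset(self, labels) -> "GenotypeCohort":
        """Cohort restricted to the given phenotype labels, order preserved."""
        if isinstance(labels, str):
            labels = [labels]
        mask = self.samples["LABEL"].isin(labels).to_numpy()
        return GenotypeCohort(
            dosages=self.dosages[mask],
            samples=self.samples[mask].reset_index(drop=True),
            snvs=self.snvs, meta=self.meta)

    def label_counts(self) -> dict:
        return self.samples["LABEL"].value_counts().to_dict()

    def eaf(self) -> np.ndarray:
        """Empirical effect-allele frequencies (missing dosages ignored)."""
        return np.nanmean(np.asarray(self.dosages, dtype=float), axis=0) / 2.0

    def write(self, prefix: str, provenance: list[str] | None = None) -> None:
        """Write ``<prefix>.dosages.tsv`` (SNVs x individuals) and
        ``<prefix>.samples.tsv``."""
        header = "".join(f"# {line}\n" for line in provenance or [])
        with open(f"{prefix}.samples.tsv", "w") as fh:
            fh.write(header)
            self.samples.to_csv(fh, sep="\t", index=False)
        meta_cols = [c for c in SNV_COLUMNS if c in self.snvs.columns]
        dose = pd.concat(
            [self.snvs[meta_cols].reset_index(drop=True),
             pd.DataFrame(np.asarray(self.dosages).T,
                          columns=self.samples["IID"].astype(str))],
            axis=1)
        with open(f"{prefix}.dosages.tsv", "w") as fh:
            fh.write(header)
            dose.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str) -> "GenotypeCohort":
        samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", comment="#")
        samples["IID"] = samples["IID"].astype(str)
        dose = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", comment="#")
        meta_cols = [c for c in SNV_COLUMNS if c in dose.columns]
        snvs = dose[meta_cols].copy()
        if "CHR" in snvs.columns:
            snvs["CHR"] = snvs["CHR"].astype(str)
        mat = dose.drop(columns=meta_cols).to_numpy(float).T
        return cls(dosages=mat, samples=samples, snvs=snvs)


def read_vcf_cohort(vcf_path: str, samples: pd.DataFrame) -> GenotypeCohort:
    """Build a cohort from a VCF (DS field preferred, else GT allele count).

    ``samples`` is the sample sheet (IID, LABEL, SEX, ...); its IID order
    must match the VCF sample order.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    if list(samples["IID"].astype(str)) != list(vcf.samples):
        raise ValidationError("sample sheet IIDs do not match VCF sample order")
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNVs only
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.genotypes)[:, :2]
            ds = np.where((gt < 0).any(axis=1), np.nan, gt.clip(min=0).sum(axis=1)).astype(float)
        rows.append(ds)
        meta.append({"SNP": var.ID or f"{var.CHROM}:{var.POS}", "CHR": str(var.CHROM),
                     "BP": int(var.POS), "A1": var.ALT[0], "A2": var.REF,
                     "MAF": float("nan"), "BLOCK": -1})
    if not rows:
        raise ValidationError("no biallelic SNVs found in VCF")
    return GenotypeCohort(dosages=np.array(rows).T,
                          samples=samples.reset_index(drop=True),
                          snvs=pd.DataFrame(meta))
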