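"""Liability-threshold simulation of paired case-control GWASs.

The generator emulates the study design behind a case-case GWAS of
treatment-resistant schizophrenia (TRS): a shared polygenic liability to
schizophrenia determines case status at a population prevalence ``K_scz``;
among cases, an independent TRS-specific polygenic liability determines who
is treatment resistant (target fraction ``trs_fraction``, defaulting to the
25% midpoint of the 20%-30% range reported for TRS).  TRS and non-TRS cases
are each compared with an *independent* set of screened controls, and a
held-out cases-only cohort (TRS/non-TRS labelled) is produced for PRS
validation.

Genotypes are HWE-exact trinomial dosages generated through a Gaussian
copula: SNVs are partitioned into LD blocks and, within a block, a shared
latent factor induces an exchangeable dosage correlation calibrated to the
configured target r^2 by solving the bivariate-normal orthant equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import GenotypeCohort
from .errors import SimulationError, ValidationError
from .gwas import run_gwas
from .ldsc import LDScorePanel, compute_ld_scores

logger = logging.getLogger("casediff.simulate")

#: Hard cap on the number of individuals drawn while filling group quotas.
REJECTION_CAP = 5_000_000


@dataclass
class SimConfig:
    """Study conditions of the simulated two-GWAS design.

    Heritabilities are liability-scale variance fractions; ``h2_shared``
    drives schizophrenia case status, ``h2_specific`` drives TRS status
    among cases.  Sample counts are the per-group quotas of the discovery
    design; control sets 1 and 2 are disjoint by construction.
    """

    m_snvs: int = 5000
    block_size: int = 10
    within_block_r2: float = 0.2
    maf_range: tuple = (0.05, 0.5)
    h2_shared: float = 0.25
    h2_specific: float = 0.1
    K_scz: float = 0.01
    trs_fraction: float = 0.25
    n_trs_cases: int = 2000
    n_nontrs_cases: int = 2000
    n_controls_1: int = 2000
    n_controls_2: int = 2000
    n_validation: int = 800
    n_reference: int = 500
    causal_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not 0 <= self.h2_shared < 1 or not 0 <= self.h2_specific < 1:
            raise ValidationError("heritabilities must lie in [0, 1)")
        if not 0 < self.K_scz < 1 or not 0 < self.trs_fraction < 1:
            raise ValidationError("K_scz and trs_fraction must lie in (0, 1)")
        if min(self.n_trs_cases, self.n_nontrs_cases, self.n_controls_1,
               self.n_controls_2, self.n_reference) <= 0:
            raise ValidationError("all group sizes must be positive")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.within_block_r2 < 1:
            raise ValidationError("within_block_r2 must lie in [0, 1)")
        if self.block_size < 1 or self.m_snvs < 1:
            raise ValidationError("m_snvs and block_size must be positive")
        return self


@dataclass
class ReferencePanel:
    """Simulated LD reference: SNV frame, copula parameters, dosage sample."""

    snvs: pd.DataFrame            # SNP CHR BP A1 A2 MAF BLOCK
    latent_rho: np.ndarray        # per-SNV latent correlation with its block factor
    dosages: np.ndarray           # reference sample (n_reference x m)
    ld: LDScorePanel

    @property
    def thresholds(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.snvs["MAF"].to_numpy(float)
        q1 = stats.norm.ppf((1 - p) ** 2)
        q2 = stats.norm.ppf((1 - p) ** 2 + 2 * p * (1 - p))
        return q1, q2


# ------------------------------------------------------- copula calibration

def _dosage_corr(rho: float, p1: float, p2: float) -> float:
    """Correlation of two copula dosages whose latents correlate at ``rho``."""
    qs = []
    for p in (p1, p2):
        qs.append((stats.norm.ppf((1 - p) ** 2),
                   stats.norm.ppf((1 - p) ** 2 + 2 * p * (1 - p))))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    e = 0.0
    for s in range(2):
        for t in range(2):
            # P(z1 > q1s, z2 > q2t) via the BVN CDF of the lower orthant
            lo = stats.multivariate_normal.cdf([-qs[0][s], -qs[1][t]],
                                               mean=[0, 0], cov=cov)
            e += lo
    means = [2 * p for p in (p1, p2)]
    sds = [np.sqrt(2 * p * (1 - p)) for p in (p1, p2)]
    return (e - means[0] * means[1]) / (sds[0] * sds[1])


_RHO_CACHE: dict = {}


def calibrate_latent_rho(target_r2: float, maf: float) -> float:
    """Latent correlation giving the target squared dosage correlation.

    Pairwise latent correlation within a block is ``rho_pair``; each SNV
    loads on the block factor with ``sqrt(rho_pair)``.  Raises if the target
    is unreachable for the given MAF.
    """
    if target_r2 == 0:
        return 0.0
    # calibration runs on MAF/target rounded to the cache resolution so the
    # result is a pure function of the key (call order cannot matter)
    maf = round(float(maf), 3)
    target_r2 = round(float(target_r2), 4)
    key = (maf, target_r2)
    if key in _RHO_CACHE:
        return _RHO_CACHE[key]
    target = np.sqrt(target_r2)

    def f(rho):
        return _dosage_corr(rho, maf, maf) - target

    hi = 0.9999
    if f(hi) < 0:
        raise SimulationError(
            f"within-block r2 target {target_r2} infeasible at MAF {maf:.3f}")
    rho = optimize.brentq(f, 0.0, hi, xtol=1e-4)
    _RHO_CACHE[key] = rho
    return rho


# ------------------------------------------------------------- generation

def _draw_dosages(rng: np.random.Generator, n: int, ref: ReferencePanel) -> np.ndarray:
    """n individuals' copula dosages (uint8) under the panel's LD structure."""
    m = len(ref.snvs)
    blocks = ref.snvs["BLOCK"].to_numpy(int)
    n_blocks = blocks.max() + 1
    q1, q2 = ref.thresholds
    a = np.sqrt(ref.latent_rho).astype(np.float32)
    c = np.sqrt(1.0 - ref.latent_rho).astype(np.float32)
    u = rng.standard_normal((n, n_blocks), dtype=np.float32)
    z = rng.standard_normal((n, m), dtype=np.float32)
    z *= c
    z += u[:, blocks] * a
    d = (z > q1.astype(np.float32)).astype(np.uint8)
    d += z > q2.astype(np.float32)
    return d


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None):
    """Build the LD reference: SNV frame, copula parameters, LD-score panel.

    SNVs sit on chromosome 1 at 5 kb spacing in consecutive blocks; LD
    scores are computed from a fresh reference dosage sample.
    """
    config = config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.m_snvs
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    blocks = np.arange(m) // config.block_size
    # one calibration per block at its mean MAF (cached across blocks)
    rho = np.empty(m)
    for b in np.unique(blocks):
        idx = blocks == b
        rho[idx] = calibrate_latent_rho(config.within_block_r2, float(maf[idx].mean())) \
            if idx.sum() > 1 else 0.0
    bases = np.array(["A", "C", "G", "T"])
    a1 = bases[rng.integers(0, 4, size=m)]
    a2 = np.array([bases[(list(bases).index(x) + 1 + int(k)) % 4]
                   for x, k in zip(a1, rng.integers(0, 3, size=m))])
    snvs = pd.DataFrame({
        "SNP": [f"rs{j + 1}" for j in range(m)],
        "CHR": "1", "BP": 5000 * (np.arange(m) + 1),
        "A1": a1, "A2": a2, "MAF": maf, "BLOCK": blocks,
    })
    ref = ReferencePanel(snvs=snvs, latent_rho=rho, dosages=None, ld=None)
    ref.dosages = _draw_dosages(rng, config.n_reference, ref)
    ref.ld = compute_ld_scores(ref.dosages, blocks, snv_ids=snvs["SNP"].to_numpy())
    return ref


def _draw_effects(rng: np.random.Generator, config: SimConfig, m: int):
    """Per-seed liability effect vectors on the standardized-dosage scale."""
    n_causal = max(1, round(config.causal_fraction * m))
    out = []
    for h2 in (config.h2_shared, config.h2_specific):
        b = np.zeros(m)
        if h2 > 0:
            causal = rng.choice(m, size=n_causal, replace=False)
            b[causal] = rng.normal(0.0, np.sqrt(h2 / n_causal), size=n_causal)
        out.append(b)
    return out


def simulate_cohort(config: SimConfig, ref: ReferencePanel | None = None,
                    rng: np.random.Generator | None = None,
                    quotas: dict | None = None,
                    n_natural_cases: int = 0) -> GenotypeCohort:
    """Sample a labelled cohort under the two-layer liability model.

    Individuals are drawn in batches; each draw's schizophrenia liability
    ``L1 = x.b_shared + e1`` classifies it as case (``L1 > Phi^-1(1-K)``) or
    control, and each case's TRS liability ``L2 = x.b_specific + e2``
    labels it TRS or non-TRS at the ``Phi^-1(1-trs_fraction)`` threshold.
    ``quotas`` maps labels to required counts (defaults from the config);
    ``n_natural_cases`` additionally collects that many cases at the natural
    TRS mix (used for validation cohorts).  Raises when the draw cap is hit.
    """
    config = config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if ref is None:
        ref = simulate_reference(config, rng)
    if quotas is None:
        quotas = {"case_TRS": config.n_trs_cases,
                  "case_nonTRS": config.n_nontrs_cases,
                  "control": config.n_controls_1}
    m = len(ref.snvs)
    b_shared, b_specific = _draw_effects(rng, config, m)
    maf = ref.snvs["MAF"].to_numpy(float)
    sd = np.sqrt(2 * maf * (1 - maf))
    w1 = (b_shared / sd).astype(np.float32)
    w2 = (b_specific / sd).astype(np.float32)
    c1 = float(2 * maf @ (b_shared / sd))
    c2 = float(2 * maf @ (b_specific / sd))
    s1_resid = np.sqrt(max(1.0 - config.h2_shared, 1e-12))
    s2_resid = np.sqrt(max(1.0 - config.h2_specific, 1e-12))
    t1 = stats.norm.isf(config.K_scz)
    t2 = stats.norm.isf(config.trs_fraction)

    need = dict(quotas)
    need_natural = n_natural_cases
    chunks, labels, natural_flags = [], [], []
    n_drawn = n_cases_drawn = 0
    batch = max(1000, min(20000, int(2e7 // max(m, 1))))
    while (any(v > 0 for v in need.values()) or need_natural > 0):
        if n_drawn >= REJECTION_CAP:
            raise SimulationError(
                f"rejection-sampling cap of {REJECTION_CAP} draws exceeded; "
                f"unfilled quotas: { {k: v for k, v in need.items() if v > 0} }")
        d = _draw_dosages(rng, batch, ref)
        g = d.astype(np.float32)
        L1 = g @ w1 - c1 + s1_resid * rng.standard_normal(batch)
        L2 = g @ w2 - c2 + s2_resid * rng.standard_normal(batch)
        is_case = L1 > t1
        is_trs = is_case & (L2 > t2)
        n_drawn += batch
        n_cases_drawn += int(is_case.sum())
        lab = np.where(is_trs, "case_TRS",
                       np.where(is_case, "case_nonTRS", "control"))
        keep = np.zeros(batch, dtype=bool)
        natural = np.zeros(batch, dtype=bool)
        for i in range(batch):
            li = lab[i]
            if need_natural > 0 and li != "control":
                keep[i] = natural[i] = True
                need_natural -= 1
            elif need.get(li, 0) > 0:
                keep[i] = True
                need[li] -= 1
        if keep.any():
            chunks.append(d[keep])
            labels.append(lab[keep])
            natural_flags.append(natural[keep])

    dosages = np.concatenate(chunks, axis=0)
    label_arr = np.concatenate(labels)
    natural_arr = np.concatenate(natural_flags)
    n_total = dosages.shape[0]
    samples = pd.DataFrame({
        "IID": [f"i{k:07d}" for k in range(n_total)],
        "LABEL": label_arr,
        "SEX": rng.integers(0, 2, size=n_total),
        "NATURAL_CASE_MIX": natural_arr.astype(int),
    })
    meta = {
        "b_shared": b_shared, "b_specific": b_specific,
        "config": config, "n_drawn": n_drawn,
        "realized_prevalence": n_cases_drawn / n_drawn,
        "liability_thresholds": (float(t1), float(t2)),
    }
    logger.info("simulate_cohort: drew %d individuals for %d kept "
                "(realized prevalence %.4f)", n_drawn, n_total,
                meta["realized_prevalence"])
    return GenotypeCohort(dosages=dosages, samples=samples,
                          snvs=ref.snvs, meta=meta)


@dataclass
class PairedStudy:
    """Output of the full simulated two-GWAS design."""

    sumstats_trs: pd.DataFrame      # TRS cases vs control set 1
    sumstats_nontrs: pd.DataFrame   # non-TRS cases vs control set 2
    validation: GenotypeCohort      # held-out cases only, natural TRS mix
    reference: ReferencePanel
    meta: dict = field(default_factory=dict)


def make_paired_gwas(config: SimConfig, ref: ReferencePanel | None = None,
                     rng: np.random.Generator | None = None) -> PairedStudy:
    """Simulate the full design: two GWASs on disjoint controls + validation.

    The TRS GWAS compares TRS cases with control set 1 and the non-TRS GWAS
    compares non-TRS cases with the disjoint control set 2; both share the
    reference SNV frame.  The validation cohort holds ``n_validation`` cases
    drawn at the natural TRS mix and never used in the discovery GWASs.
    """
    config = config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if ref is None:
        ref = simulate_reference(config, rng)
    quotas = {"case_TRS": config.n_trs_cases,
              "case_nonTRS": config.n_nontrs_cases,
              "control": config.n_controls_1 + config.n_controls_2}
    cohort = simulate_cohort(config, ref=ref, rng=rng, quotas=quotas,
                             n_natural_cases=config.n_validation)
    s = cohort.samples
    is_ctrl = (s["LABEL"] == "control").to_numpy()
    ctrl_pos = np.flatnonzero(is_ctrl)
    set1 = np.zeros(len(s), dtype=bool)
    set1[ctrl_pos[:config.n_controls_1]] = True
    set2 = np.zeros(len(s), dtype=bool)
    set2[ctrl_pos[config.n_controls_1:]] = True
    natural = s["NATURAL_CASE_MIX"].to_numpy(bool)

    def pick(mask):
        return GenotypeCohort(dosages=cohort.dosages[mask],
                              samples=s[mask].reset_index(drop=True),
                              snvs=cohort.snvs, meta=cohort.meta)

    gwas1_cohort = pick((~natural & (s["LABEL"] == "case_TRS").to_numpy()) | set1)
    gwas2_cohort = pick((~natural & (s["LABEL"] == "case_nonTRS").to_numpy()) | set2)
    validation = pick(natural)
    ss1 = run_gwas(gwas1_cohort, "case_TRS", "control")
    ss2 = run_gwas(gwas2_cohort, "case_nonTRS", "control")
    meta = dict(cohort.meta)
    meta["control_ids_1"] = s.loc[set1, "IID"].tolist()
    meta["control_ids_2"] = s.loc[set2, "IID"].tolist()
    return PairedStudy(sumstats_trs=ss1, sumstats_nontrs=ss2,
                       validation=validation, reference=ref, meta=meta)


# ------------------------------------------------- direct sumstats draws

def simulate_sumstats_direct(h2: float, N: float, panel: LDScorePanel,
                             rng) -> np.ndarray:
    """z scores drawn straight from the LD-score-regression model.

    ``z_j ~ Normal(0, 1 + N*h2*l_j/M)``, independent across SNVs — a fast
    generator for exercising the heritability estimator.
    """
    if not 0 <= h2 < 1:
        raise ValidationError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    var = 1.0 + N * h2 * panel.l2 / panel.M
    return rng.standard_normal(len(panel.table)) * np.sqrt(var)


def simulate_paired_sumstats_direct(h2_1: float, h2_2: float, rg: float,
                                    N1: float, N2: float, panel: LDScorePanel,
                                    rng) -> tuple[np.ndarray, np.ndarray]:
    """Paired z scores with genetic correlation ``rg`` between the traits.

    Each trait follows the single-trait model; the polygenic components
    share a fraction ``rg`` of their architecture (``rg = 1`` is the fully
    shared case mirroring near-unity TRS/non-TRS correlation).
    """
    if not -1 <= rg <= 1:
        raise ValidationError("rg must lie in [-1, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = len(panel.table)
    lam = panel.l2 / panel.M
    a = rng.standard_normal(m)
    a2 = rng.standard_normal(m)
    g1 = np.sqrt(N1 * h2_1 * lam) * a
    g2 = np.sqrt(N2 * h2_2 * lam) * (rg * a + np.sqrt(1 - rg * rg) * a2)
    z1 = g1 + rng.standard_normal(m)
    z2 = g2 + rng.standard_normal(m)
    return z1, z2
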