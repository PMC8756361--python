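"""Clumping + P-value-thresholding polygenic risk scores and their evaluation.

The C+T pipeline greedily keeps the most significant SNV of every LD
neighbourhood (r^2 and physical-window pruning against a reference panel),
sums effect-allele dosages weighted by the training log odds ratios below a
P cutoff, and tests the standardized score against a binary phenotype by
logistic regression with covariates.  Variance explained is reported as
Nagelkerke R^2 on the observed scale and via the liability-scale conversion
of Lee et al.'s epidemiological transform; scan-level multiple testing uses
the Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import GenotypeCohort
from .errors import DegenerateInputError, SeparationError, ValidationError
from .sumstats import _COMPLEMENT

logger = logging.getLogger("casediff.prs")

DEFAULT_THRESHOLDS = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


# ---------------------------------------------------------------- clumping

def clump(sumstats: pd.DataFrame, reference: GenotypeCohort,
          r2_threshold: float = 0.1, window_kb: float = 250.0,
          allow_missing: bool = False) -> list[str]:
    """Greedy LD clumping: keep SNVs by ascending P, pruning neighbours.

    A visited SNV is kept unless its squared correlation with an
    already-kept SNV within ``window_kb`` on the same chromosome exceeds
    ``r2_threshold``.  Ties in P break by (chromosome, position).  SNVs
    absent from the reference are dropped unless ``allow_missing``; a
    warning is logged when they exceed 5% of the input.
    """
    ref_idx = {s: j for j, s in enumerate(reference.snvs["SNP"])}
    present = sumstats["SNP"].map(ref_idx).notna().to_numpy()
    n_missing = int((~present).sum())
    if n_missing > 0.05 * len(sumstats):
        logger.warning("clump: reference missing %d/%d SNVs", n_missing, len(sumstats))
    order = sumstats.sort_values(["P", "CHR", "BP"], kind="mergesort")

    G = np.asarray(reference.dosages, dtype=np.float64)
    G = G - G.mean(axis=0)
    norms = np.sqrt((G * G).sum(axis=0))

    kept: list[str] = []
    kept_by_chrom: dict[str, list[tuple[int, int]]] = {}
    window = window_kb * 1000.0
    for snp, chrom, bp in zip(order["SNP"], order["CHR"].astype(str), order["BP"]):
        j = ref_idx.get(snp)
        if j is None:
            if allow_missing:
                kept.append(snp)
            continue
        pruned = False
        for bp_k, k in kept_by_chrom.get(chrom, ()):
            if abs(bp - bp_k) > window:
                continue
            denom = norms[j] * norms[k]
            if denom == 0:
                continue
            r = float(G[:, j] @ G[:, k]) / denom
            if r * r > r2_threshold:
                pruned = True
                break
        if not pruned:
            kept.append(snp)
            kept_by_chrom.setdefault(chrom, []).append((int(bp), j))
    return kept


# ---------------------------------------------------------------- scoring

def _align_weights(weights: pd.DataFrame, snvs: pd.DataFrame) -> pd.DataFrame:
    """Match weight rows to cohort SNVs, fixing swaps/strand flips.

    Returns a frame with cohort column index ``J`` and the aligned ``BETA``;
    unresolvable alleles are dropped.
    """
    cs = snvs.reset_index()[["index", "SNP", "A1", "A2"]].rename(
        columns={"index": "J", "A1": "CA1", "A2": "CA2"})
    w = weights.merge(cs, on="SNP")
    a1, a2 = w["A1"].astype(str), w["A2"].astype(str)
    c1, c2 = w["CA1"].astype(str), w["CA2"].astype(str)
    a1f = a1.map(_COMPLEMENT)
    a2f = a2.map(_COMPLEMENT)
    same = ((a1 == c1) & (a2 == c2)) | ((a1f == c1) & (a2f == c2))
    swap = ((a1 == c2) & (a2 == c1)) | ((a1f == c2) & (a2f == c1))
    w = w[same | swap].copy()
    w["BETA"] = np.where(same[same | swap], w["BETA"], -w["BETA"])
    return w


def score(cohort: GenotypeCohort, weights: pd.DataFrame,
          threshold: float = 1.0) -> pd.DataFrame:
    """Per-individual PRS from SNVs with training P <= threshold.

    ``weights`` needs columns SNP, A1, A2, BETA and (if thresholding) P.
    Missing dosages are mean-imputed per SNV.  Returns IID, RAW and the
    z-standardized score Z.
    """
    w = weights if "P" not in weights.columns else weights[weights["P"] <= threshold]
    w = _align_weights(w, cohort.snvs)
    if w.empty:
        raise DegenerateInputError(f"no SNVs pass threshold {threshold}")
    G = np.asarray(cohort.dosages, dtype=float)[:, w["J"].to_numpy(int)]
    if np.isnan(G).any():
        means = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), means[None, :], G)
    raw = G @ w["BETA"].to_numpy(float)
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return pd.DataFrame({"IID": cohort.samples["IID"], "RAW": raw, "Z": z})


# ---------------------------------------------------------------- association

@dataclass
class PrsAssociation:
    """Logistic association of a standardized PRS with a binary phenotype."""

    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    or_lower: float
    or_upper: float
    ll_null: float
    ll_full: float
    n: int
    auc: float

    def summary(self) -> str:
        return (f"PRS association: OR per SD {self.odds_ratio:.3f} "
                f"(95% CI {self.or_lower:.3f}-{self.or_upper:.3f}), "
                f"P = {self.p:.3g}, n = {self.n}, AUC = {self.auc:.3f}")


def _auc(score_vec: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve."""
    r = stats.rankdata(score_vec)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def associate_prs(prs, phenotype, covariates=None) -> PrsAssociation:
    """Fit phenotype ~ z(PRS) + covariates by logistic regression (IRLS).

    Raises :class:`SeparationError` on (quasi-)perfect separation.
    """
    s = np.asarray(prs, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both phenotype classes must be present")
    sd = s.std()
    if sd == 0:
        raise DegenerateInputError("PRS is constant")
    s = (s - s.mean()) / sd
    X = [np.ones_like(s), s]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != s.size:
            C = C.T
        X.extend(C.T)
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X[:, 2:] - X[:, 2:].mean(axis=0)) < X.shape[1] - 2:
        raise ValidationError("covariate matrix is rank deficient")
    try:
        with np.errstate(all="ignore"):
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            null = sm.GLM(y, np.delete(X, 1, axis=1),
                          family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # statsmodels PerfectSeparation and friends
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    mu = full.fittedvalues
    if np.abs(full.params[1]) > 30 or mu.min() < 1e-10 or mu.max() > 1 - 1e-10:
        raise SeparationError("perfect or quasi-perfect separation detected")
    beta, se = float(full.params[1]), float(full.bse[1])
    zst = beta / se
    p = 2.0 * stats.norm.sf(abs(zst))
    return PrsAssociation(
        beta=beta, se=se, z=float(zst), p=float(p),
        odds_ratio=float(np.exp(beta)),
        or_lower=float(np.exp(beta - 1.96 * se)),
        or_upper=float(np.exp(beta + 1.96 * se)),
        ll_null=float(null.llf), ll_full=float(full.llf),
        n=int(y.size), auc=_auc(s, y))


# ---------------------------------------------------------------- metrics

def r2_nagelkerke(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from the two model log-likelihoods."""
    if n <= 0:
        raise ValidationError("n must be positive")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    return float(cox_snell / (1.0 - np.exp(2.0 * ll_null / n)))


def r2_liability(r2_obs: float, K: float, P: float) -> float:
    """Liability-scale variance explained from observed-scale R^2.

    Lee et al.'s transform for ascertained case-control samples: ``K`` is the
    population prevalence of the phenotype, ``P`` the sample case fraction.
    """
    if not (0 < K < 1) or not (0 < P < 1) or not (0 <= r2_obs < 1):
        raise ValidationError("require 0<K<1, 0<P<1, 0<=r2_obs<1")
    t = stats.norm.isf(K)
    zd = stats.norm.pdf(t)
    C = K * (1 - K) / (zd * zd) * K * (1 - K) / (P * (1 - P))
    mean_case = zd / K
    u = mean_case * (P - K) / (1 - K)
    theta = u * (u - t)
    return float(r2_obs * C / (1.0 + r2_obs * theta * C))


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("P values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def meta_fixed(betas, ses):
    """Inverse-variance fixed-effect pooling of effect estimates."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.size == 0:
        raise ValidationError("betas and ses must be equal-length, non-empty")
    if np.any(ses <= 0):
        raise ValidationError("standard errors must be positive")
    w = 1.0 / (ses * ses)
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def group_profile(prs, covariates, group_labels) -> pd.DataFrame:
    """Covariate-adjusted standardized PRS means per group with 95% CIs.

    PRS is residualized on the covariates by least squares (with intercept),
    z-standardized on the whole sample, then summarized per group as
    mean +/- 1.96 * sd / sqrt(n).
    """
    s = np.asarray(prs, dtype=float)
    groups = pd.Series(group_labels).reset_index(drop=True)
    if groups.nunique() < 2:
        raise ValidationError("need at least two groups")
    X = np.ones((s.size, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    resid = s - X @ np.linalg.lstsq(X, s, rcond=None)[0]
    sd = resid.std()
    z = resid / sd if sd > 0 else resid
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        vals = z[np.asarray(idx)]
        if vals.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 members")
        half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
        rows.append({"GROUP": g, "N": vals.size, "MEAN": vals.mean(),
                     "CI_LOWER": vals.mean() - half, "CI_UPPER": vals.mean() + half})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- scan

@dataclass
class PrsResult:
    """One row of a threshold scan."""

    threshold: float
    n_snvs_used: int
    beta: float
    se: float
    p: float
    q: float
    odds_ratio: float
    or_lower: float
    or_upper: float
    r2_nagelkerke: float
    r2_liability: float
    auc: float


def threshold_scan(sumstats: pd.DataFrame, cohort: GenotypeCohort,
                   phenotype, covariates=None, reference: GenotypeCohort | None = None,
                   thresholds=DEFAULT_THRESHOLDS, clump_r2: float = 0.1,
                   window_kb: float = 250.0, K: float = 0.25) -> pd.DataFrame:
    """C+T scan: clump once, then score/associate at each P threshold.

    ``K`` is the population prevalence used for the liability-scale R^2
    (for the TRS-among-cases phenotype, the TRS fraction).  FDR q values are
    computed across the scan (one training/testing pairing).
    """
    ref = reference if reference is not None else cohort
    kept = clump(sumstats, ref, r2_threshold=clump_r2, window_kb=window_kb)
    weights = sumstats[sumstats["SNP"].isin(set(kept))]
    y = np.asarray(phenotype, dtype=float)
    case_fraction = float(y.mean())
    rows = []
    for thr in sorted(thresholds):
        sel = weights[weights["P"] <= thr]
        if sel.empty:
            logger.info("threshold_scan: no SNV at P<=%g; skipped", thr)
            continue
        prs = score(cohort, sel, threshold=thr)
        assoc = associate_prs(prs["Z"].to_numpy(), y, covariates)
        r2n = r2_nagelkerke(assoc.ll_null, assoc.ll_full, assoc.n)
        rows.append(PrsResult(
            threshold=thr, n_snvs_used=int(len(sel)),
            beta=assoc.beta, se=assoc.se, p=assoc.p, q=np.nan,
            odds_ratio=assoc.odds_ratio, or_lower=assoc.or_lower,
            or_upper=assoc.or_upper, r2_nagelkerke=r2n,
            r2_liability=r2_liability(max(r2n, 0.0), K, case_fraction),
            auc=assoc.auc))
    if not rows:
        raise DegenerateInputError("no threshold yielded any SNVs")
    out = pd.DataFrame([asdict(r) for r in rows])
    out["q"] = fdr_bh(out["p"].to_numpy())
    return out


def pca_covariates(dosages: np.ndarray, k: int = 2) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix."""
    G = np.asarray(dosages, dtype=float)
    G = G - G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    G = G / sd
    u, s, _ = np.linalg.svd(G, full_matrices=False)
    return u[:, :k] * s[:k]
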