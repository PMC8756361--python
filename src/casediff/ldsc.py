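"""LD-score-regression-style estimation of heritability and genetic correlation.

Under a polygenic model, the expected association chi-square of SNV j is

    E[chi2_j] = 1 + a + N * h2 * l_j / M

where ``l_j`` is SNV j's LD score (sum of squared correlations with the SNVs
of its LD neighbourhood, including itself), ``M`` the number of modelled SNVs,
``N`` the GWAS sample size, ``h2`` the observed-scale SNV heritability and
``1 + a`` an intercept capturing confounding and miscalibration.  Regressing
chi-square on ``N*l/M`` therefore separates polygenic signal (slope) from
confounding (intercept).  For two traits the same regression on the product
``z1*z2`` estimates the genetic covariance, and the genetic correlation is
``rg = gencov / sqrt(h2_1 * h2_2)``.

The estimator here uses a single weight update (initial OLS pass, then one
weighted fit with the standard heteroskedasticity/overcounting weights
``1 / (l_j * (intercept + slope * N*l_j/M)^2)``) and a delete-a-block
jackknife over contiguous SNV blocks for standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

_VAR_FLOOR = 0.05  # floor on the modelled E[chi2] inside the weights


@dataclass
class LDScorePanel:
    """Per-SNV LD scores plus the total number of modelled SNVs M.

    ``table`` has columns ``SNP`` and ``L2`` (LD score, >= 1 when the
    self-correlation is included).
    """

    table: pd.DataFrame
    M: int

    def __post_init__(self):
        if self.M < len(self.table):
            raise ValidationError("panel M must be >= number of scored SNVs")

    @property
    def snvs(self) -> pd.Series:
        return self.table["SNP"]

    @property
    def l2(self) -> np.ndarray:
        return self.table["L2"].to_numpy(float)

    def restrict(self, snv_ids) -> "LDScorePanel":
        """Keep only the listed SNVs (e.g. a HapMap3-style marker filter).

        M is kept: the model's denominator is the panel size, not the
        regression subset.
        """
        keep = self.table["SNP"].isin(set(snv_ids))
        return LDScorePanel(table=self.table[keep].reset_index(drop=True), M=self.M)

    def write(self, path, provenance: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in provenance or []:
                fh.write(f"# {line}\n")
            fh.write(f"# M={self.M}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "LDScorePanel":
        M = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.strip().startswith("# M="):
                    M = int(line.strip().split("=", 1)[1])
        table = pd.read_csv(path, sep="\t", comment="#")
        if M is None:
            M = len(table)
        return cls(table=table, M=M)


def compute_ld_scores(dosages: np.ndarray, blocks, snv_ids=None) -> LDScorePanel:
    """LD scores from a reference dosage matrix with disjoint LD blocks.

    ``l_j`` is the sum of squared Pearson correlations of SNV j with every
    SNV of its block, including itself.  Zero-variance SNVs are dropped.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[0] < 2:
        raise ValidationError("need at least 2 individuals to correlate dosages")
    blocks = np.asarray(blocks)
    m = dosages.shape[1]
    if snv_ids is None:
        snv_ids = np.array([f"snv{j}" for j in range(m)])
    snv_ids = np.asarray(snv_ids)
    sd = dosages.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("all SNVs are constant in the reference sample")
    l2 = np.full(m, np.nan)
    for b in np.unique(blocks):
        idx = np.flatnonzero((blocks == b) & keep)
        if idx.size == 0:
            continue
        r = np.corrcoef(dosages[:, idx], rowvar=False)
        r = np.atleast_2d(r)
        l2[idx] = (r * r).sum(axis=1)
    table = pd.DataFrame({"SNP": snv_ids[keep], "L2": l2[keep]})
    return LDScorePanel(table=table, M=int(keep.sum()))


def _wls(y, x, w):
    """Two-parameter weighted least squares: returns (intercept, slope)."""
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / sw
    return intercept, slope


def _block_bounds(n, n_blocks):
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _delete_block(v, a, b):
    return np.concatenate([v[:a], v[b:]])


def _jackknife_se(loo: np.ndarray) -> np.ndarray:
    B = loo.shape[0]
    return np.sqrt((B - 1) / B * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))


def _resolve_blocks(n_snvs: int, n_blocks: int) -> int:
    n_blocks = min(n_blocks, n_snvs // 10) if n_snvs < 10 * n_blocks else n_blocks
    if n_blocks < 2:
        raise DegenerateInputError(
            f"too few SNVs ({n_snvs}) for a block jackknife")
    return n_blocks


@dataclass
class LdscFit:
    """Results of a single-trait LD-score regression."""

    intercept: float
    h2_obs: float
    se_intercept: float
    se_h2: float
    n_snvs: int
    n_blocks: int
    N: float
    mean_chi2: float
    _loo: np.ndarray = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "LD-score regression (single trait)",
            f"  SNVs: {self.n_snvs}   jackknife blocks: {self.n_blocks}   N: {self.N:g}",
            f"  mean chi2:  {self.mean_chi2:.4f}",
            f"  intercept:  {self.intercept:.4f}  (SE {self.se_intercept:.4f})",
            f"  h2 (obs):   {self.h2_obs:.4f}  (SE {self.se_h2:.4f})",
        ]
        return "\n".join(lines)


@dataclass
class LdscPairFit:
    """Results of a cross-trait LD-score regression (genetic correlation)."""

    fit1: LdscFit
    fit2: LdscFit
    gencov: float
    se_gencov: float
    cov_intercept: float
    rg: float
    se_rg: float
    rg_defined: bool
    n_blocks: int

    def summary(self) -> str:
        rg_line = (f"  rg:         {self.rg:.4f}  (SE {self.se_rg:.4f})"
                   if self.rg_defined else
                   "  rg:         undefined (non-positive h2 in a trait)")
        return "\n".join([
            "LD-score regression (cross-trait)",
            f"  gencov:     {self.gencov:.4f}  (SE {self.se_gencov:.4f})",
            f"  h2 trait 1: {self.fit1.h2_obs:.4f}  (SE {self.fit1.se_h2:.4f})",
            f"  h2 trait 2: {self.fit2.h2_obs:.4f}  (SE {self.fit2.se_h2:.4f})",
            rg_line,
        ])


class LdScoreRegression:
    """Model object for the chi-square-on-LD-score regression of one trait.

    Parameters
    ----------
    z : array
        Association z scores aligned to ``panel``'s SNVs.
    N : float
        GWAS sample size.
    panel : LDScorePanel
    n_blocks : int
        Jackknife blocks (contiguous in SNV order), auto-reduced when SNVs
        are few.
    """

    def __init__(self, z, N: float, panel: LDScorePanel, n_blocks: int = 200):
        z = np.asarray(z, dtype=float)
        if z.size != len(panel.table):
            raise ValidationError("z vector not aligned to panel SNVs")
        if N <= 1:
            raise ValidationError("N must exceed 1")
        l2 = panel.l2
        if np.ptp(l2) == 0:
            raise DegenerateInputError(
                "constant LD scores: slope and intercept are not separable")
        self.z, self.N, self.panel = z, float(N), panel
        self.l2 = l2
        self.x = self.N * l2 / panel.M
        self.n_blocks = _resolve_blocks(z.size, n_blocks)

    def weights(self, intercept: float, slope: float) -> np.ndarray:
        return self._weights(self.l2, self.x, intercept, slope)

    @staticmethod
    def _weights(l2, x, intercept: float, slope: float) -> np.ndarray:
        """Heteroskedasticity/overcounting weights at given coefficients."""
        ev = np.maximum(intercept + slope * x, _VAR_FLOOR)
        return 1.0 / (np.maximum(l2, 1.0) * ev * ev)

    @classmethod
    def _two_pass_w(cls, chi2, x, l2):
        """OLS seed, single weight update, WLS fit.

        Returns ``((intercept, slope), weights_used)``.  The clip bounds on
        the seed sit far outside its sampling range so the weights stay a
        smooth functional of the data (the variance floor guards against
        non-positive modelled variances); a kink at h = 0 would sit exactly
        on the null and spoil the jackknife.
        """
        a0, h0 = _wls(chi2, x, np.ones_like(chi2))
        a0 = float(np.clip(a0, 0.1, 10.0))
        h0 = float(np.clip(h0, -1.0, 1.0))
        w = cls._weights(l2, x, a0, h0)
        return _wls(chi2, x, w), w

    @classmethod
    def _two_pass(cls, chi2, x, l2):
        return cls._two_pass_w(chi2, x, l2)[0]

    def fit(self) -> LdscFit:
        """Fit, with the whole two-pass procedure re-run per jackknife block."""
        chi2 = self.z * self.z
        theta = self._two_pass(chi2, self.x, self.l2)
        bounds = _block_bounds(chi2.size, self.n_blocks)
        loo = np.array([
            self._two_pass(_delete_block(chi2, a, b), _delete_block(self.x, a, b),
                           _delete_block(self.l2, a, b))
            for a, b in zip(bounds[:-1], bounds[1:])])
        se = _jackknife_se(loo)
        return LdscFit(
            intercept=float(theta[0]), h2_obs=float(theta[1]),
            se_intercept=float(se[0]), se_h2=float(se[1]),
            n_snvs=int(chi2.size), n_blocks=self.n_blocks, N=self.N,
            mean_chi2=float(chi2.mean()), _loo=loo)


def estimate_h2(z, N: float, panel: LDScorePanel, n_blocks: int = 200) -> LdscFit:
    """Observed-scale SNV heritability of one trait (free intercept)."""
    return LdScoreRegression(z, N, panel, n_blocks=n_blocks).fit()


def estimate_rg(z1, N1, z2, N2, panel: LDScorePanel, n_blocks: int = 200) -> LdscPairFit:
    """Genetic correlation between two traits from their z scores.

    No sample-overlap term is modelled in the cross-trait intercept: the
    intended design uses independent control sets.  If either trait's h2
    estimate is non-positive, rg is undefined and flagged.
    """
    m1 = LdScoreRegression(z1, N1, panel, n_blocks=n_blocks)
    m2 = LdScoreRegression(z2, N2, panel, n_blocks=n_blocks)
    fit1, fit2 = m1.fit(), m2.fit()
    xc = np.sqrt(m1.N * m2.N) * panel.l2 / panel.M
    l2 = panel.l2

    def pair_fit(z1v, z2v, x1v, x2v, xcv, l2v):
        """Full pair procedure on one (sub)sample; returns (a_c, gencov, rg)."""
        (a1, h1), w1 = LdScoreRegression._two_pass_w(z1v * z1v, x1v, l2v)
        (a2, h2), w2 = LdScoreRegression._two_pass_w(z2v * z2v, x2v, l2v)
        w = np.sqrt(w1 * w2)
        ac, gencov = _wls(z1v * z2v, xcv, w)
        rg = gencov / np.sqrt(max(h1, 1e-12) * max(h2, 1e-12))
        return ac, gencov, rg

    ac, gencov, rg_point = pair_fit(m1.z, m2.z, m1.x, m2.x, xc, l2)
    n_blocks_r = min(m1.n_blocks, m2.n_blocks)
    bounds = _block_bounds(l2.size, n_blocks_r)
    loo = np.array([
        pair_fit(*(_delete_block(v, a, b) for v in (m1.z, m2.z, m1.x, m2.x, xc, l2)))
        for a, b in zip(bounds[:-1], bounds[1:])])
    se = _jackknife_se(loo)
    se_gencov = float(se[1])

    defined = fit1.h2_obs > 0 and fit2.h2_obs > 0
    rg = float(rg_point) if defined else float("nan")
    se_rg = float(se[2]) if defined else float("nan")
    return LdscPairFit(fit1=fit1, fit2=fit2, gencov=float(gencov),
                       se_gencov=se_gencov, cov_intercept=float(ac),
                       rg=rg, se_rg=se_rg,
                       rg_defined=bool(defined), n_blocks=n_blocks_r)


def h2_observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale h2 of a binary trait to the liability scale.

    ``K`` is the population prevalence, ``P`` the sample case fraction; the
    multiplier is ``K^2 (1-K)^2 / (z^2 P (1-P))`` with ``z`` the standard
    normal density at the liability threshold.
    """
    if not (0 < K < 1) or not (0 < P < 1):
        raise ValidationError("K and P must lie in (0, 1)")
    t = stats.norm.isf(K)
    zd = stats.norm.pdf(t)
    return h2_obs * K * K * (1 - K) ** 2 / (zd * zd * P * (1 - P))
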