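"""Clumping, scoring, PRS association, variance conversions, FDR and pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casediff.cohort import GenotypeCohort
from casediff.errors import DegenerateInputError, SeparationError, ValidationError
from casediff.prs import (
    associate_prs,
    clump,
    fdr_bh,
    group_profile,
    meta_fixed,
    pca_covariates,
    r2_liability,
    r2_nagelkerke,
    score,
    threshold_scan,
)


def _two_snv_reference(r2: float, gap_bp: int, n: int = 400, seed: int = 0):
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=n)
    rho = np.sqrt(r2)
    z1 = shared
    z2 = rho * shared + np.sqrt(1 - rho * rho) * rng.normal(size=n)
    dos = np.column_stack([(z1 > 0).astype(float) + (z1 > 1),
                           (z2 > 0).astype(float) + (z2 > 1)])
    snvs = pd.DataFrame({"SNP": ["rs1", "rs2"], "CHR": "1",
                         "BP": [10_000, 10_000 + gap_bp],
                         "A1": "A", "A2": "G", "MAF": 0.3, "BLOCK": 0})
    samples = pd.DataFrame({"IID": [f"i{k}" for k in range(n)],
                            "LABEL": "control", "SEX": 0})
    return GenotypeCohort(dosages=dos, samples=samples, snvs=snvs)


class TestClump:
    def _ss(self, ps, bps):
        return pd.DataFrame({"SNP": ["rs1", "rs2"], "CHR": "1", "BP": bps,
                             "A1": "A", "A2": "G", "EAF": 0.3, "BETA": 0.1,
                             "SE": 0.05, "P": ps, "N_CAS": 100, "N_CON": 100})

    def test_correlated_neighbour_pruned(self):
        ref = _two_snv_reference(r2=0.5, gap_bp=10_000)
        kept = clump(self._ss([1e-8, 1e-4], [10_000, 20_000]), ref)
        assert kept == ["rs1"]

    def test_weakly_correlated_pair_both_kept(self):
        ref = _two_snv_reference(r2=0.0, gap_bp=10_000, seed=3)
        kept = clump(self._ss([1e-8, 1e-4], [10_000, 20_000]), ref)
        assert sorted(kept) == ["rs1", "rs2"]

    def test_window_rule_ignores_distant_pair(self):
        ref = _two_snv_reference(r2=0.9, gap_bp=300_000)
        kept = clump(self._ss([1e-8, 1e-4], [10_000, 310_000]), ref)
        assert sorted(kept) == ["rs1", "rs2"]

    def test_missing_snvs_dropped_unless_allowed(self):
        ref = _two_snv_reference(r2=0.0, gap_bp=10_000)
        ss = self._ss([1e-8, 1e-4], [10_000, 20_000])
        ss.loc[1, "SNP"] = "rs_absent"
        assert clump(ss, ref) == ["rs1"]
        assert sorted(clump(ss, ref, allow_missing=True)) == ["rs1", "rs_absent"]

    def test_deterministic(self, tiny_study):
        from casediff.interaction import run_interaction_gwas, interaction_to_sumstats
        from casediff.sumstats import harmonize

        ss = interaction_to_sumstats(run_interaction_gwas(
            harmonize(tiny_study.sumstats_trs, tiny_study.sumstats_nontrs)))
        ref = GenotypeCohort(
            dosages=tiny_study.reference.dosages,
            samples=pd.DataFrame({
                "IID": [f"r{k}" for k in range(tiny_study.reference.dosages.shape[0])],
                "LABEL": "control", "SEX": 0}),
            snvs=tiny_study.reference.snvs)
        assert clump(ss, ref) == clump(ss, ref)


class TestScore:
    def _cohort(self, dosages):
        n, m = dosages.shape
        return GenotypeCohort(
            dosages=dosages,
            samples=pd.DataFrame({"IID": [f"i{k}" for k in range(n)],
                                  "LABEL": "control", "SEX": 0}),
            snvs=pd.DataFrame({"SNP": [f"rs{j}" for j in range(m)], "CHR": "1",
                               "BP": 1000 * np.arange(m), "A1": "A", "A2": "G",
                               "MAF": 0.3, "BLOCK": 0}))

    def _weights(self, betas):
        m = len(betas)
        return pd.DataFrame({"SNP": [f"rs{j}" for j in range(m)],
                             "A1": "A", "A2": "G", "BETA": betas,
                             "P": np.full(m, 0.5)})

    def test_weighted_sum_arithmetic(self):
        cohort = self._cohort(np.array([[2.0, 1.0]]))
        prs = score(cohort, self._weights([0.1, -0.2]))
        assert prs["RAW"].iloc[0] == pytest.approx(0.0)

    def test_missing_dosage_mean_imputed(self):
        dos = np.array([[2.0, 1.0], [1.0, np.nan], [0.0, 1.4]])
        prs = score(self._cohort(dos), self._weights([0.0, 1.0]))
        assert prs["RAW"].iloc[1] == pytest.approx(1.2)

    def test_doubling_weights_scales_raw_not_z(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(50, 4)).astype(float)
        w = self._weights([0.1, 0.2, -0.1, 0.05])
        w2 = w.assign(BETA=2 * w["BETA"])
        p1, p2 = score(self._cohort(dos), w), score(self._cohort(dos), w2)
        assert np.allclose(p2["RAW"], 2 * p1["RAW"])
        assert np.allclose(p2["Z"], p1["Z"])

    def test_swapped_alleles_negate_contribution(self):
        dos = np.array([[2.0], [1.0], [0.0]])
        w = pd.DataFrame({"SNP": ["rs0"], "A1": "G", "A2": "A",
                          "BETA": [0.5], "P": [0.5]})
        prs = score(self._cohort(dos), w)
        # dosage counts A; weight is for G, so contribution flips sign
        assert np.allclose(prs["RAW"], [-1.0, -0.5, 0.0])

    def test_no_snv_passing_threshold_rejected(self):
        cohort = self._cohort(np.array([[1.0, 2.0]]))
        with pytest.raises(DegenerateInputError):
            score(cohort, self._weights([0.1, 0.2]), threshold=1e-10)


class TestAssociatePrs:
    def test_null_prs_rejection_rate(self):
        """Independent PRS: |z| < 1.96 in about 95% of seeds."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            s = rng.normal(size=2000)
            y = rng.binomial(1, 0.3, 2000)
            hits += abs(associate_prs(s, y).z) < 1.96
        assert hits >= 33  # binomial 99% band around 0.95*40

    def test_intercept_only_recovers_logit_case_fraction(self):
        rng = np.random.default_rng(2)
        y = rng.binomial(1, 0.35, 3000)
        a = associate_prs(rng.normal(size=3000), y)
        # null model log-likelihood equals Bernoulli at the case fraction
        phat = y.mean()
        ll = 3000 * (phat * np.log(phat) + (1 - phat) * np.log(1 - phat))
        assert a.ll_null == pytest.approx(ll, rel=1e-6)

    def test_perfect_separation_raises(self):
        s = np.r_[np.ones(50), -np.ones(50)]
        y = np.r_[np.ones(50), np.zeros(50)]
        with pytest.raises(SeparationError):
            associate_prs(s, y)

    def test_effect_recovered_with_covariates(self):
        rng = np.random.default_rng(3)
        n = 4000
        s = rng.normal(size=n)
        sex = rng.integers(0, 2, n)
        logit = -1.0 + 0.5 * s + 0.3 * sex
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        a = associate_prs(s, y, covariates=sex.astype(float))
        assert abs(a.beta - 0.5) < 3 * a.se
        assert a.or_lower < a.odds_ratio < a.or_upper
        assert 0.5 < a.auc < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            associate_prs(np.random.default_rng(0).normal(size=10), np.ones(10))


class TestVarianceMetrics:
    def test_nagelkerke_zero_when_no_improvement(self):
        assert r2_nagelkerke(-100.0, -100.0, 200) == 0.0

    def test_nagelkerke_monotone_and_bounded(self):
        vals = [r2_nagelkerke(-100.0, ll, 200) for ll in (-90, -70, -50, -1e-9)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= 1.0

    def test_liability_zero_maps_to_zero(self):
        assert r2_liability(0.0, 0.25, 0.3) == 0.0

    def test_liability_balanced_case_closed_form(self):
        # K = P: theta = 0 so r2_l = C * r2_obs; at K = 0.5, C = pi/2
        assert r2_liability(0.1, 0.5, 0.5) == pytest.approx(0.1 * 1.570796, abs=1e-6)

    def test_liability_monotone_in_observed_r2(self):
        vals = [r2_liability(r, 0.25, 0.4) for r in (0.0, 0.05, 0.1, 0.3)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            r2_liability(1.5, 0.25, 0.4)


def brute_force_bh(p):
    """Direct step-up definition: q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_i, m))
    return q


class TestFdrBH:
    def test_textbook_vectors(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(fdr_bh([0.001, 0.5]), [0.002, 0.5])
        assert fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_equals_brute_force_definition(self, p):
        assert np.allclose(fdr_bh(p), brute_force_bh(p), atol=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(1e-6, 1, 200)
        assert np.allclose(fdr_bh(p), multipletests(p, method="fdr_bh")[1])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, 100)
        assert np.all(fdr_bh(p) >= p - 1e-15)


class TestMetaFixed:
    def test_single_study_unchanged(self):
        b, se, _ = meta_fixed([0.2], [0.1])
        assert b == pytest.approx(0.2, abs=1e-15)
        assert se == pytest.approx(0.1, abs=1e-15)

    def test_two_identical_studies(self):
        b, se, _ = meta_fixed([0.2, 0.2], [0.1, 0.1])
        assert b == pytest.approx(0.2)
        assert se == pytest.approx(0.070711, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 1)),
                    min_size=1, max_size=8))
    def test_pooled_se_never_exceeds_best_input(self, studies):
        betas = [s[0] for s in studies]
        ses = [s[1] for s in studies]
        _, se, _ = meta_fixed(betas, ses)
        assert se <= min(ses) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            meta_fixed([0.1, 0.2], [0.1])


class TestGroupProfile:
    def test_null_groups_cover_zero(self):
        rng = np.random.default_rng(21)
        s = rng.normal(size=400)
        groups = ["a"] * 200 + ["b"] * 200
        prof = group_profile(s, None, groups)
        assert ((prof["CI_LOWER"] <= 0) & (0 <= prof["CI_UPPER"])).all()

    def test_constant_covariate_changes_nothing(self):
        rng = np.random.default_rng(22)
        s = rng.normal(size=100)
        groups = ["a"] * 50 + ["b"] * 50
        p1 = group_profile(s, None, groups)
        p2 = group_profile(s, np.ones(100), groups)
        assert np.allclose(p1["MEAN"], p2["MEAN"])

    def test_grand_mean_is_zero(self):
        rng = np.random.default_rng(23)
        s = rng.normal(size=300)
        groups = ["a"] * 100 + ["b"] * 100 + ["c"] * 100
        prof = group_profile(s, rng.normal(size=300), groups)
        grand = (prof["MEAN"] * prof["N"]).sum() / prof["N"].sum()
        assert abs(grand) < 1e-10

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            group_profile(np.arange(10.0), None, ["a"] * 10)


class TestThresholdScan:
    @pytest.fixture(scope="class")
    def scan(self, tiny_study):
        from casediff.interaction import run_interaction_gwas, interaction_to_sumstats
        from casediff.sumstats import harmonize

        ss = interaction_to_sumstats(run_interaction_gwas(
            harmonize(tiny_study.sumstats_trs, tiny_study.sumstats_nontrs)))
        val = tiny_study.validation
        y = (val.samples["LABEL"] == "case_TRS").to_numpy(float)
        covs = np.column_stack([val.samples["SEX"].to_numpy(float),
                                pca_covariates(val.dosages, 2)])
        ref = GenotypeCohort(
            dosages=tiny_study.reference.dosages,
            samples=pd.DataFrame({
                "IID": [f"r{k}" for k in range(tiny_study.reference.dosages.shape[0])],
                "LABEL": "control", "SEX": 0}),
            snvs=tiny_study.reference.snvs)
        return threshold_scan(ss, val, y, covariates=covs, reference=ref, K=0.25)

    def test_snv_count_weakly_increasing_with_threshold(self, scan):
        assert (np.diff(scan["n_snvs_used"]) >= 0).all()

    def test_q_at_least_p_and_r2_bounds(self, scan):
        assert (scan["q"] >= scan["p"] - 1e-15).all()
        assert scan["r2_liability"].between(0, 1).all()
        assert scan["r2_nagelkerke"].max() == scan["r2_nagelkerke"].iloc[
            scan["r2_nagelkerke"].idxmax()]

    def test_empty_thresholds_skipped(self, scan):
        # 5e-8 yields no SNV at desk scale and must be absent, not failing
        assert 5e-8 not in set(scan["threshold"])


def test_pca_covariates_shape_and_orthogonality():
    rng = np.random.default_rng(30)
    d = rng.integers(0, 3, size=(120, 40)).astype(float)
    pcs = pca_covariates(d, k=3)
    assert pcs.shape == (120, 3)
    gram = pcs.T @ pcs
    off = gram - np.diag(np.diag(gram))
    assert np.all(np.abs(off) < 1e-8 * np.abs(gram).max())
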