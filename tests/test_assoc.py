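"""Association engine: closed-form oracle, GLM cross-check, inflation."""

import numpy as np
import pandas as pd
import pytest

from caseonly.assoc import (CASE_ONLY, CONTROL_ONLY, Contrast, compute_pcs,
                            contrast_mask, fit_case_only, fit_control_only,
                            fit_variant, genomic_inflation,
                            heterogeneity_by_country, leave_one_country_out,
                            scan)
from caseonly.simdata import SimConfig, simulate_cohorts


def _two_by_two_samples(a, b, c, d):
    """CIMBA cases a with allele / b without; BCAC cases c with / d without."""
    cohort = ["CIMBA"] * (a + b) + ["BCAC"] * (c + d)
    dosage = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    n = len(cohort)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "cohort": cohort, "status": "case",
        "carrier_gene": ["BRCA1" if x == "CIMBA" else "none" for x in cohort],
        "age": 50.0, "country": "C1", "er_status": "unknown",
    })
    return dosage, samples


def test_unadjusted_fit_equals_closed_form_or():
    dosage, samples = _two_by_two_samples(30, 70, 200, 800)
    res = fit_case_only(dosage, samples, adjust=(), min_cimba_per_country=0)
    expected = (30 * 800) / (70 * 200)
    assert res.or_ == pytest.approx(expected, rel=1e-6)
    assert res.p < 0.05


def test_fit_matches_statsmodels_glm(small_cohorts):
    """Dual-route check: own IRLS vs an independent GLM fit with covariates."""
    import statsmodels.api as sm

    _, matrix, samples, _ = small_cohorts
    contrast = CASE_ONLY("BRCA1")
    mask = contrast_mask(samples, contrast, 0)
    sub = samples.loc[mask]
    d = matrix.dosage_for("var00002")[mask]
    y = (sub["cohort"] == "CIMBA").astype(float).to_numpy()
    X = pd.get_dummies(sub[["age", "country"]], columns=["country"], drop_first=True)
    X = sm.add_constant(X.astype(float))
    X["dosage"] = d
    full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    red = sm.GLM(y, X.drop(columns="dosage"), family=sm.families.Binomial()).fit()
    from scipy import stats
    lrt_p = stats.chi2.sf(2 * (full.llf - red.llf), 1)

    res = fit_case_only(d, sub, min_cimba_per_country=0)
    assert res.beta == pytest.approx(full.params["dosage"], abs=1e-5)
    assert res.se == pytest.approx(full.bse["dosage"], rel=1e-4)
    assert res.p == pytest.approx(lrt_p, rel=1e-3, abs=1e-12)


def test_constant_dosage_gives_p_one(toy_samples):
    res = fit_case_only(np.ones(len(toy_samples)), toy_samples,
                        adjust=("age", "country"), min_cimba_per_country=0)
    assert res.p == 1.0 and res.beta == 0.0


def test_er_restriction_applies_to_population_side_only(small_cohorts):
    _, matrix, samples, _ = small_cohorts
    mask = contrast_mask(samples, Contrast("case_only_er_neg", "BRCA1"), 0)
    sub = samples.loc[mask]
    bcac = sub[sub.cohort == "BCAC"]
    cimba = sub[sub.cohort == "CIMBA"]
    assert (bcac.er_status == "negative").all()
    assert set(cimba.er_status.unique()) - {"negative"}  # carriers not filtered
    assert (sub.status == "case").all()


def test_country_minimum_drops_small_strata(small_cohorts):
    _, _, samples, _ = small_cohorts
    few = samples.copy()
    # shrink one country's CIMBA cases below the threshold
    c1_cimba_cases = few[(few.country == "C1") & (few.cohort == "CIMBA")
                         & (few.status == "case")].index
    few = few.drop(c1_cimba_cases[5:])
    mask = contrast_mask(few, CASE_ONLY("BRCA1"), min_cimba_per_country=10)
    assert "C1" not in set(few.loc[mask, "country"])


class TestInflation:
    def test_lambda_one_fixed_point(self):
        assert genomic_inflation(lam=1.0, n=123, m=45).lambda_1000 == pytest.approx(1.0)

    def test_identity_at_n_m_1000(self):
        assert genomic_inflation(lam=1.5, n=1000, m=1000).lambda_1000 == pytest.approx(1.5)

    def test_published_study_sizes(self):
        out = genomic_inflation(lam=1.2, n=60_212, m=7_257)
        assert out.lambda_1000 == pytest.approx(1.0154, abs=5e-5)

    def test_limit_large_n_m(self):
        out = genomic_inflation(lam=1.4, n=10**9, m=10**9)
        assert out.lambda_1000 == pytest.approx(1.0, abs=1e-5)

    def test_from_p_values(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=5000)
        out = genomic_inflation(p_values=p, n=1000, m=1000)
        assert out.lam == pytest.approx(1.0, abs=0.06)

    def test_too_few_statistics(self):
        with pytest.raises(ValueError, match="100"):
            genomic_inflation(p_values=np.full(10, 0.5), n=10, m=10)


class TestPcs:
    def test_pc1_separates_subpopulations(self):
        cfg = SimConfig(n_bcac_cases=500, n_bcac_controls=50, n_cimba_cases=500,
                        n_cimba_unaffected=50, n_blocks=50, snps_per_block=4,
                        ld_rho=0.0, fst_like_shift=0.1, genotyped_fraction=1.0,
                        subpop_b_prob={"BCAC": 0.5, "CIMBA": 0.5}, seed=21)
        matrix, samples, _ = simulate_cohorts(cfg)
        pcs = compute_pcs(matrix, 4)
        subpop = (samples["subpop"] == "B").astype(float)
        assert abs(np.corrcoef(pcs[:, 0], subpop)[0, 1]) > 0.8

    def test_no_structure_no_separation(self):
        cfg = SimConfig(n_bcac_cases=400, n_bcac_controls=50, n_cimba_cases=400,
                        n_cimba_unaffected=50, n_blocks=40, snps_per_block=4,
                        ld_rho=0.0, fst_like_shift=0.0, genotyped_fraction=1.0, seed=22)
        matrix, samples, _ = simulate_cohorts(cfg)
        pcs = compute_pcs(matrix, 4)
        subpop = (samples["subpop"] == "B").astype(float)
        assert abs(np.corrcoef(pcs[:, 0], subpop)[0, 1]) < 0.2

    def test_pcs_deterministic(self, small_cohorts):
        _, matrix, _, _ = small_cohorts
        a = compute_pcs(matrix, 4)
        b = compute_pcs(matrix, 4)
        np.testing.assert_array_equal(a, b)

    def test_too_few_variants(self, small_cohorts):
        _, matrix, _, _ = small_cohorts
        with pytest.raises(ValueError, match="PCs"):
            compute_pcs(matrix.subset_variants(np.arange(matrix.n_variants) < 2), 4)


def test_pc_adjustment_reduces_inflation():
    """Structured-null confounding inflates lambda; PCs restore calibration."""
    cfg = SimConfig(n_bcac_cases=600, n_bcac_controls=60, n_cimba_cases=600,
                    n_cimba_unaffected=60, n_blocks=60, snps_per_block=4,
                    ld_rho=0.0, fst_like_shift=0.08, genotyped_fraction=1.0,
                    subpop_b_prob={"BCAC": 0.3, "CIMBA": 0.7}, seed=23)
    matrix, samples, _ = simulate_cohorts(cfg)
    res0 = scan(matrix, samples, CASE_ONLY("BRCA1"), min_cimba_per_country=0)
    lam0 = genomic_inflation(res0["p"], n=600, m=600)
    pcs = compute_pcs(matrix, 4)
    res1 = scan(matrix, samples, CASE_ONLY("BRCA1"), adjust=("age", "country", "pcs"),
                pcs=pcs, min_cimba_per_country=0)
    lam1 = genomic_inflation(res1["p"], n=600, m=600)
    assert lam0.lam > 1.1
    assert lam1.lam < lam0.lam
    assert abs(lam1.lambda_1000 - 1.0) < abs(lam0.lambda_1000 - 1.0)


class TestHeterogeneity:
    def _country_effect_data(self, beta_by_country, n_per=1500, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        dosage = []
        for ci, (country, beta) in enumerate(beta_by_country.items()):
            d = rng.binomial(2, 0.3, n_per).astype(float)
            eta = 0.0 + beta * d
            is_cimba = rng.random(n_per) < 1 / (1 + np.exp(-eta))
            for i in range(n_per):
                rows.append({
                    "sample_id": f"s{ci}_{i}",
                    "cohort": "CIMBA" if is_cimba[i] else "BCAC",
                    "status": "case",
                    "carrier_gene": "BRCA1" if is_cimba[i] else "none",
                    "age": float(rng.uniform(35, 65)),
                    "country": country, "er_status": "unknown",
                })
            dosage.append(d)
        return np.concatenate(dosage), pd.DataFrame(rows)

    def test_departing_country_detected(self):
        d, samples = self._country_effect_data(
            {"C1": np.log(1.8), "C2": 0.0, "C3": 0.0, "C4": 0.0}, seed=1)
        p, df = heterogeneity_by_country(d, samples, CASE_ONLY("BRCA1"),
                                         min_cimba_per_country=0)
        assert df == 3 and p < 0.05

    def test_homogeneous_effect_null(self):
        d, samples = self._country_effect_data(
            {c: np.log(1.3) for c in ["C1", "C2", "C3", "C4"]}, seed=2)
        p, df = heterogeneity_by_country(d, samples, CASE_ONLY("BRCA1"),
                                         min_cimba_per_country=0)
        assert p > 0.001

    def test_single_country_rejected(self):
        d, samples = self._country_effect_data({"C1": 0.0}, n_per=200, seed=3)
        with pytest.raises(ValueError, match="countr"):
            heterogeneity_by_country(d, samples, CASE_ONLY("BRCA1"),
                                     min_cimba_per_country=0)

    def test_leave_one_out_flags_driving_country(self):
        d, samples = self._country_effect_data(
            {"C1": np.log(2.2), "C2": 0.0, "C3": 0.0, "C4": 0.0}, seed=4)
        tab = leave_one_country_out(d, samples, CASE_ONLY("BRCA1"),
                                    min_cimba_per_country=0)
        assert tab.loc[tab.excluded_country == "C1", "outside_full_ci"].item()

    def test_leave_one_out_homogeneous_stable(self):
        d, samples = self._country_effect_data(
            {c: np.log(1.3) for c in ["C1", "C2", "C3"]}, seed=5)
        tab = leave_one_country_out(d, samples, CASE_ONLY("BRCA1"),
                                    min_cimba_per_country=0)
        assert not tab["outside_full_ci"].any()

    def test_leave_one_out_needs_three_countries(self):
        d, samples = self._country_effect_data({"C1": 0.0, "C2": 0.0}, n_per=300, seed=6)
        with pytest.raises(ValueError, match="3"):
            leave_one_country_out(d, samples, CASE_ONLY("BRCA1"),
                                  min_cimba_per_country=0)


def test_control_only_detects_linked_variant(small_cohorts):
    _, matrix, samples, truth = small_cohorts
    linked = truth.loc[truth.carrier_linked, "variant_id"].item()
    res = fit_control_only(matrix.dosage_for(linked), samples, min_cimba_per_country=0)
    assert res.p < 1e-4
    null = fit_control_only(matrix.dosage_for("var00000"), samples, min_cimba_per_country=0)
    assert null.p > 1e-4
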