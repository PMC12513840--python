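"""Causal integration: coloc oracle, MR estimators, tiers, convergence."""

import math

import numpy as np
import pandas as pd
import pytest

from metabogen.causal import (
    MRResult,
    apply_mr_filters,
    bh_fdr,
    coloc_abf,
    instrument_tiers,
    ivw,
    ldl_independence,
    level_locus_convergence,
    mr_analysis,
    mr_egger,
    wald_ratio,
)
from metabogen.finemap import wakefield_log_abf


def brute_force_coloc(b1, s1, b2, s2, p1=1e-4, p2=1e-4, p12=5e-6, w=0.04):
    """Independent enumeration of the five hypotheses in extended precision."""
    m = len(b1)
    abf1 = [np.exp(np.longdouble(wakefield_log_abf(b1[j], s1[j], w))) for j in range(m)]
    abf2 = [np.exp(np.longdouble(wakefield_log_abf(b2[j], s2[j], w))) for j in range(m)]
    h = [np.longdouble(0)] * 5
    h[0] = np.longdouble(1)
    for j in range(m):
        h[1] += p1 * abf1[j]
        h[2] += p2 * abf2[j]
        h[4] += p12 * abf1[j] * abf2[j]
    for i in range(m):
        for j in range(m):
            if i != j:
                h[3] += p1 * p2 * abf1[i] * abf2[j]
    total = sum(h)
    return np.array([float(x / total) for x in h])


class TestColoc:
    def _stats(self, betas, ses):
        return pd.DataFrame({"beta": betas, "se": ses})

    def test_three_variant_toy_matches_brute_force(self):
        b1, s1 = [0.3, 0.05, 0.01], [0.04, 0.04, 0.05]
        b2, s2 = [0.25, 0.02, 0.0], [0.05, 0.05, 0.04]
        res = coloc_abf(self._stats(b1, s1), self._stats(b2, s2), min_variants=2)
        expected = brute_force_coloc(b1, s1, b2, s2)
        assert np.allclose(res.pp, expected, atol=1e-10)

    def test_random_grids_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(2, 10))
            b1 = rng.normal(0, 0.2, m)
            b2 = rng.normal(0, 0.2, m)
            s1 = rng.uniform(0.01, 0.1, m)
            s2 = rng.uniform(0.01, 0.1, m)
            res = coloc_abf(self._stats(b1, s1), self._stats(b2, s2), min_variants=2)
            assert np.allclose(res.pp, brute_force_coloc(b1, s1, b2, s2), atol=1e-10)
            assert res.pp.sum() == pytest.approx(1.0, abs=1e-10)

    def test_null_outcome_gives_h0_h1_mass(self):
        rng = np.random.default_rng(1)
        b1 = np.r_[0.5, rng.normal(0, 0.01, 19)]
        b2 = rng.normal(0, 0.01, 20)
        se = np.full(20, 0.01)
        res = coloc_abf(self._stats(b1, se), self._stats(b2, se))
        assert res.pp[0] + res.pp[1] > 0.9

    def test_p12_monotonically_raises_pp4(self):
        rng = np.random.default_rng(2)
        b = np.r_[0.09, rng.normal(0, 0.02, 9)]  # moderate shared signal
        se = np.full(10, 0.02)
        s1, s2 = self._stats(b, se), self._stats(b * 0.8, se)
        pp4s = [coloc_abf(s1, s2, p12=p12).pp[4] for p12 in (1e-8, 1e-6, 5e-6, 1e-4)]
        assert all(np.diff(pp4s) > 0)

    def test_few_shared_variants_flagged(self):
        res = coloc_abf(self._stats([0.1], [0.05]), self._stats([0.1], [0.05]))
        assert res.low_confidence


class TestWaldRatio:
    def test_arithmetic(self):
        res = wald_ratio(0.2, 0.01, 0.06, 0.01)
        assert res["beta"] == pytest.approx(0.3)
        assert res["se"] == pytest.approx(0.05)

    def test_null_outcome(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.01)["beta"] == 0.0

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.06, 0.01)

    def test_weak_instrument_flagged(self):
        assert wald_ratio(0.01, 0.01, 0.0, 0.01)["weak_instrument"]


class TestIvw:
    def test_shared_ratio_recovered_exactly(self, toy_instruments):
        assert ivw(toy_instruments)["beta"] == pytest.approx(0.3)

    def test_hand_computed_weighted_formula(self):
        tab = pd.DataFrame(
            {
                "beta_exposure": [0.1, 0.2, 0.25],
                "se_exposure": 0.01,
                "beta_outcome": [0.02, 0.07, 0.08],
                "se_outcome": [0.02, 0.01, 0.03],
            }
        )
        w = 1 / tab["se_outcome"] ** 2
        expected = (w * tab["beta_exposure"] * tab["beta_outcome"]).sum() / (
            w * tab["beta_exposure"] ** 2
        ).sum()
        res = ivw(tab)
        assert res["beta"] == pytest.approx(expected)
        assert res["se"] == pytest.approx(1 / math.sqrt((w * tab["beta_exposure"] ** 2).sum()))

    def test_single_instrument_rejected(self, toy_instruments):
        with pytest.raises(ValueError):
            ivw(toy_instruments.iloc[:1])


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        tab = pd.DataFrame(
            {
                "beta_exposure": bx,
                "se_exposure": 0.01,
                "beta_outcome": 0.1 + 0.3 * bx,
                "se_outcome": [0.01, 0.02, 0.01, 0.03],
            }
        )
        res = mr_egger(tab)
        assert res["intercept"] == pytest.approx(0.1, abs=1e-10)
        assert res["beta"] == pytest.approx(0.3, abs=1e-10)

    def test_orientation_flips_negative_exposures(self):
        bx = np.array([0.1, -0.2, 0.3])
        tab = pd.DataFrame(
            {
                "beta_exposure": bx,
                "se_exposure": 0.01,
                "beta_outcome": 0.3 * bx,
                "se_outcome": 0.01,
            }
        )
        res = mr_egger(tab)
        assert res["beta"] == pytest.approx(0.3, abs=1e-10)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_balanced_pleiotropy_slope_unbiased(self):
        rng = np.random.default_rng(3)
        slopes, intercepts = [], []
        for _ in range(100):
            bx = rng.uniform(0.05, 0.2, 50)
            alpha = rng.normal(0, 0.01, 50)
            tab = pd.DataFrame(
                {
                    "beta_exposure": bx,
                    "se_exposure": 0.003,
                    "beta_outcome": 0.3 * bx + alpha + rng.normal(0, 0.01, 50),
                    "se_outcome": 0.01,
                }
            )
            res = mr_egger(tab)
            slopes.append(res["beta"])
            intercepts.append(res["intercept"])
        assert abs(np.mean(slopes) - 0.3) < 0.05
        assert abs(np.mean(intercepts)) < 0.005

    def test_too_few_instruments(self, toy_instruments):
        with pytest.raises(ValueError):
            mr_egger(toy_instruments.iloc[:2])


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestTiers:
    def _setup(self):
        leads = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "trait_id": ["t", "t", "t"],
                "group_id": [0, 1, 2],
            }
        )
        sentinels = leads.iloc[:1].copy()
        modes = {0: "specific", 1: "pathway", 2: "nonspecific"}
        efo = {0: "specific", 1: "unspecific", 2: "specific"}
        return leads, sentinels, modes, efo

    def test_mode_filter_removes_nonspecific(self):
        leads, sent, modes, efo = self._setup()
        tiers = instrument_tiers(leads, sent, modes, efo)
        assert set(tiers["molecular_filtered"]["variant_id"]) == {"v1", "v2"}

    def test_efo_filter_additionally_requires_specific(self):
        leads, sent, modes, efo = self._setup()
        tiers = instrument_tiers(leads, sent, modes, efo)
        assert set(tiers["molecular_phenotypic_filtered"]["variant_id"]) == {"v1"}

    def test_tier_nesting(self):
        leads, sent, modes, efo = self._setup()
        tiers = instrument_tiers(leads, sent, modes, efo)
        t2 = set(tiers["leads"]["variant_id"])
        t3 = set(tiers["molecular_filtered"]["variant_id"])
        t4 = set(tiers["molecular_phenotypic_filtered"]["variant_id"])
        assert t4 <= t3 <= t2

    def test_all_specific_makes_tiers_identical(self):
        leads, sent, _, _ = self._setup()
        modes = {g: "specific" for g in range(3)}
        efo = {g: "specific" for g in range(3)}
        tiers = instrument_tiers(leads, sent, modes, efo)
        assert set(tiers["molecular_phenotypic_filtered"]["variant_id"]) == set(leads["variant_id"])


class TestFiltersAndConvergence:
    def _mr(self, exposure="t", outcome="cad", tier="leads", p=1e-5, intercept_p=0.5,
            beta=0.3, egger=0.28, med=0.29):
        r = MRResult(exposure, outcome, tier, beta_ivw=beta, se_ivw=0.05, p_ivw=p)
        r.beta_egger, r.egger_intercept_p, r.median_wald = egger, intercept_p, med
        return r

    def test_pass_filters_requires_all_conditions(self):
        good = self._mr()
        pleiotropic = self._mr(intercept_p=1e-6)
        discordant = self._mr(egger=-0.2)
        out = apply_mr_filters([good, pleiotropic, discordant])
        assert out[0].pass_filters
        assert not out[1].pass_filters
        assert not out[2].pass_filters

    def test_ldl_independence_readings(self):
        ldl = pd.DataFrame({"beta": [0.02, 0.01], "p": [1e-5, 1e-3]})
        effects = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        # no genome-wide LDL hit, small LDL betas below the 80th percentile
        assert ldl_independence(ldl, effects) is True
        strong = pd.DataFrame({"beta": [0.45], "p": [1e-12]})
        assert ldl_independence(strong, effects) is False
        # 'or' reading: either missing condition suffices
        mid = pd.DataFrame({"beta": [0.45], "p": [1e-3]})  # high rank, not significant
        assert ldl_independence(mid, effects, rank_rule="and") is False
        assert ldl_independence(mid, effects, rank_rule="or") is True

    def test_convergence_table(self):
        mr = apply_mr_filters([self._mr(), self._mr(outcome="stroke", p=0.9)])
        coloc = pd.DataFrame(
            {
                "group_id": [0, 1],
                "trait_id": ["t", "t"],
                "outcome": ["cad", "stroke"],
                "pp4": [0.95, 0.95],
            }
        )
        modes = {0: "specific", 1: "nonspecific"}
        ldl_stats = {0: pd.DataFrame({"beta": [0.01], "p": [0.5]})}
        effects = {0: np.linspace(0.1, 0.5, 10)}
        out = level_locus_convergence(mr, coloc, modes, ldl_stats, effects)
        assert len(out) == 1  # stroke fails the level filter; cad converges
        row = out.iloc[0]
        assert row["outcome"] == "cad"
        assert bool(row["ldl_independent"]) is True

    def test_unspecific_locus_excluded_from_locus_effects(self):
        mr = apply_mr_filters([self._mr()])
        coloc = pd.DataFrame(
            {"group_id": [1], "trait_id": ["t"], "outcome": ["cad"], "pp4": [0.99]}
        )
        out = level_locus_convergence(mr, coloc, {1: "nonspecific"})
        assert out.empty

    def test_no_coloc_gives_empty_table(self):
        mr = apply_mr_filters([self._mr()])
        coloc = pd.DataFrame(columns=["group_id", "trait_id", "outcome", "pp4"])
        assert level_locus_convergence(mr, coloc, {}).empty

    def test_most_stringent_tier_prioritized(self):
        mr = apply_mr_filters(
            [self._mr(tier="leads"), self._mr(tier="molecular_phenotypic_filtered", beta=0.25, egger=0.24, med=0.24)]
        )
        coloc = pd.DataFrame(
            {"group_id": [0], "trait_id": ["t"], "outcome": ["cad"], "pp4": [0.9]}
        )
        out = level_locus_convergence(mr, coloc, {0: "specific"})
        assert out.iloc[0]["tier"] == "molecular_phenotypic_filtered"


class TestMrAnalysis:
    def test_combines_estimators(self, toy_instruments):
        res = mr_analysis(toy_instruments, "t", "cad")
        assert res.beta_ivw == pytest.approx(0.3)
        assert np.isfinite(res.beta_egger)
        assert res.median_wald == pytest.approx(0.3)
        assert len(res.wald_ratios) == 3
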