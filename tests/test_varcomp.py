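import numpy as np
import pandas as pd
import pytest

import methfam as mf
from methfam.varcomp import _AELikelihood, mixture_lrt_pvalue


def mvn_profile_loglik(y, V):
    """Independent dense-matrix oracle: profile out the intercept by GLS and
    evaluate the multivariate-normal log-likelihood directly."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    beta = (ones @ Vinv @ y) / (ones @ Vinv @ ones)
    r = y - beta
    return -0.5 * (logdet + r @ Vinv @ r + n * np.log(2 * np.pi))


@pytest.fixture(scope="module")
def small_cohort():
    spec = {"n_extra_sibs": {1: 1.0}, "twin_zygosity": {"MZ": 0.5, "DZ": 0.5}}
    ped = mf.generate_pedigree(12, family_spec=spec, seed=61)
    kin = mf.additive_relationship(ped)
    sheet = mf.generate_sample_sheet(ped, seed=62)
    return ped, kin, sheet


class TestFitVarcomp:
    def test_matches_dense_grid_search_oracle(self, small_cohort):
        """ML estimates agree with a dense (Va, Ve) grid search using an
        independent dense-matrix likelihood."""
        ped, kin, sheet = small_cohort
        probes = mf.uniform_probes(20, va=0.4, vf=0.0, ve=0.6)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=63)
        resid = mf.logit_values(sim.beta)
        A = kin.A.to_numpy()
        n = A.shape[0]
        I = np.eye(n)
        for _, row in resid.values.iterrows():
            y = row.to_numpy()
            vy = y.var()
            vas = np.linspace(0, 2.5 * vy, 41)
            ves = np.linspace(0.01 * vy, 2.5 * vy, 41)
            lls = np.full((41, 41), -np.inf)
            for i, va in enumerate(vas):
                for j, ve in enumerate(ves):
                    lls[i, j] = mvn_profile_loglik(y, va * A + ve * I)
            gi, gj = np.unravel_index(np.argmax(lls), lls.shape)
            fit = mf.fit_varcomp(y, kin, model="AE")
            assert fit.loglik >= lls[gi, gj] - 1e-6
            assert abs(fit.va - vas[gi]) <= (vas[1] - vas[0])
            assert abs(fit.ve - ves[gj]) <= (ves[1] - ves[0])

    def test_mz_only_perfect_heritability_boundary(self):
        """Noise-free identical MZ pairs drive the heritability estimate to
        the upper boundary."""
        rows = []
        for k in range(20):
            for t in (1, 2):
                rows.append(
                    (f"t{k}_{t}", f"f{k}", None, None, "female", 14.0,
                     "MZ_twin", f"pair{k}")
                )
        ped = pd.DataFrame(
            rows,
            columns=["individual_id", "family_id", "father_id", "mother_id",
                     "sex", "age", "zygosity", "twin_pair_id"],
        )
        kin = mf.additive_relationship(ped)
        rng = np.random.default_rng(3)
        pair_vals = rng.normal(size=20)
        y = np.repeat(pair_vals, 2)
        fit = mf.fit_varcomp(y, kin, model="AE")
        assert fit.h2 > 0.999

    def test_full_loglik_never_below_null(self, small_cohort, rng):
        ped, kin, _ = small_cohort
        n = len(kin.ids)
        for _ in range(20):
            y = rng.standard_normal(n)
            fit = mf.fit_varcomp(y, kin, model="AE")
            assert fit.loglik >= fit.null_loglik - 1e-9
            assert 0.0 <= fit.p_value <= 1.0

    def test_loglik_invariant_to_family_permutation(self):
        """Whole-family relabelling leaves the AE likelihood unchanged."""
        spec = {"n_extra_sibs": {1: 1.0}, "twin_zygosity": {"MZ": 1.0, "DZ": 0.0}}
        ped = mf.generate_pedigree(8, family_spec=spec, seed=64)
        kin = mf.additive_relationship(ped)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(len(kin.ids))
        fit = mf.fit_varcomp(y, kin, model="AE")
        # identical family composition -> block-permute y by whole families
        fam_size = 5
        y_perm = y.reshape(8, fam_size)[::-1].ravel()
        fit_perm = mf.fit_varcomp(y_perm, kin, model="AE")
        assert fit_perm.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert fit_perm.h2 == pytest.approx(fit.h2, abs=1e-4)

    def test_estimate_beats_random_feasible_points(self, small_cohort, rng):
        ped, kin, sheet = small_cohort
        probes = mf.uniform_probes(20, va=0.2, vf=0.0, ve=0.8)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=65)
        resid = mf.logit_values(sim.beta)
        for _, row in resid.values.iterrows():
            y = row.to_numpy()
            fit = mf.fit_varcomp(y, kin, model="AE")
            lik = _AELikelihood(y, np.ones((len(y), 1)), kin.A.to_numpy())
            vy = y.var()
            pts = rng.uniform(0.0, 3.0 * vy, size=(100, 2)) + [0.0, 1e-8]
            lls = np.array([-lik.negloglik(p) for p in pts])
            assert fit.loglik >= lls.max() - 1e-6

    def test_afe_recovers_family_variance_and_ae_inflates(self):
        """With Vf > 0 in truth, AE pushes the family variance into h2 while
        AFE separates it (common environment vs heritability confounding)."""
        ped = mf.generate_pedigree(150, seed=66)
        kin = mf.additive_relationship(ped)
        sheet = mf.generate_sample_sheet(ped, seed=67)
        probes = mf.uniform_probes(40, va=0.2, vf=0.2, ve=0.6)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=68)
        resid = mf.logit_values(sim.beta)
        ae = mf.heritability_screen(resid, kin, model="AE")
        afe = mf.heritability_screen(resid, kin, model="AFE")
        assert afe["c2"].mean() == pytest.approx(0.2, abs=0.05)
        assert ae["h2"].mean() > afe["h2"].mean() + 0.05
        assert ((afe["h2"] + afe["c2"]) <= 1.0 + 1e-9).all()

    def test_preconditions_and_validation(self, small_cohort, rng):
        ped, kin, _ = small_cohort
        y = np.full(len(kin.ids), np.nan)
        y[:5] = rng.standard_normal(5)
        with pytest.raises(ValueError, match="at least 10"):
            mf.fit_varcomp(y, kin, model="AE")
        with pytest.raises(ValueError, match="unknown model"):
            mf.fit_varcomp(rng.standard_normal(len(kin.ids)), kin, model="ACE")
        with pytest.raises(ValueError, match="component"):
            mf.fit_varcomp(rng.standard_normal(len(kin.ids)), kin, model="AE", test="vf")

    def test_per_probe_missing_subsetting(self, small_cohort, rng):
        ped, kin, sheet = small_cohort
        probes = mf.uniform_probes(5, va=0.3, vf=0.0, ve=0.7)
        sim = mf.simulate_methylation(ped, sheet, probes, missing_rate=0.1, seed=69)
        screen = mf.heritability_screen(mf.logit_values(sim.beta), kin, model="AE")
        assert (screen["n_used"] < len(kin.ids)).all()
        assert screen["converged"].all()
        assert screen["h2"].between(0, 1).all()


class TestScreenCalibration:
    def test_screen_slope_against_truth(self, ped117, kin117, sheet117):
        rng = np.random.default_rng(70)
        h2true = rng.uniform(0.0, 0.4, 400)
        probes = mf.uniform_probes(400, va=h2true, vf=0.0, ve=1.0 - h2true)
        sim = mf.simulate_methylation(ped117, sheet117, probes, seed=71)
        screen = mf.heritability_screen(mf.logit_values(sim.beta), kin117, model="AE")
        slope = np.polyfit(h2true, screen["h2"].to_numpy(), 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_zero_truth_gives_near_zero_mean(self, null_screen):
        # Under the null the boundary-censored estimate has mean
        # 0.5 * E|Z| * sd(h2_unconstrained) ~ 0.02 on this design; assert a
        # bound with headroom for Monte-Carlo noise.
        assert null_screen["h2"].mean() < 0.03

    def test_cell_adjustment_removes_composition_confounding(self):
        """Family-correlated cell composition inflates unadjusted h2 at
        signature probes; entering the proportions as fixed-effect
        covariates brings those probes back toward truth while barely moving
        the rest."""
        from methfam.simulate import CELL_TYPES

        ped = mf.generate_pedigree(117, seed=72)
        kin = mf.additive_relationship(ped)
        sheet = mf.generate_sample_sheet(
            ped, seed=73, with_cell_props=True,
            cell_concentration=60.0, cell_family_concentration=30.0,
        )
        probes = mf.uniform_probes(60, va=0.1, vf=0.0, ve=0.4)
        for p in probes[:12]:
            p.cell_signature = {"granulocytes": 4.0, "CD4_T": -3.0}
        sim = mf.simulate_methylation(ped, sheet, probes, seed=74)
        resid = mf.logit_values(sim.beta)
        cells = sheet.set_index("individual_id")[list(CELL_TYPES[:-1])]
        plain = mf.heritability_screen(resid, kin, model="AE")
        adj = mf.heritability_screen(resid, kin, model="AE", covariates=cells)
        sig = [p.probe_id for p in probes[:12]]
        rest = [p.probe_id for p in probes[12:]]
        drop_sig = plain.loc[sig, "h2"].mean() - adj.loc[sig, "h2"].mean()
        assert drop_sig > 0.03
        assert abs(adj.loc[sig, "h2"].mean() - 0.2) < abs(
            plain.loc[sig, "h2"].mean() - 0.2
        )
        assert (plain.loc[rest, "h2"] - adj.loc[rest, "h2"]).abs().mean() < 0.02


class TestFDRAndZeroBound:
    def test_step_up_hand_computation(self):
        mask = mf.bh_fdr([0.01, 0.02, 0.9], q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_ones_none_significant(self):
        assert not mf.bh_fdr([1.0] * 5, q=0.05).any()

    def test_mask_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        mask = mf.bh_fdr(p, q=0.1)
        if mask.any():
            assert p[mask].max() <= p[~mask].min() or not (~mask).any()

    def test_empty_input(self):
        assert mf.bh_fdr([], q=0.05).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mf.bh_fdr([0.5, 1.5], q=0.05)

    @pytest.mark.parametrize(
        "p0,expected",
        [(0.171, 65.8), (0.5, 0.0), (0.0, 100.0), (0.75, 0.0)],
    )
    def test_zero_fraction_bound_arithmetic(self, p0, expected):
        n = 1000
        k = int(round(p0 * n))
        h2 = np.concatenate([np.zeros(k), np.full(n - k, 0.3)])
        frac, bound = mf.zero_fraction_bound(h2)
        assert frac == pytest.approx(p0, abs=1e-9)
        assert bound == pytest.approx(expected, abs=1e-6)


def test_mixture_pvalue_halves_chisquare_tail():
    from scipy.stats import chi2

    assert mixture_lrt_pvalue(0.0) == 1.0
    assert mixture_lrt_pvalue(3.84) == pytest.approx(0.5 * chi2.sf(3.84, 1))
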