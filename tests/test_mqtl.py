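import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import norm

import methfam as mf


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Direct enumeration of all genotype configurations with the observed
    allele counts, summing probabilities <= the observed one."""
    n = n_aa + n_ab + n_bb
    n_b = 2 * n_bb + n_ab
    probs = {}
    for het in range(n_b % 2, min(n_b, 2 * n - n_b) + 1, 2):
        bb = (n_b - het) // 2
        aa = n - het - bb
        if aa < 0:
            continue
        logp = (
            gammaln(n + 1) - gammaln(aa + 1) - gammaln(het + 1) - gammaln(bb + 1)
            + het * np.log(2)
            + gammaln(n_b + 1) + gammaln(2 * n - n_b + 1) - gammaln(2 * n + 1)
        )
        probs[het] = np.exp(logp)
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))


class TestSnpQC:
    def test_hwe_exact_matches_enumeration(self):
        for counts in [(90, 0, 10), (50, 30, 20), (5, 10, 5), (100, 40, 4)]:
            assert mf.hwe_exact_pvalue(*counts) == pytest.approx(
                hwe_enumeration_oracle(*counts), rel=1e-9
            )

    def test_extreme_het_deficit_removed(self, ped117):
        """Founders with counts (AA=90, Aa=0, aa=10) fail HWE at 1e-6."""
        assert mf.hwe_exact_pvalue(90, 0, 10) < 1e-6

    def test_maf_strictly_less_than(self):
        n = 200
        ids = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)

        def snp_with_maf(maf):
            k = int(round(2 * n * maf))
            alleles = np.zeros(2 * n)
            alleles[:k] = 1
            rng.shuffle(alleles)
            return alleles.reshape(n, 2).sum(axis=1)

        dosage = pd.DataFrame(
            [snp_with_maf(0.04), snp_with_maf(0.05)],
            index=["low", "edge"], columns=ids,
        )
        geno = mf.GenotypeMatrix(dosage=dosage)
        kept, tally = mf.snp_qc(geno, hwe_alpha=1e-300)
        assert "low" not in kept.snp_ids  # MAF < 0.05 removed
        assert "edge" in kept.snp_ids  # exactly 0.05 retained
        assert tally["maf"] == 1

    def test_missingness_strictly_more_than(self):
        n = 100
        ids = [f"s{i}" for i in range(n)]
        base = np.tile([0.0, 1.0, 2.0, 1.0], n // 4)
        d = pd.DataFrame([base, base.copy()], index=["ok", "gappy"], columns=ids)
        d.loc["gappy", ids[:11]] = np.nan  # 11% missing
        d.loc["ok", ids[:10]] = np.nan  # exactly 10%
        geno = mf.GenotypeMatrix(dosage=d)
        kept, tally = mf.snp_qc(geno, hwe_alpha=1e-300)
        assert "gappy" not in kept.snp_ids
        assert "ok" in kept.snp_ids
        assert tally["missingness"] == 1

    def test_hwe_uses_founders_only(self, ped117):
        """A SNP in perfect founder HWE passes even though pedigree copying
        (MZ twins, siblings) distorts the full-sample genotype counts."""
        geno = mf.simulate_genotypes(ped117, n_snps=60, seed=80)
        kept, tally = mf.snp_qc(geno, ped=ped117, maf_min=0.01)
        assert tally["hwe"] == 0


@pytest.fixture(scope="module")
def mqtl_cohort():
    ped = mf.generate_pedigree(117, seed=81)
    kin = mf.additive_relationship(ped)
    sheet = mf.generate_sample_sheet(ped, seed=82)
    geno = mf.simulate_genotypes(ped, n_snps=400, seed=83)
    return ped, kin, sheet, geno


class TestAssocScan:
    def test_null_pvalues_uniform_and_family_blind_inflated(self, mqtl_cohort):
        """With the kinship model the null p-values are uniform; pretending
        individuals are unrelated (identity A) inflates small p-values."""
        from scipy.stats import kstest

        ped, kin, sheet, geno = mqtl_cohort
        probes = mf.uniform_probes(5, va=0.5, vf=0.0, ve=0.5)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=84)
        resid = mf.logit_values(sim.beta)
        ps, ps_blind = [], []
        ident = mf.KinshipMatrix(
            A=pd.DataFrame(np.eye(len(kin.ids)), index=kin.ids, columns=kin.ids),
            H=kin.H,
        )
        for _, row in resid.values.iterrows():
            ps.append(mf.assoc_scan(row, geno, kin)["p_value"].to_numpy())
            ps_blind.append(mf.assoc_scan(row, geno, ident)["p_value"].to_numpy())
        ps = np.concatenate(ps)
        ps_blind = np.concatenate(ps_blind)
        assert kstest(ps, "uniform").pvalue > 0.01
        assert (ps_blind < 0.05).mean() > (ps < 0.05).mean() + 0.02

    def test_strong_cis_snp_detected_with_correct_sign(self, mqtl_cohort):
        ped, kin, sheet, geno = mqtl_cohort
        snp = "snp000200"
        maf = float(geno.snp_map.set_index("snp_id").loc[snp, "maf"])
        beta = np.sqrt(1.0 / (2 * maf * (1 - maf)))  # SNP explains ~50%
        probes = [
            mf.ProbeModel(probe_id="hit", va=0.2, ve=0.8, mqtl_snp=snp,
                          mqtl_beta=beta)
        ]
        sim = mf.simulate_methylation(ped, sheet, probes, geno=geno, seed=85)
        scan = mf.assoc_scan(
            mf.logit_values(sim.beta).values.iloc[0], geno, kin
        ).set_index("snp_id")
        assert scan.loc[snp, "p_value"] < 5e-8
        assert scan.loc[snp, "effect"] > 0
        assert scan.loc[snp, "effect"] == pytest.approx(beta, rel=0.25)

    def test_wald_p_consistent_with_effect_over_se(self, mqtl_cohort):
        ped, kin, sheet, geno = mqtl_cohort
        probes = mf.uniform_probes(1, va=0.3, ve=0.7)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=86)
        scan = mf.assoc_scan(mf.logit_values(sim.beta).values.iloc[0], geno, kin)
        z = scan["effect"] / scan["se"]
        np.testing.assert_allclose(
            scan["p_value"], 2 * norm.sf(np.abs(z)), atol=1e-6
        )

    def test_unrelated_subset_reduces_to_ols(self):
        """On founders-only data the GLS pathway collapses to OLS."""
        rows = []
        for k in range(200):
            rows.append((f"a{k}", f"f{k}", None, None, "male", 40.0, "none", None))
        ped = pd.DataFrame(
            rows,
            columns=["individual_id", "family_id", "father_id", "mother_id",
                     "sex", "age", "zygosity", "twin_pair_id"],
        )
        kin = mf.additive_relationship(ped)
        geno = mf.simulate_genotypes(ped, n_snps=10, seed=87)
        rng = np.random.default_rng(88)
        y = rng.standard_normal(200)
        scan = mf.assoc_scan(y, geno, kin).set_index("snp_id")
        import statsmodels.api as sm

        sigma2_null = y.var()  # ML, intercept-only: the variance held fixed per SNP
        for snp in scan.index:
            g = geno.dosage.loc[snp].to_numpy()
            ols = sm.OLS(y, sm.add_constant(g)).fit()
            se_oracle = np.sqrt(sigma2_null / ((g - g.mean()) ** 2).sum())
            assert scan.loc[snp, "effect"] == pytest.approx(ols.params[1], abs=1e-6)
            assert scan.loc[snp, "se"] == pytest.approx(se_oracle, abs=1e-6)

    def test_allele_flip_negates_effect(self, mqtl_cohort):
        ped, kin, sheet, geno = mqtl_cohort
        probes = mf.uniform_probes(1, va=0.3, ve=0.7)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=89)
        y = mf.logit_values(sim.beta).values.iloc[0]
        scan = mf.assoc_scan(y, geno, kin).set_index("snp_id")
        flipped = mf.GenotypeMatrix(dosage=2.0 - geno.dosage, snp_map=geno.snp_map)
        scan_f = mf.assoc_scan(y, flipped, kin).set_index("snp_id")
        np.testing.assert_allclose(scan["effect"], -scan_f["effect"], atol=1e-8)
        np.testing.assert_allclose(scan["p_value"], scan_f["p_value"], atol=1e-8)

    def test_monomorphic_skipped_and_missing_subset(self, mqtl_cohort):
        ped, kin, sheet, geno = mqtl_cohort
        d = geno.dosage.copy()
        d.iloc[0, :] = 1.0  # monomorphic
        d.iloc[1, : len(d.columns) // 3] = np.nan
        g2 = mf.GenotypeMatrix(dosage=d, snp_map=geno.snp_map)
        probes = mf.uniform_probes(1, va=0.3, ve=0.7)
        sim = mf.simulate_methylation(ped, sheet, probes, seed=90)
        scan = mf.assoc_scan(mf.logit_values(sim.beta).values.iloc[0], g2, kin)
        assert d.index[0] not in set(scan["snp_id"])
        row = scan.set_index("snp_id").loc[d.index[1]]
        assert row["n_used"] < len(kin.ids)
        assert np.isfinite(row["p_value"])


class TestBonferroniAndRegion:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 417_069, 1.2e-7), (0.05, 1, 0.05), (0.01, 100, 1e-4)],
    )
    def test_threshold_values(self, alpha, n, expected):
        assert mf.bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=0.05)
        assert mf.bonferroni_threshold(alpha, n) * n == pytest.approx(alpha, rel=1e-12)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            mf.bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            mf.bonferroni_threshold(1.5, 10)

    def test_regional_bidirectional_recovery(self, mqtl_cohort):
        """One SNP driving 20 probes in both directions is recovered with
        matching signs."""
        ped, kin, sheet, geno = mqtl_cohort
        snp = "snp000100"
        pos = int(geno.snp_map.set_index("snp_id").loc[snp, "position"])
        maf = float(geno.snp_map.set_index("snp_id").loc[snp, "maf"])
        b = np.sqrt(0.5 / (2 * maf * (1 - maf)))
        signs = np.resize([1.0, -1.0], 20)
        probes = [
            mf.ProbeModel(
                probe_id=f"reg{k}", va=0.1, ve=0.4, mqtl_snp=snp,
                mqtl_beta=signs[k] * b, position=pos + (k - 10) * 50_000,
            )
            for k in range(20)
        ] + [
            mf.ProbeModel(probe_id=f"far{k}", va=0.1, ve=0.4,
                          position=pos + 30_000_000 + k)
            for k in range(3)
        ]
        sim = mf.simulate_methylation(ped, sheet, probes, geno=geno, seed=91)
        resid = mf.logit_values(sim.beta)
        table = mf.region_effects(snp, resid, geno, kin, window_bp=8_000_000)
        assert set(table["probe_id"]) == {f"reg{k}" for k in range(20)}
        hits = table[table["significant"]]
        assert len(hits) >= 18
        est_signs = np.sign(table.set_index("probe_id")["effect"])
        truth = pd.Series(signs, index=[f"reg{k}" for k in range(20)])
        agree = (est_signs == truth).mean()
        assert agree == 1.0

    def test_null_region_and_degenerate_window(self, mqtl_cohort):
        ped, kin, sheet, geno = mqtl_cohort
        snp = "snp000050"
        pos = int(geno.snp_map.set_index("snp_id").loc[snp, "position"])
        probes = [
            mf.ProbeModel(probe_id=f"n{k}", va=0.1, ve=0.4,
                          position=pos + (k + 1) * 1000)
            for k in range(10)
        ]
        sim = mf.simulate_methylation(ped, sheet, probes, geno=geno, seed=92)
        resid = mf.logit_values(sim.beta)
        table = mf.region_effects(snp, resid, geno, kin, window_bp=8_000_000)
        assert table["significant"].sum() <= 1  # at most chance flags
        at_snp = mf.region_effects(snp, resid, geno, kin, window_bp=0)
        assert set(at_snp["probe_id"]) == set()
        probes[0].position = pos
        sim2 = mf.simulate_methylation(ped, sheet, probes, geno=geno, seed=93)
        at_snp2 = mf.region_effects(
            snp, mf.logit_values(sim2.beta), geno, kin, window_bp=0
        )
        assert list(at_snp2["probe_id"]) == ["n0"]
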