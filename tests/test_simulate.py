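"""Synthetic-data generator: architecture, GWAS emulation, pleiotropy, LD panels."""

from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import norm

import smoketrace as st
from smoketrace.errors import ConfigError
from smoketrace.simulate import (
    LdBlock,
    OutcomeSpec,
    StratumMoments,
    bin_thresholds_and_rho,
)


class TestDefaultConfig:
    def test_panel_sizes_match_the_published_architecture(self):
        cfg = st.default_config(0.1)
        assert len(cfg.cpd_loci) == 55
        assert len(cfg.nmr_loci) == 7

    def test_expected_variance_sums_hit_targets(self):
        """Closed-form variance sums: sum(2*maf*(1-maf)*a^2) equals 0.38 for NMR
        and 0.04/rho^2 for the latent CPD scale (so the binned scale hits 4%)."""
        cfg = st.default_config(0.1)
        v_nmr = sum(2 * l.maf * (1 - l.maf) * l.beta**2 for l in cfg.nmr_loci)
        assert v_nmr == pytest.approx(0.38, abs=1e-12)
        _, rho = bin_thresholds_and_rho(cfg.cpd_bin_probs)
        v_cpd = sum(2 * l.maf * (1 - l.maf) * l.beta**2 for l in cfg.cpd_loci)
        assert v_cpd * rho**2 == pytest.approx(0.04, abs=1e-12)

    def test_bin_distribution_has_unit_moments(self):
        probs = np.array(st.default_config(0.1).cpd_bin_probs)
        k = np.arange(1, 6)
        assert float(probs @ k) == pytest.approx(3.0)
        assert float(probs @ (k - 3) ** 2) == pytest.approx(1.0)

    def test_infeasible_feedback_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            replace(st.default_config(0.05), lambda_nmr_to_cpd=0.99)

    def test_scale_factor_domain(self):
        with pytest.raises(ConfigError):
            st.default_config(0.0)


class TestSimulateCohort:
    def test_same_seed_identical_cohorts(self):
        cfg = st.default_config(0.005, seed=3)
        a = st.simulate_cohort(cfg, 3)
        b = st.simulate_cohort(cfg, 3)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.outcomes["heart_rate"], b.outcomes["heart_rate"])
        c = st.simulate_cohort(cfg, 4)
        assert not np.array_equal(a.nmr, c.nmr)

    def test_genotypes_are_dosages_and_never_smokers_unexposed(self, small_cohort):
        assert set(np.unique(small_cohort.genotypes)) <= {0, 1, 2}
        never = small_cohort.mask("never")
        assert np.all(small_cohort.cpd_bin[never] == 0)
        assert np.all(small_cohort.dose[never] == 0.0)
        smokers = small_cohort.mask("ever")
        assert np.all(small_cohort.cpd_bin[smokers] >= 1)
        assert np.all(small_cohort.cpd_bin[smokers] <= 5)

    def test_stratum_prevalences_within_binomial_error(self, small_cohort):
        cfg = small_cohort.config
        for stratum, mu in (("current", 0.06), ("former", 0.02), ("never", 0.005)):
            mask = small_cohort.mask(stratum)
            n = mask.sum()
            obs = small_cohort.outcomes["copd"][mask].mean()
            tol = 4 * np.sqrt(mu * (1 - mu) / n)
            assert obs == pytest.approx(mu, abs=tol), stratum

    def test_diagram_degeneracy_decouples_exposures(self):
        """With lambda = 0 the NMR and CPD genetic scores are uncorrelated in
        expectation, so their sample correlation is at noise level."""
        cfg = replace(st.default_config(seed=5), lambda_nmr_to_cpd=0.0,
                      n_current=30_000, n_former=0, n_never=0, outcomes={})
        coh = st.simulate_cohort(cfg, 5)
        r = np.corrcoef(coh.nmr, coh.cpd_bin)[0, 1]
        assert abs(r) < 4 / np.sqrt(coh.n)

    def test_empty_configuration_rejected(self):
        with pytest.raises(ConfigError):
            st.simulate_cohort(
                replace(st.default_config(0.01), n_current=0, n_former=0, n_never=0)
            )


class TestRunGwas:
    def test_beta_matches_closed_form_ols_oracle(self, small_cohort):
        stats = st.run_gwas(small_cohort, "heart_rate", "current")
        mask = small_cohort.mask("current")
        y = small_cohort.outcomes["heart_rate"][mask]
        for j in [0, 3, 20, 61]:
            g = small_cohort.genotypes[mask, j].astype(float)
            slope = np.cov(g, y)[0, 1] / np.var(g, ddof=1)
            rsid = small_cohort.config.loci[j].rsid
            assert stats[rsid].beta == pytest.approx(slope, abs=1e-10)
            fit = sm.OLS(y, sm.add_constant(g)).fit()
            assert stats[rsid].se == pytest.approx(fit.bse[1], rel=1e-9)

    def test_null_trait_p_values_uniform(self):
        """An outcome with zero effects everywhere: ~5% of locus p-values fall
        below 0.05 across replicate cohorts."""
        null_spec = OutcomeSpec(
            name="noise", kind="continuous", theta_nmr=0.0, theta_cpd=0.0,
            confounder_loading=0.0,
            strata={s: StratumMoments(mean=0.0, sd=1.0) for s in ("current", "former", "never")},
        )
        cfg = replace(st.default_config(seed=6), n_current=4000, n_former=0, n_never=0,
                      outcomes={"noise": null_spec})
        hits, total = 0, 0
        for rep in range(6):
            coh = st.simulate_cohort(cfg, 60 + rep)
            stats = st.run_gwas(coh, "noise", "current")
            pv = np.array([r.pvalue for r in stats.records.values()])
            hits += (pv < 0.05).sum()
            total += len(pv)
        rate = hits / total
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / total))

    def test_binary_gwas_reaches_liability_scale_with_z_preserved(self, small_cohort):
        lin = st.run_gwas(small_cohort, "copd", "ever", liability=False)
        lia = st.run_gwas(small_cohort, "copd", "ever")
        assert lin.scale is st.EffectScale.LINEAR
        assert lia.scale is st.EffectScale.LOG_ODDS_LIABILITY
        mu = lia.prevalence
        obs = small_cohort.outcomes["copd"][small_cohort.mask("ever")].mean()
        assert mu == pytest.approx(obs)
        for rsid in list(lia.records)[:5]:
            assert lia[rsid].beta == pytest.approx(
                lin[rsid].beta / (mu * (1 - mu)), rel=1e-12
            )
            assert lia[rsid].zscore == pytest.approx(lin[rsid].zscore, rel=1e-12)

    def test_panel_restriction_and_empty_stratum(self, small_cohort):
        panel = [l.rsid for l in small_cohort.config.cpd_loci]
        stats = st.run_gwas(small_cohort, "cpd", "ever", loci=panel)
        assert set(stats.records) == set(panel)
        cfg = replace(small_cohort.config, n_never=0)
        coh = st.simulate_cohort(cfg, 1)
        with pytest.raises(st.SmoketraceError, match="empty"):
            st.run_gwas(coh, "heart_rate", "never")


class TestInjectPleiotropy:
    def test_zero_proportion_is_identity(self):
        cfg = st.default_config(0.01)
        assert st.inject_pleiotropy(cfg, "directional", 0.0, 0.1).pleiotropy.mode == "none"

    def test_directional_and_balanced_effect_vectors(self):
        from smoketrace.simulate import _pleiotropy_effects

        cfg = st.default_config(0.01)
        d = _pleiotropy_effects(st.inject_pleiotropy(cfg, "directional", 0.3, 0.05))
        assert (d != 0).sum() == round(0.3 * 55)
        assert np.all(d[d != 0] == 0.05)
        assert np.all(d[:7] == 0)  # NMR loci untouched when targeting CPD
        b = _pleiotropy_effects(st.inject_pleiotropy(cfg, "balanced", 0.3, 0.05))
        assert abs(b.sum()) <= 0.05  # alternating signs, near-zero mean
        n = st.inject_pleiotropy(cfg, "directional", 0.3, 0.05, target="nmr")
        dn = _pleiotropy_effects(n)
        assert np.all(dn[7:] == 0) and (dn[:7] != 0).sum() == round(0.3 * 7)

    def test_directional_pleiotropy_surfaces_in_never_smokers(self):
        """Never smokers carry no exposure effects, so any genotype-outcome
        association there comes from the injected direct path."""
        cfg = st.inject_pleiotropy(
            replace(st.default_config(seed=8), n_current=0, n_former=0, n_never=20_000),
            "directional", 1.0, 0.05,
        )
        coh = st.simulate_cohort(cfg, 8)
        stats = st.run_gwas(coh, "heart_rate", "never")
        z = np.array([stats[l.rsid].zscore for l in cfg.cpd_loci])
        assert np.mean(z) > 2  # systematic positive shift at magnitude 0.05


class TestMetabolismPleiotropy:
    def test_cotinine_model_picks_up_metabolism_path_nmr_model_absorbs_it(self):
        """With a metabolism->outcome liability path switched on, the
        cotinine-proxy multivariable model shows a spurious direct effect on
        lung cancer (metabolism is not its modelled exposure), while with the
        path off the cotinine effect is null.  Qualitative contrast only."""
        from smoketrace.harmonise import combine_instruments

        def cot_estimate(m):
            cfg = replace(
                st.default_config(seed=21, outcomes=["lung_cancer"]),
                metabolism_pleiotropy=m,
            )
            exp_cfg = replace(cfg, n_current=8_000, n_former=0, n_never=0, outcomes={})
            cpd_cfg = replace(cfg, n_current=12_000, n_former=28_000, n_never=0, outcomes={})
            out_cfg = replace(cfg, n_current=8_000, n_former=22_000, n_never=0)
            g_cot = st.run_gwas(st.simulate_cohort(exp_cfg, 31), "cotinine", "current")
            g_cpd = st.run_gwas(st.simulate_cohort(cpd_cfg, 32), "cpd", "ever")
            out = st.run_gwas(st.simulate_cohort(out_cfg, 33 + int(m * 100)),
                              "lung_cancer", "ever")
            rsids = [l.rsid for l in cfg.loci]
            inst = st.InstrumentSet("panel", rsids, {r: 1e-10 for r in rsids})
            H = st.harmonise([g_cot, g_cpd], out, inst)
            return st.mvmr_ivw(H).estimates["cotinine"]

        biased = cot_estimate(0.4)
        clean = cot_estimate(0.0)
        assert biased.pvalue < 0.05
        assert abs(biased.beta) > abs(clean.beta)


class TestLdPanel:
    def test_independent_loci_and_duplicates(self):
        cfg = st.default_config(0.01)
        ref = st.make_ld_panel(cfg, [], n=2000, seed=1)
        a, b = cfg.loci[0].rsid, cfg.loci[1].rsid
        assert ref.r2(a, b) == 0.0
        dup = st.make_ld_panel(
            cfg, [LdBlock(members=(a, "rsCOPY"), maf=0.2, r2=1.0)], n=2000, seed=1
        )
        assert dup.r2(a, "rsCOPY") == pytest.approx(1.0)

    def test_achieved_r2_near_target(self):
        cfg = st.default_config(0.01)
        block = LdBlock(members=("rsX1", "rsX2"), maf=0.3, r2=0.5)
        ref = st.make_ld_panel(cfg, [block], n=10_000, seed=2)
        assert ref.r2("rsX1", "rsX2") == pytest.approx(0.5, abs=0.05)

    def test_infeasible_block_rejected(self):
        with pytest.raises(ConfigError):
            LdBlock(members=("a", "b"), maf=0.3, r2=1.5)

    def test_round_trip_through_three_column_file(self, tmp_path):
        cfg = st.default_config(0.01)
        ref = st.make_ld_panel(
            cfg, [LdBlock(members=("rsY1", "rsY2"), maf=0.25, r2=0.8)], n=5000, seed=3
        )
        path = tmp_path / "panel.tsv"
        ref.to_file(path)
        back = st.LdReference.from_file(path)
        assert back.r2("rsY1", "rsY2") == pytest.approx(ref.r2("rsY1", "rsY2"), rel=1e-9)
        assert cfg.loci[0].rsid in back
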