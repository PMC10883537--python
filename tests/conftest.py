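"""Shared fixtures: hand-built summary statistics and study-scale simulated GWAS."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smoketrace as st
from smoketrace.harmonise import HarmonisedData, combine_instruments

settings.register_profile(
    "default",
    settings(
        max_examples=25,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


def make_record(
    rsid: str,
    beta: float,
    se: float,
    *,
    chrom: str = "1",
    pos: int = 1000,
    ea: str = "A",
    oa: str = "G",
    eaf: float | None = 0.3,
    pvalue: float | None = None,
    n: int = 10_000,
) -> st.VariantRecord:
    from scipy.stats import norm

    if pvalue is None:
        pvalue = float(np.clip(2 * norm.sf(abs(beta / se)), 1e-300, 1.0))
    return st.VariantRecord(
        rsid=rsid,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_stats(records, *, trait="exposure", stratum="all", **kw) -> st.GwasSumStats:
    kw.setdefault("trait_type", "continuous")
    return st.GwasSumStats.from_records(records, trait=trait, stratum=stratum, **kw)


def make_harmonised(gamma, gamma_se, Gamma, Gamma_se, names=("exposure",)) -> HarmonisedData:
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if gamma.shape[0] == 1 and gamma.shape[1] != len(names):
        gamma = gamma.T
    gamma_se = np.atleast_2d(np.asarray(gamma_se, dtype=float))
    if gamma_se.shape != gamma.shape:
        gamma_se = gamma_se.T
    L = gamma.shape[0]
    return HarmonisedData(
        rsids=[f"rs{i}" for i in range(L)],
        exposure_names=list(names),
        exposure_beta=gamma,
        exposure_se=gamma_se,
        outcome_beta=np.asarray(Gamma, dtype=float),
        outcome_se=np.asarray(Gamma_se, dtype=float),
    )


@pytest.fixture(scope="session")
def study_exposure_gwas():
    """Exposure GWAS at the study's sample sizes: NMR in 5,185 current smokers,
    CPD in the full 337,334-strong ever-smoker cohort; instruments selected from
    each exposure's own conditionally-independent panel."""
    from dataclasses import replace

    cfg = st.default_config(seed=1)
    nmr_cfg = replace(cfg, n_current=5185, n_former=0, n_never=0, outcomes={})
    ever = st.simulate.CPD_GWAS_N
    n_cur = round(ever * 49_721 / 213_341)
    cpd_cfg = replace(cfg, n_current=n_cur, n_former=ever - n_cur, n_never=0, outcomes={})
    nmr_stats = st.run_gwas(st.simulate_cohort(nmr_cfg, 101), "nmr", "current")
    cpd_stats = st.run_gwas(st.simulate_cohort(cpd_cfg, 102), "cpd", "ever")
    nmr_inst = st.select_instruments(nmr_stats.subset([l.rsid for l in cfg.nmr_loci]))
    cpd_inst = st.select_instruments(cpd_stats.subset([l.rsid for l in cfg.cpd_loci]))
    return {
        "config": cfg,
        "nmr_stats": nmr_stats,
        "cpd_stats": cpd_stats,
        "nmr_inst": nmr_inst,
        "cpd_inst": cpd_inst,
        "combined": combine_instruments([nmr_inst, cpd_inst]),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with all strata and outcomes, reused by read-only tests."""
    cfg = st.default_config(0.02, seed=7)
    return st.simulate_cohort(cfg, 7)
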