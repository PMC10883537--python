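"""Worked example: direct effects of nicotine metabolism and smoking heaviness
on heart rate, from simulated two-sample GWAS summary statistics.

Run from the repository root:  python examples/heart_rate_mvmr.py
"""

from dataclasses import replace

import smoketrace as st
from smoketrace.harmonise import combine_instruments

cfg = st.default_config(seed=1, outcomes=["heart_rate", "lung_cancer"])

# Three non-overlapping cohorts, mirroring the two-sample design:
# NMR GWAS (5,185 current smokers), CPD GWAS (337,334 ever smokers),
# outcome GWAS (21,334 ever smokers, a 10x downscale).
nmr_cohort = st.simulate_cohort(
    replace(cfg, n_current=5_185, n_former=0, n_never=0, outcomes={}), 11
)
cpd_cohort = st.simulate_cohort(
    replace(cfg, n_current=78_619, n_former=258_715, n_never=0, outcomes={}), 12
)
out_cohort = st.simulate_cohort(
    replace(cfg, n_current=4_972, n_former=16_362, n_never=0), 13
)

g_nmr = st.run_gwas(nmr_cohort, "nmr", "current")
g_cpd = st.run_gwas(cpd_cohort, "cpd", "ever")
g_hr = st.run_gwas(out_cohort, "heart_rate", "current")

inst = combine_instruments([
    st.select_instruments(g_nmr.subset([l.rsid for l in cfg.nmr_loci])),
    st.select_instruments(g_cpd.subset([l.rsid for l in cfg.cpd_loci])),
])
H = st.harmonise([g_nmr, g_cpd], g_hr, inst)
fit = st.mvmr_ivw(H)

for name, est in fit.estimates.items():
    print(
        f"{name:4s} direct effect on heart rate: "
        f"{est.beta:+.2f} bpm/SD (95% CI {est.ci_low:+.2f} to {est.ci_high:+.2f}), "
        f"p = {est.pvalue:.3g}, nSNP = {est.n_snps}"
    )
print("conditional F:", {k: round(v, 1) for k, v in fit.diagnostics.conditional_f.items()})
flipped = st.flip_direction(fit.estimates["nmr"])
print(
    f"nicotine-per-cigarette reading: {flipped.beta:+.2f} bpm/SD "
    f"(95% CI {flipped.ci_low:+.2f} to {flipped.ci_high:+.2f})"
)
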