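"""Full-study orchestration: exposures x outcomes x strata x methods, with controls.

``run_study`` replays the whole analysis on synthetic data: three
non-overlapping cohorts stand in for the NMR GWAS (current smokers), the
smoking-heaviness GWAS (ever smokers) and the outcome GWAS (all strata);
instruments are selected and clumped, each outcome/stratum combination is
harmonised against both exposures, and every requested univariable and
multivariable estimator is run with its diagnostics.  NMR multivariable rows
gain a flipped-interpretation companion (the nicotine-per-cigarette
reading).  Combinations that cannot be estimated (missing stratum, too few
common SNPs) are logged and skipped rather than aborting the run.

``evaluate_negative_controls`` encodes the study's causal-inference guards:
nicotine is expected to raise heart rate (positive control), is not thought
to be carcinogenic (lung-cancer negative control), and no genuine exposure
effect can exist among never smokers — so never-smoker signal or excess
heterogeneity flags horizontal pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .harmonise import (
    HarmonisedData,
    combine_instruments,
    harmonise,
    select_instruments,
)
from .mvmr import flip_direction, mvmr_egger, mvmr_ivw
from .simulate import (
    CPD_GWAS_N,
    FULL_STRATUM_SIZES,
    NMR_GWAS_N,
    default_config,
    inject_pleiotropy,
    run_gwas,
    simulate_cohort,
)
from .sumstats import EffectScale, GwasSumStats
from .univariable import (
    MREstimate,
    attach_odds_ratio,
    egger,
    f_statistic,
    ivw,
    weighted_median,
    weighted_mode,
)

__all__ = ["StudyConfig", "StudyResults", "run_study", "evaluate_negative_controls", "format_results"]

RESULT_COLUMNS = [
    "method",
    "exposure",
    "outcome",
    "stratum",
    "nsnp",
    "beta",
    "se",
    "lo",
    "hi",
    "p",
    "or",
    "or_lo",
    "or_hi",
    "q",
    "q_df",
    "q_p",
    "f_stat",
    "conditional_f_nmr",
    "conditional_f_cpd",
    "intercept",
    "intercept_se",
    "intercept_p",
    "flipped",
    "q_exceeds_nsnp",
    "conditional_f_below_10",
    "never_smoker_signal",
]

_UNIVARIABLE = {
    "ivw": lambda H, nb, sd: ivw(H),
    "egger": lambda H, nb, sd: egger(H),
    "weighted_median": lambda H, nb, sd: (weighted_median(H, n_boot=nb, seed=sd), None),
    "weighted_mode": lambda H, nb, sd: (weighted_mode(H, n_boot=nb, seed=sd), None),
}


class StudyConfig(BaseModel):
    """Declarative study description; validated on construction.

    The three cohort ids assert the two-sample design: exposure and outcome
    statistics must come from non-overlapping samples, so sharing an id is a
    configuration error.
    """

    scale_factor: float = Field(0.05, gt=0.0, le=1.0, description="outcome-cohort downscale")
    cpd_gwas_scale: float = Field(0.1, gt=0.0, le=1.0, description="CPD GWAS cohort downscale")
    nmr_gwas_n: int = Field(NMR_GWAS_N, gt=1)
    outcomes: list[str] | None = None
    strata: list[str] = ["ever", "current", "former", "never"]
    methods: list[str] = ["ivw", "egger", "weighted_median", "weighted_mode"]
    mvmr: bool = True
    p_threshold: float = Field(5e-8, gt=0.0, lt=1.0)
    n_boot: int = Field(1000, ge=100)
    pleiotropy_mode: str = "none"
    pleiotropy_proportion: float = 0.0
    pleiotropy_magnitude: float = 0.0
    nmr_cohort_id: str = "nmr_gwas"
    cpd_cohort_id: str = "cpd_gwas"
    outcome_cohort_id: str = "outcome_gwas"

    @model_validator(mode="after")
    def _distinct_cohorts(self) -> "StudyConfig":
        ids = [self.nmr_cohort_id, self.cpd_cohort_id, self.outcome_cohort_id]
        if len(set(ids)) != 3:
            raise ValueError(
                "two-sample design violated: exposure and outcome cohort ids must be distinct"
            )
        unknown = set(self.methods) - set(_UNIVARIABLE)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        return self


@dataclass
class StudyResults:
    table: pd.DataFrame
    log: list[tuple[str, str]] = field(default_factory=list)

    def rows(self, **filters) -> pd.DataFrame:
        df = self.table
        for col, val in filters.items():
            df = df[df[col] == val]
        return df


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _estimate_row(
    est: MREstimate,
    diag,
    outcome: str,
    stratum: str,
    *,
    binary: bool,
    flipped: bool = False,
) -> dict:
    if binary:
        est = attach_odds_ratio(est)
    row = {
        "method": est.method,
        "exposure": est.exposure,
        "outcome": outcome,
        "stratum": stratum,
        "nsnp": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "lo": est.ci_low,
        "hi": est.ci_high,
        "p": est.pvalue,
        "or": est.or_,
        "or_lo": est.or_low,
        "or_hi": est.or_high,
        "q": diag.q_stat if diag else np.nan,
        "q_df": diag.q_df if diag else np.nan,
        "q_p": diag.q_pvalue if diag else np.nan,
        "f_stat": diag.f_stat if diag else np.nan,
        "conditional_f_nmr": (diag.conditional_f.get("nmr") if diag else None),
        "conditional_f_cpd": (diag.conditional_f.get("cpd") if diag else None),
        "intercept": est.intercept,
        "intercept_se": est.intercept_se,
        "intercept_p": est.intercept_p,
        "flipped": flipped,
    }
    q, nsnp = row["q"], row["nsnp"]
    row["q_exceeds_nsnp"] = bool(q > nsnp) if q == q else False
    cfs = [v for v in (row["conditional_f_nmr"], row["conditional_f_cpd"]) if v is not None]
    row["conditional_f_below_10"] = bool(cfs and min(cfs) < 10.0)
    row["never_smoker_signal"] = bool(stratum == "never" and row["p"] < 0.05)
    return row


def _available_strata(spec, requested: list[str]) -> list[str]:
    declared = set(spec.available_strata)
    if {"current", "former"} <= declared:
        declared.add("ever")
    return [s for s in requested if s in declared]


def run_study(config: StudyConfig, seed: int) -> StudyResults:
    """Execute every available (exposure, outcome, stratum, method) combination.

    Deterministic given ``config`` and ``seed``.
    """
    s_nmr, s_cpd, s_out, s_boot = _child_seeds(seed, 4)
    log: list[tuple[str, str]] = []

    base = default_config(outcomes=config.outcomes)
    if config.pleiotropy_mode != "none":
        base = inject_pleiotropy(
            base,
            config.pleiotropy_mode,  # type: ignore[arg-type]
            config.pleiotropy_proportion,
            config.pleiotropy_magnitude,
        )
    ever_full = FULL_STRATUM_SIZES["current"] + FULL_STRATUM_SIZES["former"]
    cpd_total = round(CPD_GWAS_N * config.cpd_gwas_scale)

    from dataclasses import replace as dc_replace

    # Exposure cohorts carry no outcome phenotypes: summary statistics for the
    # outcomes always come from the third, non-overlapping cohort.
    nmr_cfg = dc_replace(
        base, seed=s_nmr, n_current=config.nmr_gwas_n, n_former=0, n_never=0, outcomes={}
    )
    cpd_cfg = dc_replace(
        base,
        seed=s_cpd,
        n_current=round(cpd_total * FULL_STRATUM_SIZES["current"] / ever_full),
        n_former=round(cpd_total * FULL_STRATUM_SIZES["former"] / ever_full),
        n_never=0,
        outcomes={},
    )
    out_cfg = dc_replace(
        base,
        seed=s_out,
        n_current=max(2, round(FULL_STRATUM_SIZES["current"] * config.scale_factor)),
        n_former=max(2, round(FULL_STRATUM_SIZES["former"] * config.scale_factor)),
        n_never=max(2, round(FULL_STRATUM_SIZES["never"] * config.scale_factor)),
    )

    nmr_stats = run_gwas(simulate_cohort(nmr_cfg), "nmr", "current")
    cpd_stats = run_gwas(simulate_cohort(cpd_cfg), "cpd", "ever")
    outcome_cohort = simulate_cohort(out_cfg)

    # Instrument selection is restricted to each exposure GWAS's own
    # conditionally-independent panel (the published variant lists); the full
    # summary statistics remain available for cross-exposure harmonisation.
    nmr_panel = [l.rsid for l in base.nmr_loci]
    cpd_panel = [l.rsid for l in base.cpd_loci]
    nmr_inst = select_instruments(nmr_stats.subset(nmr_panel), config.p_threshold)
    cpd_inst = select_instruments(cpd_stats.subset(cpd_panel), config.p_threshold)
    log.append(("instruments", f"nmr: {len(nmr_inst)} selected, cpd: {len(cpd_inst)} selected"))
    combined = combine_instruments([nmr_inst, cpd_inst])

    rows: list[dict] = []
    for name, spec in out_cfg.outcomes.items():
        for stratum in _available_strata(spec, config.strata):
            try:
                out_stats = run_gwas(outcome_cohort, name, stratum)
            except Exception as exc:  # missing stratum tolerated, run continues
                log.append((f"{name}/{stratum}", f"skipped: {exc}"))
                continue
            binary = out_stats.scale in (EffectScale.LOG_ODDS, EffectScale.LOG_ODDS_LIABILITY)

            for exp_stats, inst in ((nmr_stats, nmr_inst), (cpd_stats, cpd_inst)):
                try:
                    H = harmonise([exp_stats], out_stats, inst)
                except InsufficientInstrumentsError as exc:
                    log.append((f"{name}/{stratum}/{exp_stats.trait}", f"skipped: {exc}"))
                    continue
                for method in config.methods:
                    try:
                        est, diag = _UNIVARIABLE[method](H, config.n_boot, s_boot)
                        if diag is None:
                            _, diag = ivw(H)
                            diag.egger_intercept = None
                        rows.append(_estimate_row(est, diag, name, stratum, binary=binary))
                    except (
                        InsufficientInstrumentsError,
                        DegenerateInstrumentError,
                        CollinearityError,
                    ) as exc:
                        log.append((f"{name}/{stratum}/{exp_stats.trait}/{method}", f"failed: {exc}"))

            if config.mvmr:
                try:
                    H2 = harmonise([nmr_stats, cpd_stats], out_stats, combined)
                    for fit in (mvmr_ivw(H2), mvmr_egger(H2, orient_on="nmr")):
                        for exp_name, est in fit.estimates.items():
                            rows.append(
                                _estimate_row(est, fit.diagnostics, name, stratum, binary=binary)
                            )
                            if exp_name == "nmr":
                                rows.append(
                                    _estimate_row(
                                        flip_direction(
                                            attach_odds_ratio(est) if binary else est
                                        ),
                                        fit.diagnostics,
                                        name,
                                        stratum,
                                        binary=False,  # OR already attached pre-flip
                                        flipped=True,
                                    )
                                )
                except (
                    InsufficientInstrumentsError,
                    DegenerateInstrumentError,
                    CollinearityError,
                ) as exc:
                    log.append((f"{name}/{stratum}/mvmr", f"failed: {exc}"))

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return StudyResults(table=table, log=log)


def evaluate_negative_controls(results: StudyResults) -> pd.DataFrame:
    """Positive/negative-control verdicts recomputed from the result rows.

    * positive control — the flipped NMR direct effect (nicotine per
      cigarette) on heart rate should be positive and distinguishable from 0;
    * negative control — the flipped NMR direct effect on lung cancer should
      be consistent with no effect;
    * never-smoker nulls — no genuine exposure effect can exist among never
      smokers, so a non-null estimate there *together with* excess
      heterogeneity indicates pleiotropy, misreported smoking status, or
      population stratification.

    Checks whose rows are absent return status ``indeterminate``.
    """
    df = results.table
    checks: list[dict] = []

    def add(check: str, outcome: str, stratum: str, status: str, stat: str, value: float) -> None:
        checks.append(
            {
                "check": check,
                "outcome": outcome,
                "stratum": stratum,
                "status": status,
                "statistic": stat,
                "value": value,
            }
        )

    hr = df[
        (df["outcome"] == "heart_rate")
        & (df["method"] == "mvmr_ivw")
        & (df["exposure"] == "nmr")
        & df["flipped"]
        & (df["stratum"].isin(["ever", "current"]))
    ]
    if hr.empty:
        add("positive_control_heart_rate", "heart_rate", "ever", "indeterminate", "beta", math.nan)
    else:
        row = hr.iloc[0]
        status = "pass" if (row["beta"] > 0 and row["p"] < 0.05) else "fail"
        add("positive_control_heart_rate", "heart_rate", row["stratum"], status, "beta", row["beta"])

    lc = df[
        (df["outcome"] == "lung_cancer")
        & (df["method"] == "mvmr_ivw")
        & (df["exposure"] == "nmr")
        & df["flipped"]
        & (df["stratum"] == "ever")
    ]
    if lc.empty:
        add("negative_control_lung_cancer", "lung_cancer", "ever", "indeterminate", "p", math.nan)
    else:
        row = lc.iloc[0]
        add(
            "negative_control_lung_cancer",
            "lung_cancer",
            "ever",
            "pass" if row["p"] >= 0.05 else "fail",
            "p",
            row["p"],
        )

    never = df[(df["stratum"] == "never") & (df["method"] == "ivw") & ~df["flipped"]]
    if never.empty:
        add("never_smoker_null", "(all)", "never", "indeterminate", "p", math.nan)
    for _, row in never.iterrows():
        # Pleiotropy verdict needs both signals: a non-null never-smoker
        # estimate together with heterogeneity.  Q > nsnp alone fires ~44%
        # of the time under homogeneity (chi-square with L-1 df), so it is
        # reported as a descriptive flag but does not fail the check alone.
        clean = not (row["never_smoker_signal"] and row["q_p"] < 0.05)
        add(
            f"never_smoker_null_{row['exposure']}",
            row["outcome"],
            "never",
            "pass" if clean else "fail",
            "p",
            row["p"],
        )
    return pd.DataFrame(checks)


def format_results(
    results: StudyResults, out_dir: str | Path, style: str = "table"
) -> list[Path]:
    """Write the fixed-schema results CSV and a forest-plot-ready companion.

    Byte-identical for identical inputs; header-only files for empty results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    main = out_dir / "results.csv"
    results.table.to_csv(main, index=False, float_format="%.10g")
    paths.append(main)
    if style in ("table", "forest_csv"):
        forest = results.table[
            ["method", "exposure", "outcome", "stratum", "flipped", "beta", "lo", "hi"]
        ].rename(columns={"beta": "point"})
        fpath = out_dir / "forest.csv"
        forest.to_csv(fpath, index=False, float_format="%.10g")
        paths.append(fpath)
    logpath = out_dir / "run.log"
    logpath.write_text("".join(f"{k}\t{v}\n" for k, v in results.log))
    paths.append(logpath)
    return paths
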