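"""Synthetic cohorts under the study's causal diagram, and per-stratum GWAS emulation.

The generative model mirrors the two-exposure design the estimators target:

* 7 independent loci drive the nicotine metabolite ratio (NMR, SD units),
  jointly explaining 38% of its variance in current smokers;
* 55 independent loci drive a latent smoking-heaviness scale; faster nicotine
  metabolism feeds forward into heavier smoking through a positive
  coefficient ``lambda_nmr_to_cpd``;
* the latent heaviness is discretised into the 5 ordered cigarettes-per-day
  (CPD) bins with fixed standard-normal thresholds whose bin probabilities
  give mean 3 and SD 1 among smokers.  Because binning attenuates the
  genotype signal by the squared bin/latent correlation ``rho^2``, the latent
  genetic variance is set to ``h2_cpd / rho^2`` so the *binned* variable's
  genotype R-squared hits the 4% target;
* outcomes depend linearly on NMR (the nicotine-per-cigarette path, sign
  reversed in interpretation) and on the centred CPD bin (the smoke path),
  plus a shared standard-normal confounder.  Continuous outcomes are
  calibrated to per-stratum means and SDs; binary outcomes arise from a
  unit-variance liability thresholded at the per-stratum prevalence, with
  the liability coefficient chosen so the full summary-statistics pipeline
  (linear GWAS on 0/1, division by mu*(1-mu)) recovers the configured
  log odds ratio;
* never smokers carry the same genotypes but receive no nicotine and no
  smoke exposure: their outcomes depend only on the confounder (and on any
  injected horizontal pleiotropy, which by definition bypasses the
  exposures and is active in every stratum).

GWAS emulation is per-locus simple least squares of the trait on genotype
dosage within a stratum; binary traits are analysed on the linear scale and
passed through the liability transformation at the observed case fraction,
mirroring how linear-mixed-model statistics for binary traits are rescaled
in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, SmoketraceError
from .harmonise import LdReference
from .sumstats import (
    EffectScale,
    GwasSumStats,
    TraitType,
    VariantRecord,
    liability_transform,
)

__all__ = [
    "Locus",
    "StratumMoments",
    "OutcomeSpec",
    "PleiotropySpec",
    "SimulationConfig",
    "Cohort",
    "LdBlock",
    "default_config",
    "simulate_cohort",
    "run_gwas",
    "inject_pleiotropy",
    "make_ld_panel",
    "bin_thresholds_and_rho",
    "FULL_STRATUM_SIZES",
]

#: Study-scale stratum sizes (UK Biobank smoking strata).
FULL_STRATUM_SIZES = {"never": 258_056, "current": 49_721, "former": 163_620}

#: NMR GWAS sample size (current smokers) and CPD GWAS sample size (ever smokers).
NMR_GWAS_N = 5_185
CPD_GWAS_N = 337_334

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class Locus:
    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float
    beta: float  # per-allele effect on the (latent) phenotype, SD scale
    role: Literal["nmr", "cpd"]


@dataclass(frozen=True)
class StratumMoments:
    """Target moments for one outcome in one stratum."""

    prevalence: float | None = None  # binary outcomes
    mean: float | None = None  # continuous outcomes
    sd: float | None = None


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome: its direct-effect truths and per-stratum calibration targets.

    ``theta_nmr`` / ``theta_cpd`` are per-SD direct effects — in native trait
    units for continuous outcomes and as log odds ratios for binary ones.
    ``confounder_loading`` is in native units (continuous) or liability SDs
    (binary).
    """

    name: str
    kind: Literal["continuous", "binary"]
    theta_nmr: float
    theta_cpd: float
    confounder_loading: float
    strata: dict[str, StratumMoments]

    def moments_for(self, stratum: str) -> StratumMoments | None:
        if stratum in self.strata:
            return self.strata[stratum]
        if stratum in ("current", "former") and "ever" in self.strata:
            return self.strata["ever"]
        return None

    @property
    def available_strata(self) -> list[str]:
        return list(self.strata)


@dataclass(frozen=True)
class PleiotropySpec:
    mode: Literal["none", "balanced", "directional"] = "none"
    proportion: float = 0.0
    magnitude: float = 0.0  # per-allele, in outcome-SD (continuous) or liability (binary) units
    target: Literal["cpd", "nmr"] = "cpd"

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ConfigError(f"pleiotropy proportion {self.proportion} outside [0, 1]")


@dataclass
class SimulationConfig:
    seed: int
    n_current: int
    n_former: int
    n_never: int
    nmr_loci: list[Locus]
    cpd_loci: list[Locus]
    h2_nmr: float = 0.38
    h2_cpd: float = 0.04
    lambda_nmr_to_cpd: float = 0.1
    eta: float = 0.3  # nicotine-per-cigarette decline per SD of NMR
    dose_floor: float = 0.05
    cpd_bin_probs: tuple[float, ...] = (0.07, 0.22, 0.42, 0.22, 0.07)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    metabolism_pleiotropy: float = 0.0  # liability-scale metabolism->outcome path (cotinine contrast)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is required")
        for h2, label in ((self.h2_nmr, "h2_nmr"), (self.h2_cpd, "h2_cpd")):
            if not (0.0 < h2 < 1.0):
                raise ConfigError(f"{label} = {h2} outside (0, 1)")
        for locus in (*self.nmr_loci, *self.cpd_loci):
            if not (0.01 < locus.maf <= 0.5):
                raise ConfigError(f"{locus.rsid}: maf {locus.maf} outside (0.01, 0.5]")
        for spec in self.outcomes.values():
            for stratum, m in spec.strata.items():
                if spec.kind == "binary":
                    if m.prevalence is None or not (0.0 < m.prevalence < 1.0):
                        raise ConfigError(
                            f"{spec.name}/{stratum}: binary outcome needs prevalence in (0, 1)"
                        )
                else:
                    if m.mean is None or m.sd is None or m.sd <= 0:
                        raise ConfigError(
                            f"{spec.name}/{stratum}: continuous outcome needs mean and sd > 0"
                        )
        _, rho = bin_thresholds_and_rho(self.cpd_bin_probs)
        v_latent = self.h2_cpd / rho**2
        if v_latent + self.lambda_nmr_to_cpd**2 >= 1.0:
            raise ConfigError(
                "infeasible calibration: latent CPD genetic variance plus the NMR "
                "feedback exceeds the unit latent variance"
            )

    @property
    def loci(self) -> list[Locus]:
        return [*self.nmr_loci, *self.cpd_loci]

    def locus_frame(self) -> pd.DataFrame:
        return pd.DataFrame([l.__dict__ for l in self.loci])


@dataclass
class Cohort:
    """One realised individual-level sample across strata."""

    config: SimulationConfig
    loci: pd.DataFrame
    genotypes: np.ndarray  # (n, L_total) dosages in {0, 1, 2}
    stratum: np.ndarray  # per-individual label: current / former / never
    nmr: np.ndarray
    cpd_bin: np.ndarray  # 1..5 for smokers, 0 for never smokers
    cpd_latent: np.ndarray  # nan for never smokers
    dose: np.ndarray  # circulating-nicotine proxy, 0 for never smokers
    confounder: np.ndarray
    outcomes: dict[str, np.ndarray]
    cotinine: np.ndarray | None = None

    def mask(self, stratum: str) -> np.ndarray:
        if stratum == "all":
            return np.ones(len(self.stratum), dtype=bool)
        if stratum == "ever":
            return (self.stratum == "current") | (self.stratum == "former")
        return self.stratum == stratum

    @property
    def n(self) -> int:
        return len(self.stratum)


def bin_thresholds_and_rho(probs: Sequence[float]) -> tuple[np.ndarray, float]:
    """Standard-normal bin thresholds for the CPD categories, and the bin/latent correlation.

    ``rho`` is the correlation between the discretised bin variable and the
    unit-normal latent it is cut from; the generator divides the binned-scale
    heritability target by ``rho^2`` to undo the discretisation attenuation.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or len(probs) < 2 or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs <= 0):
        raise ConfigError("bin probabilities must be positive and sum to 1")
    k = np.arange(1, len(probs) + 1)
    mean = float(np.sum(probs * k))
    var = float(np.sum(probs * (k - mean) ** 2))
    thresholds = norm.ppf(np.cumsum(probs)[:-1])
    pdf = np.concatenate([[0.0], norm.pdf(thresholds), [0.0]])
    cov = float(np.sum(k * (pdf[:-1] - pdf[1:])))
    return thresholds, cov / math.sqrt(var)


def _solve_effects(mafs: np.ndarray, h2: float) -> np.ndarray:
    """Per-allele effects with equal per-locus variance shares summing to ``h2``."""
    var_per_locus = h2 / len(mafs)
    return np.sqrt(var_per_locus / (2.0 * mafs * (1.0 - mafs)))


def _build_loci(prefix: str, role: str, mafs: np.ndarray, h2: float, chrom_offset: int) -> list[Locus]:
    betas = _solve_effects(mafs, h2)
    loci = []
    for i, (maf, beta) in enumerate(zip(mafs, betas)):
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        loci.append(
            Locus(
                rsid=f"rs{prefix}{i + 1:03d}",
                chrom=str((chrom_offset + i) % 22 + 1),
                pos=1_000_000 * (i + 1),
                effect_allele=ea,
                other_allele=oa,
                maf=float(maf),
                beta=float(beta),
                role=role,
            )
        )
    return loci


def default_config(
    scale_factor: float = 1.0,
    *,
    seed: int = 0,
    outcomes: Iterable[str] | None = None,
) -> SimulationConfig:
    """Packaged defaults reproducing the study's assumed architecture.

    7 NMR loci explaining 38% of NMR variance, 55 CPD loci explaining 4% of
    variance in the binned heaviness measure, stratum sizes scaled from the
    UK Biobank never/current/former counts by ``scale_factor``, and outcome
    truths taken from the study-scale multivariable estimates (e.g. heart
    rate: +4.22 bpm per SD of CPD, -0.30 bpm per SD of NMR).
    """
    if not (0.0 < scale_factor <= 1.0):
        raise ConfigError(f"scale_factor {scale_factor} outside (0, 1]")
    _, rho = bin_thresholds_and_rho((0.07, 0.22, 0.42, 0.22, 0.07))
    nmr_loci = _build_loci("nmr", "nmr", np.linspace(0.15, 0.40, 7), 0.38, 0)
    cpd_loci = _build_loci("cpd", "cpd", np.linspace(0.10, 0.45, 55), 0.04 / rho**2, 7)

    all_specs = {
        "heart_rate": OutcomeSpec(
            name="heart_rate",
            kind="continuous",
            theta_nmr=-0.30,
            theta_cpd=4.22,
            confounder_loading=2.0,
            strata={
                "current": StratumMoments(mean=71.27, sd=11.58),
                "former": StratumMoments(mean=68.40, sd=11.23),
                "never": StratumMoments(mean=68.93, sd=11.10),
            },
        ),
        "fev1": OutcomeSpec(
            name="fev1",
            kind="continuous",
            theta_nmr=-0.01777,
            theta_cpd=-0.27236,
            confounder_loading=0.10,
            strata={
                "current": StratumMoments(mean=2.78, sd=0.83),
                "former": StratumMoments(mean=2.83, sd=0.76),
                "never": StratumMoments(mean=2.88, sd=0.78),
            },
        ),
        "fvc": OutcomeSpec(
            name="fvc",
            kind="continuous",
            theta_nmr=-0.01350,
            theta_cpd=-0.19531,
            confounder_loading=0.10,
            strata={
                "current": StratumMoments(mean=3.81, sd=1.02),
                "former": StratumMoments(mean=3.78, sd=0.96),
                "never": StratumMoments(mean=3.78, sd=0.99),
            },
        ),
        "copd": OutcomeSpec(
            name="copd",
            kind="binary",
            theta_nmr=math.log(1.03),
            theta_cpd=math.log(7.24),
            confounder_loading=0.10,
            strata={
                # Never-smoker prevalence is printed as "<1%"; the midpoint
                # 0.5% is used because the liability threshold needs a number.
                "current": StratumMoments(prevalence=0.06),
                "former": StratumMoments(prevalence=0.02),
                "never": StratumMoments(prevalence=0.005),
            },
        ),
        "chd": OutcomeSpec(
            name="chd",
            kind="binary",
            theta_nmr=0.0,
            theta_cpd=math.log(1.32),
            confounder_loading=0.10,
            strata={
                "current": StratumMoments(prevalence=0.11),
                "former": StratumMoments(prevalence=0.11),
                "never": StratumMoments(prevalence=0.06),
            },
        ),
        "lung_cancer": OutcomeSpec(
            name="lung_cancer",
            kind="binary",
            theta_nmr=0.0,
            theta_cpd=math.log(2.94),
            confounder_loading=0.10,
            strata={
                # Case-control sampling frame: ever/never strata only.
                "ever": StratumMoments(prevalence=0.57),
                "never": StratumMoments(prevalence=0.24),
            },
        ),
    }
    if outcomes is not None:
        all_specs = {k: v for k, v in all_specs.items() if k in set(outcomes)}

    return SimulationConfig(
        seed=seed,
        n_current=max(2, round(FULL_STRATUM_SIZES["current"] * scale_factor)),
        n_former=max(2, round(FULL_STRATUM_SIZES["former"] * scale_factor)),
        n_never=max(2, round(FULL_STRATUM_SIZES["never"] * scale_factor)),
        nmr_loci=nmr_loci,
        cpd_loci=cpd_loci,
        outcomes=all_specs,
    )


def inject_pleiotropy(
    config: SimulationConfig,
    mode: Literal["none", "balanced", "directional"],
    proportion: float,
    magnitude: float,
    target: Literal["cpd", "nmr"] = "cpd",
) -> SimulationConfig:
    """Return a config whose outcomes receive direct locus effects bypassing the exposures.

    The first ``round(proportion * L)`` loci of the target panel (a fixed,
    deterministic choice) acquire a per-allele effect on every outcome:
    constant-sign under ``directional``, alternating-sign (zero mean) under
    ``balanced``.  Active in all strata, never smokers included — which is
    exactly why never-smoker estimates serve as a pleiotropy alarm.
    """
    if proportion == 0.0 or mode == "none":
        return replace(config, pleiotropy=PleiotropySpec())
    return replace(
        config,
        pleiotropy=PleiotropySpec(
            mode=mode, proportion=proportion, magnitude=magnitude, target=target
        ),
    )


def _pleiotropy_effects(config: SimulationConfig) -> np.ndarray:
    """Per-locus direct outcome effects (length L_total), in outcome-SD/liability units."""
    n_nmr, n_cpd = len(config.nmr_loci), len(config.cpd_loci)
    delta = np.zeros(n_nmr + n_cpd)
    spec = config.pleiotropy
    if spec.mode == "none" or spec.proportion == 0.0:
        return delta
    if spec.target == "cpd":
        size, offset = n_cpd, n_nmr
    else:
        size, offset = n_nmr, 0
    k = int(round(spec.proportion * size))
    signs = np.ones(k) if spec.mode == "directional" else (-1.0) ** np.arange(k)
    delta[offset : offset + k] = spec.magnitude * signs
    return delta


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Draw one individual-level sample for all configured strata.

    Deterministic given the seed: the same seed yields identical cohorts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = config.loci
    mafs = np.array([l.maf for l in loci])
    n_nmr = len(config.nmr_loci)
    a = np.array([l.beta for l in config.nmr_loci])
    b = np.array([l.beta for l in config.cpd_loci])
    thresholds, rho = bin_thresholds_and_rho(config.cpd_bin_probs)
    lam = config.lambda_nmr_to_cpd
    v_latent = float(np.sum(2 * mafs[n_nmr:] * (1 - mafs[n_nmr:]) * b**2))
    sigma_cpd = math.sqrt(1.0 - v_latent - lam**2)
    sigma_nmr = math.sqrt(1.0 - config.h2_nmr)
    delta = _pleiotropy_effects(config)
    # Correlation between NMR and the centred CPD bin among smokers; enters
    # the variance bookkeeping of outcomes that load on both exposures.
    cov_nmr_bin = lam * rho

    parts: dict[str, list[np.ndarray]] = {k: [] for k in (
        "stratum", "nmr", "cpd_bin", "cpd_latent", "dose", "confounder", "cotinine"
    )}
    geno_parts: list[np.ndarray] = []
    outcome_parts: dict[str, list[np.ndarray]] = {name: [] for name in config.outcomes}

    for stratum, n in (
        ("current", config.n_current),
        ("former", config.n_former),
        ("never", config.n_never),
    ):
        if n <= 0:
            continue
        # Binomial(2, maf) drawn as two Bernoulli trials: ~3x faster than
        # rng.binomial for the cohort-scale matrices this generator produces.
        maf32 = mafs.astype(np.float32)
        g = (
            (rng.random((n, len(loci)), dtype=np.float32) < maf32).astype(np.int8)
            + (rng.random((n, len(loci)), dtype=np.float32) < maf32).astype(np.int8)
        )
        g32 = g.astype(np.float32)
        # Centred genetic scores via scalar offsets (population means exact).
        nmr_gen = g32[:, :n_nmr] @ a.astype(np.float32) - float(2.0 * mafs[:n_nmr] @ a)
        nmr = nmr_gen.astype(float) + rng.normal(0.0, sigma_nmr, n)
        u = rng.normal(0.0, 1.0, n)
        smoker = stratum != "never"
        if smoker:
            cpd_gen = g32[:, n_nmr:] @ b.astype(np.float32) - float(2.0 * mafs[n_nmr:] @ b)
            latent = cpd_gen.astype(float) + lam * nmr + rng.normal(0.0, sigma_cpd, n)
            cpd_bin = (np.digitize(latent, thresholds) + 1).astype(np.int8)
            cpd_c = cpd_bin - 3.0
            dose = cpd_bin * np.maximum(1.0 - config.eta * nmr, config.dose_floor)
        else:
            latent = np.full(n, np.nan)
            cpd_bin = np.zeros(n, dtype=np.int8)
            cpd_c = np.zeros(n)
            dose = np.zeros(n)
        # Cotinine-style alternative nicotine proxy: rises with intake, falls
        # with metabolism speed; purely interpretive concretisation.
        if smoker:
            dose_c = (dose - dose.mean()) / max(dose.std(), 1e-12)
            cot = 0.4 * dose_c - 0.5 * nmr + rng.normal(0.0, math.sqrt(1 - 0.4**2 - 0.5**2), n)
        else:
            cot = np.zeros(n)

        if np.any(delta):  # active in every stratum, including never smokers
            pleio = (g32 @ delta.astype(np.float32)).astype(float) - float(2.0 * mafs @ delta)
        else:
            pleio = 0.0
        m_met = config.metabolism_pleiotropy

        for name, spec in config.outcomes.items():
            mom = spec.moments_for(stratum)
            if mom is None:
                outcome_parts[name].append(np.full(n, np.nan))
                continue
            c = spec.confounder_loading
            if spec.kind == "continuous":
                if smoker:
                    tn, tc = spec.theta_nmr, spec.theta_cpd
                    explained = tn**2 + tc**2 + 2 * tn * tc * cov_nmr_bin + c**2
                    if explained >= mom.sd**2:
                        raise ConfigError(
                            f"{name}/{stratum}: systematic variance {explained:.3g} exceeds "
                            f"target variance {mom.sd ** 2:.3g}"
                        )
                    resid = math.sqrt(mom.sd**2 - explained)
                    y = (
                        mom.mean
                        + tn * nmr
                        + tc * cpd_c
                        + c * u
                        + mom.sd * pleio
                        + rng.normal(0.0, resid, n)
                    )
                else:
                    resid = math.sqrt(mom.sd**2 - c**2)
                    y = mom.mean + c * u + mom.sd * pleio + rng.normal(0.0, resid, n)
                outcome_parts[name].append(y)
            else:
                mu = mom.prevalence
                t_thr = norm.ppf(1.0 - mu)
                if smoker:
                    # Liability coefficients are scaled so the downstream
                    # linear-GWAS + mu(1-mu) pipeline recovers the configured
                    # log odds ratios (average-derivative identity under a
                    # Gaussian systematic score).
                    conv = mu * (1.0 - mu) / norm.pdf(t_thr)
                    tn = spec.theta_nmr * conv
                    tc = spec.theta_cpd * conv
                    tm = m_met * conv
                    explained = (
                        (tn + tm) ** 2 + tc**2 + 2 * (tn + tm) * tc * cov_nmr_bin + c**2
                    )
                    if explained >= 1.0:
                        raise ConfigError(
                            f"{name}/{stratum}: liability loadings explain {explained:.3g} >= 1"
                        )
                    liability = (
                        (tn + tm) * nmr
                        + tc * cpd_c
                        + c * u
                        + pleio
                        + rng.normal(0.0, math.sqrt(1.0 - explained), n)
                    )
                else:
                    liability = c * u + pleio + rng.normal(0.0, math.sqrt(1.0 - c**2), n)
                outcome_parts[name].append((liability > t_thr).astype(np.int8))

        geno_parts.append(g)
        parts["stratum"].append(np.full(n, stratum))
        parts["nmr"].append(nmr)
        parts["cpd_bin"].append(cpd_bin)
        parts["cpd_latent"].append(latent)
        parts["dose"].append(dose)
        parts["confounder"].append(u)
        parts["cotinine"].append(cot)

    if not geno_parts:
        raise ConfigError("no stratum has a positive sample size")
    return Cohort(
        config=config,
        loci=config.locus_frame(),
        genotypes=np.vstack(geno_parts),
        stratum=np.concatenate(parts["stratum"]),
        nmr=np.concatenate(parts["nmr"]),
        cpd_bin=np.concatenate(parts["cpd_bin"]),
        cpd_latent=np.concatenate(parts["cpd_latent"]),
        dose=np.concatenate(parts["dose"]),
        confounder=np.concatenate(parts["confounder"]),
        outcomes={k: np.concatenate(v) for k, v in outcome_parts.items()},
        cotinine=np.concatenate(parts["cotinine"]),
    )


def _trait_values(cohort: Cohort, trait: str) -> tuple[np.ndarray, TraitType]:
    if trait == "nmr":
        return cohort.nmr, TraitType.CONTINUOUS
    if trait == "cpd":
        return cohort.cpd_bin.astype(float), TraitType.CONTINUOUS
    if trait == "cotinine":
        return cohort.cotinine, TraitType.CONTINUOUS
    if trait in cohort.outcomes:
        kind = cohort.config.outcomes[trait].kind
        return (
            cohort.outcomes[trait].astype(float),
            TraitType.BINARY if kind == "binary" else TraitType.CONTINUOUS,
        )
    raise SmoketraceError(f"unknown trait {trait!r}")


def run_gwas(
    cohort: Cohort,
    trait: str,
    stratum: str,
    *,
    liability: bool = True,
    loci: Sequence[str] | None = None,
) -> GwasSumStats:
    """Per-locus simple least squares of a trait on genotype dosage within a stratum.

    Binary traits are analysed on the linear (0/1) scale and, when
    ``liability`` is left on, rescaled to liability log odds at the observed
    case fraction.  Returns one record per simulated locus, or per requested
    rsid when ``loci`` restricts the panel (emulating a source GWAS that
    publishes only its conditionally independent variants).
    """
    mask = cohort.mask(stratum)
    n = int(mask.sum())
    if n == 0:
        raise SmoketraceError(f"stratum {stratum!r} is empty")
    y, trait_type = _trait_values(cohort, trait)
    y = y[mask]
    if np.any(np.isnan(y)):
        raise SmoketraceError(f"trait {trait!r} is not defined in stratum {stratum!r}")
    all_loci = cohort.config.loci
    if loci is None:
        keep = list(range(len(all_loci)))
    else:
        wanted = set(loci)
        keep = [j for j, l in enumerate(all_loci) if l.rsid in wanted]
    X = cohort.genotypes[np.ix_(mask, np.asarray(keep, dtype=int))].astype(float)

    xm = X.mean(axis=0)
    ym = float(y.mean())
    yc = y - ym
    # Non-central sums avoid materialising a centred copy of X.
    sxx = np.einsum("ij,ij->j", X, X) - n * xm**2
    sxy = X.T @ yc - xm * yc.sum()
    syy = float(yc @ yc)
    beta = sxy / sxx
    dof = n - 2
    resid_ss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(resid_ss / dof / sxx)
    se = np.maximum(se, np.finfo(float).tiny)
    z = beta / se
    pvals = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)

    records = []
    for j, locus in enumerate(all_loci[k] for k in keep):
        records.append(
            VariantRecord(
                rsid=locus.rsid,
                chrom=locus.chrom,
                pos=locus.pos,
                effect_allele=locus.effect_allele,
                other_allele=locus.other_allele,
                eaf=float(xm[j] / 2.0),
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(pvals[j]),
                n=n,
            )
        )
    stats = GwasSumStats.from_records(
        records,
        trait=trait,
        trait_type=trait_type,
        stratum=stratum,
        scale=EffectScale.LINEAR,
    )
    if trait_type is TraitType.BINARY and liability:
        stats = liability_transform(stats, float(np.clip(ym, 1e-6, 1 - 1e-6)))
    return stats


@dataclass(frozen=True)
class LdBlock:
    """A group of variants generated to share LD: each member tracks the first at target r2."""

    members: tuple[str, ...]
    maf: float
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ConfigError(f"target r2 {self.r2} outside [0, 1]")
        if not (0.01 < self.maf <= 0.5):
            raise ConfigError(f"block maf {self.maf} outside (0.01, 0.5]")
        if len(self.members) < 1:
            raise ConfigError("a block needs at least one member")


def make_ld_panel(
    config: SimulationConfig,
    block_spec: Sequence[LdBlock] = (),
    n: int = 10_000,
    seed: int = 0,
) -> LdReference:
    """Synthetic LD reference: blockwise-correlated genotypes, empirical r2 table.

    Non-base block members copy the base genotype with probability sqrt(r2)
    per individual (giving pairwise correlation sqrt(r2), hence r-squared r2
    against the base).  All loci of ``config`` not named in any block enter as
    independent singleton variants, so clumping a default instrument panel is
    a no-op.  The emitted r2 values are the empirical squared correlations of
    the generated genotypes.
    """
    rng = np.random.default_rng(seed)
    ref = LdReference()
    in_blocks = {m for blk in block_spec for m in blk.members}
    positions: dict[str, tuple[str, int]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for locus in config.loci:
        positions[locus.rsid] = (locus.chrom, locus.pos)
        alleles[locus.rsid] = (locus.effect_allele, locus.other_allele)
        if locus.rsid not in in_blocks:
            ref.add(locus.rsid, locus.rsid, 1.0)

    for bi, blk in enumerate(block_spec):
        base = rng.binomial(2, blk.maf, n).astype(float)
        genos = {blk.members[0]: base}
        pi = math.sqrt(blk.r2)
        for member in blk.members[1:]:
            keep = rng.random(n) < pi
            fresh = rng.binomial(2, blk.maf, n).astype(float)
            genos[member] = np.where(keep, base, fresh)
        base_pos = positions.get(blk.members[0], (str(bi % 22 + 1), 50_000_000 + bi * 100_000))
        for mi, member in enumerate(blk.members):
            positions.setdefault(member, (base_pos[0], base_pos[1] + mi * 1_000))
            alleles.setdefault(member, ("A", "G"))
        names = list(blk.members)
        for i_a in range(len(names)):
            ref.add(names[i_a], names[i_a], 1.0)
            for i_b in range(i_a + 1, len(names)):
                ga, gb = genos[names[i_a]], genos[names[i_b]]
                if ga.std() == 0 or gb.std() == 0:
                    raise ConfigError("degenerate genotype column in LD block (maf too extreme)")
                r = float(np.corrcoef(ga, gb)[0, 1])
                ref.add(names[i_a], names[i_b], min(r * r, 1.0))

    ref.positions.update(positions)
    ref.alleles.update(alleles)
    for v in positions:
        if v not in ref:
            ref.add(v, v, 1.0)
    return ref
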