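"""GWAS summary-statistics containers, file IO, and effect-scale transforms.

Summary statistics are one record per biallelic SNV: the per-allele effect
``beta`` of the effect allele on the trait, its standard error, p-value,
effect-allele frequency and sample size.  A dataset carries an explicit
effect-scale tag so that the liability transformation for binary traits
(dividing linear-model statistics by ``mu*(1-mu)``, ``mu`` the case
prevalence) can only be applied once: re-application is a detectable state
error rather than a silent double scaling.

Files are tab-delimited with a fixed header; trait-level metadata (trait,
type, stratum, scale, prevalence) travels in a JSON sidecar next to the
table so a dataset round-trips losslessly through disk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    DomainError,
    DuplicateKeyError,
    SchemaError,
    StateError,
    ValidationError,
)

__all__ = [
    "EffectScale",
    "TraitType",
    "VariantRecord",
    "GwasSumStats",
    "read_sumstats",
    "write_sumstats",
    "liability_transform",
    "to_odds_ratio",
    "SUMSTATS_COLUMNS",
]

#: Fixed on-disk column order.
SUMSTATS_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

_VALID_ALLELES = frozenset("ACGT")

#: Two-sided 95% normal quantile (1.959964... at full precision).
Z_95 = float(norm.ppf(0.975))


class EffectScale(str, Enum):
    LINEAR = "linear"
    LOG_ODDS = "log_odds"
    LOG_ODDS_LIABILITY = "log_odds_liability"


class TraitType(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"


@dataclass(frozen=True)
class VariantRecord:
    """One SNP-trait association on some declared effect scale.

    ``eaf`` may be ``None`` (unknown frequency); such variants are read and
    written normally but are ineligible for frequency-based palindrome
    resolution during harmonisation.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in _VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a "
                "single A/C/G/T base (multi-allelic or indel records are rejected)"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} is not a single A/C/G/T base"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")
        if self.n <= 0:
            raise ValidationError(f"{self.rsid}: sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand cannot be inferred from alleles."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return self.other_allele == comp[self.effect_allele]

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class GwasSumStats:
    """All per-variant records for one trait in one smoking stratum."""

    trait: str
    trait_type: TraitType
    stratum: str
    scale: EffectScale
    records: dict[str, VariantRecord] = field(default_factory=dict)
    prevalence: float | None = None

    def __post_init__(self) -> None:
        self.trait_type = TraitType(self.trait_type)
        self.scale = EffectScale(self.scale)
        if self.scale is EffectScale.LOG_ODDS_LIABILITY:
            if self.trait_type is not TraitType.BINARY:
                raise ValidationError("liability scale is only meaningful for binary traits")
            if self.prevalence is None:
                raise ValidationError("liability-scale statistics require a stored prevalence")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValidationError(f"prevalence {self.prevalence} outside (0, 1)")
        for rsid, rec in self.records.items():
            if rsid != rec.rsid:
                raise ValidationError(f"record keyed {rsid!r} holds rsid {rec.rsid!r}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantRecord],
        *,
        trait: str,
        trait_type: TraitType | str,
        stratum: str = "all",
        scale: EffectScale | str = EffectScale.LINEAR,
        prevalence: float | None = None,
    ) -> "GwasSumStats":
        keyed: dict[str, VariantRecord] = {}
        for rec in records:
            if rec.rsid in keyed:
                raise DuplicateKeyError(f"duplicate rsid {rec.rsid!r}")
            keyed[rec.rsid] = rec
        return cls(
            trait=trait,
            trait_type=TraitType(trait_type),
            stratum=stratum,
            scale=EffectScale(scale),
            records=keyed,
            prevalence=prevalence,
        )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> VariantRecord:
        return self.records[rsid]

    def subset(self, rsids: Iterable[str]) -> "GwasSumStats":
        """Restriction to the given rsids (silently skipping absent ones), same metadata."""
        wanted = set(rsids)
        return GwasSumStats(
            trait=self.trait,
            trait_type=self.trait_type,
            stratum=self.stratum,
            scale=self.scale,
            records={r: rec for r, rec in self.records.items() if r in wanted},
            prevalence=self.prevalence,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(SUMSTATS_COLUMNS))

    def metadata(self) -> dict:
        return {
            "trait": self.trait,
            "trait_type": self.trait_type.value,
            "stratum": self.stratum,
            "scale": self.scale.value,
            "prevalence": self.prevalence,
        }


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str = "\t",
    trait: str | None = None,
    trait_type: TraitType | str | None = None,
    stratum: str | None = None,
    scale: EffectScale | str | None = None,
    prevalence: float | None = None,
) -> GwasSumStats:
    """Read a delimited summary-statistics file into a validated container.

    ``dialect`` maps *file* column names onto the canonical field names, e.g.
    ``{"SNP": "rsid", "A1": "effect_allele", ...}``.  Metadata comes from the
    JSON sidecar written by :func:`write_sumstats` when present; explicit
    keyword arguments override it.  Malformed rows raise with their (1-based
    data) row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=["NA"])
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if trait is not None:
        meta["trait"] = trait
    if trait_type is not None:
        meta["trait_type"] = trait_type
    if stratum is not None:
        meta["stratum"] = stratum
    if scale is not None:
        meta["scale"] = scale
    if prevalence is not None:
        meta["prevalence"] = prevalence
    meta.setdefault("trait", path.stem)
    meta.setdefault("trait_type", TraitType.CONTINUOUS)
    meta.setdefault("stratum", "all")
    meta.setdefault("scale", EffectScale.LINEAR)
    meta.setdefault("prevalence", None)

    records: dict[str, VariantRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = VariantRecord(
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=int(row.n),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, data row {i}: {exc}") from exc
        if rec.rsid in records:
            raise DuplicateKeyError(f"{path}, data row {i}: duplicate rsid {rec.rsid!r}")
        records[rec.rsid] = rec

    return GwasSumStats(
        trait=meta["trait"],
        trait_type=TraitType(meta["trait_type"]),
        stratum=meta["stratum"],
        scale=EffectScale(meta["scale"]),
        records=records,
        prevalence=meta["prevalence"],
    )


def write_sumstats(stats: GwasSumStats, path: str | Path, *, sep: str = "\t") -> None:
    """Write the fixed-header table plus its JSON metadata sidecar.

    Floats are written with 12 significant digits so read(write(x)) round-trips
    below any test tolerance; missing eaf is written as ``NA``.
    """
    path = Path(path)
    df = stats.to_frame()
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.12g")
    _sidecar_path(path).write_text(json.dumps(stats.metadata(), indent=1) + "\n")


def liability_transform(stats: GwasSumStats, prevalence: float) -> GwasSumStats:
    """Rescale linear-model statistics for a binary trait to the liability log-odds scale.

    Every beta and standard error is divided by ``mu*(1-mu)`` where ``mu`` is
    the case prevalence (first-order Taylor rescaling of a linear-probability
    effect to a log odds ratio).  The Wald statistic ``beta/se``, and hence the
    p-value, is invariant.
    """
    if not (0.0 < prevalence < 1.0):
        raise DomainError(f"prevalence must lie in (0, 1), got {prevalence}")
    if stats.trait_type is not TraitType.BINARY:
        raise StateError("liability transform applies to binary traits only")
    if stats.scale is not EffectScale.LINEAR:
        raise StateError(
            f"input is already on scale {stats.scale.value!r}; the transform applies once, "
            "to linear-scale statistics"
        )
    denom = prevalence * (1.0 - prevalence)
    new_records = {
        rsid: replace(rec, beta=rec.beta / denom, se=rec.se / denom)
        for rsid, rec in stats.records.items()
    }
    return GwasSumStats(
        trait=stats.trait,
        trait_type=stats.trait_type,
        stratum=stats.stratum,
        scale=EffectScale.LOG_ODDS_LIABILITY,
        records=new_records,
        prevalence=prevalence,
    )


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into an odds ratio with its 95% CI.

    ``se = 0`` is accepted as the degenerate limit (point-mass CI); negative
    se is a domain error.
    """
    if se < 0:
        raise DomainError(f"se must be >= 0, got {se}")
    return (
        math.exp(beta),
        math.exp(beta - Z_95 * se),
        math.exp(beta + Z_95 * se),
    )


def normal_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Two-sided normal-theory confidence interval."""
    z = norm.ppf(0.5 + level / 2.0)
    return beta - z * se, beta + z * se
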