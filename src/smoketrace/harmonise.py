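"""Instrument selection, LD handling, and exposure/outcome allele alignment.

Instruments are genome-wide-significant variants (default p < 5e-8), greedily
clumped on a p-value ranking against a pairwise r-squared reference so the
retained set is mutually independent.  Harmonisation places every variant that
is present in all exposure datasets and the outcome dataset onto the first
exposure's effect-allele frame: swapped alleles flip the outcome sign,
strand flips are resolved by complementing, and palindromic (A/T, C/G)
variants are kept only when both effect-allele frequencies fall outside the
ambiguity band on the same side.  Every exclusion is logged with a reason so
candidate count = retained + excluded always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientInstrumentsError,
    LookupMissError,
    SmoketraceError,
    ValidationError,
)
from .sumstats import GwasSumStats, VariantRecord

__all__ = [
    "InstrumentSet",
    "LdReference",
    "HarmonisedData",
    "select_instruments",
    "clump",
    "find_proxy",
    "harmonise",
    "combine_instruments",
    "GWAS_SIGNIFICANCE",
]

#: Conventional genome-wide significance threshold used for instrument selection.
GWAS_SIGNIFICANCE = 5e-8

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


@dataclass
class InstrumentSet:
    """An ordered (ascending p) list of candidate instruments for one exposure.

    ``selection_log`` records, for every candidate examined, whether it was
    selected or dropped and why.  ``pvalues`` keeps the selection p-value per
    retained variant so later clumping can rank without re-reading the GWAS.
    """

    exposure: str
    variants: list[str] = field(default_factory=list)
    pvalues: dict[str, float] = field(default_factory=dict)
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("instrument set contains duplicate rsids")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


class LdReference:
    """Pairwise r-squared lookup with optional per-variant position/allele metadata.

    Unlisted pairs are taken as r2 = 0 (unlinked); r2(a, a) = 1 by definition.
    """

    def __init__(
        self,
        r2: dict[tuple[str, str], float] | None = None,
        positions: dict[str, tuple[str, int]] | None = None,
        alleles: dict[str, tuple[str, str]] | None = None,
        variants: Iterable[str] | None = None,
    ) -> None:
        self._r2: dict[frozenset, float] = {}
        self._variants: set[str] = set(variants or ())
        self.positions = dict(positions or {})
        self.alleles = dict(alleles or {})
        self._variants.update(self.positions)
        for (a, b), v in (r2 or {}).items():
            self.add(a, b, v)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        self._variants.update((a, b))
        if a != b:
            self._r2[frozenset((a, b))] = r2

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._variants

    @property
    def variants(self) -> set[str]:
        return set(self._variants)

    def r2(self, a: str, b: str) -> float:
        for rsid in (a, b):
            if rsid not in self._variants:
                raise LookupMissError(f"variant {rsid!r} absent from LD reference")
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def distance_kb(self, a: str, b: str) -> float:
        """Base-pair distance in kb; +inf across chromosomes or with unknown positions."""
        pa, pb = self.positions.get(a), self.positions.get(b)
        if pa is None or pb is None or pa[0] != pb[0]:
            return float("inf")
        return abs(pa[1] - pb[1]) / 1000.0

    def to_file(self, path: str | Path) -> None:
        """Serialise as the 3-column (rsid_a, rsid_b, r2) table; self-pairs mark membership."""
        rows = [(v, v, 1.0) for v in sorted(self._variants)]
        rows += [(min(k), max(k), v) for k, v in sorted(self._r2.items(), key=lambda kv: sorted(kv[0]))]
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "LdReference":
        df = pd.read_csv(path, sep="\t")
        ref = cls()
        for row in df.itertuples(index=False):
            ref.add(str(row.rsid_a), str(row.rsid_b), float(row.r2))
        return ref


@dataclass
class HarmonisedData:
    """Aligned SNP-exposure and SNP-outcome effects ready for the estimators.

    ``exposure_beta`` / ``exposure_se`` are L x K (variants x exposures) on the
    first exposure's allele frame; ``outcome_beta`` / ``outcome_se`` are the
    length-L aligned outcome effects.
    """

    rsids: list[str]
    exposure_names: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    outcome_name: str = "outcome"
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_beta = np.atleast_2d(np.asarray(self.exposure_beta, dtype=float))
        self.exposure_se = np.atleast_2d(np.asarray(self.exposure_se, dtype=float))
        if self.exposure_beta.shape[0] == 1 and len(self.rsids) > 1:
            self.exposure_beta = self.exposure_beta.T
            self.exposure_se = self.exposure_se.T
        self.outcome_beta = np.asarray(self.outcome_beta, dtype=float).ravel()
        self.outcome_se = np.asarray(self.outcome_se, dtype=float).ravel()
        L = len(self.rsids)
        if not (
            self.exposure_beta.shape == self.exposure_se.shape == (L, len(self.exposure_names))
            and self.outcome_beta.shape == self.outcome_se.shape == (L,)
        ):
            raise ValidationError("harmonised matrices have inconsistent dimensions")
        if L and (np.any(self.exposure_se <= 0) or np.any(self.outcome_se <= 0)):
            raise ValidationError("all standard errors must be > 0")

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def single(self, exposure: str | int = 0) -> "HarmonisedData":
        """Univariable view: one exposure column with the same outcome."""
        k = exposure if isinstance(exposure, int) else self.exposure_names.index(exposure)
        return HarmonisedData(
            rsids=list(self.rsids),
            exposure_names=[self.exposure_names[k]],
            exposure_beta=self.exposure_beta[:, [k]],
            exposure_se=self.exposure_se[:, [k]],
            outcome_beta=self.outcome_beta.copy(),
            outcome_se=self.outcome_se.copy(),
            outcome_name=self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"rsid": self.rsids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.exposure_beta[:, k]
            data[f"se_{name}"] = self.exposure_se[:, k]
        data["outcome_beta"] = self.outcome_beta
        data["outcome_se"] = self.outcome_se
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome_name: str = "outcome") -> "HarmonisedData":
        names = [c[5:] for c in df.columns if c.startswith("beta_")]
        return cls(
            rsids=[str(r) for r in df["rsid"]],
            exposure_names=names,
            exposure_beta=df[[f"beta_{n}" for n in names]].to_numpy(),
            exposure_se=df[[f"se_{n}" for n in names]].to_numpy(),
            outcome_beta=df["outcome_beta"].to_numpy(),
            outcome_se=df["outcome_se"].to_numpy(),
            outcome_name=outcome_name,
        )


def select_instruments(
    stats: GwasSumStats, p_threshold: float = GWAS_SIGNIFICANCE
) -> InstrumentSet:
    """Keep variants with p < threshold, ordered by ascending p.

    An empty result is valid (no instruments reach significance); rejections
    are recorded in the selection log.
    """
    selected: list[VariantRecord] = []
    log: list[tuple[str, str, str]] = []
    for rec in stats.records.values():
        if rec.pvalue < p_threshold:
            selected.append(rec)
            log.append((rec.rsid, "selected", f"p={rec.pvalue:.3g} < {p_threshold:g}"))
        else:
            log.append((rec.rsid, "dropped", f"p={rec.pvalue:.3g} >= {p_threshold:g}"))
    selected.sort(key=lambda r: (r.pvalue, r.rsid))
    return InstrumentSet(
        exposure=stats.trait,
        variants=[r.rsid for r in selected],
        pvalues={r.rsid: r.pvalue for r in selected},
        selection_log=log,
    )


def combine_instruments(sets: Sequence[InstrumentSet]) -> InstrumentSet:
    """Union of several exposures' instruments ranked by the minimum p across exposures.

    This is the joint list used for multivariable models, where the combined
    exposure datasets are clumped together.
    """
    pmin: dict[str, float] = {}
    for s in sets:
        for rsid in s.variants:
            p = s.pvalues.get(rsid, 1.0)
            pmin[rsid] = min(p, pmin.get(rsid, 1.0))
    order = sorted(pmin, key=lambda r: (pmin[r], r))
    return InstrumentSet(
        exposure="+".join(s.exposure for s in sets),
        variants=order,
        pvalues=pmin,
        selection_log=[(r, "selected", "union of exposure instruments") for r in order],
    )


def clump(
    instruments: InstrumentSet,
    ld: LdReference,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
) -> InstrumentSet:
    """Greedy p-value-ranked LD clumping.

    Variants are visited in ascending-p order; one is kept iff, against every
    already-kept variant, it is either beyond ``window_kb`` (or on another
    chromosome) or has r2 < ``r2_max``.  Deterministic given the ranking; ties
    in p are broken lexicographically by rsid.
    """
    order = sorted(instruments.variants, key=lambda r: (instruments.pvalues.get(r, 1.0), r))
    kept: list[str] = []
    log: list[tuple[str, str, str]] = []
    for rsid in order:
        if rsid not in ld:
            raise LookupMissError(f"instrument {rsid!r} absent from LD reference")
        clash = None
        for other in kept:
            if ld.distance_kb(rsid, other) <= window_kb and ld.r2(rsid, other) >= r2_max:
                clash = other
                break
        if clash is None:
            kept.append(rsid)
            log.append((rsid, "selected", "independent of all retained variants"))
        else:
            log.append((rsid, "dropped", f"r2 >= {r2_max:g} with better-ranked {clash}"))
    return InstrumentSet(
        exposure=instruments.exposure,
        variants=kept,
        pvalues={r: instruments.pvalues.get(r, 1.0) for r in kept},
        selection_log=log,
    )


def find_proxy(
    rsid: str,
    target: GwasSumStats,
    ld: LdReference,
    r2_min: float = 0.8,
) -> str | None:
    """Best available stand-in for a variant missing from ``target``.

    Returns the variant present in ``target`` with maximal r2 >= ``r2_min``
    to the query; ties break by smaller base-pair distance, then by
    lexicographic rsid.  ``None`` when no candidate qualifies.
    """
    if rsid not in ld:
        raise LookupMissError(f"query variant {rsid!r} absent from LD reference")
    best: tuple[float, float, str] | None = None  # (-r2, distance, rsid)
    for cand in target.records:
        if cand == rsid or cand not in ld:
            continue
        r2 = ld.r2(rsid, cand)
        if r2 < r2_min:
            continue
        key = (-r2, ld.distance_kb(rsid, cand), cand)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def _align_record(
    frame: VariantRecord,
    rec: VariantRecord,
    band: tuple[float, float],
) -> tuple[float, str] | None:
    """Orientation of ``rec`` relative to ``frame``'s effect allele.

    Returns ``(sign, note)`` with sign +1 (as-is) or -1 (flip beta, 1-eaf),
    or ``None`` with the reason encoded by raising through the caller's log.
    """
    ea, oa = frame.effect_allele, frame.other_allele
    rea, roa = rec.effect_allele, rec.other_allele

    if frame.is_palindromic or rec.is_palindromic:
        # Allele strings cannot distinguish strand for A/T and C/G variants:
        # fall back on allele-frequency concordance.
        if {rea, roa} != {ea, oa} and {_complement(rea), _complement(roa)} != {ea, oa}:
            return None
        sign = 1.0 if rea == ea or _complement(rea) == ea else -1.0
        if frame.eaf is None or rec.eaf is None:
            return None
        eaf = rec.eaf if sign > 0 else 1.0 - rec.eaf
        lo, hi = band
        same_low = frame.eaf < lo and eaf < lo
        same_high = frame.eaf > hi and eaf > hi
        if not (same_low or same_high):
            return None
        return sign, "palindromic, aligned by eaf"

    if (rea, roa) == (ea, oa):
        return 1.0, "already aligned"
    if (rea, roa) == (oa, ea):
        return -1.0, "alleles swapped"
    crea, croa = _complement(rea), _complement(roa)
    if (crea, croa) == (ea, oa):
        return 1.0, "strand flipped"
    if (crea, croa) == (oa, ea):
        return -1.0, "strand flipped and swapped"
    return None


def harmonise(
    exposures: Sequence[GwasSumStats] | GwasSumStats,
    outcome: GwasSumStats,
    instruments: InstrumentSet,
    palindromic_eaf_window: tuple[float, float] = (0.30, 0.70),
) -> HarmonisedData:
    """Align K exposure datasets and one outcome dataset on a shared allele frame.

    The first exposure defines the reference frame.  A variant is retained only
    if present in every dataset and unambiguously orientable in each; palindromic
    variants additionally need both eafs outside the ambiguity band on the same
    side (otherwise they are dropped, including when either eaf is missing).
    """
    if isinstance(exposures, GwasSumStats):
        exposures = [exposures]
    if len(exposures) == 0:
        raise SmoketraceError("at least one exposure dataset is required")

    ref = exposures[0]
    rsids: list[str] = []
    exclusions: list[tuple[str, str]] = []
    exp_beta: list[list[float]] = []
    exp_se: list[list[float]] = []
    out_beta: list[float] = []
    out_se: list[float] = []

    for rsid in instruments.variants:
        missing = next(
            (ds for ds in (*exposures, outcome) if rsid not in ds),
            None,
        )
        if missing is not None:
            exclusions.append((rsid, f"absent from {missing.trait} ({missing.stratum})"))
            continue
        frame = ref[rsid]
        betas: list[float] = []
        ses: list[float] = []
        ok = True
        for ds in exposures:
            res = _align_record(frame, ds[rsid], palindromic_eaf_window)
            if res is None:
                exclusions.append((rsid, f"unresolvable alleles vs {ds.trait}"))
                ok = False
                break
            sign, _ = res
            betas.append(sign * ds[rsid].beta)
            ses.append(ds[rsid].se)
        if not ok:
            continue
        res = _align_record(frame, outcome[rsid], palindromic_eaf_window)
        if res is None:
            exclusions.append((rsid, f"unresolvable alleles vs {outcome.trait}"))
            continue
        sign, _ = res
        rsids.append(rsid)
        exp_beta.append(betas)
        exp_se.append(ses)
        out_beta.append(sign * outcome[rsid].beta)
        out_se.append(outcome[rsid].se)

    if len(rsids) < 2:
        raise InsufficientInstrumentsError(
            f"only {len(rsids)} variant(s) survive harmonisation "
            f"({len(exclusions)} excluded); at least 2 are required"
        )
    return HarmonisedData(
        rsids=rsids,
        exposure_names=[e.trait for e in exposures],
        exposure_beta=np.array(exp_beta, dtype=float),
        exposure_se=np.array(exp_se, dtype=float),
        outcome_beta=np.array(out_beta, dtype=float),
        outcome_se=np.array(out_se, dtype=float),
        outcome_name=outcome.trait,
        exclusion_log=exclusions,
    )
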