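"""Instrument selection, LD clumping, harmonization and instrument strength.

Selection is greedy p-value clumping: candidates passing the p-value
threshold are sorted (p ascending, ties broken by variant id), the best
remaining candidate is kept, and everything correlated with it above the
r^2 threshold is discarded — the standard procedure, made deterministic.

Harmonization aligns exposure and outcome effects onto the exposure's
effect allele, resolving allele swaps and strand complements, and handling
palindromic (A/T, C/G) variants by allele-frequency inference or by
dropping them.  Each kept variant carries its Wald ratio beta_y/beta_x and
first-order standard error se_y/|beta_x|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    EmptySelectionError,
    HarmonizationError,
    InsufficientInstrumentsError,
)
from .io import COMPLEMENT, GeneRegion, LDMatrix, SumstatRecord

logger = logging.getLogger("targetmr")

PalindromePolicy = Literal["drop", "infer"]


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on a shared effect allele."""

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    wald_ratio: float
    ratio_se: float
    flipped: bool
    palindromic: bool


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered set of harmonized instruments for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    instruments: tuple[HarmonizedInstrument, ...]
    target: str | None = None

    def __post_init__(self) -> None:
        ids = [i.variant_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise DataValidationError("InstrumentSet: variant ids must be unique")

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(i.variant_id for i in self.instruments)

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([i.beta_x for i in self.instruments])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([i.se_x for i in self.instruments])

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([i.beta_y for i in self.instruments])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([i.se_y for i in self.instruments])

    @property
    def wald_ratios(self) -> np.ndarray:
        return np.array([i.wald_ratio for i in self.instruments])

    @property
    def ratio_ses(self) -> np.ndarray:
        return np.array([i.ratio_se for i in self.instruments])

    def subset(self, keep_ids: Iterable[str]) -> "InstrumentSet":
        keep = set(keep_ids)
        return replace(
            self,
            instruments=tuple(i for i in self.instruments if i.variant_id in keep),
        )

    def drop(self, drop_ids: Iterable[str]) -> "InstrumentSet":
        gone = set(drop_ids)
        return replace(
            self,
            instruments=tuple(i for i in self.instruments if i.variant_id not in gone),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "wald_ratio": self.wald_ratios,
                "ratio_se": self.ratio_ses,
                "flipped": [i.flipped for i in self.instruments],
                "palindromic": [i.palindromic for i in self.instruments],
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        target: str | None = None,
    ) -> "InstrumentSet":
        instruments = tuple(
            HarmonizedInstrument(
                variant_id=str(r.variant_id),
                beta_x=float(r.beta_x),
                se_x=float(r.se_x),
                beta_y=float(r.beta_y),
                se_y=float(r.se_y),
                wald_ratio=float(r.wald_ratio),
                ratio_se=float(r.ratio_se),
                flipped=bool(r.flipped),
                palindromic=bool(r.palindromic),
            )
            for r in df.itertuples(index=False)
        )
        return cls(
            exposure_name=exposure_name,
            outcome_name=outcome_name,
            target=target,
            instruments=instruments,
        )

    def write(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(
                f"# exposure={self.exposure_name}\toutcome={self.outcome_name}"
                f"\ttarget={self.target or 'NA'}\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g", lineterminator="\n")

    @classmethod
    def read(cls, path: str | Path) -> "InstrumentSet":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().lstrip("#").strip()
            meta = dict(item.split("=") for item in header.split("\t"))
            df = pd.read_csv(fh, sep="\t")
        target = meta.get("target")
        return cls.from_dataframe(
            df,
            exposure_name=meta.get("exposure", "exposure"),
            outcome_name=meta.get("outcome", "outcome"),
            target=None if target in (None, "NA") else target,
        )


# ---------------------------------------------------------------------------
# selection


def _clump(
    candidates: Sequence[SumstatRecord], ld: LDMatrix, r2_threshold: float
) -> list[str]:
    ordered = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    missing = [r.variant_id for r in ordered if r.variant_id not in ld]
    if missing:
        logger.info(
            "%d candidate id(s) absent from the LD matrix; treated as uncorrelated",
            len(missing),
        )
    kept: list[str] = []
    remaining = list(ordered)
    while remaining:
        best = remaining.pop(0)
        kept.append(best.variant_id)
        remaining = [
            r for r in remaining if ld.r2(best.variant_id, r.variant_id) <= r2_threshold
        ]
    return kept


def select_genomewide(
    exposure: Sequence[SumstatRecord],
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.1,
) -> list[str]:
    """Greedy p-value/LD clumping over all variants passing ``p_threshold``.

    Returns kept variant ids in selection order (best p first).  Raises
    :class:`EmptySelectionError` when no candidate passes the threshold.
    """
    if ld is None:
        ld = LDMatrix(variant_ids=(), r=np.zeros((0, 0)))
    candidates = [r for r in exposure if r.pvalue <= p_threshold]
    if not candidates:
        raise EmptySelectionError(
            f"no variant passes p <= {p_threshold:g} (n input = {len(exposure)})"
        )
    return _clump(candidates, ld, r2_threshold)


def select_cis(
    exposure: Sequence[SumstatRecord],
    region: GeneRegion,
    flank: int = 100_000,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.1,
) -> list[str]:
    """Clump within ``region`` +/- ``flank`` bp (cis drug-target selection).

    Summary-statistic positions are 1-based; the region is 0-based
    half-open, so a variant at 1-based position ``pos`` is in the window iff
    ``region.start - flank <= pos - 1 < region.end + flank``.
    """
    in_window = [
        r
        for r in exposure
        if r.chrom == region.chrom
        and region.start - flank <= r.pos - 1 < region.end + flank
    ]
    if not in_window:
        raise EmptySelectionError(
            f"no variant falls in {region.name} ({region.chrom}:"
            f"{region.start}-{region.end} +/-{flank})"
        )
    return select_genomewide(in_window, p_threshold, ld, r2_threshold)


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    selected_ids: Sequence[str],
    palindrome_policy: PalindromePolicy = "infer",
    eaf_window: float = 0.08,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    target: str | None = None,
) -> InstrumentSet:
    """Align outcome effects onto each exposure record's effect allele.

    Allele swaps negate the outcome beta (``flipped``); strand complements
    are equivalent to the direct orientation.  Palindromic variants are
    dropped under policy ``drop``; under ``infer`` they are kept only when
    both effect-allele frequencies are outside ``0.5 +/- eaf_window``, and
    are frequency-aligned.  Variants with incompatible alleles or
    ``beta_x == 0`` are dropped with a log message.
    """
    exp_by_id = {}
    for r in exposure:
        exp_by_id.setdefault(r.variant_id, r)
    out_by_id = {}
    for r in outcome:
        out_by_id.setdefault(r.variant_id, r)

    missing = [
        v for v in selected_ids if v not in exp_by_id or v not in out_by_id
    ]
    if missing:
        raise HarmonizationError(
            f"selected id(s) missing from exposure or outcome: {missing}"
        )

    kept: list[HarmonizedInstrument] = []
    n_dropped = 0
    for vid in selected_ids:
        ex = exp_by_id[vid]
        ou = out_by_id[vid]
        ea, oa = ex.effect_allele, ex.other_allele
        pair = (ou.effect_allele, ou.other_allele)
        comp_pair = (COMPLEMENT.get(ou.effect_allele), COMPLEMENT.get(ou.other_allele))
        if pair == (ea, oa) or comp_pair == (ea, oa):
            beta_y, eaf_y, flipped = ou.beta, ou.eaf, False
        elif pair == (oa, ea) or comp_pair == (oa, ea):
            beta_y = -ou.beta
            eaf_y = None if ou.eaf is None else 1.0 - ou.eaf
            flipped = True
        else:
            logger.info("dropping %s: incompatible alleles %s vs %s", vid, (ea, oa), pair)
            n_dropped += 1
            continue

        palindromic = _is_palindromic(ea, oa)
        if palindromic:
            if palindrome_policy == "drop":
                n_dropped += 1
                continue
            # policy `infer`: need both frequencies informatively off 0.5
            if ex.eaf is None or eaf_y is None:
                n_dropped += 1
                continue
            if (
                abs(ex.eaf - 0.5) <= eaf_window
                or abs(eaf_y - 0.5) <= eaf_window
            ):
                logger.info("dropping palindromic %s: EAF too close to 0.5", vid)
                n_dropped += 1
                continue
            if (ex.eaf - 0.5) * (eaf_y - 0.5) < 0:
                # frequencies disagree: the outcome is on the other strand
                beta_y = -beta_y
                flipped = not flipped

        if ex.beta == 0:
            logger.info("dropping %s: exposure beta is 0 (undefined Wald ratio)", vid)
            n_dropped += 1
            continue

        kept.append(
            HarmonizedInstrument(
                variant_id=vid,
                beta_x=ex.beta,
                se_x=ex.se,
                beta_y=beta_y,
                se_y=ou.se,
                wald_ratio=beta_y / ex.beta,
                ratio_se=ou.se / abs(ex.beta),
                flipped=flipped,
                palindromic=palindromic,
            )
        )
    if n_dropped:
        logger.warning("harmonize: dropped %d of %d selected variant(s)", n_dropped, len(selected_ids))
    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        target=target,
        instruments=tuple(kept),
    )


def mean_f_statistic(instrument_set: InstrumentSet) -> tuple[float, np.ndarray]:
    """Per-variant F statistics beta_x^2/se_x^2 and their arithmetic mean.

    Mean F > 10 is the conventional adequate-strength threshold.
    """
    if len(instrument_set) == 0:
        raise InsufficientInstrumentsError("mean_f_statistic: empty instrument set")
    f = instrument_set.beta_x**2 / instrument_set.se_x**2
    return float(f.mean()), f
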