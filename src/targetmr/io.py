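"""Readers and writers for GWAS summary statistics and companion files.

Summary statistics are tab-delimited with a fixed canonical header
(GWAS-SSF-inspired)::

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pvalue  n

Positions are 1-based in summary statistics (the GWAS convention) and
0-based half-open in BED gene regions; cis selection performs the
conversion.  Variant matching across traits is by ``variant_id``.  All
files are UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    EmptyInputError,
    ParseError,
    SchemaError,
)

logger = logging.getLogger("targetmr")

SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")

#: Watson-Crick complement, used for strand resolution during harmonization.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` (trait
    units for continuous traits, log-odds for binary ones); ``eaf`` is the
    effect-allele frequency and may be ``None`` when the source file does
    not report it.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def is_valid(self) -> bool:
        """Check the record invariants (distinct ACGT alleles, se>0, ...)."""
        if self.effect_allele not in _VALID_ALLELES:
            return False
        if self.other_allele not in _VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (math.isfinite(self.beta) and math.isfinite(self.se)):
            return False
        if self.se <= 0:
            return False
        if not (0 < self.pvalue <= 1):
            return False
        if self.eaf is not None and not (0 < self.eaf < 1):
            return False
        if self.pos < 1:
            return False
        if self.n <= 0 or not math.isfinite(self.n):
            return False
        return True


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval (BED convention: 0-based start, exclusive end)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataValidationError(
                f"GeneRegion {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass(frozen=True)
class LDMatrix:
    """A square matrix of pairwise correlations (r, not r^2) between variants."""

    variant_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        k = len(self.variant_ids)
        if r.ndim != 2 or r.shape != (k, k):
            raise DataValidationError(
                f"LDMatrix: matrix shape {r.shape} does not match {k} variant ids"
            )
        if len(set(self.variant_ids)) != k:
            raise DataValidationError("LDMatrix: variant ids must be unique")
        if k and np.max(np.abs(r - r.T)) > 1e-8:
            raise DataValidationError("LDMatrix: matrix is not symmetric (tolerance 1e-8)")
        if k and np.max(np.abs(np.diag(r) - 1.0)) > 1e-8:
            raise DataValidationError("LDMatrix: diagonal entries must equal 1")
        if k and np.max(np.abs(r)) > 1 + 1e-8:
            raise DataValidationError("LDMatrix: |r| must be <= 1")
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.variant_ids)})

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants; 0.0 if either is absent."""
        idx: dict = self._index  # type: ignore[attr-defined]
        ia = idx.get(a)
        ib = idx.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# summary statistics


def _float_or_none(x) -> float | None:
    if x is None:
        return None
    f = float(x)
    return None if math.isnan(f) else f


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SumstatRecord]:
    """Read summary statistics, dropping (and counting) invalid rows.

    Parameters
    ----------
    path
        Tab-delimited file with the canonical header, or any header that
        ``column_map`` translates (mapping canonical name -> file column).
    column_map
        Optional aliases for non-canonical headers.

    Returns
    -------
    list of SumstatRecord in file order.  Rows violating the record
    invariants are dropped; the count is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; expected {SUMSTAT_COLUMNS}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    records: list[SumstatRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        try:
            rec = SumstatRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=_float_or_none(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=float(row.n),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if rec.is_valid():
            records.append(rec)
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("%s: dropped %d row(s) failing record invariants", path, n_dropped)
    return records


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    return format(float(x), ".17g")


def write_sumstats(records: Iterable[SumstatRecord], path: str | Path) -> None:
    """Write records tab-delimited with the canonical header.

    Floats are written with 17 significant digits so a write-read round
    trip is the identity to better than 1e-12.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SUMSTAT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pvalue),
                        _fmt(r.n),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene regions (BED)


def read_regions(path: str | Path) -> list[GeneRegion]:
    """Read BED-3+1 gene regions (chrom, start, end, name), order preserved."""
    path = Path(path)
    regions: list[GeneRegion] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 BED fields, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                regions.append(GeneRegion(name=name, chrom=chrom, start=start, end=end))
            except DataValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[GeneRegion], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in regions:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")


# ---------------------------------------------------------------------------
# LD matrix and exclusion lists


def read_ld(path: str | Path) -> LDMatrix:
    """Read a plain-text LD matrix: header of variant ids, then square rows."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.strip():
            raise EmptyInputError(f"{path}: empty LD file")
        ids = tuple(header.split("\t"))
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            if len(vals) != len(ids):
                raise SchemaError(
                    f"{path}:{lineno}: row has {len(vals)} entries, expected {len(ids)}"
                )
            rows.append([float(v) for v in vals])
    if len(rows) != len(ids):
        raise SchemaError(f"{path}: {len(rows)} rows for {len(ids)} header ids (not square)")
    return LDMatrix(variant_ids=ids, r=np.array(rows, dtype=float))


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ld.variant_ids) + "\n")
        for row in ld.r:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line variant exclusion list; ``#`` starts a comment."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out
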