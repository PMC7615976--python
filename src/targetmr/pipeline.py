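"""Study orchestration: targets x outcomes, unit scaling, FDR, reporting.

A study runs one exposure against a panel of outcomes, proxied genome-wide
and/or through cis gene regions (drug targets).  For every target x
outcome pair the pipeline selects and harmonizes instruments, computes
instrument strength and diagnostics, runs the configured estimators,
rescales effects to a per-unit (e.g. per 1 mg/dL) change of the exposure,
converts binary-outcome effects to odds ratios, and applies
Benjamini-Hochberg FDR across the main (IVW) p-values of the run.

Effects are reported per 1 unit *decrease* of the exposure by default
(``direction="decrease"``), matching how protective lipid-lowering effects
are conventionally displayed; ``sd_to_unit`` converts SD-scaled GWAS
effects to the reporting unit (default 38.67, approximately 1 SD of LDL
cholesterol in mg/dL; set 1.0 to disable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator
from statsmodels.stats.multitest import multipletests

from . import diagnostics as diag
from . import instruments as instr
from .estimators import MREstimate
from .exceptions import DataValidationError, EmptySelectionError, HarmonizationError
from .io import (
    read_exclusion_list,
    read_ld,
    read_regions,
    read_sumstats,
)

logger = logging.getLogger("targetmr")

_NA = "NA"

RESULT_COLUMNS = [
    "target",
    "outcome",
    "method",
    "n_variants",
    "beta_per_unit",
    "se",
    "ci_low",
    "ci_high",
    "or_value",
    "or_low",
    "or_high",
    "pvalue",
    "qvalue",
    "significant",
]

DIAGNOSTIC_COLUMNS = [
    "target",
    "outcome",
    "n_variants",
    "mean_f",
    "q_stat",
    "q_df",
    "q_pvalue",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_p",
]


# ---------------------------------------------------------------------------
# transformations


def rescale_per_unit(
    estimate: MREstimate,
    sd_to_unit: float = 38.67,
    direction: Literal["decrease", "increase"] = "decrease",
) -> MREstimate:
    """Rescale an estimate to a 1-unit change of the exposure.

    ``beta' = s * beta / sd_to_unit`` with ``s = -1`` for ``decrease``
    (effects per unit *lowering*) and ``+1`` for ``increase``.  SEs are
    divided by the factor, CI bounds transformed consistently (they swap
    under the sign flip), and the p-value is unchanged.
    """
    if sd_to_unit <= 0:
        raise DataValidationError(f"sd_to_unit must be > 0, got {sd_to_unit}")
    s = -1.0 if direction == "decrease" else 1.0
    f = s / sd_to_unit

    def tx(lo: float, hi: float) -> tuple[float, float]:
        a, b = lo * f, hi * f
        return (a, b) if a <= b else (b, a)

    lo, hi = tx(estimate.ci_low, estimate.ci_high)
    intervals = None
    if estimate.ci_intervals is not None:
        intervals = tuple(sorted(tx(a, b) for a, b in estimate.ci_intervals))
    return replace(
        estimate,
        beta=estimate.beta * f,
        se=None if estimate.se is None else estimate.se / sd_to_unit,
        ci_low=lo,
        ci_high=hi,
        ci_intervals=intervals,
    )


def to_odds_ratio(estimate: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, OR ci_low, OR ci_high)."""
    return (
        float(np.exp(estimate.beta)),
        float(np.exp(estimate.ci_low)),
        float(np.exp(estimate.ci_high)),
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataValidationError("pvalues must all lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# configuration


class SelectionParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    flank: int = 100_000


class OutcomeSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    path: str
    binary: bool = False


class TargetSpec(BaseModel):
    """A drug-target gene; selection params default to the study-wide ones."""

    model_config = ConfigDict(frozen=True)

    name: str
    p_threshold: float | None = None
    r2_threshold: float | None = None
    flank: int | None = None


class StudyConfig(BaseModel):
    """Full configuration of one MR study run."""

    model_config = ConfigDict(frozen=True)

    exposure_label: str
    exposure_path: str
    outcomes: tuple[OutcomeSpec, ...]
    ld_path: str | None = None
    regions_path: str | None = None
    targets: tuple[TargetSpec, ...] = ()
    genomewide: bool = False
    selection: SelectionParams = SelectionParams()
    methods: tuple[str, ...] = ("ivw", "egger", "wm", "conmix")
    sd_to_unit: float = 38.67
    direction: Literal["decrease", "increase"] = "decrease"
    fdr_alpha: float = 0.05
    n_boot: int = 1000
    psi: float | Literal["auto"] = "auto"
    palindrome_policy: Literal["drop", "infer"] = "infer"
    eaf_window: float = 0.08
    seed: int = 0
    exclusions_path: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if self.sd_to_unit <= 0:
            raise DataValidationError("sd_to_unit must be > 0")
        if not self.outcomes:
            raise DataValidationError("outcomes: at least one outcome is required")
        labels = [o.label for o in self.outcomes]
        if len(set(labels)) != len(labels):
            raise DataValidationError("outcomes: labels must be unique")
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise DataValidationError("targets: names must be unique")
        if not self.targets and not self.genomewide:
            raise DataValidationError(
                "at least one target or genomewide=true is required"
            )
        if self.targets and not self.regions_path:
            raise DataValidationError("regions_path is required when targets are given")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# study runner


@dataclass
class StudyResult:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    sensitivity: pd.DataFrame | None
    log: list[str]
    instrument_sets: dict[tuple[str, str], instr.InstrumentSet]


_METHOD_LABEL = {
    "ivw": "IVW-random",
    "egger": "Egger-slope",
    "wm": "WeightedMedian",
    "conmix": "ConMix",
}


def _na_rows(target: str, outcome: str, methods: Sequence[str], reason: str):
    rows = []
    for m in methods:
        rows.append(
            {
                "target": target,
                "outcome": outcome,
                "method": _METHOD_LABEL.get(m, m),
                "n_variants": 0,
                "beta_per_unit": None,
                "se": None,
                "ci_low": None,
                "ci_high": None,
                "or_value": None,
                "or_low": None,
                "or_high": None,
                "pvalue": None,
                "qvalue": None,
                "significant": None,
                "_is_main": m == "ivw",
                "_reason": reason,
            }
        )
    return rows


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full study and (optionally) write its output files.

    Writes ``results.tsv``, ``diagnostics.tsv``, ``run.log``, a resolved
    copy of the configuration, and ``sensitivity.tsv`` when an exclusion
    list is configured.  Deterministic given the configuration, including
    its seed: running twice yields byte-identical files.
    """
    log: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    exposure = read_sumstats(config.exposure_path)
    note(f"exposure {config.exposure_label}: {len(exposure)} variants read")
    ld = read_ld(config.ld_path) if config.ld_path else None
    regions = {r.name: r for r in read_regions(config.regions_path)} if config.regions_path else {}
    for t in config.targets:
        if t.name not in regions:
            raise DataValidationError(f"target {t.name!r} not found in {config.regions_path}")
    exclusions = (
        read_exclusion_list(config.exclusions_path) if config.exclusions_path else None
    )

    # unit analyses: genome-wide first, then targets in config order
    units: list[tuple[str, TargetSpec | None]] = []
    if config.genomewide:
        units.append(("genomewide", None))
    units.extend((t.name, t) for t in config.targets)

    ss = np.random.SeedSequence(config.seed)
    pair_seeds = iter(ss.spawn(len(units) * len(config.outcomes) * 2))

    rows: list[dict] = []
    diag_rows: list[dict] = []
    sens_rows: list[dict] = []
    isets: dict[tuple[str, str], instr.InstrumentSet] = {}

    for target_name, tspec in units:
        for outcome_spec in config.outcomes:
            pair_seed = int(next(pair_seeds).generate_state(1)[0] % 2**31)
            sens_seed = int(next(pair_seeds).generate_state(1)[0] % 2**31)
            pair = (target_name, outcome_spec.label)
            try:
                outcome = read_sumstats(outcome_spec.path)
                if tspec is None:
                    selected = instr.select_genomewide(
                        exposure,
                        p_threshold=config.selection.p_threshold,
                        ld=ld,
                        r2_threshold=config.selection.r2_threshold,
                    )
                else:
                    sel = config.selection
                    selected = instr.select_cis(
                        exposure,
                        regions[tspec.name],
                        flank=tspec.flank if tspec.flank is not None else sel.flank,
                        p_threshold=(
                            tspec.p_threshold
                            if tspec.p_threshold is not None
                            else sel.p_threshold
                        ),
                        ld=ld,
                        r2_threshold=(
                            tspec.r2_threshold
                            if tspec.r2_threshold is not None
                            else sel.r2_threshold
                        ),
                    )
                iset = instr.harmonize(
                    exposure,
                    outcome,
                    selected,
                    palindrome_policy=config.palindrome_policy,
                    eaf_window=config.eaf_window,
                    exposure_name=config.exposure_label,
                    outcome_name=outcome_spec.label,
                    target=None if tspec is None else tspec.name,
                )
            except (EmptySelectionError, HarmonizationError) as exc:
                note(f"{pair}: no usable instruments ({exc}); emitting NA row")
                rows.extend(_na_rows(target_name, outcome_spec.label, config.methods, str(exc)))
                continue
            if len(iset) == 0:
                note(f"{pair}: all selected variants dropped in harmonization; NA row")
                rows.extend(
                    _na_rows(target_name, outcome_spec.label, config.methods, "harmonization dropped all")
                )
                continue
            isets[pair] = iset
            note(f"{pair}: {len(iset)} harmonized instrument(s)")

            estimates = diag.run_estimators(
                iset,
                config.methods,
                n_boot=config.n_boot,
                psi=config.psi,
                seed=pair_seed,
            )
            if len(iset) >= 2:
                report = diag.build_report(iset)
                diag_rows.append(
                    {
                        "target": target_name,
                        "outcome": outcome_spec.label,
                        "n_variants": report.n_variants,
                        "mean_f": report.mean_f,
                        "q_stat": report.q_stat,
                        "q_df": report.q_df,
                        "q_pvalue": report.q_pvalue,
                        "egger_intercept": report.egger_intercept,
                        "egger_intercept_se": report.egger_intercept_se,
                        "egger_intercept_p": report.egger_intercept_p,
                    }
                )
            for m in config.methods:
                e = estimates.get(m)
                if e is None:
                    rows.extend(_na_rows(target_name, outcome_spec.label, [m], "method minimum"))
                    continue
                scaled = rescale_per_unit(e, config.sd_to_unit, config.direction)
                or_v = or_lo = or_hi = None
                if outcome_spec.binary:
                    or_v, or_lo, or_hi = to_odds_ratio(scaled)
                rows.append(
                    {
                        "target": target_name,
                        "outcome": outcome_spec.label,
                        "method": scaled.method,
                        "n_variants": scaled.n_variants,
                        "beta_per_unit": scaled.beta,
                        "se": scaled.se,
                        "ci_low": scaled.ci_low,
                        "ci_high": scaled.ci_high,
                        "or_value": or_v,
                        "or_low": or_lo,
                        "or_high": or_hi,
                        "pvalue": scaled.pvalue,
                        "qvalue": None,
                        "significant": None,
                        "_is_main": m == "ivw",
                        "_reason": "",
                    }
                )

            if exclusions is not None:
                sens = diag.exclude_and_refit(
                    iset,
                    exclusions,
                    methods=config.methods,
                    n_boot=config.n_boot,
                    psi=config.psi,
                    seed=sens_seed,
                )
                for m in config.methods:
                    b, a = sens.before.get(m), sens.after.get(m)
                    sens_rows.append(
                        {
                            "target": target_name,
                            "outcome": outcome_spec.label,
                            "method": _METHOD_LABEL.get(m, m),
                            "beta_before": None if b is None else b.beta,
                            "beta_after": None if a is None else a.beta,
                            "abs_change": None
                            if (a is None or b is None)
                            else abs(a.beta - b.beta),
                            "n_before": len(iset),
                            "n_after": len(sens.reduced_set),
                        }
                    )

    results = pd.DataFrame(rows)
    # FDR family: the main-analysis (IVW) p-values across all pairs in the run
    main = results["_is_main"] & results["pvalue"].notna()
    if main.any():
        q = bh_fdr(results.loc[main, "pvalue"].to_numpy())
        results.loc[main, "qvalue"] = q
        results.loc[main, "significant"] = q <= config.fdr_alpha
    note(f"FDR family: {int(main.sum())} IVW p-value(s); alpha = {config.fdr_alpha}")
    for _, r in results[results["_reason"].astype(bool)].iterrows():
        note(f"({r['target']}, {r['outcome']}, {r['method']}): {r['_reason']}")
    results = results[RESULT_COLUMNS]
    diagnostics = pd.DataFrame(diag_rows, columns=DIAGNOSTIC_COLUMNS)
    sensitivity = pd.DataFrame(sens_rows) if exclusions is not None else None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_table(results, out_dir / "results.tsv")
        _write_table(diagnostics, out_dir / "diagnostics.tsv")
        if sensitivity is not None:
            _write_table(sensitivity, out_dir / "sensitivity.tsv")
        config.to_yaml(out_dir / "config.yaml")
        with open(out_dir / "run.log", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(log) + "\n")
    return StudyResult(
        results=results,
        diagnostics=diagnostics,
        sensitivity=sensitivity,
        log=log,
        instrument_sets=isets,
    )


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype == object or df[col].dtype.kind == "f":
            df[col] = df[col].map(
                lambda v: _NA
                if v is None or (isinstance(v, float) and np.isnan(v))
                else (format(v, ".10g") if isinstance(v, (float, np.floating)) else v)
            )
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, lineterminator="\n")
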