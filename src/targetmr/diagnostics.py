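"""Heterogeneity and pleiotropy diagnostics, and exclusion sensitivity.

Cochran's Q is computed on the beta scale: residuals of the outcome
effects from the through-origin fixed-effect IVW fit, weighted by
1/se_y^2.  Under homogeneity it is chi-square with J-1 degrees of freedom.
The Egger intercept test re-exports the intercept of the MR-Egger fit.
``exclude_and_refit`` supports the sensitivity workflow in which variants
flagged as potentially pleiotropic (e.g. by a phenome-wide lookup) are
removed and all estimators rerun.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Iterable, Sequence
import logging

import numpy as np
from scipy import stats

from . import estimators as est
from .exceptions import InsufficientInstrumentsError
from .instruments import InstrumentSet, mean_f_statistic

logger = logging.getLogger("targetmr")


@dataclass(frozen=True)
class QResult:
    q_stat: float
    q_df: int
    q_pvalue: float
    contributions: np.ndarray  # per-variant terms; sum equals q_stat


@dataclass(frozen=True)
class DiagnosticsReport:
    """Heterogeneity, pleiotropy and strength diagnostics for one set."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    mean_f: float
    n_variants: int


def cochran_q(instrument_set: InstrumentSet) -> QResult:
    """Cochran's Q heterogeneity statistic about the fixed-effect IVW fit."""
    j = len(instrument_set)
    if j < 2:
        raise InsufficientInstrumentsError(f"cochran_q: needs >= 2 instruments, got {j}")
    bx, by, sy = instrument_set.beta_x, instrument_set.beta_y, instrument_set.se_y
    theta_hat, _, _ = est._ivw_beta_and_q(bx, by, sy)
    contributions = (by - theta_hat * bx) ** 2 / sy**2
    q = float(contributions.sum())
    df = j - 1
    p = float(stats.chi2.sf(q, df))
    return QResult(q_stat=q, q_df=df, q_pvalue=max(p, 5e-324), contributions=contributions)


def egger_intercept_test(instrument_set: InstrumentSet) -> tuple[float, float, float]:
    """(estimate, SE, p) of the MR-Egger intercept — directional pleiotropy."""
    _, intercept = est.egger(instrument_set)
    assert intercept.se is not None and intercept.pvalue is not None
    return intercept.beta, intercept.se, intercept.pvalue


def build_report(instrument_set: InstrumentSet) -> DiagnosticsReport:
    """Full diagnostics: Q, Egger intercept (when J >= 3), mean F."""
    qres = cochran_q(instrument_set)
    mean_f, _ = mean_f_statistic(instrument_set)
    if len(instrument_set) >= 3:
        eg_b, eg_se, eg_p = egger_intercept_test(instrument_set)
    else:
        eg_b = eg_se = eg_p = None
    return DiagnosticsReport(
        q_stat=qres.q_stat,
        q_df=qres.q_df,
        q_pvalue=qres.q_pvalue,
        egger_intercept=eg_b,
        egger_intercept_se=eg_se,
        egger_intercept_p=eg_p,
        mean_f=mean_f,
        n_variants=len(instrument_set),
    )


_METHOD_RUNNERS: dict[str, Callable[..., Any]] = {
    "ivw": lambda s, **kw: est.ivw(s, model=kw.get("ivw_model", "random")),
    "egger": lambda s, **kw: est.egger(s)[0],
    "wm": lambda s, **kw: est.weighted_median(
        s, n_boot=kw.get("n_boot", 1000), seed=kw.get("seed")
    ),
    "conmix": lambda s, **kw: est.conmix(s, psi=kw.get("psi", "auto")),
}


def run_estimators(
    instrument_set: InstrumentSet, methods: Sequence[str], **kwargs
) -> dict[str, est.MREstimate | None]:
    """Run the named estimators; a method below its instrument minimum maps to None."""
    out: dict[str, est.MREstimate | None] = {}
    for m in methods:
        runner = _METHOD_RUNNERS.get(m)
        if runner is None:
            raise ValueError(f"unknown method {m!r}; choose from {sorted(_METHOD_RUNNERS)}")
        try:
            out[m] = runner(instrument_set, **kwargs)
        except InsufficientInstrumentsError as exc:
            logger.warning("%s unavailable: %s", m, exc)
            out[m] = None
    return out


@dataclass(frozen=True)
class ExclusionSensitivity:
    """Paired estimates before and after excluding flagged variants."""

    reduced_set: InstrumentSet
    before: dict[str, est.MREstimate | None]
    after: dict[str, est.MREstimate | None]
    excluded_ids: tuple[str, ...]

    @property
    def abs_change(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for m, b in self.before.items():
            a = self.after.get(m)
            out[m] = None if (a is None or b is None) else abs(a.beta - b.beta)
        return out


def exclude_and_refit(
    instrument_set: InstrumentSet,
    exclusion_ids: Iterable[str],
    methods: Sequence[str] = ("ivw",),
    **kwargs,
) -> ExclusionSensitivity:
    """Remove flagged variants and rerun the requested estimators.

    Ids not present in the set are ignored with a warning.  A method whose
    instrument minimum is no longer met after exclusion is reported as
    ``None`` rather than raising.
    """
    exclusion = set(exclusion_ids)
    present = set(instrument_set.variant_ids)
    absent = exclusion - present
    if absent:
        logger.warning("exclusion ids not in the instrument set (ignored): %s", sorted(absent))
    before = run_estimators(instrument_set, methods, **kwargs)
    reduced = instrument_set.drop(exclusion)
    after = run_estimators(reduced, methods, **kwargs)
    return ExclusionSensitivity(
        reduced_set=reduced,
        before=before,
        after=after,
        excluded_ids=tuple(sorted(exclusion & present)),
    )
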