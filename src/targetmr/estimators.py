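"""Causal-effect estimators for two-sample Mendelian randomization.

Four estimators operate on a harmonized :class:`~targetmr.instruments.InstrumentSet`:

``ivw``
    Inverse-variance weighted estimate — the through-origin weighted
    regression of outcome on exposure effects with weights 1/se_y^2.  The
    multiplicative random-effects model inflates the standard error by
    sqrt(Q/(J-1)) when Cochran's Q exceeds its degrees of freedom (the
    factor never deflates below 1).
``egger``
    Weighted regression with an intercept after orienting all exposure
    effects positive; a nonzero intercept indicates directional pleiotropy
    (valid under the InSIDE assumption).
``weighted_median``
    The 50% weighted quantile of the per-variant Wald ratios; consistent
    when instruments carrying at least half the weight are valid.  Its
    standard error comes from a parametric bootstrap.
``conmix``
    Contamination-mixture profile likelihood: at each candidate causal
    value each instrument is classified valid (ratio ~ Normal(theta, se^2))
    or invalid (ratio ~ Normal(0, se^2 + psi^2)); the estimate maximises
    the profile log-likelihood and the 95% confidence region, obtained by
    likelihood-ratio inversion, may be a union of disjoint intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .instruments import HarmonizedInstrument, InstrumentSet

#: 95% normal critical value, used for all single-interval CIs
Z95 = 1.96

#: chi-square(1) 95% quantile, used for likelihood-ratio confidence regions
CHI2_1_95 = 3.841


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the beta (per-SD-of-exposure) scale.

    ``se`` and ``pvalue`` are ``None`` for the contamination mixture, whose
    inference is by confidence region; ``ci_intervals`` then carries the
    (possibly disjoint) region and ``ci_low``/``ci_high`` its envelope.
    """

    method: str
    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    pvalue: float | None
    n_variants: int
    ci_intervals: tuple[tuple[float, float], ...] | None = None
    extras: dict[str, Any] = field(default_factory=dict)


def _normal_p(beta: float, se: float) -> float:
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return max(p, 5e-324)  # keep p in (0, 1] even when sf underflows


def _wald_estimate(method: str, beta: float, se: float, n: int, **extras) -> MREstimate:
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta, se),
        n_variants=n,
        extras=extras,
    )


def ratio_single(instrument: HarmonizedInstrument) -> MREstimate:
    """Wald-ratio estimate from a single instrument (first-order SE)."""
    return _wald_estimate(
        "WaldRatio", instrument.wald_ratio, instrument.ratio_se, 1
    )


def _ivw_beta_and_q(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(
    instrument_set: InstrumentSet,
    model: Literal["fixed", "random"] = "random",
) -> MREstimate:
    """Inverse-variance weighted causal estimate.

    With a single instrument the estimate degenerates to that instrument's
    Wald ratio (labelled ``WaldRatio``).  Under ``model="random"`` the
    fixed-effect SE is multiplied by ``max(1, sqrt(Q/(J-1)))`` — the
    multiplicative overdispersion model.
    """
    j = len(instrument_set)
    if j == 0:
        raise InsufficientInstrumentsError("ivw: empty instrument set")
    if j == 1:
        return ratio_single(instrument_set.instruments[0])
    bx, by, sy = instrument_set.beta_x, instrument_set.beta_y, instrument_set.se_y
    beta, se_fixed, q = _ivw_beta_and_q(bx, by, sy)
    if model == "random":
        scale = max(1.0, np.sqrt(q / (j - 1)))
        se = se_fixed * scale
        method = "IVW-random"
    else:
        se = se_fixed
        method = "IVW-fixed"
    return _wald_estimate(method, beta, se, j, q=q)


def egger(instrument_set: InstrumentSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Instruments are oriented so every exposure effect is non-negative
    (negating both betas where needed — the Wald ratio is unchanged), then
    outcome effects are regressed on exposure effects with an intercept,
    weights 1/se_y^2.  Both coefficient SEs are inflated by
    ``max(1, sqrt(RSS_w/(J-2)))``.
    """
    j = len(instrument_set)
    if j < 3:
        raise InsufficientInstrumentsError(f"egger: needs >= 3 instruments, got {j}")
    bx = instrument_set.beta_x.copy()
    by = instrument_set.beta_y.copy()
    sy = instrument_set.se_y
    neg = bx < 0
    bx[neg] *= -1
    by[neg] *= -1
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    # statsmodels' bse already include the scale estimate RSS_w/(J-2);
    # clamp the inflation at 1 (no deflation below the fixed-effect SE)
    se_unit = np.sqrt(np.diag(np.linalg.inv(X.T @ (w[:, None] * X))))
    inflation = max(1.0, float(np.sqrt(fit.scale)))
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_intercept, se_slope = se_unit * inflation
    slope_est = _wald_estimate("Egger-slope", slope, float(se_slope), j)
    intercept_est = _wald_estimate("Egger-intercept", intercept, float(se_intercept), j)
    return slope_est, intercept_est


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights[order].sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    instrument_set: InstrumentSet,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Weights are proportional to the inverse squared first-order Wald-ratio
    SEs.  The bootstrap redraws each ratio from
    ``Normal(wald_ratio_j, ratio_se_j^2)``.
    """
    j = len(instrument_set)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median: needs >= 3 instruments, got {j}"
        )
    ratios = instrument_set.wald_ratios
    ses = instrument_set.ratio_ses
    weights = ses**-2
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    draws = ratios + rng.standard_normal((n_boot, j)) * ses
    for b in range(n_boot):
        boots[b] = _weighted_median(draws[b], weights)
    se = float(np.std(boots, ddof=1))
    return _wald_estimate("WeightedMedian", beta, se, j, n_boot=n_boot)


def conmix(
    instrument_set: InstrumentSet,
    psi: float | Literal["auto"] = "auto",
    grid_halfwidth_sd: float = 3.0,
    grid_points: int = 2001,
) -> MREstimate:
    """Contamination-mixture causal estimate via profile likelihood.

    ``psi`` is the SD of invalid instruments' direct effects on the ratio
    scale; ``"auto"`` sets it to 1.5 x SD of the Wald ratios (falling back
    to 1 with a warning when that SD is 0).  The estimate is the argmax of
    the profile log-likelihood over a uniform grid of ``grid_points``
    values spanning ``[min ratio - k, max ratio + k]`` with ``k =
    grid_halfwidth_sd x SD(ratios)``; ties go to the smallest grid value.
    No p-value or SE is reported; inference is by the (possibly disjoint)
    95% likelihood-ratio confidence region.
    """
    j = len(instrument_set)
    if j < 2:
        raise InsufficientInstrumentsError(f"conmix: needs >= 2 instruments, got {j}")
    ratios = instrument_set.wald_ratios
    ses = instrument_set.ratio_ses
    sd = float(np.std(ratios, ddof=1))
    if psi == "auto":
        if sd == 0.0:
            warnings.warn(
                "conmix: SD of Wald ratios is 0; falling back to psi = 1",
                stacklevel=2,
            )
            psi_val = 1.0
        else:
            psi_val = 1.5 * sd
    else:
        psi_val = float(psi)

    k = grid_halfwidth_sd * sd
    grid = np.linspace(ratios.min() - k, ratios.max() + k, grid_points)
    # log-density of each ratio under the valid model at every grid theta
    ll_valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=ses[None, :])
    ll_invalid = stats.norm.logpdf(ratios, loc=0.0, scale=np.sqrt(ses**2 + psi_val**2))
    ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)
    best = int(np.argmax(ll))  # first max = smallest theta on ties
    beta = float(grid[best])
    valid_at_opt = ll_valid[best] > ll_invalid
    in_region = 2.0 * (ll[best] - ll) <= CHI2_1_95
    intervals = _contiguous_intervals(grid, in_region)
    return MREstimate(
        method="ConMix",
        beta=beta,
        se=None,
        ci_low=float(intervals[0][0]),
        ci_high=float(intervals[-1][1]),
        pvalue=None,
        n_variants=j,
        ci_intervals=tuple(intervals),
        extras={
            "psi": psi_val,
            "valid_ids": tuple(
                np.asarray(instrument_set.variant_ids)[valid_at_opt]
            ),
            "n_valid": int(valid_at_opt.sum()),
        },
    )


def _contiguous_intervals(
    grid: np.ndarray, mask: np.ndarray
) -> list[tuple[float, float]]:
    """Maximal runs of True in ``mask`` as (grid_start, grid_end) pairs."""
    intervals: list[tuple[float, float]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return intervals
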