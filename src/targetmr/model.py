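"""Model/Results front end for two-sample Mendelian randomization.

:class:`MRModel` wraps a harmonized instrument set; :meth:`MRModel.fit`
runs the requested estimators together with heterogeneity and pleiotropy
diagnostics and returns an :class:`MRResults` carrying the estimates,
their uncertainties and a plain-text ``summary()`` table.

Example
-------
>>> from targetmr import MRModel, simulate
>>> exp, out, truth = simulate.simulate_two_sample(simulate.SimulationConfig(seed=1))
>>> from targetmr.instruments import harmonize
>>> iset = harmonize(exp, out, [r.variant_id for r in exp])
>>> res = MRModel(iset).fit(seed=1)
>>> round(res.estimates["ivw"].beta, 2)
0.3
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticsReport, build_report, run_estimators
from .estimators import MREstimate
from .instruments import InstrumentSet

DEFAULT_METHODS = ("ivw", "egger", "wm", "conmix")


class MRModel:
    """A two-sample MR model over one harmonized exposure-outcome pair."""

    def __init__(self, instrument_set: InstrumentSet):
        self.instrument_set = instrument_set

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        target: str | None = None,
    ) -> "MRModel":
        """Build from a DataFrame with the harmonized-instrument columns."""
        return cls(
            InstrumentSet.from_dataframe(
                df, exposure_name=exposure_name, outcome_name=outcome_name, target=target
            )
        )

    def fit(
        self,
        methods: Sequence[str] = DEFAULT_METHODS,
        ivw_model: str = "random",
        n_boot: int = 1000,
        psi: float | str = "auto",
        seed: int | None = None,
    ) -> "MRResults":
        estimates = run_estimators(
            self.instrument_set,
            methods,
            ivw_model=ivw_model,
            n_boot=n_boot,
            psi=psi,
            seed=seed,
        )
        diagnostics = (
            build_report(self.instrument_set) if len(self.instrument_set) >= 2 else None
        )
        return MRResults(model=self, estimates=estimates, diagnostics=diagnostics)


@dataclass
class MRResults:
    """Estimates and diagnostics from :meth:`MRModel.fit`."""

    model: MRModel
    estimates: dict[str, MREstimate | None]
    diagnostics: DiagnosticsReport | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, e in self.estimates.items():
            if e is None:
                continue
            rows.append(
                {
                    "method": e.method,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pvalue": e.pvalue,
                    "n_variants": e.n_variants,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.model.instrument_set
        lines = [
            "Two-sample Mendelian randomization results",
            "=" * 74,
            f"Exposure: {s.exposure_name}    Outcome: {s.outcome_name}"
            + (f"    Target: {s.target}" if s.target else ""),
            f"Instruments: {len(s)}",
            "-" * 74,
            f"{'method':<16}{'beta':>10}{'se':>10}{'ci_low':>10}{'ci_high':>10}{'p':>12}",
        ]
        for e in self.estimates.values():
            if e is None:
                continue
            se = f"{e.se:.4f}" if e.se is not None else "--"
            p = f"{e.pvalue:.3g}" if e.pvalue is not None else "--"
            lines.append(
                f"{e.method:<16}{e.beta:>10.4f}{se:>10}{e.ci_low:>10.4f}"
                f"{e.ci_high:>10.4f}{p:>12}"
            )
        if self.diagnostics is not None:
            d = self.diagnostics
            lines.append("-" * 74)
            lines.append(
                f"Cochran's Q = {d.q_stat:.3f} (df {d.q_df}, p = {d.q_pvalue:.3g})"
                f"    mean F = {d.mean_f:.1f}"
            )
            if d.egger_intercept is not None:
                lines.append(
                    f"Egger intercept = {d.egger_intercept:.5f}"
                    f" (se {d.egger_intercept_se:.5f}, p = {d.egger_intercept_p:.3g})"
                )
        lines.append("=" * 74)
        return "\n".join(lines)

    def plot_scatter(self, ax=None):
        """Scatter of outcome vs exposure effects with the fitted IVW slope."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.instrument_set
        ax.errorbar(
            s.beta_x, s.beta_y, xerr=s.se_x, yerr=s.se_y, fmt="o", ms=4, alpha=0.7
        )
        ivw = self.estimates.get("ivw")
        if ivw is not None:
            xs = np.array([0.0, float(np.max(np.abs(s.beta_x))) * 1.05])
            ax.plot(xs, ivw.beta * xs, label=f"{ivw.method} (beta={ivw.beta:.3f})")
            ax.legend()
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel(f"effect on {s.exposure_name}")
        ax.set_ylabel(f"effect on {s.outcome_name}")
        return ax
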