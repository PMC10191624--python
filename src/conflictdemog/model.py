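"""Model/Results interface over the full male-harm analysis.

:class:`MaleHarm` wraps a cohort (from a file or a simulation) and its
``fit`` runs the whole pipeline: per-female fitness components, relative
harm H with bootstrap CIs per temperature, lifespan decreases, life tables
and rate-sensitive fitness across an r grid, and (optionally) the Box-Cox /
type-III-F / BH model scaffold for each response.  The returned
:class:`MaleHarmResults` carries the tables and renders a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fitness as _fitness
from . import ratesens as _ratesens
from . import stats as _stats
from .records import CohortDataset, read_cohort

__all__ = ["MaleHarm", "MaleHarmResults"]

DEFAULT_RESPONSES = ("lrs", "early", "repro_aging", "lifespan")


class MaleHarm:
    """Male-harm demographic analysis of one monogamy-vs-polyandry cohort.

    Parameters
    ----------
    cohort
        A validated :class:`~conflictdemog.records.CohortDataset` with both
        mating systems at each temperature.
    """

    def __init__(self, cohort: CohortDataset):
        self.cohort = cohort

    @classmethod
    def from_file(cls, path, **read_kwargs) -> "MaleHarm":
        return cls(read_cohort(path, **read_kwargs))

    def fit(
        self,
        n_boot: int = 2000,
        seed: Optional[int] = None,
        r_grid: Sequence[float] = _ratesens.DEFAULT_R_GRID,
        responses: Sequence[str] = DEFAULT_RESPONSES,
        run_models: bool = True,
    ) -> "MaleHarmResults":
        """Estimate every stage of the analysis.

        ``seed`` drives the harm bootstrap; the linear-model scaffold is run
        for each entry of ``responses`` on Box-Cox transformed values (the
        collinearity refit without the main mating-system effect, as the
        interaction is the quantity of interest).
        """
        cohort = self.cohort
        comp = _fitness.components_table(cohort)
        harm = _fitness.harm_by_temperature(cohort, n_boot=n_boot, seed=seed)
        lifespan = _fitness.lifespan_decrease(cohort)
        ratesens = _ratesens.rate_sensitive_table(cohort, r_grid)
        omega_ind = _ratesens.omega_individual_table(cohort, r_grid)
        summary = _fitness.group_summary(cohort)

        models: list[_stats.ModelResult] = []
        followups: list[_stats.ModelResult] = []
        if run_models:
            for resp in responses:
                vals = comp[resp].dropna().astype(float)
                bc = _stats.boxcox_fit(vals)
                tdf = comp.dropna(subset=[resp]).copy()
                tdf[f"{resp}_bc"] = _stats.boxcox_transform(tdf[resp].astype(float), bc)
                models.append(
                    _stats.fit_interaction_model(
                        tdf, f"{resp}_bc", include_main_system=False
                    )
                )
                followups.extend(_stats.per_temperature_models(tdf, f"{resp}_bc"))
            _stats.apply_bh(models)
            _stats.apply_bh(followups)
        return MaleHarmResults(
            cohort=cohort,
            components=comp,
            harm=harm,
            lifespan=lifespan,
            rate_sensitive=ratesens,
            omega_ind=omega_ind,
            group_summary=summary,
            interaction_models=models,
            followup_models=followups,
        )


@dataclass
class MaleHarmResults:
    """Fitted tables and estimates from :meth:`MaleHarm.fit`."""

    cohort: CohortDataset
    components: pd.DataFrame
    harm: list[_fitness.HarmEstimate]
    lifespan: pd.DataFrame
    rate_sensitive: pd.DataFrame
    omega_ind: pd.DataFrame
    group_summary: pd.DataFrame
    interaction_models: list[_stats.ModelResult] = field(default_factory=list)
    followup_models: list[_stats.ModelResult] = field(default_factory=list)

    @property
    def harm_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "temperature": h.temperature,
                    "W_mono": h.W_mono,
                    "W_poly": h.W_poly,
                    "H": h.H,
                    "ci_low": h.ci_low,
                    "ci_high": h.ci_high,
                    "n_mono": h.n_mono,
                    "n_poly": h.n_poly,
                }
                for h in self.harm
            ]
        )

    def models_frame(self) -> pd.DataFrame:
        frames = [m.to_frame() for m in self.interaction_models + self.followup_models]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def summary(self) -> str:
        """Readable report: harm per temperature, lifespan decreases, and the
        population cost of polyandry across background growth rates."""
        lines = ["Male harm analysis", "=" * 66]
        lines.append(f"females analysed (uncensored): {len(self.components)}")
        lines.append("")
        lines.append("Relative harm H = (W_mono - W_poly)/W_mono, 95% bootstrap CI")
        for h in self.harm:
            lines.append(
                f"  {h.temperature:>5.1f} degC  H = {h.H:6.3f}  "
                f"[{h.ci_low:6.3f}, {h.ci_high:6.3f}]  "
                f"(W_mono={h.W_mono:.1f}, W_poly={h.W_poly:.1f}, "
                f"n={h.n_mono}/{h.n_poly})"
            )
        lines.append("")
        lines.append("Mean lifespan decrease under polyandry")
        for _, row in self.lifespan.iterrows():
            lines.append(
                f"  {row.temperature:>5.1f} degC  {row.decrease_pct:5.1f}%  "
                f"({row.mean_lifespan_mono:.1f} -> {row.mean_lifespan_poly:.1f} days)"
            )
        lines.append("")
        lines.append("Population cost of polyandry, 1 - C_r (rows: temperature)")
        piv = self.rate_sensitive.pivot(index="temperature", columns="r", values="pop_cost")
        lines.append("        " + "  ".join(f"r={r:+.2f}" for r in piv.columns))
        for T, row in piv.iterrows():
            lines.append(f"  {T:4.1f}  " + "  ".join(f"{v:7.3f}" for v in row.values))
        if self.interaction_models:
            lines.append("")
            lines.append("Type-III F (Box-Cox response ~ temperature x mating system)")
            for m in self.interaction_models:
                t = m.term("temperature:mating_system")
                lines.append(
                    f"  {m.response:<16} F_{t.df_num},{t.df_den} = {t.F:7.2f}  "
                    f"p = {t.p:.3g}  p_BH = {t.p_adj:.3g}"
                )
        return "\n".join(lines)

    def plot_pop_cost(self, ax=None):
        """Population cost 1 - C_r against r, one line per temperature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for T, sub in self.rate_sensitive.groupby("temperature"):
            ax.plot(sub["r"], sub["pop_cost"], marker="o", label=f"{T:g} degC")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("intrinsic growth rate r (per day)")
        ax.set_ylabel("population cost of polyandry (1 - $C_r$)")
        ax.legend()
        return ax
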