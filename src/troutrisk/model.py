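"""Model/Results front door over the risk-assessment pipeline.

``TroutRiskModel`` is built from a trait-score table (plus an optional
threat-status table and reach table); ``fit()`` runs weighted scoring, the
Monte Carlo perturbation, natural-breaks tier classification, and — where
the inputs allow — the threat-status regression and the river-reach overlap
summary, returning a ``TroutRiskResults`` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import reach_overlap as ro
from . import risk_classes as rc
from . import threat_regression as tr
from . import trait_matrix as tm
from . import uncertainty as mc

__all__ = ["TroutRiskModel", "TroutRiskResults"]


@dataclass(frozen=True)
class TroutRiskResults:
    """Fitted pipeline outputs.

    Attributes
    ----------
    scores : DataFrame of per-factor contributions and totals per species.
    mc_summary : per-species median/quartile table ordered by median.
    classification : tier assignment with the break set used.
    regression : RegressionFit of score on threat ordinal, or None.
    overlap : OverlapSummary of river-length co-occurrence, or None.
    """

    model: "TroutRiskModel"
    scores: pd.DataFrame
    mc_result: mc.MCResult
    mc_summary: pd.DataFrame
    classification: rc.RiskClassification
    regression: tr.RegressionFit | None = None
    overlap: ro.OverlapSummary | None = None

    @property
    def totals(self) -> dict[str, int]:
        return {sp: int(t) for sp, t in self.scores["total"].items()}

    @property
    def rank_stability(self) -> float:
        return self.mc_result.rank_stability

    def summary(self) -> str:
        """Human-readable run summary, statsmodels-style."""
        cls = self.classification
        lines = [
            "Trait-based trout-pressure risk assessment",
            "=" * 58,
            f"Species: {len(self.scores)}   Factors: "
            f"{self.model.table.n_factors}   "
            f"Score bounds: {tm.score_bounds(self.model.table.weights)}",
            f"Monte Carlo: {self.mc_result.config.n_iterations} iterations, "
            f"{self.mc_result.config.n_elements} elements perturbed, "
            f"seed {self.mc_result.config.seed}",
            f"Rank stability (Spearman raw vs MC median): "
            f"{self.rank_stability:.3f}",
            f"Natural breaks (k={cls.break_set.k}): class boundaries at "
            f"{list(cls.break_set.breaks)}, GVF {cls.break_set.gvf:.3f}",
            "Tier counts: "
            + ", ".join(f"{t}={n}" for t, n in sorted(cls.tier_counts.items())),
        ]
        if self.regression is not None:
            r = self.regression
            lines.append(
                f"Score ~ threat level: adj R2 = {r.adjusted_r_squared:.2f}, "
                f"F({r.df[0]},{r.df[1]}) = {r.f_statistic:.2f}, "
                f"p {r.format_p()}"
            )
        if self.overlap is not None:
            for t in self.overlap.tiers.values():
                pct = "n/a" if t.overlap_pct is None else f"{t.overlap_pct:.1f}%"
                lines.append(
                    f"{t.tier}-risk extent {t.extent_km:.0f} km, trout overlap "
                    f"{t.overlap_km:.0f} km ({pct})"
                )
        lines.append("-" * 58)
        tbl = self.mc_summary.copy()
        tbl["tier"] = [cls.tiers[sp] for sp in tbl["species"]]
        lines.append(tbl.to_string(index=False))
        return "\n".join(lines)


class TroutRiskModel:
    """Trait-based risk assessment of native fish vulnerability to trout.

    Parameters
    ----------
    table : TraitScoreTable
        Species x factor scores with factor weights.
    statuses : optional mapping species -> threat-status label.
    reaches : optional ReachTable for co-occurrence summaries.
    """

    def __init__(
        self,
        table: tm.TraitScoreTable,
        statuses: Mapping[str, str] | None = None,
        reaches: ro.ReachTable | None = None,
    ) -> None:
        self.table = table
        self.statuses = dict(statuses) if statuses else None
        self.reaches = reaches

    @classmethod
    def from_csv(
        cls,
        trait_path: str | Path,
        status_path: str | Path | None = None,
        reach_path: str | Path | None = None,
    ) -> "TroutRiskModel":
        """Build a model from the comma-separated file dialects."""
        table = tm.load_trait_table(trait_path)
        statuses = tr.load_status_table(status_path) if status_path else None
        reaches = ro.load_reach_table(reach_path) if reach_path else None
        return cls(table, statuses=statuses, reaches=reaches)

    @classmethod
    def packaged(cls, **kwargs) -> "TroutRiskModel":
        """Model over the packaged 35-species screening matrix."""
        return cls(tm.packaged_trait_table(), **kwargs)

    def fit(
        self,
        n_iterations: int = 10_000,
        n_elements: int = 30,
        seed: int = 0,
        k: int = 3,
        tau: float = 0.5,
        encoding: Mapping[str, int] | None = None,
    ) -> TroutRiskResults:
        """Run scoring, Monte Carlo, classification, and optional stages."""
        config = mc.PerturbationConfig(n_iterations=n_iterations,
                                       n_elements=n_elements, seed=seed)
        scores = tm.scores_frame(self.table)
        result = mc.run_monte_carlo(self.table, config=config)
        summary = mc.summarize_mc(result)
        classification = rc.classify(self.totals_dict(scores), k=k)
        regression = None
        if self.statuses:
            regression = tr.regress_scores_on_status(
                self.totals_dict(scores), self.statuses, encoding
            )
        overlap = None
        if self.reaches is not None:
            overlap = ro.summarize_overlap(self.reaches, classification, tau=tau)
        return TroutRiskResults(
            model=self,
            scores=scores,
            mc_result=result,
            mc_summary=summary,
            classification=classification,
            regression=regression,
            overlap=overlap,
        )

    @staticmethod
    def totals_dict(scores: pd.DataFrame) -> dict[str, float]:
        return {sp: float(t) for sp, t in scores["total"].items()}
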