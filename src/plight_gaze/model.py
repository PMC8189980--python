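"""Model-style entry point for the preferential-looking statistical battery.

``PreferentialLookingModel`` binds the per-participant metrics table to the
participant covariate table; ``fit()`` runs the full battery (group ANCOVAs
with BH adjustment, chance-level and paired signed-rank tests, the symptom
severity grid, IQ strata, and the metric-by-symptom partial-correlation
grid) and returns a ``PreferentialLookingResults`` whose ``summary()`` gives
a compact table of the primary group comparisons.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .stats import METRIC_COLUMNS, StatsConfig, run_full_battery

__all__ = ["PreferentialLookingModel", "PreferentialLookingResults"]


class PreferentialLookingModel:
    """Two-group preferential-looking analysis bound to its data tables.

    Parameters
    ----------
    metrics : DataFrame with ``participant_id`` and the five metric columns.
    participants : DataFrame with ``participant_id``, ``group``, ``age``,
        ``gender`` and optionally ``iq`` and symptom-subscale columns.
    config : StatsConfig, optional.
    """

    def __init__(
        self,
        metrics: pd.DataFrame,
        participants: pd.DataFrame,
        config: StatsConfig | None = None,
    ) -> None:
        for col in ("participant_id", *METRIC_COLUMNS):
            if col not in metrics.columns:
                raise ValueError(f"metrics table missing column {col!r}")
        for col in ("participant_id", "group", "age", "gender"):
            if col not in participants.columns:
                raise ValueError(f"participant table missing column {col!r}")
        self.metrics = metrics
        self.participants = participants
        self.config = config or StatsConfig()

    @classmethod
    def from_dataframes(
        cls,
        metrics: pd.DataFrame,
        participants: pd.DataFrame,
        config: StatsConfig | None = None,
    ) -> "PreferentialLookingModel":
        return cls(metrics, participants, config)

    def fit(self) -> "PreferentialLookingResults":
        report = run_full_battery(self.metrics, self.participants, self.config)
        return PreferentialLookingResults(self, report)


class PreferentialLookingResults:
    """Fitted battery: structured report plus tabular accessors."""

    def __init__(self, model: PreferentialLookingModel, report: dict) -> None:
        self.model = model
        self.report = report

    @property
    def group_effects(self) -> pd.DataFrame:
        rows = []
        for metric, cell in self.report["group_effects"].items():
            means = cell["estimate"]
            rows.append(
                {
                    "metric": metric,
                    **{f"mean_{g}": v for g, v in means.items()},
                    "cohens_d": cell.get("cohens_d"),
                    "partial_eta_sq": cell.get("partial_eta_sq"),
                    "F": cell["statistic"],
                    "p_raw": cell["p_raw"],
                    "p_adjusted": cell.get("p_adjusted"),
                    "n": cell["n"],
                }
            )
        return pd.DataFrame(rows).set_index("metric")

    @property
    def correlation_grid(self) -> pd.DataFrame:
        grid = self.report["correlation_grid"]
        rows = []
        for metric, cols in grid.items():
            for symptom, cell in cols.items():
                rows.append(
                    {
                        "metric": metric,
                        "symptom": symptom,
                        "r": cell.get("estimate"),
                        "p": cell.get("p_raw"),
                        "n": cell.get("n"),
                    }
                )
        return pd.DataFrame(rows)

    @property
    def severity_grid(self) -> pd.DataFrame:
        rows = []
        for symptom, levels in self.report["severity_grid"].items():
            for level, cell in levels.items():
                rows.append({"symptom": symptom, "level": level, **cell})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.group_effects
        lines = [
            "Preferential-looking group comparison (ANCOVA: metric ~ group + age + gender)",
            "=" * 78,
            f"{'metric':<22}{'mean(asd)':>10}{'mean(td)':>10}{'d':>7}"
            f"{'eta_p^2':>9}{'F':>8}{'p_adj':>10}",
            "-" * 78,
        ]
        for metric, row in df.iterrows():
            lines.append(
                f"{metric:<22}"
                f"{row.get('mean_asd', np.nan):>10.1f}"
                f"{row.get('mean_td', np.nan):>10.1f}"
                f"{row['cohens_d']:>7.2f}"
                f"{row['partial_eta_sq']:>9.3f}"
                f"{row['F']:>8.2f}"
                f"{row['p_adjusted']:>10.2g}"
            )
        lines.append("-" * 78)
        chance = self.report.get("chance_tests", {})
        for group, tests in chance.items():
            cell = tests.get("preference_bio_pct", {})
            if "p_raw" in cell:
                lines.append(
                    f"preference vs chance ({group}): mean {cell['estimate']:.1f}%, "
                    f"p = {cell['p_raw']:.2g} (n = {cell['n']})"
                )
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=1, default=float)
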