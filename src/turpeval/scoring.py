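"""Percentage scorecards, radar-chart export and group comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScoreCard", "GroupComparison", "make_scorecard", "compare_groups",
           "export_radar", "PARAMETERS"]

PARAMETERS = ("preservation", "smoothness", "circularity")
_ATTR = {"preservation": "r_pres", "smoothness": "r_smoo", "circularity": "r_circ"}


@dataclass
class ScoreCard:
    """Normalized percentage scores (0-100) of one operator across cases."""

    operator: str
    scores_percent: dict
    std_percent: dict
    per_case: dict
    n_cases: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"operator": self.operator, "parameter": p,
                 "score_percent": self.scores_percent[p],
                 "std_percent": self.std_percent[p],
                 "n_cases": self.n_cases} for p in PARAMETERS]
        return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Two-sample t-test on one parameter between two operator groups."""

    parameter: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    std_a: float
    std_b: float
    t_statistic: float
    p_value: float
    alpha: float = 0.01
    welch: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def make_scorecard(cases: list, operator: str) -> ScoreCard:
    """Average each aggregate ratio across cases, scaled to percent.

    Scores are 100 x mean ratio, clipped to [0, 100]; spreads are the
    standard deviation across cases (ddof=1 when more than one case).
    """
    if not cases:
        raise ValueError("at least one case is required")
    per_case = {p: [100.0 * getattr(c, _ATTR[p]) for c in cases] for p in PARAMETERS}
    scores = {p: float(np.clip(np.mean(v), 0.0, 100.0)) for p, v in per_case.items()}
    stds = {p: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for p, v in per_case.items()}
    return ScoreCard(operator=operator, scores_percent=scores, std_percent=stds,
                     per_case=per_case, n_cases=len(cases))


def compare_groups(a, b, parameter: str = "", group_a: str = "a", group_b: str = "b",
                   alpha: float = 0.01, welch: bool = False) -> GroupComparison:
    """Two-sample two-tailed t-test (equal-variance Student's t by default).

    Identical constant samples yield ``t = 0, p = 1`` by convention; a
    degenerate zero-variance comparison with unequal means raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if np.isclose(a.mean(), b.mean()):
            t_stat, p_val = 0.0, 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        parameter=parameter, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        std_a=float(a.std(ddof=1)), std_b=float(b.std(ddof=1)),
        t_statistic=t_stat, p_value=p_val, alpha=alpha, welch=welch,
    )


def scorecards_table(scorecards: list) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in scorecards], ignore_index=True)


def export_radar(scorecards: list, figure_path=None, table_path=None):
    """Write the three-axis radar chart and its underlying table.

    Axis order and 0-100 scaling are identical for all operators on one
    chart.  Returns the table as a DataFrame.
    """
    if not scorecards:
        raise ValueError("at least one scorecard is required")
    table = scorecards_table(scorecards)
    if table_path is not None:
        table.to_csv(table_path, index=False)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        angles = np.linspace(0.0, 2 * np.pi, len(PARAMETERS), endpoint=False)
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
        for card in scorecards:
            vals = [card.scores_percent[p] for p in PARAMETERS]
            ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=card.operator)
            ax.fill(np.r_[angles, angles[0]], np.r_[vals, vals[0]], alpha=0.15)
        ax.set_xticks(angles)
        ax.set_xticklabels([p.capitalize() for p in PARAMETERS])
        ax.set_ylim(0, 100)
        ax.set_yticks([25, 50, 75, 100])
        ax.legend(loc="lower right", bbox_to_anchor=(1.15, -0.1), fontsize=8)
        fig.savefig(figure_path, bbox_inches="tight")
        plt.close(fig)
    return table
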