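"""Table-1-style cohort summaries with between-group tests.

Categorical characteristics are summarized as count (percent) per outcome
group and compared with a continuity-corrected chi-square test, replaced
by Fisher's exact test when any expected cell count is below 5.
Continuous characteristics are summarized as median (IQR) and compared
with a two-sided Mann-Whitney U test (normal approximation with tie
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "percent",
    "categorical_assoc",
    "continuous_assoc",
    "build_table1",
]


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Proportion as a percentage rounded to ``decimals`` (Table-1 format)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of exposed/unexposed x died/survived.

    ``a`` exposed-died, ``b`` exposed-survived, ``c`` unexposed-died,
    ``d`` unexposed-survived.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @property
    def n_died(self) -> int:
        return self.a + self.c

    @property
    def n_survived(self) -> int:
        return self.b + self.d


def categorical_assoc(table: ContingencyTable2x2) -> dict:
    """Group proportions, association p-value, and odds ratio for a 2x2 table.

    Returns a dict with ``prop_died``/``prop_survived`` (exposure percentage
    within each outcome group, 1 decimal), ``p_value`` (chi-square with
    continuity correction, or Fisher exact when any expected count < 5),
    ``p_chi2``, ``p_fisher``, ``test`` (name used for ``p_value``) and
    ``odds_ratio`` (ad/bc; ``inf``/``0`` sentinels on empty cells).
    """
    t = table
    if t.n_died == 0 or t.n_survived == 0:
        raise ValueError("empty outcome margin")
    counts = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)

    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / counts.sum()

    if (row == 0).any() or (col == 0).any():
        p_chi2 = 1.0
        chi2_stat = 0.0
    else:
        chi2_stat, p_chi2, _, _ = stats.chi2_contingency(counts, correction=True)
    _, p_fisher = stats.fisher_exact(counts)

    use_fisher = (expected < 5).any()
    if t.b * t.c == 0:
        odds_ratio = float("inf") if t.a * t.d > 0 else 0.0
    else:
        odds_ratio = (t.a * t.d) / (t.b * t.c)

    return {
        "prop_died": percent(t.a, t.n_died),
        "prop_survived": percent(t.b, t.n_survived),
        "chi2": float(chi2_stat),
        "p_chi2": float(p_chi2),
        "p_fisher": float(p_fisher),
        "test": "fisher" if use_fisher else "chi2",
        "p_value": float(p_fisher if use_fisher else p_chi2),
        "odds_ratio": float(odds_ratio),
    }


def continuous_assoc(x, y) -> dict:
    """Median (IQR) per group and a two-sided Mann-Whitney U p-value.

    Percentiles use linear interpolation; the U test uses the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")

    def summary(v):
        return {
            "median": float(np.percentile(v, 50)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }

    _, p = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return {"group1": summary(x), "group2": summary(y), "p_value": float(p)}


def _fmt_count_pct(count: int, total: int) -> str:
    return f"{count} ({percent(count, total)})"


def _fmt_median_iqr(s: dict) -> str:
    return f"{s['median']:g} ({s['q25']:g}-{s['q75']:g})"


def build_table1(
    annotation: pd.DataFrame, variable_spec: list[tuple[str, str]]
) -> pd.DataFrame:
    """Render a Table-1-style cohort summary.

    ``variable_spec`` is a list of ``(column_name, kind)`` with kind
    'categorical' (boolean/0-1 column) or 'continuous'.  The first row
    always summarizes overall mortality.  Output columns: Variable,
    Overall, Died, Survived, p-Value.
    """
    died_mask = annotation["outcome"] == "died"
    n, n_died, n_surv = len(annotation), int(died_mask.sum()), int((~died_mask).sum())

    rows = [
        {
            "Variable": "Died during hospitalization",
            "Overall": _fmt_count_pct(n_died, n),
            "Died": str(n_died),
            "Survived": str(n_surv),
            "p-Value": "",
        }
    ]
    for name, kind in variable_spec:
        if name not in annotation.columns:
            raise ValueError(f"unknown variable {name!r}")
        col = annotation[name]
        if kind == "categorical":
            a = int(col[died_mask].astype(bool).sum())
            b = int(col[~died_mask].astype(bool).sum())
            res = categorical_assoc(
                ContingencyTable2x2(a=a, b=b, c=n_died - a, d=n_surv - b)
            )
            rows.append(
                {
                    "Variable": name,
                    "Overall": _fmt_count_pct(a + b, n),
                    "Died": _fmt_count_pct(a, n_died),
                    "Survived": _fmt_count_pct(b, n_surv),
                    "p-Value": f"{res['p_value']:.3g}",
                }
            )
        elif kind == "continuous":
            res = continuous_assoc(col[died_mask], col[~died_mask])
            overall = continuous_assoc(col, col)["group1"]
            rows.append(
                {
                    "Variable": f"{name}, Median (IQR)",
                    "Overall": _fmt_median_iqr(overall),
                    "Died": _fmt_median_iqr(res["group1"]),
                    "Survived": _fmt_median_iqr(res["group2"]),
                    "p-Value": f"{res['p_value']:.3g}",
                }
            )
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows, columns=["Variable", "Overall", "Died", "Survived", "p-Value"])
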