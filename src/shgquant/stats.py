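"""The statistical layer: factorial group comparison of pipeline metrics.

Two study modes mirror the two experimental designs:

* ``aim1`` — a two-factor (sex x diet) screen: a two-way ANOVA first checks
  whether sex matters; if neither the sex main effect nor the interaction is
  significant at alpha, sexes are pooled and a two-tailed independent t test
  compares the diet groups.  Otherwise a warning is emitted and per-sex
  t tests are reported instead.
* ``aim2`` — a 2x2 fixed-effects ANOVA (genotype x treatment) with
  interaction, Type III sums of squares under sum-to-zero contrasts (so the
  unbalanced case is handled the way GraphPad Prism does), followed by
  Bonferroni-adjusted planned contrasts: by default the four cell contrasts
  the figures of such designs report (within-genotype treatment effects and
  within-treatment genotype effects).

Percent differences are always computed against the declared reference group
mean: ``100 * (mean_exp - mean_ref) / mean_ref``.  All data are judged
significant at P <= alpha (default 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .exceptions import DesignError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_METRICS = ("mean_intensity", "entropy_bits", "percent_area", "chp_mean_intensity")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def percent_difference(mean_ref: float, mean_exp: float) -> float:
    """``100 * (mean_exp - mean_ref) / mean_ref`` relative to the reference group."""
    if mean_ref == 0:
        raise ParameterError("percent difference undefined for zero reference mean")
    return 100.0 * (mean_exp - mean_ref) / mean_ref


def t_test_two_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Two-tailed independent-samples t test; returns ``(t, df, p)``.

    Student's pooled-variance t by default (Welch via ``equal_var=False``).
    Degenerate zero-variance data use the conventions p = 1 for equal means
    and p = 0 (with a warning) for different means.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DesignError(f"t test needs n >= 2 per group, got {a.size} and {b.size}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        logger.warning("zero within-group variance with unequal means; p = 0 by convention")
        return float("inf") if a.mean() > b.mean() else float("-inf"), df, 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA with interaction (Type III, sum-to-zero)."""

    factor_names: tuple[str, str]
    p_factor_a: float
    p_factor_b: float
    p_interaction: float
    f_factor_a: float
    f_factor_b: float
    f_interaction: float
    ss: dict[str, float]
    mse: float
    df_resid: float
    cell_stats: pd.DataFrame
    table: pd.DataFrame

    def p_for(self, name: str) -> float:
        if name == self.factor_names[0]:
            return self.p_factor_a
        if name == self.factor_names[1]:
            return self.p_factor_b
        if name == "interaction":
            return self.p_interaction
        raise KeyError(name)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    factor_names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Fixed-effects two-factor linear model with interaction.

    Type III sums of squares with sum-to-zero contrasts, which coincide with
    the classical balanced decomposition on balanced data and handle
    unbalanced designs (e.g. n = 12 vs 11).
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=np.float64),
        "A": list(factor_a),
        "B": list(factor_b),
    })
    if df["y"].isna().any():
        raise ParameterError("ANOVA input contains missing values")
    levels_a = sorted(df["A"].unique())
    levels_b = sorted(df["B"].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise DesignError("two-way ANOVA needs >= 2 levels per factor")
    sizes = df.groupby(["A", "B"], sort=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in sizes.index:
                raise DesignError(
                    f"empty design cell ({factor_names[0]}={la}, {factor_names[1]}={lb})"
                )
    if not (sizes >= 2).any():
        raise DesignError("at least one cell needs n >= 2 to estimate error variance")

    model = ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # F on zero residual variance
        table = sm.stats.anova_lm(model, typ=3)
    row_a, row_b = "C(A, Sum)", "C(B, Sum)"
    row_ab = "C(A, Sum):C(B, Sum)"
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    cell_stats = (
        df.groupby(["A", "B"], sort=True)["y"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"A": factor_names[0], "B": factor_names[1],
                         "std": "sd", "count": "n"})
    )
    return AnovaResult(
        factor_names=factor_names,
        p_factor_a=float(table.loc[row_a, "PR(>F)"]),
        p_factor_b=float(table.loc[row_b, "PR(>F)"]),
        p_interaction=float(table.loc[row_ab, "PR(>F)"]),
        f_factor_a=float(table.loc[row_a, "F"]),
        f_factor_b=float(table.loc[row_b, "F"]),
        f_interaction=float(table.loc[row_ab, "F"]),
        ss={
            factor_names[0]: float(table.loc[row_a, "sum_sq"]),
            factor_names[1]: float(table.loc[row_b, "sum_sq"]),
            "interaction": float(table.loc[row_ab, "sum_sq"]),
            "residual": float(table.loc["Residual", "sum_sq"]),
        },
        mse=mse,
        df_resid=float(table.loc["Residual", "df"]),
        cell_stats=cell_stats,
        table=table,
    )


@dataclass
class PosthocContrast:
    """One planned pairwise contrast with its Bonferroni-adjusted p value."""

    name: str
    cell_a: tuple[str, ...]
    cell_b: tuple[str, ...]
    mean_a: float
    mean_b: float
    percent_difference: float | None
    t: float
    raw_p: float
    adjusted_p: float


def bonferroni_pairwise(
    cells: Mapping[tuple[str, ...], Sequence[float]],
    contrasts: Sequence[tuple[tuple[str, ...], tuple[str, ...]]],
    mse: float,
    df_resid: float,
    n_comparisons: int | None = None,
) -> list[PosthocContrast]:
    """Planned pairwise contrasts using the ANOVA residual mean square.

    Each contrast is a pooled-variance t with ``df_resid`` degrees of
    freedom; adjusted p = ``min(1, raw_p * k)`` with ``k`` the number of
    planned comparisons (default: ``len(contrasts)``).
    """
    k = n_comparisons if n_comparisons is not None else len(contrasts)
    if k < 1:
        raise ParameterError("need at least one planned comparison")
    out: list[PosthocContrast] = []
    for cell_a, cell_b in contrasts:
        for c in (cell_a, cell_b):
            if c not in cells:
                raise DesignError(f"unknown design cell {c}")
        a = np.asarray(cells[cell_a], dtype=np.float64)
        b = np.asarray(cells[cell_b], dtype=np.float64)
        se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            t = 0.0 if a.mean() == b.mean() else float("inf")
            raw_p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t = float((b.mean() - a.mean()) / se)
            raw_p = float(2.0 * scipy.stats.t.sf(abs(t), df_resid))
        pct = None
        if a.mean() != 0:
            pct = percent_difference(float(a.mean()), float(b.mean()))
        out.append(PosthocContrast(
            name=f"{':'.join(cell_a)} vs {':'.join(cell_b)}",
            cell_a=cell_a,
            cell_b=cell_b,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            percent_difference=pct,
            t=t,
            raw_p=raw_p,
            adjusted_p=min(1.0, raw_p * k),
        ))
    return out


def planned_2x2_contrasts(
    levels_a: Sequence[str], levels_b: Sequence[str]
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """The four planned contrasts of a 2x2 design: within-A treatment effects
    and within-B genotype effects (not all six pairs)."""
    (a1, a2), (b1, b2) = levels_a, levels_b
    return [
        ((a1, b1), (a1, b2)),
        ((a2, b1), (a2, b2)),
        ((a1, b1), (a2, b1)),
        ((a1, b2), (a2, b2)),
    ]


# ---------------------------------------------------------------------------
# the full study workflow
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Group statistics and tests for one metric."""

    metric: str
    group_stats: pd.DataFrame
    percent_difference: float | None = None
    t_statistic: float | None = None
    t_df: float | None = None
    t_p: float | None = None
    anova_p: dict[str, float] = field(default_factory=dict)
    posthoc: list[PosthocContrast] = field(default_factory=list)
    alpha: float = 0.05
    pooled_for_sex: bool | None = None
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "metric": self.metric,
            "percent_difference": self.percent_difference,
            "t_statistic": self.t_statistic,
            "t_df": self.t_df,
            "t_p": self.t_p,
            "alpha": self.alpha,
            "pooled_for_sex": self.pooled_for_sex,
        }
        for name, p in self.anova_p.items():
            row[f"anova_p_{name}"] = p
        for c in self.posthoc:
            key = c.name.replace(" ", "_").replace(":", ".")
            row[f"posthoc_{key}_p_adj"] = c.adjusted_p
        return row


def _results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results.copy()
    return pd.DataFrame([r.to_row() for r in results])


def _ordered_levels(series: pd.Series, declared: Sequence[str] | None) -> list[str]:
    if declared is not None:
        missing = set(series.unique()) - set(declared)
        if missing:
            raise DesignError(f"data contain undeclared levels {sorted(missing)}")
        return [l for l in declared if l in set(series.unique())]
    return list(dict.fromkeys(series))  # order of appearance


def run_study(
    results,
    mode: str = "aim1",
    factor_names: tuple[str, str] | None = None,
    level_order: Mapping[str, Sequence[str]] | None = None,
    metrics: Sequence[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    aggregate_by: str | None = None,
) -> dict[str, ComparisonTable]:
    """Run the per-metric statistical workflow over a cohort of results.

    ``results`` is a list of :class:`~shgquant.quantify.QuantResult` or an
    equivalent DataFrame.  ``factor_names`` defaults to ``("sex", "diet")``
    for aim1 and ``("genotype", "treatment")`` for aim2; the first declared
    level of the experimental factor is the reference group for percent
    differences.  ``aggregate_by`` optionally averages the metric per
    grouping unit (e.g. one value per animal) before testing.
    """
    if mode not in ("aim1", "aim2"):
        raise DesignError(f"unknown study mode {mode!r}")
    df = _results_frame(results)
    if factor_names is None:
        factor_names = ("sex", "diet") if mode == "aim1" else ("genotype", "treatment")
    fa, fb = factor_names
    for f in factor_names:
        if f not in df.columns:
            raise DesignError(f"results lack the design factor column {f!r}")
    if metrics is None:
        metrics = [m for m in DEFAULT_METRICS if m in df.columns and df[m].notna().any()]
    if not metrics:
        raise DesignError("no metrics to compare")

    tables: dict[str, ComparisonTable] = {}
    for metric in metrics:
        sub = df[[fa, fb, metric] + ([aggregate_by] if aggregate_by else [])].dropna(
            subset=[metric]
        )
        if aggregate_by:
            sub = (
                sub.groupby([fa, fb, aggregate_by], as_index=False)[metric].mean()
            )
        levels_a = _ordered_levels(sub[fa], level_order.get(fa) if level_order else None)
        levels_b = _ordered_levels(sub[fb], level_order.get(fb) if level_order else None)
        anova = two_way_anova(
            sub[metric], sub[fa], sub[fb], factor_names=(fa, fb)
        )
        group_stats = anova.cell_stats
        table = ComparisonTable(
            metric=metric,
            group_stats=group_stats,
            anova_p={fa: anova.p_factor_a, fb: anova.p_factor_b,
                     "interaction": anova.p_interaction},
            alpha=alpha,
        )

        if mode == "aim1":
            # pool over the nuisance factor (sex) only when it is inert;
            # NaN p (zero residual variance) is no evidence of an effect
            pooled = not (anova.p_factor_a <= alpha) and not (
                anova.p_interaction <= alpha
            )
            table.pooled_for_sex = pooled
            ref, exp = levels_b[0], levels_b[-1]
            if pooled:
                a_vals = sub.loc[sub[fb] == ref, metric].to_numpy()
                b_vals = sub.loc[sub[fb] == exp, metric].to_numpy()
                t, tdf, p = t_test_two_tailed(a_vals, b_vals, equal_var=equal_var)
                table.t_statistic, table.t_df, table.t_p = t, tdf, p
                table.percent_difference = percent_difference(
                    float(a_vals.mean()), float(b_vals.mean())
                )
            else:
                msg = (
                    f"{metric}: {fa} effect or interaction significant "
                    f"(p={anova.p_factor_a:.3g}, p_int={anova.p_interaction:.3g}); "
                    f"not pooling — reporting per-{fa} contrasts"
                )
                logger.warning(msg)
                table.notes.append(msg)
                cells = {
                    (la, lb): sub.loc[(sub[fa] == la) & (sub[fb] == lb), metric].to_numpy()
                    for la in levels_a for lb in levels_b
                }
                contrasts = [((la, ref), (la, exp)) for la in levels_a]
                table.posthoc = bonferroni_pairwise(
                    cells, contrasts, anova.mse, anova.df_resid
                )
        else:
            cells = {
                (la, lb): sub.loc[(sub[fa] == la) & (sub[fb] == lb), metric].to_numpy()
                for la in levels_a for lb in levels_b
            }
            if len(levels_a) == 2 and len(levels_b) == 2:
                contrasts = planned_2x2_contrasts(levels_a, levels_b)
            else:
                raise DesignError("aim2 mode expects a 2x2 design")
            table.posthoc = bonferroni_pairwise(
                cells, contrasts, anova.mse, anova.df_resid
            )
            # headline percent difference: treatment effect within the
            # reference genotype
            ref_cell = (levels_a[0], levels_b[0])
            exp_cell = (levels_a[0], levels_b[-1])
            m_ref = float(np.mean(cells[ref_cell]))
            m_exp = float(np.mean(cells[exp_cell]))
            if m_ref != 0:
                table.percent_difference = percent_difference(m_ref, m_exp)
        tables[metric] = table
    return tables


def comparison_frame(tables: Mapping[str, ComparisonTable]) -> pd.DataFrame:
    """Flatten ComparisonTables into one row per metric for CSV output."""
    return pd.DataFrame([t.to_row() for t in tables.values()])
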