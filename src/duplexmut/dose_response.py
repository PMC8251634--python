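"""Dose-response statistics: linear trend, one-way ANOVA, and Dunnett
many-to-one comparisons against a shared vehicle control.

Operates on replicate-by-concentration endpoint tables (mutant
frequencies, %DNA in Tail, or any scalar endpoint). The Dunnett critical
value is estimated by seeded Monte Carlo from the joint distribution of
the correlated t-vector induced by the shared control and the group
sizes, which handles unequal replication exactly as defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("concentration", "value")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    stderr: float
    t_statistic: float
    p_value: float
    df: int


@dataclass(frozen=True)
class GroupComparison:
    concentration: float
    mean_difference: float
    t_statistic: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class DunnettResult:
    comparisons: tuple[GroupComparison, ...]
    critical_value: float
    critical_value_se: float
    alternative: str
    alpha: float
    df: int

    def flagged(self) -> tuple[float, ...]:
        return tuple(c.concentration for c in self.comparisons if c.significant)


def endpoint_table(
    concentrations: Sequence[float],
    values: Sequence[float],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble a replicate-by-concentration endpoint table."""
    df = pd.DataFrame({"concentration": concentrations, "value": values})
    if sample_ids is not None:
        df["sample_id"] = sample_ids
    df["replicate"] = df.groupby("concentration").cumcount() + 1
    return df


def read_endpoint_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"endpoint table lacks columns: {missing}")
    return df


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"endpoint table lacks columns: {missing}")
    if (table["concentration"] < 0).any():
        raise ValueError("concentrations must be non-negative")
    return table


def linear_trend(
    table: pd.DataFrame,
    on: Literal["replicates", "means"] = "replicates",
    scale: Literal["linear", "log"] = "linear",
) -> TrendResult:
    """Ordinary least squares of endpoint value on concentration, with a
    t-test on the slope.

    ``on="means"`` regresses the per-concentration group means (one point
    per concentration); ``scale="log"`` replaces concentration by the
    within-table group index, accommodating a zero dose.
    """
    table = _validate(table)
    if on == "means":
        g = table.groupby("concentration")["value"].mean().reset_index()
        x = g["concentration"].to_numpy(dtype=float)
        y = g["value"].to_numpy(dtype=float)
    else:
        x = table["concentration"].to_numpy(dtype=float)
        y = table["value"].to_numpy(dtype=float)
    if scale == "log":
        order = {c: i for i, c in enumerate(sorted(set(x)))}
        x = np.array([order[v] for v in x], dtype=float)
    if len(x) < 3:
        raise ValueError("trend test needs at least 3 points")
    if len(set(x)) < 2:
        raise ValueError("degenerate design: all concentrations equal")
    fit = stats.linregress(x, y)
    df = len(x) - 2
    t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    return TrendResult(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        t_statistic=float(t),
        p_value=float(fit.pvalue),
        df=df,
    )


def one_way_anova(table: pd.DataFrame) -> tuple[float, int, int, float]:
    """Standard between/within F decomposition.

    Returns (F, df_between, df_within, p). Every group must hold at
    least two replicates; no silent pooling.
    """
    table = _validate(table)
    groups = [g["value"].to_numpy(dtype=float)
              for _, g in table.groupby("concentration")]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs >= 2 replicates")
    res = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(res.statistic), df1, df2, float(res.pvalue)


def _dunnett_critical(
    n_control: int,
    n_treated: Sequence[int],
    df: int,
    alpha: float,
    alternative: str,
    mc_reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo (1-alpha) quantile of the max (or max-|.|) of the
    correlated null t-vector, plus its Monte-Carlo standard error."""
    k = len(n_treated)
    z_ctrl = rng.standard_normal(mc_reps)
    z_trt = rng.standard_normal((mc_reps, k))
    s = np.sqrt(rng.chisquare(df, mc_reps) / df)
    a0 = 1.0 / np.sqrt(n_control)
    t_mat = np.empty((mc_reps, k))
    for j, nj in enumerate(n_treated):
        aj = 1.0 / np.sqrt(nj)
        t_mat[:, j] = (z_trt[:, j] * aj - z_ctrl * a0) / (
            np.sqrt(1.0 / nj + 1.0 / n_control) * s)
    if alternative == "two_sided":
        m = np.abs(t_mat).max(axis=1)
    else:
        m = t_mat.max(axis=1)
    m.sort()
    p = 1.0 - alpha
    crit = float(np.quantile(m, p))
    # SE of the quantile estimate: binomial error / local density,
    # density from the spread of nearby order statistics.
    eps = 0.005
    lo, hi = np.quantile(m, [p - eps, p + eps])
    dens = max((hi - lo), 1e-12) / (2 * eps)
    se = float(np.sqrt(p * (1 - p) / mc_reps) * dens)
    return crit, se


def dunnett_test(
    table: pd.DataFrame,
    control: float = 0.0,
    alternative: Literal["two_sided", "greater"] = "two_sided",
    alpha: float = 0.05,
    mc_reps: int = 100_000,
    seed: int = 0,
    log: bool = False,
) -> DunnettResult:
    """Dunnett many-to-one comparison of each treated group to control.

    t statistics use the pooled within-group variance over all groups;
    the family-wise critical value is the Monte-Carlo (1-alpha) quantile
    of the max (``greater``) or max-absolute (``two_sided``) of the
    correlated null t-vector. ``log=True`` analyses log10-transformed
    values, appropriate for endpoints with multiplicative dispersion
    such as mutant frequencies. Flags are reproducible for a fixed seed.
    """
    table = _validate(table)
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if mc_reps < 10_000:
        raise ValueError("mc_reps must be >= 10000")
    work = table.copy()
    if log:
        if (work["value"] <= 0).any():
            raise ValueError("log scale requires positive values")
        work["value"] = np.log10(work["value"])
    concs = sorted(work["concentration"].unique())
    if control not in concs:
        raise ValueError(f"control concentration {control} absent from table")
    groups = {c: work.loc[work["concentration"] == c, "value"].to_numpy(float)
              for c in concs}
    treated = [c for c in concs if c != control]
    if not treated:
        raise ValueError("no treated groups")
    ctrl = groups[control]

    n_total = sum(len(g) for g in groups.values())
    k_groups = len(groups)
    df = n_total - k_groups
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    s2 = ss_within / df
    if s2 <= 0:
        raise ValueError("zero within-group variance")

    rng = np.random.default_rng(seed)
    crit, crit_se = _dunnett_critical(
        len(ctrl), [len(groups[c]) for c in treated], df, alpha,
        alternative, mc_reps, rng)

    # Adjusted p-values share the same null draws, regenerated for
    # independence from the quantile path.
    rng_p = np.random.default_rng(seed + 1)
    z_ctrl = rng_p.standard_normal(mc_reps)
    z_trt = rng_p.standard_normal((mc_reps, len(treated)))
    s = np.sqrt(rng_p.chisquare(df, mc_reps) / df)
    t_null = np.empty((mc_reps, len(treated)))
    for j, c in enumerate(treated):
        nj = len(groups[c])
        t_null[:, j] = (z_trt[:, j] / np.sqrt(nj)
                        - z_ctrl / np.sqrt(len(ctrl))) / (
            np.sqrt(1.0 / nj + 1.0 / len(ctrl)) * s)
    null_max = (np.abs(t_null) if alternative == "two_sided" else t_null).max(axis=1)

    comparisons = []
    for c in treated:
        g = groups[c]
        diff = g.mean() - ctrl.mean()
        se = np.sqrt(s2 * (1.0 / len(g) + 1.0 / len(ctrl)))
        t = diff / se
        stat = abs(t) if alternative == "two_sided" else t
        adj_p = float((null_max >= stat).mean())
        comparisons.append(GroupComparison(
            concentration=float(c),
            mean_difference=float(diff),
            t_statistic=float(t),
            adjusted_p=adj_p,
            significant=bool(stat > crit),
        ))
    return DunnettResult(
        comparisons=tuple(comparisons),
        critical_value=crit,
        critical_value_se=crit_se,
        alternative=alternative,
        alpha=alpha,
        df=df,
    )
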