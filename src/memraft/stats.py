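"""Replicate-level aggregation and hypothesis tests for the pipeline.

Conventions: the unbiased standard deviation (n-1 denominator) everywhere;
one-way ANOVA (classical F test) for overall group differences; versus-
control contrasts as two-sided Welch t tests, flagged at 0.05 and 0.01,
with optional Bonferroni correction; Pearson correlation with the t-based
p value; and fold-change tables computed on replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError


def aggregate(
    table: pd.DataFrame,
    value_col: str = "value",
    group_cols: tuple = ("system", "species", "metric"),
) -> pd.DataFrame:
    """Mean +/- unbiased sd per group; single replicates get sd=NaN + flag."""
    if table.empty:
        raise AnalysisError("empty replicate table")
    g = table.groupby(list(group_cols))[value_col]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["single_replicate"] = out["n"] < 2
    out.loc[out["single_replicate"], "sd"] = np.nan
    return out


@dataclass
class ComparisonResult:
    group_means: dict
    group_sds: dict
    f_statistic: float
    p_value: float
    vs_control: dict  # label -> p value (Welch t test, two-sided)
    significant_005: dict
    significant_001: dict
    control: str | None
    correction: str


def one_way_anova(
    groups: dict[str, np.ndarray],
    control: str | None = None,
    correction: str = "none",
) -> ComparisonResult:
    """Classical one-way ANOVA plus versus-control Welch t contrasts.

    ``correction="bonferroni"`` multiplies contrast p values by the number
    of contrasts (Dunnett-style conservative adjustment); the default runs
    each contrast uncorrected, and the choice is recorded in the result.
    """
    if len(groups) < 2:
        raise AnalysisError("ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise AnalysisError(f"group {k!r} has fewer than 2 values")
    if all(np.var(v) == 0 for v in arrays.values()):
        raise AnalysisError("all groups have zero within-group variance")
    f, p = sps.f_oneway(*arrays.values())
    vs: dict[str, float] = {}
    if control is not None:
        if control not in arrays:
            raise AnalysisError(f"control group {control!r} not present")
        others = [k for k in arrays if k != control]
        for k in others:
            _, pk = sps.ttest_ind(arrays[k], arrays[control], equal_var=False)
            if correction == "bonferroni":
                pk = min(float(pk) * len(others), 1.0)
            vs[k] = float(pk)
    return ComparisonResult(
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        group_sds={k: float(v.std(ddof=1)) for k, v in arrays.items()},
        f_statistic=float(f),
        p_value=float(p),
        vs_control=vs,
        significant_005={k: v < 0.05 for k, v in vs.items()},
        significant_001={k: v < 0.01 for k, v in vs.items()},
        control=control,
        correction=correction,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with the t-based two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise AnalysisError("pearson needs matched arrays of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AnalysisError("pearson requires finite values")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ratio_table(
    binding_times: pd.DataFrame,
    control: str,
    compound_col: str = "compound",
    value_col: str = "mean_time_ns",
    group_cols: tuple = ("membrane", "lipid"),
) -> pd.DataFrame:
    """Fold change of mean binding time versus a control compound.

    Fold changes are ratios of replicate means (not means of per-replicate
    ratios).  ``fold_change`` keeps full precision; ``fold_change_1dp`` is
    the 1-decimal report rounding.
    """
    if control not in set(binding_times[compound_col]):
        raise AnalysisError(f"control compound {control!r} not in table")
    rows = []
    for key, grp in binding_times.groupby(list(group_cols)):
        ctrl = grp[grp[compound_col] == control]
        if ctrl.empty:
            continue
        ref = float(ctrl[value_col].iloc[0])
        if ref == 0:
            raise AnalysisError(f"control mean is zero for {key}")
        for _, row in grp.iterrows():
            fc = float(row[value_col]) / ref
            rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            rec.update(
                {
                    compound_col: row[compound_col],
                    value_col: float(row[value_col]),
                    "fold_change": fc,
                    "fold_change_1dp": round(fc, 1),
                }
            )
            rows.append(rec)
    return pd.DataFrame(rows)
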