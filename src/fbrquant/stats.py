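"""Group-comparison statistics for subject-level measurements.

The experimental unit throughout is the mouse: per-section or per-image
values are averaged to one value per subject before testing. Provided
tests: one-way fixed-effects ANOVA, Dunnett's many-to-one post hoc against
a named control (family-wise adjustment via seeded Monte Carlo sampling of
the equicorrelated multivariate-t null), Tukey's all-pairs HSD, two-way
ANOVA with Type II sums of squares for unbalanced layouts, Student's t and
the Mann-Whitney U test (exact null for small samples without ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "one_way_anova",
    "dunnett_test",
    "dunnett_critical_value",
    "tukey_hsd",
    "two_way_anova",
    "t_test",
    "mann_whitney",
    "AnovaResult",
]


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = {g: values[groups == g] for g in pd.unique(groups)}
    for g, v in out.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return out


def one_way_anova(values, groups) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA on subject-level values."""
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n = sum(len(v) for v in arrays.values())
    flat = np.concatenate(list(arrays.values()))
    if np.all(flat == flat[0]):  # degenerate 0/0: no variation at all
        return AnovaResult(0.0, len(arrays) - 1, n - len(arrays), 1.0)
    f, p = stats.f_oneway(*arrays.values())
    return AnovaResult(
        f_statistic=float(f),
        df_between=len(arrays) - 1,
        df_within=n - len(arrays),
        p_value=float(p),
    )


def dunnett_test(
    values,
    groups,
    control: str,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett's many-to-one comparisons against the control group.

    Each treatment mean is compared with the control mean using the pooled
    within-group error from all groups. Family-wise adjusted p-values are
    P(max_i |T_i| >= |t_obs|) under the joint null, estimated by seeded
    Monte Carlo over the multivariate-t distribution implied by the group
    sizes (correlated through the shared control mean and error estimate).
    """
    arrays = _group_arrays(values, groups)
    if control not in arrays:
        raise ValueError(f"control group {control!r} not present")
    treatments = [g for g in arrays if g != control]
    if not treatments:
        raise ValueError("need at least one treatment group")

    n = {g: len(v) for g, v in arrays.items()}
    total_n = sum(n.values())
    k_groups = len(arrays)
    df = total_n - k_groups
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values()) / df

    t_obs = np.array(
        [
            (arrays[g].mean() - arrays[control].mean())
            / np.sqrt(mse * (1 / n[g] + 1 / n[control]))
            for g in treatments
        ]
    )

    # Monte Carlo null: group-mean deviations u_g ~ N(0, 1/n_g), shared
    # variance estimate s2 ~ chi2_df / df.
    rng = np.random.default_rng(seed)
    u_ctrl = rng.normal(0, np.sqrt(1 / n[control]), size=mc_draws)
    max_t = np.zeros(mc_draws)
    s = np.sqrt(rng.chisquare(df, size=mc_draws) / df)
    for g in treatments:
        u_g = rng.normal(0, np.sqrt(1 / n[g]), size=mc_draws)
        t_null = np.abs(u_g - u_ctrl) / (s * np.sqrt(1 / n[g] + 1 / n[control]))
        np.maximum(max_t, t_null, out=max_t)

    adj_p = np.array([(np.count_nonzero(max_t >= abs(t)) + 1) / (mc_draws + 1) for t in t_obs])
    raw_p = 2 * stats.t.sf(np.abs(t_obs), df)
    return pd.DataFrame(
        {
            "comparison": [f"{g} - {control}" for g in treatments],
            "t": t_obs,
            "p_raw": raw_p,
            "p_adjusted": np.minimum(1.0, np.maximum(adj_p, raw_p)),
        }
    )


def dunnett_critical_value(
    group_sizes: dict[str, int], control: str, alpha: float = 0.05,
    mc_draws: int = 200_000, seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value |T| for the given design, by Monte Carlo."""
    treatments = [g for g in group_sizes if g != control]
    df = sum(group_sizes.values()) - len(group_sizes)
    rng = np.random.default_rng(seed)
    u_ctrl = rng.normal(0, np.sqrt(1 / group_sizes[control]), size=mc_draws)
    s = np.sqrt(rng.chisquare(df, size=mc_draws) / df)
    max_t = np.zeros(mc_draws)
    for g in treatments:
        u_g = rng.normal(0, np.sqrt(1 / group_sizes[g]), size=mc_draws)
        t_null = np.abs(u_g - u_ctrl) / (s * np.sqrt(1 / group_sizes[g] + 1 / group_sizes[control]))
        np.maximum(max_t, t_null, out=max_t)
    return float(np.quantile(max_t, 1 - alpha))


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Tukey's honestly-significant-difference test over all group pairs.

    Adjusted p-values come from the studentized-range null distribution.
    """
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    names = list(arrays)
    res = stats.tukey_hsd(*arrays.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "comparison": f"{names[i]} - {names[j]}",
                    "mean_difference": float(np.mean(arrays[names[i]]) - np.mean(arrays[names[j]])),
                    "p_adjusted": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction, Type II sums of squares.

    Type II marginal sums of squares are appropriate for the mildly
    unbalanced designs that arise when group sizes differ (e.g. 7 vs 8
    mice). Empty factor-level combinations make effects inestimable and
    are rejected with the offending cells named.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "a": np.asarray(factor_a), "b": np.asarray(factor_b)}
    )
    cell_counts = df.groupby(["a", "b"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [df["a"].unique(), df["b"].unique()], names=["a", "b"]
    )
    empty = sorted(set(full) - set(cell_counts.index))
    if empty:
        raise ValueError(f"empty design cells make effects inestimable: {empty}")
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={"C(a)": "factor_a", "C(b)": "factor_b", "C(a):C(b)": "interaction"}
    )
    return table


def t_test(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t test (pooled variance by default)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used when both groups have at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(u), float(p)
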