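"""Cohort-level group comparisons on sleep-architecture metrics.

Two procedures, matching the cage-change experimental design:

* one-way ANOVA with Tukey's HSD post hoc test (treatment effects
  within a window or hour);
* two-way ANOVA (handling x treatment, Type-II sums of squares; on
  balanced designs this coincides with the classical decomposition)
  with Bonferroni-corrected planned cell contrasts.

Input is a long cohort table with one row per
(animal_id, handling, treatment, window, metric). Censored latency
values (animals with no qualifying NREM bout) enter at the window
length; callers can re-run excluding them as a sensitivity check.
Normality and homoscedasticity are not tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


def cohort_table(per_animal_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-animal long tables into one cohort table."""
    tab = pd.concat(per_animal_tables, ignore_index=True)
    key = ["animal_id", "handling", "treatment", "window", "metric"]
    if tab.duplicated(key).any():
        raise ValueError("cohort table has duplicate (animal, window, metric) rows")
    return tab


def _select(table: pd.DataFrame, metric: str, window: str | None,
            drop_censored: bool = False) -> pd.DataFrame:
    sel = table[table["metric"] == metric]
    if window is not None:
        sel = sel[sel["window"] == window]
    if drop_censored and "censored" in sel:
        sel = sel[~sel["censored"].astype(bool)]
    sel = sel.dropna(subset=["value"])
    if sel.empty:
        raise ValueError(f"no rows for metric {metric!r} in window {window!r}")
    return sel


@dataclass
class OneWayResult:
    metric: str
    F: float
    p: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame | None
    group_summary: pd.DataFrame
    tested: bool = True
    note: str = ""


def one_way_anova_tukey(
    table: pd.DataFrame,
    metric: str,
    window: str | None = None,
    group_col: str = "treatment",
    groups: list[str] | None = None,
    alpha: float = ALPHA,
    drop_censored: bool = False,
) -> OneWayResult:
    """Classical one-way ANOVA plus Tukey HSD pairwise comparisons.

    Degenerate inputs (zero total variance) are flagged ``tested=False``
    rather than raising: there is nothing to test.
    """
    sel = _select(table, metric, window, drop_censored)
    if groups is not None:
        sel = sel[sel[group_col].isin(groups)]
    arrays = [g["value"].to_numpy(float) for _, g in sel.groupby(group_col, sort=True)]
    labels = [name for name, _ in sel.groupby(group_col, sort=True)]
    if len(arrays) < 2:
        raise ValueError(f"need >= 2 groups, got {labels}")
    for name, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [a.size for a in arrays],
            "mean": [a.mean() for a in arrays],
            "sem": [a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else np.nan
                    for a in arrays],
        }
    )
    values = np.concatenate(arrays)
    if np.ptp(values) == 0:
        return OneWayResult(metric, np.nan, np.nan, len(arrays) - 1,
                            values.size - len(arrays), None, summary,
                            tested=False, note="zero total variance")
    F, p = sstats.f_oneway(*arrays)
    codes = np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)])
    try:
        tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
        tukey = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
    except Exception:
        tukey = None
    return OneWayResult(metric, float(F), float(p), len(arrays) - 1,
                        values.size - len(arrays), tukey, summary)


@dataclass
class TwoWayResult:
    metric: str
    anova: pd.DataFrame  # effect, sum_sq, df, F, p
    contrasts: pd.DataFrame  # cell_a, cell_b, estimate, t, p_raw, p_bonferroni, significant
    group_summary: pd.DataFrame
    tested: bool = True
    note: str = ""


def default_contrasts(handlings, treatments) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Planned contrasts: handling effect within each treatment, and
    each treatment vs vehicle within each handling level."""
    pairs = []
    if len(handlings) == 2:
        for t in treatments:
            pairs.append(((handlings[0], t), (handlings[1], t)))
    ref = "Veh" if "Veh" in treatments else treatments[0]
    for h in handlings:
        for t in treatments:
            if t != ref:
                pairs.append(((h, ref), (h, t)))
    return pairs


def two_way_anova_bonferroni(
    table: pd.DataFrame,
    metric: str,
    window: str | None = None,
    alpha: float = ALPHA,
    contrasts: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    drop_censored: bool = False,
) -> TwoWayResult:
    """Two-factor (handling x treatment) ANOVA with Bonferroni contrasts.

    Type-II sums of squares on the full factorial fit; each planned
    cell contrast is a t-test on the residual mean square, its p-value
    multiplied by the number of contrasts (capped at 1).
    """
    sel = _select(table, metric, window, drop_censored).copy()
    handlings = sorted(sel["handling"].unique())
    treatments = sorted(sel["treatment"].unique())
    cells = sel.groupby(["handling", "treatment"])["value"]
    sizes = cells.size()
    for h in handlings:
        for t in treatments:
            if (h, t) not in sizes.index or sizes[(h, t)] < 2:
                raise ValueError(f"design cell ({h}, {t}) is empty or has n < 2")
    summary = cells.agg(n="size", mean="mean",
                        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))).reset_index()
    if np.ptp(sel["value"].to_numpy(float)) == 0:
        empty = pd.DataFrame()
        return TwoWayResult(metric, empty, empty, summary, tested=False,
                            note="zero total variance")
    model = smf.ols("value ~ C(handling) * C(treatment)", data=sel).fit()
    an = sm.stats.anova_lm(model, typ=2).reset_index().rename(
        columns={"index": "effect", "sum_sq": "sum_sq", "PR(>F)": "p"}
    )
    mse = model.mse_resid
    dfr = model.df_resid
    if contrasts is None:
        contrasts = [
            c for c in default_contrasts(handlings, treatments)
            if c[0] in sizes.index and c[1] in sizes.index
        ]
    m = max(len(contrasts), 1)
    rows = []
    for (cell_a, cell_b) in contrasts:
        va = sel[(sel["handling"] == cell_a[0]) & (sel["treatment"] == cell_a[1])]["value"]
        vb = sel[(sel["handling"] == cell_b[0]) & (sel["treatment"] == cell_b[1])]["value"]
        est = vb.mean() - va.mean()
        se = np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0:
            t_stat, p_raw = np.nan, np.nan
        else:
            t_stat = est / se
            p_raw = 2 * sstats.t.sf(abs(t_stat), dfr)
        p_adj = min(1.0, p_raw * m) if np.isfinite(p_raw) else np.nan
        rows.append(
            {
                "cell_a": f"{cell_a[0]}-{cell_a[1]}",
                "cell_b": f"{cell_b[0]}-{cell_b[1]}",
                "estimate": est,
                "t": t_stat,
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "significant": bool(np.isfinite(p_adj) and p_adj < alpha),
            }
        )
    return TwoWayResult(metric, an, pd.DataFrame(rows), summary)


def hourly_one_way(
    table: pd.DataFrame,
    metric_prefix: str,
    window: str,
    group_col: str = "treatment",
    groups: list[str] | None = None,
    alpha: float = ALPHA,
    correct_across_hours: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA per hour for an hourly metric family.

    Per-hour tests are emitted uncorrected by default (each hour is a
    separate planned comparison); ``correct_across_hours`` applies a
    Bonferroni factor equal to the number of hours tested.
    """
    metrics = sorted(
        m for m in table["metric"].unique() if m.startswith(metric_prefix)
    )
    rows = []
    for m in metrics:
        try:
            res = one_way_anova_tukey(table, m, window, group_col, groups, alpha)
        except ValueError:
            continue
        rows.append({"metric": m, "F": res.F, "p": res.p, "tested": res.tested})
    out = pd.DataFrame(rows)
    if correct_across_hours and not out.empty:
        out["p_corrected"] = np.minimum(1.0, out["p"] * len(out))
    return out
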