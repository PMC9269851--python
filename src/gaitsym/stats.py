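"""Cohort-level statistics for the symmetry/speed tables.

The central model is a split-plot (mixed) two-way ANOVA: age group as the
between-subjects factor, speed condition as the within-subjects (repeated)
factor.  Repeated-measures F tests are Greenhouse-Geisser corrected: Box's
epsilon is computed from the double-centered pooled within-group covariance
of the condition responses and multiplies both numerator and denominator
degrees of freedom.  Normality (Shapiro-Wilk) and homogeneity of variance
(Levene) checks, one-way ANOVAs and Bonferroni-corrected pairwise
comparisons complete the battery.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distributional checks
# ---------------------------------------------------------------------------

def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); n must be in [3, 5000]."""
    x = np.asarray(sample, float)
    if not (3 <= len(x) <= 5000):
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise StatsError("constant sample: Shapiro-Wilk undefined (zero variance)")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def levene(*groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances.

    Classic form uses deviations from the group mean; ``center='median'``
    gives the Brown-Forsythe variant.
    """
    if len(groups) < 2:
        raise StatsError("Levene's test needs >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise StatsError("every group needs n >= 2")
    if center not in ("mean", "median"):
        raise StatsError(f"unknown center {center!r}")
    f, p = sps.levene(*arrays, center=center)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# repeated-measures machinery
# ---------------------------------------------------------------------------

def _gg_epsilon(pooled_cov: np.ndarray) -> float:
    """Box's sphericity epsilon from a K x K within-subject covariance."""
    k = pooled_cov.shape[0]
    if k < 2:
        raise StatsError("epsilon needs >= 2 within-subject levels")
    row = pooled_cov.mean(axis=0, keepdims=True)
    col = pooled_cov.mean(axis=1, keepdims=True)
    grand = pooled_cov.mean()
    dc = pooled_cov - row - col + grand  # double-centered
    tr = np.trace(dc)
    denom = (k - 1) * float((dc * dc).sum())
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _wide_matrix(table: pd.DataFrame, dv: str):
    """Pivot the long cohort table to (subjects x conditions) with groups."""
    required = {"participant_id", "group", "condition", dv}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"cohort table missing columns: {sorted(missing)}")
    wide = table.pivot_table(index="participant_id", columns="condition",
                             values=dv, aggfunc="mean")
    n_before = wide.shape[0]
    wide = wide.dropna(axis=0)
    n_dropped = n_before - wide.shape[0]
    if n_dropped:
        log.warning("listwise deletion removed %d subjects with incomplete "
                    "repeated measures", n_dropped)
    groups = (table.drop_duplicates("participant_id")
              .set_index("participant_id")["group"])
    groups = groups.loc[wide.index]
    return wide, groups, n_dropped


@dataclass
class EffectResult:
    name: str
    ss: float
    df: float
    ms: float
    f: float
    p: float
    ss_error: float
    df_error: float
    epsilon: float | None = None
    df_gg: tuple | None = None
    p_gg: float | None = None


@dataclass
class MixedAnovaResult:
    dv: str
    effects: dict  # name -> EffectResult
    epsilon_gg: float
    n_subjects: int
    n_groups: int
    k_conditions: int
    n_dropped: int = 0
    ss_total: float = 0.0

    def table(self) -> pd.DataFrame:
        rows = []
        for eff in self.effects.values():
            rows.append({
                "effect": eff.name, "SS": eff.ss, "df": eff.df, "MS": eff.ms,
                "F": eff.f, "p": eff.p, "epsilon_GG": eff.epsilon,
                "df_GG": f"{eff.df_gg[0]:.1f},{eff.df_gg[1]:.1f}" if eff.df_gg else "",
                "p_GG": eff.p_gg,
            })
        return pd.DataFrame(rows)


def _f_p(f, df1, df2):
    if df1 <= 0 or df2 <= 0:
        return np.nan
    return float(sps.f.sf(f, df1, df2))


def mixed_anova(table: pd.DataFrame, dv: str = "si") -> MixedAnovaResult:
    """Split-plot ANOVA: between = group, within = condition, plus interaction.

    Expects one row per participant x condition (aggregate trials first);
    incomplete subjects are removed listwise (logged).  Greenhouse-Geisser
    adjusted p values are reported for the within and interaction effects.
    """
    wide, groups, n_dropped = _wide_matrix(table, dv)
    y = wide.to_numpy(float)
    n, k = y.shape
    labels = groups.to_numpy()
    uniq = pd.unique(labels)
    j = len(uniq)
    if n < 2 or j < 2 or k < 2:
        raise StatsError("mixed ANOVA needs >= 2 subjects, groups and conditions")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {g: y[labels == g].mean() for g in uniq}
    cell_means = {g: y[labels == g].mean(axis=0) for g in uniq}
    n_g = {g: int((labels == g).sum()) for g in uniq}
    cond_means = y.mean(axis=0)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in uniq))
    ss_subj_within = ss_between_subj - ss_group

    ss_condition = float(n * ((cond_means - grand) ** 2).sum())
    ss_cells = float(sum(n_g[g] * ((cell_means[g] - grand) ** 2).sum() for g in uniq))
    ss_interaction = ss_cells - ss_group - ss_condition
    ss_within_subj = ss_total - ss_between_subj
    ss_error_within = ss_within_subj - ss_condition - ss_interaction

    df_group, df_subj = j - 1, n - j
    df_cond = k - 1
    df_inter = (j - 1) * (k - 1)
    df_err_w = (n - j) * (k - 1)

    # pooled within-group covariance of the condition responses
    pooled = np.zeros((k, k))
    for g in uniq:
        sub = y[labels == g]
        if sub.shape[0] > 1:
            pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
    pooled /= max(n - j, 1)
    eps = _gg_epsilon(pooled)

    def effect(name, ss, df, ss_err, df_err, use_gg):
        ms, ms_err = ss / df, ss_err / df_err
        f = ms / ms_err if ms_err > 0 else 0.0
        res = EffectResult(name, ss, df, ms, f, _f_p(f, df, df_err), ss_err, df_err)
        if use_gg:
            res.epsilon = eps
            res.df_gg = (df * eps, df_err * eps)
            res.p_gg = _f_p(f, df * eps, df_err * eps)
        return res

    effects = {
        "group": effect("group", ss_group, df_group, ss_subj_within, df_subj, False),
        "condition": effect("condition", ss_condition, df_cond, ss_error_within,
                            df_err_w, True),
        "interaction": effect("interaction", ss_interaction, df_inter,
                              ss_error_within, df_err_w, True),
    }
    return MixedAnovaResult(dv=dv, effects=effects, epsilon_gg=eps, n_subjects=n,
                            n_groups=j, k_conditions=k, n_dropped=n_dropped,
                            ss_total=ss_total)


def rm_anova_oneway(table: pd.DataFrame, dv: str = "si") -> MixedAnovaResult:
    """One-way repeated-measures ANOVA (single group) with GG correction."""
    tbl = table.copy()
    tbl["group"] = "all"
    wide, _groups, n_dropped = _wide_matrix(tbl, dv)
    y = wide.to_numpy(float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise StatsError("repeated-measures ANOVA needs >= 2 subjects and conditions")
    grand = y.mean()
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_condition = float(n * ((cond_means - grand) ** 2).sum())
    resid = y - subj_means[:, None] - cond_means[None, :] + grand
    ss_error = float((resid ** 2).sum())
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    eps = _gg_epsilon(np.cov(y, rowvar=False)) if n > 1 else 1.0
    ms, ms_err = ss_condition / df_cond, ss_error / df_err
    f = ms / ms_err if ms_err > 0 else 0.0
    res = EffectResult("condition", ss_condition, df_cond, ms, f,
                       _f_p(f, df_cond, df_err), ss_error, df_err,
                       epsilon=eps, df_gg=(df_cond * eps, df_err * eps),
                       p_gg=_f_p(f, df_cond * eps, df_err * eps))
    return MixedAnovaResult(dv=dv, effects={"condition": res}, epsilon_gg=eps,
                            n_subjects=n, n_groups=1, k_conditions=k,
                            n_dropped=n_dropped,
                            ss_total=float(((y - grand) ** 2).sum()))


def oneway_anova(groups_values) -> EffectResult:
    """One-way independent-measures ANOVA over a list of group samples."""
    arrays = [np.asarray(g, float) for g in groups_values]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise StatsError("one-way ANOVA needs >= 2 groups with n >= 2")
    all_y = np.concatenate(arrays)
    grand = all_y.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = len(arrays) - 1, len(all_y) - len(arrays)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else 0.0
    return EffectResult("between", ss_between, df_b, ms_b, f,
                        _f_p(f, df_b, df_w), ss_within, df_w)


# ---------------------------------------------------------------------------
# pairwise comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseTable:
    family: str
    m: int  # family size (number of comparisons)
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)


def bonferroni_pairwise(samples: dict, paired: bool = False,
                        family: str = "") -> PairwiseTable:
    """All pairwise t-tests with Bonferroni correction.

    ``samples`` maps unit label -> 1-D values; ``paired=True`` uses paired
    t-tests (within-subject comparisons, arrays must align).  The adjusted
    p is min(1, m * p_raw) with m the number of pairs in the family, capped
    at 1 as printed in standard software output.
    """
    labels = list(samples)
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    if m < 1:
        raise StatsError("need >= 2 units for pairwise comparisons")
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(samples[a], float), np.asarray(samples[b], float)
        if paired:
            stat = sps.ttest_rel(xa, xb)
        else:
            stat = sps.ttest_ind(xa, xb, equal_var=True)
        p_raw = float(stat.pvalue)
        rows.append({"unit_a": a, "unit_b": b,
                     "mean_diff": float(xa.mean() - xb.mean()),
                     "t": float(stat.statistic), "p_raw": p_raw,
                     "p_bonferroni": min(1.0, m * p_raw)})
    return PairwiseTable(family=family, m=m, rows=pd.DataFrame(rows))
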