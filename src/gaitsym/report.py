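"""Render the full statistical battery on a cohort table.

Produces, for each dependent variable (SI and normalized speed): the
omnibus split-plot ANOVA, Bonferroni pairwise group comparisons per speed
condition, per-group repeated-measures comparisons across conditions, and
the per-condition discriminant analysis, as CSV files plus a human-readable
text summary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as gstats
from .discriminant import LdaError, lda_per_condition


def _pairwise_groups(table: pd.DataFrame, dv: str, condition: str) -> gstats.PairwiseTable:
    sub = table[table["condition"] == condition]
    samples = {g: s[dv].to_numpy() for g, s in sub.groupby("group", sort=False)}
    return gstats.bonferroni_pairwise(samples, paired=False,
                                      family=f"groups@{condition}")


def _pairwise_conditions(table: pd.DataFrame, dv: str, group: str) -> gstats.PairwiseTable:
    sub = table[table["group"] == group]
    wide = sub.pivot_table(index="participant_id", columns="condition",
                           values=dv).dropna()
    samples = {c: wide[c].to_numpy() for c in wide.columns}
    return gstats.bonferroni_pairwise(samples, paired=True, family=f"conditions@{group}")


def analysis_report(table: pd.DataFrame, out_dir, dvs=("si", "normalized_speed"),
                    alpha: float = 0.05) -> dict:
    """Run the battery and write the report files; returns the results dict.

    ``table`` is the aggregated cohort table: one row per participant x
    condition with columns participant_id, group, condition and the
    dependent variables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dvs = [dv for dv in dvs if dv in table.columns]
    conditions = list(pd.unique(table["condition"]))
    groups = list(pd.unique(table["group"]))
    results: dict = {"omnibus": {}, "oneway_condition": {}, "rm_by_group": {},
                     "pairwise_groups": {}, "pairwise_conditions": {},
                     "lda": {}, "checks": {}}
    lines: list[str] = ["Cohort analysis report", "=" * 40, ""]

    omni_rows = []
    for dv in dvs:
        res = gstats.mixed_anova(table, dv=dv)
        results["omnibus"][dv] = res
        tbl = res.table()
        tbl.insert(0, "dv", dv)
        omni_rows.append(tbl)
        lines.append(f"[{dv}] split-plot ANOVA (GG epsilon = {res.epsilon_gg:.3f})")
        for eff in res.effects.values():
            p_rep = eff.p_gg if eff.p_gg is not None else eff.p
            lines.append(f"  {eff.name:<12} F({eff.df:.1f},{eff.df_error:.1f}) = "
                         f"{eff.f:.3f}, p = {p_rep:.4g}")
        lines.append("")

        # normality / variance checks per condition
        checks = []
        for cond in conditions:
            vals = table.loc[table["condition"] == cond, dv].dropna().to_numpy()
            w, p_sw = gstats.shapiro_wilk(vals)
            grp_samples = [s[dv].dropna().to_numpy()
                           for _g, s in table[table["condition"] == cond].groupby("group")]
            f_lev, p_lev = gstats.levene(*grp_samples)
            checks.append({"dv": dv, "condition": cond, "shapiro_W": w,
                           "shapiro_p": p_sw, "levene_F": f_lev, "levene_p": p_lev})
        results["checks"][dv] = pd.DataFrame(checks)

        # per-condition one-way ANOVA over groups + pairwise matrices
        for cond in conditions:
            sub = table[table["condition"] == cond]
            samples = [s[dv].dropna().to_numpy() for _g, s in sub.groupby("group", sort=False)]
            results["oneway_condition"][(dv, cond)] = gstats.oneway_anova(samples)
            pw = _pairwise_groups(table, dv, cond)
            results["pairwise_groups"][(dv, cond)] = pw
            if dv == dvs[0]:
                pw.rows.to_csv(out / f"pairwise_groups_{cond}.csv", index=False)

        # per-group repeated-measures ANOVA + condition pairwise
        for grp in groups:
            sub = table[table["group"] == grp]
            results["rm_by_group"][(dv, grp)] = gstats.rm_anova_oneway(sub, dv=dv)
            pw = _pairwise_conditions(table, dv, grp)
            results["pairwise_conditions"][(dv, grp)] = pw
            if dv == dvs[0]:
                safe = grp.replace(" ", "_")
                pw.rows.to_csv(out / f"pairwise_conditions_{safe}.csv", index=False)

    pd.concat(omni_rows, ignore_index=True).to_csv(out / "anova_omnibus.csv", index=False)

    # discriminant analysis per condition (needs both features)
    if set(dvs) >= {"si", "normalized_speed"}:
        for cond in conditions:
            sub = table[table["condition"] == cond]
            try:
                lda = lda_per_condition(sub)
            except LdaError as exc:
                lines.append(f"[LDA {cond}] skipped: {exc}")
                continue
            results["lda"][cond] = lda
            lda.table().to_csv(out / f"lda_{cond}.csv", index=False)
            lines.append(f"[LDA {cond}] function 1: {lda.proportions[0]:.1f}% of "
                         f"variance, Wilks' Lambda = {lda.wilks_lambda[0]:.3f}, "
                         f"p = {lda.p_values[0]:.4g}")
            for name in lda.feature_names:
                lines.append(f"    loading {name}: "
                             f"{float(lda.structure_matrix.loc[name].iloc[0]):.3f}")
        lines.append("")

    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return results
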