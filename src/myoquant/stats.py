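"""Cohort statistics: mixed-design repeated-measures ANOVA, Fisher's LSD
post hoc comparisons, and Pearson regressions.

Fiber-level measurements are pseudo-replicates within a subject, so cohort
comparisons operate on subject-level means (one value per subject × time ×
fiber type × measure).  The design is 2 (group, between) × 2 (time,
within), for which sphericity is moot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

CohortResult = pd.DataFrame  # long form: subject, group, time, fiber_type, measure, value


def aggregate_subject_means(
    fiber_values: pd.DataFrame, measure: str, value_col: str = "value"
) -> CohortResult:
    """Average fiber-level values to one row per subject × time × fiber type."""
    keys = [k for k in ("subject", "group", "time", "fiber_type") if k in fiber_values.columns]
    out = fiber_values.groupby(keys, as_index=False)[value_col].mean()
    out["measure"] = measure
    return out


def _check_design(data: pd.DataFrame) -> None:
    for col in ("subject", "group", "time", "value"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    cells = data.groupby(["group", "time"])["value"]
    counts = cells.count()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("need both groups at both times with >= 2 subjects per cell")


def rm_anova(cohort: CohortResult, measure: str | None = None) -> pd.DataFrame:
    """Mixed-design ANOVA: group (between) × time (within-subject).

    Returns a frame with rows ``group``, ``time`` and ``group*time``
    (columns ``effect``, ``F``, ``df1``, ``df2``, ``p``).  Rejects designs
    with missing cells or zero residual variance.
    """
    data = cohort if measure is None else cohort[cohort["measure"] == measure]
    data = data.dropna(subset=["value"])
    _check_design(data)
    piv = data.pivot_table(index="subject", columns="time", values="value")
    if piv.isna().any().any():
        raise ValueError("incomplete within-subject data: every subject needs PRE and POST")
    resid = data.groupby(["group", "time"])["value"].var(ddof=1)
    if np.allclose(resid.fillna(0), 0):
        raise ValueError("zero residual variance in all cells; ANOVA undefined")
    aov = pg.mixed_anova(
        data=data, dv="value", within="time", subject="subject", between="group"
    )
    aov = aov.rename(
        columns={"Source": "effect", "p-unc": "p", "p_unc": "p", "DF1": "df1", "DF2": "df2"}
    )
    aov["effect"] = aov["effect"].replace({"Interaction": "group*time"})
    return aov[["effect", "F", "df1", "df2", "p"]]


def fisher_lsd(cohort: CohortResult, measure: str | None = None) -> pd.DataFrame:
    """Unadjusted pairwise comparisons between the four group×time cells.

    Within-group PRE-vs-POST pairs use the paired error of the subject
    difference scores; between-group pairs at a given time use the pooled
    two-sample error.  No multiplicity adjustment (least significant
    difference convention).
    """
    data = cohort if measure is None else cohort[cohort["measure"] == measure]
    data = data.dropna(subset=["value"])
    _check_design(data)
    cells = {k: g for k, g in data.groupby(["group", "time"])}
    rows = []
    keys = sorted(cells)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            ga, ta = a
            gb, tb = b
            xa = cells[a].set_index("subject")["value"]
            xb = cells[b].set_index("subject")["value"]
            if ga == gb and ta != tb:  # within-subject comparison
                common = xa.index.intersection(xb.index)
                d = xa.loc[common] - xb.loc[common]
                if np.allclose(d.std(ddof=1), 0):
                    t, p = (0.0, 1.0) if np.allclose(d.mean(), 0) else (np.inf, 0.0)
                else:
                    t, p = sps.ttest_rel(xa.loc[common], xb.loc[common])
            else:
                if np.allclose(np.concatenate([xa, xb]).std(ddof=1), 0):
                    t, p = 0.0, 1.0
                else:
                    t, p = sps.ttest_ind(xa, xb)
            rows.append(
                {
                    "cell_a": f"{ga}/{ta}",
                    "cell_b": f"{gb}/{tb}",
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def pearson_regression(x, y) -> dict[str, float]:
    """Pearson r with two-sided p plus the least-squares line.

    Returns ``{"r", "p", "slope", "intercept", "n"}``; requires n ≥ 3 and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x and y with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    lr = sps.linregress(x, y)
    return {
        "r": float(lr.rvalue),
        "p": float(lr.pvalue),
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "n": int(x.size),
    }
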