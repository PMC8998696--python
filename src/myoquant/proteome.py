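"""Differential protein testing and functional class scoring (FCS).

The pipeline starts from a quantified label-free abundance table (log2
scale, proteins × samples).  Proteins not detected in every sample are
removed, per-protein two-sided Student's t-tests (paired PRE-vs-POST or
unpaired between groups) are corrected for multiple testing
(Benjamini–Hochberg FDR by default), and set-level coordination is scored
with a two-sample Kolmogorov–Smirnov statistic on the ranks of in-set vs
out-of-set proteins, Benjamini–Yekutieli-corrected across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_CORRECTIONS = {"BH": "fdr_bh", "BY": "fdr_by", "bonferroni": "bonferroni"}


def filter_complete(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only proteins quantified in every sample."""
    out = table.dropna(axis=0)
    if out.empty:
        raise ValueError("no protein is quantified in all samples")
    log.info("filter_complete: retained %d of %d proteins", len(out), len(table))
    return out


def differential_test(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str, str],
    paired: bool = False,
    correction: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein two-sided t-tests for ``contrast = (column, level_a, level_b)``.

    ``metadata`` maps sample names to ``subject``/``group``/``time``.  For
    paired tests samples are aligned by subject.  Zero-variance proteins get
    undefined p (NaN) and are excluded from the adjustment.  Returns
    ``protein``, ``t``, ``log2fc`` (a − b), ``p``, ``p_adj``, ``significant``.
    """
    col, lv_a, lv_b = contrast
    meta = metadata.set_index("sample")
    a_samples = meta.index[meta[col] == lv_a]
    b_samples = meta.index[meta[col] == lv_b]
    a_samples = [s for s in a_samples if s in table.columns]
    b_samples = [s for s in b_samples if s in table.columns]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("need >= 2 samples on each side of the contrast")
    a = table[a_samples].to_numpy(float)
    b = table[b_samples].to_numpy(float)
    if paired:
        subj_a = meta.loc[a_samples, "subject"]
        subj_b = meta.loc[b_samples, "subject"]
        common = subj_a[subj_a.isin(subj_b)].tolist()
        if len(common) < 2:
            raise ValueError("paired test needs >= 2 matched subjects")
        a = table[[a_samples[list(subj_a).index(s)] for s in common]].to_numpy(float)
        b = table[[b_samples[list(subj_b).index(s)] for s in common]].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = sps.ttest_rel(a, b, axis=1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = sps.ttest_ind(a, b, axis=1)
    out = pd.DataFrame(
        {
            "protein": table.index,
            "t": t,
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "p": p,
        }
    )
    out["p_adj"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(
            out.loc[valid, "p"], method=_CORRECTIONS[correction]
        )[1]
    out["significant"] = out["p_adj"] < alpha
    out["undefined"] = ~valid
    return out


def ks_rank_statistic(in_ranks: np.ndarray, out_ranks: np.ndarray) -> float:
    """Two-sample KS statistic between in-set and out-of-set rank ECDFs."""
    return float(sps.ks_2samp(in_ranks, out_ranks, mode="auto").statistic)


def functional_class_scoring(
    ranking: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.01,
    min_size: int = 3,
    stat_col: str = "stat",
) -> pd.DataFrame:
    """KS-based set enrichment on a ranked protein list.

    ``ranking`` has columns ``protein`` and ``stat_col``; proteins are ranked
    by decreasing statistic (rank 1 = most extreme).  Each set is compared to
    its complement with a two-sided two-sample KS test on the ranks;
    ``direction`` is "enriched" when the set sits above the mid-rank.
    P-values are Benjamini–Yekutieli-adjusted across sets; sets mapping to
    fewer than ``min_size`` proteins are skipped.
    """
    df = ranking.dropna(subset=[stat_col]).copy()
    df["rank"] = df[stat_col].rank(ascending=False, method="average")
    rank_of = dict(zip(df["protein"], df["rank"]))
    n = len(df)
    rows = []
    for name, members in gene_sets.items():
        in_ranks = np.array([rank_of[p] for p in members if p in rank_of], dtype=float)
        if len(in_ranks) < min_size:
            log.info("skipping set %s: only %d mapped proteins", name, len(in_ranks))
            continue
        mask = df["protein"].isin(members)
        out_ranks = df.loc[~mask, "rank"].to_numpy(float)
        if len(out_ranks) == 0:
            stat, p = 0.0, 1.0
        else:
            res = sps.ks_2samp(in_ranks, out_ranks, mode="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        direction = "enriched" if in_ranks.mean() < (n + 1) / 2 else "depleted"
        rows.append(
            {"set": name, "ks": stat, "direction": direction, "n_mapped": len(in_ranks), "p": p}
        )
    out = pd.DataFrame(rows, columns=["set", "ks", "direction", "n_mapped", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_by")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_gmt(path, gene_sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, ""] + list(members)) + "\n")
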