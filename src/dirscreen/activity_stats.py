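"""Reporter activity normalization and two-stage regulatory-SNP nomination.

The estimand per construct and replicate is the RNA/DNA ratio of
counts-per-million (CPM) barcode abundances; the reported *activity* is that
ratio divided by the promoter-only blank construct's ratio in the same
replicate, so activity 1 means "no effect beyond the bare promoter".

A SNP is nominated in two stages:

* stage 1 — the two alleles drive expression differently: two-tailed
  two-sample Student's t-test (pooled variance) on the replicate values,
  p < 0.05;
* stage 2 — the effect is not a wash relative to the blank: the replicate
  mean activity of at least one allele is < 0.8 or > 1.2.

By default the stage-1 test runs on the raw RNA/DNA ratios rather than the
blank-calibrated activities: dividing both alleles by the same replicate's
blank ratio injects a shared noise term that an unpaired t-test cannot
cancel, making it conservative, while the allele contrast itself is
invariant to the blank.  ``calibrated_test=True`` switches to testing the
calibrated activities.  Benjamini-Hochberg q-values are reported alongside
but the nomination uses the raw p < 0.05 rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .snp_library import BLANK_ID, Construct, SampleSheet, constructs_to_frame

CPM_TOTAL = 1_000_000.0


def normalize_cpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Scale each sample column to one million total counts."""
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"all-zero count column {counts.name!r}")
        return counts * (CPM_TOTAL / total)
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {zero.index.tolist()}")
    return counts * (CPM_TOTAL / totals)


def compute_activity(
    cpm_rna: pd.Series, cpm_dna: pd.Series, blank_id: str = BLANK_ID
) -> pd.DataFrame:
    """Per-construct ratio and blank-calibrated activity for one replicate.

    Constructs with zero DNA CPM are flagged ``excluded`` (their ratio is
    undefined for this replicate).  A missing or zero blank is a hard error
    because it is the calibration point.
    """
    if blank_id not in cpm_rna.index or blank_id not in cpm_dna.index:
        raise ValueError(f"blank construct {blank_id!r} missing from the table")
    if cpm_dna[blank_id] <= 0 or cpm_rna[blank_id] <= 0:
        raise ValueError(f"blank construct {blank_id!r} has zero counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cpm_rna / cpm_dna
    blank_ratio = ratio[blank_id]
    out = pd.DataFrame(
        {
            "cpm_rna": cpm_rna,
            "cpm_dna": cpm_dna,
            "ratio": ratio,
            "activity": ratio / blank_ratio,
            "excluded": cpm_dna <= 0,
        }
    )
    out.loc[out["excluded"], ["ratio", "activity"]] = np.nan
    return out


def activity_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    blank_id: str = BLANK_ID,
) -> pd.DataFrame:
    """Tidy per-replicate activity table across cell lines.

    ``samples`` needs columns sample_id, cell_line, fraction, replicate; each
    (cell_line, replicate) must have one DNA and one RNA sample.
    """
    cpm = normalize_cpm(counts)
    frames = []
    for (cell, rep), grp in samples.groupby(["cell_line", "replicate"]):
        by_frac = dict(zip(grp["fraction"], grp["sample_id"]))
        if set(by_frac) != {"DNA", "RNA"}:
            raise ValueError(f"{cell} replicate {rep}: need exactly one DNA and one RNA sample")
        rec = compute_activity(cpm[by_frac["RNA"]], cpm[by_frac["DNA"]], blank_id)
        rec.insert(0, "replicate", rep)
        rec.insert(0, "cell_line", cell)
        rec.index.name = "construct_id"
        frames.append(rec.reset_index())
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# allele test


def _pooled_t(normal: np.ndarray, risk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t over the last axis.

    Degenerate cases: zero pooled variance with equal means -> p = 1; with
    unequal means -> p = 0.
    """
    n1, n2 = normal.shape[-1], risk.shape[-1]
    m1, m2 = normal.mean(-1), risk.mean(-1)
    v1, v2 = normal.var(-1, ddof=1), risk.var(-1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se == 0
    p = np.where(zero_var & (m1 == m2), 1.0, p)
    p = np.where(zero_var & (m1 != m2), 0.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.where(m1 == m2, 0.0, np.inf * np.sign(m2 - m1)), t)
    return t, p


def allelic_test(
    activities_normal: Sequence[float],
    activities_risk: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-tailed two-sample Student's t-test between the alleles.

    Returns ``(p_value, fold_change)`` with fold = mean(risk)/mean(normal).
    Pooled-variance (classic) form by default; ``welch=True`` uses the
    unequal-variance form.
    """
    a = np.asarray(activities_normal, dtype=float)
    b = np.asarray(activities_risk, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each allele needs at least 2 replicate activities")
    if welch:
        res = stats.ttest_ind(b, a, equal_var=False)
        p = float(res.pvalue)
        if np.isnan(p):  # zero variance in both groups
            p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        _, p = _pooled_t(a[None, :], b[None, :])
        p = float(p[0])
    return p, float(b.mean() / a.mean())


def allelic_results(
    activity: pd.DataFrame,
    constructs: Sequence[Construct] | pd.DataFrame,
    cell_line: str | None = None,
    *,
    calibrated_test: bool = False,
    welch: bool = False,
    max_excluded_replicates: int = 1,
) -> pd.DataFrame:
    """Per-SNP allelic summary for one cell line.

    ``activity`` is the tidy table from :func:`activity_table`.  SNPs with a
    construct excluded (zero DNA) in more than ``max_excluded_replicates``
    replicates are dropped from testing and flagged, since a one-sided
    allele estimate would bias the fold change.
    """
    cons = constructs if isinstance(constructs, pd.DataFrame) else constructs_to_frame(constructs)
    cons = cons[cons["allele_class"] != "blank"][["construct_id", "rs_id", "allele_class"]]
    df = activity.merge(cons, on="construct_id", how="inner")
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
    elif df["cell_line"].nunique() > 1:
        raise ValueError("multiple cell lines present; pass cell_line=")

    test_col = "activity" if calibrated_test else "ratio"
    piv_t = df.pivot(index="construct_id", columns="replicate", values=test_col)
    piv_a = df.pivot(index="construct_id", columns="replicate", values="activity")
    pairs = cons[cons["construct_id"].isin(piv_t.index)].pivot(
        index="rs_id", columns="allele_class", values="construct_id"
    )
    if not {"normal", "risk"} <= set(pairs.columns):
        raise ValueError("need both normal and risk constructs")
    pairs = pairs.dropna().sort_index()
    rs_ids = pairs.index.to_numpy()
    nt = piv_t.loc[pairs["normal"]].to_numpy()
    rt = piv_t.loc[pairs["risk"]].to_numpy()
    na = piv_a.loc[pairs["normal"]].to_numpy()
    ra = piv_a.loc[pairs["risk"]].to_numpy()
    n_rep = nt.shape[1]

    # drop SNPs whose constructs lack too many replicates (zero DNA CPM);
    # a one-sided allele estimate would bias the fold change
    n_missing = np.isnan(nt).sum(1) + np.isnan(rt).sum(1)
    complete = n_missing == 0
    droppable = n_missing > max_excluded_replicates

    p = np.full(len(rs_ids), np.nan)
    mean_normal = np.full(len(rs_ids), np.nan)
    mean_risk = np.full(len(rs_ids), np.nan)
    if complete.any():
        if welch:
            res_w = stats.ttest_ind(rt[complete], nt[complete], axis=1, equal_var=False)
            pw = np.asarray(res_w.pvalue)
            eq = rt[complete].mean(1) == nt[complete].mean(1)
            p[complete] = np.where(np.isnan(pw), np.where(eq, 1.0, 0.0), pw)
        else:
            _, p[complete] = _pooled_t(nt[complete], rt[complete])
        mean_normal[complete] = na[complete].mean(1)
        mean_risk[complete] = ra[complete].mean(1)
    # partial SNPs: test on the replicates observed for all four vectors
    for i in np.flatnonzero(~complete & ~droppable):
        keep = ~(np.isnan(nt[i]) | np.isnan(rt[i]))
        if keep.sum() < 2:
            continue
        p[i], _ = allelic_test(nt[i, keep], rt[i, keep], welch=welch)
        mean_normal[i] = na[i, keep].mean()
        mean_risk[i] = ra[i, keep].mean()

    res = pd.DataFrame(
        {
            "rs_id": rs_ids,
            "mean_normal": mean_normal,
            "mean_risk": mean_risk,
            "fold_change": mean_risk / mean_normal,
            "p_value": p,
            "n_replicates": np.where(np.isnan(p), 0, n_rep - n_missing),
            "excluded": np.isnan(p),
        }
    )
    tested = ~res["excluded"]
    res["q_value"] = np.nan
    if tested.any():
        res.loc[tested, "q_value"] = multipletests(
            res.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return classify(res)


def classify(
    results: pd.DataFrame,
    p_thresh: float = 0.05,
    low: float = 0.8,
    high: float = 1.2,
) -> pd.DataFrame:
    """Apply the two-stage rule to an allelic result table (thresholds as printed:
    p < 0.05, activity band [0.8, 1.2])."""
    res = results.copy()
    res["passes_stage1"] = (res["p_value"] < p_thresh).fillna(False)
    outside = (
        (res["mean_normal"] < low)
        | (res["mean_normal"] > high)
        | (res["mean_risk"] < low)
        | (res["mean_risk"] > high)
    )
    res["passes_stage2"] = outside.fillna(False)
    res["regulatory"] = res["passes_stage1"] & res["passes_stage2"]
    res["direction"] = np.where(res["fold_change"] > 1, "increased", "decreased")
    res.loc[res["fold_change"].isna(), "direction"] = "na"
    return res


def volcano_table(results: pd.DataFrame, p_thresh: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """log2 fold vs -log10 p per SNP, plus the direction counts at p < p_thresh."""
    res = results[~results["excluded"]].copy()
    res["log2_fold"] = np.log2(res["fold_change"])
    with np.errstate(divide="ignore"):
        res["neg_log10_p"] = -np.log10(res["p_value"])
    sig = res["p_value"] < p_thresh
    summary = {
        "n_snps": int(len(res)),
        "n_significant": int(sig.sum()),
        "n_increased": int((sig & (res["fold_change"] > 1)).sum()),
        "n_decreased": int((sig & (res["fold_change"] < 1)).sum()),
    }
    cols = ["rs_id", "log2_fold", "neg_log10_p", "p_value", "fold_change", "direction"]
    return res[cols].reset_index(drop=True), summary
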