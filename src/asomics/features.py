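"""Regulatory-feature calling and gene linking.

Covers the interpretation layer between raw signals and genes: calling
enhancer RNAs (eRNAs) at intergenic accessible regions, linking distal
features to genes by proximity or chromatin loops, pulling genes near GWAS
loci, a simple count-based differential test, and allele-specific
expression ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Interval helpers (half-open [start, end) coordinates throughout)
# ---------------------------------------------------------------------------


def gap_distance(start1: int, end1: int, start2: int, end2: int) -> int:
    """Gap between two half-open intervals; 0 if they touch or overlap."""
    if end1 <= start2:
        return start2 - end1
    if end2 <= start1:
        return start1 - end2
    return 0


def _min_gap_to_set(chrom, start, end, table: pd.DataFrame) -> float:
    sub = table[table["chrom"] == chrom]
    if sub.empty:
        return float("inf")
    gaps = np.maximum(
        sub["start"].to_numpy() - end, start - sub["end"].to_numpy()
    )
    return float(max(0, gaps.min()))


# ---------------------------------------------------------------------------
# eRNA calling
# ---------------------------------------------------------------------------


def call_ernas(
    peaks: pd.DataFrame,
    rna_reads: pd.DataFrame,
    coding: pd.DataFrame,
    min_distance: int = 3_000,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Call eRNAs: uniquely mapping RNA reads inside accessible peaks lying
    strictly more than ``min_distance`` from any coding sequence.

    ``peaks`` needs ``peak, chrom, start, end``; ``rna_reads`` needs
    ``chrom, pos, unique``; ``coding`` needs ``chrom, start, end``.
    Returns the qualifying peaks with their unique-read counts.
    """
    uniq = rna_reads[rna_reads["unique"]]
    rows = []
    for pk in peaks.itertuples(index=False):
        d = _min_gap_to_set(pk.chrom, pk.start, pk.end, coding)
        if not d > min_distance:
            continue
        n = int(
            (
                (uniq["chrom"] == pk.chrom)
                & (uniq["pos"] >= pk.start)
                & (uniq["pos"] < pk.end)
            ).sum()
        )
        if n >= min_reads:
            rows.append((pk.peak, pk.chrom, pk.start, pk.end, n, d))
    return pd.DataFrame(
        rows, columns=["erna", "chrom", "start", "end", "unique_reads",
                       "coding_distance"]
    )


# ---------------------------------------------------------------------------
# Gene linking
# ---------------------------------------------------------------------------


def _overlap_len(s1, e1, s2, e2) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def link_to_genes(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    loops: pd.DataFrame | None = None,
    max_distance: int = 50_000,
    min_anchor_overlap: float = 0.5,
) -> pd.DataFrame:
    """Link distal features to genes by proximity or chromatin loops.

    A feature is linked to a gene when the gap between them is strictly
    below ``max_distance``, or when a loop anchor covers strictly more than
    ``min_anchor_overlap`` of the feature (overlap measured relative to the
    feature's own length), in which case the link target is the gene at the
    loop's other anchor.

    ``features`` needs an id column (first column), ``chrom``, ``start``,
    ``end``.  ``loops`` needs ``chrom1, start1, end1, gene`` with the first
    anchor over the feature side.  Returns one row per (feature, gene,
    evidence) link.
    """
    feat_id_col = features.columns[0]
    rows = []
    for ft in features.itertuples(index=False):
        fid = getattr(ft, feat_id_col)
        flen = ft.end - ft.start
        sub = genes[genes["chrom"] == ft.chrom]
        for g in sub.itertuples(index=False):
            d = gap_distance(ft.start, ft.end, g.start, g.end)
            if d < max_distance:
                rows.append((fid, g.gene, "proximity", d))
        if loops is not None:
            for lp in loops.itertuples(index=False):
                if lp.chrom1 != ft.chrom:
                    continue
                ov = _overlap_len(ft.start, ft.end, lp.start1, lp.end1)
                if flen > 0 and ov / flen > min_anchor_overlap:
                    rows.append((fid, lp.gene, "loop", None))
    out = pd.DataFrame(rows, columns=["feature", "gene", "evidence", "distance"])
    return out.drop_duplicates(subset=["feature", "gene", "evidence"]).reset_index(
        drop=True
    )


def genes_near_loci(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """Genes whose body lies within ``window`` of a lead SNP (gap distance
    <= window).  Returns (snp, gene, distance) rows."""
    rows = []
    for sp in snps.itertuples(index=False):
        sub = genes[genes["chrom"] == sp.chrom]
        for g in sub.itertuples(index=False):
            d = gap_distance(sp.pos, sp.pos + 1, g.start, g.end)
            if d <= window:
                rows.append((sp.snp, g.gene, d))
    return pd.DataFrame(rows, columns=["snp", "gene", "distance"])


# ---------------------------------------------------------------------------
# Differential features
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per column."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    return counts / totals * 1e6


def differential_features(
    counts: pd.DataFrame,
    groups: dict,
    alpha: float = 0.05,
    min_fold_change: float = 1.5,
) -> pd.DataFrame:
    """Case/control differential test on a count matrix.

    Counts are CPM-normalised; Welch's t-test is applied per feature on
    log2(CPM + 1); p-values are Benjamini-Hochberg adjusted.  The fold
    change is the ratio of group CPM means, and a feature is called
    significant when padj < ``alpha`` and the fold change exceeds
    ``min_fold_change`` in either direction.
    """
    case_cols = [s for s in counts.columns if groups[s] == "case"]
    ctrl_cols = [s for s in counts.columns if groups[s] == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least two samples per group")
    norm = cpm(counts)
    logn = np.log2(norm + 1)
    t, p = stats.ttest_ind(
        logn[case_cols], logn[ctrl_cols], axis=1, equal_var=False
    )
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    mean_case = norm[case_cols].mean(axis=1).to_numpy()
    mean_ctrl = norm[ctrl_cols].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_ctrl
        log2fc = np.log2(fc)
    res = pd.DataFrame(
        {
            "feature": counts.index,
            "mean_case_cpm": mean_case,
            "mean_control_cpm": mean_ctrl,
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "t": t,
            "p": p,
            "padj": padj,
        }
    )
    fc_extreme = np.maximum(fc, np.where(fc > 0, 1 / fc, np.inf))
    res["significant"] = (res["padj"] < alpha) & (fc_extreme > min_fold_change)
    return res.reset_index(drop=True)


def select_top_features(results: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-``n`` significant features, ranked by (padj ascending, absolute
    log2 fold change descending, feature id ascending) for a stable order."""
    sig = results[results["significant"]].copy()
    sig["_abs"] = sig["log2_fold_change"].abs()
    sig = sig.sort_values(
        ["padj", "_abs", "feature"], ascending=[True, False, True]
    ).drop(columns="_abs")
    return sig.head(n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Allele-specific expression
# ---------------------------------------------------------------------------


def allelic_ratio(
    allele_counts: pd.DataFrame, min_reads: int = 5
) -> pd.DataFrame:
    """Per-variant allelic expression over heterozygous individuals.

    ``allele_counts`` needs ``variant, individual, ref_reads, alt_reads``
    with one row per heterozygous individual.  Individuals with fewer than
    ``min_reads`` total mapping reads are dropped; the ratio is pooled
    alternate-allele fraction over the remaining individuals.
    """
    ac = allele_counts.copy()
    ac["total"] = ac["ref_reads"] + ac["alt_reads"]
    ac = ac[ac["total"] >= min_reads]
    rows = []
    for variant, grp in ac.groupby("variant"):
        tot = int(grp["total"].sum())
        alt = int(grp["alt_reads"].sum())
        rows.append((variant, len(grp), alt / tot if tot else np.nan, alt, tot))
    return pd.DataFrame(
        rows,
        columns=["variant", "n_individuals", "alt_fraction", "alt_reads",
                 "total_reads"],
    )
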