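"""Enrichment statistics: GWAS-locus overlap and pathway over-representation.

Locus enrichment asks whether a class of regulatory features falls near
disease-associated SNPs more often than expected, at increasingly stringent
association tiers, using Fisher exact tests with Woolf confidence
intervals.  Pathway enrichment scores gene sets with the hypergeometric
tail and Benjamini-Hochberg control.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default GWAS p-value tiers, strict upper bounds from permissive to
#: genome-wide significant
DEFAULT_TIERS = (1.0, 0.1, 5e-7, 5e-8)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def _odds_ratio_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio with Woolf (log-normal) 95% CI.

    When any cell is zero, the Haldane-Anscombe 0.5 correction is applied
    to the odds ratio and its interval only — never to the p-value.
    """
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    orr = (a2 * d2) / (b2 * c2)
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    return orr, orr * math.exp(-Z_95 * se), orr * math.exp(Z_95 * se)


def fisher_enrichment(a: int, b: int, c: int, d: int) -> dict:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]] with odds ratio
    and Woolf CI.  ``a`` = in-class hits, ``b`` = in-class misses, ``c`` =
    out-of-class hits, ``d`` = out-of-class misses."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    orr, lo, hi = _odds_ratio_ci(a, b, c, d)
    return {"odds_ratio": orr, "ci_low": lo, "ci_high": hi, "p": float(p),
            "table": [[a, b], [c, d]]}


def locus_enrichment(
    features: pd.DataFrame,
    snps: pd.DataFrame,
    class_column: str = "distal",
    tiers: tuple = DEFAULT_TIERS,
    window: int = 500_000,
) -> pd.DataFrame:
    """Enrichment of a feature class near associated SNPs, per p-value tier.

    For each tier, a SNP is retained when its association p is strictly
    below the tier threshold, and a feature counts as a hit when it lies
    within ``window`` of any retained SNP (gap distance).  The 2x2 table
    contrasts hit rates between features inside and outside the class given
    by boolean ``class_column``; Bonferroni adjustment is applied across
    all tier x class tests reported.  Tiers where either margin of the
    table is empty are flagged non-assessable with NaN statistics.
    """
    in_class = features[class_column].astype(bool).to_numpy()
    rows = []
    for tier in tiers:
        kept = snps[snps["p"] < tier]
        hit = np.zeros(len(features), dtype=bool)
        for i, ft in enumerate(features.itertuples(index=False)):
            sub = kept[kept["chrom"] == ft.chrom]
            if sub.empty:
                continue
            gaps = np.maximum(
                sub["pos"].to_numpy() - ft.end,
                ft.start - sub["pos"].to_numpy() - 1,
            )
            hit[i] = (np.maximum(gaps, 0) <= window).any()
        a = int((hit & in_class).sum())
        b = int((~hit & in_class).sum())
        c = int((hit & ~in_class).sum())
        d = int((~hit & ~in_class).sum())
        assessable = (a + b) > 0 and (c + d) > 0 and (a + c) > 0 and (b + d) > 0
        if assessable:
            res = fisher_enrichment(a, b, c, d)
        else:
            res = {"odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "p": np.nan}
        rows.append(
            {
                "tier": tier,
                "class": class_column,
                "n_snps": len(kept),
                "hits_in_class": a,
                "miss_in_class": b,
                "hits_out_class": c,
                "miss_out_class": d,
                "odds_ratio": res["odds_ratio"],
                "ci_low": res["ci_low"],
                "ci_high": res["ci_high"],
                "p": res["p"],
                "assessable": assessable,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), len(out))
    return out


def bonferroni(p: np.ndarray, n_tests: int) -> np.ndarray:
    """Bonferroni adjustment capped at 1; NaN passes through."""
    return np.minimum(np.asarray(p, dtype=float) * n_tests, 1.0)


# ---------------------------------------------------------------------------
# Pathway over-representation
# ---------------------------------------------------------------------------


def hypergeom_enrichment(x: int, n: int, K: int, N: int) -> dict:
    """One-sided hypergeometric over-representation test.

    ``x`` hits in a selection of size ``n`` from a universe of ``N`` genes
    of which ``K`` are in the pathway; p = P(X >= x).  The Z-score is the
    exact hypergeometric standardisation of ``x``.
    """
    if N <= 0:
        raise ValueError("empty gene universe")
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(n, K)):
        raise ValueError("inconsistent hypergeometric parameters")
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    mean = n * K / N
    var = mean * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
    z = (x - mean) / math.sqrt(var) if var > 0 else np.nan
    return {"p": p, "z": z, "expected": mean}


def pathway_enrichment(
    selected: set,
    pathways: dict,
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene selection in each pathway.

    ``pathways`` maps pathway name to a gene set; genes outside
    ``universe`` are ignored.  Returns per-pathway hits, expectation,
    Z-score, raw p and Benjamini-Hochberg q.
    """
    if not universe:
        raise ValueError("empty gene universe")
    sel = set(selected) & set(universe)
    N, n = len(universe), len(sel)
    rows = []
    for name, members in pathways.items():
        mem = set(members) & set(universe)
        K = len(mem)
        x = len(sel & mem)
        r = hypergeom_enrichment(x, n, K, N)
        rows.append((name, K, x, r["expected"], r["z"], r["p"]))
    out = pd.DataFrame(
        rows, columns=["pathway", "size", "hits", "expected", "z", "p"]
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out
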