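"""Network-based therapeutic-target prioritisation.

Evidence from GWAS proximity, eQTL colocalisation, chromatin contacts,
differential expression and differential regulatory activity is assembled
into a gene-by-predictor matrix, diffused over a protein/gene interaction
network with a random walk with restart, rescaled to comparable ranks,
and combined into a 0-5 star rating.  Ratings are benchmarked by AUC
against known positives, and top-rated genes are expanded into their
maximum-scoring connected pathway neighbourhood.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

PREDICTORS = (
    "nGene", "eGene", "cGene", "RNA", "ATAC", "eRNA", "H3K4me3", "H3K27ac"
)

#: decay span of GWAS proximity evidence, in bp
NGENE_SPAN = 500_000


# ---------------------------------------------------------------------------
# Predictor matrix
# ---------------------------------------------------------------------------


def build_predictor_matrix(
    genes: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    eqtl_genes: pd.DataFrame | None = None,
    loop_links: pd.DataFrame | None = None,
    rna_results: pd.DataFrame | None = None,
    feature_links: dict | None = None,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Assemble the gene x predictor evidence matrix (non-negative scores).

    - ``nGene``: GWAS proximity; for each gene the maximum over SNPs of
      ``-log10(p) * max(0, 1 - d / 500000)`` with ``d`` the gap between SNP
      and gene body.
    - ``eGene``: ``-log10(p)`` from an eQTL gene table (``gene``, optional
      ``p``; 1.0 when no p column).
    - ``cGene``: chromatin-contact evidence from loop links (``gene``,
      optional ``p``; 1.0 per linked gene when no p column).
    - ``RNA``: ``-log10(padj)`` from a differential-expression table
      indexed by ``feature`` = gene id (all genes, significant or not).
    - ``ATAC``/``eRNA``/``H3K4me3``/``H3K27ac``: from ``feature_links``, a
      mapping of predictor name to a (links, results) pair where ``links``
      has ``feature, gene`` rows and ``results`` is a differential table
      over the features; each gene scores the maximum ``-log10(padj)`` over
      its linked features (significant features only when
      ``significant_only``).

    Genes appearing in evidence but absent from ``genes`` trigger a warning
    and are skipped.  Missing evidence sources leave zero columns.
    """
    gene_ids = list(genes["gene"])
    known = set(gene_ids)
    X = pd.DataFrame(0.0, index=gene_ids, columns=list(PREDICTORS))

    def _check(gs, source):
        unknown = set(gs) - known
        if unknown:
            warnings.warn(
                f"{len(unknown)} unknown gene id(s) in {source} evidence "
                f"skipped (e.g. {sorted(unknown)[:3]})", stacklevel=3
            )
        return [g for g in gs if g in known]

    if snps is not None and len(snps):
        for g in genes.itertuples(index=False):
            sub = snps[snps["chrom"] == g.chrom]
            if sub.empty:
                continue
            # gap between the SNP point and the gene body (half-open)
            d = np.maximum(
                np.maximum(sub["pos"].to_numpy() - g.end,
                           g.start - sub["pos"].to_numpy() - 1),
                0,
            )
            w = np.maximum(0.0, 1.0 - d / NGENE_SPAN)
            score = -np.log10(sub["p"].to_numpy()) * w
            X.loc[g.gene, "nGene"] = max(0.0, float(score.max()))

    for col, table in (("eGene", eqtl_genes), ("cGene", loop_links)):
        if table is None or not len(table):
            continue
        for g in _check(table["gene"], col):
            rows = table[table["gene"] == g]
            if "p" in table.columns:
                val = float(-np.log10(rows["p"]).max())
            else:
                val = 1.0
            X.loc[g, col] = max(X.loc[g, col], val)

    if rna_results is not None and len(rna_results):
        for g in _check(rna_results["feature"], "RNA"):
            padj = rna_results.loc[rna_results["feature"] == g, "padj"].min()
            X.loc[g, "RNA"] = float(-np.log10(max(padj, 1e-300)))

    for pred, (links, results) in (feature_links or {}).items():
        if pred not in PREDICTORS:
            raise ValueError(f"unknown predictor {pred!r}")
        res = results
        if significant_only and "significant" in res.columns:
            res = res[res["significant"]]
        score_of = {
            f: float(-np.log10(max(p, 1e-300)))
            for f, p in zip(res["feature"], res["padj"])
        }
        merged = links[links["feature"].isin(score_of)]
        for g in _check(merged["gene"].unique(), pred):
            feats = merged.loc[merged["gene"] == g, "feature"]
            X.loc[g, pred] = max(score_of[f] for f in feats)

    return X


# ---------------------------------------------------------------------------
# Network propagation
# ---------------------------------------------------------------------------


class Network:
    """Undirected gene network with a column-normalised walk matrix.

    Isolated genes get a self-loop so every column of the transition
    matrix sums to one.
    """

    def __init__(self, edges: pd.DataFrame, nodes: list):
        self.nodes = list(nodes)
        self._index = {g: i for i, g in enumerate(self.nodes)}
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b in zip(edges.iloc[:, 0], edges.iloc[:, 1]):
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge ({a}, {b}) references unknown gene")
            g.add_edge(a, b)
        for n in self.nodes:
            if g.degree(n) == 0:
                g.add_edge(n, n)
        self.graph = g
        A = nx.to_numpy_array(g, nodelist=self.nodes)
        self.W = A / A.sum(axis=0, keepdims=True)

    @property
    def n(self) -> int:
        return len(self.nodes)


def network_propagate(
    net: Network,
    seeds: np.ndarray,
    restart: float = 0.75,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    name: str = "seed vector",
) -> np.ndarray:
    """Random walk with restart: iterate p <- (1 - r) W p + r p0 until the
    L1 change falls below ``tol``.

    The seed vector is L1-normalised; since W is column-stochastic the
    propagated vector conserves total probability mass.  An all-zero seed
    vector is an error (named so a failing predictor is identifiable).
    """
    p0 = np.asarray(seeds, dtype=float)
    if p0.shape != (net.n,):
        raise ValueError("seed vector length does not match network")
    if (p0 < 0).any():
        raise ValueError("seed scores must be non-negative")
    total = p0.sum()
    if total == 0:
        raise ValueError(f"cannot propagate {name}: all seed scores are zero")
    p0 = p0 / total
    p = p0.copy()
    for _ in range(max_iter):
        nxt = (1 - restart) * (net.W @ p) + restart * p0
        if np.abs(nxt - p).sum() < tol:
            return nxt
        p = nxt
    warnings.warn("random walk did not converge within max_iter", stacklevel=2)
    return p


def propagate_matrix(
    net: Network, X: pd.DataFrame, restart: float = 0.75, tol: float = 1e-6
) -> pd.DataFrame:
    """Propagate every predictor column of X over the network."""
    out = {}
    for col in X.columns:
        out[col] = network_propagate(
            net, X[col].reindex(net.nodes).to_numpy(), restart, tol, name=col
        )
    return pd.DataFrame(out, index=net.nodes)


# ---------------------------------------------------------------------------
# Combination and benchmarking
# ---------------------------------------------------------------------------


def combine_predictors(P: pd.DataFrame) -> pd.DataFrame:
    """Combine propagated predictor columns into a 0-5 star rating.

    Each column is rescaled to (0, 1] by fractional rank (average ranks for
    ties, divided by the number of genes); the rating is five times the
    mean rescaled score.  Output is sorted by rating descending, gene id
    ascending.
    """
    ranks = P.apply(lambda c: stats.rankdata(c) / len(c), axis=0)
    rating = 5.0 * ranks.mean(axis=1)
    out = pd.DataFrame({"gene": P.index, "rating": rating.to_numpy()})
    out = out.sort_values(["rating", "gene"], ascending=[False, True])
    return out.reset_index(drop=True)


def benchmark_auc(
    ratings: pd.DataFrame,
    positives: list,
    n_negatives: int | None = None,
    seed: int = 0,
) -> dict:
    """AUC of the rating at recovering known positives.

    Negatives are sampled uniformly without replacement from the non-positive
    genes (all of them when ``n_negatives`` is None).  The AUC uses the
    rank formulation with half credit for ties.  Also returns ROC points.
    """
    score = dict(zip(ratings["gene"], ratings["rating"]))
    pos = [g for g in positives if g in score]
    if not pos:
        raise ValueError("no positives present in the rating table")
    neg_pool = [g for g in score if g not in set(pos)]
    rng = np.random.default_rng(seed)
    if n_negatives is None:
        neg = neg_pool
    else:
        if n_negatives > len(neg_pool):
            raise ValueError(
                f"requested {n_negatives} negatives but only "
                f"{len(neg_pool)} non-positive genes available"
            )
        neg = list(rng.choice(neg_pool, size=n_negatives, replace=False))
    y = np.array([1] * len(pos) + [0] * len(neg))
    s = np.array([score[g] for g in pos] + [score[g] for g in neg])
    r = stats.rankdata(s)
    n1, n0 = len(pos), len(neg)
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-s, kind="stable")
    tp = np.cumsum(y[order] == 1)
    fp = np.cumsum(y[order] == 0)
    roc = pd.DataFrame({"fpr": fp / n0, "tpr": tp / n1})
    return {"auc": float(auc), "n_positives": n1, "n_negatives": n0, "roc": roc}


# ---------------------------------------------------------------------------
# Pathway crosstalk around top targets
# ---------------------------------------------------------------------------


@dataclass
class CrosstalkSubnetwork:
    genes: list
    score: float
    seed_gene: str
    method: str
    edges: list = field(default_factory=list)


def _subgraph_score(scores: dict, nodes) -> float:
    return float(sum(scores[n] for n in nodes))


def _exact_best(g: nx.Graph, scores: dict, seed: str) -> tuple[list, float]:
    """Maximum-score connected subgraph containing ``seed`` by exhaustive
    enumeration over node subsets (graphs of a dozen-odd nodes)."""
    others = [n for n in g.nodes if n != seed]
    best_nodes, best = [seed], scores[seed]
    for k in range(1, len(others) + 1):
        for combo in itertools.combinations(others, k):
            nodes = (seed, *combo)
            sub = g.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            sc = _subgraph_score(scores, nodes)
            if sc > best:
                best, best_nodes = sc, list(nodes)
    return best_nodes, best


def _greedy_best(g: nx.Graph, scores: dict, seed: str) -> tuple[list, float]:
    """Greedy expansion with two-step bridging for large graphs."""
    current = {seed}
    improved = True
    while improved:
        improved = False
        frontier = {
            nb for n in current for nb in g.neighbors(n)
        } - current
        best_gain, best_add = 0.0, None
        for nb in frontier:
            gain = scores[nb]
            if gain > best_gain:
                best_gain, best_add = gain, {nb}
            # two-step bridge: a negative neighbour opening a positive node
            for nb2 in g.neighbors(nb):
                if nb2 in current or nb2 == nb:
                    continue
                gain2 = scores[nb] + scores[nb2]
                if gain2 > best_gain:
                    best_gain, best_add = gain2, {nb, nb2}
        if best_add and best_gain > 0:
            current |= best_add
            improved = True
    return sorted(current), _subgraph_score(scores, current)


def pathway_crosstalk(
    net: Network,
    ratings: pd.DataFrame,
    top_fraction: float = 0.1,
    max_exact_nodes: int = 15,
) -> CrosstalkSubnetwork:
    """Pathway neighbourhood of the top-rated gene.

    Node scores are rating minus the (1 - top_fraction) rating quantile, so
    roughly the top fraction of genes score positive.  The result is the
    maximum-score connected subgraph containing the top-rated gene: found
    exactly for networks up to ``max_exact_nodes`` nodes, and by greedy
    expansion with two-step bridging beyond that size.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    rating = dict(zip(ratings["gene"], ratings["rating"]))
    theta = float(np.quantile(list(rating.values()), 1 - top_fraction))
    scores = {g: rating[g] - theta for g in net.nodes}
    seed = ratings.iloc[0]["gene"]
    g = self_free_graph(net)
    if net.n <= max_exact_nodes:
        nodes, score = _exact_best(g, scores, seed)
        method = "exact"
    else:
        nodes, score = _greedy_best(g, scores, seed)
        method = "greedy"
    edges = [(a, b) for a, b in g.subgraph(nodes).edges if a != b]
    return CrosstalkSubnetwork(sorted(nodes), score, seed, method, edges)


def self_free_graph(net: Network) -> nx.Graph:
    """Copy of the network graph without self-loops."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from((a, b) for a, b in net.graph.edges if a != b)
    return g
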