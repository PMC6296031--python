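"""Ensemble co-expression network inference and consensus modules.

The ensemble strategy: several base inference methods each score every gene
pair; per method, edges are ranked by descending weight (average ranks on
ties); the per-edge mean rank across methods is the aggregate score; the
final edge set is chosen by greedy local-neighborhood selection — for each
gene, candidate neighbors are added in aggregate-rank order to a linear
regression of that gene on its selected neighbors while the Bayesian
Information Criterion strictly decreases — and a pair is an edge if either
endpoint selects it.

Base methods (symmetric non-negative weights):

- ``corr_adjacency``: soft-threshold correlation adjacency |r|**beta.
- ``mi_aracne``: binned mutual information with data-processing-inequality
  pruning (the weakest edge of a triangle is zeroed when it falls below
  (1 - eps) of the smaller of the other two).
- ``lasso_neighborhood`` / ``ridge_neighborhood``: per-gene sparse/dense
  linear neighborhood regressions, symmetrized by the max |coefficient|.
- ``mrnet_like``: MI relevance minus mean redundancy (MRMR-flavoured).
- ``c3net_like``: an MI edge survives only if it is the maximal MI of at
  least one of its endpoints.

Modules are then found by consensus: several community-detection algorithms
are run on the selected network, a co-assignment frequency matrix is
averaged over them, pairs co-assigned in at least half the methods form the
consensus graph, and a final seeded Louvain pass on that graph gives the
module partition (numbered by decreasing size). Modules are annotated with
cell types by Fisher enrichment against marker sets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import igraph as ig
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BASE_METHODS",
    "COMMUNITY_METHODS",
    "GeneNetwork",
    "mutual_information_matrix",
    "infer_base",
    "aggregate_ranks",
    "select_edges_bic",
    "consensus_modules",
    "annotate_celltypes",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=1, keepdims=True)) / sd


def _corr_adjacency(x: np.ndarray, beta: float = 6.0) -> np.ndarray:
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    return np.abs(np.nan_to_num(r)) ** beta


def _bin_codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Equal-frequency binning into ceil(n_samples ** (1/3)) bins per gene.

    Cube-root binning keeps the plug-in MI bias (~(B-1)^2 / 2n nats) small;
    with B ~ sqrt(n) the bias is ~0.5 nats independent of n, which compresses
    MI ratios enough to defeat the multiplicative DPI tolerance.
    """
    n = x.shape[1]
    n_bins = max(3, int(np.ceil(n ** (1.0 / 3.0))))
    codes = np.empty_like(x, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for i in range(x.shape[0]):
        edges = np.unique(np.quantile(x[i], qs))
        codes[i] = np.searchsorted(edges, x[i], side="right")
    return codes, n_bins


def mutual_information_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise mutual information (nats) from equal-frequency binned data."""
    codes, n_bins = _bin_codes(x)
    g, n = codes.shape
    mi = np.zeros((g, g))
    marg = [np.bincount(codes[i], minlength=n_bins) / n for i in range(g)]
    for i in range(g):
        for j in range(i + 1, g):
            joint = np.bincount(codes[i] * n_bins + codes[j], minlength=n_bins * n_bins)
            joint = joint.reshape(n_bins, n_bins) / n
            outer = np.outer(marg[i], marg[j])
            nz = joint > 0
            val = float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return mi


def _aracne(x: np.ndarray, eps: float = 0.15) -> np.ndarray:
    mi = mutual_information_matrix(x)
    w = mi.copy()
    g = w.shape[0]
    remove = np.zeros_like(w, dtype=bool)
    for k in range(g):
        col = mi[:, k]
        # min(MI[i,k], MI[j,k]) for every pair, only over existing triangles
        pair_min = np.minimum.outer(col, col)
        valid = (col[:, None] > 0) & (col[None, :] > 0) & (mi > 0)
        remove |= valid & (mi < (1.0 - eps) * pair_min)
    np.fill_diagonal(remove, False)
    w[remove] = 0.0
    return w


def _neighborhood(x: np.ndarray, kind: str) -> np.ndarray:
    from sklearn.linear_model import LassoLarsIC, Ridge

    z = _zscore(x)
    g = z.shape[0]
    coefs = np.zeros((g, g))
    for j in range(g):
        y = z[j]
        mask = np.arange(g) != j
        design = z[mask].T
        if kind == "lasso":
            model = LassoLarsIC(criterion="bic")
        else:
            model = Ridge(alpha=1.0)
        model.fit(design, y)
        coefs[j, mask] = np.abs(model.coef_)
    return np.maximum(coefs, coefs.T)


def _mrnet_like(x: np.ndarray) -> np.ndarray:
    mi = mutual_information_matrix(x)
    g = mi.shape[0]
    if g < 3:
        return mi
    row_mean = (mi.sum(axis=1)[:, None] - mi) / (g - 2)  # mean MI of i excluding pair j
    score = mi - 0.5 * (row_mean + row_mean.T)
    np.fill_diagonal(score, 0.0)
    return np.maximum(score, 0.0)


def _c3net_like(x: np.ndarray) -> np.ndarray:
    mi = mutual_information_matrix(x)
    g = mi.shape[0]
    keep = np.zeros_like(mi, dtype=bool)
    best = mi.argmax(axis=1)
    rows = np.arange(g)
    keep[rows, best] = mi[rows, best] > 0
    keep |= keep.T
    return np.where(keep, mi, 0.0)


BASE_METHODS = {
    "corr_adjacency": _corr_adjacency,
    "mi_aracne": _aracne,
    "lasso_neighborhood": lambda x: _neighborhood(x, "lasso"),
    "ridge_neighborhood": lambda x: _neighborhood(x, "ridge"),
    "mrnet_like": _mrnet_like,
    "c3net_like": _c3net_like,
}


def infer_base(method: str, data: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Symmetric non-negative edge weights for one base method.

    ``data`` is a gene x sample DataFrame; returns a gene x gene DataFrame
    with a zero diagonal.
    """
    if method not in BASE_METHODS:
        raise ValueError(f"unknown method {method!r}; available: {sorted(BASE_METHODS)}")
    w = BASE_METHODS[method](data.values, **kwargs)
    np.fill_diagonal(w, 0.0)
    return pd.DataFrame(w, index=data.index, columns=data.index)


def _pair_index(genes) -> pd.MultiIndex:
    pairs = [(genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))]
    return pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"])


def aggregate_ranks(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-method descending-weight edge ranks and their mean.

    Ranks are averaged on ties (1 = strongest edge). Returns a DataFrame
    indexed by unordered pair with one rank column per method plus
    ``mean_rank``, ordered by (mean_rank, lexicographic pair).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 methods to aggregate")
    items = sorted(tables.items())
    genes = list(items[0][1].index)
    for name, table in items:
        if list(table.index) != genes or list(table.columns) != genes:
            raise ValueError(f"method {name!r} has a mismatched gene universe")
    iu = np.triu_indices(len(genes), k=1)
    out = pd.DataFrame(index=_pair_index(genes))
    for name, table in items:
        out[f"rank_{name}"] = rankdata(-table.values[iu], method="average")
    out["mean_rank"] = out[[c for c in out.columns if c.startswith("rank_")]].mean(axis=1)
    return out.sort_values(
        ["mean_rank", "gene_a", "gene_b"], kind="stable"
    )


@dataclass
class GeneNetwork:
    """Undirected gene network with aggregate edge ranks and modules."""

    nodes: list[str]
    edges: pd.DataFrame  # columns gene_a, gene_b, mean_rank
    modules: pd.Series | None = None  # gene -> module id
    celltype_of_module: dict[int, str] = field(default_factory=dict)
    #: per-node count of neighbors chosen during BIC selection (selection
    #: view; union degree can be larger since either endpoint may select).
    neighborhood_sizes: pd.Series | None = None

    @property
    def degree(self) -> pd.Series:
        counts = pd.Series(0, index=pd.Index(self.nodes, name="gene"), dtype=int)
        for col in ("gene_a", "gene_b"):
            vc = self.edges[col].value_counts()
            counts = counts.add(vc, fill_value=0)
        return counts.astype(int)

    def to_igraph(self) -> ig.Graph:
        index = {g: i for i, g in enumerate(self.nodes)}
        es = [(index[a], index[b]) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])]
        graph = ig.Graph(n=len(self.nodes), edges=es)
        graph.vs["name"] = self.nodes
        return graph

    def to_tsv(self, edges_path, modules_path=None) -> None:
        self.edges.to_csv(edges_path, sep="\t", index=False)
        if modules_path is not None and self.modules is not None:
            table = self.modules.rename("module_id").to_frame()
            table["celltype"] = [
                self.celltype_of_module.get(m, "unassigned") for m in table["module_id"]
            ]
            table.index.name = "gene"
            table.to_csv(modules_path, sep="\t")


def _bic(y: np.ndarray, design: np.ndarray | None) -> float:
    n = len(y)
    if design is None or design.shape[1] == 0:
        resid = y - y.mean()
        k = 1
    else:
        x = np.column_stack([np.ones(n), design])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        k = x.shape[1]
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + k * np.log(n)


def select_edges_bic(
    ranks: pd.DataFrame, data: pd.DataFrame, max_neighbors: int = 10
) -> GeneNetwork:
    """Greedy BIC neighborhood selection over aggregate-rank-ordered candidates.

    For each gene, candidate neighbors (its pairs in ascending mean-rank
    order) are added to an OLS regression of the gene on its selected
    neighbors while BIC strictly decreases; selection stops at the first
    non-improving candidate or at ``max_neighbors``. An edge is kept if
    either endpoint selected it.
    """
    genes = list(data.index)
    n = data.shape[1]
    if n <= max_neighbors + 1:
        raise ValueError("need n_samples > max_neighbors + 1 for BIC selection")
    x = data.values
    gi = {g: i for i, g in enumerate(genes)}

    candidates: dict[str, list[tuple[float, str, tuple[str, str]]]] = {g: [] for g in genes}
    for (a, b), mean_rank in ranks["mean_rank"].items():
        candidates[a].append((mean_rank, b, (a, b)))
        candidates[b].append((mean_rank, a, (a, b)))

    selected: set[tuple[str, str]] = set()
    n_chosen: dict[str, int] = {}
    for g in genes:
        y = x[gi[g]]
        chosen: list[int] = []
        best = _bic(y, None)
        for _, other, pair in sorted(candidates[g], key=lambda t: (t[0], t[1])):
            trial = chosen + [gi[other]]
            bic = _bic(y, x[trial].T)
            if bic < best:
                best = bic
                chosen = trial
                selected.add(pair)
                if len(chosen) >= max_neighbors:
                    break
            else:
                break
        n_chosen[g] = len(chosen)

    kept = ranks.loc[[p for p in ranks.index if p in selected]]
    edges = kept.reset_index()[["gene_a", "gene_b", "mean_rank"]]
    sizes = pd.Series(n_chosen, name="neighborhood_size").reindex(genes)
    return GeneNetwork(genes, edges, neighborhood_sizes=sizes)


def _community(graph: ig.Graph, method: str, seed: int) -> list[int]:
    random.seed(seed)
    if method == "louvain":
        return graph.community_multilevel().membership
    if method == "walktrap":
        return graph.community_walktrap().as_clustering().membership
    if method == "fast_greedy":
        simple = graph.simplify()
        return simple.community_fastgreedy().as_clustering().membership
    if method == "label_propagation":
        return graph.community_label_propagation().membership
    raise ValueError(f"unknown community method {method!r}")


COMMUNITY_METHODS = ("louvain", "walktrap", "fast_greedy", "label_propagation")


def consensus_modules(
    net: GeneNetwork,
    methods: tuple[str, ...] = COMMUNITY_METHODS,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[pd.Series, np.ndarray]:
    """Consensus community detection over several algorithms.

    Returns (gene -> module id Series, co-assignment frequency matrix). The
    consensus graph keeps node pairs co-assigned with frequency >= threshold;
    the final partition is a seeded Louvain pass on that graph, with modules
    renumbered by decreasing size (ties by smallest member gene).
    """
    if len(methods) < 2:
        raise ValueError("need >= 2 community methods")
    graph = net.to_igraph()
    n = graph.vcount()
    consensus = np.zeros((n, n))
    for method in methods:
        membership = np.asarray(_community(graph, method, seed))
        consensus += (membership[:, None] == membership[None, :]).astype(float)
    consensus /= len(methods)
    np.fill_diagonal(consensus, 1.0)

    iu = np.triu_indices(n, k=1)
    keep = consensus[iu] >= threshold
    cons_graph = ig.Graph(
        n=n, edges=[(int(i), int(j)) for i, j in zip(iu[0][keep], iu[1][keep])]
    )
    random.seed(seed)
    membership = cons_graph.community_multilevel().membership

    by_module: dict[int, list[str]] = {}
    for gene, m in zip(net.nodes, membership):
        by_module.setdefault(m, []).append(gene)
    order = sorted(by_module, key=lambda m: (-len(by_module[m]), min(by_module[m])))
    renumber = {m: i + 1 for i, m in enumerate(order)}
    modules = pd.Series(
        [renumber[m] for m in membership], index=pd.Index(net.nodes, name="gene"), dtype=int
    )
    net.modules = modules
    return modules, consensus


def annotate_celltypes(
    modules: pd.Series,
    markers: dict[str, set[str]],
    universe: set[str] | None = None,
    q_cut: float = 0.05,
) -> dict[int, str]:
    """Label each module with its most-enriched cell-type marker set.

    Marker genes appearing in more than one set are dropped first. Per
    (module, cell type), a Fisher exact test on the 2x2 membership table is
    computed over the universe (default: the partitioned genes); BH is
    applied across all tests and a module gets the best label only if that
    label's q < q_cut, otherwise "unassigned".
    """
    universe = set(universe) if universe is not None else set(modules.index)
    counts: dict[str, int] = {}
    for s in markers.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    clean = {name: {g for g in s if counts[g] == 1} & universe for name, s in markers.items()}

    rows = []
    for mod in sorted(modules.unique()):
        members = set(modules.index[modules == mod]) & universe
        for name, s in sorted(clean.items()):
            a = len(members & s)
            b = len(members - s)
            c = len(s - members)
            d = len(universe) - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append({"module": mod, "celltype": name, "k": a, "p_value": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return {}
    table["q_value"] = multipletests(table["p_value"].values, method="fdr_bh")[1]

    labels: dict[int, str] = {}
    for mod, sub in table.groupby("module"):
        best = sub.sort_values(["p_value", "celltype"], kind="stable").iloc[0]
        labels[int(mod)] = best["celltype"] if best["q_value"] < q_cut else "unassigned"
    return labels
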