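"""Cross-species mapping of DEG sets onto a co-expression network.

DEG lists from the mouse factorial analysis are mapped through an ortholog
table onto the gene universe of a human-style co-expression network, each
(age group, module) pair is tested for overlap with a two-sided Fisher exact
test (odds ratio with Haldane-Anscombe 0.5 correction on zero cells, BH
Q-values across all tested pairs), and network connectivity (node degree) of
the mapped DEG sets is compared between age groups with two-sided Wilcoxon
rank-sum tests (exact enumeration for small groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrthologMap",
    "read_ortholog_map",
    "map_orthologs",
    "odds_ratio",
    "overlap_enrichment",
    "wilcoxon_rank_sum",
    "connectivity_compare",
]


@dataclass
class OrthologMap:
    """Source -> target gene pairs; mode 'one_to_one' keeps only unambiguous
    pairs, mode 'all' keeps every mapping."""

    pairs: pd.DataFrame  # columns source_gene, target_gene
    mode: str = "one_to_one"

    def __post_init__(self) -> None:
        if self.mode not in ("one_to_one", "all"):
            raise ValueError("mode must be 'one_to_one' or 'all'")


def read_ortholog_map(path, mode: str = "one_to_one") -> OrthologMap:
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_gene", "target_gene"}
    if not required <= set(pairs.columns):
        raise ValueError(f"ortholog map must have columns {sorted(required)}")
    bad = pairs.index[pairs["source_gene"].isna() | pairs["target_gene"].isna()]
    if len(bad):
        raise ValueError(f"malformed ortholog rows at lines: {[int(i) + 2 for i in bad]}")
    return OrthologMap(pairs, mode)


def map_orthologs(genes: set[str], omap: OrthologMap) -> tuple[set[str], dict[str, list[str]]]:
    """Map a gene set through the ortholog table.

    Returns (mapped target genes, report). In one-to-one mode, source genes
    with zero or multiple targets (or whose target is hit by several sources)
    are dropped and reported under "unmapped" / "ambiguous".
    """
    pairs = omap.pairs
    report: dict[str, list[str]] = {"unmapped": [], "ambiguous": []}
    if omap.mode == "all":
        hits = pairs[pairs["source_gene"].isin(genes)]
        report["unmapped"] = sorted(genes - set(hits["source_gene"]))
        return set(hits["target_gene"]), report

    src_counts = pairs["source_gene"].value_counts()
    tgt_counts = pairs["target_gene"].value_counts()
    unambiguous = pairs[
        pairs["source_gene"].map(src_counts).eq(1) & pairs["target_gene"].map(tgt_counts).eq(1)
    ]
    lookup = dict(zip(unambiguous["source_gene"], unambiguous["target_gene"]))
    mapped = set()
    known_sources = set(pairs["source_gene"])
    for g in sorted(genes):
        if g in lookup:
            mapped.add(lookup[g])
        elif g in known_sources:
            report["ambiguous"].append(g)
        else:
            report["unmapped"].append(g)
    return mapped, report


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c), adding 0.5 to every cell when any is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def overlap_enrichment(
    deg_sets: dict, modules: pd.Series, universe: set[str]
) -> pd.DataFrame:
    """Fisher overlap of every DEG set with every module over a shared universe.

    ``deg_sets`` maps an age label to a mapped gene set; ``modules`` maps
    gene -> module id. Returns one row per (age, module): the 2x2 cells
    a (in set & in module), b (in set only), c (in module only), d (neither),
    the corrected odds ratio, the two-sided Fisher p, and BH q across all
    tested pairs.
    """
    if not universe:
        raise ValueError("empty universe")
    modules = modules[modules.index.isin(universe)]
    rows = []
    for age, genes in sorted(deg_sets.items(), key=lambda kv: str(kv[0])):
        genes = set(genes) & universe
        for mod in sorted(modules.unique()):
            members = set(modules.index[modules == mod])
            a = len(genes & members)
            b = len(genes - members)
            c = len(members - genes)
            d = len(universe) - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "age": age,
                    "module": mod,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds_ratio(a, b, c, d),
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"].values, method="fdr_bh")[1]
    return out


def wilcoxon_rank_sum(x, y, exact_max: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (via the Mann-Whitney U distribution) when both groups
    have at most ``exact_max`` observations and no ties across groups,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= exact_max and len(y) <= exact_max and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def connectivity_compare(network, deg_sets: dict) -> pd.DataFrame:
    """Compare network degree distributions of mapped DEG sets across ages.

    Returns one row per unordered age pair with the group sizes, mean
    degrees, and the two-sided Wilcoxon rank-sum p (missing when a group has
    no mapped gene in the network).
    """
    if len(deg_sets) < 2:
        raise ValueError("need >= 2 age groups")
    degree = network.degree
    vectors = {
        age: degree[degree.index.isin(set(genes))].values for age, genes in deg_sets.items()
    }
    rows = []
    for age_a, age_b in combinations(sorted(vectors, key=str), 2):
        va, vb = vectors[age_a], vectors[age_b]
        row = {
            "age_a": age_a,
            "age_b": age_b,
            "n_a": len(va),
            "n_b": len(vb),
            "mean_degree_a": float(va.mean()) if len(va) else np.nan,
            "mean_degree_b": float(vb.mean()) if len(vb) else np.nan,
        }
        row["p_value"] = wilcoxon_rank_sum(va, vb) if len(va) and len(vb) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
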