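"""Over-representation analysis and upstream-regulator statistics.

ORA uses the hypergeometric upper tail P(X >= k) for the overlap k between a
query gene list (size n) and a named gene set (size K) within a universe of
size N, with Benjamini-Hochberg Q-values across the tested sets and the
conventional 0.05 / 0.1 p / Q significance cutoffs.

The upstream-regulator statistic scores a signed regulon (regulator with
predicted +1/-1 effects on target genes) against observed DEG directions:
the activation z-score is sum(sign matches) / sqrt(N) over the regulon's DEG
targets, so |z| <= sqrt(N) with equality only when all matches agree; the
direction-blind enrichment p-value is the hypergeometric enrichment of the
regulon's targets in the DEG list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "ora",
    "activation_z",
    "upstream_regulators",
    "top_regulators",
]

P_CUT = 0.05
Q_CUT = 0.1


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe; empty sets are dropped."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        restricted = {name: set(s) & self.universe for name, s in self.sets.items()}
        self.sets = {name: s for name, s in restricted.items() if s}


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_regulons(path) -> list[tuple[str, dict[str, int]]]:
    """Read a regulon TSV (regulator, target, sign in {+1, -1})."""
    table = pd.read_csv(path, sep="\t")
    out = []
    for reg, sub in table.groupby("regulator", sort=True):
        out.append((str(reg), dict(zip(sub["target"].astype(str), sub["sign"].astype(int)))))
    return out


def write_regulons(regulons, path) -> None:
    rows = [
        {"regulator": reg, "target": t, "sign": s}
        for reg, targets in regulons
        for t, s in sorted(targets.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ora(
    query: set[str],
    collection: GeneSetCollection,
    p_cut: float = P_CUT,
    q_cut: float = Q_CUT,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    Genes outside the universe are dropped from the query. Returns one row
    per set: overlap k, set size K, query size n, universe size N, p (upper
    tail), BH q across sets, and a significance flag (p < 0.05 and q < 0.1).
    """
    query = set(query) & collection.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    n_universe = len(collection.universe)
    rows = []
    for name, members in sorted(collection.sets.items()):
        k = len(query & members)
        big_k = len(members)
        p = stats.hypergeom.sf(k - 1, n_universe, big_k, len(query))
        rows.append({"set": name, "k": k, "K": big_k, "n": len(query), "N": n_universe, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"].values, method="fdr_bh")[1]
    out["significant"] = (out["p_value"] < p_cut) & (out["q_value"] < q_cut)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def activation_z(predicted: dict[str, int], observed: dict[str, int]) -> tuple[float, int]:
    """Activation z-score over targets with observed directions.

    z = sum over shared targets of (+1 if predicted sign agrees with observed
    sign else -1), divided by sqrt(number of shared targets).
    """
    shared = [t for t in predicted if t in observed]
    n = len(shared)
    if n == 0:
        return float("nan"), 0
    matches = sum(1 if predicted[t] == observed[t] else -1 for t in shared)
    return matches / np.sqrt(n), n


def upstream_regulators(
    contrast_table: pd.DataFrame,
    regulons: list[tuple[str, dict[str, int]]],
    month,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Score each regulon against the DEG directions at one month.

    Returns one row per regulator: n_overlap (DEG targets), activation z
    (NaN when there are no DEG targets), and the direction-blind
    hypergeometric enrichment p of the regulon's targets in the DEG list.
    """
    sub = contrast_table[contrast_table["month"] == month]
    if universe is None:
        universe = set(sub["gene"])
    deg = sub[sub["is_deg"]]
    observed = dict(zip(deg["gene"], np.sign(deg["log2fc"]).astype(int)))
    n_universe = len(universe)
    n_deg = len(set(observed) & universe)

    rows = []
    for reg, predicted in regulons:
        targets = set(predicted) & universe
        z, n_overlap = activation_z(predicted, observed)
        k = len(targets & set(observed))
        p = stats.hypergeom.sf(k - 1, n_universe, len(targets), n_deg) if targets else 1.0
        rows.append({"regulator": reg, "N": n_overlap, "z": z, "p_value": p})
    return pd.DataFrame(rows)


def top_regulators(scores: pd.DataFrame, p_cut: float = P_CUT, n_top: int = 10) -> pd.DataFrame:
    """Gate by enrichment p < p_cut, rank by |z| descending (ties broken by
    regulator name), and keep the top ``n_top``."""
    gated = scores[(scores["p_value"] < p_cut) & scores["z"].notna()].copy()
    gated["abs_z"] = gated["z"].abs()
    gated = gated.sort_values(["abs_z", "regulator"], ascending=[False, True], kind="stable")
    return gated.head(n_top).drop(columns="abs_z").reset_index(drop=True)
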