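"""Factorial differential expression with per-contrast FDR.

Each gene's log2 signal is fitted with the full-interaction cell-means form
of the 2 (genotype) x 4 (month) factorial linear model; the residual variance
is pooled across all eight design cells. The genotype contrast (TG - WT) is
estimated within each month with a t-statistic on the pooled variance, and
the Benjamini-Hochberg procedure is applied across genes separately within
each month ("FDR per contrast"). A DEG is a gene with per-contrast
FDR < 0.05 and |signed fold change| > 1.5, where the signed fold change is
sign(log2fc) * 2**|log2fc|.

The module follows the Model/Results convention: ``FactorialDE(signals,
meta).fit()`` returns a :class:`FactorialDEResults` carrying the estimates,
the DEG calls, Venn-style summaries and a ``summary()`` table.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FactorialDE",
    "FactorialDEResults",
    "signed_fold_change",
    "call_degs",
    "summarize_degs",
    "compare_deg_sets",
]

ALPHA = 0.05
FC_CUT = 1.5


def signed_fold_change(log2fc):
    """Signed anti-logged fold change: sign(log2fc) * 2**|log2fc|."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.sign(log2fc) * 2.0 ** np.abs(log2fc)


class FactorialDE:
    """Per-gene 2 x (number of months) factorial linear model.

    Parameters
    ----------
    signals : gene x sample DataFrame of log2 signals (or GeneSignalMatrix).
    meta : sample metadata with ``genotype`` in {WT, TG} and ``month``,
        indexed by sample id matching the signal columns.
    """

    def __init__(self, signals, meta: pd.DataFrame):
        if hasattr(signals, "signals"):
            signals = signals.signals
        meta = meta.loc[list(signals.columns)]
        self.signals = signals
        self.meta = meta
        self.months = sorted(meta["month"].unique())
        self.genotypes = ("WT", "TG")
        for m in self.months:
            for g in self.genotypes:
                n = int(((meta["genotype"] == g) & (meta["month"] == m)).sum())
                if n == 0:
                    raise ValueError(f"empty design cell: genotype={g}, month={m}")
                if n < 2:
                    raise ValueError(
                        f"design cell genotype={g}, month={m} has {n} replicate; >= 2 required"
                    )

    @classmethod
    def from_tsv(cls, signals_path, meta_path) -> "FactorialDE":
        signals = pd.read_csv(signals_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(signals, meta)

    def fit(self) -> "FactorialDEResults":
        x = self.signals.values
        n_genes, n_samples = x.shape
        cells = [
            (g, m, np.flatnonzero((self.meta["genotype"] == g) & (self.meta["month"] == m)).tolist())
            for g in self.genotypes
            for m in self.months
        ]
        df_resid = n_samples - len(cells)
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom; need > 1 replicate per cell")

        means = {}
        sse = np.zeros(n_genes)
        counts = {}
        for g, m, idx in cells:
            sub = x[:, idx]
            mu = sub.mean(axis=1)
            means[(g, m)] = mu
            counts[(g, m)] = len(idx)
            sse += ((sub - mu[:, None]) ** 2).sum(axis=1)
        s2 = sse / df_resid

        rows = []
        for m in self.months:
            diff = means[("TG", m)] - means[("WT", m)]
            var = s2 * (1.0 / counts[("TG", m)] + 1.0 / counts[("WT", m)])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / np.sqrt(var)
            p = 2.0 * stats.t.sf(np.abs(t), df_resid)
            degenerate = s2 <= 0
            # Zero residual variance: no effect -> p = 1; nonzero effect -> p = 0.
            p = np.where(degenerate & (diff == 0), 1.0, p)
            p = np.where(degenerate & (diff != 0), 0.0, p)
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.signals.index,
                        "month": m,
                        "log2fc": diff,
                        "fold_change": signed_fold_change(diff),
                        "t": np.where(degenerate, np.nan, t),
                        "p_value": p,
                        "degenerate": degenerate,
                    }
                )
            )
        fits = pd.concat(rows, ignore_index=True)
        return FactorialDEResults(self, fits, df_resid)


def call_degs(fits: pd.DataFrame, alpha: float = ALPHA, fc_cut: float = FC_CUT) -> pd.DataFrame:
    """Apply BH within each month's contrast and flag DEGs.

    DEG iff fdr < alpha and |fold_change| > fc_cut (strict inequalities).
    """
    if fits.empty:
        raise ValueError("no fitted genes")
    out = fits.copy()
    out["fdr"] = np.nan
    for m, idx in out.groupby("month").groups.items():
        out.loc[idx, "fdr"] = multipletests(out.loc[idx, "p_value"].values, method="fdr_bh")[1]
    out["is_deg"] = (out["fdr"] < alpha) & (out["fold_change"].abs() > fc_cut)
    return out


def summarize_degs(table: pd.DataFrame) -> dict:
    """Table-1 / Venn style summary of a per-gene-per-month contrast table.

    Returns per-month totals with up/down and |FC| > 2 partitions, the DEG
    union, all non-empty Venn cells over month subsets, and the persistence
    fraction (DEGs at the earliest month still DEGs at every later month).
    """
    months = sorted(table["month"].unique())
    deg = table[table["is_deg"]]
    per_month = {}
    for m in months:
        sub = deg[deg["month"] == m]
        per_month[m] = {
            "total": int(len(sub)),
            "up": int((sub["fold_change"] > 0).sum()),
            "down": int((sub["fold_change"] < 0).sum()),
            "n_abs_fc_gt2": int((sub["fold_change"].abs() > 2).sum()),
            "n_abs_fc_le2": int((sub["fold_change"].abs() <= 2).sum()),
        }
    membership = {m: set(deg.loc[deg["month"] == m, "gene"]) for m in months}
    union = set().union(*membership.values()) if membership else set()

    venn = {}
    for r in range(1, len(months) + 1):
        for subset in combinations(months, r):
            inside = set(union)
            for m in subset:
                inside &= membership[m]
            for m in months:
                if m not in subset:
                    inside -= membership[m]
            if inside:
                venn[subset] = inside

    persistence = None
    if months and membership[months[0]]:
        first = membership[months[0]]
        persistent = set(first)
        for m in months[1:]:
            persistent &= membership[m]
        persistence = len(persistent) / len(first)
    return {
        "per_month": per_month,
        "union": union,
        "venn_partition": venn,
        "persistence_fraction": persistence,
    }


def compare_deg_sets(set_a: dict, set_b: dict, set_c: dict) -> dict:
    """Three-way DEG intersection with direction concordance.

    Each argument maps gene -> direction sign (+1 up, -1 down). Returns the
    common genes, a per-gene concordance flag (same sign in all three), and
    counts of concordant up/down genes.
    """
    common = sorted(set(set_a) & set(set_b) & set(set_c))
    concordant = {g: (set_a[g] == set_b[g] == set_c[g]) for g in common}
    up = sum(1 for g in common if concordant[g] and set_a[g] > 0)
    down = sum(1 for g in common if concordant[g] and set_a[g] < 0)
    return {
        "common": common,
        "concordant": concordant,
        "n_common": len(common),
        "n_concordant_up": up,
        "n_concordant_down": down,
    }


class FactorialDEResults:
    """Results of the factorial fit: contrasts, DEG calls and summaries."""

    def __init__(self, model: FactorialDE, fits: pd.DataFrame, df_resid: int):
        self.model = model
        self.fits = fits
        self.df_resid = df_resid
        self._table = None

    def contrast_table(self, alpha: float = ALPHA, fc_cut: float = FC_CUT) -> pd.DataFrame:
        """Per gene x month: log2fc, fold_change, p, per-contrast FDR, DEG flag."""
        if self._table is None:
            self._table = call_degs(self.fits, alpha=alpha, fc_cut=fc_cut)
        return self._table

    def deg_summary(self) -> dict:
        return summarize_degs(self.contrast_table())

    def deg_sets(self) -> dict[int, dict[str, int]]:
        """Per month: DEG gene -> direction sign."""
        table = self.contrast_table()
        deg = table[table["is_deg"]]
        return {
            m: dict(zip(sub["gene"], np.sign(sub["log2fc"]).astype(int)))
            for m, sub in deg.groupby("month")
        }

    def summary(self) -> str:
        summ = self.deg_summary()
        lines = [
            "Factorial differential expression (TG - WT contrast per month)",
            f"genes: {self.model.signals.shape[0]}  samples: {self.model.signals.shape[1]}"
            f"  residual df: {self.df_resid}",
            f"{'month':>6} {'DEG':>6} {'up':>6} {'down':>6} {'|FC|>2':>7} {'|FC|<=2':>8}",
        ]
        for m, row in summ["per_month"].items():
            lines.append(
                f"{m:>6} {row['total']:>6} {row['up']:>6} {row['down']:>6}"
                f" {row['n_abs_fc_gt2']:>7} {row['n_abs_fc_le2']:>8}"
            )
        lines.append(f"DEG union across months: {len(summ['union'])}")
        if summ["persistence_fraction"] is not None:
            lines.append(
                f"persistence of earliest-month DEGs: {100 * summ['persistence_fraction']:.2f}%"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.contrast_table().to_csv(path, sep="\t", index=False)
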