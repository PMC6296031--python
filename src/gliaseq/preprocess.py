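"""Sample QC exclusion and the exon-to-gene "rollup".

The rollup converts exon-level counts into one robust log2 signal per gene
and sample:

1. exons whose counts are low in most samples are removed;
2. for each gene, a two-way additive model (sample effect + exon effect) is
   fitted robustly to the log2(count + 1) exon matrix — by default with
   median polish, optionally with Huber M-estimation — and the per-sample
   effect is the gene signal;
3. per-sample signal distributions are median-normalized (additive shift to
   the grand median on the log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "GeneSignalMatrix",
    "exclude_failed_samples",
    "filter_exons",
    "median_polish",
    "rollup_gene",
    "rollup",
    "median_normalize",
]

PSEUDOCOUNT = 1.0
LOW_COUNT = 10  # "less than 10 counts"
LOW_FRACTION = 0.80  # "more than 80% of samples"


@dataclass
class QCThresholds:
    """Pass range per QC metric (inclusive). Defaults are permissive."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mapping_rate": (0.70, 1.0),
            "mapped_reads": (10_000_000, float("inf")),
            "three_prime_bias": (0.5, 2.0),
            "rrna_mito_fraction": (0.0, 0.20),
            "adapter_content": (0.0, 0.10),
        }
    )


@dataclass
class GeneSignalMatrix:
    """Gene x sample log2 signals plus the per-sample normalization offsets."""

    signals: pd.DataFrame
    normalization_offsets: pd.Series | None = None

    def to_tsv(self, path) -> None:
        out = self.signals.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GeneSignalMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def exclude_failed_samples(
    qc: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[list[str], dict[str, list[str]]]:
    """Exclude samples with any QC metric outside its pass range.

    Returns (kept sample ids, excluded sample -> violated metric names).
    """
    thresholds = thresholds or QCThresholds()
    missing = [m for m in thresholds.ranges if m not in qc.columns]
    if missing:
        raise ValueError(f"QC table is missing metrics: {missing}")
    if qc[list(thresholds.ranges)].isna().any().any():
        bad = qc.index[qc[list(thresholds.ranges)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing QC metric values for samples: {bad}")

    kept: list[str] = []
    report: dict[str, list[str]] = {}
    for sample, row in qc.iterrows():
        violated = [
            metric
            for metric, (lo, hi) in thresholds.ranges.items()
            if not (lo <= row[metric] <= hi)
        ]
        if violated:
            report[str(sample)] = violated
        else:
            kept.append(str(sample))
    return kept, report


def filter_exons(counts: pd.DataFrame, exon_to_gene: pd.Series):
    """Drop exons where more than 80% of samples have fewer than 10 counts.

    The boundary is strict on both sides: a fraction of exactly 0.80 is
    retained, a count of exactly 10 is not "low". Genes losing every exon are
    dropped and reported.

    Returns (filtered counts, filtered exon_to_gene, list of dropped genes).
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty exon count matrix")
    low_frac = (counts.values < LOW_COUNT).mean(axis=1)
    keep = low_frac <= LOW_FRACTION
    kept_counts = counts.loc[keep]
    kept_map = exon_to_gene.loc[keep]
    dropped_genes = sorted(set(exon_to_gene) - set(kept_map))
    return kept_counts, kept_map, dropped_genes


def median_polish(
    x: np.ndarray, max_iter: int = 20, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a rows x cols matrix.

    Returns (overall, row_effects, col_effects, residuals) with row and column
    effects median-centred at zero.
    """
    x = np.asarray(x, dtype=float)
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        if max(np.abs(rmed).max(initial=0.0), np.abs(cmed).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def _huber_two_way(x: np.ndarray) -> np.ndarray:
    """Huber M-fit of value ~ sample + exon; returns per-sample effects."""
    import statsmodels.api as sm

    n_exons, n_samples = x.shape
    y = x.ravel(order="F")  # sample-major
    # Cell-means design for samples, sum-to-zero contrasts for exons.
    ds = np.kron(np.eye(n_samples), np.ones((n_exons, 1)))
    if n_exons > 1:
        de = np.vstack([np.eye(n_exons - 1), -np.ones(n_exons - 1)])
        design = np.hstack([ds, np.tile(de, (n_samples, 1))])
    else:
        design = ds
    fit = sm.RLM(y, design, M=sm.robust.norms.HuberT()).fit()
    return np.asarray(fit.params[:n_samples])


def rollup_gene(exon_log2: np.ndarray, method: str = "median_polish") -> np.ndarray:
    """Robust per-sample gene signal from one gene's exon x sample log2 matrix.

    Fits the additive model log2 value ~ gene-sample effect + exon effect and
    returns the per-sample effect (overall + column effect for median polish),
    with exon effects centred at zero. A single-exon gene passes through
    unchanged.
    """
    x = np.asarray(exon_log2, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("exon_log2 must be a 2-D matrix with >= 1 exon row")
    if np.isnan(x).all(axis=1).any():
        raise ValueError("all-missing exon row")
    if x.shape[0] == 1:
        return x[0].copy()
    if method == "median_polish":
        overall, sample_eff, exon_eff, _ = median_polish(x.T)  # rows = samples
        # Re-centre exon effects to mean zero so that on exactly additive
        # data the sample effects reproduce per-sample means.
        return overall + sample_eff + exon_eff.mean()
    if method == "huber":
        return _huber_two_way(x)
    raise ValueError(f"unknown rollup method: {method}")


def median_normalize(signals: pd.DataFrame) -> GeneSignalMatrix:
    """Shift each sample additively so per-sample medians equal the grand
    median of the per-sample medians; offsets are recorded."""
    if signals.shape[1] < 2:
        raise ValueError("median normalization needs >= 2 samples")
    medians = signals.median(axis=0)
    target = float(np.median(medians.values))
    offsets = target - medians
    return GeneSignalMatrix(signals.add(offsets, axis=1), offsets)


def rollup(
    exon_counts,
    method: str = "median_polish",
    normalize: bool = True,
    pseudocount: float = PSEUDOCOUNT,
):
    """Full exon-to-gene pipeline on an :class:`ExonCountMatrix`.

    Returns (GeneSignalMatrix, dropped gene list).
    """
    counts, exon_to_gene, dropped = filter_exons(exon_counts.counts, exon_counts.exon_to_gene)
    log2 = np.log2(counts.values + pseudocount)
    order = exon_to_gene.values
    rows = {}
    for gene in pd.unique(order):
        block = log2[order == gene]
        rows[gene] = rollup_gene(block, method=method)
    signals = pd.DataFrame.from_dict(rows, orient="index")
    signals.columns = counts.columns
    signals.index.name = "gene_id"
    if normalize and signals.shape[1] >= 2:
        return median_normalize(signals), dropped
    return GeneSignalMatrix(signals), dropped
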