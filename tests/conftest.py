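import numpy as np
import pandas as pd
import pytest

from gliaseq import simulate

MONTHS = (2, 4, 6, 8)


def make_meta(n_replicates: int = 4, months=MONTHS) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{g}_{m}m_{r + 1}", "genotype": g, "month": m, "replicate": r + 1}
        for g in ("WT", "TG")
        for m in months
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def gaussian_signals(
    meta: pd.DataFrame, n_genes: int, sigma: float, seed: int, tg_shift: float = 0.0,
    n_shifted: int = 0,
) -> pd.DataFrame:
    """Gene x sample Gaussian log2 signals; the first ``n_shifted`` genes get
    ``tg_shift`` added to every TG sample."""
    rng = np.random.default_rng(seed)
    x = 5.0 + sigma * rng.standard_normal((n_genes, len(meta)))
    if n_shifted:
        x[:n_shifted, (meta["genotype"] == "TG").values] += tg_shift
    return pd.DataFrame(x, index=[f"g{i:04d}" for i in range(n_genes)], columns=meta.index)


def pattern_signals(n_per_pattern: int, sigma: float, seed: int, n_replicates: int = 4):
    """Replicate-level signals following the four canonical temporal patterns.

    Returns (signals, meta, gene -> planted pattern id).
    """
    rng = np.random.default_rng(seed)
    meta = make_meta(n_replicates)
    curves = simulate.default_pattern_curves()
    month_index = {m: i for i, m in enumerate(MONTHS)}
    shift = np.array(
        [
            [curves[p][row["genotype"]][month_index[row["month"]]] for _, row in meta.iterrows()]
            for p in (1, 2, 3, 4)
        ]
    )
    genes, blocks, labels = [], [], {}
    for pi, pattern in enumerate((1, 2, 3, 4)):
        base = rng.uniform(4, 8, n_per_pattern)
        noise = sigma * rng.standard_normal((n_per_pattern, len(meta)))
        blocks.append(base[:, None] + shift[pi][None, :] + noise)
        for i in range(n_per_pattern):
            name = f"p{pattern}_g{i:03d}"
            genes.append(name)
            labels[name] = pattern
    signals = pd.DataFrame(np.vstack(blocks), index=genes, columns=meta.index)
    return signals, meta, labels


@pytest.fixture
def meta32() -> pd.DataFrame:
    return make_meta(4)


@pytest.fixture
def small_exon_matrix() -> simulate.ExonCountMatrix:
    spec = simulate.DesignSpec(n_genes=60, seed=11, base_log2_range=(5, 9))
    truth = simulate.make_planted_truth(spec, n_deg_per_pattern=5, seed=11)
    return simulate.generate_exon_counts(spec, truth)
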