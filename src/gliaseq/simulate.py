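"""Synthetic data with planted ground truth.

Emulates a longitudinal microglia RNA-seq study: a 2 (genotype: WT vs
tau-transgenic TG) x 4 (age in months: 2, 4, 6, 8) factorial design with
negative-binomial exon-level counts, library-size and dispersion variation,
and four planted temporal differential-expression patterns:

1. TG down-regulated with age, WT flat
2. TG up-regulated with age, WT flat
3. TG up-regulated peaking mid-course, WT drifting down
4. TG down-regulated, WT moderately up

A separate latent-factor generator produces gene co-expression matrices with
planted modules (standing in for a human cortex co-expression dataset), and
helpers emit gene sets, signed regulons, cell-type marker sets and ortholog
maps consistent with the planted truth, so that every downstream stage of the
pipeline can be tested without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "PlantedTruth",
    "ExonCountMatrix",
    "default_pattern_curves",
    "make_planted_truth",
    "generate_exon_counts",
    "generate_qc_metrics",
    "generate_coexpression_samples",
    "generate_genesets_and_regulons",
]

GENOTYPES = ("WT", "TG")

#: log2 mean-shift per month for each planted temporal pattern.
#: Keys are pattern ids; values map genotype -> one shift per design month.
DEFAULT_PATTERN_CURVES: dict[int, dict[str, tuple[float, ...]]] = {
    1: {"TG": (0.0, -1.0, -1.5, -2.0), "WT": (0.0, 0.0, 0.0, 0.0)},
    2: {"TG": (0.5, 1.0, 1.5, 2.0), "WT": (0.0, 0.0, 0.0, 0.0)},
    3: {"TG": (0.5, 1.5, 1.5, 0.5), "WT": (0.0, -0.5, -1.0, -1.5)},
    4: {"TG": (-0.5, -1.0, -1.5, -2.0), "WT": (0.0, 0.3, 0.6, 1.0)},
}


def default_pattern_curves() -> dict[int, dict[str, tuple[float, ...]]]:
    """Return a copy of the four canonical temporal pattern curves."""
    return {k: {g: tuple(v) for g, v in d.items()} for k, d in DEFAULT_PATTERN_CURVES.items()}


@dataclass
class DesignSpec:
    """Parameters of the factorial RNA-seq design to simulate.

    Parameters
    ----------
    n_genes : total number of genes in the universe.
    months : strictly increasing ages at which animals are profiled.
    n_replicates : biological replicates per genotype x month cell.
    exons_per_gene : inclusive (low, high) range for the number of exons.
    library_size_sdlog : sd of the log-normal per-sample library factor.
    base_log2_range : uniform range for baseline log2 gene expression.
    dispersion_meanlog, dispersion_sdlog : log-normal parameters of the
        per-gene NB dispersion phi (variance = mu + phi * mu**2).
    seed : fully determines the generated data.
    """

    n_genes: int
    months: tuple[int, ...] = (2, 4, 6, 8)
    n_replicates: int = 4
    exons_per_gene: tuple[int, int] = (1, 10)
    library_size_sdlog: float = 0.2
    base_log2_range: tuple[float, float] = (3.0, 9.0)
    dispersion_meanlog: float = float(np.log(0.05))
    dispersion_sdlog: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")
        if list(self.months) != sorted(set(self.months)):
            raise ValueError("months must be strictly increasing")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("exons_per_gene must be a valid range with low >= 1")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{g}_{m}m_{r + 1}", "genotype": g, "month": m, "replicate": r + 1}
            for g in GENOTYPES
            for m in self.months
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class PlantedTruth:
    """Ground truth planted into a simulation.

    deg_genes maps gene -> temporal pattern id (1-4); genes absent from the
    map are nulls. module_assignment maps gene -> co-expression module id;
    celltype_of_module labels each module with a cell type.
    """

    deg_genes: dict[str, int] = field(default_factory=dict)
    pattern_curves: dict[int, dict[str, tuple[float, ...]]] = field(
        default_factory=default_pattern_curves
    )
    module_assignment: dict[str, int] = field(default_factory=dict)
    celltype_of_module: dict[int, str] = field(default_factory=dict)

    def shift(self, gene: str, genotype: str, month_index: int) -> float:
        pattern = self.deg_genes.get(gene)
        if pattern is None:
            return 0.0
        return self.pattern_curves[pattern][genotype][month_index]

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["pattern_curves"] = {
            str(k): {g: list(v) for g, v in d.items()} for k, d in self.pattern_curves.items()
        }
        payload["celltype_of_module"] = {str(k): v for k, v in self.celltype_of_module.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class ExonCountMatrix:
    """Exon x sample integer counts plus the exon->gene map and metadata."""

    counts: pd.DataFrame  # exons x samples, int
    exon_to_gene: pd.Series  # index exon_id -> gene_id
    samples: pd.DataFrame  # index sample_id; columns genotype, month, replicate

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate exon ids")
        if not self.counts.index.equals(self.exon_to_gene.index):
            raise ValueError("counts rows and exon_to_gene index differ")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns must match sample metadata order")

    def to_tsv(self, counts_path, meta_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_id", self.exon_to_gene)
        out.index.name = "exon_id"
        out.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            self.samples.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "ExonCountMatrix":
        table = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        exon_to_gene = table.pop("gene_id")
        counts = table[meta.index]
        counts.columns.name = meta.index.name
        return cls(counts, exon_to_gene, meta)


def make_planted_truth(
    spec: DesignSpec,
    n_deg_per_pattern: int = 0,
    pattern_curves: dict[int, dict[str, tuple[float, ...]]] | None = None,
    n_modules: int = 0,
    genes_per_module: int = 0,
    celltypes: tuple[str, ...] = (
        "microglia",
        "endothelial",
        "astrocyte",
        "neuron",
        "oligodendrocyte",
    ),
    seed: int = 0,
) -> PlantedTruth:
    """Assign planted patterns and modules over the spec's gene universe.

    Pattern genes and module genes are drawn without replacement from the
    front of a seeded permutation, so planted sets are disjoint across
    patterns (and across modules).
    """
    rng = np.random.default_rng(seed)
    genes = np.array(spec.gene_ids)
    perm = rng.permutation(genes)
    curves = pattern_curves or default_pattern_curves()
    for pat, d in curves.items():
        for g in GENOTYPES:
            if len(d[g]) != len(spec.months):
                raise ValueError(f"pattern {pat} curve for {g} must have one shift per month")

    deg_genes: dict[str, int] = {}
    cursor = 0
    for pattern in sorted(curves):
        for g in perm[cursor : cursor + n_deg_per_pattern]:
            deg_genes[str(g)] = pattern
        cursor += n_deg_per_pattern
    if cursor > len(genes):
        raise ValueError("not enough genes for the requested planted DEGs")

    module_assignment: dict[str, int] = {}
    celltype_of_module: dict[int, str] = {}
    mod_perm = rng.permutation(genes)
    mcursor = 0
    for mod in range(1, n_modules + 1):
        for g in mod_perm[mcursor : mcursor + genes_per_module]:
            module_assignment[str(g)] = mod
        celltype_of_module[mod] = celltypes[(mod - 1) % len(celltypes)]
        mcursor += genes_per_module
    if mcursor > len(genes):
        raise ValueError("not enough genes for the requested modules")

    return PlantedTruth(deg_genes, curves, module_assignment, celltype_of_module)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + phi*mu^2 (Poisson where phi == 0)."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / phi[~pois]
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def generate_exon_counts(spec: DesignSpec, truth: PlantedTruth) -> ExonCountMatrix:
    """Simulate NB exon counts under the factorial design.

    Every exon of a gene shares the gene-level expectation scaled by a fixed
    (Dirichlet-drawn) exon proportion, so the exon->gene rollup's additive
    model holds on the log scale in expectation. Planted genes' expectations
    follow their pattern curve; all samples share per-gene dispersion and
    carry a log-normal library-size factor.
    """
    unknown = set(truth.deg_genes) - set(spec.gene_ids)
    if unknown:
        raise ValueError(f"planted genes outside the spec's gene universe: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    samples = spec.sample_table()
    n_samples = len(samples)
    month_index = {m: i for i, m in enumerate(spec.months)}

    base = rng.uniform(*spec.base_log2_range, size=len(genes))
    phi = rng.lognormal(spec.dispersion_meanlog, spec.dispersion_sdlog, size=len(genes))
    n_exons = rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1, size=len(genes))
    lib = rng.lognormal(0.0, spec.library_size_sdlog, size=n_samples)

    shifts = np.zeros((len(genes), n_samples))
    for j, (_, row) in enumerate(samples.iterrows()):
        mi = month_index[row["month"]]
        for i, g in enumerate(genes):
            shifts[i, j] = truth.shift(g, row["genotype"], mi)
    gene_mean = (2.0 ** (base[:, None] + shifts)) * lib[None, :]

    exon_ids, exon_gene, blocks = [], [], []
    for i, g in enumerate(genes):
        k = int(n_exons[i])
        props = rng.dirichlet(np.full(k, 2.0))
        mu = gene_mean[i][None, :] * props[:, None]
        blocks.append(_nb_draw(rng, mu, phi[i]))
        exon_ids.extend(f"{g}_e{e + 1}" for e in range(k))
        exon_gene.extend([g] * k)

    counts = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(exon_ids, name="exon_id"), columns=samples.index
    )
    return ExonCountMatrix(counts, pd.Series(exon_gene, index=counts.index, name="gene_id"), samples)


def generate_qc_metrics(
    samples: pd.DataFrame, n_corrupt: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Per-sample QC metric table, with ``n_corrupt`` samples given a failing
    mapping rate to exercise sample exclusion."""
    rng = np.random.default_rng(seed)
    n = len(samples)
    qc = pd.DataFrame(
        {
            "mapping_rate": rng.uniform(0.85, 0.98, n),
            "mapped_reads": rng.integers(40_000_000, 120_000_000, n),
            "three_prime_bias": rng.uniform(0.9, 1.3, n),
            "rrna_mito_fraction": rng.uniform(0.01, 0.08, n),
            "adapter_content": rng.uniform(0.0, 0.02, n),
        },
        index=samples.index,
    )
    if n_corrupt:
        bad = rng.choice(n, size=n_corrupt, replace=False)
        qc.iloc[bad, qc.columns.get_loc("mapping_rate")] = rng.uniform(0.1, 0.4, n_corrupt)
    return qc


def generate_coexpression_samples(
    n_samples: int,
    modules: PlantedTruth,
    noise_sd: float,
    seed: int = 0,
    loading: float = 1.0,
) -> pd.DataFrame:
    """Latent-factor gene expression with planted co-expression modules.

    Each module has an independent standard-normal factor per sample; a
    member gene is ``loading * factor + noise_sd * N(0,1)``. Genes with no
    module are independent N(0,1) noise. Within-module expected correlation
    is loading^2 / (loading^2 + noise_sd^2) > 0 = between-module.

    Returns a gene x sample DataFrame on a log-expression-like scale.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = sorted(modules.module_assignment) if modules.module_assignment else []
    mod_ids = sorted(set(modules.module_assignment.values()))
    factors = {m: rng.standard_normal(n_samples) for m in mod_ids}
    rows = {
        g: loading * factors[modules.module_assignment[g]]
        + noise_sd * rng.standard_normal(n_samples)
        for g in genes
    }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = [f"s{j + 1:03d}" for j in range(n_samples)]
    data.index.name = "gene_id"
    return data


def generate_genesets_and_regulons(
    truth: PlantedTruth,
    universe: list[str],
    seed: int = 0,
    n_null_sets: int = 10,
    null_set_size: int = 40,
    n_null_regulons: int = 10,
    regulon_size: int = 30,
    ortholog_fraction: float = 1.0,
):
    """Emit gene sets, signed regulons, marker sets and an ortholog map.

    Returns (gene_sets, regulons, marker_sets, ortholog_map):

    - gene_sets: one set per planted pattern (its exact member genes) plus
      ``n_null_sets`` random sets, as name -> set of genes.
    - regulons: list of (regulator, {target: sign}); the first, "REG_ACTIVE",
      targets pattern-2 genes with sign +1 (matching their planted
      up-regulation); the rest have random targets and random signs.
    - marker_sets: cell type -> genes of the module(s) planted with that type.
    - ortholog_map: DataFrame (source_gene, target_gene), one-to-one on a
      ``ortholog_fraction`` of the universe; targets are uppercased ids.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)

    gene_sets: dict[str, set[str]] = {}
    by_pattern: dict[int, list[str]] = {}
    for g, p in truth.deg_genes.items():
        by_pattern.setdefault(p, []).append(g)
    for p, members in sorted(by_pattern.items()):
        gene_sets[f"pattern{p}_set"] = set(members)
    for i in range(n_null_sets):
        gene_sets[f"null_set_{i + 1}"] = set(
            rng.choice(universe, size=min(null_set_size, len(universe)), replace=False)
        )

    regulons: list[tuple[str, dict[str, int]]] = []
    p2 = sorted(by_pattern.get(2, []))
    if p2:
        targets = list(rng.choice(p2, size=min(regulon_size, len(p2)), replace=False))
        regulons.append(("REG_ACTIVE", {t: 1 for t in targets}))
    for i in range(n_null_regulons):
        targets = rng.choice(universe, size=min(regulon_size, len(universe)), replace=False)
        signs = rng.choice([-1, 1], size=len(targets))
        regulons.append((f"REG_NULL_{i + 1}", dict(zip(map(str, targets), map(int, signs)))))

    marker_sets: dict[str, set[str]] = {}
    for g, m in truth.module_assignment.items():
        label = truth.celltype_of_module.get(m, f"module{m}")
        marker_sets.setdefault(label, set()).add(g)

    n_mapped = int(round(ortholog_fraction * len(universe)))
    mapped = sorted(rng.choice(universe, size=n_mapped, replace=False))
    ortholog_map = pd.DataFrame(
        {"source_gene": mapped, "target_gene": [f"H_{g.upper()}" for g in mapped]}
    )
    return gene_sets, regulons, marker_sets, ortholog_map
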