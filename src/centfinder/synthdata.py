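"""Synthetic study generator with planted ground truth.

Generates every input the pipeline consumes — a log2 expression matrix
with correlated gene modules differentially active across cell types
and confounded by batch shifts, a motif ranking database with planted
regulons among random decoys, and negative-binomial count matrices
with planted fold changes — together with the truth used to plant
them, so that module detection, motif enrichment, activity scoring,
differential expression and TF ranking can all be validated by
recovery of known structure.

The default expression design is 2000 genes × 60 samples: three
planted modules of 50 genes, three cell types of 20 samples each, and
a latent module factor per sample (unit within-cell-type variance,
cell-type-specific means) loaded with gene-specific weights drawn from
U(0.5, 1). One planted TF per module carries a fixed high loading so
that its module-membership centrality is strong by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .containers import ExpressionMatrix, MotifRankingDB, SampleRecord

__all__ = [
    "SyntheticTruth",
    "StudyData",
    "simulate_expression",
    "simulate_ranking_db",
    "simulate_counts",
    "simulate_study",
    "positivity_summary",
]


@dataclass
class SyntheticTruth:
    """Planted structure behind a simulated dataset."""

    seed: int
    module_assignment: dict[str, str] = field(default_factory=dict)
    celltype_module_means: dict[str, dict[str, float]] = field(default_factory=dict)
    batch_shifts: dict[str, float] = field(default_factory=dict)
    planted_regulons: dict[str, list[str]] = field(default_factory=dict)
    planted_tfs: dict[str, str] = field(default_factory=dict)  # tf -> module
    planted_log2fc: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _default_celltype_means(n_modules: int, n_celltypes: int, strength: float = 2.0):
    """Module m is active (mean ``strength``) in cell type m, quiet elsewhere."""
    means = np.zeros((n_modules, n_celltypes))
    for m in range(n_modules):
        means[m, m % n_celltypes] = strength
    return means


def simulate_expression(
    n_genes: int = 2000,
    n_samples: int = 60,
    module_sizes=(50, 50, 50),
    n_celltypes: int = 3,
    celltype_means: np.ndarray | None = None,
    batch_shifts=(0.0,),
    noise_sd: float = 0.5,
    baseline: float = 8.0,
    planted_tfs: bool = True,
    tf_loading: float = 0.9,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2 expression matrix with planted modules.

    x_gj = loading_g · f_{m(g), j} + batch_shift_{b(j)} + ε_gj (+ baseline),
    with f drawn per sample around its cell type's module mean (unit
    SD), loadings ~ U(0.5, 1), ε ~ N(0, noise_sd). Genes outside the
    planted modules are pure noise. Batches alternate within cell
    types so batch and cell type are not confounded.
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed the number of genes")
    if n_samples < 3 * n_celltypes:
        raise ValueError("each cell type needs at least 3 samples")
    rng = np.random.default_rng(seed)
    n_modules = len(module_sizes)
    if celltype_means is None:
        celltype_means = _default_celltype_means(n_modules, n_celltypes)
    celltype_means = np.asarray(celltype_means, dtype=float)

    celltype_of = np.repeat(np.arange(n_celltypes), int(np.ceil(n_samples / n_celltypes)))[:n_samples]
    batch_of = np.arange(n_samples) % len(batch_shifts)

    gene_ids = []
    module_of = np.full(n_genes, -1)
    pos = 0
    tf_names: dict[str, str] = {}
    for m, size in enumerate(module_sizes):
        for i in range(size):
            if planted_tfs and i == 0:
                name = f"TF{m + 1}"
                tf_names[name] = f"M{m + 1}"
            else:
                name = f"M{m + 1}_G{i:03d}"
            gene_ids.append(name)
            module_of[pos] = m
            pos += 1
    for i in range(pos, n_genes):
        gene_ids.append(f"G{i:05d}")

    loadings = rng.uniform(0.5, 1.0, size=n_genes)
    if planted_tfs:
        for m, size in enumerate(module_sizes):
            start = sum(module_sizes[:m])
            loadings[start] = tf_loading

    # latent factor per (module, sample)
    f = rng.normal(celltype_means[:, celltype_of], 1.0)  # modules × samples
    x = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    in_module = module_of >= 0
    x[in_module] += loadings[in_module, None] * f[module_of[in_module]]
    x += np.asarray(batch_shifts)[batch_of][None, :]
    x += baseline

    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    samples = [
        SampleRecord(
            sample_id=sample_ids[j],
            organism="Homo sapiens",
            label="biotin",
            platform_id=f"A-AFFY-{batch_of[j]:02d}",
            study_id="synthetic",
            cell_type=f"CT{celltype_of[j] + 1}",
        )
        for j in range(n_samples)
    ]
    em = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        log2_scale=True,
        samples=samples,
    )
    truth = SyntheticTruth(
        seed=seed,
        module_assignment={
            g: (f"M{module_of[i] + 1}" if module_of[i] >= 0 else "none")
            for i, g in enumerate(gene_ids)
        },
        celltype_module_means={
            f"M{m + 1}": {f"CT{c + 1}": float(celltype_means[m, c]) for c in range(n_celltypes)}
            for m in range(n_modules)
        },
        batch_shifts={f"A-AFFY-{b:02d}": float(s) for b, s in enumerate(batch_shifts)},
        planted_tfs=tf_names,
    )
    return em, truth


def simulate_ranking_db(
    n_motifs: int,
    genes,
    regulons: dict[str, list[str]],
    top_quantile: float = 0.01,
    seed: int = 0,
) -> MotifRankingDB:
    """Motif ranking database: planted motifs rank their regulon targets
    uniformly within the top ``top_quantile`` of the ranking; decoy
    motifs are fully random permutations."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    top = max(int(np.floor(top_quantile * n)), 1)
    col_of = {g: i for i, g in enumerate(genes)}
    rows = {}
    annotations = {}
    for tf, targets in sorted(regulons.items()):
        missing = [t for t in targets if t not in col_of]
        if missing:
            raise ValueError(f"regulon targets not in gene universe: {missing[:5]}")
        if len(targets) > top:
            raise ValueError(
                f"regulon of {tf} ({len(targets)}) exceeds the {top} top rank positions"
            )
        ranks = np.empty(n, dtype=int)
        top_positions = rng.choice(np.arange(1, top + 1), size=len(targets), replace=False)
        target_cols = np.array([col_of[t] for t in targets])
        ranks[target_cols] = top_positions
        rest_cols = np.setdiff1d(np.arange(n), target_cols)
        rest_ranks = np.setdiff1d(np.arange(1, n + 1), top_positions)
        ranks[rest_cols] = rng.permutation(rest_ranks)
        motif = f"motif_{tf}"
        rows[motif] = ranks
        annotations[motif] = frozenset({tf})
    for d in range(n_motifs):
        rows[f"decoy_{d:04d}"] = rng.permutation(np.arange(1, n + 1))
    ranks_df = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    ranks_df.index.name = "motif"
    return MotifRankingDB(ranks=ranks_df, annotations=annotations, validate=False)


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: int = 10,
    planted: dict[str, float] | None = None,
    mean: float = 100.0,
    dispersion: float = 0.05,
    gene_ids=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Two-group NB counts with planted log2 fold changes.

    Group "target" gets mean · 2^{+lfc/2}, group "reference"
    mean · 2^{−lfc/2}, so the planted contrast target-vs-reference is
    2^lfc. Returns (counts, group labels, truth).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length mismatch")
    planted = dict(planted or {})
    lfc = np.array([planted.get(g, 0.0) for g in gene_ids])
    mu_t = mean * 2.0 ** (lfc / 2.0)
    mu_r = mean * 2.0 ** (-lfc / 2.0)
    r = 1.0 / dispersion

    def draw(mu):
        return rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, n_per_group))

    counts = np.hstack([draw(mu_t), draw(mu_r)])
    cols = [f"T{j}" for j in range(n_per_group)] + [f"R{j}" for j in range(n_per_group)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=cols)
    groups = pd.Series(["target"] * n_per_group + ["reference"] * n_per_group, index=cols)
    truth = SyntheticTruth(seed=seed, planted_log2fc={g: float(v) for g, v in planted.items()})
    return counts_df, groups, truth


@dataclass
class StudyData:
    """All inputs for one simulated study, plus the planted truth."""

    expression: ExpressionMatrix
    ranking_db: MotifRankingDB
    counts_by_celltype: dict[str, tuple[pd.DataFrame, pd.Series]]
    truth: SyntheticTruth


def simulate_study(
    seed: int = 13,
    n_genes: int = 2000,
    module_sizes=(50, 50, 50),
    n_celltypes: int = 3,
    batch_shifts=(0.0, 1.0),
    noise_sd: float = 0.5,
    n_decoy_motifs: int = 200,
    regulon_frac: float = 0.6,
    top_quantile: float = 0.02,
    counts_per_group: int = 10,
    tf_log2fc: float = 3.0,
    module_log2fc: float = 1.5,
    count_mean: float = 100.0,
    dispersion: float = 0.05,
) -> StudyData:
    """Generate a coherent multi-modal study with one planted TF per module.

    Each planted TF's regulon covers ``regulon_frac`` of its module;
    counts are generated per cell type against a shared reference
    population with the cell type's TF (strongly) and its module genes
    (moderately) upregulated.
    """
    rng = np.random.default_rng(seed)
    em, truth = simulate_expression(
        n_genes=n_genes,
        n_samples=20 * n_celltypes,
        module_sizes=module_sizes,
        n_celltypes=n_celltypes,
        batch_shifts=batch_shifts,
        noise_sd=noise_sd,
        seed=seed,
    )
    # planted regulons: a fixed fraction of each module, TF excluded
    regulons: dict[str, list[str]] = {}
    for tf, mod in truth.planted_tfs.items():
        members = [g for g, m in truth.module_assignment.items() if m == mod and g != tf]
        k = int(round(regulon_frac * (len(members) + 1)))
        chosen = sorted(rng.choice(members, size=min(k, len(members)), replace=False))
        regulons[tf] = list(chosen)
    truth.planted_regulons = regulons

    db = simulate_ranking_db(
        n_decoy_motifs, em.gene_ids, regulons, top_quantile=top_quantile,
        seed=int(rng.integers(2**31 - 1)),
    )

    counts_by_celltype = {}
    for c in range(n_celltypes):
        celltype = f"CT{c + 1}"
        planted: dict[str, float] = {}
        for tf, mod in truth.planted_tfs.items():
            if mod == f"M{c + 1}":
                planted[tf] = tf_log2fc
                for g, m in truth.module_assignment.items():
                    if m == mod and g != tf:
                        planted[g] = module_log2fc
        counts, groups, ct_truth = simulate_counts(
            n_genes=n_genes,
            n_per_group=counts_per_group,
            planted=planted,
            mean=count_mean,
            dispersion=dispersion,
            gene_ids=em.gene_ids,
            seed=int(rng.integers(2**31 - 1)),
        )
        counts_by_celltype[celltype] = (counts, groups)
        truth.planted_log2fc.update({f"{celltype}:{g}": v for g, v in ct_truth.planted_log2fc.items()})
    return StudyData(expression=em, ranking_db=db, counts_by_celltype=counts_by_celltype, truth=truth)


def positivity_summary(positives: int, total: int) -> tuple[float, tuple[float, float]]:
    """Positivity percentage with a 95% Wilson score interval.

    The reporting helper for count data of the form "n positive out of
    N cells": returns (percent rounded to 2 decimals, (lo, hi) CI on
    the percent scale).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    percent = round(100.0 * positives / total, 2)
    lo, hi = proportion_confint(positives, total, alpha=0.05, method="wilson")
    return percent, (100.0 * lo, 100.0 * hi)
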