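"""Core data containers shared across the pipeline.

All matrix-like containers wrap :class:`pandas.DataFrame` in the
genes-by-samples orientation that is conventional for expression data;
the sklearn-style estimators in the individual modules use the
transposed samples-by-features orientation and the wrapper functions
translate between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "ProbeMatrix",
    "ExpressionMatrix",
    "PlatformSummary",
    "ModuleSet",
    "MotifRankingDB",
    "MotifEnrichmentResult",
    "Regulon",
    "ActivityMatrix",
]


@dataclass
class SampleRecord:
    """Metadata for one array/sample, mirroring an SDRF-like table row."""

    sample_id: str
    organism: str = ""
    label: str = ""
    platform_id: str = ""
    study_id: str = ""
    cell_type: str = ""
    characteristics: list[str] = field(default_factory=list)


@dataclass
class ProbeMatrix:
    """Probe-level intensities (linear scale) with a partial probe→gene map."""

    values: pd.DataFrame  # probes × samples
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("probe intensities must be finite")
        if np.any(vals < 0):
            raise ValueError("probe intensities must be non-negative")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values plus per-sample metadata.

    ``log2_scale`` records whether ``values`` are on log2 scale; the
    network, batch-adjustment and gene-filter stages require log2 data.
    """

    values: pd.DataFrame  # genes × samples
    log2_scale: bool = True
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if not np.all(np.isfinite(self.values.values)):
            raise ValueError("expression values must be finite")
        if self.samples:
            ids = [s.sample_id for s in self.samples]
            if ids != list(self.values.columns):
                raise ValueError("sample metadata does not align with matrix columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_frame(self) -> pd.DataFrame:
        """Per-sample metadata as a DataFrame indexed by sample id."""
        if not self.samples:
            return pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        rows = {
            s.sample_id: {
                "organism": s.organism,
                "label": s.label,
                "platform_id": s.platform_id,
                "study_id": s.study_id,
                "cell_type": s.cell_type,
            }
            for s in self.samples
        }
        return pd.DataFrame.from_dict(rows, orient="index").loc[self.sample_ids]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.log2_scale, self.samples)


@dataclass
class PlatformSummary:
    """Sample count and measured gene universe of one array platform."""

    platform_id: str
    n_samples: int
    gene_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        self.gene_set = frozenset(self.gene_set)
        if not self.gene_set:
            raise ValueError("gene_set must be non-empty")


@dataclass
class ModuleSet:
    """Gene→module assignment with module eigengenes and kME centralities.

    ``assignment`` maps gene → colour label; ``"grey"`` marks unassigned
    genes. ``eigengenes`` is modules × samples (unit-norm rows); ``kme``
    is genes × modules Pearson correlation with the eigengenes.
    """

    assignment: pd.Series  # gene -> colour label
    eigengenes: pd.DataFrame  # module × sample
    kme: pd.DataFrame  # gene × module

    def module_genes(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)

    def as_gene_sets(self, include_grey: bool = False) -> dict[str, list[str]]:
        out = {}
        for m in self.assignment.unique():
            if m == "grey" and not include_grey:
                continue
            out[m] = self.module_genes(m)
        return out


@dataclass
class MotifRankingDB:
    """Motif × gene integer rank matrix with motif→TF annotations.

    Each row is a permutation of 1..N over the gene universe: rank 1 is
    the gene whose regulatory region scores best for that motif.
    """

    ranks: pd.DataFrame  # motifs × genes, integer ranks
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    validate: bool = True

    def __post_init__(self) -> None:
        self.annotations = {m: frozenset(t) for m, t in self.annotations.items()}
        if self.validate:
            n = self.ranks.shape[1]
            expected = np.arange(1, n + 1)
            arr = np.sort(self.ranks.values, axis=1)
            if not np.array_equal(arr, np.broadcast_to(expected, arr.shape)):
                raise ValueError("each motif row must be a permutation of 1..N")

    @property
    def motif_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass
class MotifEnrichmentResult:
    module: str
    motif_id: str
    auc: float
    nes: float
    tfs: frozenset[str]
    leading_edge: frozenset[str]


@dataclass
class Regulon:
    """A TF with the module targets supported by its enriched motifs."""

    tf: str
    module: str
    targets: frozenset[str]
    best_nes: float


@dataclass
class ActivityMatrix:
    """Per-sample module activity scores plus per-cell-type means."""

    scores: pd.DataFrame  # modules × samples, values in [-1, 1]
    celltype_means: pd.DataFrame  # modules × cell types

    def __post_init__(self) -> None:
        if np.any(np.abs(self.scores.values) > 1 + 1e-12):
            raise ValueError("activity scores must lie in [-1, 1]")
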