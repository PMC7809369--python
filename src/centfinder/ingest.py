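"""Reading expression matrices and metadata, sample inclusion rules,
probe→gene aggregation, quantile normalisation and platform selection.

The ingestion stage works entirely offline from TSV files: an
SDRF-like sample table, probe- or gene-level matrices and a
probe→gene map. Platform selection follows the product rule: choose
the platform subset maximising (total samples) × (common genes),
optionally forcing platforms in (e.g. the only available arrays for a
rare cell type, even if they shrink the common gene universe).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import ExpressionMatrix, PlatformSummary, ProbeMatrix, SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InclusionRules",
    "filter_samples",
    "aggregate_probes",
    "QuantileNormalizer",
    "quantile_normalize",
    "select_platforms",
    "assemble_matrix",
    "read_matrix_tsv",
    "read_metadata_tsv",
    "read_probe_map_tsv",
]

#: substrings flagging cancerous samples; matched case-insensitively
DEFAULT_DENYLIST = ("carcinoma", "tumor", "tumour", "cancer", "hcc")


@dataclass
class InclusionRules:
    """Sample-inclusion configuration.

    A record is kept iff its organism and label are whitelisted, its
    platform id starts with one of the allowed prefixes, and none of
    its free-text characteristics contains a denied substring
    (case-insensitive). The defaults keep human, biotin-labelled
    Affymetrix samples of non-cancerous origin.
    """

    organisms: tuple[str, ...] = ("Homo sapiens",)
    labels: tuple[str, ...] = ("biotin",)
    platform_prefixes: tuple[str, ...] = ("A-AFFY",)
    deny_substrings: tuple[str, ...] = DEFAULT_DENYLIST


def filter_samples(records: list[SampleRecord], rules: InclusionRules) -> list[SampleRecord]:
    """Apply the four inclusion rules, preserving input order.

    Malformed records (missing organism) are rejected with a logged
    reason rather than raising; an empty result is a warning only.
    """
    kept: list[SampleRecord] = []
    deny = tuple(d.lower() for d in rules.deny_substrings)
    for rec in records:
        if not rec.organism:
            logger.warning("sample %s rejected: missing organism", rec.sample_id)
            continue
        if rec.organism not in rules.organisms:
            continue
        if rec.label not in rules.labels:
            continue
        if not any(rec.platform_id.startswith(p) for p in rules.platform_prefixes):
            continue
        chars = " ; ".join(rec.characteristics).lower()
        if any(d in chars for d in deny):
            continue
        kept.append(rec)
    if not kept:
        warnings.warn("no samples pass the inclusion rules", stacklevel=2)
    return kept


def aggregate_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Collapse probe intensities to genes by their geometric mean.

    Probes with no gene mapping are dropped. Mapped probes must be
    strictly positive (the geometric mean is undefined otherwise).
    Output is linear scale (``log2_scale=False``).
    """
    mapped = [p for p in pm.values.index if p in pm.probe_to_gene]
    if not mapped:
        raise ValueError("no probe maps to a gene")
    sub = pm.values.loc[mapped]
    bad = np.argwhere(sub.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity for mapped probe {sub.index[i]!r} "
            f"in sample {sub.columns[j]!r}"
        )
    genes = pd.Index([pm.probe_to_gene[p] for p in mapped], name="gene")
    logvals = np.log(sub.values)
    out = pd.DataFrame(logvals, index=genes, columns=sub.columns).groupby(level=0).mean()
    return ExpressionMatrix(np.exp(out), log2_scale=False)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample onto a common reference distribution.

    sklearn-style transformer over ``X`` of shape (n_samples, n_genes):
    ``fit`` learns the reference distribution (the pointwise mean of
    the sorted sample vectors) and ``transform`` replaces each sample's
    values by the reference values at the matching ranks. Ties within
    a sample all receive the mean of the reference values over the tied
    block, so the map is well defined and rank-preserving.

    A convenience stand-in for full probe-level normalisation when the
    input matrices are already summarised at gene level.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        ref = self.reference_
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            order = np.argsort(row, kind="stable")
            mapped = np.empty_like(ref)
            # tie blocks share the mean reference value of their positions
            sorted_vals = row[order]
            start = 0
            for stop in range(1, len(row) + 1):
                if stop == len(row) or sorted_vals[stop] != sorted_vals[start]:
                    mapped[start:stop] = ref[start:stop].mean()
                    start = stop
            out[i, order] = mapped
        return out


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise the samples of an expression matrix."""
    if em.values.shape[1] < 2:
        raise ValueError("quantile normalisation requires at least 2 samples")
    qn = QuantileNormalizer()
    normalised = qn.fit_transform(em.values.values.T).T
    return ExpressionMatrix(
        pd.DataFrame(normalised, index=em.values.index, columns=em.values.columns),
        em.log2_scale,
        em.samples,
    )


def _objective(platforms: list[PlatformSummary], subset: tuple[int, ...]) -> tuple[int, frozenset]:
    common = frozenset.intersection(*(platforms[i].gene_set for i in subset))
    n = sum(platforms[i].n_samples for i in subset)
    return n * len(common), common


def select_platforms(
    platforms: list[PlatformSummary],
    forced: set[str] = frozenset(),
    max_exhaustive: int = 20,
) -> tuple[set[str], set[str]]:
    """Choose the platform subset maximising samples × common genes.

    Every subset containing ``forced`` is scored exhaustively (ties
    broken by the lexicographically smallest id set); above
    ``max_exhaustive`` platforms a greedy forward search is used
    instead. Returns the chosen platform ids and their common genes.
    """
    ids = [p.platform_id for p in platforms]
    missing = set(forced) - set(ids)
    if missing:
        raise ValueError(f"forced platform(s) not available: {sorted(missing)}")
    for p in platforms:
        if p.n_samples == 1:
            warnings.warn(
                f"platform {p.platform_id} has a single sample; single-sample "
                "platforms should normally be excluded upstream",
                stacklevel=2,
            )
    forced_idx = [i for i, p in enumerate(platforms) if p.platform_id in forced]
    free_idx = [i for i in range(len(platforms)) if i not in forced_idx]

    if len(platforms) <= max_exhaustive:
        best = None
        for r in range(len(free_idx) + 1):
            for combo in itertools.combinations(free_idx, r):
                subset = tuple(forced_idx) + combo
                if not subset:
                    continue
                score, common = _objective(platforms, subset)
                key = tuple(sorted(ids[i] for i in subset))
                if best is None or score > best[0] or (score == best[0] and key < best[1]):
                    best = (score, key, subset, common)
        assert best is not None
        _, _, subset, common = best
    else:  # greedy forward search
        subset = tuple(forced_idx)
        if not subset:
            subset = (max(range(len(platforms)), key=lambda i: _objective(platforms, (i,))[0]),)
        score, common = _objective(platforms, subset)
        remaining = [i for i in free_idx if i not in subset]
        improved = True
        while improved and remaining:
            improved = False
            scored = [(_objective(platforms, subset + (i,))[0], ids[i], i) for i in remaining]
            cand_score, _, cand = max(scored, key=lambda t: (t[0], [-ord(c) for c in t[1]]))
            if cand_score > score:
                subset = subset + (cand,)
                score, common = _objective(platforms, subset)
                remaining.remove(cand)
                improved = True
    return {ids[i] for i in subset}, set(common)


def assemble_matrix(
    ems: dict[str, ExpressionMatrix],
    chosen: set[str],
) -> ExpressionMatrix:
    """Merge per-platform matrices on their common genes.

    Columns are concatenated platform by platform (sorted id order for
    determinism); matrices flagged linear-scale are transformed with
    log2(x + 1). The platform id is recorded on each sample so that it
    can serve as the batch key downstream.
    """
    order = sorted(chosen)
    gene_sets = [frozenset(ems[p].gene_ids) for p in order]
    common = frozenset.intersection(*gene_sets)
    if not common:
        raise ValueError("chosen platforms share no genes")
    genes = sorted(common)
    blocks = []
    samples: list[SampleRecord] = []
    for p in order:
        em = ems[p]
        vals = em.values.loc[genes]
        if not em.log2_scale:
            vals = np.log2(vals + 1.0)
        blocks.append(vals)
        recs = em.samples or [SampleRecord(sample_id=s) for s in em.sample_ids]
        for r in recs:
            samples.append(
                SampleRecord(
                    sample_id=r.sample_id,
                    organism=r.organism,
                    label=r.label,
                    platform_id=p,
                    study_id=r.study_id,
                    cell_type=r.cell_type,
                    characteristics=list(r.characteristics),
                )
            )
    merged = pd.concat(blocks, axis=1)
    return ExpressionMatrix(merged, log2_scale=True, samples=samples)


# ---------------------------------------------------------------------------
# TSV readers


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a gene/probe × sample TSV matrix (first column = row id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path) -> list[SampleRecord]:
    """Read an SDRF-like sample metadata TSV.

    Expected columns: sample_id, organism, label, platform_id,
    study_id, cell_type, characteristics (semicolon-joined).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        chars = [c.strip() for c in row.get("characteristics", "").split(";") if c.strip()]
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                organism=row.get("organism", ""),
                label=row.get("label", ""),
                platform_id=row.get("platform_id", ""),
                study_id=row.get("study_id", ""),
                cell_type=row.get("cell_type", ""),
                characteristics=chars,
            )
        )
    return records


def read_probe_map_tsv(path) -> dict[str, str]:
    """Read a two-column probe→gene TSV (header ignored by name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
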