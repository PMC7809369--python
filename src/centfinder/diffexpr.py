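"""Length-aware TPM quantification and differential expression.

Bulk counts are normalised by median-of-ratios size factors and tested
gene-by-gene with a two-group negative-binomial log-linear model: a
method-of-moments gene-wise dispersion, an IRLS fit of the group
effect, and a Wald test on the group coefficient, followed by
Benjamini–Hochberg adjustment. This is a deliberately plain NB Wald
test — no dispersion shrinkage towards a mean–dispersion trend and no
fold-change shrinkage — adequate for the moderately replicated
synthetic designs it is exercised on. Marker testing for single-cell
labels uses the Wilcoxon rank-sum test, and a cross-dataset consensus
rule keeps genes whose fold change clears a threshold in every study.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix  # noqa: F401  (re-exported context)

logger = logging.getLogger(__name__)

__all__ = [
    "merged_exon_length",
    "exon_lengths_from_gtf",
    "tpm",
    "size_factors",
    "nb_wald_de",
    "bh_adjust",
    "wilcoxon_markers",
    "consensus_markers",
    "sample_quality_gate",
]


def merged_exon_length(exons) -> int:
    """Total length (bp) of the union of 1-based inclusive exon intervals."""
    if not exons:
        raise ValueError("gene model needs at least one exon")
    ivals = []
    for chrom, start, end in exons:
        if start > end or start < 1:
            raise ValueError(f"malformed interval ({chrom}, {start}, {end})")
        ivals.append((chrom, int(start), int(end)))
    ivals.sort()
    total = 0
    cur = None
    for chrom, start, end in ivals:
        if cur is None or chrom != cur[0] or start > cur[2] + 1:
            if cur is not None:
                total += cur[2] - cur[1] + 1
            cur = [chrom, start, end]
        else:
            cur[2] = max(cur[2], end)
    total += cur[2] - cur[1] + 1
    return total


def exon_lengths_from_gtf(gtf_path) -> pd.Series:
    """Merged exon length per gene from a GTF file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="merge", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    lengths = {}
    for feat in db.features_of_type("exon"):
        gene = feat.attributes.get("gene_id", ["?"])[0]
        lengths.setdefault(gene, []).append((feat.seqid, feat.start, feat.end))
    return pd.Series(
        {g: merged_exon_length(exons) for g, exons in sorted(lengths.items())},
        name="merged_exon_length",
    )


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and merged exon lengths."""
    lengths = lengths.reindex(counts.index)
    nonzero = counts.sum(axis=1) > 0
    bad = lengths[nonzero][(lengths[nonzero].isna()) | (lengths[nonzero] <= 0)]
    if len(bad):
        raise ValueError(f"zero/missing length for expressed gene(s): {list(bad.index[:5])}")
    rate = counts.div(lengths.replace(0, np.nan), axis=0).fillna(0.0)
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(f"all-zero sample column(s): {list(denom.index[zero_cols])}", stacklevel=2)
        denom = denom.replace(0, np.nan)
    out = rate.div(denom, axis=1) * 1e6
    return out.fillna(0.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    arr = counts.values.astype(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    log_geo = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns, name="size_factor")


def _nb_irls(y: np.ndarray, g: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             n_iter: int = 50, tol: float = 1e-8):
    """Vectorised two-group NB IRLS across genes.

    y: genes × samples counts; g: 0/1 group indicator per sample;
    offset: log size factor per sample; alpha: per-gene dispersion.
    Returns beta0, beta1, se(beta1).
    """
    n_genes = y.shape[0]
    in0, in1 = g == 0, g == 1
    # init from group means of normalised counts
    ynorm = y / np.exp(offset)[None, :]
    mu0 = np.maximum(ynorm[:, in0].mean(axis=1), 1e-8)
    mu1 = np.maximum(ynorm[:, in1].mean(axis=1), 1e-8)
    b0 = np.log(mu0)
    b1 = np.log(mu1) - np.log(mu0)
    for _ in range(n_iter):
        eta = b0[:, None] + b1[:, None] * g[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        s00 = w.sum(axis=1)
        s01 = (w * g).sum(axis=1)
        s11 = (w * g * g).sum(axis=1)
        r0 = (w * z).sum(axis=1)
        r1 = (w * g * z).sum(axis=1)
        det = s00 * s11 - s01**2
        det = np.where(det <= 0, np.nan, det)
        nb0 = (s11 * r0 - s01 * r1) / det
        nb1 = (s00 * r1 - s01 * r0) / det
        step = max(np.nanmax(np.abs(nb0 - b0), initial=0), np.nanmax(np.abs(nb1 - b1), initial=0))
        b0 = np.where(np.isfinite(nb0), nb0, b0)
        b1 = np.where(np.isfinite(nb1), nb1, b1)
        if step < tol:
            break
    eta = b0[:, None] + b1[:, None] * g[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1)
    s01 = (w * g).sum(axis=1)
    s11 = (w * g * g).sum(axis=1)
    det = s00 * s11 - s01**2
    se1 = np.sqrt(np.where(det > 0, s00 / det, np.nan))
    return b0, b1, se1


def nb_wald_de(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    reference: str | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression.

    The reported log2 fold change contrasts the non-reference group
    against ``reference`` (default: the first group label seen).
    Significance combines the BH-adjusted p value (< ``alpha``) with
    the biological-relevance rule |log2 fold change| ≥ ``lfc_threshold``
    (i.e. at least twofold by default).
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among groups {levels}")
    target = next(lv for lv in levels if lv != reference)
    g = (groups == target).astype(float).values
    if (g == 0).sum() < 2 or (g == 1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    sf = size_factors(counts)
    y = counts.values.astype(float)
    offset = np.log(sf.values)
    ynorm = y / sf.values[None, :]

    # method-of-moments dispersion from within-group variability
    means = np.stack([ynorm[:, g == 0].mean(axis=1), ynorm[:, g == 1].mean(axis=1)])
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    ss = (ynorm[:, g == 0] - means[0][:, None]) ** 2
    ss1 = (ynorm[:, g == 1] - means[1][:, None]) ** 2
    var_within = (ss.sum(axis=1) + ss1.sum(axis=1)) / (n0 + n1 - 2)
    mu_bar = ynorm.mean(axis=1)
    disp = np.maximum((var_within - mu_bar) / np.maximum(mu_bar, 1e-8) ** 2, 1e-8)

    b0, b1, se1 = _nb_irls(y, g, offset, disp)
    z = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)
    padj = bh_adjust(p)
    log2fc = b1 / np.log(2.0)
    df = pd.DataFrame(
        {
            "base_mean": mu_bar,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "significant": (padj < alpha) & (np.abs(log2fc) >= lfc_threshold),
        },
        index=counts.index,
    )
    df.attrs["contrast"] = (str(target), str(reference))
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_markers(
    expr: pd.DataFrame,
    labels,
    target_label: str,
    exact_max: int = 8,
) -> pd.DataFrame:
    """Per-gene rank-sum marker test of ``target_label`` vs the rest.

    Uses exact enumeration when both sides have at most ``exact_max``
    observations and no ties, the tie-corrected normal approximation
    otherwise. Fold change compares linear-scale group means.
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    if labels.nunique() < 2:
        raise ValueError("need at least two distinct labels")
    in_t = (labels == target_label).values
    n_t, n_o = int(in_t.sum()), int((~in_t).sum())
    if n_t < 3 or n_o < 3:
        raise ValueError("need at least 3 cells per side")
    pvals = np.empty(expr.shape[0])
    log2fc = np.empty(expr.shape[0])
    for i, (_, row) in enumerate(expr.iterrows()):
        a = row.values[in_t].astype(float)
        b = row.values[~in_t].astype(float)
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[i] = 1.0
        else:
            method = "exact" if (n_t <= exact_max and n_o <= exact_max and not has_ties) else "asymptotic"
            pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        mean_a, mean_b = a.mean(), b.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc[i] = np.log2(mean_a / mean_b) if mean_b > 0 else np.inf if mean_a > 0 else 0.0
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "padj": bh_adjust(pvals)}, index=expr.index
    )


def consensus_markers(
    fc_tables: list[pd.Series],
    microarray_fc: pd.Series,
    threshold: float = 7.0,
) -> pd.Series:
    """Genes above the fold-change threshold in every dataset.

    Survivors are ranked by the microarray fold change, descending.
    Genes missing from any table are dropped; infinite fold changes
    (zero denominators upstream) survive the threshold and are logged.
    """
    if not fc_tables:
        raise ValueError("need at least one fold-change table")
    common = set(microarray_fc.index)
    for t in fc_tables:
        common &= set(t.index)
    keep = [g for g in common if all(t[g] > threshold for t in fc_tables)]
    n_inf = sum(1 for g in keep if any(np.isinf(t[g]) for t in fc_tables))
    if n_inf:
        logger.info("%d gene(s) kept with infinite fold change", n_inf)
    out = microarray_fc.loc[keep].sort_values(ascending=False)
    out.index.name = "gene"
    return out


def sample_quality_gate(
    tpm_matrix: pd.DataFrame,
    required_genes,
    min_tpm: float = 1.0,
) -> list[str]:
    """Samples expressing every required marker above ``min_tpm`` TPM.

    Screens out mislabelled samples, e.g. nominal LSEC libraries that
    do not express the canonical LSEC receptors.
    """
    required = [g for g in required_genes if g in tpm_matrix.index]
    missing = set(required_genes) - set(required)
    if missing:
        warnings.warn(f"required gene(s) absent from matrix: {sorted(missing)}", stacklevel=2)
    if not required:
        return list(tpm_matrix.columns)
    ok = (tpm_matrix.loc[required] > min_tpm).all(axis=0)
    return list(tpm_matrix.columns[ok])
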