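"""Gene-inclusion rules applied before network construction.

Transcription factors are kept only when they vary at least twofold
across the samples (log2 range >= 1); all other genes are ranked by
the standard deviation of their log2 values and either capped to a
total gene budget or thresholded on that standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["filter_genes", "read_tf_list"]


def filter_genes(
    em: ExpressionMatrix,
    tf_list: set[str],
    total_cap: int | None = None,
    sd_threshold: float | None = None,
) -> ExpressionMatrix:
    """Apply the TF twofold rule and the non-TF variability cap.

    Exactly one of ``total_cap`` (total gene budget; non-TFs fill the
    room left by kept TFs, most variable first) or ``sd_threshold``
    (keep non-TFs with log2 SD strictly above it) must be given. Ties
    at the cap boundary are broken by gene symbol ascending. The
    returned matrix keeps the original row order.
    """
    if (total_cap is None) == (sd_threshold is None):
        raise ValueError("give exactly one of total_cap / sd_threshold")
    if not em.log2_scale:
        raise ValueError("gene filtering expects log2-scale data")

    genes = em.values.index
    unknown = set(tf_list) - set(genes)
    if unknown:
        warnings.warn(f"{len(unknown)} TF symbol(s) not in the matrix; ignored", stacklevel=2)
    tfs = [g for g in genes if g in tf_list]
    non_tfs = [g for g in genes if g not in tf_list]

    vals = em.values
    log2_range = vals.loc[tfs].max(axis=1) - vals.loc[tfs].min(axis=1)
    kept_tfs = [g for g in tfs if log2_range[g] >= 1.0]

    sd = vals.loc[non_tfs].std(axis=1, ddof=1) if non_tfs else pd.Series(dtype=float)
    if total_cap is not None:
        room = total_cap - len(kept_tfs)
        if room < 0:
            raise ValueError(
                f"total_cap={total_cap} smaller than the {len(kept_tfs)} TFs kept"
            )
        order = sorted(non_tfs, key=lambda g: (-sd[g], g))
        kept_non_tfs = set(order[:room])
    else:
        kept_non_tfs = {g for g in non_tfs if sd[g] > sd_threshold}

    keep = [g for g in genes if (g in kept_non_tfs or g in set(kept_tfs))]
    return em.subset_genes(keep)


def read_tf_list(path) -> set[str]:
    """Read a one-symbol-per-line TF list (as distributed by humantfs)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
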