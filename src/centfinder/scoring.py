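"""Per-sample module activity scoring and GO annotation of modules.

Module activity uses gene-set variation scoring: each gene's
expression is turned into a smooth empirical CDF estimate across
samples (Gaussian kernel, bandwidth s/4), genes are ranked per sample,
and a weighted Kolmogorov–Smirnov random walk over the ranking
measures whether the module's genes concentrate at the top (score near
+1) or bottom (near −1) of that sample's profile. Scores are
summarised per cell type, and modules are annotated by one-sided
Fisher exact GO term enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ActivityMatrix, ExpressionMatrix

__all__ = [
    "GSVAScorer",
    "gsva_scores",
    "celltype_activity",
    "go_fisher",
    "read_gmt",
    "propagate_obo",
]


class GSVAScorer(TransformerMixin, BaseEstimator):
    """Transform samples × genes expression into samples × sets activity.

    Parameters
    ----------
    gene_sets : mapping set name → list of member genes.
    tau : exponent on the symmetric rank statistic weighting in-set
        steps of the random walk.
    kcdf : only the Gaussian kernel CDF is implemented.
    mx_diff : score = (max positive walk deviation) + (min negative
        deviation) when True; the single largest |deviation| otherwise.

    The kernel CDF is estimated within the transformed matrix itself
    (every sample is compared against all samples of the same call),
    so scoring is relative to the cohort being scored.
    """

    def __init__(self, gene_sets=None, tau: float = 1.0, kcdf: str = "gaussian",
                 mx_diff: bool = True):
        self.gene_sets = gene_sets
        self.tau = tau
        self.kcdf = kcdf
        self.mx_diff = mx_diff

    def fit(self, X, y=None, feature_names=None):
        X = np.asarray(X, dtype=float)
        if self.kcdf != "gaussian":
            raise ValueError("only the gaussian kernel CDF is supported")
        if not self.gene_sets:
            raise ValueError("gene_sets is required")
        if feature_names is None:
            feature_names = [str(i) for i in range(X.shape[1])]
        self.feature_names_ = list(feature_names)
        self.set_names_ = list(self.gene_sets)
        name_to_col = {g: i for i, g in enumerate(self.feature_names_)}
        n = len(self.feature_names_)
        self.set_indices_ = {}
        for name, members in self.gene_sets.items():
            idx = sorted({name_to_col[g] for g in members if g in name_to_col})
            if len(idx) < 2:
                raise ValueError(f"gene set {name!r} has fewer than 2 genes in the matrix")
            if len(idx) >= n:
                raise ValueError(f"gene set {name!r} covers the whole gene universe")
            self.set_indices_[name] = np.array(idx)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        n_samples, n_genes = X.shape
        if n_samples < 3:
            raise ValueError("scoring requires at least 3 samples")
        if n_genes != len(self.feature_names_):
            raise ValueError("gene universe mismatch")

        z = self._kernel_cdf(X)
        # per-sample ranking, rank 1 = highest kernel-CDF statistic
        order = np.argsort(-z, axis=1, kind="stable")
        ranks = np.empty_like(order)
        rows = np.arange(n_samples)[:, None]
        ranks[rows, order] = np.arange(1, n_genes + 1)
        r_sym = np.abs(n_genes / 2.0 - ranks) ** self.tau

        scores = np.empty((n_samples, len(self.set_names_)))
        for s_i, name in enumerate(self.set_names_):
            member = np.zeros(n_genes, dtype=bool)
            member[self.set_indices_[name]] = True
            n_out = n_genes - member.sum()
            in_sorted = member[order]  # walk order per sample
            w = np.where(in_sorted, np.take_along_axis(r_sym, order, axis=1), 0.0)
            w_sum = w.sum(axis=1, keepdims=True)
            steps = np.where(in_sorted, w / w_sum, -1.0 / n_out)
            walk = np.cumsum(steps, axis=1)
            if self.mx_diff:
                pos = np.clip(walk.max(axis=1), 0.0, None)
                neg = np.clip(walk.min(axis=1), None, 0.0)
                scores[:, s_i] = pos + neg
            else:
                imax = np.argmax(np.abs(walk), axis=1)
                scores[:, s_i] = walk[np.arange(n_samples), imax]
        return scores

    def _kernel_cdf(self, X: np.ndarray) -> np.ndarray:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd < 1e-8):
            warnings.warn("constant gene(s): kernel bandwidth floored at 1e-8", stacklevel=2)
        h = np.maximum(sd / 4.0, 1e-8)
        # z[j, g] = mean_k Phi((x_jg - x_kg) / h_g)
        diff = (X[:, None, :] - X[None, :, :]) / h[None, None, :]
        return norm.cdf(diff).mean(axis=1)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)


def gsva_scores(
    em: ExpressionMatrix,
    module_sets: dict[str, list[str]],
    tau: float = 1.0,
    kcdf: str = "gaussian",
    mx_diff: bool = True,
) -> ActivityMatrix:
    """Score each module gene set in every sample; means per cell type."""
    scorer = GSVAScorer(gene_sets=module_sets, tau=tau, kcdf=kcdf, mx_diff=mx_diff)
    scores = scorer.fit_transform(em.values.values.T, feature_names=em.gene_ids)
    score_df = pd.DataFrame(scores.T, index=scorer.set_names_, columns=em.sample_ids)
    meta = em.sample_frame()
    if "cell_type" in meta.columns and meta["cell_type"].astype(bool).any():
        means = score_df.T.groupby(meta["cell_type"]).mean().T
    else:
        means = pd.DataFrame(index=score_df.index)
    return ActivityMatrix(scores=score_df, celltype_means=means)


def celltype_activity(
    am: ActivityMatrix,
    metadata: pd.DataFrame,
    target_celltype: str,
    per_type: bool = False,
) -> pd.DataFrame:
    """Per module: is it more active in the target cell type?

    ``target_active`` compares the mean score over target samples to
    the pooled mean over all other samples (strict inequality), or —
    with ``per_type=True`` — requires the target mean to exceed every
    other cell type's mean individually.
    """
    cell_types = metadata.loc[am.scores.columns, "cell_type"]
    target_mask = (cell_types == target_celltype).values
    if not target_mask.any():
        raise ValueError(f"no samples of cell type {target_celltype!r}")
    if target_mask.all():
        raise ValueError("all samples belong to the target cell type")
    tgt = am.scores.loc[:, target_mask].mean(axis=1)
    other = am.scores.loc[:, ~target_mask].mean(axis=1)
    if per_type:
        others = am.scores.T.groupby(cell_types.values).mean().T.drop(columns=target_celltype)
        active = others.lt(tgt, axis=0).all(axis=1)
    else:
        active = tgt > other
    return pd.DataFrame(
        {"module": am.scores.index, "target_mean": tgt.values,
         "other_mean": other.values, "target_active": active.values}
    ).set_index("module")


def go_fisher(
    module_genes,
    background,
    annotations: pd.DataFrame,
    top_n: int = 15,
) -> pd.DataFrame:
    """One-sided Fisher exact GO enrichment, top terms per category.

    ``annotations`` has columns gene, term, category (BP/CC/MF),
    already propagated to ancestor terms (see :func:`propagate_obo`).
    Returns the ``top_n`` smallest-p terms per category, ties broken
    by term id.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    module = set(module_genes)
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    ann = annotations[annotations["gene"].isin(background)]
    rows = []
    n_mod = len(module)
    n_bg = len(background)
    for (term, category), grp in ann.groupby(["term", "category"], sort=True):
        annotated = set(grp["gene"])
        k = len(module & annotated)
        big_k = len(annotated)
        table = [[k, n_mod - k], [big_k - k, n_bg - n_mod - (big_k - k)]]
        p = fisher_exact(table, alternative="greater")[1]
        rows.append((category, term, k, big_k, n_mod, n_bg, float(p)))
    df = pd.DataFrame(
        rows, columns=["category", "term", "module_hits", "background_hits",
                       "module_size", "background_size", "p"]
    )
    out = (
        df.sort_values(["category", "p", "term"])
        .groupby("category", group_keys=False)
        .head(top_n)
        .reset_index(drop=True)
    )
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def propagate_obo(annotations: pd.DataFrame, obo_path) -> pd.DataFrame:
    """Propagate gene→term annotations to is_a/part_of ancestors.

    Needs the optional :mod:`obonet` reader; the returned frame has the
    same columns with ancestor rows added (category inherited from the
    ontology namespace when available, else from the child row).
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(obo_path)
    ns_map = {"biological_process": "BP", "cellular_component": "CC",
              "molecular_function": "MF"}
    rows = []
    for _, row in annotations.iterrows():
        term = row["term"]
        rows.append((row["gene"], term, row["category"]))
        if term not in graph:
            continue
        for anc in nx.descendants(graph, term):  # edges point child -> parent
            ns = graph.nodes[anc].get("namespace", "")
            rows.append((row["gene"], anc, ns_map.get(ns, row["category"])))
    out = pd.DataFrame(rows, columns=["gene", "term", "category"]).drop_duplicates()
    return out.reset_index(drop=True)
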