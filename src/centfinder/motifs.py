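"""Motif ranking-recovery enrichment (cisTarget-style) and regulons.

Each motif in the ranking database orders the whole gene universe by
how well the genes' regulatory regions score for that motif. For a
module gene set S the recovery curve rec(x) counts the members of S
found within the top x ranks; the area under this curve up to a small
fraction of the ranking (the AUC) measures motif enrichment. AUCs are
standardised across all motifs in the database into a normalised
enrichment score (NES), and for enriched motifs the leading edge — the
set members recovered before the recovery curve's maximal excursion
above the mean + 2·SD critical curve — gives the motif's predicted
targets. Motif→TF annotations then lift enriched motifs to TF regulons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MotifEnrichmentResult, MotifRankingDB, Regulon

__all__ = [
    "recovery_curve",
    "recovery_auc",
    "module_enrichment",
    "build_regulons",
    "read_ranking_db",
    "read_annotations_tsv",
]


def _top_rank(n_genes: int, top_frac: float) -> int:
    t = int(np.ceil(top_frac * n_genes))
    if t < 1:
        raise ValueError("top_frac too small: no ranks to inspect")
    return t


def _set_ranks(db: MotifRankingDB, gene_set) -> tuple[list[str], np.ndarray]:
    genes = [g for g in gene_set if g in db.ranks.columns]
    dropped = len(set(gene_set)) - len(set(genes))
    if dropped:
        warnings.warn(f"{dropped} gene(s) absent from the ranking db; dropped", stacklevel=3)
    if not genes:
        raise ValueError("gene set empty after intersecting with the ranking db")
    return genes, db.ranks[genes].values


def recovery_curve(db: MotifRankingDB, motif: str, gene_set, top_frac: float = 0.05) -> np.ndarray:
    """rec(x) for x = 1..T: members of ``gene_set`` at rank ≤ x."""
    t = _top_rank(db.ranks.shape[1], top_frac)
    _, ranks = _set_ranks(db, gene_set)
    r = ranks[db.motif_ids.index(motif)]
    return np.array([(r <= x).sum() for x in range(1, t + 1)], dtype=float)


def recovery_auc(db: MotifRankingDB, motif: str, gene_set, top_frac: float = 0.05) -> float:
    """AUC = Σ_{x=1..T} rec(x) / (T · |S|), in [0, 1]."""
    t = _top_rank(db.ranks.shape[1], top_frac)
    genes, ranks = _set_ranks(db, gene_set)
    r = ranks[db.motif_ids.index(motif)]
    # each member at rank r ≤ T contributes (T - r + 1) to the sum of rec
    contrib = np.clip(t - r + 1, 0, None).sum()
    return float(contrib / (t * len(genes)))


def _all_aucs(ranks: np.ndarray, t: int) -> np.ndarray:
    contrib = np.clip(t - ranks + 1, 0, None).sum(axis=1)
    return contrib / (t * ranks.shape[1])


def module_enrichment(
    db: MotifRankingDB,
    module_genes,
    module: str = "",
    nes_cut: float = 3.0,
    top_frac: float = 0.05,
    min_genes: int = 5,
) -> list[MotifEnrichmentResult]:
    """Score every motif against a module gene set and keep NES ≥ cut.

    The NES standardises each motif's AUC against the AUC distribution
    of *all* motifs in the database for this same gene set. For kept
    motifs the leading edge collects the set members ranked at or
    before the point where the recovery curve most exceeds the
    across-motif critical curve mean(rec) + 2·sd(rec).
    """
    if db.ranks.shape[0] < 2:
        raise ValueError("NES undefined: database has fewer than 2 motifs")
    genes, ranks = _set_ranks(db, module_genes)
    if len(genes) < min_genes:
        raise ValueError(f"module has {len(genes)} genes in the db; needs >= {min_genes}")
    t = _top_rank(db.ranks.shape[1], top_frac)
    aucs = _all_aucs(ranks, t)
    sd = aucs.std()
    if sd == 0:
        raise ValueError("degenerate database: all AUCs identical")
    nes = (aucs - aucs.mean()) / sd
    keep = np.where(nes >= nes_cut)[0]
    if keep.size == 0:
        return []

    # recovery curves for all motifs -> critical curve mean + 2 sd
    xs = np.arange(1, t + 1)
    rec_all = (ranks[:, None, :] <= xs[None, :, None]).sum(axis=2).astype(float)
    critical = rec_all.mean(axis=0) + 2.0 * rec_all.std(axis=0)

    results = []
    gene_arr = np.array(genes, dtype=object)
    for i in keep:
        excess = rec_all[i] - critical
        x_star = int(xs[np.argmax(excess)])
        leading = frozenset(gene_arr[ranks[i] <= x_star])
        motif_id = db.motif_ids[i]
        results.append(
            MotifEnrichmentResult(
                module=module,
                motif_id=motif_id,
                auc=float(aucs[i]),
                nes=float(nes[i]),
                tfs=db.annotations.get(motif_id, frozenset()),
                leading_edge=leading,
            )
        )
    results.sort(key=lambda r: (-r.nes, r.motif_id))
    return results


def build_regulons(results: list[MotifEnrichmentResult]) -> list[Regulon]:
    """Collapse enriched, annotated motifs into per-(TF, module) regulons.

    Targets are the union of the leading edges of the TF's enriched
    motifs within a module; the best (largest) NES is recorded.
    """
    acc: dict[tuple[str, str], dict] = {}
    for res in results:
        for tf in res.tfs:
            key = (tf, res.module)
            entry = acc.setdefault(key, {"targets": set(), "best_nes": -np.inf})
            entry["targets"] |= res.leading_edge
            entry["best_nes"] = max(entry["best_nes"], res.nes)
    return [
        Regulon(tf=tf, module=mod, targets=frozenset(v["targets"]), best_nes=float(v["best_nes"]))
        for (tf, mod), v in sorted(acc.items())
    ]


def read_ranking_db(rankings_path, annotations_path=None) -> MotifRankingDB:
    """Read a motif × gene rank matrix (TSV or feather) and annotations."""
    path = str(rankings_path)
    if path.endswith(".feather"):
        ranks = pd.read_feather(path)
        ranks = ranks.set_index(ranks.columns[0])
    else:
        ranks = pd.read_csv(path, sep="\t", index_col=0)
    ranks = ranks.astype(int)
    annotations = read_annotations_tsv(annotations_path) if annotations_path else {}
    return MotifRankingDB(ranks=ranks, annotations=annotations)


def read_annotations_tsv(path) -> dict[str, frozenset[str]]:
    """Read motif→TF annotations (columns motif_id, tf[, annotation_type])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "annotation_type" in df.columns:
        df = df[df["annotation_type"].fillna("direct") == "direct"]
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["motif_id"], set()).add(row["tf"])
    return {k: frozenset(v) for k, v in out.items()}
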