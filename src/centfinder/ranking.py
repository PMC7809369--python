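"""Integration of DE, module centrality, module activity and regulons
into a ranked list of candidate master-regulator TFs, plus network
table export for visualisation tools.

A (TF, module) pair becomes a candidate when the TF is significantly
higher expressed in the target cell type, its kME in the module
exceeds the centrality cut, the module is more active in the target
cell type, and the TF has a motif-supported regulon in that module
with NES at or above the enrichment cut. Candidates are ranked by the
fraction of the module covered by the TF's regulon — a TF predicted
to regulate most of a module it is central to is the strongest
master-regulator candidate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ModuleSet, Regulon

__all__ = ["rank_tfs", "export_network", "rank_all_celltypes"]

RANKING_COLUMNS = [
    "tf", "module", "kme", "best_nes", "log2fc", "padj",
    "fraction_regulated", "rank",
]


def rank_tfs(
    de: pd.DataFrame,
    modules: ModuleSet,
    activity: pd.DataFrame,
    regulons: list[Regulon],
    kme_cut: float = 0.5,
    nes_cut: float = 3.0,
    require_twofold: bool = True,
) -> pd.DataFrame:
    """Filter and rank candidate (TF, module) pairs.

    ``de`` is the table from :func:`centfinder.diffexpr.nb_wald_de`
    with the target cell type as the contrast numerator; ``activity``
    the table from :func:`centfinder.scoring.celltype_activity` for the
    same target. A TF may appear in several rows when it is central to
    several modules. With ``require_twofold=False`` filter (a) demands
    only padj < 0.05 and a positive fold change, not the twofold rule.
    """
    by_pair: dict[tuple[str, str], Regulon] = {}
    for r in regulons:
        key = (r.tf, r.module)
        prev = by_pair.get(key)
        if prev is None or r.best_nes > prev.best_nes:
            by_pair[key] = r

    rows = []
    for (tf, module), reg in sorted(by_pair.items()):
        if reg.best_nes < nes_cut:
            continue
        if tf not in de.index:
            continue
        de_row = de.loc[tf]
        up = de_row["log2fc"] > 0
        if require_twofold:
            if not (de_row["significant"] and up):
                continue
        else:
            if not (de_row["padj"] < 0.05 and up):
                continue
        if module not in activity.index or not bool(activity.loc[module, "target_active"]):
            continue
        if tf not in modules.kme.index or module not in modules.kme.columns:
            warnings.warn(f"no kME for candidate ({tf}, {module}); dropped", stacklevel=2)
            continue
        kme = float(modules.kme.loc[tf, module])
        if not kme > kme_cut:
            continue
        module_genes = set(modules.module_genes(module))
        if not module_genes:
            continue
        fraction = len(set(reg.targets) & module_genes) / len(module_genes)
        rows.append(
            {"tf": tf, "module": module, "kme": kme, "best_nes": float(reg.best_nes),
             "log2fc": float(de_row["log2fc"]), "padj": float(de_row["padj"]),
             "fraction_regulated": fraction}
        )
    if not rows:
        return pd.DataFrame(columns=RANKING_COLUMNS)
    df = pd.DataFrame(rows)
    df["abs_lfc"] = df["log2fc"].abs()
    df = df.sort_values(
        ["fraction_regulated", "abs_lfc", "tf"], ascending=[False, False, True]
    ).drop(columns="abs_lfc")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)[RANKING_COLUMNS]


def export_network(
    rows: pd.DataFrame,
    regulons: list[Regulon],
    de: pd.DataFrame,
    modules: ModuleSet,
    top_targets: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for network-visualisation tools.

    Per ranked TF, edges go to the ``top_targets`` regulon targets with
    the largest |log2 fold change|. Node styling encodes the biology:
    colour is the module colour (TFs assigned elsewhere but central to
    the module of interest are recoloured to it), shape is an ellipse
    for genes up in the target cell type and a rectangle otherwise,
    and size grows with the number of downstream targets
    (10 + 2 × out-degree).
    """
    by_pair = {(r.tf, r.module): r for r in regulons}
    edges = []
    node_module: dict[str, str] = {}
    out_degree: dict[str, int] = {}
    for _, row in rows.iterrows():
        tf, module = row["tf"], row["module"]
        reg = by_pair.get((tf, module))
        if reg is None:
            continue
        targets = [t for t in reg.targets if t != tf]
        lfc = {t: abs(float(de.loc[t, "log2fc"])) if t in de.index else 0.0 for t in targets}
        chosen = sorted(targets, key=lambda t: (-lfc[t], t))[:top_targets]
        for t in chosen:
            edges.append({"source": tf, "target": t, "interaction": "regulates"})
        out_degree[tf] = out_degree.get(tf, 0) + len(chosen)
        node_module[tf] = module  # recolour central TFs to the module of interest
        for t in chosen:
            node_module.setdefault(t, modules.assignment.get(t, "grey"))

    node_rows = []
    for node in sorted(node_module):
        lfc = float(de.loc[node, "log2fc"]) if node in de.index else 0.0
        node_rows.append(
            {"id": node, "colour": node_module[node],
             "shape": "ellipse" if lfc > 0 else "rectangle",
             "size": 10 + 2 * out_degree.get(node, 0)}
        )
    node_df = pd.DataFrame(node_rows, columns=["id", "colour", "shape", "size"])
    edge_df = pd.DataFrame(edges, columns=["source", "target", "interaction"])
    return node_df, edge_df


def rank_all_celltypes(
    de_by_celltype: dict[str, pd.DataFrame],
    modules: ModuleSet,
    activity_by_celltype: dict[str, pd.DataFrame],
    regulons: list[Regulon],
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run :func:`rank_tfs` with each cell type as the target."""
    out = {}
    for celltype in sorted(de_by_celltype):
        out[celltype] = rank_tfs(
            de_by_celltype[celltype], modules, activity_by_celltype[celltype],
            regulons, **kwargs,
        )
    return out
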