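"""End-to-end orchestration: expression matrix → ranked TF candidates.

Chains the pipeline stages on in-memory objects: batch adjustment,
soft-threshold selection, module detection, per-module motif
enrichment, regulon assembly, module activity scoring, differential
expression and the integrated TF ranking. Each stage remains
individually callable; this module only wires defaults together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .batch import adjust_combat, fit_combat
from .containers import ExpressionMatrix, ModuleSet, MotifRankingDB, Regulon
from .diffexpr import nb_wald_de
from .motifs import build_regulons, module_enrichment
from .network import SoftThresholdReport, detect_modules, pick_soft_threshold
from .ranking import rank_tfs
from .scoring import celltype_activity, gsva_scores

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    adjusted: ExpressionMatrix
    soft_threshold: SoftThresholdReport
    modules: ModuleSet
    enrichment: list = field(default_factory=list)
    regulons: list[Regulon] = field(default_factory=list)
    activity: pd.DataFrame | None = None
    de: pd.DataFrame | None = None
    ranking: pd.DataFrame | None = None


def run_pipeline(
    em: ExpressionMatrix,
    ranking_db: MotifRankingDB,
    counts: pd.DataFrame,
    groups: pd.Series,
    target_celltype: str,
    batch_key: str | None = "platform_id",
    power: int | None = None,
    min_module_size: int = 30,
    nes_cut: float = 3.0,
    kme_cut: float = 0.5,
    top_frac: float = 0.05,
) -> PipelineResult:
    """Run the full prioritisation chain for one target cell type.

    ``counts``/``groups`` define the DE contrast whose numerator is the
    target cell type. ``batch_key=None`` skips batch adjustment;
    ``power=None`` picks the soft threshold automatically.
    """
    meta = em.sample_frame()
    if batch_key is not None and meta[batch_key].nunique() > 1:
        adjusted = adjust_combat(em, fit_combat(em, batch_key))
    else:
        adjusted = em

    report = pick_soft_threshold(adjusted)
    if power is None:
        power = report.chosen_power
    modules = detect_modules(adjusted, power=power, min_module_size=min_module_size)

    enrichment = []
    for module, genes in modules.as_gene_sets().items():
        enrichment.extend(
            module_enrichment(ranking_db, genes, module=module, nes_cut=nes_cut,
                              top_frac=top_frac)
        )
    regulons = build_regulons(enrichment)

    activity_scores = gsva_scores(adjusted, modules.as_gene_sets())
    activity = celltype_activity(activity_scores, meta, target_celltype)

    de = nb_wald_de(counts, groups, reference="reference" if "reference" in set(groups) else None)
    ranking = rank_tfs(de, modules, activity, regulons, kme_cut=kme_cut, nes_cut=nes_cut)
    return PipelineResult(
        adjusted=adjusted,
        soft_threshold=report,
        modules=modules,
        enrichment=enrichment,
        regulons=regulons,
        activity=activity,
        de=de,
        ranking=ranking,
    )
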