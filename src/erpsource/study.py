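"""In-memory end-to-end study runs.

The disk-backed :class:`~erpsource.pipeline.Pipeline` is the user-facing
orchestrator; this module runs the identical analysis chain without I/O,
which is what replicate-based calibration studies (type-I error, FDR,
planted-effect recovery) need.  Geometry, lead field and inverse operator
are computed once and shared across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import erp as erp_mod
from .config import PipelineConfig
from .forward import LeadField, compute_leadfield
from .geometry import HeadGeometry, Montage, RoiMaskSet, SourceSpace
from .inverse import (
    InverseOperator,
    apply_inverse_window,
    cdr_scores,
    make_inverse_operator,
    roi_aggregate,
)
from .preprocess import preprocess
from .simulate import CONDITIONS, GroundTruth, StudyDesign, simulate_subject
from .stats import StatTable, build_stat_report

__all__ = ["StudyContext", "StudyResult", "build_context", "run_study"]


@dataclass
class StudyContext:
    """Replicate-invariant machinery: geometry, lead field, inverse."""

    head: HeadGeometry
    montage: Montage
    source_space: SourceSpace
    masks: RoiMaskSet
    leadfield: LeadField
    operator: InverseOperator
    config: PipelineConfig


@dataclass
class StudyResult:
    anovas: dict[str, erp_mod.AnovaResult]
    posthoc: dict[str, pd.DataFrame]
    stat_tables: list[StatTable]
    roi_cdr: pd.DataFrame
    n_included: int
    excluded: list[str]


def build_context(config: PipelineConfig) -> StudyContext:
    """Compute the shared geometry/forward/inverse objects for a config."""
    from .config import build_geometry

    head, montage, src, masks = build_geometry(config)
    lf = compute_leadfield(head, src, montage, config.inverse.truncation_L)
    op = make_inverse_operator(
        lf,
        alpha=config.inverse.alpha,
        tol=config.inverse.tol,
        max_iter=config.inverse.max_iter,
    )
    return StudyContext(head, montage, src, masks, lf, op, config)


def run_study(
    ctx: StudyContext,
    design: StudyDesign | None = None,
    truth: GroundTruth | None = None,
) -> StudyResult:
    """Simulate and analyze one study entirely in memory.

    ``design`` / ``truth`` default to the context config; passing them lets
    replicate loops vary the master seed (or the plants) while reusing the
    context.
    """
    cfg = ctx.config
    design = design or cfg.design
    truth = (truth if truth is not None else cfg.truth).resolve(ctx.masks)

    clean = {}
    excluded = []
    for i in range(design.n_subjects):
        epochs, _ = simulate_subject(
            design, ctx.montage, ctx.source_space, truth, ctx.leadfield, i
        )
        out, report = preprocess(epochs, cfg.preproc, ctx.montage)
        if report.excluded:
            excluded.append(report.subject_id)
        else:
            clean[report.subject_id] = out
    if not clean:
        raise RuntimeError("no included subjects")

    wcfg = cfg.windows
    windows = {
        sid: {
            "P2": erp_mod.locate_p2_window(
                ep, ctx.montage, wcfg.p2_search_ms, wcfg.p2_window_ms
            ),
            "LSW": erp_mod.locate_lsw_window(wcfg.lsw_window_ms, design.epoch_ms),
        }
        for sid, ep in clean.items()
    }

    anovas: dict[str, erp_mod.AnovaResult] = {}
    posthoc: dict[str, pd.DataFrame] = {}
    cdr_rows = []
    mask_meta = {m.name: m for m in ctx.masks}
    for comp in ("P2", "LSW"):
        frames = []
        for sid, ep in clean.items():
            w = windows[sid][comp]
            reb = erp_mod.rebaseline(ep, w)
            cm = erp_mod.cluster_means(reb, w, ctx.montage)
            cm.insert(0, "subject", sid)
            frames.append(cm)
            for cond in CONDITIONS:
                mom = apply_inverse_window(ctx.operator, reb, w, cond)
                cdr = cdr_scores(mom)
                for roi, val in roi_aggregate(cdr, ctx.masks).items():
                    m = mask_meta[roi]
                    cdr_rows.append(
                        {
                            "subject": sid,
                            "component": comp,
                            "roi": roi,
                            "family": m.family,
                            "hemisphere": m.hemisphere,
                            "condition": cond,
                            "cdr": val,
                        }
                    )
        amps = pd.concat(frames, ignore_index=True)
        anovas[comp] = erp_mod.rm_anova_2x3x3(amps)
        posthoc[comp] = erp_mod.emm_tukey_posthoc(amps, anovas[comp], by="cell")

    roi_cdr = pd.DataFrame(cdr_rows)
    tables, _ = build_stat_report(roi_cdr, ctx.masks, cfg.stats.fdr_level)
    return StudyResult(anovas, posthoc, tables, roi_cdr, len(clean), excluded)
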