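"""End-to-end orchestration: from raw tables to loading calls, footprints,
TRL matrices, confirmed MRE pairs and ceRNA networks.

This is glue over the stage modules; every scientific decision lives in those
modules. The ceRNA stage works on replicate-pooled fragments per time point
(footprints re-called on the pooled start counts, merged at 20 nt, strengths
from the pooled CLIP library and replicate-mean RPKM, miRNA loading as
replicate-mean RPM), since the dominance rules are defined per time point.
"""

from __future__ import annotations

import pandas as pd

from . import (
    cerna_networks,
    footprint_calling,
    io_formats,
    mirna_loading,
    mre_prediction,
    trl_analysis,
)
from .io_formats import TIME_POINTS, PipelineConfig, TranscriptModel

POOLED = "pooled"


def clip_library_sizes(fragments: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Total CLIP mRNA reads per (time_point, replicate)."""
    sizes = fragments.groupby(["time_point", "replicate"])["count"].sum()
    return {key: int(v) for key, v in sizes.items()}


def pool_replicates(fragments: pd.DataFrame) -> pd.DataFrame:
    """Sum fragment counts across replicates; replicate label becomes 'pooled'."""
    pooled = fragments.groupby(["transcript_id", "start", "length", "time_point"],
                               as_index=False)["count"].sum()
    pooled["replicate"] = POOLED
    return pooled[io_formats.FRAGMENT_COLUMNS]


def run_pipeline(
    transcripts: list[TranscriptModel],
    fragments: pd.DataFrame,
    mirna_counts: pd.DataFrame,
    rnaseq_counts: pd.DataFrame,
    mirnas: dict[str, str],
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on in-memory inputs; returns a dict of result tables."""
    cfg = config or PipelineConfig()
    results: dict = {"config": cfg}

    # --- miRNA loading ------------------------------------------------------
    loading = mirna_loading.compute_rpm(mirna_counts)
    loading = mirna_loading.global_normalize(
        loading, rpm_differential=cfg.rpm_differential)
    results["loading"] = loading
    results["detected_mirnas"] = mirna_loading.detect_loaded(loading, cfg.rpm_detect)
    results["loading_calls"] = mirna_loading.call_differential_loading(
        loading, fdr_max=cfg.fdr_loading, rpm_differential=cfg.rpm_differential)

    # --- expression and footprints -----------------------------------------
    expression = footprint_calling.compute_rpkm(rnaseq_counts, transcripts)
    results["expression"] = expression
    lengths = {t.transcript_id: t.length for t in transcripts}
    libs = clip_library_sizes(fragments)
    starts = footprint_calling.index_starts(fragments, lengths)
    footprints = footprint_calling.call_footprints(
        starts, cfg.min_reads, cfg.assign_window, cfg.footprint_len)
    footprints = footprint_calling.compute_strengths(
        footprints, libs, expression, cfg.rpkm_floor_strength)
    results["footprints"] = footprints

    # --- TRL ----------------------------------------------------------------
    results["trl"] = trl_analysis.compute_trl(footprints)
    per_rep_trl = footprints.dropna(subset=["strength"]) \
        .groupby(["transcript_id", "time_point", "replicate"])["strength"] \
        .sum().reset_index().rename(columns={"strength": "value"})
    results["trl_matrix"] = trl_analysis.build_matrix(
        per_rep_trl, floor=cfg.trl_min, floor_inclusive=False)
    mrna_values = expression.rename(columns={"rpkm": "value"})[
        ["transcript_id", "time_point", "replicate", "value"]]
    results["mrna_matrix"] = trl_analysis.build_matrix(
        mrna_values, floor=cfg.rpkm_min, floor_inclusive=True)

    # --- MRE prediction and confirmation -----------------------------------
    pairs = mre_prediction.seed_scan(mirnas, transcripts)
    criteria = mre_prediction.ConfirmationCriteria(
        cfg.rpm_detect, cfg.mre_window, cfg.strength_min)
    confirmed = mre_prediction.confirm_mres(pairs, footprints, loading, criteria)
    results["mre_pairs"] = confirmed
    results["refinement"] = mre_prediction.summarize_refinement(pairs, confirmed)

    # --- ceRNA networks -----------------------------------------------------
    (results["cerna_edges_by_tp"], results["cerna_summary"],
     results["cerna_confirmed_pairs"]) = build_cerna(
        transcripts, fragments, pairs, loading, expression, cfg)
    return results


def build_cerna(
    transcripts: list[TranscriptModel],
    fragments: pd.DataFrame,
    raw_pairs: pd.DataFrame,
    loading: pd.DataFrame,
    expression: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-time-point ceRNA edge tables, the merged summary network, and the
    pooled-confirmation pair table the networks are built from."""
    lengths = {t.transcript_id: t.length for t in transcripts}
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}

    pooled = pool_replicates(fragments)
    pooled_libs = clip_library_sizes(pooled)
    pooled_expr = expression.groupby(["transcript_id", "time_point"], as_index=False)[
        "rpkm"].mean()
    pooled_expr["replicate"] = POOLED
    pooled_load = loading.groupby(["mirna_id", "time_point"], as_index=False)[
        "rpm"].mean()
    pooled_load["replicate"] = POOLED

    starts = footprint_calling.index_starts(pooled, lengths)
    fps = footprint_calling.call_footprints(
        starts, cfg.min_reads, cfg.assign_window, cfg.footprint_len)
    fps = footprint_calling.compute_strengths(
        fps, pooled_libs, pooled_expr, cfg.rpkm_floor_strength)
    merged = footprint_calling.merge_footprints(fps, cfg.cerna_merge_bp)

    criteria = mre_prediction.ConfirmationCriteria(
        cfg.rpm_detect, cfg.mre_window, cfg.strength_min)
    confirmed = mre_prediction.confirm_mres(raw_pairs, merged, pooled_load, criteria)

    per_tp: dict[str, pd.DataFrame] = {}
    for tp in TIME_POINTS:
        tp_fps = merged[merged["time_point"] == tp]
        tp_load = pooled_load[pooled_load["time_point"] == tp] \
            .set_index("mirna_id")["rpm"]
        per_tp[tp] = cerna_networks.build_network_for_time_point(
            tp_fps, confirmed, tp_load, tp, gene_of=gene_of,
            frac=cfg.cerna_second_fp_frac, ratio=cfg.cerna_mirna_ratio)
    summary = cerna_networks.merge_networks(per_tp)
    return per_tp, summary, confirmed
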