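"""Coalesce CLIP fragment starts into Ago footprints and weight them by expression.

A footprint is anchored at the locally strongest accumulation of fragment 5'
ends: the caller repeatedly takes the position with the highest start count
(leftmost on ties), assigns all starts within +/- ``assign_window`` nt to it,
and emits a fixed-length interval beginning at the anchor, until no position
reaches ``min_reads``. Footprint strength is the footprint's RPM in the CLIP
mRNA library divided by the transcript's RNA-seq RPKM — RISC occupancy
weighted by how abundant the mRNA is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import FOOTPRINT_COLUMNS, TranscriptModel


class ExpressionLookupError(KeyError):
    """A transcript or condition is missing from the expression table."""


def compute_rpkm(counts: pd.DataFrame, models: list[TranscriptModel]) -> pd.DataFrame:
    """Reads per kilobase per million: raw_count / (length_kb * library_millions)."""
    lengths = {m.transcript_id: m.length for m in models}
    df = counts.copy()
    unknown = set(df["transcript_id"]) - set(lengths)
    if unknown:
        raise ExpressionLookupError(f"unknown transcripts in counts: {sorted(unknown)[:5]}")
    if "library_size" not in df.columns:
        df["library_size"] = df.groupby(["time_point", "replicate"])["raw_count"] \
                               .transform("sum")
    length_kb = df["transcript_id"].map(lengths) / 1000.0
    df["rpkm"] = df["raw_count"] / (length_kb * df["library_size"] / 1e6)
    return df


def index_starts(fragments: pd.DataFrame, transcript_length: dict[str, int]
                 ) -> dict[tuple[str, str, str], np.ndarray]:
    """Per (transcript, time_point, replicate) vector of read 5'-end counts.

    ``v[p]`` = total reads whose fragment start is position p.
    """
    out: dict[tuple[str, str, str], np.ndarray] = {}
    for (tx, tp, rep), grp in fragments.groupby(
            ["transcript_id", "time_point", "replicate"]):
        v = np.zeros(transcript_length[tx], dtype=np.int64)
        np.add.at(v, grp["start"].to_numpy(), grp["count"].to_numpy())
        out[(tx, tp, rep)] = v
    return out


def call_footprints_vector(
    start_counts: np.ndarray,
    min_reads: int = 5,
    assign_window: int = 10,
    footprint_len: int = 50,
) -> list[tuple[int, int, int, int]]:
    """Greedy footprint calls on one start-count vector.

    Returns ``(anchor, start, end, reads)`` tuples in emission order. At each
    step the position with the maximal remaining start count is the anchor
    (leftmost on ties); if its count is below ``min_reads`` the caller stops.
    All starts within ``anchor +/- assign_window`` are consumed by the
    footprint, whose interval is ``[anchor, anchor + footprint_len)`` clipped
    to the transcript.
    """
    v = np.asarray(start_counts, dtype=np.int64).copy()
    L = len(v)
    out = []
    while True:
        anchor = int(np.argmax(v))  # argmax returns the leftmost maximum
        if v[anchor] < min_reads:
            break
        lo, hi = max(0, anchor - assign_window), min(L, anchor + assign_window + 1)
        reads = int(v[lo:hi].sum())
        v[lo:hi] = 0
        out.append((anchor, anchor, min(anchor + footprint_len, L), reads))
    return out


def call_footprints(
    start_index: dict[tuple[str, str, str], np.ndarray],
    min_reads: int = 5,
    assign_window: int = 10,
    footprint_len: int = 50,
) -> pd.DataFrame:
    """Run the greedy caller over every (transcript, time_point, replicate).

    Returns a DataFrame with FOOTPRINT_COLUMNS; footprint ids encode the
    condition and the emission rank within the transcript.
    """
    rows = []
    for (tx, tp, rep), v in sorted(start_index.items()):
        for i, (anchor, start, end, reads) in enumerate(
                call_footprints_vector(v, min_reads, assign_window, footprint_len)):
            fid = f"{tx}:{tp}:{rep}:fp{i + 1}"
            rows.append((fid, tx, anchor, start, end, reads, tp, rep))
    return pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)


def compute_strengths(
    footprints: pd.DataFrame,
    clip_library_sizes: dict[tuple[str, str], int],
    expression: pd.DataFrame,
    rpkm_floor: float = 0.1,
) -> pd.DataFrame:
    """Attach RPM and expression-weighted strength (RPM/RPKM) to footprints.

    ``clip_library_sizes`` maps (time_point, replicate) to total aligned CLIP
    mRNA reads. Transcripts whose RPKM in the matching condition falls below
    ``rpkm_floor`` get ``strength_defined = False`` and NaN strength; they are
    excluded by downstream consumers.
    """
    df = footprints.copy()
    missing = set(zip(df["time_point"], df["replicate"])) - set(clip_library_sizes)
    if missing:
        raise ExpressionLookupError(f"no CLIP library size for conditions {sorted(missing)}")
    lib = df.apply(lambda r: clip_library_sizes[(r["time_point"], r["replicate"])], axis=1)
    df["rpm"] = df["reads"] / lib * 1e6

    expr_key = expression.set_index(["transcript_id", "time_point", "replicate"])["rpkm"]
    keys = list(zip(df["transcript_id"], df["time_point"], df["replicate"]))
    try:
        rpkm = np.array([expr_key.loc[k] for k in keys], dtype=float) \
            if keys else np.array([], dtype=float)
    except KeyError as exc:
        raise ExpressionLookupError(f"missing expression record {exc}") from exc
    df["rpkm"] = rpkm
    df["strength_defined"] = df["rpkm"] >= rpkm_floor
    df["strength"] = np.where(df["strength_defined"], df["rpm"] / df["rpkm"], np.nan)
    return df


def merge_footprints(footprints: pd.DataFrame, max_gap: int = 20) -> pd.DataFrame:
    """Union footprints on the same transcript and condition within ``max_gap`` nt.

    Merging is the transitive closure of "interval gap <= max_gap"; reads, RPM
    and strength are summed, the merged anchor is the anchor of the strongest
    constituent (highest strength if present, else most reads), and the merged
    id joins the constituent ids with ``+``. Constituent anchors are kept in
    ``member_anchors`` for provenance.
    """
    if footprints.empty:
        out = footprints.copy()
        out["member_anchors"] = pd.Series(dtype=object)
        return out
    has_strength = "strength" in footprints.columns
    rows = []
    for (tx, tp, rep), grp in footprints.groupby(
            ["transcript_id", "time_point", "replicate"]):
        grp = grp.sort_values(["start", "end"])
        cluster: list[pd.Series] = []
        cluster_end = None
        for _, fp in grp.iterrows():
            if cluster and fp["start"] - cluster_end > max_gap:
                rows.append(_merge_cluster(cluster, has_strength))
                cluster = []
            cluster.append(fp)
            cluster_end = max(cluster_end, fp["end"]) if cluster_end is not None else fp["end"]
        if cluster:
            rows.append(_merge_cluster(cluster, has_strength))
    return pd.DataFrame(rows).reset_index(drop=True)


def _merge_cluster(cluster: list[pd.Series], has_strength: bool) -> dict:
    if has_strength:
        key = [(-1e18 if pd.isna(fp["strength"]) else fp["strength"]) for fp in cluster]
    else:
        key = [fp["reads"] for fp in cluster]
    best = cluster[int(np.argmax(key))]
    merged = {
        "footprint_id": "+".join(fp["footprint_id"] for fp in cluster),
        "transcript_id": best["transcript_id"],
        "anchor": int(best["anchor"]),
        "start": int(min(fp["start"] for fp in cluster)),
        "end": int(max(fp["end"] for fp in cluster)),
        "reads": int(sum(fp["reads"] for fp in cluster)),
        "time_point": best["time_point"],
        "replicate": best["replicate"],
        "member_anchors": [int(fp["anchor"]) for fp in cluster],
    }
    if "rpm" in best.index:
        merged["rpm"] = float(sum(fp["rpm"] for fp in cluster))
    if has_strength:
        strengths = [fp["strength"] for fp in cluster if not pd.isna(fp["strength"])]
        merged["strength"] = float(sum(strengths)) if strengths else np.nan
        merged["strength_defined"] = bool(strengths)
    return merged
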