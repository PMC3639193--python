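"""Candidate miRNA regulatory elements and their confirmation by Ago footprints.

Raw candidate sites come either from the internal seed scanner (perfect
Watson-Crick complements to miRNA seed nucleotides 2-8 and the canonical site
classes built on them) or from an imported miRanda-style table. A candidate is
confirmed when, in some (time point, replicate), the miRNA is loaded in the
Ago-short library at >= 100 RPM and the site lies 5-43 nt downstream of the
anchor of a footprint with strength >= 0.31 RPM/RPKM — the experimental filter
that shrinks the computational search space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FormatError, TranscriptModel
from .synthetic_data import reverse_complement

MRE_COLUMNS = ["mirna_id", "transcript_id", "mre_start", "site_type", "score", "energy"]

#: canonical seed-site classes, best first
SITE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "imported": 0}

_VALID_NT = set("ACGUT")


@dataclass(frozen=True)
class ConfirmationCriteria:
    """Thresholds of the footprint-confirmation filter (all inclusive)."""

    min_mirna_rpm: float = 100.0
    window: tuple[int, int] = (5, 43)   # nt downstream of the footprint anchor
    min_strength: float = 0.31          # RPM/RPKM

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValueError("window lower bound exceeds upper bound")


def _complement(base: str) -> str:
    return reverse_complement(base)


def seed_scan(
    mirnas: dict[str, str],
    transcripts: list[TranscriptModel],
    min_class: str = "7mer-m8",
) -> pd.DataFrame:
    """Scan transcript sequences (all regions) for seed-complementary sites.

    For each miRNA the 6mer core is the reverse complement of seed nucleotides
    2-7; a match extends to 7mer-m8 when the preceding transcript base pairs
    with miRNA nt 8, to 7mer-A1 when an A faces miRNA nt 1, and to 8mer when
    both hold. Each genomic occurrence is reported once with its best class;
    ``mre_start`` is the 5'-most transcript coordinate of the matched element.
    Classes below ``min_class`` are dropped.
    """
    if min_class not in SITE_RANK:
        raise ValueError(f"unknown site class {min_class!r}")
    min_rank = SITE_RANK[min_class]
    rows = []
    for mid, mseq in mirnas.items():
        m = mseq.upper().replace("U", "T")
        if set(m) - set("ACGT"):
            raise FormatError(f"miRNA {mid} contains non-nucleotide characters")
        if len(m) < 8:
            raise FormatError(f"miRNA {mid} shorter than 8 nt")
        core6 = reverse_complement(m[1:7])       # matches seed nt 2-7
        m8_pair = _complement(m[7])              # transcript base pairing nt 8
        for tx in transcripts:
            if tx.sequence is None:
                raise FormatError(f"transcript {tx.transcript_id} has no sequence")
            seq = tx.sequence.upper()
            if set(seq) - set("ACGTN"):
                raise FormatError(
                    f"transcript {tx.transcript_id} contains non-nucleotide characters")
            q = seq.find(core6)
            while q != -1:
                has_m8 = q > 0 and seq[q - 1] == m8_pair
                has_a1 = q + 6 < len(seq) and seq[q + 6] == "A"
                if has_m8 and has_a1:
                    site, start = "8mer", q - 1
                elif has_m8:
                    site, start = "7mer-m8", q - 1
                elif has_a1:
                    site, start = "7mer-A1", q
                else:
                    site, start = "6mer", q
                if SITE_RANK[site] >= min_rank:
                    rows.append((mid, tx.transcript_id, start, site,
                                 float(SITE_RANK[site]), np.nan))
                q = seq.find(core6, q + 1)
    return pd.DataFrame(rows, columns=MRE_COLUMNS) \
             .drop_duplicates(["mirna_id", "transcript_id", "mre_start"]) \
             .sort_values(["mirna_id", "transcript_id", "mre_start"], ignore_index=True)


def read_miranda_hits(
    path, min_score: float = 140.0, max_energy: float = -10.0
) -> pd.DataFrame:
    """Import miRanda-style tabular hits (mirna, transcript, position, score, energy).

    The score and free-energy thresholds are re-applied defensively: rows with
    score < ``min_score`` or energy > ``max_energy`` kcal/mol are dropped.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                mid, tx = parts[0], parts[1]
                pos, score, energy = int(parts[2]), float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row") from exc
            if score >= min_score and energy <= max_energy:
                rows.append((mid, tx, pos, "imported", score, energy))
    return pd.DataFrame(rows, columns=MRE_COLUMNS)


def confirm_mres(
    pairs: pd.DataFrame,
    footprints: pd.DataFrame,
    loading: pd.DataFrame,
    criteria: ConfirmationCriteria = ConfirmationCriteria(),
) -> pd.DataFrame:
    """Confirm candidate sites against footprints, per replicate and time point.

    A pair is confirmed in condition (t, r) when the miRNA's Ago-short RPM in
    that replicate reaches ``min_mirna_rpm`` and some footprint on the
    transcript has defined strength >= ``min_strength`` with
    ``mre_start - anchor`` inside ``window`` (downstream = increasing
    transcript coordinate; all bounds inclusive). The returned table adds
    ``confirmed``, ``n_supporting`` and ``supporting`` (list of
    (time_point, replicate, footprint_id)); the confirmed set is the union
    over all conditions.
    """
    out = pairs.copy().reset_index(drop=True)
    out["confirmed"] = False
    out["supporting"] = [[] for _ in range(len(out))]
    conditions = sorted(set(zip(footprints["time_point"], footprints["replicate"])))
    load_conditions = set(zip(loading["time_point"], loading["replicate"]))
    missing = set(conditions) - load_conditions
    if missing:
        raise ValueError(f"loading table missing conditions {sorted(missing)}")
    lo, hi = criteria.window
    fps = footprints
    if "strength_defined" in fps.columns:
        fps = fps[fps["strength_defined"]]
    fps = fps.dropna(subset=["strength"])
    fps = fps[fps["strength"] >= criteria.min_strength]
    for tp, rep in conditions:
        lib = loading[(loading["time_point"] == tp) & (loading["replicate"] == rep)]
        loaded = set(lib.loc[lib["rpm"] >= criteria.min_mirna_rpm, "mirna_id"])
        cond_fps = fps[(fps["time_point"] == tp) & (fps["replicate"] == rep)]
        if cond_fps.empty:
            continue
        cand = out[out["mirna_id"].isin(loaded)]
        if cand.empty:
            continue
        joined = cand.reset_index().merge(
            cond_fps[["transcript_id", "anchor", "footprint_id"]], on="transcript_id")
        offset = joined["mre_start"] - joined["anchor"]
        hit = joined[(offset >= lo) & (offset <= hi)]
        for _, row in hit.iterrows():
            i = int(row["index"])
            out.at[i, "confirmed"] = True
            out.at[i, "supporting"].append((tp, rep, row["footprint_id"]))
    out["n_supporting"] = out["supporting"].map(len)
    return out


def summarize_refinement(raw_pairs: pd.DataFrame, confirmed_pairs: pd.DataFrame) -> dict:
    """Unique-pair counts before/after confirmation and the refinement fold."""
    def n_unique(df: pd.DataFrame) -> int:
        return len(df[["mirna_id", "transcript_id"]].drop_duplicates())

    n_raw = n_unique(raw_pairs)
    conf = confirmed_pairs
    if "confirmed" in conf.columns:
        conf = conf[conf["confirmed"]]
    n_conf = n_unique(conf)
    return {
        "n_raw_pairs": n_raw,
        "n_confirmed_pairs": n_conf,
        "refinement_fold": (n_raw / n_conf) if n_conf else float("inf"),
    }
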