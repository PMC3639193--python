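"""Readers/writers for the formats the pipeline touches, plus shared conventions.

All coordinates are transcript-space, 0-based half-open. Fragments, counts,
footprints, loading tables and MRE pairs are pandas DataFrames with the column
schemas documented on each reader; transcript models and configuration are
dataclasses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("riscprof")

TIME_POINTS = ("0h", "1h", "36h", "48h")
#: hours post-hepatectomy for each time-point label (G0, G1, S, M)
TIME_HOURS = {"0h": 0.0, "1h": 1.0, "36h": 36.0, "48h": 48.0}
REGION_KINDS = ("five_prime_utr", "cds", "three_prime_utr")

FRAGMENT_COLUMNS = ["transcript_id", "start", "length", "count", "replicate", "time_point"]
FOOTPRINT_COLUMNS = [
    "footprint_id", "transcript_id", "anchor", "start", "end",
    "reads", "time_point", "replicate",
]


class FormatError(ValueError):
    """Malformed input file (bad column, bad value, duplicate key)."""


class CoordinateError(ValueError):
    """A coordinate falls outside its transcript or violates the convention."""


# ---------------------------------------------------------------------------
# domain dataclasses
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """An mRNA with optional sequence and UTR/CDS region annotation.

    ``regions`` is a list of ``(kind, start, end)`` tuples in transcript
    coordinates, 0-based half-open, disjoint and ordered.
    """

    transcript_id: str
    gene_id: str
    length: int
    sequence: str | None = None
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CoordinateError(f"{self.transcript_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise CoordinateError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != {self.length}"
            )
        prev_end = 0
        for kind, start, end in self.regions:
            if kind not in REGION_KINDS:
                raise FormatError(f"{self.transcript_id}: unknown region kind {kind!r}")
            if not (0 <= start < end <= self.length):
                raise CoordinateError(
                    f"{self.transcript_id}: region {kind} [{start},{end}) outside [0,{self.length})"
                )
            if start < prev_end:
                raise CoordinateError(f"{self.transcript_id}: overlapping/unordered regions")
            prev_end = end

    def region_at(self, position: int) -> str | None:
        """Region kind containing ``position``, or None if unannotated."""
        for kind, start, end in self.regions:
            if start <= position < end:
                return kind
        return None


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the published defaults."""

    rpm_detect: float = 100.0          # RISC-detection floor, RPM
    rpm_differential: float = 1000.0   # floor for differential-loading calls, RPM
    fdr_loading: float = 0.20          # BH FDR ceiling for loading calls
    mre_window: tuple[int, int] = (5, 43)   # nt downstream of footprint anchor, inclusive
    strength_min: float = 0.31         # RPM/RPKM floor for confirming footprints
    cerna_merge_bp: int = 20           # merge footprints within this many nt
    cerna_second_fp_frac: float = 0.25  # rule 1: second footprint < frac * strongest
    cerna_mirna_ratio: float = 10.0    # rule 2: top miRNA >= ratio * second
    rpkm_min: float = 2.0              # mRNA matrix floor
    trl_min: float = 1.0               # TRL matrix floor (strictly over)
    kmeans_k_range: tuple[int, int] = (4, 30)
    kmeans_k: int = 12
    min_reads: int = 5                 # footprint anchor depth floor
    assign_window: int = 10            # +/- nt of starts assigned to an anchor
    footprint_len: int = 50            # nt extent of an emitted footprint
    rpkm_floor_strength: float = 0.1   # below this, footprint strength is undefined
    seed: int = 0
    coordinates: str = "0-based-half-open"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"config field {f.name} must be non-negative")
        if self.mre_window[0] > self.mre_window[1]:
            raise ValueError("mre_window lower bound exceeds upper bound")
        if self.kmeans_k_range[0] > self.kmeans_k_range[1]:
            raise ValueError("kmeans_k_range lower bound exceeds upper bound")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        typemap = {f.name: f for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in typemap:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, tuple):
                parts = [p.strip() for p in value.split(",")]
                kwargs[key] = tuple(type(d)(p) for d, p in zip(default, parts))
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = type(default)(value)
        return cls(**kwargs)

    def override(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GFF) -> 0-based half-open."""
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GFF)."""
    return start + 1, end


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

def _parse_region_lines(path: Path) -> Iterable[tuple[str, str, int, int]]:
    """Yield (transcript_id, kind, start, end) in internal coordinates.

    Accepts BED (tx, start, end, kind) or transcript-space GFF3
    (tx, source, kind, start, end, ...); dispatch on extension.
    """
    is_gff = path.suffix.lower() in (".gff", ".gff3", ".gtf")
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        try:
            if is_gff:
                tx, kind = parts[0], parts[2].lower()
                start, end = gff_to_internal(int(parts[3]), int(parts[4]))
            else:
                tx, kind = parts[0], parts[3].lower()
                start, end = int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed region line: {raw!r}") from exc
        yield tx, kind, start, end


def read_transcript_models(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    gene_map: dict[str, str] | None = None,
) -> list[TranscriptModel]:
    """Load transcript sequences (FASTA) and optional region annotation (BED/GFF).

    The FASTA id is the transcript id; the gene id defaults to the transcript
    id unless ``gene_map`` provides one (or the description carries
    ``gene=<id>``).
    """
    seqs: dict[str, str] = {}
    genes: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate transcript_id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("gene="):
                genes[rec.id] = token[5:]
    regions: dict[str, list[tuple[str, int, int]]] = {tx: [] for tx in seqs}
    if annotation_path is not None:
        n = 0
        for tx, kind, start, end in _parse_region_lines(Path(annotation_path)):
            if tx not in seqs:
                raise FormatError(f"region for unknown transcript {tx!r}")
            if not (0 <= start < end <= len(seqs[tx])):
                raise CoordinateError(
                    f"region [{start},{end}) outside transcript {tx} (length {len(seqs[tx])})"
                )
            regions[tx].append((kind, start, end))
            n += 1
        if n == 0:
            logger.warning("annotation file %s contains no regions", annotation_path)
    models = []
    for tx, seq in seqs.items():
        gene = (gene_map or {}).get(tx) or genes.get(tx, tx)
        models.append(
            TranscriptModel(tx, gene, len(seq), seq, sorted(regions[tx], key=lambda r: r[1]))
        )
    return models


def write_transcript_fasta(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            if m.sequence is None:
                raise ValueError(f"{m.transcript_id} has no sequence")
            fh.write(f">{m.transcript_id} gene={m.gene_id}\n{m.sequence}\n")


def write_regions_bed(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for kind, start, end in m.regions:
                fh.write(f"{m.transcript_id}\t{start}\t{end}\t{kind}\n")


# ---------------------------------------------------------------------------
# fragment table
# ---------------------------------------------------------------------------

def read_fragment_table(tsv_path: str | Path) -> pd.DataFrame:
    """Read aligned CLIP mRNA fragments.

    TSV columns: transcript_id, start, length, count, replicate, time_point.
    Rows with identical (transcript_id, start, length, replicate, time_point)
    have their counts summed. Returns a DataFrame with FRAGMENT_COLUMNS.
    """
    try:
        df = pd.read_csv(tsv_path, sep="\t", dtype={"transcript_id": str,
                                                    "replicate": str, "time_point": str})
    except ValueError as exc:
        raise FormatError(f"{tsv_path}: {exc}") from exc
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing)}")
    for col in ("start", "length", "count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, after header
            raise FormatError(f"{tsv_path}: non-integer {col} at line {row}")
        df[col] = vals.astype(int)
    if (df["start"] < 0).any():
        row = int(df.index[df["start"] < 0][0]) + 2
        raise FormatError(f"{tsv_path}: negative start at line {row}")
    if (df["count"] < 1).any():
        row = int(df.index[df["count"] < 1][0]) + 2
        raise FormatError(f"{tsv_path}: count < 1 at line {row}")
    if (df["length"] < 1).any():
        row = int(df.index[df["length"] < 1][0]) + 2
        raise FormatError(f"{tsv_path}: length < 1 at line {row}")
    keys = ["transcript_id", "start", "length", "replicate", "time_point"]
    df = df.groupby(keys, as_index=False)["count"].sum()
    return df[FRAGMENT_COLUMNS].sort_values(keys, ignore_index=True)


def write_fragment_table(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_fragments(fragments: pd.DataFrame, models: Sequence[TranscriptModel]) -> None:
    """Check every fragment lies within its transcript."""
    lengths = {m.transcript_id: m.length for m in models}
    for tx, grp in fragments.groupby("transcript_id"):
        if tx not in lengths:
            raise FormatError(f"fragment on unknown transcript {tx!r}")
        if ((grp["start"] + grp["length"]) > lengths[tx]).any():
            raise CoordinateError(f"fragment extends past end of transcript {tx}")


# ---------------------------------------------------------------------------
# counts tables (miRNA Ago-short and RNA-seq)
# ---------------------------------------------------------------------------

def read_counts_table(tsv_path: str | Path, id_col: str = "entity_id") -> pd.DataFrame:
    """Read a raw counts table: (id_col, replicate, time_point, raw_count[, library_size])."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={id_col: str, "replicate": str,
                                                "time_point": str})
    required = {id_col, "replicate", "time_point", "raw_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing)}")
    if (df["raw_count"] < 0).any():
        raise FormatError(f"{tsv_path}: negative raw_count")
    if "library_size" in df.columns:
        if (df["library_size"] <= 0).any():
            raise FormatError(f"{tsv_path}: non-positive library_size")
        if (df["raw_count"] > df["library_size"]).any():
            raise FormatError(f"{tsv_path}: raw_count exceeds library_size")
    return df


def write_counts_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def write_footprints_bed(footprints: pd.DataFrame, path: str | Path) -> None:
    """BED6: score = footprint strength x 1000, capped at 1000 (0 if undefined)."""
    with open(path, "w") as fh:
        fh.write('track name="ago_footprints"\n')
        for _, row in footprints.iterrows():
            strength = row.get("strength", float("nan"))
            score = 0 if pd.isna(strength) else min(1000, int(round(strength * 1000)))
            fh.write(
                f"{row['transcript_id']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row['footprint_id']}\t{score}\t+\n"
            )


def read_footprints_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith(("track", "#", "browser")):
            continue
        parts = raw.split("\t")
        rows.append(
            {"transcript_id": parts[0], "start": int(parts[1]), "end": int(parts[2]),
             "footprint_id": parts[3], "score": int(parts[4])}
        )
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "footprint_id", "score"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic TSV writer used for loading, TRL, MRE-pair and network tables."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
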