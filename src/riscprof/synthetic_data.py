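"""Fully synthetic Ago HITS-CLIP study with recorded ground truth.

Emulates the experimental design the pipeline expects: two biological
replicates at four time points (0h quiescent, 1h, 36h, 48h), an Ago-short
miRNA library (true loading spanning ~10-1e5 RPM with a dynamically recruited
subset), RNA-seq abundances spanning ~0.1-1e3 RPKM, CLIP mRNA fragments whose
start positions pile up at planted footprints over a uniform background, and
seed-match MREs written into the transcript sequences 5-43 nt downstream of
footprint anchors.

Counts are drawn with negative-binomial noise so that the two replicates show
realistic overdispersion. Every planted feature is recorded in a
:class:`SyntheticTruth` so downstream recovery can be scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    TIME_POINTS,
    FRAGMENT_COLUMNS,
    TranscriptModel,
)

logger = logging.getLogger("riscprof")

_DNA = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

REPLICATES = ("r1", "r2")


def reverse_complement(seq: str) -> str:
    """Reverse complement; RNA input (U) is handled via U==T equivalence."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def seed_site(mirna_seq: str) -> str:
    """DNA sequence on the mRNA matching miRNA nt 2-8 (a 7mer-m8 element)."""
    return reverse_complement(mirna_seq.upper().replace("U", "T")[1:8])


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator (defaults are the tested conditions)."""

    n_transcripts: int = 60
    n_mirnas: int = 30
    n_planted_footprints: int = 50
    transcript_length_range: tuple[int, int] = (800, 3000)
    mirna_length: int = 22
    #: expected background fragments per nt per CLIP library
    background_rate: float = 2e-4
    fragment_length_range: tuple[int, int] = (25, 50)
    start_jitter_sd: float = 2.0
    clip_library_size: int = 2_000_000
    mirna_library_size: int = 1_000_000
    rnaseq_library_size: int = 10_000_000
    #: negative-binomial dispersion (var = mu + disp * mu^2)
    dispersion: float = 0.05
    #: number of miRNAs given a fold-change trajectory, and its magnitude
    n_dynamic_mirnas: int = 5
    dynamic_fold: float = 5.0
    rpm_range: tuple[float, float] = (10.0, 1e5)
    rpkm_range: tuple[float, float] = (0.1, 1e3)
    #: planted footprints only on transcripts at least this expressed (RPKM),
    #: so their read depth (strength x RPKM x library/1e6) is callable
    min_planted_rpkm: float = 10.0
    strength_range: tuple[float, float] = (0.5, 5.0)
    mre_offset_range: tuple[int, int] = (5, 43)
    #: decoy seed matches planted well outside any footprint window
    n_decoys: int = 25
    #: optional planted ceRNA hub: one miRNA made the sole dominant regulator
    #: of ``hub_n_targets`` single-footprint transcripts, with a weakly loaded
    #: decoy miRNA sharing each footprint
    plant_hub: bool = False
    hub_n_targets: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_footprints > self.n_transcripts * 4:
            raise ValueError(
                "n_planted_footprints exceeds transcript capacity "
                f"({self.n_planted_footprints} > 4 x {self.n_transcripts})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study.

    planted_footprints: rows (footprint_idx, transcript_id, anchor,
        mirna_id, true_strength_<tp>...) — true strength is the expected
        footprint RPM divided by the true transcript RPKM at that time point.
    planted_mres: rows (mirna_id, transcript_id, mre_start, offset_from_anchor,
        footprint_idx, decoy) — decoy rows are seed matches planted outside
        every footprint window.
    true_loading: expected RPM per miRNA per time point.
    true_expression: expected RPKM per transcript per time point.
    """

    planted_footprints: pd.DataFrame
    planted_mres: pd.DataFrame
    true_loading: pd.DataFrame
    true_expression: pd.DataFrame
    hub_mirna: str | None = None
    hub_targets: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_footprints": self.planted_footprints.to_dict(orient="records"),
            "planted_mres": self.planted_mres.to_dict(orient="records"),
            "true_loading": self.true_loading.to_dict(orient="records"),
            "true_expression": self.true_expression.to_dict(orient="records"),
            "hub_mirna": self.hub_mirna,
            "hub_targets": self.hub_targets,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            pd.DataFrame(d["planted_footprints"]),
            pd.DataFrame(d["planted_mres"]),
            pd.DataFrame(d["true_loading"]),
            pd.DataFrame(d["true_expression"]),
            d.get("hub_mirna"),
            d.get("hub_targets", []),
        )


# ---------------------------------------------------------------------------
# count noise
# ---------------------------------------------------------------------------

def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (Poisson if 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-300))
    out = rng.negative_binomial(size, p)
    out[mean == 0] = 0
    return out


def simulate_loading_counts(
    true_rpm: np.ndarray,
    rng: np.random.Generator,
    library_size: int = 1_000_000,
    dispersion: float = 0.05,
    n_replicates: int = 2,
    time_points: tuple[str, ...] = TIME_POINTS,
    mirna_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw an Ago-short miRNA counts table around per-miRNA true RPM.

    ``true_rpm`` is (n_mirnas,) for a static study or (n_mirnas, n_timepoints)
    for a dynamic one. Returns a counts DataFrame with columns
    (mirna_id, time_point, replicate, raw_count, library_size).
    """
    true_rpm = np.asarray(true_rpm, dtype=float)
    if true_rpm.ndim == 1:  # static loading: same trajectory at every time point
        true_rpm = np.tile(true_rpm, (len(time_points), 1))
    if true_rpm.shape[0] != len(time_points):
        raise ValueError("true_rpm must be 1-D or (n_time_points, n_mirnas)")
    n_mirnas = true_rpm.shape[1]
    ids = mirna_ids or [f"mir-{i + 1}" for i in range(n_mirnas)]
    rows = []
    for ti, tp in enumerate(time_points):
        mu = true_rpm[ti] / 1e6 * library_size
        for rep in REPLICATES[:n_replicates]:
            counts = nb_counts(rng, mu, dispersion)
            lib = int(counts.sum())
            for mid, c in zip(ids, counts):
                rows.append((mid, tp, rep, int(c), lib))
    return pd.DataFrame(rows, columns=["mirna_id", "time_point", "replicate",
                                       "raw_count", "library_size"])


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _random_transcripts(cfg: SyntheticConfig, rng: np.random.Generator) -> list[TranscriptModel]:
    models = []
    lo, hi = cfg.transcript_length_range
    for i in range(cfg.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_DNA, size=length))
        # simple region split: 10% 5'UTR, 50% CDS, 40% 3'UTR
        a, b = int(0.1 * length), int(0.6 * length)
        regions = [("five_prime_utr", 0, a), ("cds", a, b), ("three_prime_utr", b, length)]
        models.append(TranscriptModel(f"tx{i + 1}", f"gene{i + 1}", length, seq, regions))
    return models


def _random_mirnas(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, str]:
    mirnas = {}
    for i in range(cfg.n_mirnas):
        seq = "".join(rng.choice(np.array(list("ACGU")), size=cfg.mirna_length))
        mirnas[f"mir-{i + 1}"] = seq
    return mirnas


def generate_study(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[TranscriptModel], pd.DataFrame, pd.DataFrame, pd.DataFrame,
           dict[str, str], SyntheticTruth]:
    """Simulate a complete study.

    Returns ``(transcripts, fragments, mirna_counts, rnaseq_counts, mirnas,
    truth)``. ``fragments`` has FRAGMENT_COLUMNS; the counts tables have
    (id, time_point, replicate, raw_count, library_size). The same seed yields
    identical outputs.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_tp = len(TIME_POINTS)

    transcripts = _random_transcripts(cfg, rng)
    mirnas = _random_mirnas(cfg, rng)
    mirna_ids = list(mirnas)

    # --- true miRNA loading (RPM trajectories) -----------------------------
    log_lo, log_hi = np.log10(cfg.rpm_range[0]), np.log10(cfg.rpm_range[1])
    base_rpm = 10 ** rng.uniform(log_lo, log_hi, size=cfg.n_mirnas)
    base_rpm *= 1e6 / base_rpm.sum()
    loading = np.tile(base_rpm, (n_tp, 1))  # (tp, mirna)
    dynamic = rng.choice(cfg.n_mirnas, size=min(cfg.n_dynamic_mirnas, cfg.n_mirnas),
                         replace=False)
    for j, mi in enumerate(dynamic):
        tp_idx = 1 + (j % (n_tp - 1))  # recruited at 1h, 36h or 48h
        fold = cfg.dynamic_fold if j % 2 == 0 else 1.0 / cfg.dynamic_fold
        loading[tp_idx, mi] = base_rpm[mi] * fold
    true_loading = pd.DataFrame(
        [(mirna_ids[m], TIME_POINTS[t], loading[t, m])
         for m in range(cfg.n_mirnas) for t in range(n_tp)],
        columns=["mirna_id", "time_point", "true_rpm"],
    )

    # --- true mRNA expression (RPKM trajectories, mildly dynamic) ----------
    e_lo, e_hi = np.log10(cfg.rpkm_range[0]), np.log10(cfg.rpkm_range[1])
    base_rpkm = 10 ** rng.uniform(e_lo, e_hi, size=cfg.n_transcripts)
    expr = np.tile(base_rpkm, (n_tp, 1)) * 2 ** rng.normal(0, 0.25, (n_tp, cfg.n_transcripts))
    true_expression = pd.DataFrame(
        [(transcripts[i].transcript_id, TIME_POINTS[t], expr[t, i])
         for i in range(cfg.n_transcripts) for t in range(n_tp)],
        columns=["transcript_id", "time_point", "true_rpkm"],
    )

    # --- plant footprints ---------------------------------------------------
    hub_mirna = mirna_ids[int(np.argmax(base_rpm))] if cfg.plant_hub else None
    expressed = np.flatnonzero(expr.min(axis=0) >= cfg.min_planted_rpkm)
    if len(expressed) == 0:
        raise ValueError("no transcript expressed above min_planted_rpkm")
    s_lo, s_hi = np.log10(cfg.strength_range[0]), np.log10(cfg.strength_range[1])
    fp_rows = []
    hub_targets: list[str] = []
    used_anchors: dict[int, list[int]] = {}
    margin = cfg.mre_offset_range[1] + 10
    hub_target_idx: set[int] = set()
    for k in range(cfg.n_planted_footprints):
        is_hub_fp = cfg.plant_hub and k < cfg.hub_n_targets
        for _ in range(200):
            ti = int(rng.choice(expressed))
            tx = transcripts[ti]
            if is_hub_fp and (tx.transcript_id in hub_targets or
                              used_anchors.get(ti)):
                continue  # hub targets carry exactly one footprint
            if not is_hub_fp and ti in hub_target_idx:
                continue  # keep hub transcripts single-footprint
            anchor = int(rng.integers(50, tx.length - margin - 50))
            # keep planted footprints well separated on a transcript
            if all(abs(anchor - a) > 150 for a in used_anchors.get(ti, [])):
                break
        else:
            raise ValueError("could not place planted footprint; transcripts too crowded")
        used_anchors.setdefault(ti, []).append(anchor)
        strength = 10 ** rng.uniform(s_lo, s_hi)
        profile = np.full(n_tp, strength)
        if not is_hub_fp and rng.random() < 0.3:  # a third of footprints are dynamic
            profile[int(rng.integers(1, n_tp))] *= cfg.dynamic_fold
        if is_hub_fp:
            mid = hub_mirna
            hub_targets.append(tx.transcript_id)
            hub_target_idx.add(ti)
        else:
            while True:  # hub miRNA regulates only its planted targets
                mid = mirna_ids[int(rng.integers(cfg.n_mirnas))]
                if not cfg.plant_hub or mid != hub_mirna:
                    break
        row = {"footprint_idx": k, "transcript_id": tx.transcript_id,
               "anchor": anchor, "mirna_id": mid}
        for t, tp in enumerate(TIME_POINTS):
            row[f"true_strength_{tp}"] = profile[t]
        fp_rows.append(row)
    planted_footprints = pd.DataFrame(fp_rows)

    truth = SyntheticTruth(
        planted_footprints=planted_footprints,
        planted_mres=pd.DataFrame(
            columns=["mirna_id", "transcript_id", "mre_start",
                     "offset_from_anchor", "footprint_idx", "decoy"]),
        true_loading=true_loading,
        true_expression=true_expression,
        hub_mirna=hub_mirna,
        hub_targets=hub_targets,
    )
    plant_mres(truth, transcripts, mirnas, cfg.mre_offset_range, rng)
    _plant_decoys(truth, transcripts, mirnas, cfg, rng)
    if cfg.plant_hub:
        _plant_hub_decoy_mres(truth, transcripts, mirnas, base_rpm, mirna_ids, cfg, rng)
    _scrub_chance_sites(truth, transcripts, mirnas, cfg.mre_offset_range)

    # --- CLIP fragments -----------------------------------------------------
    fragments = _simulate_fragments(cfg, rng, transcripts, truth, expr)

    # --- count tables -------------------------------------------------------
    mirna_counts = simulate_loading_counts(
        loading, rng, cfg.mirna_library_size, cfg.dispersion,
        time_points=TIME_POINTS, mirna_ids=mirna_ids,
    )
    rnaseq_counts = _simulate_rnaseq(cfg, rng, transcripts, expr)
    return transcripts, fragments, mirna_counts, rnaseq_counts, mirnas, truth


def plant_mres(
    truth: SyntheticTruth,
    transcripts: list[TranscriptModel],
    mirnas: dict[str, str],
    offset_range: tuple[int, int] = (5, 43),
    rng: np.random.Generator | None = None,
) -> None:
    """Write the reverse complement of each footprint miRNA's seed (nt 2-8)
    into the transcript at anchor + offset, offset uniform in ``offset_range``.

    Footprints whose transcript is too short for the insertion are skipped
    with a warning. ``truth.planted_mres`` gains one row per planted site.
    """
    rng = rng or np.random.default_rng(0)
    by_id = {t.transcript_id: t for t in transcripts}
    rows = list(truth.planted_mres.to_dict(orient="records"))
    for _, fp in truth.planted_footprints.iterrows():
        tx = by_id[fp["transcript_id"]]
        offset = int(rng.integers(offset_range[0], offset_range[1] + 1))
        start = int(fp["anchor"]) + offset
        site = seed_site(mirnas[fp["mirna_id"]])
        if start + len(site) + 1 > tx.length:
            logger.warning("skipping MRE for footprint %s: transcript %s too short",
                           fp["footprint_idx"], tx.transcript_id)
            continue
        seq = tx.sequence
        # avoid an accidental 'A' opposite nt1 deciding site class at random:
        # leave the following base as drawn
        tx.sequence = seq[:start] + site + seq[start + len(site):]
        rows.append({"mirna_id": fp["mirna_id"], "transcript_id": tx.transcript_id,
                     "mre_start": start, "offset_from_anchor": offset,
                     "footprint_idx": int(fp["footprint_idx"]), "decoy": False})
    truth.planted_mres = pd.DataFrame(rows)


def _plant_decoys(truth, transcripts, mirnas, cfg, rng) -> None:
    """Seed matches planted far (>150 nt) from every footprint anchor."""
    by_id = {t.transcript_id: t for t in transcripts}
    anchors: dict[str, list[int]] = {}
    for _, fp in truth.planted_footprints.iterrows():
        anchors.setdefault(fp["transcript_id"], []).append(int(fp["anchor"]))
    mirna_ids = list(mirnas)
    rows = list(truth.planted_mres.to_dict(orient="records"))
    planted = 0
    for _ in range(cfg.n_decoys * 50):
        if planted >= cfg.n_decoys:
            break
        tx = transcripts[int(rng.integers(len(transcripts)))]
        start = int(rng.integers(0, tx.length - 10))
        if any(abs(start - a) <= 150 for a in anchors.get(tx.transcript_id, [])):
            continue
        mid = mirna_ids[int(rng.integers(len(mirna_ids)))]
        site = seed_site(mirnas[mid])
        tx.sequence = tx.sequence[:start] + site + tx.sequence[start + len(site):]
        rows.append({"mirna_id": mid, "transcript_id": tx.transcript_id,
                     "mre_start": start, "offset_from_anchor": -1,
                     "footprint_idx": -1, "decoy": True})
        planted += 1
    truth.planted_mres = pd.DataFrame(rows)


def _plant_hub_decoy_mres(truth, transcripts, mirnas, base_rpm, mirna_ids, cfg, rng) -> None:
    """Give each hub footprint a second, weakly loaded miRNA's MRE so the
    10x dominance rule is actually exercised (not just vacuously passed)."""
    weak = mirna_ids[int(np.argmin(base_rpm))]
    by_id = {t.transcript_id: t for t in transcripts}
    rows = list(truth.planted_mres.to_dict(orient="records"))
    hub_fps = truth.planted_footprints[
        truth.planted_footprints["mirna_id"] == truth.hub_mirna]
    site = seed_site(mirnas[weak])
    for _, fp in hub_fps.iterrows():
        tx = by_id[fp["transcript_id"]]
        # place the decoy MRE inside the window but clear of the hub MRE
        hub_off = int(truth.planted_mres.query(
            "footprint_idx == @fp.footprint_idx and not decoy")["offset_from_anchor"].iloc[0])
        offset = hub_off + 10 if hub_off <= 26 else hub_off - 10
        start = int(fp["anchor"]) + offset
        tx.sequence = tx.sequence[:start] + site + tx.sequence[start + len(site):]
        rows.append({"mirna_id": weak, "transcript_id": tx.transcript_id,
                     "mre_start": start, "offset_from_anchor": offset,
                     "footprint_idx": int(fp["footprint_idx"]), "decoy": False})
    truth.planted_mres = pd.DataFrame(rows)


def _scrub_chance_sites(truth, transcripts, mirnas,
                        offset_range: tuple[int, int] = (5, 43)) -> None:
    """Mutate chance seed-core matches inside planted footprint windows.

    The simulated truth promises that the miRNAs with a regulatory element in
    a planted footprint's confirmation window are exactly the planted ones;
    random sequence occasionally violates that by chance (a 6mer core appears
    about once per 4 kb per miRNA). Any unplanted core occurrence inside a
    window is disrupted by a single deterministic base change, leaving
    planted sites untouched.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    protected: dict[str, set[int]] = {}
    for r in truth.planted_mres.itertuples():
        protected.setdefault(r.transcript_id, set()).update(
            range(r.mre_start - 1, r.mre_start + 8))
    cores = {seed_site(seq)[1:] for seq in mirnas.values()}  # revcomp of nt 2-7
    lo, hi = offset_range
    for fp in truth.planted_footprints.itertuples():
        tx = by_id[fp.transcript_id]
        prot = protected.get(fp.transcript_id, set())
        w_lo, w_hi = fp.anchor + lo - 1, fp.anchor + hi + 1  # both site classes
        for _ in range(10):  # a mutation can itself create a new core match
            dirty = False
            seq = tx.sequence
            for core in cores:
                q = seq.find(core, max(w_lo, 0))
                while q != -1 and q <= w_hi:
                    mutable = [p for p in range(q, q + 6) if p not in prot]
                    if mutable:
                        p = mutable[len(mutable) // 2]
                        repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
                        seq = seq[:p] + repl + seq[p + 1:]
                        dirty = True
                    q = seq.find(core, q + 1)
            tx.sequence = seq
            if not dirty:
                break


def _simulate_fragments(cfg, rng, transcripts, truth, expr) -> pd.DataFrame:
    """Fragment starts: NB-deep pileups at planted anchors (normal jitter)
    plus a uniform background over all transcript positions."""
    by_id = {t.transcript_id: t for t in transcripts}
    tp_index = {tp: i for i, tp in enumerate(TIME_POINTS)}
    tx_index = {t.transcript_id: i for i, t in enumerate(transcripts)}
    lengths = np.array([t.length for t in transcripts])
    total_nt = int(lengths.sum())
    cum = np.concatenate([[0], np.cumsum(lengths)])
    flo, fhi = cfg.fragment_length_range
    records: list[tuple] = []
    for tp in TIME_POINTS:
        t = tp_index[tp]
        for rep in REPLICATES:
            # planted footprints
            for _, fp in truth.planted_footprints.iterrows():
                tx = by_id[fp["transcript_id"]]
                rpkm = expr[t, tx_index[tx.transcript_id]]
                mean_reads = (fp[f"true_strength_{tp}"] * rpkm / 1e6
                              * cfg.clip_library_size)
                n = int(nb_counts(rng, np.array([mean_reads]), cfg.dispersion)[0])
                if n == 0:
                    continue
                if cfg.start_jitter_sd > 0:
                    starts = int(fp["anchor"]) + np.rint(
                        rng.normal(0, cfg.start_jitter_sd, n)).astype(int)
                else:
                    starts = np.full(n, int(fp["anchor"]))
                starts = np.clip(starts, 0, tx.length - fhi - 1)
                lens = rng.integers(flo, fhi + 1, n)
                for s, ln in zip(starts, lens):
                    records.append((tx.transcript_id, int(s), int(ln), rep, tp))
            # uniform background
            n_bg = rng.poisson(cfg.background_rate * total_nt)
            if n_bg:
                pos = rng.integers(0, total_nt, n_bg)
                ti_bg = np.searchsorted(cum, pos, side="right") - 1
                for p, i in zip(pos, ti_bg):
                    tx = transcripts[i]
                    s = int(min(p - cum[i], max(tx.length - fhi - 1, 0)))
                    ln = int(rng.integers(flo, min(fhi, tx.length - s) + 1))
                    records.append((tx.transcript_id, s, ln, rep, tp))
    df = pd.DataFrame(records, columns=["transcript_id", "start", "length",
                                        "replicate", "time_point"])
    df = df.groupby(["transcript_id", "start", "length", "replicate", "time_point"],
                    as_index=False).size().rename(columns={"size": "count"})
    return df[FRAGMENT_COLUMNS].sort_values(
        ["transcript_id", "start", "replicate", "time_point"], ignore_index=True)


def _simulate_rnaseq(cfg, rng, transcripts, expr) -> pd.DataFrame:
    lengths_kb = np.array([t.length for t in transcripts]) / 1000.0
    lib_m = cfg.rnaseq_library_size / 1e6
    rows = []
    for t, tp in enumerate(TIME_POINTS):
        mu = expr[t] * lengths_kb * lib_m
        for rep in REPLICATES:
            counts = nb_counts(rng, mu, cfg.dispersion)
            for tx, c in zip(transcripts, counts):
                rows.append((tx.transcript_id, tp, rep, int(c), cfg.rnaseq_library_size))
    return pd.DataFrame(rows, columns=["transcript_id", "time_point", "replicate",
                                       "raw_count", "library_size"])


def write_study(out_dir: str | Path, transcripts, fragments, mirna_counts,
                rnaseq_counts, mirnas, truth) -> None:
    """Write the simulated study in the formats the pipeline reads."""
    from . import io_formats as io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_transcript_fasta(transcripts, out / "transcripts.fa")
    io.write_regions_bed(transcripts, out / "regions.bed")
    io.write_fragment_table(fragments, out / "fragments.tsv")
    io.write_counts_table(mirna_counts, out / "mirna_counts.tsv")
    io.write_counts_table(rnaseq_counts, out / "rnaseq_counts.tsv")
    with open(out / "mirnas.fa", "w") as fh:
        for mid, seq in mirnas.items():
            fh.write(f">{mid}\n{seq}\n")
    truth.to_json(out / "truth.json")
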