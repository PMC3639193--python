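"""Total regulatory load (TRL) profiles, normalized matrices and clustering.

TRL of an mRNA is the sum of the expression-weighted strengths of all its Ago
footprints, averaged over the two biological replicates at each time point.
mRNA (RPKM) and TRL time-course matrices are built as log2 values, quantile
normalized across replicate libraries, replicate-averaged, and clustered with
k-means over row-mean-centered profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import TIME_POINTS, TIME_HOURS
from .overlap_analysis import fisher_one_sided, bh_adjust

#: pseudocount added before log2 on TRL / RPKM values
LOG_PSEUDOCOUNT = 0.1


def compute_trl(
    footprints: pd.DataFrame,
    time_points: tuple[str, ...] = TIME_POINTS,
) -> pd.DataFrame:
    """Per-transcript TRL per time point, with Min/Max/fold-change summary.

    Footprint strengths are summed per (transcript, time_point, replicate)
    then averaged over replicates; conditions without any footprint on a
    transcript contribute 0. Footprints with undefined strength are ignored.
    Returns a DataFrame indexed by transcript_id with one column per time
    point plus ``min``, ``max`` and ``fold_change`` (max/min; inf if min 0).
    """
    fp = footprints
    if "strength_defined" in fp.columns:
        fp = fp[fp["strength_defined"]]
    fp = fp.dropna(subset=["strength"])
    if fp.empty:
        cols = list(time_points) + ["min", "max", "fold_change"]
        return pd.DataFrame(columns=cols).rename_axis("transcript_id")
    per_rep = fp.groupby(["transcript_id", "time_point", "replicate"])["strength"] \
                .sum().reset_index()
    n_reps = {tp: per_rep[per_rep["time_point"] == tp]["replicate"].nunique()
              for tp in time_points}
    # mean over replicates, counting absent (zero-footprint) replicates as 0
    wide = per_rep.pivot_table(index="transcript_id", columns="time_point",
                               values="strength", aggfunc="sum", fill_value=0.0)
    for tp in time_points:
        if tp not in wide.columns:
            wide[tp] = 0.0
        wide[tp] = wide[tp] / max(n_reps.get(tp, 0), 1)
    wide = wide[list(time_points)]
    wide.columns.name = None
    wide["min"] = wide[list(time_points)].min(axis=1)
    wide["max"] = wide[list(time_points)].max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wide["fold_change"] = np.where(wide["min"] > 0, wide["max"] / wide["min"], np.inf)
    return wide


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization of columns (ties share the mean of
    their tied target values). All columns end with identical sorted values."""
    arr = df.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy() - 1.0
        out[:, j] = np.interp(ranks, np.arange(n), target)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def build_matrix(
    values: pd.DataFrame,
    floor: float,
    floor_inclusive: bool = True,
    log_pseudocount: float = LOG_PSEUDOCOUNT,
    time_points: tuple[str, ...] = TIME_POINTS,
) -> pd.DataFrame:
    """Normalized log2 time-course matrix from per-replicate values.

    ``values`` has columns (transcript_id, time_point, replicate, value).
    Rows are kept when the replicate-mean raw value passes ``floor`` at >= 1
    time point (>= if ``floor_inclusive`` — the "at least 2 RPKM" rule — else
    strictly greater — the "TRL over 1" rule). Kept rows are log2(v + pc) per
    replicate library, quantile normalized across libraries, then replicate
    averaged. Returns rows x time points.
    """
    if values.empty:
        return pd.DataFrame(columns=list(time_points)).rename_axis("transcript_id")
    for tp in time_points:
        if values[values["time_point"] == tp].empty:
            raise ValueError(f"no replicates at time point {tp!r}")
    means = values.pivot_table(index="transcript_id", columns="time_point",
                               values="value", aggfunc="mean")
    passes = (means >= floor) if floor_inclusive else (means > floor)
    keep = passes.any(axis=1)
    keep_ids = keep[keep].index
    libs = values.pivot_table(index="transcript_id",
                              columns=["time_point", "replicate"], values="value")
    libs = libs.loc[keep_ids].fillna(0.0)
    logged = np.log2(libs + log_pseudocount)
    normed = quantile_normalize(logged)
    averaged = normed.T.groupby(level="time_point").mean().T
    return averaged[list(time_points)]


def kmeans_profiles(
    matrix: pd.DataFrame,
    k_final: int = 12,
    k_range: tuple[int, int] = (4, 30),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.Series, dict[int, float]]:
    """Cluster row-mean-centered profiles with k-means.

    Returns ``(assignments, inertia_by_k)``: assignments at ``k_final`` and
    the within-cluster sum of squares for each k in ``k_range`` (clipped to
    the number of rows). Deterministic for a fixed seed.
    """
    n = len(matrix)
    if k_final > n:
        raise ValueError(f"k_final={k_final} exceeds {n} rows")
    centered = matrix.sub(matrix.mean(axis=1), axis=0).to_numpy()
    inertia: dict[int, float] = {}
    for k in range(k_range[0], min(k_range[1], n) + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(centered)
        inertia[k] = float(km.inertia_)
    km = KMeans(n_clusters=k_final, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(centered)
    return pd.Series(labels, index=matrix.index, name="cluster"), inertia


def contrast_profiles(
    gene_ids: list[str],
    mrna_matrix: pd.DataFrame,
    trl_matrix: pd.DataFrame,
    time_points: tuple[str, ...] = TIME_POINTS,
) -> tuple[pd.DataFrame, set[str]]:
    """Paired (mRNA, TRL) profiles with a lead/lag summary per gene.

    ``lag_hours`` = hours of the TRL peak minus hours of the mRNA peak; a
    negative lag means regulatory load peaks before the mRNA does. Genes
    absent from either matrix are returned in the skipped set.
    """
    rows = []
    skipped = set()
    hours = np.array([TIME_HOURS[tp] for tp in time_points])
    for g in gene_ids:
        if g not in mrna_matrix.index or g not in trl_matrix.index:
            skipped.add(g)
            continue
        m = mrna_matrix.loc[g, list(time_points)].to_numpy(dtype=float)
        t = trl_matrix.loc[g, list(time_points)].to_numpy(dtype=float)
        row = {"gene_id": g,
               "mrna_peak": time_points[int(np.argmax(m))],
               "trl_peak": time_points[int(np.argmax(t))],
               "lag_hours": float(hours[int(np.argmax(t))] - hours[int(np.argmax(m))])}
        for i, tp in enumerate(time_points):
            row[f"mrna_{tp}"] = m[i]
            row[f"trl_{tp}"] = t[i]
        rows.append(row)
    return pd.DataFrame(rows), skipped


def gene_set_enrichment(
    cluster_members: dict[int, set[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of each gene set in each cluster, BH-adjusted.

    Columns: (cluster, gene_set, k, m, n, N, p, fdr), m = cluster size within
    the universe, n = gene-set size within the universe, k = their overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    rows = []
    for cl, members in cluster_members.items():
        mem = members & universe
        if not mem:
            continue
        for name, gs in gene_sets.items():
            g = gs & universe
            k = len(mem & g)
            rows.append((cl, name, k, len(mem), len(g), N,
                         fisher_one_sided(k, len(mem), len(g), N)))
    df = pd.DataFrame(rows, columns=["cluster", "gene_set", "k", "m", "n", "N", "p"])
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"].values)
        df = df.sort_values(["p", "cluster"], ignore_index=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df
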