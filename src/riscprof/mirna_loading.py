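"""Quantify miRNA recruitment to the RISC from Ago-short library counts.

Loading is expressed as reads per million (RPM) within each replicate's
Ago-short library. A 100 RPM floor defines the detected RISC-loaded set;
differential loading against the quiescent (0h) reference uses global
median-of-log-ratio normalization, a stricter 1000 RPM floor, a pooled-variance
z-test on log2 normalized RPM and Benjamini-Hochberg control at FDR <= 20%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .overlap_analysis import bh_adjust

logger = logging.getLogger("riscprof")

#: pseudocount, in reads, applied only inside log-ratio computations
LOG_PSEUDO_READS = 0.5


class LoadingError(ValueError):
    """Invalid input to a loading computation."""


def compute_rpm(counts: pd.DataFrame, id_col: str = "mirna_id") -> pd.DataFrame:
    """Add an ``rpm`` column: raw_count / library_size * 1e6.

    If ``library_size`` is absent it is taken as the total raw count of the
    (time_point, replicate) library, in which case RPM sums to 1e6 per library.
    """
    df = counts.copy()
    if "library_size" not in df.columns:
        df["library_size"] = df.groupby(["time_point", "replicate"])["raw_count"] \
                               .transform("sum")
    if (df["library_size"] <= 0).any():
        raise LoadingError("zero or negative library size")
    df["rpm"] = df["raw_count"] / df["library_size"] * 1e6
    return df


def detect_loaded(loading: pd.DataFrame, rpm_detect: float = 100.0) -> set[str]:
    """miRNAs whose replicate-mean RPM reaches ``rpm_detect`` at >= 1 time point."""
    means = loading.groupby(["mirna_id", "time_point"])["rpm"].mean()
    return set(means[means >= rpm_detect].index.get_level_values("mirna_id"))


def global_normalize(
    loading: pd.DataFrame,
    reference_time: str = "0h",
    rpm_differential: float = 1000.0,
    min_mirnas: int = 5,
) -> pd.DataFrame:
    """Median-of-log-ratio normalization against the quiescent reference.

    Each library is rescaled so the median log-ratio of its RPM to the
    reference-time replicate-mean RPM, over miRNAs whose reference mean is at
    least ``rpm_differential``, becomes zero; the reference libraries' scale
    factors are then geometric-mean-centered to 1. Adds ``normalized_rpm``.

    With fewer than ``min_mirnas`` high-abundance miRNAs the normalization is
    a no-op (scale 1 everywhere) and a warning is logged.
    """
    df = loading.copy()
    if reference_time not in set(df["time_point"]):
        raise LoadingError(f"reference time point {reference_time!r} missing")
    ref = df[df["time_point"] == reference_time]
    ref_mean = ref.groupby("mirna_id")["rpm"].mean()
    high = ref_mean[ref_mean >= rpm_differential].index
    if len(high) < min_mirnas:
        logger.warning(
            "only %d miRNAs above %g RPM at %s; skipping global normalization",
            len(high), rpm_differential, reference_time)
        df["normalized_rpm"] = df["rpm"]
        return df
    scales: dict[tuple[str, str], float] = {}
    for (tp, rep), lib in df.groupby(["time_point", "replicate"]):
        # pseudocount floors zeros only, so ratios of observed RPM stay exact
        pseudo = LOG_PSEUDO_READS / lib["library_size"].iloc[0] * 1e6
        lib = lib.set_index("mirna_id").reindex(high)
        logratio = np.log(np.maximum(lib["rpm"], pseudo)
                          / np.maximum(ref_mean.loc[high], pseudo))
        scales[(tp, rep)] = float(np.exp(-np.nanmedian(logratio)))
    ref_scales = [s for (tp, _), s in scales.items() if tp == reference_time]
    center = float(np.exp(np.mean(np.log(ref_scales))))
    df["normalized_rpm"] = [
        row.rpm * scales[(row.time_point, row.replicate)] / center
        for row in df.itertuples()
    ]
    return df


def call_differential_loading(
    loading: pd.DataFrame,
    fdr_max: float = 0.20,
    rpm_differential: float = 1000.0,
    reference_time: str = "0h",
    variance_pool_floor: float = 100.0,
) -> pd.DataFrame:
    """Call differentially RISC-loaded miRNAs vs the quiescent reference.

    For each miRNA and post-reference time point, the fold change of mean
    normalized RPM is tested with a two-sided z-test on log2 normalized RPM
    whose replicate variance is pooled across all miRNA x condition cells with
    mean normalized RPM >= ``variance_pool_floor``. P-values are BH-adjusted
    per time point over the miRNAs passing the ``rpm_differential`` floor at
    the tested or reference time point.

    Returns a DataFrame (mirna_id, time_point, fold_change, log2fc, p, fdr,
    direction, called).
    """
    if "normalized_rpm" not in loading.columns:
        raise LoadingError("run global_normalize first (normalized_rpm missing)")
    if reference_time not in set(loading["time_point"]):
        raise LoadingError(f"reference time point {reference_time!r} missing")
    df = loading.copy()
    pseudo = LOG_PSEUDO_READS / df["library_size"] * 1e6
    df["log2_norm"] = np.log2(np.maximum(df["normalized_rpm"], pseudo))

    cell = df.groupby(["mirna_id", "time_point"]).agg(
        mean_norm=("normalized_rpm", "mean"),
        mean_log2=("log2_norm", "mean"),
        var_log2=("log2_norm", "var"),   # ddof=1
        n=("log2_norm", "size"),
    ).reset_index()
    pool = cell[(cell["mean_norm"] >= variance_pool_floor) & (cell["n"] > 1)]
    if pool.empty:
        raise LoadingError("no cells available for pooled variance estimation")
    s2 = float(pool["var_log2"].mean())

    ref = cell[cell["time_point"] == reference_time].set_index("mirna_id")
    rows = []
    for tp in sorted(set(cell["time_point"]) - {reference_time}):
        sub = cell[cell["time_point"] == tp].set_index("mirna_id")
        common = sub.index.intersection(ref.index)
        if common.empty:
            continue
        a, b = sub.loc[common], ref.loc[common]
        log2fc = a["mean_log2"] - b["mean_log2"]
        se = np.sqrt(s2 / a["n"] + s2 / b["n"])
        z = np.where(se > 0, log2fc / se, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
        floor_ok = (a["mean_norm"] >= rpm_differential) | (b["mean_norm"] >= rpm_differential)
        tested = pd.DataFrame({
            "mirna_id": common, "time_point": tp,
            "fold_change": np.power(2.0, log2fc.values),
            "log2fc": log2fc.values, "p": p,
            "floor_ok": floor_ok.values,
        })
        tested = tested[tested["floor_ok"]].drop(columns="floor_ok")
        if tested.empty:
            continue
        tested["fdr"] = bh_adjust(tested["p"].values)
        tested["direction"] = np.where(tested["log2fc"] > 0, "up", "down")
        tested["called"] = (tested["fdr"] <= fdr_max) & (tested["log2fc"] != 0)
        rows.append(tested)
    if not rows:
        return pd.DataFrame(columns=["mirna_id", "time_point", "fold_change",
                                     "log2fc", "p", "fdr", "direction", "called"])
    return pd.concat(rows, ignore_index=True)
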