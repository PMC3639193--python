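"""Gene-set overlap statistics for confirmed miRNA target sets.

The significance of the overlap between a miRNA's confirmed target genes and
an externally defined regulated-gene set is the one-sided Fisher exact test
(upper hypergeometric tail), corrected across miRNAs with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_one_sided(k: int, m: int, n: int, N: int) -> float:
    """One-sided (over-enrichment) Fisher exact p-value.

    P(X >= k) for X ~ Hypergeom(population N, m marked, n drawn): the chance
    of seeing at least ``k`` genes shared between a target set of size ``m``
    and a gene set of size ``n`` drawn from a universe of ``N`` genes.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"m={m}, n={n} must lie in [0, N={N}]")
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"k={k} must lie in [0, min(m={m}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_table(
    target_sets: dict[str, set[str]],
    gene_set: set[str],
    universe: set[str],
    label: str = "gene_set",
) -> pd.DataFrame:
    """One OverlapResult row per target set vs one regulated-gene set.

    Columns: (mirna_id, gene_set_label, k, m, n, N, p, fdr), BH-adjusted
    across the target sets, sorted by ascending p.
    """
    if not universe:
        raise ValueError("empty universe")
    outside = gene_set - universe
    if outside:
        raise ValueError(f"gene set members outside universe: {sorted(outside)[:5]}")
    n, N = len(gene_set), len(universe)
    rows = []
    for mirna_id, targets in target_sets.items():
        t = targets & universe
        if not t:
            continue
        k = len(t & gene_set)
        rows.append((mirna_id, label, k, len(t), n, N, fisher_one_sided(k, len(t), n, N)))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_set_label", "k", "m", "n", "N", "p"])
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"].values)
        df = df.sort_values(["p", "mirna_id"], ignore_index=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def rank_mirnas_by_overlap(
    confirmed_pairs: pd.DataFrame,
    gene_set: set[str],
    universe: set[str],
    gene_of: dict[str, str] | None = None,
    label: str = "gene_set",
) -> pd.DataFrame:
    """Rank miRNAs by overlap of their confirmed target genes with a gene set.

    ``confirmed_pairs`` needs columns (mirna_id, transcript_id[, gene_id]);
    transcripts are collapsed to genes (a gene is a target if any of its
    transcripts carries a confirmed pair). Only genes in the universe count.
    """
    pairs = confirmed_pairs.copy()
    if "gene_id" not in pairs.columns:
        if gene_of is None:
            raise ValueError("need gene_id column or gene_of mapping")
        pairs["gene_id"] = pairs["transcript_id"].map(gene_of)
    target_sets = {
        mid: set(grp["gene_id"]) for mid, grp in pairs.groupby("mirna_id")
    }
    return overlap_table(target_sets, gene_set, universe, label=label)
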