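"""Candidate ceRNA networks from dominant footprints and dominant miRNAs.

An mRNA enters a ceRNA network at a time point when (1) after merging
footprints within 20 nt, its second strongest footprint is less than 25% as
strong as its strongest (strict), and (2) the most loaded miRNA with a
confirmed regulatory element in that strongest footprint is at least 10x more
loaded than the second most (inclusive); either rule passes vacuously when
there is a single footprint or a single confirmed miRNA. Edges connect the
dominant miRNA (hub) to the mRNA; per-time-point networks are merged across
time points into summary networks with per-edge provenance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDGE_COLUMNS = ["hub_mirna", "gene_id", "transcript_id", "footprint_id", "strength",
                "time_point"]


def select_dominant_footprint(footprints: pd.DataFrame, frac: float = 0.25):
    """Strongest merged footprint of one mRNA, iff the second strongest is
    strictly below ``frac`` of it; a single footprint passes vacuously.
    Returns the footprint row (Series) or None."""
    fps = footprints.dropna(subset=["strength"])
    if fps.empty:
        return None
    order = fps.sort_values("strength", ascending=False)
    if len(order) == 1:
        return order.iloc[0]
    top, second = order.iloc[0], order.iloc[1]
    if second["strength"] < frac * top["strength"]:
        return top
    return None


def select_dominant_mirna(loadings: dict[str, float] | pd.Series, ratio: float = 10.0):
    """Most loaded miRNA among those confirmed in a footprint, iff it is at
    least ``ratio`` times the second most loaded (inclusive); a single miRNA
    passes vacuously. Returns the miRNA id or None."""
    s = pd.Series(loadings, dtype=float).sort_values(ascending=False)
    if s.empty:
        return None
    if len(s) == 1:
        return s.index[0]
    top, second = s.iloc[0], s.iloc[1]
    if second == 0:
        return s.index[0]
    if top >= ratio * second:
        return s.index[0]
    return None


def build_network_for_time_point(
    merged_footprints: pd.DataFrame,
    confirmed_pairs: pd.DataFrame,
    loading_rpm: pd.Series,
    time_point: str,
    gene_of: dict[str, str] | None = None,
    frac: float = 0.25,
    ratio: float = 10.0,
) -> pd.DataFrame:
    """Edges (hub miRNA <-> mRNA) for one time point.

    ``merged_footprints``: footprints of this time point, already merged at
    20 nt, with strengths. ``confirmed_pairs``: confirmed MRE pairs whose
    ``supporting`` lists reference these footprint ids. ``loading_rpm``:
    replicate-mean miRNA RPM at this time point.
    """
    pairs = confirmed_pairs[confirmed_pairs.get("confirmed", True)] \
        if "confirmed" in confirmed_pairs.columns else confirmed_pairs
    # footprint id -> set of confirmed miRNAs with an MRE in it
    fp_mirnas: dict[str, set[str]] = {}
    for _, p in pairs.iterrows():
        for tp, _rep, fid in p.get("supporting", []):
            if tp == time_point:
                fp_mirnas.setdefault(fid, set()).add(p["mirna_id"])
    edges = []
    for tx, grp in merged_footprints.groupby("transcript_id"):
        dom = select_dominant_footprint(grp, frac=frac)
        if dom is None:
            continue
        mirnas = fp_mirnas.get(dom["footprint_id"], set())
        if not mirnas:
            continue
        loads = {m: float(loading_rpm.get(m, 0.0)) for m in mirnas}
        hub = select_dominant_mirna(loads, ratio=ratio)
        if hub is None:
            continue
        gene = (gene_of or {}).get(tx, tx)
        edges.append((hub, gene, tx, dom["footprint_id"], float(dom["strength"]),
                      time_point))
    return pd.DataFrame(edges, columns=EDGE_COLUMNS)


def merge_networks(per_time_point: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of per-time-point networks into summary networks.

    One row per (hub miRNA, transcript) with ``time_points`` listing every
    supporting time point (sorted, comma-joined) and the maximal strength seen.
    Idempotent and independent of time-point order.
    """
    frames = []
    for df in per_time_point.values():
        if df.empty:
            continue
        df = df.rename(columns={"time_point": "time_points"})
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["hub_mirna", "gene_id", "transcript_id",
                                     "footprint_id", "strength", "time_points"])
    allp = pd.concat(frames, ignore_index=True)
    rows = []
    for (hub, tx), grp in allp.groupby(["hub_mirna", "transcript_id"]):
        tps = sorted(set(",".join(grp["time_points"].astype(str)).split(",")))
        best = grp.loc[grp["strength"].idxmax()]
        rows.append({"hub_mirna": hub, "gene_id": best["gene_id"], "transcript_id": tx,
                     "footprint_id": best["footprint_id"],
                     "strength": float(grp["strength"].max()),
                     "time_points": ",".join(tps)})
    return pd.DataFrame(rows).sort_values(["hub_mirna", "transcript_id"],
                                          ignore_index=True)


def networks_by_hub(edges: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group a (merged or per-time-point) edge table into one network per hub."""
    return {hub: grp.reset_index(drop=True)
            for hub, grp in edges.groupby("hub_mirna")}


def to_graph(edges: pd.DataFrame):
    """Bipartite miRNA <-> gene graph (networkx) from an edge table."""
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_node(e["hub_mirna"], kind="mirna", bipartite=0)
        g.add_node(e["gene_id"], kind="gene", bipartite=1)
        attrs = {"strength": float(e["strength"]), "transcript": e["transcript_id"]}
        if "time_points" in e.index:
            attrs["time_points"] = e["time_points"]
        elif "time_point" in e.index:
            attrs["time_points"] = e["time_point"]
        g.add_edge(e["hub_mirna"], e["gene_id"], **attrs)
    return g


def write_graphml(edges: pd.DataFrame, path) -> None:
    import networkx as nx

    nx.write_graphml(to_graph(edges), path)
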