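"""Hierarchical clustering of post-blank intensity profiles.

Deconditioning does not hit every analyte equally: in plasma-like batches
the late-eluting lipophilic fraction responds strongly while early-eluting
polar analytes barely move.  To find such response families, each
feature's corrected areas are averaged per relative position within a
cycle (blank positions, then sample positions 1..8) over all cycles of one
deconditioning type, z-scored per feature, and clustered hierarchically
with 1 - Pearson correlation as the distance (average linkage by default).
The two main clusters are then summarised by membership, m/z and RT
quartiles, and their median normalised profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import PeakTable

__all__ = ["build_profiles", "hca_pearson", "cluster_summary", "linkage_newick"]


def build_profiles(table: PeakTable, cycle_type: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Cycle-averaged position profiles per feature.

    Returns ``(profiles, normalized, constant_ids)``: the mean area per
    relative position (columns ``B1..Bg, S1..S8``), the row-wise z-scored
    profiles with constant rows dropped, and the ids of those constant
    (flagged) rows.
    """
    seq = table.sequence
    cyc = seq[seq["cycle_type"] == cycle_type]
    if cyc["cycle_id"].nunique() < 2:
        raise ValueError(f"need >= 2 {cycle_type} cycles to average profiles")
    cols, labels = [], []
    for sclass, prefix in (("blank", "B"), ("sample", "S")):
        sub = cyc[cyc["sample_class"] == sclass]
        for p in sorted(sub["position_after_blank"].dropna().unique()):
            cols.append(sub.index[sub["position_after_blank"] == p])
            labels.append(f"{prefix}{int(p)}")
    prof = pd.DataFrame(
        {lab: table.area[c].mean(axis=1) for lab, c in zip(labels, cols)},
        index=table.feature_ids,
    )
    vals = prof.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    norm = (vals - vals.mean(axis=1, keepdims=True)) / np.where(constant, 1.0, sd)[:, None]
    normalized = pd.DataFrame(norm, index=prof.index, columns=prof.columns)[~constant]
    return prof, normalized, prof.index[constant]


def hca_pearson(
    profiles: pd.DataFrame,
    k: int = 2,
    method: str = "average",
    rt_median: pd.Series | None = None,
):
    """Agglomerative clustering with d = 1 - Pearson correlation.

    Returns ``(labels, Z)``: integer cluster labels (1..k) indexed like
    ``profiles`` and the scipy linkage matrix.  Cluster 1 is the largest
    cluster; ties go to the cluster with the lower mean median-RT when
    ``rt_median`` is given, else to the one containing the first feature.
    """
    if len(profiles) < k:
        raise ValueError(f"need >= {k} non-constant profiles, got {len(profiles)}")
    X = profiles.to_numpy(dtype=float)
    d = pdist(X, metric="correlation")
    Z = hierarchy.linkage(d, method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel: 1 = largest cluster (tie -> lower mean RT / first occurrence)
    sizes = pd.Series(raw).value_counts()
    order = []
    for lab in sizes.index:
        mean_rt = (
            float(rt_median.loc[profiles.index[raw == lab]].mean())
            if rt_median is not None
            else float(np.argmax(raw == lab))
        )
        order.append((-sizes[lab], mean_rt, lab))
    mapping = {lab: i + 1 for i, (_, _, lab) in enumerate(sorted(order))}
    labels = pd.Series([mapping[r] for r in raw], index=profiles.index, name="cluster")
    return labels, Z


def cluster_summary(
    labels: pd.Series,
    features: pd.DataFrame,
    normalized: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster membership, m/z-RT quartiles and median normalised profile.

    Returns ``(summary, median_profiles)``; empty clusters are dropped with
    a warning.
    """
    rows, med = [], {}
    total = len(labels)
    for lab in sorted(labels.unique()):
        ids = labels.index[labels == lab]
        if len(ids) == 0:  # pragma: no cover - fcluster never emits empties
            warnings.warn(f"cluster {lab} is empty, dropped", stacklevel=2)
            continue
        f = features.loc[ids]
        q = lambda s: np.percentile(s.to_numpy(dtype=float), [25, 50, 75])
        rt_q = q(f["rt_median"])
        mz_q = q(f["mz"])
        rows.append(
            {
                "cluster": lab,
                "n_members": len(ids),
                "fraction": len(ids) / total,
                "rt_q25": rt_q[0], "rt_median": rt_q[1], "rt_q75": rt_q[2],
                "mz_q25": mz_q[0], "mz_median": mz_q[1], "mz_q75": mz_q[2],
            }
        )
        med[lab] = normalized.loc[ids].median(axis=0)
    summary = pd.DataFrame(rows).set_index("cluster")
    median_profiles = pd.DataFrame(med).T.rename_axis("cluster")
    return summary, median_profiles


def linkage_newick(Z: np.ndarray, leaf_names) -> str:
    """Newick-like text rendering of a scipy linkage matrix."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def walk(node):
        if node.is_leaf():
            return str(names[node.id])
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree) + ";"
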