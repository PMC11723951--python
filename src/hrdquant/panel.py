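"""Construct-panel assembly, hierarchical clustering, and group statistics.

Combines per-cell partition coefficients and FRAP fit metrics into one row
per construct (medians across cells), clusters constructs on z-scored
features (Euclidean distance, average linkage), and runs the nonparametric
group comparisons used for partition-coefficient data: a Kruskal-Wallis
test across groups followed by pairwise Wilcoxon rank-sum tests with Holm
adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_FEATURES",
    "assemble_panel",
    "zscore_features",
    "cluster_panel",
    "linkage_to_newick",
    "compare_pc",
]

#: clustering features (mobile fraction is displayed but not clustered on by default)
DEFAULT_FEATURES = ("pc", "recovery_5s", "recovery_100s")

MOTIF_FLAG_ORDER = ("1", "H", "C", "2", "L", "3")


def assemble_panel(
    pc_records: pd.DataFrame,
    frap_fits: pd.DataFrame,
    construct_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per construct: median features plus provenance counts.

    ``pc_records`` needs columns ``construct_id, pc``; ``frap_fits`` needs
    ``construct_id, recovery_5s, recovery_100s, mobile_fraction``.
    ``construct_map`` (optional) carries motif presence/mutation flags named
    after the motif abbreviations (1, H, C, 2, L, 3) and is joined through.
    Constructs missing a modality are kept with NaN features and
    ``complete = False`` (excluded from clustering).
    """
    pc_g = pc_records.groupby("construct_id")["pc"].agg(["median", "size"])
    pc_g.columns = ["pc", "n_cells_pc"]
    feat_cols = [
        c for c in ("recovery_5s", "recovery_100s", "mobile_fraction") if c in frap_fits
    ]
    fr_g = frap_fits.groupby("construct_id")[feat_cols].median()
    fr_g["n_cells_frap"] = frap_fits.groupby("construct_id").size()
    panel = pc_g.join(fr_g, how="outer")
    panel["n_cells"] = panel[["n_cells_pc", "n_cells_frap"]].fillna(0).min(axis=1).astype(int)
    panel["complete"] = panel[["pc", *feat_cols]].notna().all(axis=1)
    panel = panel.reset_index()
    if construct_map is not None:
        panel = panel.merge(construct_map, on="construct_id", how="left")
    return panel


def zscore_features(panel: pd.DataFrame, features=DEFAULT_FEATURES) -> np.ndarray:
    """Column-wise z-scores (population sd) of the feature matrix."""
    x = panel.loc[:, list(features)].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def cluster_panel(
    panel: pd.DataFrame,
    k: int,
    features=DEFAULT_FEATURES,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Agglomerative clustering of the construct panel.

    Features are z-scored per column before distance computation; the tree
    is cut at ``k`` clusters and labels are renumbered 1..k by decreasing
    mean partition coefficient (deterministic ordering).  Returns the
    labeled panel, the scipy linkage matrix, and a Newick rendering of the
    tree.  Constructs with missing features are excluded and returned with
    label 0.
    """
    usable = panel[panel[list(features)].notna().all(axis=1)]
    if k > len(usable):
        raise ValueError(f"k={k} exceeds the {len(usable)} constructs with complete features")
    if k < 1:
        raise ValueError("k must be >= 1")
    z = zscore_features(usable, features)
    zlink = linkage(z, method=method, metric=metric)
    raw = fcluster(zlink, t=k, criterion="maxclust")
    # deterministic relabeling: cluster 1 has the highest mean pc
    order = (
        pd.DataFrame({"raw": raw, "pc": usable["pc"].to_numpy()})
        .groupby("raw")["pc"]
        .mean()
        .sort_values(ascending=False)
        .index.tolist()
    )
    remap = {r: i + 1 for i, r in enumerate(order)}
    out = panel.copy()
    out["cluster_label"] = 0
    out.loc[usable.index, "cluster_label"] = [remap[r] for r in raw]
    newick = linkage_to_newick(zlink, usable["construct_id"].tolist())
    return out, zlink, newick


def linkage_to_newick(zlink: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = to_tree(zlink)

    def walk(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def compare_pc(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across groups plus pairwise Wilcoxon rank-sum tests.

    Pairwise p-values use the exact rank-sum null when sample sizes allow
    (no ties, n small) and are reported both raw and Holm-adjusted.
    Returns a dict report; if every value across all groups is tied the
    global p is 1 with a ``"all_tied"`` flag.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size < 3 for a in arrays):
        raise ValueError("each group needs n >= 3")
    flags = []
    flat = np.concatenate(arrays)
    if np.allclose(flat, flat[0]):
        h, p = 0.0, 1.0
        flags.append("all_tied")
    else:
        h, p = kruskal(*arrays)
    pairs, raw_p, stats = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            pairs.append((names[i], names[j]))
            raw_p.append(float(res.pvalue))
            stats.append(float(res.statistic))
    adj = multipletests(raw_p, method="holm")[1] if raw_p else []
    return {
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "pairwise": [
            {
                "groups": list(pair),
                "statistic": s,
                "p_raw": pr,
                "p_holm": float(pa),
            }
            for pair, s, pr, pa in zip(pairs, stats, raw_p, adj)
        ],
        "flags": flags,
    }
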