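"""Ten-point profile construction and self-organizing-tree clustering.

Each gene is summarized by a ten-point profile: log2 fold-change of TR
relative to time 0 at the five post-shift times, concatenated with the
same for RA.  Time 0 is implicitly 0 on the log scale for both halves,
so the profile captures the shape of the transcriptional change and of
its downstream effect on the transcript pool on a common scale.

Clustering uses a self-organizing tree algorithm (SOTA): a divisive
binary tree of centroids grown from a single cell.  In each growth step
the profiles are presented one by one; the best-matching leaf (and,
more weakly, its sibling and parent) is pulled toward the presented
profile by small learning rates.  When the epoch-to-epoch change in
mean winner distance falls below a tolerance, the most heterogeneous
leaf (largest mean member distance to its centroid) is split into two
children and training resumes.  Growth stops at ``max_clusters`` leaves
or when every leaf is more homogeneous than a threshold.  After growth,
members are reassigned to their nearest leaf and leaf centroids set to
member means until stable, so the final leaves satisfy the
centroid-equals-member-mean property.  The default distance is
1 - Pearson correlation between profiles, the customary choice for
expression shapes (scale- and offset-invariant); squared-Euclidean is
available for magnitude-sensitive partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics_core import DecayProfile, GeneKinetics

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Gene x 10 matrix of log2 relative TR (5 points) ++ log2 relative RA."""

    gene_ids: list[str]
    values: np.ndarray
    excluded: dict[str, str] = field(default_factory=dict)  # gene -> reason

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 10:
            raise ValueError("profile matrix must have exactly 10 columns")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile matrix must be finite")


def build_profiles(genes: list[GeneKinetics]) -> ProfileMatrix:
    """Ten-point relative log2 profiles; genes with zero time-0 values excluded."""
    ids, rows, excluded = [], [], {}
    for g in genes:
        if g.tr[0] <= 0:
            excluded[g.gene_id] = "TR(t0) not positive"
            continue
        if g.ra[0] <= 0:
            excluded[g.gene_id] = "RA(t0) not positive"
            continue
        if np.any(g.tr[1:] <= 0) or np.any(g.ra[1:] <= 0):
            excluded[g.gene_id] = "zero TR/RA at a post-shift point"
            continue
        rows.append(
            np.concatenate(
                [np.log2(g.tr[1:] / g.tr[0]), np.log2(g.ra[1:] / g.ra[0])]
            )
        )
        ids.append(g.gene_id)
    for gid, reason in excluded.items():
        logger.info("profile excluded: %s (%s)", gid, reason)
    return ProfileMatrix(ids, np.asarray(rows).reshape(len(ids), 10), excluded)


# --- distances ---------------------------------------------------------------


def _corr_dist(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """1 - Pearson r between a profile x and each row of c; degenerate rows -> 1."""
    xc = x - x.mean()
    cc = c - c.mean(axis=1, keepdims=True)
    nx = np.sqrt((xc * xc).sum())
    ncs = np.sqrt((cc * cc).sum(axis=1))
    denom = nx * ncs
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cc @ xc) / denom
    r = np.where(denom > 0, r, 0.0)
    return 1.0 - r


def _eucl_dist(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    d = c - x
    return (d * d).sum(axis=1)


_DISTANCES = {"correlation": _corr_dist, "euclidean": _eucl_dist}


def _working_metric(distance: str):
    """Metric applied to working-space profiles (see :class:`ClusterTree`)."""
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    # in correlation mode rows are standardized, where squared Euclidean
    # distance is 2*(1 - r): same ordering, mean-friendly geometry
    return _eucl_dist


def _working_space(values: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return centered / norms


@dataclass
class SotaParams:
    """SOTA hyper-parameters (winner/sibling/parent rates follow the published defaults)."""

    max_clusters: int = 16
    distance: str = "correlation"
    lr_winner: float = 0.01
    lr_sibling: float = 0.005
    lr_parent: float = 0.001
    epoch_tol: float = 1e-6
    max_epochs: int = 200
    heterogeneity_threshold: float = 0.0  # stop early if all leaves below this
    refine: bool = True  # final reassign/recompute passes


@dataclass
class SotaNode:
    node_id: int
    centroid: np.ndarray
    parent: "SotaNode | None" = None
    children: list = field(default_factory=list)
    members: list[int] = field(default_factory=list)  # row indices; leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    """Binary centroid tree; leaves partition the clustered genes.

    ``values`` holds the working-space profiles: for correlation distance
    these are the row-standardized profiles (centered, unit norm), in
    which 1 - r equals half the squared Euclidean distance, so centroids
    can be member means in every mode.
    """

    root: SotaNode
    gene_ids: list[str]
    values: np.ndarray
    distance: str

    def leaves(self) -> list[SotaNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def assignments(self) -> pd.Series:
        """gene -> leaf cluster label (leaf order of the tree traversal)."""
        labels = {}
        for i, leaf in enumerate(self.leaves(), start=1):
            for row in leaf.members:
                labels[self.gene_ids[row]] = f"c{i:02d}"
        return pd.Series(labels, name="cluster").loc[self.gene_ids]

    def heterogeneity(self, node: SotaNode) -> float:
        """Mean member distance to the leaf centroid (working-space metric)."""
        if not node.members:
            return 0.0
        dist = _working_metric(self.distance)
        return float(
            np.mean(
                [dist(self.values[i], node.centroid[None, :])[0] for i in node.members]
            )
        )

    def newick(self) -> str:
        """Cluster dendrogram as a Newick string (leaf names = cluster labels)."""
        leaf_names = {id(l): f"c{i:02d}" for i, l in enumerate(self.leaves(), start=1)}

        def rec(node: SotaNode) -> str:
            if node.is_leaf:
                return leaf_names[id(node)]
            return "(" + ",".join(rec(c) for c in node.children) + ")"

        return rec(self.root) + ";"


def sota_cluster(m: ProfileMatrix, params: SotaParams | None = None) -> ClusterTree:
    """Cluster profiles with a divisive self-organizing tree.

    Deterministic for a fixed input order: profiles are presented in row
    order every epoch and ties go to the earlier leaf.
    """
    params = params or SotaParams()
    if params.max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    if params.distance not in _DISTANCES:
        raise ValueError(f"unknown distance {params.distance!r}")
    x = _working_space(m.values, params.distance)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 profiles to cluster")
    dist = _working_metric(params.distance)

    next_id = [0]

    def new_node(centroid, parent=None):
        node = SotaNode(next_id[0], centroid.copy(), parent)
        next_id[0] += 1
        return node

    root = new_node(x.mean(axis=0))
    root.members = list(range(n))
    tree = ClusterTree(root, list(m.gene_ids), x, params.distance)

    def train_epochs(leaves: list[SotaNode]) -> None:
        """Run presentation epochs until the mean winner distance stabilizes."""
        prev_err = np.inf
        for _ in range(params.max_epochs):
            for leaf in leaves:
                leaf.members = []
            err = 0.0
            centroids = np.array([l.centroid for l in leaves])
            for i in range(n):
                d = dist(x[i], centroids)
                w = int(np.argmin(d))  # ties -> earlier leaf
                err += d[w]
                winner = leaves[w]
                winner.members.append(i)
                winner.centroid += params.lr_winner * (x[i] - winner.centroid)
                centroids[w] = winner.centroid
                parent = winner.parent
                if parent is not None:
                    sib = parent.children[0] if parent.children[1] is winner else parent.children[1]
                    if sib.is_leaf and sib in leaves:
                        sib.centroid += params.lr_sibling * (x[i] - sib.centroid)
                        centroids[leaves.index(sib)] = sib.centroid
                    parent.centroid += params.lr_parent * (x[i] - parent.centroid)
            err /= n
            if abs(prev_err - err) < params.epoch_tol:
                break
            prev_err = err

    leaves = [root]
    train_epochs(leaves)
    while len(leaves) < params.max_clusters:
        het = [tree.heterogeneity(l) if l.members else 0.0 for l in leaves]
        worst = int(np.argmax(het))
        if het[worst] <= params.heterogeneity_threshold:
            break
        target = leaves[worst]
        if len(target.members) < 2:
            break
        # children start on either side of the leaf's principal axis so the
        # presentation epochs differentiate them quickly and deterministically
        mem = x[target.members]
        centered = mem - mem.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0] * centered.std(axis=0).mean()
        target.children = [
            new_node(target.centroid + 0.5 * axis, target),
            new_node(target.centroid - 0.5 * axis, target),
        ]
        target.members = []
        leaves = tree.leaves()
        train_epochs(leaves)
        if params.refine:
            # batch convergence after each growth step: reassign to nearest
            # leaf and set centroids to member means until stable, so leaves
            # always satisfy the centroid-equals-member-mean property
            _refine(tree, leaves, dist)

    if params.refine:
        _refine(tree, leaves, dist)
    # drop empty leaves' sibling structure is kept; assignments skip empties
    return tree


def _refine(tree: ClusterTree, leaves: list[SotaNode], dist, max_iter: int = 50) -> None:
    """Reassign members to nearest leaf and set centroids to member means."""
    x = tree.values
    for _ in range(max_iter):
        centroids = np.array([l.centroid for l in leaves])
        assign = np.array([int(np.argmin(dist(x[i], centroids))) for i in range(x.shape[0])])
        changed = False
        for j, leaf in enumerate(leaves):
            members = list(np.where(assign == j)[0])
            if members != leaf.members:
                changed = True
            leaf.members = members
            if members:
                new_c = x[members].mean(axis=0)
                if not np.allclose(new_c, leaf.centroid):
                    changed = True
                leaf.centroid = new_c
        if not changed:
            break


# --- per-cluster summary curves ----------------------------------------------


def cluster_mean_kd(
    tree: ClusterTree,
    profiles: dict[str, DecayProfile],
    include_flags: tuple[str, ...] = ("ok", "at_zero_bound", "no_positive_root"),
) -> pd.DataFrame:
    """Per-cluster mean relative k_D at each interval midpoint, with SE.

    Relative k_D is each gene's interval estimate divided by its own
    steady-state value, so 1 marks unchanged stability.  Interval results
    whose solver flag is not in ``include_flags`` are dropped from the mean.
    """
    rows = []
    assignments = tree.assignments()
    for cluster, genes in assignments.groupby(assignments):
        gene_list = list(genes.index)
        any_profile = profiles[gene_list[0]]
        for k, interval in enumerate(any_profile.intervals):
            vals = [
                profiles[g].intervals[k].kd_relative
                for g in gene_list
                if profiles[g].intervals[k].flag in include_flags
                and np.isfinite(profiles[g].intervals[k].kd_relative)
            ]
            if not vals:
                logger.warning("cluster %s: no usable kd at midpoint %s", cluster, interval.t_mid)
                continue
            vals = np.asarray(vals)
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append(
                {
                    "cluster": cluster,
                    "t_mid": interval.t_mid,
                    "mean_kd_relative": float(vals.mean()),
                    "se": se,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def cluster_mean_ra(
    tree: ClusterTree,
    genes: dict[str, GeneKinetics],
    theoretical: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-cluster mean experimental and theoretical RA curves.

    Curves are the cluster mean at each time divided by the cluster mean
    at time 0, for the measured RA and for the frozen-k_D prediction.
    """
    rows = []
    assignments = tree.assignments()
    for cluster, members in assignments.groupby(assignments):
        gene_list = list(members.index)
        ra = np.array([genes[g].ra for g in gene_list])
        theo = np.array([theoretical[g] for g in gene_list])
        times = np.asarray(genes[gene_list[0]].grid.times)
        mean_ra = ra.mean(axis=0)
        mean_theo = theo.mean(axis=0)
        for j, t in enumerate(times):
            rows.append(
                {
                    "cluster": cluster,
                    "time": t,
                    "mean_ra_relative": mean_ra[j] / mean_ra[0],
                    "mean_ra_theoretical_relative": mean_theo[j] / mean_theo[0],
                    "n": len(gene_list),
                }
            )
    return pd.DataFrame(rows)
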