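"""Homogeneity-constrained time-course co-expression clustering.

Genes are clustered on the shape of their per-gene standardized mean
profile over timepoints.  A cluster is acceptable only if its
*homogeneity* — the mean Pearson correlation of member profiles against
the cluster centroid — reaches a configured minimum (default 0.85).

The algorithm is average-linkage agglomeration on Pearson distance whose
dendrogram is cut top-down to the largest subtrees meeting the
homogeneity constraint, followed by an adoption pass in which pooled
genes join a cluster when they correlate with its centroid at or above
the same threshold and the cluster's homogeneity survives the adoption.
Input gene order never affects the result: genes are sorted internally
before linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each gene's profile to mean 0, sd 1.

    Raises ``ValueError`` listing the offending genes if any profile has
    zero variance (a flat profile carries no shape information).
    """
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flat = profiles.index[sd == 0]
    if len(flat):
        raise ValueError(
            f"zero-variance gene profiles: {sorted(map(str, flat))[:10]}"
        )
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def _centroid(std: np.ndarray) -> np.ndarray:
    return std.mean(axis=0)


def _pearson_to(profile_rows: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    c = centroid - centroid.mean()
    cn = np.linalg.norm(c)
    if cn == 0:
        return np.zeros(profile_rows.shape[0])
    rows = profile_rows - profile_rows.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(rows, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = rows @ c / (rn * cn)
    return np.where(rn == 0, 0.0, r)


def homogeneity(std_rows: np.ndarray) -> float:
    """Mean Pearson correlation of member rows against their centroid."""
    if std_rows.shape[0] == 1:
        return 1.0
    return float(_pearson_to(std_rows, _centroid(std_rows)).mean())


@dataclass
class GeneCluster:
    """One co-expression cluster over the time course."""

    id: str
    members: list[str]
    centroid: np.ndarray
    homogeneity: float
    direction: str | None = None          # "up" | "down"
    stage: int | None = None              # 1-based temporal rank
    homogeneity_ok: bool = True           # False when a merge dropped it

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Ordered disjoint clusters plus the unclustered gene pool."""

    clusters: list[GeneCluster]
    pool: list[str]
    timepoints: np.ndarray
    profiles: pd.DataFrame = field(repr=False, default=None)  # standardized

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c.members:
                raise ValueError(f"cluster {c.id} is empty")
            overlap = seen & set(c.members)
            if overlap:
                raise ValueError(f"overlapping membership: {sorted(overlap)[:5]}")
            seen |= set(c.members)
        if seen & set(self.pool):
            raise ValueError("pool overlaps cluster membership")

    @property
    def all_genes(self) -> set[str]:
        out = set(self.pool)
        for c in self.clusters:
            out |= set(c.members)
        return out

    def membership(self) -> dict[str, str]:
        return {g: c.id for c in self.clusters for g in c.members}

    def by_id(self, cid: str) -> GeneCluster:
        for c in self.clusters:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": c.id,
                    "size": len(c),
                    "homogeneity": c.homogeneity,
                    "direction": c.direction,
                    "stage": c.stage,
                }
                for c in self.clusters
            ]
        )


def cluster_timecourse(
    profiles: pd.DataFrame,
    h_min: float = 0.85,
    min_size: int = 10,
    split_r: float = 0.90,
) -> ClusterSet:
    """Cluster per-gene mean profiles under a homogeneity constraint.

    Parameters
    ----------
    profiles:
        genes x timepoints DataFrame of mean log2 expression (columns are
        day labels, strictly increasing).  Profiles are standardized
        internally; zero-variance profiles are rejected.
    h_min:
        Minimum cluster homogeneity (mean member-vs-centroid Pearson r).
    min_size:
        Smallest cluster emitted; smaller groups stay in the pool.
    split_r:
        A homogeneous subtree is still split while its two children's
        centroids correlate below this value — i.e. while the children
        look like two distinct patterns rather than one.

    Every returned cluster satisfies ``homogeneity >= h_min`` and
    ``size >= min_size``.  Genes fitting no cluster land in the pool.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    std = standardize_profiles(profiles).sort_index(key=lambda ix: ix.astype(str))
    genes = list(std.index)
    arr = std.to_numpy(dtype=float)
    n = len(genes)
    clusters: list[list[int]] = []
    pool_idx: list[int] = []

    if n >= 2:
        Z = linkage(arr, method="average", metric="correlation")
        root = to_tree(Z)
        stack = [root]
        while stack:
            node = stack.pop()
            leaves = node.pre_order(lambda leaf: leaf.id)
            if len(leaves) < min_size:
                pool_idx.extend(leaves)
                continue
            # Accept the largest subtree that is homogeneous AND whose two
            # children share one pattern (centroid correlation >= split_r).
            # Without the child check, two distinct templates correlated at
            # ~0.5 merge into one "homogeneous" cluster at h_min = 0.85.
            accept = homogeneity(arr[leaves]) >= h_min
            if accept and not node.is_leaf():
                left = node.get_left().pre_order(lambda leaf: leaf.id)
                right = node.get_right().pre_order(lambda leaf: leaf.id)
                r_children = float(
                    np.corrcoef(_centroid(arr[left]), _centroid(arr[right]))[0, 1]
                )
                accept = r_children >= split_r
            if accept:
                clusters.append(sorted(leaves))
            else:
                stack.append(node.get_left())
                stack.append(node.get_right())
    else:
        pool_idx = list(range(n))

    # Adoption pass: pooled genes join the best-correlated cluster when
    # r >= h_min and the cluster's homogeneity survives.  Candidates are
    # processed in descending best-r order for determinism.
    member_sets = [set(c) for c in clusters]
    if clusters and pool_idx:
        centroids = [_centroid(arr[c]) for c in clusters]
        cand = []
        for gi in pool_idx:
            rs = [
                float(_pearson_to(arr[gi][None, :], cen)[0]) for cen in centroids
            ]
            best = int(np.argmax(rs))
            if rs[best] >= h_min:
                cand.append((-rs[best], genes[gi], gi, best))
        for _, _, gi, best in sorted(cand):
            trial = sorted(member_sets[best] | {gi})
            if homogeneity(arr[trial]) >= h_min:
                member_sets[best].add(gi)
        adopted = set().union(*member_sets) - set().union(*map(set, clusters))
        pool_idx = [gi for gi in pool_idx if gi not in adopted]

    # Order clusters by size descending, ties by first member id.
    finished = sorted(
        member_sets,
        key=lambda s: (-len(s), genes[min(s)]),
    )
    out_clusters = []
    for k, s in enumerate(finished, start=1):
        idx = sorted(s)
        rows = arr[idx]
        out_clusters.append(
            GeneCluster(
                id=f"C{k}",
                members=[genes[i] for i in idx],
                centroid=_centroid(rows),
                homogeneity=homogeneity(rows),
            )
        )
    return ClusterSet(
        clusters=out_clusters,
        pool=sorted(genes[i] for i in pool_idx),
        timepoints=pd.to_numeric(pd.Index(profiles.columns)).to_numpy(),
        profiles=std,
    )


def merge_similar_clusters(
    cs: ClusterSet, r_merge: float = 0.90, h_min: float = 0.85
) -> ClusterSet:
    """Group similarly patterned clusters by centroid correlation.

    Iteratively merges the pair with the highest centroid Pearson r while
    any pair reaches ``r_merge``.  Merged clusters get a compound id
    ("C2 + C5"); their homogeneity is recomputed and, when it falls below
    the original constraint, flagged via ``homogeneity_ok=False`` rather
    than rejected — grouping is a presentation step, not a re-clustering.
    """
    if not 0 < r_merge < 1:
        raise ValueError("r_merge must lie in (0, 1)")
    work = [
        GeneCluster(c.id, list(c.members), c.centroid.copy(), c.homogeneity,
                    c.direction, c.stage, c.homogeneity_ok)
        for c in cs.clusters
    ]
    arr = cs.profiles
    while len(work) > 1:
        best = None
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                r = float(np.corrcoef(work[i].centroid, work[j].centroid)[0, 1])
                if r >= r_merge and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = work[i], work[j]
        members = sorted(set(a.members) | set(b.members))
        rows = arr.loc[members].to_numpy()
        h = homogeneity(rows)
        merged = GeneCluster(
            id=f"{a.id} + {b.id}",
            members=members,
            centroid=_centroid(rows),
            homogeneity=h,
            direction=a.direction if a.direction == b.direction else None,
            # may legitimately fall below the clustering constraint after
            # grouping; flagged rather than dropped
            homogeneity_ok=h >= h_min,
        )
        work = [c for k, c in enumerate(work) if k not in (i, j)] + [merged]
    return ClusterSet(
        clusters=sorted(work, key=lambda c: (-len(c), c.members[0])),
        pool=list(cs.pool),
        timepoints=cs.timepoints,
        profiles=cs.profiles,
    )


def label_direction_and_stage(
    cs: ClusterSet, reference_timepoint: float | int | None = None
) -> ClusterSet:
    """Label clusters up/down versus a reference day and order into stages.

    A cluster is "up" when its centroid's mean over post-reference
    timepoints exceeds the centroid value at the reference timepoint,
    else "down".  Up clusters receive stage ranks 1..k by centroid argmax
    time (ties broken by the earliest crossing of the centroid's
    half-maximum); down clusters continue the ranking, ordered by argmin
    time.
    """
    t = np.asarray(cs.timepoints, dtype=float)
    ref = float(t[0]) if reference_timepoint is None else float(reference_timepoint)
    if ref not in set(t.tolist()):
        raise ValueError(f"reference timepoint {ref} not in {t.tolist()}")
    ref_i = int(np.where(t == ref)[0][0])
    post = t > ref

    def sort_key_up(c: GeneCluster):
        cen = c.centroid
        peak_t = float(t[int(np.argmax(cen))])
        half = cen.min() + 0.5 * (cen.max() - cen.min())
        above = np.where(cen >= half)[0]
        half_t = float(t[above[0]]) if len(above) else peak_t
        return (peak_t, half_t, c.id)

    def sort_key_down(c: GeneCluster):
        cen = c.centroid
        trough_t = float(t[int(np.argmin(cen))])
        return (trough_t, c.id)

    ups, downs = [], []
    for c in cs.clusters:
        up = bool(c.centroid[post].mean() > c.centroid[ref_i]) if post.any() \
            else bool(c.centroid[-1] > c.centroid[ref_i])
        c.direction = "up" if up else "down"
        (ups if up else downs).append(c)
    ordered = sorted(ups, key=sort_key_up) + sorted(downs, key=sort_key_down)
    for rank, c in enumerate(ordered, start=1):
        c.stage = rank
    return ClusterSet(
        clusters=ordered,
        pool=list(cs.pool),
        timepoints=cs.timepoints,
        profiles=cs.profiles,
    )
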