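"""Hypergeometric gene-set enrichment and table-driven classification.

Given a cluster of K genes inside a universe of N, and a target list
restricted to m universe genes, the overlap n is scored with the exact
upper tail P(X >= n) of the hypergeometric distribution — the chance of
drawing at least n list genes when K genes are sampled from the universe
without replacement.  The percentage reported alongside is 100*n/m, the
share of the target list captured by the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import GeneSet
from .clustering import GeneCluster


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) \
        - gammaln(np.asarray(n) - np.asarray(k) + 1)


def hypergeom_upper(n: int, K: int, m: int, N: int) -> float:
    """Exact upper tail P(X >= n), X ~ Hypergeometric(N, m, K).

    ``N`` universe size, ``m`` list size, ``K`` cluster (sample) size,
    ``n`` observed overlap.  Computed as a log-space sum of point masses
    C(m,k) C(N-m,K-k) / C(N,K) over k = n..min(K,m) for numerical
    stability at large N.
    """
    for name, v in (("n", n), ("K", K), ("m", m), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if m > N or K > N:
        raise ValueError("m and K must not exceed N")
    if n > min(K, m):
        raise ValueError(f"overlap n={n} exceeds min(K, m)={min(K, m)}")
    if n <= max(0, K + m - N):
        return 1.0
    ks = np.arange(n, min(K, m) + 1)
    log_terms = (
        _log_comb(m, ks) + _log_comb(N - m, K - ks) - _log_comb(N, K)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding used for displayed percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentRecord:
    """Overlap of one cluster with one target gene list."""

    cluster: str
    list_name: str
    universe_size: int     # N
    cluster_size: int      # K
    list_size: int         # m, after restriction to the universe
    overlap: int           # n
    percentage: float      # 100 * n / m (full precision)
    p: float               # P(X >= n)

    @property
    def percentage_display(self) -> float:
        return round_half_up(self.percentage, 1)


def list_representation(
    cluster: GeneCluster | set[str],
    gene_list: GeneSet,
    universe: set[str],
    *,
    cluster_name: str | None = None,
) -> EnrichmentRecord:
    """Score how much of a target list a cluster captures.

    The list is first restricted to the universe (genes never measured
    cannot be drawn); the overlap n with the cluster, the percentage
    100*n/m of the restricted list, and the hypergeometric upper-tail
    p-value are reported.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if isinstance(cluster, GeneCluster):
        members = set(cluster.members)
        cname = cluster_name or cluster.id
    else:
        members = set(cluster)
        cname = cluster_name or "cluster"
    members &= universe
    in_universe = set(gene_list.genes) & universe
    if not in_universe:
        raise ValueError(
            f"list {gene_list.name!r} shares no genes with the universe"
        )
    n = len(members & in_universe)
    m = len(in_universe)
    return EnrichmentRecord(
        cluster=cname,
        list_name=gene_list.name,
        universe_size=len(universe),
        cluster_size=len(members),
        list_size=m,
        overlap=n,
        percentage=100.0 * n / m,
        p=hypergeom_upper(n, len(members), m, len(universe)),
    )


def enrichment_table(
    clusters: list[GeneCluster],
    gene_lists: list[GeneSet],
    universe: set[str],
    *,
    correction: str = "bonferroni",
) -> "pd.DataFrame":
    """All (cluster x list) enrichment records with multiple-testing control.

    ``correction`` is "bonferroni" (default) or "bh" across the full
    cluster-by-list family.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    records = [
        list_representation(c, gl, universe)
        for c in clusters
        for gl in gene_lists
    ]
    df = pd.DataFrame(
        {
            "cluster": [r.cluster for r in records],
            "list": [r.list_name for r in records],
            "N": [r.universe_size for r in records],
            "K": [r.cluster_size for r in records],
            "m": [r.list_size for r in records],
            "n": [r.overlap for r in records],
            "percentage": [r.percentage_display for r in records],
            "p": [r.p for r in records],
        }
    )
    if len(df):
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
        df["q"] = multipletests(df["p"], method=method)[1]
    else:
        df["q"] = []
    return df


def classify_genes(
    genes: set[str] | list[str],
    class_table: dict[str, set[str] | list[str]] | "pd.DataFrame",
) -> dict[str, set[str]]:
    """Partition genes by functional class from a user-supplied table.

    ``class_table`` maps gene -> one or more class labels (a DataFrame
    with ``gene``/``class`` columns is also accepted).  A gene carrying
    several classes appears in each; genes absent from the table are
    returned under the key ``"unclassified"``.
    """
    import pandas as pd

    if isinstance(class_table, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for g, c in zip(class_table["gene"], class_table["class"]):
            mapping.setdefault(str(g), set()).add(str(c))
    else:
        mapping = {
            g: ({cs} if isinstance(cs, str) else set(cs))
            for g, cs in class_table.items()
        }
    out: dict[str, set[str]] = {}
    unclassified: set[str] = set()
    for g in set(genes):
        classes = mapping.get(g)
        if not classes:
            unclassified.add(g)
            continue
        for c in classes:
            out.setdefault(c, set()).add(g)
    out["unclassified"] = unclassified
    return out
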