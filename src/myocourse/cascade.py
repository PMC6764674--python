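"""Staged transcription-factor cascade inference.

Combines per-cluster motif enrichments with the cluster membership of
each motif's parent transcription factor.  A TF whose motif is
significantly enriched in the cluster it itself belongs to is a *self*
regulator; a TF sitting in the stage immediately before the enriched
cluster is a *next* regulator (an edge into the subsequent stage); a TF
with both kinds of evidence across the enrichment table is classed
*both*.  Motifs whose parent TF is in no cluster contribute nothing.

Dimer motifs named "A::B" resolve to both components unless an explicit
alias overrides the attribution (e.g. a bHLH dimer site attributed to a
different factor with a near-identical consensus).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd


@dataclass(frozen=True)
class CascadeEdge:
    tf: str
    home_stage: int
    target_stage: int
    cls: str                 # "self" | "next" | "both"
    motifs: tuple[str, ...]  # supporting motif ids

    def __post_init__(self) -> None:
        if self.cls == "self" and self.home_stage != self.target_stage:
            raise ValueError("self edge must stay within its stage")
        if self.cls == "next" and self.target_stage != self.home_stage + 1:
            raise ValueError("next edge must advance exactly one stage")
        if self.cls == "both" and self.target_stage not in (
            self.home_stage, self.home_stage + 1
        ):
            raise ValueError("both edges target home or home+1 only")


def resolve_parent_tf(
    motif_id: str, tf_name: str, aliases: dict[str, str] | None = None
) -> list[str]:
    """Gene symbol(s) a motif's evidence is attributed to.

    An alias entry (keyed by motif id) wins outright; otherwise a dimer
    name "A::B" resolves to both components and a plain name to itself.
    """
    aliases = aliases or {}
    if motif_id in aliases:
        return [aliases[motif_id]]
    if tf_name in aliases:
        return [aliases[tf_name]]
    if "::" in tf_name:
        return [part for part in tf_name.split("::") if part]
    return [tf_name]


def infer_cascade(
    enrichments: pd.DataFrame,
    cluster_set,
    aliases: dict[str, str] | None = None,
) -> list[CascadeEdge]:
    """Turn significant motif enrichments into staged cascade edges.

    ``enrichments`` is the tidy table from
    :func:`myocourse.motifs.cluster_motif_enrichment` (columns
    ``motif_id``, ``tf_name``, ``cluster``, ``z``, ``significant``);
    ``cluster_set`` must carry stage ranks and directions (see
    :func:`myocourse.clustering.label_direction_and_stage`).

    Rules, per significant (cluster, motif) row with parent TF g:

    * g in no cluster -> no edge;
    * g's home cluster is the enriched cluster -> *self* evidence;
    * the enriched cluster is up-direction and g's home stage is exactly
      one stage earlier -> *next* evidence;
    * a TF with self and next evidence anywhere in the table -> both its
      edges are re-classed *both*.

    Output is a deterministic, order-independent list sorted by
    (home stage, TF, target stage).
    """
    clusters = cluster_set.clusters
    stage_of_cluster = {c.id: c.stage for c in clusters}
    direction_of_cluster = {c.id: c.direction for c in clusters}
    if any(v is None for v in stage_of_cluster.values()):
        raise ValueError("clusters lack stage ranks; label stages first")
    stages = sorted(stage_of_cluster.values())
    if len(set(stages)) != len(stages):
        raise ValueError("inconsistent stage ranks (duplicates)")
    home: dict[str, int] = {}
    for c in clusters:
        for g in c.members:
            home[g] = c.stage

    sig = enrichments[enrichments["significant"]]
    # evidence[(tf, home, target)] -> set of motif ids
    evidence: dict[tuple[str, int, int], set[str]] = {}
    for row in sig.itertuples(index=False):
        target = stage_of_cluster.get(row.cluster)
        if target is None:
            raise ValueError(f"unknown cluster {row.cluster!r} in enrichment table")
        for g in resolve_parent_tf(row.motif_id, row.tf_name, aliases):
            h = home.get(g)
            if h is None:
                continue
            if h == target:
                evidence.setdefault((g, h, target), set()).add(row.motif_id)
            elif (
                h == target - 1
                and direction_of_cluster.get(row.cluster) == "up"
            ):
                evidence.setdefault((g, h, target), set()).add(row.motif_id)

    has_self = {tf for (tf, h, t) in evidence if h == t}
    has_next = {tf for (tf, h, t) in evidence if t == h + 1}
    edges = []
    for (tf, h, t), motifs in evidence.items():
        if tf in has_self and tf in has_next:
            cls = "both"
        elif h == t:
            cls = "self"
        else:
            cls = "next"
        edges.append(
            CascadeEdge(
                tf=tf,
                home_stage=h,
                target_stage=t,
                cls=cls,
                motifs=tuple(sorted(motifs)),
            )
        )
    edges.sort(key=lambda e: (e.home_stage, e.tf, e.target_stage))
    return edges


_DOT_COLOR = {"self": "red", "next": "blue", "both": "green"}


def export_cascade_dot(edges: list[CascadeEdge]) -> str:
    """Render edges as a DOT digraph, one node per (TF, stage)."""
    lines = ["digraph cascade {", "  rankdir=LR;"]
    stages = sorted({e.home_stage for e in edges} | {e.target_stage for e in edges})
    for s in stages:
        tfs = sorted({e.tf for e in edges if e.home_stage == s})
        lines.append(f'  subgraph cluster_stage{s} {{ label="stage {s}";')
        for tf in tfs:
            lines.append(f'    "{tf}@{s}";')
        lines.append("  }")
    for e in edges:
        lines.append(
            f'  "{e.tf}@{e.home_stage}" -> "stage{e.target_stage}_targets"'
            f' [color={_DOT_COLOR[e.cls]}, label="{e.cls}"];'
        )
    for s in sorted({e.target_stage for e in edges}):
        lines.append(f'  "stage{s}_targets" [shape=box, label="stage {s} genes"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_cascade_json(edges: list[CascadeEdge]) -> str:
    return json.dumps([asdict(e) for e in edges], indent=2) + "\n"


def import_cascade_json(text: str) -> list[CascadeEdge]:
    return [
        CascadeEdge(
            tf=d["tf"],
            home_stage=d["home_stage"],
            target_stage=d["target_stage"],
            cls=d["cls"],
            motifs=tuple(d["motifs"]),
        )
        for d in json.loads(text)
    ]
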