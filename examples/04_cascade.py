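"""Infer a staged transcription-factor cascade from motif enrichments.

Given per-cluster motif enrichments plus the cluster membership of each
motif's parent TF, the cascade rule emits an edge when a significant
motif's TF sits in the enriched cluster itself ("self"), in the stage
immediately before it ("next"), or shows both kinds of evidence
("both").  Dimer motifs can be re-attributed by an alias, mirroring the
manual attribution of a near-identical bHLH site to a different factor.
"""

import numpy as np
import pandas as pd

import myocourse as mc


def cluster(cid, members, stage):
    return mc.GeneCluster(id=cid, members=members, centroid=np.zeros(3),
                          homogeneity=1.0, direction="up", stage=stage)


cs = mc.ClusterSet(
    clusters=[
        cluster("K1", ["T", "MSGN1", "LEF1"], 1),     # mesoderm induction
        cluster("K2", ["PAX3", "MEOX1"], 2),          # somite / progenitors
        cluster("K3", ["MYOD1", "MYOG"], 3),          # myogenic commitment
    ],
    pool=[], timepoints=np.array([0.0, 1.0, 2.0]), profiles=None,
)

enrichments = pd.DataFrame([
    # motif_id,       tf_name,      cluster, z, significant
    {"motif_id": "mLEF1", "tf_name": "LEF1", "cluster": "K1",
     "z": 21.2, "significant": True},                   # self regulator
    {"motif_id": "mT", "tf_name": "T", "cluster": "K2",
     "z": 6.6, "significant": True},                    # feeds next stage
    {"motif_id": "TAL1::TCF3", "tf_name": "TAL1::TCF3", "cluster": "K1",
     "z": 10.1, "significant": True},                   # aliased dimer site
    {"motif_id": "mMYOD", "tf_name": "MYOD1", "cluster": "K3",
     "z": 12.5, "significant": True},
    {"motif_id": "mMYOD", "tf_name": "MYOD1", "cluster": "K2",
     "z": 2.0, "significant": False},                   # ignored: Z < 5
])

aliases = {"TAL1::TCF3": "MSGN1"}   # attribute the dimer site to MSGN1
edges = mc.infer_cascade(enrichments, cs, aliases)
for e in edges:
    print(f"{e.tf:7s} stage {e.home_stage} -> {e.target_stage}  "
          f"[{e.cls}]  via {', '.join(e.motifs)}")
# LEF1 and MSGN1 regulate genes of their own (earliest) cluster; T's
# motif enrichment one stage later makes it a stage-1 -> stage-2 driver.

print()
print(mc.export_cascade_dot(edges))
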