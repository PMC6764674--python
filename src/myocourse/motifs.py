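"""PWM promoter scanning and per-cluster motif over-representation.

Promoter windows (default +/-2000 bp around the TSS) are scanned on both
strands with position weight matrices under a log-odds score against a
0-order background.  A position is a hit when its *relative* score —
(score - min) / (max - min) over all possible words — reaches the
configured threshold (default 0.85).  When a per-base conservation track
is present, hits are kept only where the window's mean conservation
reaches the conservation cutoff (default 0.60).

Over-representation per (cluster, motif) is a continuity-corrected
normal approximation to the binomial on nucleotide-level hit rates:

    Z = (x - n * p - 0.5) / sqrt(n * p * (1 - p))

with x foreground hits over n foreground nucleotides and p the
background hit rate taken from all analyzed promoters outside the
cluster.  Z >= 5 marks a significantly enriched motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position frequency matrix over (A, C, G, T), columns summing to 1."""

    id: str
    tf_name: str
    matrix: np.ndarray          # shape (4, L)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if (self.matrix < 0).any():
            raise ValueError("PWM frequencies must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            id=self.id,
            tf_name=self.tf_name,
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
        )

    @classmethod
    def from_counts(
        cls, id: str, tf_name: str, counts: np.ndarray, pseudocount: float = 0.25
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("negative counts in PFM")
        freq = counts + pseudocount
        total = freq.sum(axis=0)
        if (total == 0).any():
            raise ValueError("all-zero column with zero pseudocount")
        return cls(id=id, tf_name=tf_name, matrix=freq / total,
                   pseudocount=pseudocount)


@dataclass
class PromoterRegion:
    """Sequence around one gene's TSS, optionally with conservation."""

    gene: str
    sequence: str
    conservation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid bases in promoter of {self.gene}: {bad}")
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)
            if len(self.conservation) != len(self.sequence):
                raise ValueError("conservation track length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifHit:
    gene: str
    motif_id: str
    start: int          # 0-based, forward-strand coordinates
    strand: str         # "+" | "-"
    score: float
    rel_score: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy().view(np.uint8)


_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _CODE.items():
    _LUT[ord(_b)] = _i


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N score -inf."""
    L = lo.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    lo_ext = np.vstack([lo, np.full((1, L), -np.inf)])
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lo_ext[codes[j:j + n_win], j]
    return scores


def _merge_hits(starts: np.ndarray, width: int) -> np.ndarray:
    """Greedy left-to-right merge: drop hits starting within ``width`` of
    the previously kept hit (prevents homopolymer double counting)."""
    kept = []
    last = -width
    for s in np.sort(starts):
        if s >= last + width:
            kept.append(s)
            last = s
    return np.asarray(kept, dtype=int)


def scan_pwm(
    region: PromoterRegion,
    pwm: PWM,
    rel_score_min: float = 0.85,
    conservation_min: float = 0.60,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """All PWM hits in a promoter on both strands.

    Scores are log2 odds against ``background`` (uniform 0.25 by
    default); the relative score normalizes into [0, 1] by the best and
    worst possible words.  N-containing windows never hit.  Overlapping
    same-strand hits within one motif width are merged to the leftmost.
    """
    if not 0 < rel_score_min <= 1:
        raise ValueError("rel_score_min must lie in (0, 1]")
    L = pwm.width
    if len(region) < L:
        raise ValueError(
            f"promoter of {region.gene} ({len(region)} nt) shorter than motif ({L} nt)"
        )
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 4 frequencies summing to 1")

    codes = _LUT[_encode(region.sequence)]
    cons = region.conservation
    if cons is not None:
        csum = np.concatenate([[0.0], np.cumsum(cons)])

    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm.matrix), ("-", pwm.reverse_complement().matrix)):
        with np.errstate(divide="ignore"):
            lo = np.log2(mat) - np.log2(bg[:, None])
        smin = np.where(np.isfinite(lo), lo, np.inf).min(axis=0).sum()
        smax = lo.max(axis=0).sum()
        span = smax - smin
        scores = _window_scores(codes, lo)
        if span <= 0:
            rel = np.where(np.isfinite(scores), 1.0, -np.inf)
        else:
            rel = (scores - smin) / span
        cand = np.where(rel >= rel_score_min)[0]
        if cons is not None and len(cand):
            mean_cons = (csum[cand + L] - csum[cand]) / L
            cand = cand[mean_cons >= conservation_min]
        for s in _merge_hits(cand, L):
            hits.append(
                MotifHit(
                    gene=region.gene,
                    motif_id=pwm.id,
                    start=int(s),
                    strand=strand,
                    score=float(scores[s]),
                    rel_score=float(rel[s]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def motif_zscore(x: int, n: int, bg_hits: int, bg_nt: int) -> float:
    """Continuity-corrected binomial Z for foreground motif hit excess.

    ``x`` foreground hits over ``n`` foreground nucleotides, against a
    background rate estimated as ``bg_hits / bg_nt``.
    """
    if n <= 0 or bg_nt <= 0:
        raise ValueError("scanned lengths must be positive")
    p_hat = bg_hits / bg_nt
    if p_hat <= 0 or p_hat >= 1:
        raise ValueError(f"degenerate background rate {p_hat}")
    return (x - n * p_hat - 0.5) / math.sqrt(n * p_hat * (1 - p_hat))


@dataclass
class MotifEnrichment:
    motif_id: str
    tf_name: str
    cluster: str
    fg_hits: int
    fg_nt: int
    bg_hits: int
    bg_nt: int
    z: float
    significant: bool


def count_hits_per_gene(
    promoters: dict[str, PromoterRegion],
    pwms: list[PWM],
    rel_score_min: float = 0.85,
    conservation_min: float = 0.60,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Hit counts per (motif, gene): rows = motif ids, columns = genes."""
    genes = sorted(promoters)
    counts = np.zeros((len(pwms), len(genes)), dtype=int)
    for gj, g in enumerate(genes):
        region = promoters[g]
        for mi, pwm in enumerate(pwms):
            counts[mi, gj] = len(
                scan_pwm(region, pwm, rel_score_min, conservation_min, background)
            )
    return pd.DataFrame(counts, index=[p.id for p in pwms], columns=genes)


def cluster_motif_enrichment(
    clusters,
    promoters: dict[str, PromoterRegion],
    pwms: list[PWM],
    *,
    rel_score_min: float = 0.85,
    conservation_min: float = 0.60,
    z_min: float = 5.0,
    background: np.ndarray | None = None,
    min_promoter_coverage: float = 0.8,
) -> pd.DataFrame:
    """Per-(cluster, motif) over-representation Z against out-of-cluster
    promoters.

    ``clusters`` is a ClusterSet or a list of GeneCluster.  For each
    cluster, foreground = member promoters, background = all analyzed
    promoters not in the cluster.  Motifs whose background rate is
    degenerate (zero hits anywhere outside) get Z = NaN, never
    significant.  Returns a tidy DataFrame sorted by (cluster, -Z).
    """
    import warnings

    cluster_list = getattr(clusters, "clusters", clusters)
    lengths = {g: len(r) for g, r in promoters.items()}
    total_nt = sum(lengths.values())
    hit_df = count_hits_per_gene(
        promoters, pwms, rel_score_min, conservation_min, background
    )
    total_hits = hit_df.sum(axis=1)
    tf_of = {p.id: p.tf_name for p in pwms}

    rows = []
    for c in cluster_list:
        members = [g for g in c.members if g in promoters]
        if not members:
            raise ValueError(f"cluster {c.id} has no promoter sequences")
        coverage = len(members) / len(c.members)
        if coverage < min_promoter_coverage:
            warnings.warn(
                f"cluster {c.id}: only {coverage:.0%} of members have promoters",
                stacklevel=2,
            )
        fg_nt = sum(lengths[g] for g in members)
        bg_nt = total_nt - fg_nt
        fg = hit_df[members].sum(axis=1)
        for motif_id in hit_df.index:
            x = int(fg[motif_id])
            bg_hits = int(total_hits[motif_id]) - x
            try:
                z = motif_zscore(x, fg_nt, bg_hits, bg_nt)
            except ValueError:
                z = float("nan")
            rows.append(
                MotifEnrichment(
                    motif_id=motif_id,
                    tf_name=tf_of[motif_id],
                    cluster=c.id,
                    fg_hits=x,
                    fg_nt=fg_nt,
                    bg_hits=bg_hits,
                    bg_nt=bg_nt,
                    z=z,
                    significant=bool(z >= z_min) if math.isfinite(z) else False,
                )
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values(
        ["cluster", "z"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
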