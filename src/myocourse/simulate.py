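"""Seeded synthetic data with known ground truth for every pipeline stage.

The generator emulates the design of a 50-day differentiation expression
time course profiled in triplicate at eight timepoints (24 arrays):
genes belong to planted temporal clusters (transient peaks, sigmoidal
rises and falls) on a log2 intensity scale with additive Gaussian noise,
probes drop out of detection independently, some genes carry multiple
probes, promoters carry planted PWM consensus occurrences enriched in
chosen clusters, target gene lists have designed overlaps with clusters,
and a partner dataset reproduces the planted fold changes at a tunable
correlation with a known quadrant truth.

Everything is driven by one integer seed; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FoldChangeTable, GeneSet, ProbeGeneMap
from .crossdata import OrthologMap
from .motifs import PWM, PromoterRegion

# ---------------------------------------------------------------------------
# temporal templates

def _sigmoid(t: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - midpoint) / steepness))


def _template_value(name: str, params: dict, t: np.ndarray) -> np.ndarray:
    """Unit-amplitude template curve over days ``t`` (values in [0, 1])."""
    if name == "flat":
        return np.zeros_like(t, dtype=float)
    if name == "sigmoid-up":
        return _sigmoid(t, params.get("midpoint", 25.0), params.get("steepness", 4.0))
    if name == "sigmoid-down":
        return 1.0 - _sigmoid(
            t, params.get("midpoint", 25.0), params.get("steepness", 4.0)
        )
    if name == "transient-peak":
        peak = params.get("peak", 2.0)
        width = params.get("width", 3.0)
        return np.exp(-((t - peak) ** 2) / (2.0 * width**2))
    raise ValueError(f"unknown template name {name!r}")


@dataclass(frozen=True)
class ClusterProfile:
    """One planted cluster: a named template with parameters."""

    name: str                     # cluster label, e.g. "primitive-streak"
    template: str                 # template function name
    params: dict = field(default_factory=dict)

    def curve(self, t: np.ndarray) -> np.ndarray:
        return _template_value(self.template, self.params, np.asarray(t, float))


#: Defaults emulate the staged progression of in vitro myogenesis:
#: an early transient mesoderm burst, a somite-stage bump, two
#: successively later sustained rises (progenitor commitment, terminal
#: differentiation) and two waves of down-regulation (pluripotency
#: collapse, proliferation taper).
DEFAULT_PROFILES = (
    ClusterProfile("primitive-streak", "transient-peak", {"peak": 3.0, "width": 1.2}),
    ClusterProfile("somite", "transient-peak", {"peak": 9.0, "width": 2.5}),
    ClusterProfile("dermomyotome", "sigmoid-up", {"midpoint": 5.0, "steepness": 2.0}),
    ClusterProfile("myotome", "sigmoid-up", {"midpoint": 40.0, "steepness": 3.0}),
    ClusterProfile("pluripotency", "sigmoid-down", {"midpoint": 2.5, "steepness": 1.2}),
    ClusterProfile("cell-cycle", "sigmoid-down", {"midpoint": 30.0, "steepness": 3.0}),
)


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults mirror the profiled design: 8 timepoints (days 0-50) x 3
    replicates = 24 arrays, log2-scale noise sd 0.3, a 5% detection
    dropout, mostly single-probe genes, and an 0.25/kb background motif
    occurrence rate.
    """

    n_genes: int = 300
    n_background_genes: int = 200
    timepoints: tuple[float, ...] = (0, 2, 4, 8, 25, 35, 45, 50)
    n_replicates: int = 3
    cluster_profiles: tuple[ClusterProfile, ...] = DEFAULT_PROFILES
    noise_sd: float = 0.3
    detection_dropout_rate: float = 0.05
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    baseline: float = 6.0          # log2 units
    amplitude: float = 3.0         # log2 units (8-fold swing)
    motif_planting: dict[tuple[str, str], float] = field(default_factory=dict)
    motif_background_rate: float = 0.25          # occurrences per kb
    gc_content: float = 0.5                      # uniform base composition
    with_conservation: bool = False
    partner_shared_fraction: float = 0.9
    partner_correlation: float = 0.8
    partner_unmapped_fraction: float = 0.1
    partner_sign_flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) < 2 or not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        for name in ("detection_dropout_rate", "partner_unmapped_fraction",
                     "partner_sign_flip_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.partner_shared_fraction <= 1:
            raise ValueError("partner_shared_fraction must lie in (0, 1]")
        if not -1 < self.partner_correlation < 1 and self.partner_correlation != 1:
            raise ValueError("partner_correlation must lie in (-1, 1]")
        if self.noise_sd < 0 or self.motif_background_rate < 0:
            raise ValueError("noise and rates must be nonnegative")
        probs = np.asarray(list(self.probes_per_gene.values()), float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("probes_per_gene must be a probability distribution")
        for cp in self.cluster_profiles:
            _template_value(cp.template, cp.params, t)  # validates name

    @property
    def n_samples(self) -> int:
        return len(self.timepoints) * self.n_replicates


@dataclass
class SynthTruth:
    """Everything the generator planted, for downstream verification."""

    gene_cluster: dict[str, str | None]            # None = background
    cluster_centroids: dict[str, np.ndarray]       # noiseless log2 curves
    planted_log2fc: dict[str, float]               # final vs first timepoint
    timepoints: tuple[float, ...]
    seed: int
    motif_cluster: dict[str, str] = field(default_factory=dict)
    partner_quadrant: dict[str, str] = field(default_factory=dict)
    partner_symbols: dict[str, str] = field(default_factory=dict)
    target_lists: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clusters = set(self.cluster_centroids)
        for g, c in self.gene_cluster.items():
            if c is not None and c not in clusters:
                raise ValueError(f"gene {g} assigned to unknown cluster {c}")

    @property
    def clustered_genes(self) -> list[str]:
        return sorted(g for g, c in self.gene_cluster.items() if c is not None)

    @property
    def background_genes(self) -> list[str]:
        return sorted(g for g, c in self.gene_cluster.items() if c is None)

    def partition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.cluster_centroids}
        for g, c in sorted(self.gene_cluster.items()):
            if c is not None:
                out[c].append(g)
        return out


# ---------------------------------------------------------------------------
# stage 1: expression time course

def simulate_timecourse(
    spec: SynthSpec,
) -> tuple[ExpressionMatrix, ProbeGeneMap, SynthTruth]:
    """Planted-cluster log2 expression matrix with flags and probe map.

    Clustered genes split evenly over the configured templates; each
    gene's noiseless profile is ``baseline + amplitude * template(day)``;
    every probe of a gene shares the gene profile with independent
    Gaussian noise; detection flags drop out independently per
    (probe, sample).
    """
    rng = np.random.default_rng([spec.seed, 1])
    t = np.asarray(spec.timepoints, dtype=float)
    k = len(spec.cluster_profiles)
    per = spec.n_genes // k
    if per == 0:
        raise ValueError(f"n_genes={spec.n_genes} too small for {k} clusters")

    gene_cluster: dict[str, str | None] = {}
    centroids: dict[str, np.ndarray] = {}
    gene_profiles: dict[str, np.ndarray] = {}
    gi = 0
    for cp in spec.cluster_profiles:
        curve = spec.baseline + spec.amplitude * cp.curve(t)
        centroids[cp.name] = curve
        n_here = per + (spec.n_genes % k if cp is spec.cluster_profiles[-1] else 0)
        for _ in range(n_here):
            g = f"G{gi:04d}"
            gene_cluster[g] = cp.name
            gene_profiles[g] = curve
            gi += 1
    for bi in range(spec.n_background_genes):
        g = f"B{bi:04d}"
        gene_cluster[g] = None
        level = spec.baseline + rng.uniform(-0.5, 3.5)
        gene_profiles[g] = np.full(len(t), level)

    genes = sorted(gene_profiles)
    counts = np.asarray(sorted(spec.probes_per_gene), dtype=int)
    probs = np.asarray([spec.probes_per_gene[c] for c in counts], dtype=float)
    n_probes_per_gene = rng.choice(counts, size=len(genes), p=probs)

    probe_ids: list[str] = []
    probe_gene: dict[str, str] = {}
    rows: list[np.ndarray] = []
    day_grid = np.repeat(t, spec.n_replicates)
    for g, np_g in zip(genes, n_probes_per_gene):
        profile = np.repeat(gene_profiles[g], spec.n_replicates)
        for pi in range(int(np_g)):
            pid = f"{g}_p{pi + 1}"
            probe_ids.append(pid)
            probe_gene[pid] = g
            noise = (rng.normal(0.0, spec.noise_sd, size=len(profile))
                     if spec.noise_sd > 0 else 0.0)
            rows.append(profile + noise)

    sample_ids = [
        f"d{day:g}_r{r + 1}" for day in t for r in range(spec.n_replicates)
    ]
    values = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=sample_ids)
    flags = pd.DataFrame(
        rng.random(values.shape) >= spec.detection_dropout_rate,
        index=values.index, columns=values.columns,
    )
    samples = pd.DataFrame(
        {
            "day": day_grid,
            "condition": "timecourse",
            "replicate": [r + 1 for _ in t for r in range(spec.n_replicates)],
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(values=values, flags=flags, samples=samples)
    planted_fc = {
        g: float(gene_profiles[g][-1] - gene_profiles[g][0]) for g in genes
    }
    truth = SynthTruth(
        gene_cluster=gene_cluster,
        cluster_centroids=centroids,
        planted_log2fc=planted_fc,
        timepoints=tuple(spec.timepoints),
        seed=spec.seed,
    )
    return matrix, ProbeGeneMap(probe_gene), truth


# ---------------------------------------------------------------------------
# stage 2: promoters with planted motif occurrences

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _insert_copies(
    rng: np.random.Generator, seq: list[str], word: str, n_copies: int,
    occupied: list[tuple[int, int]],
) -> list[int]:
    """Place ``n_copies`` of ``word`` at non-overlapping random positions."""
    L = len(word)
    length = len(seq)
    placed: list[int] = []
    attempts = 0
    while len(placed) < n_copies:
        attempts += 1
        if attempts > 200 * max(1, n_copies):
            raise ValueError(
                f"insertion overflow: cannot place {n_copies} copies of a "
                f"{L}-mer in {length} nt"
            )
        pos = int(rng.integers(0, length - L + 1))
        if any(pos < e and pos + L > s for s, e in occupied):
            continue
        seq[pos:pos + L] = list(word)
        occupied.append((pos, pos + L))
        placed.append(pos)
    return placed


def simulate_promoters(
    spec: SynthSpec,
    truth: SynthTruth,
    pwms: list[PWM],
    width: int = 2000,
) -> dict[str, PromoterRegion]:
    """Random promoters with planted PWM consensus occurrences.

    Every gene in the truth gets a ``2 * width`` random sequence.  For
    each planting entry ``(cluster, motif_id) -> fg_rate`` (occurrences
    per kb), genes of that cluster receive Poisson(fg_rate * kb) consensus
    copies and all other genes Poisson(background_rate * kb); motifs not
    planted anywhere occur at the background rate everywhere.  With
    ``spec.with_conservation`` the per-base track is 1.0 at insertions
    and Uniform(0, 1) elsewhere.
    """
    by_id = {p.id: p for p in pwms}
    for (cluster, motif_id), rate in spec.motif_planting.items():
        if motif_id not in by_id:
            raise ValueError(f"planted motif {motif_id!r} not among supplied PWMs")
        if cluster not in truth.cluster_centroids:
            raise ValueError(f"planted cluster {cluster!r} unknown")
        if rate < 0:
            raise ValueError("planting rates must be nonnegative")

    rng = np.random.default_rng([truth.seed, 2])
    length = 2 * width
    kb = length / 1000.0
    fg_rate = dict(spec.motif_planting)
    promoters: dict[str, PromoterRegion] = {}
    for g in sorted(truth.gene_cluster):
        cluster = truth.gene_cluster[g]
        seq = list(_random_sequence(rng, length, spec.gc_content))
        occupied: list[tuple[int, int]] = []
        inserted: list[tuple[int, int]] = []
        for pwm in pwms:
            rate = fg_rate.get((cluster, pwm.id), spec.motif_background_rate) \
                if cluster is not None else spec.motif_background_rate
            n_copies = int(rng.poisson(rate * kb))
            if n_copies:
                for pos in _insert_copies(
                    rng, seq, pwm.consensus(), n_copies, occupied
                ):
                    inserted.append((pos, pos + pwm.width))
        conservation = None
        if spec.with_conservation:
            conservation = rng.uniform(0.0, 1.0, size=length)
            for s, e in inserted:
                conservation[s:e] = 1.0
        promoters[g] = PromoterRegion(
            gene=g, sequence="".join(seq), conservation=conservation
        )
    for (cluster, motif_id) in spec.motif_planting:
        truth.motif_cluster[motif_id] = cluster
    return promoters


# ---------------------------------------------------------------------------
# stage 3: partner dataset with known quadrant truth

def simulate_partner_dataset(
    spec: SynthSpec,
    truth: SynthTruth,
    quadrant_fold: float = 4.0,
) -> tuple[FoldChangeTable, OrthologMap, SynthTruth]:
    """Partner fold-change table correlated with the planted fold changes.

    A ``partner_shared_fraction`` subset of genes appears in the partner
    dataset under rodent-style symbols (lower-cased, mapped back by the
    ortholog map).  Partner values are the planted reference fold changes
    times a sign pattern plus Gaussian noise scaled to hit
    ``partner_correlation``; a ``partner_unmapped_fraction`` of partner
    genes get species-specific symbols absent from the map.  Quadrant
    truth is recorded from the noiseless planted values at
    ``quadrant_fold``.
    """
    rng = np.random.default_rng([truth.seed, 3])
    genes = sorted(truth.gene_cluster)
    n_shared = max(1, int(round(spec.partner_shared_fraction * len(genes))))
    shared = sorted(rng.choice(genes, size=n_shared, replace=False).tolist())

    x = np.array([truth.planted_log2fc[g] for g in shared])
    signs = np.ones(len(shared))
    n_flip = int(round(spec.partner_sign_flip_fraction * len(shared)))
    if n_flip:
        flip_idx = rng.choice(len(shared), size=n_flip, replace=False)
        signs[flip_idx] = -1.0
    y_planted = x * signs

    r = spec.partner_correlation
    sd_y = float(np.std(y_planted))
    if r == 1 or sd_y == 0:
        noise_sd = 0.0
    else:
        noise_sd = sd_y * np.sqrt(1.0 / r**2 - 1.0)
    y = y_planted + (rng.normal(0.0, noise_sd, size=len(shared))
                     if noise_sd > 0 else 0.0)

    c = np.log2(quadrant_fold)
    quad = np.full(len(shared), "NS", dtype=object)
    quad[(x >= c) & (y_planted >= c)] = "I"
    quad[(x >= c) & (y_planted <= -c)] = "II"
    quad[(x <= -c) & (y_planted <= -c)] = "III"
    quad[(x <= -c) & (y_planted >= c)] = "IV"

    n_unmapped = int(round(spec.partner_unmapped_fraction * len(shared)))
    unmapped_idx = set(
        rng.choice(len(shared), size=n_unmapped, replace=False).tolist()
    ) if n_unmapped else set()

    mapping: dict[str, str] = {}
    unmapped: set[str] = set()
    partner_symbols: dict[str, str] = {}
    rows = {}
    for i, g in enumerate(shared):
        if i in unmapped_idx:
            sym = f"{g.lower()}rik"       # species-specific, no ortholog
            unmapped.add(sym)
        else:
            sym = g.lower()
            mapping[sym] = g
        partner_symbols[g] = sym
        rows[sym] = y[i]
        truth.partner_quadrant[g] = str(quad[i])
    truth.partner_symbols = partner_symbols

    fc = FoldChangeTable(
        replicates=pd.DataFrame({"fc": pd.Series(rows)}),
        reference="partner-reference",
    )
    return fc, OrthologMap(mapping=mapping, unmapped=unmapped), truth


# ---------------------------------------------------------------------------
# stage 4: target lists with designed cluster overlaps

def simulate_target_lists(
    truth: SynthTruth,
    overlap_design: dict[str, dict[str, int]],
    list_sizes: dict[str, int] | None = None,
) -> list[GeneSet]:
    """Gene lists with exact designed overlaps against planted clusters.

    ``overlap_design`` maps list name -> {cluster name -> overlap count};
    the remainder up to ``list_sizes`` (default: overlaps + 20) is drawn
    from background genes, so overlap with every cluster is exactly as
    designed.
    """
    rng = np.random.default_rng([truth.seed, 4])
    partition = truth.partition()
    background = truth.background_genes
    out = []
    for name in sorted(overlap_design):
        design = overlap_design[name]
        members: list[str] = []
        for cluster in sorted(design):
            want = design[cluster]
            if cluster not in partition:
                raise ValueError(f"unknown cluster {cluster!r} in design")
            avail = partition[cluster]
            if want > len(avail):
                raise ValueError(
                    f"infeasible design: {want} > cluster {cluster} size {len(avail)}"
                )
            if want:
                members += rng.choice(avail, size=want, replace=False).tolist()
        size = (list_sizes or {}).get(name, len(members) + 20)
        n_bg = size - len(members)
        if n_bg < 0:
            raise ValueError(f"list size {size} below designed overlaps")
        if n_bg > len(background):
            raise ValueError(
                f"infeasible design: need {n_bg} background genes, "
                f"have {len(background)}"
            )
        if n_bg:
            members += rng.choice(background, size=n_bg, replace=False).tolist()
        gs = GeneSet(name=name, description="synthetic target list",
                     genes=frozenset(members))
        truth.target_lists[name] = gs.genes
        out.append(gs)
    return out


def truth_to_dict(truth: SynthTruth) -> dict:
    """JSON-serializable view of the planted truth."""
    return {
        "gene_cluster": truth.gene_cluster,
        "cluster_centroids": {
            c: list(map(float, v)) for c, v in truth.cluster_centroids.items()
        },
        "planted_log2fc": truth.planted_log2fc,
        "timepoints": list(truth.timepoints),
        "seed": truth.seed,
        "motif_cluster": truth.motif_cluster,
        "partner_quadrant": truth.partner_quadrant,
        "partner_symbols": truth.partner_symbols,
        "target_lists": {k: sorted(v) for k, v in truth.target_lists.items()},
    }
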