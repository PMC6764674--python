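"""Readers and writers for the pipeline's standard file formats.

Tabular data travels as TSV (expression values, detection flags, sample
metadata, fold changes, ortholog maps), gene sets as GMT, motifs as
JASPAR-text PFM, promoters as FASTA (one record per gene, optional
per-base conservation as a parallel TSV), and nested results (cascade,
planted truth) as JSON.  All writers round-trip with their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionMatrix, FoldChangeTable, GeneSet, ProbeGeneMap
from .crossdata import OrthologMap
from .motifs import PWM, PromoterRegion

# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(
    values_path: str | Path,
    metadata_path: str | Path,
    flags_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a probe x sample log2 matrix with metadata and optional flags.

    The value file has a header row of sample ids and rows keyed by probe
    id; the metadata file maps sample id -> (day, condition, replicate);
    the optional flag file is a congruent 0/1 matrix.  Missing flag file
    means every probe counts as detected.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dups[:5]}")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from exc
    samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = set(values.columns) - set(samples.index)
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)}")
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0).astype(bool)
        if (list(flags.index) != list(values.index)
                or list(flags.columns) != list(values.columns)):
            raise ValueError("flag matrix not congruent with value matrix")
    return ExpressionMatrix(values=values, flags=flags,
                            samples=samples.loc[list(values.columns)])


def write_expression_tsv(
    m: ExpressionMatrix,
    values_path: str | Path,
    metadata_path: str | Path,
    flags_path: str | Path | None = None,
    float_format: str = "%.6f",
) -> None:
    m.values.to_csv(values_path, sep="\t", float_format=float_format,
                    index_label="probe")
    m.samples.to_csv(metadata_path, sep="\t", index_label="sample")
    if flags_path is not None:
        m.flags.astype(int).to_csv(flags_path, sep="\t", index_label="probe")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: name, description, then tab-separated gene symbols.

    Duplicate genes within a set collapse; duplicate set names are an
    error; lines with fewer than three fields are rejected.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name=name, description=desc,
                                genes=frozenset(g for g in genes if g)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# JASPAR-text PFMs


def read_jaspar_pfm(
    path: str | Path,
    pseudocount: float = 0.25,
    alias_map: dict[str, str] | None = None,
) -> list[PWM]:
    """JASPAR text: ">ID NAME" then four A/C/G/T count rows of equal length.

    Counts become frequencies after adding ``pseudocount`` to every cell;
    the header NAME is the parent-TF symbol unless overridden by
    ``alias_map`` (keyed by motif id).
    """
    pwms: list[PWM] = []
    header: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {header!r}: expected 4 rows, got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"motif {header!r}: unequal row lengths {widths}")
        parts = header.split(None, 1)
        motif_id = parts[0]
        name = parts[1].strip() if len(parts) > 1 else motif_id
        if alias_map and motif_id in alias_map:
            name = alias_map[motif_id]
        pwms.append(
            PWM.from_counts(motif_id, name, np.asarray(rows), pseudocount)
        )
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
            else:
                cleaned = line.split(":", 1)[-1] if ":" in line else line
                cleaned = cleaned.strip().lstrip("ACGT").strip()
                cleaned = cleaned.strip("[]")
                rows.append([float(x) for x in cleaned.split()])
    flush()
    return pwms


def write_jaspar_pfm(pwms: list[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR text with pseudo-counts scaled to integers."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.tf_name}\n")
            counts = np.round(p.matrix * scale).astype(int)
            for base, row in zip("ACGT", counts):
                fh.write(f"{base} [ " + " ".join(map(str, row)) + " ]\n")


# ---------------------------------------------------------------------------
# promoters (FASTA + conservation TSV)


def read_promoters_fasta(
    path: str | Path, conservation_path: str | Path | None = None
) -> dict[str, PromoterRegion]:
    cons: dict[str, np.ndarray] = {}
    if conservation_path is not None:
        df = pd.read_csv(conservation_path, sep="\t")
        for gene, grp in df.groupby("gene"):
            cons[str(gene)] = grp.sort_values("position")["conservation"].to_numpy()
    out: dict[str, PromoterRegion] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = PromoterRegion(
            gene=rec.id, sequence=str(rec.seq), conservation=cons.get(rec.id)
        )
    return out


def write_promoters_fasta(
    promoters: dict[str, PromoterRegion],
    path: str | Path,
    conservation_path: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=g, description="")
        for g, p in sorted(promoters.items())
    ]
    SeqIO.write(records, str(path), "fasta")
    if conservation_path is not None:
        rows = []
        for g, p in sorted(promoters.items()):
            if p.conservation is None:
                continue
            rows.append(pd.DataFrame({
                "gene": g,
                "position": np.arange(len(p.conservation)),
                "conservation": p.conservation,
            }))
        frame = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=["gene", "position", "conservation"]))
        frame.to_csv(conservation_path, sep="\t", index=False,
                     float_format="%.4f")


# ---------------------------------------------------------------------------
# fold changes, probe maps, ortholog maps, truth


def write_foldchange_tsv(fc: FoldChangeTable, path: str | Path) -> None:
    fc.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="id")


def read_foldchange_tsv(path: str | Path, reference: str = "reference"
                        ) -> FoldChangeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    reps = df.drop(columns=["mean_log2fc"], errors="ignore")
    return FoldChangeTable(replicates=reps, reference=reference)


def write_probe_map_tsv(pg: ProbeGeneMap, path: str | Path) -> None:
    pg.to_frame().to_csv(path, sep="\t", index=False)


def read_probe_map_tsv(path: str | Path) -> ProbeGeneMap:
    return ProbeGeneMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_ortholog_map_tsv(om: OrthologMap, path: str | Path) -> None:
    rows = [{"partner": k, "reference": v} for k, v in sorted(om.mapping.items())]
    rows += [{"partner": k, "reference": ""} for k in sorted(om.unmapped)]
    pd.DataFrame(rows, columns=["partner", "reference"]).to_csv(
        path, sep="\t", index=False
    )


def read_ortholog_map_tsv(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    mapping = {
        r.partner: r.reference for r in df.itertuples() if r.reference
    }
    unmapped = {r.partner for r in df.itertuples() if not r.reference}
    return OrthologMap(mapping=mapping, unmapped=unmapped)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
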