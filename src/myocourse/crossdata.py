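"""Cross-dataset fold-change comparison: pairing, quadrants, correlation.

Gene-level mean log2 fold changes from two studies are paired by gene
symbol (an explicit ortholog map wins over case folding; partner-only
genes with no counterpart are excluded and counted), plotted against
each other, and split into four quadrants at a fold cutoff c (default
4-fold, i.e. |log2FC| >= 2):

    I   x >= c  and y >= c     (up in both)
    II  x >= c  and y <= -c    (up in reference, down in partner)
    III x <= -c and y <= -c    (down in both)
    IV  x <= -c and y >= c     (down in reference, up in partner)
    NS  otherwise

Named genes may be force-assigned to a quadrant (flagged, with a
provenance note) — mirroring disclosed judgment calls for key genes
that narrowly miss the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FoldChangeTable

QUADRANTS = ("I", "II", "III", "IV")


@dataclass
class OrthologMap:
    """partner symbol -> reference symbol; a function, not a relation."""

    mapping: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def resolve(self, partner_symbol: str) -> str | None:
        if partner_symbol in self.mapping:
            return self.mapping[partner_symbol]
        if partner_symbol in self.unmapped:
            return None
        return None


@dataclass
class PairingResult:
    table: pd.DataFrame          # index gene, columns x, y
    n_paired: int
    n_excluded: int              # partner genes without a counterpart
    n_duplicates: int            # partner symbols collapsing onto one reference


def pair_genes(
    ref_fc: FoldChangeTable | pd.Series,
    partner_fc: FoldChangeTable | pd.Series,
    ortholog_map: OrthologMap | None = None,
    *,
    case_fold: bool = True,
) -> PairingResult:
    """Pair gene-level fold changes between two datasets by symbol.

    Both inputs must already be probe-collapsed to one row per gene
    (mean log2FC is used).  Partner symbols are resolved through the
    ortholog map first; unresolved symbols fall back to uppercasing when
    ``case_fold`` is True.  Partner genes with no counterpart in the
    reference are excluded and counted.  If several partner symbols land
    on one reference symbol, the one with the greatest |log2FC| is kept
    and the collision counted.
    """
    x = ref_fc.mean if isinstance(ref_fc, FoldChangeTable) else ref_fc
    y = partner_fc.mean if isinstance(partner_fc, FoldChangeTable) else partner_fc
    mapping = ortholog_map.mapping if ortholog_map else {}

    resolved: list[tuple[str, str, float]] = []
    n_excluded = 0
    ref_index = set(map(str, x.index))
    for sym, val in y.items():
        sym = str(sym)
        target = mapping.get(sym)
        if target is None and case_fold:
            cand = sym.upper()
            target = cand if cand in ref_index else None
        if target is None or target not in ref_index:
            n_excluded += 1
            continue
        resolved.append((target, sym, float(val)))

    if not resolved:
        return PairingResult(
            pd.DataFrame(columns=["x", "y"]), 0, n_excluded, 0
        )
    df = pd.DataFrame(resolved, columns=["gene", "partner_symbol", "y"])
    n_dup = int(df["gene"].duplicated().sum())
    df["absy"] = df["y"].abs()
    df = (
        df.sort_values(["gene", "absy", "partner_symbol"],
                       ascending=[True, False, True], kind="mergesort")
        .drop_duplicates("gene", keep="first")
        .set_index("gene")
    )
    out = pd.DataFrame(
        {"x": x.loc[df.index].astype(float), "y": df["y"]}
    )
    return PairingResult(out, len(out), n_excluded, n_dup)


def quadrant_assign(
    paired: pd.DataFrame,
    fold_cutoff: float = 4.0,
    force_list: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign each paired gene a quadrant at the given fold cutoff.

    Thresholds are inclusive (a gene at exactly the cutoff is assigned).
    ``force_list`` maps gene -> quadrant for disclosed manual inclusions;
    forced rows carry ``forced=True``.  Returns the paired table with
    ``quadrant`` and ``forced`` columns.
    """
    if fold_cutoff <= 1:
        raise ValueError("fold cutoff must exceed 1 (linear fold)")
    c = math.log2(fold_cutoff)
    x = paired["x"].to_numpy(dtype=float)
    y = paired["y"].to_numpy(dtype=float)
    quad = np.full(len(paired), "NS", dtype=object)
    quad[(x >= c) & (y >= c)] = "I"
    quad[(x >= c) & (y <= -c)] = "II"
    quad[(x <= -c) & (y <= -c)] = "III"
    quad[(x <= -c) & (y >= c)] = "IV"
    out = paired.copy()
    out["quadrant"] = quad
    out["forced"] = False
    for gene, q in (force_list or {}).items():
        if q not in QUADRANTS:
            raise ValueError(f"forced quadrant must be one of {QUADRANTS}, got {q!r}")
        if gene in out.index:
            out.loc[gene, "quadrant"] = q
            out.loc[gene, "forced"] = True
    return out


def fc_correlation(paired: pd.DataFrame) -> float:
    """Pearson correlation of mean log2 fold changes over all paired genes."""
    if len(paired) < 3:
        raise ValueError("need at least 3 paired genes")
    x = paired["x"].to_numpy(dtype=float)
    y = paired["y"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance on one axis")
    return float(np.corrcoef(x, y)[0, 1])


def select_highconfidence(
    diff_results: pd.DataFrame,
    fold_cutoff: float = 8.0,
    q_max: float = 0.01,
) -> list[str]:
    """Strongly changed, strongly significant genes (|FC| >= cutoff,
    BH-adjusted q <= q_max).  Inclusive on the fold boundary."""
    if fold_cutoff <= 1:
        raise ValueError("fold cutoff must exceed 1")
    c = math.log2(fold_cutoff)
    keep = (diff_results["log2fc"].abs() >= c) & (diff_results["q"] <= q_max)
    return sorted(diff_results.index[keep.fillna(False)])
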