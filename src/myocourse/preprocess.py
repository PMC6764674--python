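"""Probe filtering, quantile normalization, fold changes and probe collapse.

The stages here mirror a standard two-colour-free microarray workflow:
probes not detected above background in enough samples are dropped, log2
intensities are quantile normalized so that every array shares one
empirical distribution, fold changes are taken against the mean of a
reference sample group (e.g. undifferentiated day 0 triplicates), and
multi-probe genes are collapsed to the probe with the greatest absolute
mean fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FoldChangeTable, ProbeGeneMap


def filter_detected(m: ExpressionMatrix, min_samples: int) -> ExpressionMatrix:
    """Keep probes detected above background in >= ``min_samples`` samples.

    The boundary is inclusive: a probe detected in exactly ``min_samples``
    samples survives.  Probe order is preserved; an empty result is legal.
    """
    if min_samples > m.values.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {m.values.shape[1]}"
        )
    counts = m.flags.sum(axis=1)
    keep = m.probes[counts >= min_samples]
    return m.subset_probes(keep)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's values are replaced by the across-column mean of sorted
    vectors, looked up at the value's within-column rank.  Ties receive the
    mean of the corresponding sorted-mean entries (average ranks,
    interpolated), which keeps the transform idempotent and rank
    preserving.
    """
    vals = m.values
    if vals.isna().any().any():
        raise ValueError("missing values present; impute or drop before normalizing")
    arr = vals.to_numpy(dtype=float)
    n = arr.shape[0]
    if n == 0:
        return m
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    ranks = vals.rank(axis=0, method="average").to_numpy()  # 1..n, may be x.5
    grid = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, sorted_means)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        flags=m.flags.copy(),
        samples=m.samples.copy(),
    )


def log2fc_vs_reference(
    m: ExpressionMatrix,
    reference: list[str] | np.ndarray,
    *,
    reference_name: str = "reference",
    drop_reference: bool = False,
) -> FoldChangeTable:
    """Per-replicate log2 fold change versus the mean of reference samples.

    ``reference`` is a list of sample ids (or a boolean mask over samples).
    Each sample's log2 value minus the reference mean; reference samples
    therefore average to a fold change of zero by construction and may be
    excluded from the output with ``drop_reference=True``.
    """
    cols = list(m.values.columns)
    if np.asarray(reference).dtype == bool:
        ref_ids = [c for c, keep in zip(cols, reference) if keep]
    else:
        ref_ids = list(reference)
    if not ref_ids:
        raise ValueError("empty reference selection")
    unknown = set(ref_ids) - set(cols)
    if unknown:
        raise ValueError(f"reference samples not in matrix: {sorted(unknown)}")
    ref_mean = m.values[ref_ids].mean(axis=1)
    fc = m.values.sub(ref_mean, axis=0)
    if drop_reference:
        fc = fc[[c for c in cols if c not in set(ref_ids)]]
    return FoldChangeTable(replicates=fc, reference=reference_name)


def collapse_to_genes(
    fc: FoldChangeTable, pg_map: ProbeGeneMap
) -> FoldChangeTable:
    """Collapse multi-probe genes to the probe with greatest |mean log2FC|.

    Ties are broken by the lexicographically smallest probe id, which makes
    the collapse deterministic and independent of row order.  Probes absent
    from the map are dropped with a warning.  Idempotent on gene-keyed
    tables when the map sends each gene symbol to itself.
    """
    df = fc.replicates
    genes = pd.Series(
        {p: pg_map.gene_of(p) for p in df.index}, name="gene"
    )
    unmapped = genes.index[genes.isna()]
    if len(unmapped):
        warnings.warn(
            f"{len(unmapped)} probes without gene mapping dropped",
            stacklevel=2,
        )
    mapped = genes.dropna()
    sub = df.loc[mapped.index]
    absfc = sub.mean(axis=1).abs()
    pick = (
        pd.DataFrame({"gene": mapped, "absfc": absfc, "probe": mapped.index})
        .sort_values(["gene", "absfc", "probe"],
                     ascending=[True, False, True],
                     kind="mergesort")
        .drop_duplicates("gene", keep="first")
    )
    out = sub.loc[pick["probe"]]
    out.index = pd.Index(pick["gene"].to_numpy(), name="gene")
    return FoldChangeTable(replicates=out.sort_index(), reference=fc.reference)


def variation_filter(
    m: ExpressionMatrix, range_min: float, expr_floor: float
) -> pd.Index:
    """Probes with (max - min) >= ``range_min`` and max >= ``expr_floor``.

    Both boundaries inclusive.  Returns the surviving probe index in input
    order; monotone in both thresholds (stricter values give subsets).
    """
    vmax = m.values.max(axis=1)
    vmin = m.values.min(axis=1)
    keep = (vmax - vmin >= range_min) & (vmax >= expr_floor)
    return m.probes[keep]


def coexpression_neighbors(
    m: ExpressionMatrix, gene: str, r_min: float
) -> pd.Series:
    """Genes whose profiles correlate with ``gene`` at Pearson r >= r_min.

    Correlation is computed across all samples.  The query correlates with
    itself at r = 1 and is always included.  Returns a Series of r values
    sorted descending (ties broken by row id for determinism).
    """
    if gene not in m.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    if m.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    query = m.values.loc[gene].to_numpy(dtype=float)
    if np.std(query) == 0:
        raise ValueError(f"query profile {gene!r} has zero variance")
    arr = m.values.to_numpy(dtype=float)
    q = (query - query.mean()) / query.std()
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (z * q).mean(axis=1)
    r[sd == 0] = np.nan
    out = pd.Series(r, index=m.values.index, name="r").dropna()
    out = out[out >= r_min]
    order = pd.DataFrame({"r": out, "id": out.index.astype(str)})
    order = order.sort_values(["r", "id"], ascending=[False, True],
                              kind="mergesort")
    return order["r"]
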