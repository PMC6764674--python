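"""Two-sample t-test differential expression with BH correction.

Mirrors the classical microarray workflow: probes are pre-filtered on
fold change and expression level, a pooled-variance two-sample t-test is
applied per probe, and Benjamini-Hochberg correction is computed over
the tested (pre-filtered) family.  A probe "passes" only if it clears
the p-value, FDR, fold-change and expression-floor thresholds together.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .containers import ExpressionMatrix


def ttest_contrast(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    cfg: AnalysisConfig,
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-probe two-sided t-test of group A versus group B (log2 data).

    Probes are pre-filtered to those with |mean log2FC| >= log2(fc_min)
    and max log2 expression >= expr_floor in at least one sample of the
    contrast; BH correction runs across that filtered family.  Fold
    change is mean(A) - mean(B) on the log2 scale.

    Probes with zero variance in both groups are flagged ``degenerate``:
    p is set to 0 when the means differ and 1 otherwise.

    Returns a DataFrame indexed by probe with columns ``mean_a``,
    ``mean_b``, ``log2fc``, ``t``, ``p``, ``q``, ``pass``, ``degenerate``.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 replicates, got {len(grp)}")
    a = m.values[list(group_a)].to_numpy(dtype=float)
    b = m.values[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b
    vmax = np.maximum(a.max(axis=1), b.max(axis=1))

    tested = (np.abs(log2fc) >= cfg.log2_fc_min) & (vmax >= cfg.expr_floor)
    idx = np.where(tested)[0]

    t_stat = np.full(len(log2fc), np.nan)
    p = np.full(len(log2fc), np.nan)
    q = np.full(len(log2fc), np.nan)
    degenerate = np.zeros(len(log2fc), dtype=bool)
    if len(idx):
        aa, bb = a[idx], b[idx]
        var0 = (aa.std(axis=1) == 0) & (bb.std(axis=1) == 0)
        res = stats.ttest_ind(aa, bb, axis=1, equal_var=not welch)
        t_stat[idx] = res.statistic
        p_idx = res.pvalue.copy()
        if var0.any():
            same = np.isclose(aa.mean(axis=1), bb.mean(axis=1))
            p_idx[var0] = np.where(same[var0], 1.0, 0.0)
            t_stat[idx[var0]] = np.where(same[var0], 0.0, np.inf)
            degenerate[idx[var0]] = True
        p[idx] = p_idx
        q[idx] = multipletests(p_idx, method="fdr_bh")[1]

    passed = (
        tested
        & (p <= cfg.p_max)
        & (q <= cfg.fdr_max)
    )
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t": t_stat,
            "p": p,
            "q": q,
            "pass": passed,
            "degenerate": degenerate,
        },
        index=m.probes,
    )
    out.index.name = "probe"
    return out


def up_down_sets(result: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split passing probes by the sign of mean log2 fold change."""
    passing = result[result["pass"]]
    up = set(passing.index[passing["log2fc"] > 0])
    down = set(passing.index[passing["log2fc"] < 0])
    return up, down


def set_overlap(
    up_a: set[str], up_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Shared and condition-unique probes between two significant sets.

    Returns ``(shared, unique_a, unique_b)`` — the Venn decomposition used
    to compare, e.g., high- versus low-induction day-2 up-regulated
    probes.
    """
    up_a, up_b = set(up_a), set(up_b)
    return up_a & up_b, up_a - up_b, up_b - up_a
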