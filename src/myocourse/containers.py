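"""Core in-memory containers for the pipeline.

The canonical expression container is a probe x sample matrix of log2
intensities backed by :class:`pandas.DataFrame`, with a congruent boolean
detection-flag matrix and per-sample metadata (day, condition, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("day", "condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Probe-level log2 expression with detection flags and sample metadata.

    Attributes
    ----------
    values:
        DataFrame of log2 intensities, index = probe ids, columns = sample
        ids (unique).
    flags:
        Boolean DataFrame congruent with ``values``; True where the probe
        was detected above background in that sample.
    samples:
        DataFrame indexed by sample id with columns ``day`` (numeric, >= 0),
        ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if (self.values.shape != self.flags.shape
                or list(self.values.index) != list(self.flags.index)
                or list(self.values.columns) != list(self.flags.columns)):
            raise ValueError("value and flag matrices must be congruent")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(
                f"samples missing metadata: {sorted(missing)}"
            )
        self.samples = self.samples.loc[list(self.values.columns)]
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        if (pd.to_numeric(self.samples["day"]) < 0).any():
            raise ValueError("days must be nonnegative")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def days(self) -> np.ndarray:
        return pd.to_numeric(self.samples["day"]).to_numpy()

    def subset_probes(self, probes) -> "ExpressionMatrix":
        probes = list(probes)
        return ExpressionMatrix(
            values=self.values.loc[probes].copy(),
            flags=self.flags.loc[probes].copy(),
            samples=self.samples.copy(),
        )

    def select_samples(self, mask) -> "ExpressionMatrix":
        cols = self.values.columns[np.asarray(mask, dtype=bool)]
        return ExpressionMatrix(
            values=self.values[cols].copy(),
            flags=self.flags[cols].copy(),
            samples=self.samples.loc[cols].copy(),
        )

    def samples_where(self, *, day=None, condition=None) -> list[str]:
        """Sample ids matching the given day and/or condition."""
        keep = pd.Series(True, index=self.samples.index)
        if day is not None:
            keep &= pd.to_numeric(self.samples["day"]) == day
        if condition is not None:
            keep &= self.samples["condition"] == condition
        return list(self.samples.index[keep])

    def mean_profile_by_day(self) -> pd.DataFrame:
        """Per-probe mean over replicates at each day (columns sorted by day)."""
        days = pd.to_numeric(self.samples["day"])
        grouped = self.values.T.groupby(days.values).mean().T
        return grouped[sorted(grouped.columns)]


@dataclass
class ProbeGeneMap:
    """Many-probes-to-one-gene mapping; each probe appears at most once."""

    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        # dict keys are unique by construction; validate types only
        for p, g in self.probe_to_gene.items():
            if not isinstance(p, str) or not isinstance(g, str):
                raise ValueError("probe and gene ids must be strings")

    def gene_of(self, probe: str) -> str | None:
        return self.probe_to_gene.get(probe)

    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.probe_to_gene.items()), columns=["probe", "gene"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeGeneMap":
        if df["probe"].duplicated().any():
            dups = df.loc[df["probe"].duplicated(), "probe"].tolist()
            raise ValueError(f"duplicate probe ids in map: {dups[:5]}")
        return cls(dict(zip(df["probe"], df["gene"])))


@dataclass
class FoldChangeTable:
    """Per-row log2 fold changes versus a named reference condition.

    ``replicates`` holds one column per non-reference replicate sample
    (log2 value minus the reference mean); ``mean`` is their arithmetic
    mean per row.  Rows may be keyed by probe or by gene (after probe
    collapse).
    """

    replicates: pd.DataFrame
    reference: str = "reference"

    def __post_init__(self) -> None:
        if not self.replicates.index.is_unique:
            raise ValueError("fold-change row keys must be unique")

    @property
    def mean(self) -> pd.Series:
        return self.replicates.mean(axis=1)

    @property
    def index(self) -> pd.Index:
        return self.replicates.index

    def to_frame(self) -> pd.DataFrame:
        out = self.replicates.copy()
        out["mean_log2fc"] = self.mean
        return out


@dataclass
class GeneSet:
    """A named gene list (GMT record); member order is not meaningful."""

    name: str
    description: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)
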