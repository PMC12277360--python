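"""Genus-level feature table container and rarefaction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "rarefy"]


@dataclass
class FeatureTable:
    """Samples x genera count table with rarefaction provenance.

    ``counts`` rows are samples, columns genera; entries are non-negative
    integers.  ``rarefaction_depth`` records the depth every row sums to
    after rarefaction (``None`` for raw tables).
    """

    counts: pd.DataFrame
    rarefaction_depth: int | None = None
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("genus names must be unique")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        if self.rarefaction_depth is not None:
            sums = self.counts.sum(axis=1)
            if not (sums == self.rarefaction_depth).all():
                raise ValueError("rarefied rows must all sum to the stated depth")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions (rows sum to 1; zero-sum rows raise)."""
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            bad = list(self.counts.index[sums == 0])
            raise ValueError(f"zero-sum samples: {bad}")
        return self.counts.div(sums, axis=0)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each genus is detected (count > 0)."""
        return (self.counts > 0).mean(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("#SampleID").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        """Read a TSV table; a leading ``#OTU ID`` header (features as rows,
        the BIOM-TSV dialect) is detected and transposed."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if str(df.index.name).strip().lstrip("#").lower() in ("otu id", "otuid"):
            df = df.T
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns.name = None
        return cls(df)


def rarefy(table: FeatureTable, depth: int, seed: int | None = None) -> FeatureTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and recorded
    in ``dropped_samples``.  Deterministic for a given seed (the draw is a
    multivariate hypergeometric per sample).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth}")
    rng = np.random.default_rng(seed)
    sub = table.counts.loc[keep]
    out = np.empty_like(sub.to_numpy())
    for i, row in enumerate(sub.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return FeatureTable(
        pd.DataFrame(out, index=sub.index, columns=sub.columns),
        rarefaction_depth=depth,
        dropped_samples=list(table.counts.index[~keep]),
    )
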