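"""Per-sample alpha-diversity summaries for rarefied genus tables.

Shannon entropy uses log base 2 (the QIIME 2 convention); Pielou's evenness
is base-invariant.  Chao1 uses the bias-corrected form
``S + F1(F1-1) / (2(F2+1))`` with singleton/doubleton counts F1/F2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._table import FeatureTable

__all__ = ["alpha_diversity"]


def _alpha_row(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        return {k: np.nan for k in ("observed", "chao1", "shannon", "simpson", "pielou")}
    present = counts[counts > 0]
    s = len(present)
    f1 = int((present == 1).sum())
    f2 = int((present == 2).sum())
    chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = present / total
    shannon = float(-(p * np.log2(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    pielou = shannon / np.log2(s) if s > 1 else np.nan
    return {
        "observed": float(s),
        "chao1": float(chao1),
        "shannon": shannon,
        "simpson": simpson,
        "pielou": pielou,
    }


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Observed genera, Chao1, Shannon (bits), Gini-Simpson and Pielou per
    sample.  All-zero samples yield NaN rows (flagged undefined); Pielou is
    NaN for single-genus samples."""
    rows = {sid: _alpha_row(row) for sid, row in
            zip(table.counts.index, table.counts.to_numpy())}
    return pd.DataFrame.from_dict(rows, orient="index")
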