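"""Gut microbiota preparation.

*Camponotus* abdominal communities are dominated by the obligate
intracellular endosymbiont *Blochmannia*; compositional analyses of the
facultative community require excluding it first and converting the
remaining ASV counts to relative abundances.  Workers whose reads are
exclusively endosymbiont keep an all-zero profile (flagged) so that worker
sets stay aligned across layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["exclude_endosymbiont", "relative_abundance"]


def exclude_endosymbiont(
    counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop taxa flagged as endosymbionts from an ASV x worker count table.

    Returns the reduced table and a boolean Series flagging workers whose
    remaining read total is zero.
    """
    flags = taxonomy.set_index("asv_id")["endosymbiont"].reindex(counts.index)
    if flags.isna().any():
        missing = list(counts.index[flags.isna()])
        raise ValueError(f"taxonomy missing for ASVs: {missing[:5]}")
    if not flags.any():
        raise ValueError("no taxon is flagged as endosymbiont")
    kept = counts.loc[~flags.to_numpy(bool)]
    empty = kept.sum(axis=0) == 0
    empty.name = "endosymbiont_only"
    return kept, empty


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise counts to per-worker proportions.

    All-zero workers stay all-zero (their column sum is left untouched); the
    flag from :func:`exclude_endosymbiont` marks them for downstream distance
    handling.
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    totals = arr.sum(axis=0)
    props = np.divide(arr, np.where(totals > 0, totals, 1.0))
    return pd.DataFrame(props, index=counts.index, columns=counts.columns)
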