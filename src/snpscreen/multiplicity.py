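"""Benjamini-Hochberg q-values for the single-stage association scan.

The step-up adjustment is delegated to statsmodels; this module adds the
input-order bookkeeping, the rank column, and the report plumbing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues: Sequence[float] | Mapping[str, float]) -> pd.DataFrame:
    """BH step-up q-values: q_(i) = min_{j>=i} min(1, p_(j) * m / j).

    Accepts a sequence of p-values or a mapping snp_id -> p.  Output rows
    follow the input order; ``rank`` is the ascending midrank of p (tied
    p-values share a rank and, by the step-up construction, a q-value).
    """
    if isinstance(pvalues, Mapping):
        ids = list(pvalues.keys())
        p = np.asarray(list(pvalues.values()), dtype=float)
    else:
        p = np.asarray(pvalues, dtype=float)
        ids = list(range(len(p)))
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "snp_id": ids,
        "p_F": p,
        "rank": rankdata(p, method="average"),
        "q_BH": q,
    })


def write_qvalue_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
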