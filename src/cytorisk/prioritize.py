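"""Three-criterion gene prioritization.

Condenses a candidate gene roster to a high-priority subset by requiring,
per gene:

1. a trend for association with distant-metastasis-free survival
   (P < 0.15) in a multivariate Cox model containing all roster genes,
   fitted on the training cohort;
2. a trend (P < 0.15) in the validation cohort, in either a univariate or
   a multivariate Cox model; and
3. statistical significance (P < 0.05) in at least one of those analyses.

A missing P value fails the criterion it serves.  Only genes passing all
three criteria are flagged high priority.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .survival import cox_fit

P_COLUMNS = ("train_mv_p", "valid_uv_p", "valid_mv_p")


@dataclass
class PrioritizationResult:
    table: pd.DataFrame = field(repr=False)  # per-gene criteria + priority
    priority_genes: list = field(default_factory=list)


def prioritize_genes(pvalues: pd.DataFrame, trend_p: float = 0.15,
                     sig_p: float = 0.05) -> PrioritizationResult:
    """Apply the three filtering criteria to a gene-by-model P-value table.

    ``pvalues`` must carry columns ``train_mv_p``, ``valid_uv_p`` and
    ``valid_mv_p`` indexed by gene; entries may be missing.
    """
    if len(pvalues) == 0:
        raise ValueError("empty P-value table")
    for col in P_COLUMNS:
        if col not in pvalues.columns:
            raise ValueError(f"P-value table missing column {col!r}")
        vals = pvalues[col].dropna()
        if ((vals <= 0) | (vals > 1)).any():
            raise ValueError(f"{col}: P values must lie in (0, 1]")

    t = pvalues[list(P_COLUMNS)].astype(float)
    c1 = t["train_mv_p"] < trend_p
    c2 = (t["valid_uv_p"] < trend_p) | (t["valid_mv_p"] < trend_p)
    c3 = t.min(axis=1, skipna=True) < sig_p
    out = t.copy()
    out["criterion1"] = c1.fillna(False)
    out["criterion2"] = c2.fillna(False)
    out["criterion3"] = c3.fillna(False)
    out["priority"] = out["criterion1"] & out["criterion2"] & out["criterion3"]
    return PrioritizationResult(table=out, priority_genes=list(out.index[out["priority"]]))


def fit_pvalue_table(train: ExpressionMatrix, train_outcome: pd.DataFrame,
                     valid: ExpressionMatrix, valid_outcome: pd.DataFrame,
                     genes=None) -> pd.DataFrame:
    """Fill the three P-value columns by Cox modeling.

    Multivariate columns come from a joint model containing every roster
    gene (complete cases); the validation univariate column from per-gene
    models.  Non-convergent fits leave the affected entries missing.
    """
    genes = list(genes) if genes is not None else list(train.genes)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"),
                         columns=list(P_COLUMNS), dtype=float)

    def _mv(m, y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = cox_fit(m.values[genes], y)
            return fit.wald_p
        except Exception as exc:  # noqa: BLE001 - survey fit, record and move on
            warnings.warn(f"multivariate Cox fit failed: {exc}")
            return pd.Series(np.nan, index=genes)

    table["train_mv_p"] = _mv(train, train_outcome).reindex(genes)
    table["valid_mv_p"] = _mv(valid, valid_outcome).reindex(genes)
    for g in genes:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = cox_fit(valid.values[[g]], valid_outcome)
            table.loc[g, "valid_uv_p"] = float(fit.wald_p.iloc[0])
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"univariate Cox fit failed for {g}: {exc}")
    return table
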