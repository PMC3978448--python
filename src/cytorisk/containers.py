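"""Core in-memory containers shared across the pipeline.

Expression data travel as a samples-by-genes :class:`pandas.DataFrame`
wrapped together with per-sample source-site labels and a platform tag
(``"rtpcr"`` for ΔΔCT-scale values, ``"microarray"`` for log-expression).
Outcome data are a plain DataFrame with ``time`` (years of follow-up) and
``event`` (1 = distant recurrence, 0 = censored) columns plus optional
clinical covariates (``nodal``, ``grade``, ``site``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognized platform tags
PLATFORMS = ("rtpcr", "microarray")

#: columns an outcome table must carry
OUTCOME_REQUIRED = ("time", "event")


@dataclass
class ExpressionMatrix:
    """Samples × genes numeric table with explicit missing values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples (unique identifiers), columns gene symbols.
        Missing measurements are ``NaN``.
    sites : pandas.Series
        Source-site label per sample, aligned to ``values.index``.
    platform : str
        ``"rtpcr"`` (ΔΔCT units) or ``"microarray"`` (log expression).
    """

    values: pd.DataFrame
    sites: pd.Series
    platform: str = "rtpcr"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        self.sites = pd.Series(self.sites).reindex(self.values.index)
        if self.sites.isna().any():
            missing = self.sites.index[self.sites.isna()].tolist()
            raise ValueError(f"samples without a site label: {missing[:5]}")
        self.values = self.values.astype(float)

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[ids], self.sites.loc[ids], self.platform)


def check_outcome(outcome: pd.DataFrame) -> pd.DataFrame:
    """Validate an outcome table (``time`` > 0 finite, ``event`` in {0,1})."""
    for col in OUTCOME_REQUIRED:
        if col not in outcome.columns:
            raise ValueError(f"outcome table missing required column {col!r}")
    t = outcome["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("follow-up times must be positive and finite")
    ev = outcome["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (distant recurrence)")
    if not outcome.index.is_unique:
        raise ValueError("duplicate sample identifiers in outcome table")
    return outcome


@dataclass
class SyntheticCohort:
    """A simulated cohort: expression + outcome + the latent truth behind them."""

    expression: ExpressionMatrix
    outcome: pd.DataFrame
    latent_scores: pd.Series
    config_echo: "object" = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.expression.samples.equals(self.outcome.index):
            raise ValueError("expression and outcome must share sample identifiers")
        if self.latent_scores.isna().any():
            raise ValueError("latent scores must be complete")
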