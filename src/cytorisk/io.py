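"""Delimited-text I/O for expression, clinical, and result tables.

Conventions: tab-delimited by default, samples as rows with a header row,
``NA`` as the missing-value token (configurable; ``"na"`` and ``""`` are
also accepted on read).  Round trips are value-exact because floats are
written with full repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, check_outcome

MISSING_TOKENS = ("NA", "na", "")


def read_expression(path, site_col: str = "site", sep: str = "\t",
                    platform: str = "rtpcr",
                    missing_tokens=MISSING_TOKENS) -> ExpressionMatrix:
    """Read a samples × genes table whose ``site`` column labels the source."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(missing_tokens),
                     keep_default_na=False, dtype={0: str})
    if site_col not in df.columns:
        raise ValueError(f"expression file missing {site_col!r} column")
    sites = df[site_col].astype(str)
    values = df.drop(columns=[site_col])
    for c in values.columns:
        coerced = pd.to_numeric(values[c], errors="coerce")
        tokens_bad = coerced.isna() & values[c].notna()
        if tokens_bad.any():
            cell = values.index[tokens_bad][0]
            raise ValueError(
                f"unknown missing token {values.loc[cell, c]!r} at sample {cell!r}, gene {c!r}"
            )
        values[c] = coerced
    return ExpressionMatrix(values, sites, platform=platform)


def write_expression(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    out = m.values.copy()
    out.insert(0, "site", m.sites)
    out.index.name = "sample"
    out.to_csv(path, sep=sep, na_rep="NA")


def read_clinical(path, sep: str = "\t") -> pd.DataFrame:
    """Read the outcome/covariate table (time, event, nodal, grade, site)."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS),
                     keep_default_na=False)
    return check_outcome(df)


def write_clinical(outcome: pd.DataFrame, path, sep: str = "\t") -> None:
    out = outcome.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=sep, na_rep="NA")


def check_alignment(m: ExpressionMatrix, outcome: pd.DataFrame) -> dict:
    """Report sample-ID overlap between expression and clinical tables."""
    e, c = set(m.samples), set(outcome.index)
    return {"shared": len(e & c), "expression_only": len(e - c),
            "clinical_only": len(c - e)}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    if isinstance(x, pd.Series):
        return x.to_dict()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="index")
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
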