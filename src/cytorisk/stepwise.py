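"""Forward-stepwise derivation of an optimized sign-adjusted-mean signature.

Starting from a candidate pool of (gene, sign) pairs — by default the
union of the IR-7 and Buck-4 constituents — genes are added one at a time,
beginning with the one most significantly associated with distant
recurrence.  At each step every unused gene is trialed: the enlarged
equal-weight index is computed, Z-transformed, and fitted as a continuous
covariate in a univariate Cox model; the gene minimizing the model's
likelihood-ratio P is added.  The selected signature is the prefix of the
addition path with the globally minimal P (ties favor the smaller
subset).  Selection is deterministic: no randomness enters the procedure.

Because the selected model's P value is the minimum over many fitted
models it carries selection bias; it describes the search, not an honest
significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._univariate_cox import fit_univariate_cox
from .containers import ExpressionMatrix, check_outcome
from .signatures import BUCK4, IR7, SignatureDefinition


def default_pool() -> list:
    """Union of IR-7 and Buck-4 constituents with signs from their parent
    formulas; a sign conflict for a shared gene is a configuration error."""
    pool = {}
    for sig in (IR7, BUCK4):
        for gene, sign in sig.terms:
            if gene in pool and pool[gene] != sign:
                raise ValueError(f"sign conflict for shared gene {gene}")
            pool[gene] = sign
    return sorted(pool.items())


@dataclass
class StepwisePath:
    """Record of a forward-selection run."""

    path: pd.DataFrame = field(repr=False)  # step, gene, sign, n, lr_p
    selected: SignatureDefinition = None
    best_p: float = float("nan")
    n_used: int = 0

    @property
    def selected_size(self) -> int:
        return self.selected.divisor


class ForwardSignatureSelector(BaseEstimator):
    """Sklearn-style estimator wrapping the forward-selection search.

    Parameters
    ----------
    pool : list of (gene, sign), optional
        Candidate genes with a-priori signs; defaults to the IR-7 ∪ Buck-4
        union.  Signs are fixed, never re-estimated per step.
    complete_cases : bool, default True
        Restrict to samples measured in every pool gene before the search
        begins, so likelihood-ratio statistics are comparable across
        candidate models.  When False, each candidate model uses its own
        complete cases (statistics then compare different sample sets).
    signature_name : str
        Name given to the selected :class:`SignatureDefinition`.

    Fitted attributes: ``path_`` (DataFrame of additions), ``signature_``
    (selected definition), ``best_p_``, ``n_used_``.
    """

    def __init__(self, pool=None, complete_cases: bool = True,
                 signature_name: str = "stepwise-optimized"):
        self.pool = pool
        self.complete_cases = complete_cases
        self.signature_name = signature_name

    def fit(self, X, y):
        pool = list(self.pool) if self.pool is not None else default_pool()
        if not pool:
            raise ValueError("candidate pool is empty")
        values = X.values if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
        missing = [g for g, _ in pool if g not in values.columns]
        if missing:
            raise ValueError(f"pool genes absent from matrix: {missing}")
        y = check_outcome(y).loc[values.index]

        expr = values[[g for g, _ in pool]].astype(float)
        if self.complete_cases:
            keep = expr.notna().all(axis=1)
            expr, y = expr[keep], y.loc[keep]
        time = y["time"].to_numpy(float)
        event = y["event"].to_numpy(int)

        signs = dict(pool)
        remaining = [g for g, _ in pool]
        chosen: list = []
        running = np.zeros(len(expr))
        records = []
        while remaining:
            best = None
            for gene in remaining:
                col = expr[gene].to_numpy(float) * signs[gene]
                if not self.complete_cases:
                    ok = ~np.isnan(running + col)
                else:
                    ok = slice(None)
                idx = (running + col)[ok] / (len(chosen) + 1)
                sd = idx.std(ddof=1)
                if not np.isfinite(sd) or sd == 0:
                    continue
                zidx = (idx - idx.mean()) / sd
                try:
                    _, _, lr_p = fit_univariate_cox(zidx, time[ok], event[ok])
                except Exception as exc:  # noqa: BLE001 - truncate path
                    warnings.warn(f"Cox fit failed adding {gene}: {exc}")
                    continue
                n_fit = len(zidx)
                if best is None or lr_p < best[1] - 1e-15:
                    best = (gene, lr_p, n_fit)
            if best is None:
                warnings.warn("no candidate model converged; path truncated")
                break
            gene, lr_p, n_fit = best
            chosen.append(gene)
            remaining.remove(gene)
            running = running + expr[gene].to_numpy(float) * signs[gene]
            records.append(
                {"step": len(chosen), "gene": gene, "sign": signs[gene],
                 "n": n_fit, "lr_p": lr_p}
            )
        if not records:
            raise ValueError("forward selection produced no usable model")
        path = pd.DataFrame.from_records(records)
        k = int(path["lr_p"].idxmin())  # first occurrence -> smaller subset on ties
        subset = path.loc[:k]
        self.path_ = path
        self.signature_ = SignatureDefinition(
            self.signature_name,
            tuple((row.gene, int(row.sign)) for row in subset.itertuples()),
        )
        self.best_p_ = float(path.loc[k, "lr_p"])
        self.n_used_ = int(len(expr))
        return self


def forward_select(pool, matrix, outcome, complete_cases: bool = True) -> StepwisePath:
    """Functional wrapper over :class:`ForwardSignatureSelector`."""
    sel = ForwardSignatureSelector(pool=pool, complete_cases=complete_cases)
    sel.fit(matrix, outcome)
    return StepwisePath(path=sel.path_, selected=sel.signature_,
                        best_p=sel.best_p_, n_used=sel.n_used_)
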