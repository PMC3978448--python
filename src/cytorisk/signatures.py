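"""Signature definitions and equal-weight sign-adjusted-mean scoring.

A signature index is the mean of its member genes' expression values after
applying a per-gene sign, oriented so that a *higher* index tracks higher
distant-recurrence risk.  Three built-in indices are provided:

* ``IR-7``  — [SPP1 − (C1QA + HLA-F + IGLC2 + LY9 + TNFRSF17 + XCL2)] / 7
* ``Buck-4`` — [RGS4 − CLIC5 + CXCL13 + RPS28//FLJ46061] / 4
* ``ICS``   — [−CLIC5 + CXCL13 + HLA-F + TNFRSF17 + XCL2] / 5

If any constituent gene of a sample is missing, the sample's index is not
computed (missing with a reason).  Index values are Z-transformed within a
cohort: scaled to sample mean 0 and (n−1) standard deviation 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix

# One place for symbol variants; qPCR assay sheets and array annotations
# disagree on hyphenation and on the RPS28 readthrough locus name.
GENE_ALIASES = {
    "HLAF": "HLA-F",
    "IGCL2": "IGLC2",
    "FLJ46061": "RPS28//FLJ46061",
    "RPS28": "RPS28//FLJ46061",
}


def canonical_gene(symbol: str) -> str:
    """Map a gene-symbol variant to its canonical spelling."""
    return GENE_ALIASES.get(symbol, symbol)


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene set with per-gene sign; the divisor is the term count."""

    name: str
    terms: tuple  # of (gene symbol, sign in {+1, -1})

    def __post_init__(self):
        terms = tuple((canonical_gene(g), int(s)) for g, s in self.terms)
        object.__setattr__(self, "terms", terms)
        genes = [g for g, _ in terms]
        if len(set(genes)) != len(genes):
            raise ValueError(f"{self.name}: duplicate gene symbols in signature")
        if any(s not in (-1, 1) for _, s in terms):
            raise ValueError(f"{self.name}: signs must be +1 or -1")
        if not terms:
            raise ValueError(f"{self.name}: signature has no terms")

    @property
    def divisor(self) -> int:
        return len(self.terms)

    @property
    def genes(self) -> list:
        return [g for g, _ in self.terms]

    @property
    def signs(self) -> dict:
        return dict(self.terms)

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "terms": [{"gene": g, "sign": s} for g, s in self.terms]}
        )

    @classmethod
    def from_json(cls, payload: str) -> "SignatureDefinition":
        d = json.loads(payload)
        return cls(d["name"], tuple((t["gene"], t["sign"]) for t in d["terms"]))


IR7 = SignatureDefinition(
    "IR-7",
    (
        ("SPP1", +1),
        ("C1QA", -1),
        ("HLA-F", -1),
        ("IGLC2", -1),
        ("LY9", -1),
        ("TNFRSF17", -1),
        ("XCL2", -1),
    ),
)

BUCK4 = SignatureDefinition(
    "Buck-4",
    (("RGS4", +1), ("CLIC5", -1), ("CXCL13", +1), ("RPS28//FLJ46061", +1)),
)

ICS = SignatureDefinition(
    "ICS",
    (("CLIC5", -1), ("CXCL13", +1), ("HLA-F", +1), ("TNFRSF17", +1), ("XCL2", +1)),
)

# Provisional roster: the 11 prioritization candidates plus MATN1.  Two of the
# original fourteen members are not identifiable from public sources; the
# roster is used for membership bookkeeping only and is never scored by
# default.  Buck-4 members keep their index signs; the rest default to +1.
BUCK14 = SignatureDefinition(
    "Buck-14",
    (
        ("CXCL13", +1),
        ("EXOC7", +1),
        ("HAPLN1", +1),
        ("RFX7", +1),
        ("RPS28//FLJ46061", +1),
        ("SSX3", +1),
        ("ZNF3", +1),
        ("ABO", +1),
        ("CLIC5", -1),
        ("PRRG3", +1),
        ("RGS4", +1),
        ("MATN1", +1),
    ),
)


def builtin_signatures() -> dict:
    """Return the built-in signature definitions keyed by name."""
    return {s.name: s for s in (IR7, BUCK4, ICS, BUCK14)}


def z_transform(values) -> pd.Series:
    """Scale to sample mean 0 and SD 1 (n−1 denominator); NaN stays NaN.

    Raises ``ValueError`` on fewer than two non-missing values or zero
    variance.
    """
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if len(obs) < 2:
        raise ValueError("z_transform needs at least two non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("z_transform: zero variance input")
    return (s - obs.mean()) / sd


@dataclass
class SignatureScores:
    """Per-sample raw and Z-transformed index values with missing reasons."""

    signature: str
    frame: pd.DataFrame = field(repr=False)  # columns: raw, z, missing_reason
    cohort: str = ""

    @property
    def raw(self) -> pd.Series:
        return self.frame["raw"]

    @property
    def z(self) -> pd.Series:
        return self.frame["z"]

    @property
    def n_missing(self) -> int:
        return int(self.frame["raw"].isna().sum())


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Compute a signature index over an expression matrix.

    Parameters
    ----------
    signature : SignatureDefinition or str
        The index to compute; a string looks up the built-in catalogue.
    flip_sign : bool, default False
        Multiply raw scores by −1.  ΔΔCT and log-expression scales run in
        opposite directions; the pipeline never flips silently — any flip is
        this explicit option.
    with_z : bool, default True
        Also Z-transform the raw scores over the cohort's non-missing values.

    The Z-transform parameters (cohort mean and SD of the raw index) are
    learned in :meth:`fit` and exposed as ``mean_`` / ``scale_``, so a
    scorer fitted on one cohort can project another onto the same scale.
    """

    def __init__(self, signature="ICS", flip_sign: bool = False, with_z: bool = True):
        self.signature = signature
        self.flip_sign = flip_sign
        self.with_z = with_z

    def _definition(self) -> SignatureDefinition:
        if isinstance(self.signature, SignatureDefinition):
            return self.signature
        catalogue = builtin_signatures()
        if self.signature not in catalogue:
            raise ValueError(f"unknown signature {self.signature!r}")
        return catalogue[self.signature]

    def _raw_scores(self, X) -> pd.DataFrame:
        values = X.values if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
        sig = self._definition()
        cols = {}
        absent = []
        for gene in sig.genes:
            if gene in values.columns:
                cols[gene] = gene
            else:
                # accept alias spellings present in the matrix
                hit = [c for c in values.columns if canonical_gene(c) == gene]
                if hit:
                    cols[gene] = hit[0]
                else:
                    absent.append(gene)
        if absent:
            raise ValueError(f"signature {sig.name}: genes absent from matrix: {absent}")
        sub = values[[cols[g] for g in sig.genes]]
        sub.columns = sig.genes
        signs = pd.Series(sig.signs)
        raw = (sub * signs).sum(axis=1, min_count=len(sig.genes)) / sig.divisor
        if self.flip_sign:
            raw = -raw
        reasons = sub.isna().apply(lambda r: ",".join(sub.columns[r]) or None, axis=1)
        return pd.DataFrame({"raw": raw, "missing_reason": reasons})

    def fit(self, X, y=None):
        frame = self._raw_scores(X)
        obs = frame["raw"].dropna()
        if self.with_z:
            if len(obs) < 2:
                raise ValueError("Z-transform needs at least two non-missing scores")
            sd = obs.std(ddof=1)
            if sd == 0:
                raise ValueError("Z-transform: zero variance in raw scores")
            self.mean_, self.scale_ = float(obs.mean()), float(sd)
        else:
            self.mean_, self.scale_ = 0.0, 1.0
        self.n_missing_ = int(frame["raw"].isna().sum())
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = self._raw_scores(X)
        frame["z"] = (frame["raw"] - self.mean_) / self.scale_ if self.with_z else frame["raw"]
        return frame[["raw", "z", "missing_reason"]]


def score_signature(definition, matrix, flip_sign: bool = False) -> SignatureScores:
    """Fit-and-score a cohort with a signature (cohort-level Z-transform)."""
    scorer = SignatureScorer(definition, flip_sign=flip_sign)
    frame = scorer.fit(matrix).transform(matrix)
    name = definition.name if isinstance(definition, SignatureDefinition) else str(definition)
    return SignatureScores(signature=name, frame=frame)
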