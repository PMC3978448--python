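"""ΔΔCT normalization of raw qPCR Ct tables and multi-site pooling QC.

The ΔΔCT method: each gene's threshold cycle (Ct) is normalized within a
sample to the mean of two reference genes (default NUP214 and PPIG), and
that ΔCt is then referenced against a universal calibrator RNA assayed
with the same genes:

    ΔCt(s, g)  = Ct(s, g) − mean(Ct(s, reference genes))
    ΔΔCt(s, g) = ΔCt(s, g) − ΔCt(calibrator, g)

Ct values at or beyond the amplification cycle cap (default 40) mean the
transcript failed to amplify and are treated as missing.  Because ΔΔCT
cohorts are pooled from several source sites, each gene is median-centered
within site before pooling, and a dendrogram-branch composition check
(Fisher exact) guards against residual source bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, hypergeom
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENES = ("NUP214", "PPIG")


@dataclass
class CtTable:
    """Raw Ct values (thermocycles) for a cohort plus the calibrator row."""

    ct: pd.DataFrame  # samples x genes, includes reference genes
    universal_reference: pd.Series  # one Ct per gene (calibrator RNA)
    sites: pd.Series
    reference_genes: tuple = DEFAULT_REFERENCE_GENES

    def __post_init__(self):
        missing_refs = [g for g in self.reference_genes if g not in self.ct.columns]
        if missing_refs:
            raise ValueError(f"reference genes absent from Ct table: {missing_refs}")
        vals = self.ct.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() <= 0:
            raise ValueError("Ct values must be positive")
        self.sites = pd.Series(self.sites).reindex(self.ct.index)


class DeltaDeltaCt(BaseEstimator, TransformerMixin):
    """Stateless transformer from a :class:`CtTable` to a ΔΔCT matrix.

    Parameters
    ----------
    cycle_cap : float, default 40
        Ct at or beyond this cycle count is treated as failed
        amplification (missing).
    """

    def __init__(self, cycle_cap: float = 40.0):
        self.cycle_cap = cycle_cap

    def fit(self, X: CtTable, y=None):
        return self

    def transform(self, X: CtTable) -> ExpressionMatrix:
        ct = X.ct.astype(float).mask(X.ct >= self.cycle_cap)
        cal = X.universal_reference.astype(float)
        cal = cal.mask(cal >= self.cycle_cap)

        refs = list(X.reference_genes)
        ref_mean = ct[refs].mean(axis=1, skipna=False)
        bad_ref = ref_mean.isna()
        if bad_ref.any():
            logger.warning(
                "%d sample(s) missing a reference-gene Ct; all their values set missing",
                int(bad_ref.sum()),
            )
        genes = [g for g in ct.columns if g not in refs]
        dct = ct[genes].sub(ref_mean, axis=0)

        cal_ref = cal[refs].mean()
        cal_dct = cal[genes] - cal_ref
        gene_missing = cal_dct.isna()
        if gene_missing.any():
            logger.warning(
                "calibrator missing gene(s) %s; those columns set missing",
                list(cal_dct.index[gene_missing]),
            )
        ddct = dct.sub(cal_dct, axis=1)
        return ExpressionMatrix(ddct, X.sites, platform="rtpcr")


class SiteMedianCenterer(BaseEstimator, TransformerMixin):
    """Median-center each gene within each source site (then pool).

    ``fit`` learns per-site per-gene medians over non-missing values;
    ``transform`` subtracts them.  Sites with no usable value for a gene
    leave that gene unchanged (with a warning).  Idempotent on the data it
    was fitted to.
    """

    def fit(self, X: ExpressionMatrix, y=None):
        medians = {}
        for site, idx in X.sites.groupby(X.sites).groups.items():
            med = X.values.loc[idx].median(axis=0, skipna=True)
            empty = med.isna() & X.values.loc[idx].isna().all(axis=0)
            if empty.any():
                warnings.warn(
                    f"site {site!r}: gene(s) {list(med.index[empty])} have no "
                    "non-missing values; left uncentered"
                )
            medians[site] = med.fillna(0.0)
        self.site_medians_ = pd.DataFrame(medians).T
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        offsets = self.site_medians_.reindex(X.sites.to_numpy()).fillna(0.0)
        offsets.index = X.values.index
        centered = X.values - offsets[X.values.columns]
        return ExpressionMatrix(centered, X.sites, platform=X.platform)


def compute_delta_delta_ct(ct: CtTable, cycle_cap: float = 40.0) -> ExpressionMatrix:
    """Functional wrapper over :class:`DeltaDeltaCt`."""
    return DeltaDeltaCt(cycle_cap=cycle_cap).fit(ct).transform(ct)


def median_center_by_site(m: ExpressionMatrix) -> ExpressionMatrix:
    """Functional wrapper: fit-and-apply site medians on the analysis set."""
    return SiteMedianCenterer().fit(m).transform(m)


@dataclass
class MissingnessReport:
    per_gene: pd.DataFrame = field(repr=False)  # n_missing, frac, per-site counts
    flagged: list = field(default_factory=list)
    threshold: float = 0.10


def missingness_report(m: ExpressionMatrix, threshold: float = 0.10) -> MissingnessReport:
    """Per-gene missing counts (overall and by site); flag genes missing in
    more than ``threshold`` of samples."""
    mask = m.missing_mask
    per_site = mask.groupby(m.sites.to_numpy()).sum().T
    per_site.columns = [f"missing_{c}" for c in per_site.columns]
    frame = pd.DataFrame(
        {"n_missing": mask.sum(), "frac_missing": mask.mean()}
    ).join(per_site)
    flagged = list(frame.index[frame["frac_missing"] > threshold])
    return MissingnessReport(per_gene=frame, flagged=flagged, threshold=threshold)


def _pairwise_complete_distance(values: pd.DataFrame) -> np.ndarray:
    """Euclidean distance over shared genes, scaled by sqrt(n_total/n_shared)."""
    x = values.to_numpy(float)
    obs = ~np.isnan(x)
    n, p = x.shape
    x0 = np.where(obs, x, 0.0)
    shared = obs.astype(float) @ obs.T.astype(float)
    # sum over shared coords of (xi - xj)^2, computed via masked expansions
    sq = x0**2
    cross = x0 @ x0.T
    si = sq @ obs.T.astype(float)  # sum_i xi^2 over coords observed in both
    d2 = si + si.T - 2 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (p / shared)
    d2[shared == 0] = np.nan
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def _table_log_prob(table: np.ndarray) -> float:
    """Log probability of a contingency table under fixed margins
    (multivariate hypergeometric)."""
    from scipy.special import gammaln

    table = np.asarray(table, float)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_rxc(table: np.ndarray, n_sim: int = 20000, seed: int = 0,
                     force_mc: bool = False) -> float:
    """Fisher exact P for an r×c table; exact for 2×2, Monte-Carlo otherwise.

    The Monte-Carlo path samples tables with the observed margins by
    permuting labels and estimates P(prob(table) ≤ prob(observed)).
    ``force_mc`` routes 2×2 tables through the Monte-Carlo path (used to
    validate the approximation against the exact computation).
    """
    table = np.asarray(table, int)
    if table.shape == (2, 2) and not force_mc:
        return float(fisher_exact(table)[1])
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    obs_lp = _table_log_prob(table)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(cols)
        sim = np.zeros_like(table)
        np.add.at(sim, (rows, perm), 1)
        if _table_log_prob(sim) <= obs_lp + 1e-9:
            hits += 1
    return (hits + 1) / (n_sim + 1)


def source_bias_check(m: ExpressionMatrix, n_branches: int = 2,
                      n_sim: int = 20000, seed: int = 0):
    """Cluster samples (complete linkage, pairwise-complete Euclidean), cut
    the dendrogram into ``n_branches``, and Fisher-test branch × site
    composition.

    Returns ``(branch assignment Series, Fisher exact P)``.
    """
    if n_branches < 2:
        raise ValueError("n_branches must be >= 2")
    if m.sites.nunique() < 2 or len(m.samples) < 4:
        raise ValueError("source_bias_check needs >= 2 sites and >= 4 samples")
    usable = ~m.missing_mask.all(axis=1)
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} all-missing sample(s) from clustering"
        )
    values = m.values.loc[usable]
    sites = m.sites.loc[usable]
    dist = _pairwise_complete_distance(values)
    if np.isnan(dist).any():
        raise ValueError("some sample pairs share no measured genes")
    z = linkage(squareform(dist, checks=False), method="complete")
    branches = pd.Series(
        fcluster(z, t=n_branches, criterion="maxclust"), index=values.index, name="branch"
    )
    table = pd.crosstab(branches, sites).to_numpy()
    p = fisher_exact_rxc(table, n_sim=n_sim, seed=seed)
    return branches, float(p)
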