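"""Survival recursive partitioning with exponential-model deviance.

This reimplements the CART survival method popularized by R's ``rpart``
(method ``"exp"``): observed follow-up times are rescaled by the
Nelson-Aalen cumulative hazard of the full sample, turning the problem
into Poisson regression of event counts d_i on "expected event"
exposures e_i.  A node's rate MLE is λ = Σd/Σe and its deviance

    D = 2 Σ_i [ d_i log(d_i/(λ e_i)) − (d_i − λ e_i) ]        (0·log 0 = 0)

which, at the MLE and with 0/1 event counts, reduces to
``−2·[D·log(D/E) + Σ_events log e_i]``.  Splits greedily maximize the
parent-minus-children deviance reduction subject to a minimum terminal
node size (default 20, a stability constraint) and a growth threshold
``cp`` (minimum relative deviance improvement, rpart's default 0.01).
The grown tree is cost-complexity pruned; the complexity parameter is the
grid value (geometric means of the weakest-link sequence) minimizing the
summed 10-fold cross-validated held-out deviance, taken literally (no
1-SE rule).  Held-out samples are scored with leaf rates shrunk toward
the fold's root rate by a weak gamma prior so event-free leaves stay
finite.

Covariates must be numeric codes: binary nodal status as 0/1, ordered
grade as 1/2/3 (splits then respect the ordering, e.g. I/II vs III), and
continuous signature scores as-is.  Samples with missing covariates are
dropped (complete cases; no surrogate splits).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import check_outcome
from .survival import km_estimate, logrank_test


def nelson_aalen_exposure(time, event) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="mergesort")
    t_sorted = time[order]
    n = len(time)
    haz_times, haz_vals = [], []
    cum = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = event[order[i:j]].sum()
        if d:
            cum += d / (n - i)
        haz_times.append(t_sorted[i])
        haz_vals.append(cum)
        i = j
    return np.interp(time, haz_times, haz_vals)


def _agg_deviance(d_total: float, e_total: float, s_logexp: float) -> float:
    """Node deviance at the rate MLE from aggregates.

    ``s_logexp`` is Σ over the node's events of log(e_i).
    """
    if d_total <= 0 or e_total <= 0:
        return 0.0
    return -2.0 * (d_total * np.log(d_total / e_total) + s_logexp)


def _heldout_deviance(d, e, lam) -> float:
    """Poisson deviance of held-out samples at an externally supplied rate."""
    d = np.asarray(d, float)
    e = np.asarray(e, float)
    mu = lam * e
    safe_mu = np.where(mu > 0, mu, 1.0)
    term = np.where(d > 0, d * np.log(np.where(d > 0, d, 1.0) / safe_mu), 0.0)
    term = np.where((d > 0) & (mu <= 0), np.inf, term)
    return float(2.0 * np.sum(term - (d - mu)))


@dataclass
class TreeNode:
    node_id: int
    depth: int
    sample_rows: np.ndarray = field(repr=False)
    n: int = 0
    events: int = 0
    exposure: float = 0.0
    rate: float = 0.0
    deviance: float = 0.0
    split_var: str = None
    split_threshold: float = None
    left: "TreeNode" = None
    right: "TreeNode" = None
    leaf_label: int = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def subtree_deviance(self) -> float:
        return sum(l.deviance for l in self.leaves())

    def to_dict(self) -> dict:
        d = {"n": self.n, "events": self.events, "rate": self.rate,
             "deviance": self.deviance}
        if not self.is_leaf:
            d["split"] = {"var": self.split_var, "threshold": self.split_threshold,
                          "left_if": "<="}
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        else:
            d["leaf"] = self.leaf_label
        return d


class SurvivalTreeModel(BaseEstimator):
    """CART-style survival tree with exponential deviance splitting.

    Parameters
    ----------
    min_terminal : int, default 20
        Minimum samples in any leaf.
    cv_folds : int, default 10
        Folds for complexity-parameter cross-validation.
    cv_seed : int, default 0
        Seed fixing the fold assignment.
    cp : float, default 0.01
        Growth threshold: a split must improve deviance by at least
        ``cp`` × root deviance.
    prune : bool, default True
        Select a complexity parameter by CV and cost-complexity prune.

    Fitted attributes: ``tree_`` (root :class:`TreeNode`), ``cp_``
    (selected complexity, relative to root deviance), ``cv_table_``,
    ``leaves_``, ``leaf_members_``, ``n_dropped_``.
    """

    def __init__(self, min_terminal: int = 20, cv_folds: int = 10,
                 cv_seed: int = 0, cp: float = 0.01, prune: bool = True):
        self.min_terminal = min_terminal
        self.cv_folds = cv_folds
        self.cv_seed = cv_seed
        self.cp = cp
        self.prune = prune

    # -- growing ---------------------------------------------------------

    def _grow(self, Xv: np.ndarray, d: np.ndarray, e: np.ndarray, columns):
        s_all = np.where(d > 0, np.log(np.where(e > 0, e, 1.0)), 0.0)
        counter = [0]

        def make_node(rows, depth):
            node = TreeNode(node_id=counter[0], depth=depth, sample_rows=rows)
            counter[0] += 1
            node.n = len(rows)
            node.events = int(d[rows].sum())
            node.exposure = float(e[rows].sum())
            node.rate = node.events / node.exposure if node.exposure > 0 else 0.0
            node.deviance = _agg_deviance(node.events, node.exposure,
                                          float(s_all[rows].sum()))
            return node

        root = make_node(np.arange(len(d)), 0)
        min_gain = max(self.cp * root.deviance, 1e-10)

        def best_split(node):
            rows = node.sample_rows
            if node.n < 2 * self.min_terminal or node.events == 0:
                return None
            best = None
            for ci, col in enumerate(columns):
                v = Xv[rows, ci]
                order = np.argsort(v, kind="mergesort")
                vs = v[order]
                ds = d[rows][order]
                es = e[rows][order]
                ss = s_all[rows][order]
                cum_d = np.cumsum(ds)
                cum_e = np.cumsum(es)
                cum_s = np.cumsum(ss)
                D, E, S = cum_d[-1], cum_e[-1], cum_s[-1]
                for k in np.nonzero(vs[1:] != vs[:-1])[0]:
                    nl = k + 1
                    if nl < self.min_terminal or node.n - nl < self.min_terminal:
                        continue
                    dev = (_agg_deviance(cum_d[k], cum_e[k], cum_s[k])
                           + _agg_deviance(D - cum_d[k], E - cum_e[k], S - cum_s[k]))
                    gain = node.deviance - dev
                    if best is None or gain > best[0] + 1e-12:
                        best = (gain, ci, (vs[k] + vs[k + 1]) / 2.0)
            return best

        def recurse(node):
            found = best_split(node)
            if found is None or found[0] <= min_gain:
                return
            gain, ci, thr = found
            mask = Xv[node.sample_rows, ci] <= thr
            node.split_var = columns[ci]
            node.split_threshold = float(thr)
            node.left = make_node(node.sample_rows[mask], node.depth + 1)
            node.right = make_node(node.sample_rows[~mask], node.depth + 1)
            recurse(node.left)
            recurse(node.right)

        if root.deviance > 0:
            recurse(root)
        return root

    # -- pruning ---------------------------------------------------------

    @staticmethod
    def _weakest_links(root: TreeNode):
        """Critical alphas of the nested cost-complexity pruning sequence
        (iteratively collapse the weakest link and recompute)."""
        work = copy.deepcopy(root)
        alphas = []
        while not work.is_leaf:
            weakest = [np.inf, None]

            def scan(node):
                if node.is_leaf:
                    return
                g = (node.deviance - node.subtree_deviance()) / (len(node.leaves()) - 1)
                if g < weakest[0]:
                    weakest[0], weakest[1] = g, node
                scan(node.left)
                scan(node.right)

            scan(work)
            alphas.append(float(weakest[0]))
            node = weakest[1]
            node.left = node.right = None
            node.split_var = None
            node.split_threshold = None
        # enforce monotone non-decreasing sequence (equal-g collapses)
        return sorted(set(np.maximum.accumulate(alphas).tolist()))

    @staticmethod
    def _prune_at(root: TreeNode, alpha: float) -> TreeNode:
        """Bottom-up collapse of subtrees whose (recomputed) weakest link
        does not beat ``alpha``; equivalent to iterative weakest-link
        pruning at that penalty."""
        root = copy.deepcopy(root)

        def collapse(node):
            if node.is_leaf:
                return 1, node.deviance
            ll, dl = collapse(node.left)
            lr, dr = collapse(node.right)
            leaves, dev = ll + lr, dl + dr
            g = (node.deviance - dev) / (leaves - 1)
            if g <= alpha + 1e-12:
                node.left = node.right = None
                node.split_var = None
                node.split_threshold = None
                return 1, node.deviance
            return leaves, dev

        collapse(root)
        return root

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        X = pd.DataFrame(X).astype(float)
        y = check_outcome(y).loc[X.index]
        keep = X.notna().all(axis=1)
        self.n_dropped_ = int((~keep).sum())
        X, y = X[keep], y.loc[keep]
        self.columns_ = list(X.columns)
        self.X_ = X
        self.y_ = y

        time = y["time"].to_numpy(float)
        event = y["event"].to_numpy(int)
        e = nelson_aalen_exposure(time, event)
        d = event.astype(float)
        Xv = X.to_numpy(float)

        full = self._grow(Xv, d, e, self.columns_)
        self.cv_table_ = None
        self.cp_ = 0.0

        if self.prune and not full.is_leaf and full.deviance > 0:
            alphas_rel = [a / full.deviance for a in self._weakest_links(full)]
            pts = [0.0] + alphas_rel
            cand = []
            for a, b in zip(pts[:-1], pts[1:]):
                cand.append(float(np.sqrt(a * b)) if a > 0 else b / 2.0)
            cand.append(alphas_rel[-1] * 2.0)
            cand = sorted(set(cand))

            rng = np.random.default_rng(self.cv_seed)
            folds = rng.permutation(len(d)) % self.cv_folds
            cv_err = np.zeros(len(cand))
            for f in range(self.cv_folds):
                tr, te = folds != f, folds == f
                if te.sum() == 0 or d[tr].sum() == 0:
                    continue
                sub = self._grow(Xv[tr], d[tr], e[tr], self.columns_)
                lam0 = max(sub.rate, 1e-9)
                colmap = {c: i for i, c in enumerate(self.columns_)}
                for ci, cp_rel in enumerate(cand):
                    pruned = self._prune_at(sub, cp_rel * max(sub.deviance, 1e-12))
                    labels = self._descend_with_map(pruned, Xv[te], colmap)
                    for li, leaf in enumerate(pruned.leaves()):
                        m = labels == li
                        if not m.any():
                            continue
                        lam = (leaf.events + 1.0) / (leaf.exposure + 1.0 / lam0)
                        cv_err[ci] += _heldout_deviance(d[te][m], e[te][m], lam)
            self.cv_table_ = pd.DataFrame({"cp": cand, "cv_deviance": cv_err})
            best = cv_err.min()
            # literal minimum; ties resolve to the larger cp (simpler tree)
            self.cp_ = float(max(c for c, err in zip(cand, cv_err)
                                 if err <= best + 1e-9))
            self.tree_ = self._prune_at(full, self.cp_ * full.deviance)
        else:
            self.tree_ = full

        self.leaves_ = self.tree_.leaves()
        for i, leaf in enumerate(self.leaves_):
            leaf.leaf_label = i
        labels = self.apply(self.X_)
        self.leaf_members_ = {i: list(labels.index[labels == i])
                              for i in range(len(self.leaves_))}
        return self

    # -- prediction ------------------------------------------------------

    def apply(self, X: pd.DataFrame) -> pd.Series:
        """Leaf index for each sample (requires complete covariates)."""
        X = pd.DataFrame(X)[self.columns_]
        Xv = X.to_numpy(float)
        colmap = {c: i for i, c in enumerate(self.columns_)}
        out = self._descend_with_map(self.tree_, Xv, colmap)
        return pd.Series(out, index=X.index, name="leaf")

    @staticmethod
    def _descend_with_map(root: TreeNode, Xv: np.ndarray, colmap) -> np.ndarray:
        pos = {id(l): i for i, l in enumerate(root.leaves())}
        out = np.empty(len(Xv), dtype=int)

        def go(node, rows):
            if node.is_leaf:
                out[rows] = pos[id(node)]
                return
            mask = Xv[rows, colmap[node.split_var]] <= node.split_threshold
            go(node.left, rows[mask])
            go(node.right, rows[~mask])

        go(root, np.arange(len(Xv)))
        return out

    predict = apply

    # -- reporting -------------------------------------------------------

    def leaf_paths(self) -> dict:
        paths = {}

        def walk(node, trail):
            if node.is_leaf:
                paths[node.leaf_label] = " & ".join(trail) or "(root)"
                return
            walk(node.left, trail + [f"{node.split_var} <= {node.split_threshold:.4g}"])
            walk(node.right, trail + [f"{node.split_var} > {node.split_threshold:.4g}"])

        walk(self.tree_, [])
        return paths

    def leaf_outcomes(self, t: float = 5.0) -> pd.DataFrame:
        """Per-leaf Kaplan-Meier DR-free fraction at horizon ``t`` years."""
        paths = self.leaf_paths()
        rows = []
        for li in sorted(self.leaf_members_):
            member = self.leaf_members_[li]
            km = km_estimate(self.y_.loc[member])
            rows.append({"leaf": li, "path": paths[li], "n": len(member),
                         "events": km.n_events,
                         "drfree": km.survival_at(t),
                         "extrapolated": km.extrapolated_at(t)})
        return pd.DataFrame(rows).set_index("leaf")

    def stratify_leaf(self, leaf: int, by: pd.Series, t: float = 5.0):
        """Post-hoc stratification of one leaf by a covariate (bypasses the
        minimum terminal size, mirroring exploratory within-leaf KM/log-rank
        analysis).  Returns ``(per-stratum summary, log-rank P)``; P is NaN
        when more than two strata are present."""
        members = self.leaf_members_[leaf]
        strata = pd.Series(by).reindex(members).dropna()
        levels = list(pd.unique(strata))
        if len(levels) < 2:
            raise ValueError("stratify_leaf: single stratum")
        rows = []
        for lev in levels:
            ids = strata.index[strata == lev]
            km = km_estimate(self.y_.loc[ids])
            rows.append({"stratum": lev, "n": len(ids), "events": km.n_events,
                         "drfree": km.survival_at(t),
                         "extrapolated": km.extrapolated_at(t)})
        summary = pd.DataFrame(rows).set_index("stratum")
        if len(levels) == 2:
            _, p = logrank_test(self.y_.loc[strata.index], strata)
        else:
            p = float("nan")
        return summary, p

    def to_json(self) -> str:
        return json.dumps({"cp": self.cp_, "min_terminal": self.min_terminal,
                           "tree": self.tree_.to_dict()})


def grow_tree(covariates: pd.DataFrame, outcome: pd.DataFrame,
              min_terminal: int = 20, cv_folds: int = 10, cv_seed: int = 0,
              cp: float = 0.01, prune: bool = True) -> SurvivalTreeModel:
    """Functional wrapper over :class:`SurvivalTreeModel`."""
    model = SurvivalTreeModel(min_terminal=min_terminal, cv_folds=cv_folds,
                              cv_seed=cv_seed, cp=cp, prune=prune)
    return model.fit(covariates, outcome)


def encode_clinical(outcome: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate codes for tree input from a clinical table.

    ``nodal``: LN-/LN+ → 0/1; ``grade``: I/II/III → 1/2/3 (ordered).
    Unknown levels become missing (complete-case dropped by the tree).
    """
    out = {}
    if "nodal" in outcome:
        out["nodal"] = outcome["nodal"].map({"LN-": 0.0, "LN+": 1.0, 0: 0.0, 1: 1.0})
    if "grade" in outcome:
        out["grade"] = outcome["grade"].map(
            {"I": 1.0, "II": 2.0, "III": 3.0, 1: 1.0, 2: 2.0, 3: 3.0})
    return pd.DataFrame(out, index=outcome.index)
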