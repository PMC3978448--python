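"""Survival-tree growing, pruning, constraints, and an R rpart cross-check."""

import json
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cytorisk import SurvivalTreeModel, grow_tree, km_estimate
from cytorisk.tree import encode_clinical, nelson_aalen_exposure


def sim_tree_data(rng, n=300, hr_binary=3.0, extra_noise=0):
    arm = (rng.random(n) < 0.5).astype(float)
    rate = 0.15 * np.where(arm == 1, hr_binary, 1.0)
    t_ev = rng.exponential(1.0 / rate)
    cens = rng.uniform(1.0, 15.0, n)
    idx = [f"s{i}" for i in range(n)]
    X = pd.DataFrame({"arm": arm}, index=idx)
    for j in range(extra_noise):
        X[f"noise{j}"] = rng.standard_normal(n)
    y = pd.DataFrame({"time": np.minimum(t_ev, cens),
                      "event": (t_ev <= cens).astype(int)}, index=idx)
    return X, y


class TestGrowing:
    def test_planted_binary_signal_single_split(self, rng):
        X, y = sim_tree_data(rng, n=300, hr_binary=3.0)
        model = grow_tree(X[["arm"]], y, min_terminal=20, cv_seed=0)
        assert not model.tree_.is_leaf
        assert model.tree_.split_var == "arm"
        assert model.tree_.left.is_leaf and model.tree_.right.is_leaf

    def test_min_terminal_over_half_forces_root(self, rng):
        X, y = sim_tree_data(rng, n=60)
        model = grow_tree(X, y, min_terminal=31)
        assert model.tree_.is_leaf

    def test_all_leaves_respect_min_terminal(self, rng):
        for _ in range(5):
            X, y = sim_tree_data(rng, n=250, hr_binary=2.5, extra_noise=2)
            model = grow_tree(X, y, min_terminal=20, cv_seed=1)
            for leaf in model.leaves_:
                assert leaf.n >= 20

    def test_deviance_non_increasing_down_unpruned_tree(self, rng):
        X, y = sim_tree_data(rng, n=400, hr_binary=2.0, extra_noise=2)
        model = SurvivalTreeModel(min_terminal=20, prune=False).fit(X, y)

        def walk(node):
            if node.is_leaf:
                return
            assert node.left.deviance + node.right.deviance <= node.deviance + 1e-9
            walk(node.left)
            walk(node.right)

        walk(model.tree_)

    def test_cv_seed_reproducible(self, rng):
        X, y = sim_tree_data(rng, n=250, hr_binary=2.0, extra_noise=1)
        m1 = grow_tree(X, y, cv_seed=42)
        m2 = grow_tree(X, y, cv_seed=42)
        assert m1.cp_ == m2.cp_
        assert m1.to_json() == m2.to_json()

    def test_missing_covariates_complete_case(self, rng):
        X, y = sim_tree_data(rng, n=120)
        X.iloc[:7, 0] = np.nan
        model = grow_tree(X, y)
        assert model.n_dropped_ == 7

    def test_exposure_transform_is_cumhaz_at_each_time(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        # H(1)=1/4, H(2)=1/4+1/3, H(3)=same, H(4)=+1
        out = nelson_aalen_exposure(t, e)
        assert np.allclose(out, [0.25, 0.25 + 1 / 3, 0.25 + 1 / 3,
                                 0.25 + 1 / 3 + 1.0])


class TestLeafReporting:
    def test_leaf_outcomes_match_km_estimate(self, rng):
        X, y = sim_tree_data(rng, n=300, hr_binary=3.0)
        model = grow_tree(X[["arm"]], y, min_terminal=20)
        table = model.leaf_outcomes(5.0)
        for li, members in model.leaf_members_.items():
            km = km_estimate(y.loc[members])
            assert table.loc[li, "drfree"] == pytest.approx(km.survival_at(5.0))

    def test_zero_event_leaf_is_one(self):
        idx = [f"s{i}" for i in range(50)]
        y = pd.DataFrame({"time": np.linspace(1, 5, 50), "event": 0}, index=idx)
        X = pd.DataFrame({"x": np.zeros(50)}, index=idx)
        model = grow_tree(X, y)
        assert model.leaf_outcomes(4.0)["drfree"].iloc[0] == 1.0

    def test_hand_built_leaf_product_limit(self):
        # 25 subjects: events at 1, 2, 4; censoring at 3 (two subjects);
        # S(5) = (24/25)(23/24) * (1-1/21) = (23/25)*(20/21)
        times = [1, 2, 3, 3, 4] + [6] * 20
        events = [1, 1, 0, 0, 1] + [0] * 20
        idx = [f"s{i}" for i in range(25)]
        y = pd.DataFrame({"time": times, "event": events}, index=idx)
        X = pd.DataFrame({"x": np.zeros(25)}, index=idx)
        model = grow_tree(X, y)
        expected = (24 / 25) * (23 / 24) * (20 / 21)
        assert model.leaf_outcomes(5.0)["drfree"].iloc[0] == pytest.approx(expected)

    def test_stratify_leaf_constant_covariate_rejected(self, rng):
        X, y = sim_tree_data(rng, n=100)
        model = grow_tree(X[["arm"]], y, min_terminal=60)  # root only
        const = pd.Series("III", index=y.index)
        with pytest.raises(ValueError, match="single stratum"):
            model.stratify_leaf(0, const)

    def test_stratify_leaf_detects_residual_hazard(self):
        # within-leaf stratum with HR 2.5, n = 80 per stratum: log-rank
        # P < 0.05 in >= 80% of replicates
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            n = 160
            grade = np.repeat(["I/II", "III"], n // 2)
            rate = 0.15 * np.where(grade == "III", 2.5, 1.0)
            t_ev = rng.exponential(1.0 / rate)
            cens = rng.uniform(1, 12, n)
            idx = [f"s{i}" for i in range(n)]
            y = pd.DataFrame({"time": np.minimum(t_ev, cens),
                              "event": (t_ev <= cens).astype(int)}, index=idx)
            X = pd.DataFrame({"x": np.zeros(n)}, index=idx)
            model = grow_tree(X, y)
            _, p = model.stratify_leaf(0, pd.Series(grade, index=idx))
            hits += p < 0.05
        assert hits / n_rep >= 0.8


class TestEncoding:
    def test_clinical_codes(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 1],
                           "nodal": ["LN-", "LN+", "unknown"],
                           "grade": ["I", "III", "II"]},
                          index=["a", "b", "c"])
        out = encode_clinical(df)
        assert list(out["nodal"][:2]) == [0.0, 1.0]
        assert np.isnan(out.loc["c", "nodal"])
        assert list(out["grade"]) == [1.0, 3.0, 2.0]


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
class TestRpartOracle:
    def test_first_split_matches_rpart(self, rng):
        """On a planted two-covariate dataset, rpart (method='exp',
        minbucket=20, cp=0.01) and our tree choose the same first split
        variable with a nearby threshold."""
        n = 200
        score = rng.standard_normal(n)
        rate = 0.12 * np.exp(0.9 * score)
        t_ev = rng.exponential(1.0 / rate)
        cens = rng.uniform(1, 12, n)
        idx = [f"s{i}" for i in range(n)]
        X = pd.DataFrame({"score": score, "noise": rng.standard_normal(n)},
                         index=idx)
        y = pd.DataFrame({"time": np.minimum(t_ev, cens),
                          "event": (t_ev <= cens).astype(int)}, index=idx)

        model = SurvivalTreeModel(min_terminal=20, prune=False).fit(X, y)
        assert model.tree_.split_var == "score"

        with tempfile.TemporaryDirectory() as td:
            data = X.join(y)
            path = Path(td) / "d.csv"
            data.to_csv(path, index=False)
            script = f"""
            suppressMessages(library(survival)); suppressMessages(library(rpart))
            d <- read.csv("{path}")
            fit <- rpart(Surv(time, event) ~ score + noise, data = d,
                         method = "exp",
                         control = rpart.control(minbucket = 20, cp = 0.01,
                                                 xval = 0))
            s <- fit$splits
            cat(rownames(s)[1], s[1, "index"], sep = "\\n")
            """
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, check=True).stdout.split()
            r_var, r_thr = out[0], float(out[1])
        assert r_var == "score"
        assert model.tree_.split_threshold == pytest.approx(r_thr, abs=0.05)
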