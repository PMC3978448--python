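"""End-to-end orchestration: simulate/load → QC → score → optimize → model.

:func:`run_pipeline` chains the analysis stages the package implements —
cohort acquisition, missingness and source-bias QC, signature scoring
(IR-7, Buck-4, ICS), continuous-variable Cox evaluation with Harrell's C,
median dichotomization with log-rank comparison, forward-stepwise
signature optimization, survival-tree risk modeling on nodal status,
grade and the optimized score, and optimal-cut-point analysis of the
node-positive subset — and emits a machine-readable report.

Randomness policy: every stochastic stage consumes a child seed derived
deterministically from the global seed via named ``SeedSequence``
substreams, so reruns are byte-identical and stages are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import ExpressionMatrix
from .normalize import missingness_report, source_bias_check
from .signatures import BUCK4, ICS, IR7, score_signature
from .simulate import CohortConfig, default_ffpe_config, generate_cohort, with_seed
from .stepwise import forward_select
from .survival import apply_threshold, cox_fit, median_dichotomize, optimal_cutpoint
from .tree import SurvivalTreeModel, encode_clinical

logger = logging.getLogger(__name__)

STAGE_SEEDS = {"simulate": 0, "qc": 1, "tree": 2}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (named substream scheme)."""
    ss = np.random.SeedSequence(entropy=global_seed,
                                spawn_key=(STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """One input source — files XOR simulation — plus analysis toggles."""

    expression_path: str = None
    clinical_path: str = None
    simulate: bool = False
    cohort_config: CohortConfig = None
    signatures: tuple = ("IR-7", "Buck-4", "ICS")
    run_stepwise: bool = True
    run_tree: bool = True
    tree_min_terminal: int = 20
    fixed_threshold: float = None
    out_dir: str = None
    seed: int = 0

    def __post_init__(self):
        files = self.expression_path is not None or self.clinical_path is not None
        if self.simulate and files:
            raise ValueError("config must name exactly one input source: files xor simulation")
        if not self.simulate:
            if self.expression_path is None or self.clinical_path is None:
                raise ValueError("config must name exactly one input source: files xor simulation")
            for p in (self.expression_path, self.clinical_path):
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")


def _cox_section(scores, outcome) -> dict:
    fit = cox_fit(scores.rename("index"), outcome)
    return {
        "hr_per_unit": float(fit.hazard_ratios.iloc[0]),
        "hr_ci": [float(fit.ci_lower.iloc[0]), float(fit.ci_upper.iloc[0])],
        "wald_p": float(fit.wald_p.iloc[0]),
        "lr_p": fit.lr_p,
        "harrells_c": fit.concordance,
        "harrells_c_ci": list(fit.concordance_ci),
        "n": fit.n,
        "n_events": fit.n_events,
        "n_dropped_missing_score": fit.n_dropped,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; return the report dict.

    Artifacts (report JSON, score tables, tree JSON) are written under
    ``cfg.out_dir`` when set.
    """
    report: dict = {"config": {"seed": cfg.seed, "signatures": list(cfg.signatures)},
                    "stages": []}

    def stage(name):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        # -- acquire ----------------------------------------------------
        stage("acquire")
        if cfg.simulate:
            base = cfg.cohort_config or default_ffpe_config()
            cohort = generate_cohort(with_seed(base, stage_seed(cfg.seed, "simulate")))
            matrix, outcome = cohort.expression, cohort.outcome
        else:
            matrix = io.read_expression(cfg.expression_path)
            outcome = io.read_clinical(cfg.clinical_path)
            align = io.check_alignment(matrix, outcome)
            if align["expression_only"] or align["clinical_only"]:
                report["alignment"] = align
            shared = [s for s in matrix.samples if s in outcome.index]
            matrix = matrix.subset_samples(shared)
            outcome = outcome.loc[shared]

        # -- QC ----------------------------------------------------------
        stage("qc")
        miss = missingness_report(matrix)
        report["qc"] = {
            "n_samples": len(matrix.samples),
            "n_events": int(outcome["event"].sum()),
            "genes_flagged_missing": miss.flagged,
        }
        try:
            _, fisher_p = source_bias_check(matrix, seed=stage_seed(cfg.seed, "qc"))
            report["qc"]["source_bias_fisher_p"] = fisher_p
        except ValueError as exc:
            report["qc"]["source_bias_fisher_p"] = None
            report["qc"]["source_bias_note"] = str(exc)

        # -- score + continuous Cox + median dichotomy -------------------
        stage("score")
        catalogue = {"IR-7": IR7, "Buck-4": BUCK4, "ICS": ICS}
        scores = {}
        report["signatures"] = {}
        for name in cfg.signatures:
            sc = score_signature(catalogue[name], matrix)
            scores[name] = sc
            sect = {"n_missing_score": sc.n_missing}
            sect["cox_continuous"] = _cox_section(sc.z, outcome)
            med = median_dichotomize(sc.z, outcome)
            sect["median_dichotomy"] = {
                "threshold": med.threshold, "logrank_p": med.logrank_p,
                "n_low": med.n_low, "n_high": med.n_high,
                "drfree_5y_low": med.drfree_5y_low,
                "drfree_5y_high": med.drfree_5y_high,
            }
            report["signatures"][name] = sect
        if "IR-7" in scores and "Buck-4" in scores:
            pair = pd.concat([scores["IR-7"].raw, scores["Buck-4"].raw], axis=1).dropna()
            report["index_correlation_ir7_buck4"] = float(pair.corr().iloc[0, 1])

        # -- stepwise optimization ---------------------------------------
        optimized = ICS
        if cfg.run_stepwise:
            stage("stepwise")
            path = forward_select(None, matrix, outcome)
            optimized = path.selected
            report["stepwise"] = {
                "selected_genes": optimized.genes,
                "selected_size": path.selected_size,
                "best_lr_p": path.best_p,
                "n_used": path.n_used,
                "path": path.path.to_dict(orient="records"),
            }

        # -- survival tree on clinical + optimized score -----------------
        if cfg.run_tree:
            stage("tree")
            opt_scores = score_signature(optimized, matrix)
            clin = encode_clinical(outcome)
            X = clin.join(opt_scores.z.rename("score"))
            model = SurvivalTreeModel(min_terminal=cfg.tree_min_terminal,
                                      cv_seed=stage_seed(cfg.seed, "tree"))
            model.fit(X, outcome)
            leaf_table = model.leaf_outcomes(5.0)
            report["tree"] = {
                "cp": model.cp_,
                "n_dropped": model.n_dropped_,
                "leaves": leaf_table.reset_index().to_dict(orient="records"),
                "rules": model.leaf_paths(),
            }
            score_splits = _score_thresholds(model)
            if score_splits:
                report["tree"]["score_thresholds"] = score_splits

            # node-positive subset: optimal cut-point of the optimized score
            if "nodal" in outcome:
                pos = outcome.index[outcome["nodal"] == "LN+"]
                if len(pos) >= 10 and outcome.loc[pos, "event"].sum() >= 2:
                    try:
                        cut = optimal_cutpoint(opt_scores.z.loc[pos], outcome.loc[pos])
                        report["node_positive_optimal_cut"] = {
                            "threshold": cut.threshold, "logrank_p": cut.logrank_p,
                            "n_low": cut.n_low, "n_high": cut.n_high,
                        }
                    except ValueError as exc:
                        report["node_positive_optimal_cut"] = {"note": str(exc)}

            if cfg.fixed_threshold is not None:
                fixed = apply_threshold(opt_scores.z, cfg.fixed_threshold, outcome)
                report["fixed_threshold"] = {
                    "threshold": fixed.threshold, "logrank_p": fixed.logrank_p,
                    "n_low": fixed.n_low, "n_high": fixed.n_high,
                    "drfree_5y_low": fixed.drfree_5y_low,
                    "drfree_5y_high": fixed.drfree_5y_high,
                }

        # -- write artifacts ---------------------------------------------
        if cfg.out_dir:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            io.write_json(report, out / "report.json")
            for name, sc in scores.items():
                sc.frame.to_csv(out / f"scores_{name.replace('-', '').lower()}.tsv",
                                sep="\t", na_rep="NA")
            if cfg.run_tree:
                (out / "tree.json").write_text(model.to_json())
        return report
    except Exception as exc:
        last = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {last!r}: {exc}") from exc


def _score_thresholds(model: SurvivalTreeModel) -> list:
    """Thresholds of any tree split on the continuous score."""
    found = []

    def walk(node):
        if node.is_leaf:
            return
        if node.split_var == "score":
            found.append(node.split_threshold)
        walk(node.left)
        walk(node.right)

    walk(model.tree_)
    return found
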